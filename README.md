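# orgatlas

Toolkit for building an "organellar atlas" from orthogroup membership tables
and a species tree: classification of green / plastid / mitochondrial
orthogroups, majority-rule functional annotation, minimal-ancestral-deviation
(MAD) tree rooting, binary single-rate (Mk/ER) ancestral presence/absence
reconstruction with per-ancestor gain calling, and PPR/mTERF-style
domain-fraction and N-terminal charge screens. A synthetic-data module
generates complete datasets with known ground truth so the whole pipeline is
testable offline.

## Command line

`atlas demo` simulates a dataset and runs the full pipeline on it:

```sh
atlas demo --seed 42 --out demo_out
```

This writes `demo_out/fixture/` (the simulated inputs: `orthogroups.tsv`,
per-species FASTA, lineage map, KO/BRITE maps, HMMER-style domain hit table,
experimental proteome lists, ground truth) and `demo_out/results/` (GOG/POG/
MOG tables, annotations, MAD-rooted tree, per-node posteriors, gain tables at
thresholds 0.65/0.75/0.85, screens, per-species summaries, `report.txt`, and
a `manifest.json` recording every threshold). Reruns with the same seed are
byte-identical.

Individual stages:

```sh
atlas classify --orthogroups F --lineages F --experimental F --out DIR
atlas annotate --orthogroups F --ko-map F --brite-map F --out annotations.tsv
atlas root     --tree F --method mad --out rooted.nwk
atlas asr      --presence F --tree F --ancestors F --tau 0.75 --out DIR
atlas screens  --orthogroups F --tblout F --out DIR
atlas run      --config run.yaml     # full pipeline from a YAML config
```

## Key rules implemented

- **GOG**: orthogroup with >= 3 green (Chloroplastida) species and < 3
  non-green species; **core GOG**: GOG present in strictly more than 90% of
  green species.
- **POG / MOG**: orthogroup containing >= 1 experimentally verified plastid /
  mitochondrial protein from a reference species; the sets may overlap.
- **Annotation**: per-protein plurality vote over KO ids (ties break
  lexicographically), then BRITE category with an editable override table.
- **ASR**: equal-rates binary Mk model, stationary root prior (1/2, 1/2),
  per-orthogroup ML rate, exact marginal posteriors via pruning + up/down
  passes. A gain at ancestor A means P_A(present) > tau and confident absence
  in A's parent (P < 1 - tau; a lax reading P < tau is selectable).
- **Screens**: orthogroup flagged when > 60% (or >= 60% via flag) of members
  carry a PPR/mTERF-family Pfam hit; N-terminal charge is (#K + #R) - (#D +
  #E) over the first 20 residues.

## Layout

```
src/orgatlas/
  datamodel_io.py   shared domain types; Orthogroups.tsv / FASTA / tblout /
                    TSV matrix readers and writers
  simulate.py       synthetic trees, gain/loss character evolution, fixtures
  classify.py       GOG / core-GOG / POG / MOG rules, per-species summaries
  annotate.py       majority-rule KO annotation, category composition
  phylotree.py      newick I/O, MAD + outgroup rooting, ancestor resolution
  asr.py            ER-model likelihoods, rate fitting, posteriors, gains
  screens.py        domain-fraction screen, N-terminal charge
  cli.py            orchestration + the `atlas` command line interface
```
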