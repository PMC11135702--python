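"""Synthetic atlas datasets with known ground truth.

Generates a clocklike species tree over labeled lineages, evolves per-OG
presence/absence under a two-state gain/loss Markov process recording every
node state, then materializes the full on-disk fixture (FASTA, orthogroup
table, lineage map, KO maps, domain hit table, experimental proteome lists)
in exactly the formats :mod:`orgatlas.datamodel_io` reads.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .datamodel_io import write_fasta, write_matrix_tsv, write_orthogroups_tsv
from .datamodel_io import OrthogroupTable, ProteinRecord
from .phylotree import label_internal_nodes, node_label, write_newick
from .screens import DEFAULT_SCREEN_ACCESSIONS

logger = logging.getLogger(__name__)

#: Lineages in backbone order (first is basal) with default tip counts.
DEFAULT_LINEAGES = {
    "outgroup_eukaryote": 3,
    "glaucophyte": 2,
    "rhodophyte": 3,
    "chlorophyte": 4,
    "zygnematophyceae": 3,
    "embryophyte": 5,
}

CATEGORIES = (
    "Photosynthesis",
    "Metabolism",
    "Information processing",
    "Membrane trafficking",
    "Mitochondrial biogenesis",
    "Protein synthesis",
)

NEUTRAL_AA = "AGSTVLIPFMNQWYC"
ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    lineage_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LINEAGES)
    )
    tree_height: float = 1.0
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    n_ogs: int = 200
    root_presence_p: float = 0.4
    copy_geom_p: float = 0.6
    koid_missing_fraction: float = 0.2
    n_pogs: int = 25
    n_mogs: int = 15
    n_rna_ogs: int = 8
    domain_positive_fraction: float = 0.9
    plastid_ref: str | None = None
    mito_ref: str | None = None
    seq_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        for name in ("root_presence_p", "koid_missing_fraction",
                     "domain_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if sum(self.lineage_sizes.values()) < 2:
            raise ValueError("need at least 2 species in total")


@dataclass
class GroundTruth:
    """True node states and per-branch events for every simulated OG."""

    states: pd.DataFrame  # rows: node labels (tips + internal), cols: og ids
    gain_events: frozenset[tuple[str, str]]  # (og_id, child node label)
    loss_events: frozenset[tuple[str, str]]


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _yule_crown(n: int, rng: np.random.Generator) -> tuple[dendropy.Node, float]:
    """Pure-birth crown subtree with n tips; returns (root node, height).

    The crown root splits at time 0, so the returned height is exactly the
    root-to-tip distance of every tip (the subtree is ultrametric).
    """
    root = dendropy.Node()
    if n == 1:
        return root, 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    height = t + rng.exponential(1.0 / n)
    for node, birth in active:
        node.edge.length = height - birth
    return root, height


def _scale_subtree(root: dendropy.Node, factor: float) -> None:
    for nd in root.preorder_iter():
        if nd is not root and nd.edge.length is not None:
            nd.edge.length *= factor


def simulate_tree(config: SimConfig) -> dendropy.Tree:
    """Rooted, binary, ultrametric species tree with lineage-tagged tips.

    The backbone is a caterpillar over the configured lineages (first lineage
    basal); within each lineage a pure-birth crown is simulated and rescaled so
    every root-to-tip path equals ``tree_height`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    lineages = [(name, n) for name, n in config.lineage_sizes.items() if n > 0]
    if len(lineages) < 2 and sum(n for _, n in lineages) < 2:
        raise ValueError("need at least 2 tips")
    H = config.tree_height
    k = len(lineages)
    step = H / (2.0 * k)

    def attach(parent: dendropy.Node, name: str, n: int, depth: float) -> None:
        crown_height = (H - depth) / 2.0
        sub, raw_h = _yule_crown(n, rng)
        if raw_h > 0:
            _scale_subtree(sub, crown_height / raw_h)
            sub.edge.length = H - depth - crown_height
        else:
            sub.edge.length = H - depth  # single tip
        parent.add_child(sub)
        for idx, leaf in enumerate(sub.leaf_iter()):
            leaf.taxon = dendropy.Taxon(label=f"{name}_{idx:02d}")

    if k == 1:
        name, n = lineages[0]
        sub, raw_h = _yule_crown(n, rng)
        if raw_h > 0:
            _scale_subtree(sub, H / raw_h)
        for idx, leaf in enumerate(sub.leaf_iter()):
            leaf.taxon = dendropy.Taxon(label=f"{name}_{idx:02d}")
        root = sub
    else:
        root = dendropy.Node()
        backbone = root
        depth = 0.0
        for i, (name, n) in enumerate(lineages[:-1]):
            attach(backbone, name, n, depth)
            if i < k - 2:
                nxt = dendropy.Node()
                nxt.edge.length = step
                backbone.add_child(nxt)
                backbone = nxt
                depth += step
        attach(backbone, *lineages[-1], depth)

    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        tree.taxon_namespace.add_taxon(leaf.taxon)
    label_internal_nodes(tree)
    return tree


# ---------------------------------------------------------------------------
# Character simulation
# ---------------------------------------------------------------------------

def simulate_og_states(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    root_p: float,
    n_ogs: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Evolve ``n_ogs`` binary characters down a rooted tree.

    Along a branch of length t the exact transition probabilities are
    P(0->1) = a/(a+b) (1 - exp(-(a+b) t)) and P(1->0) = b/(a+b) (...), i.e. no
    time discretization; every node state is recorded.
    """
    a, b = gain_rate, loss_rate
    if a == 0 and b == 0:
        logger.warning("gain and loss rates both zero: states copied from root")
    og_ids = [f"OG{i:07d}" for i in range(n_ogs)]
    label_internal_nodes(tree)
    nodes = list(tree.preorder_node_iter())
    states: dict[str, np.ndarray] = {}
    gains: list[tuple[str, str]] = []
    losses: list[tuple[str, str]] = []
    root_state = (rng.random(n_ogs) < root_p).astype(np.int8)
    states[node_label(tree.seed_node)] = root_state
    node_state = {id(tree.seed_node): root_state}
    for nd in nodes:
        if nd.parent_node is None:
            continue
        t = nd.edge.length or 0.0
        parent = node_state[id(nd.parent_node)]
        if a + b > 0:
            decay = 1.0 - math.exp(-(a + b) * t)
            p01 = (a / (a + b)) * decay
            p10 = (b / (a + b)) * decay
        else:
            p01 = p10 = 0.0
        u = rng.random(n_ogs)
        child = np.where(parent == 1, (u >= p10), (u < p01)).astype(np.int8)
        lab = node_label(nd)
        node_state[id(nd)] = child
        states[lab] = child
        flips_up = np.nonzero((parent == 0) & (child == 1))[0]
        flips_dn = np.nonzero((parent == 1) & (child == 0))[0]
        gains.extend((og_ids[j], lab) for j in flips_up)
        losses.extend((og_ids[j], lab) for j in flips_dn)
    state_df = pd.DataFrame(states, index=og_ids).T  # rows: node labels
    tip_labels = [node_label(lf) for lf in tree.leaf_node_iter()]
    presence = state_df.loc[tip_labels].T.astype(int)  # ogs x species
    truth = GroundTruth(state_df, frozenset(gains), frozenset(losses))
    return presence, truth


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def _random_sequence(
    rng: np.random.Generator, length: int, nterm_class: int
) -> str:
    head = ["M"] + [NEUTRAL_AA[j] for j in rng.integers(len(NEUTRAL_AA), size=19)]
    if nterm_class == 2:
        head[1], head[2] = "K", "R"
    tail = [ALL_AA[j] for j in rng.integers(len(ALL_AA), size=max(length - 20, 0))]
    return "".join(head + tail)[:length]


def simulate_dataset(config: SimConfig, out_dir) -> dict:
    """Write a complete synthetic fixture; returns the manifest dict.

    Files: tree_rooted.nwk / tree_unrooted.nwk, orthogroups.tsv,
    fasta/<species>.fa, lineages.tsv, ko_map.tsv, brite_map.tsv,
    domain_hits.tblout, experimental.tsv, ground_truth/*, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fasta").mkdir(exist_ok=True)
    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)

    tree = simulate_tree(config)
    rng = np.random.default_rng(config.seed + 1)
    presence, truth = simulate_og_states(
        tree, config.gain_rate, config.loss_rate,
        config.root_presence_p, config.n_ogs, rng,
    )
    og_ids = list(presence.index)
    species = list(presence.columns)
    species_lineage = {s: s.rsplit("_", 1)[0] for s in species}

    # reference species for the experimental proteomes
    def default_ref(lineage: str) -> str:
        cands = [s for s in species if species_lineage[s] == lineage]
        if not cands:
            raise ValueError(f"no simulated species in lineage {lineage!r}")
        return sorted(cands)[0]

    plastid_ref = config.plastid_ref or default_ref("embryophyte")
    mito_ref = config.mito_ref or default_ref("embryophyte")
    for ref in (plastid_ref, mito_ref):
        if ref not in species:
            raise ValueError(f"reference species {ref!r} was not simulated")

    # copy numbers (geometric, support >= 1, only where present)
    copy = pd.DataFrame(0, index=og_ids, columns=species, dtype=int)
    for og in og_ids:
        for sp in species:
            if presence.at[og, sp]:
                copy.at[og, sp] = int(rng.geometric(config.copy_geom_p))

    # proteins
    groups: dict[str, set[tuple[str, str]]] = {}
    proteins: list[ProteinRecord] = []
    og_index = {og: i for i, og in enumerate(og_ids)}
    nterm_class = {og: 2 if (i % 2 == 0) else 0 for og, i in og_index.items()}
    true_ko = {og: f"K{10000 + i:05d}" for og, i in og_index.items()}
    true_cat = {
        og: CATEGORIES[i % len(CATEGORIES)] for og, i in og_index.items()
    }
    # every 7th OG's KO is deliberately absent from the BRITE map
    unmapped = {og for og, i in og_index.items() if i % 7 == 3}
    ko_rows: list[tuple[str, str]] = []
    for og in og_ids:
        members: set[tuple[str, str]] = set()
        for sp in species:
            for j in range(copy.at[og, sp]):
                pid = f"{sp}|{og}|p{j}"
                members.add((pid, sp))
                seq = _random_sequence(rng, config.seq_length, nterm_class[og])
                has_ko = rng.random() >= config.koid_missing_fraction
                proteins.append(
                    ProteinRecord(pid, sp, seq, true_ko[og] if has_ko else None)
                )
                if has_ko:
                    ko_rows.append((pid, true_ko[og]))
        groups[og] = members
    ogs = OrthogroupTable(groups)

    # organelle truth: OGs present in the reference species
    pog_pool = sorted(og for og in og_ids if presence.at[og, plastid_ref])
    mog_pool = sorted(og for og in og_ids if presence.at[og, mito_ref])
    if config.n_pogs > len(pog_pool) or config.n_mogs > len(mog_pool):
        raise ValueError(
            "not enough orthogroups present in the reference species; "
            "lower n_pogs/n_mogs or raise root_presence_p"
        )
    true_pogs = sorted(
        rng.choice(pog_pool, size=config.n_pogs, replace=False).tolist()
    )
    true_mogs = sorted(
        rng.choice(mog_pool, size=config.n_mogs, replace=False).tolist()
    )
    exp_rows: list[tuple[str, str, str]] = []
    for organelle, ref, chosen in (
        ("plastid", plastid_ref, true_pogs),
        ("mitochondrion", mito_ref, true_mogs),
    ):
        for og in chosen:
            pids = sorted(p for p, sp in ogs.members(og) if sp == ref)
            take = max(1, min(len(pids), int(rng.integers(1, 3))))
            for pid in pids[:take]:
                exp_rows.append((organelle, ref, pid))

    # domain hits on designated RNA-metabolism OGs (subset of true POGs/MOGs)
    rna_pool = sorted(set(true_pogs) | set(true_mogs))
    n_rna = min(config.n_rna_ogs, len(rna_pool))
    rna_ogs = sorted(rng.choice(rna_pool, size=n_rna, replace=False).tolist())
    hit_rows: list[tuple[str, str]] = []
    for og in rna_ogs:
        for pid in sorted(ogs.protein_ids(og)):
            if rng.random() < config.domain_positive_fraction:
                acc = DEFAULT_SCREEN_ACCESSIONS[
                    int(rng.integers(len(DEFAULT_SCREEN_ACCESSIONS)))
                ]
                hit_rows.append((pid, acc))

    # ---- write the fixture -------------------------------------------------
    write_newick(tree, out / "tree_rooted.nwk")
    unrooted = tree.clone(depth=1)
    unrooted.deroot()
    write_newick(unrooted, out / "tree_unrooted.nwk")
    write_orthogroups_tsv(ogs, out / "orthogroups.tsv", species_order=species)
    by_species: dict[str, list[ProteinRecord]] = {s: [] for s in species}
    for rec in proteins:
        by_species[rec.species_id].append(rec)
    for sp in species:
        write_fasta(by_species[sp], out / "fasta" / f"{sp}.fa")
    with open(out / "lineages.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("species_id\tlineage\n")
        for sp in sorted(species):
            fh.write(f"{sp}\t{species_lineage[sp]}\n")
    with open(out / "ko_map.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\tkoid\n")
        for pid, ko in sorted(ko_rows):
            fh.write(f"{pid}\t{ko}\n")
    with open(out / "brite_map.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("koid\tcategory\n")
        for og in og_ids:
            if og not in unmapped:
                fh.write(f"{true_ko[og]}\t{true_cat[og]}\n")
    with open(out / "domain_hits.tblout", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# target name        accession  query name accession  "
                 "E-value score bias\n")
        for pid, acc in sorted(hit_rows):
            fh.write(f"{pid} - screen_profile {acc}.11 1e-30 99.9 0.1\n")
    with open(out / "experimental.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("organelle\treference_species\tprotein_id\n")
        for org, ref, pid in sorted(exp_rows):
            fh.write(f"{org}\t{ref}\t{pid}\n")

    write_matrix_tsv(presence, out / "ground_truth" / "presence.tsv", "og_id")
    write_matrix_tsv(copy, out / "ground_truth" / "copy_numbers.tsv", "og_id")
    write_matrix_tsv(
        truth.states.astype(int), out / "ground_truth" / "states.tsv", "node"
    )
    with open(gt_dir / "gains.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("og_id\tnode\n")
        for og, nd in sorted(truth.gain_events):
            fh.write(f"{og}\t{nd}\n")
    with open(gt_dir / "losses.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("og_id\tnode\n")
        for og, nd in sorted(truth.loss_events):
            fh.write(f"{og}\t{nd}\n")
    truth_json = {
        "true_pogs": true_pogs,
        "true_mogs": true_mogs,
        "rna_ogs": rna_ogs,
        "true_ko": true_ko,
        "true_category": true_cat,
        "unmapped_kos": sorted(true_ko[og] for og in unmapped),
        "nterm_class": nterm_class,
        "planted_domain_hits": sorted(hit_rows),
        "plastid_ref": plastid_ref,
        "mito_ref": mito_ref,
    }
    with open(gt_dir / "truth.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "tool": "orgatlas",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "files": {
            "tree_rooted": "tree_rooted.nwk",
            "tree_unrooted": "tree_unrooted.nwk",
            "orthogroups": "orthogroups.tsv",
            "lineages": "lineages.tsv",
            "ko_map": "ko_map.tsv",
            "brite_map": "brite_map.tsv",
            "domain_hits": "domain_hits.tblout",
            "experimental": "experimental.tsv",
            "ground_truth": "ground_truth",
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
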