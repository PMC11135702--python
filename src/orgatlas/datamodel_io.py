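"""Shared domain types and readers/writers for the pipeline's file formats.

All tabular output is UTF-8, tab-separated, LF-terminated, with deterministic
(lexicographic) row order so that repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field, fields

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# 20 canonical amino acids plus X (unknown) and * (stop, stripped on read).
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X" + "*")

#: Lineage labels counted as Chloroplastida ("green") by default.
DEFAULT_GREEN_LABELS = frozenset(
    {
        "chlorophyte",
        "prasinodermophyte",
        "streptophyte_alga",
        "zygnematophyceae",
        "embryophyte",
    }
)

_PFAM_RE = re.compile(r"^PF\d{5}(\.\d+)?$")


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its species of origin and optional KO label."""

    protein_id: str
    species_id: str
    sequence: str
    koid: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be nonempty")
        if not self.species_id:
            raise ValueError("species_id must be nonempty")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: illegal residue(s) {sorted(bad)}"
            )


class OrthogroupTable:
    """Mapping of orthogroup id -> set of (protein_id, species_id) members."""

    def __init__(self, groups: Mapping[str, Iterable[tuple[str, str]]]):
        self._groups: dict[str, frozenset[tuple[str, str]]] = {}
        for og_id in sorted(groups):
            members = frozenset(groups[og_id])
            if not og_id:
                raise ValueError("empty orthogroup id")
            self._groups[og_id] = members

    @property
    def og_ids(self) -> list[str]:
        return list(self._groups)

    def members(self, og_id: str) -> frozenset[tuple[str, str]]:
        return self._groups[og_id]

    def species_of(self, og_id: str) -> frozenset[str]:
        return frozenset(sp for _, sp in self._groups[og_id])

    def protein_ids(self, og_id: str) -> frozenset[str]:
        return frozenset(pid for pid, _ in self._groups[og_id])

    def all_species(self) -> frozenset[str]:
        return frozenset(sp for m in self._groups.values() for _, sp in m)

    def protein_index(self) -> dict[str, tuple[str, str]]:
        """protein_id -> (og_id, species_id); errors on a protein in two OGs."""
        index: dict[str, tuple[str, str]] = {}
        for og_id, members in self._groups.items():
            for pid, sp in sorted(members):
                if pid in index and index[pid][0] != og_id:
                    raise ValueError(
                        f"protein {pid!r} appears in orthogroups "
                        f"{index[pid][0]!r} and {og_id!r}"
                    )
                index[pid] = (og_id, sp)
        return index

    def __len__(self) -> int:
        return len(self._groups)

    def __contains__(self, og_id: str) -> bool:
        return og_id in self._groups

    def __iter__(self):
        return iter(self._groups)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OrthogroupTable) and self._groups == other._groups


@dataclass(frozen=True)
class LineageMap:
    """species_id -> lineage label, with a green/non-green flag per label."""

    species_to_label: Mapping[str, str]
    green_labels: frozenset[str] = DEFAULT_GREEN_LABELS

    def label(self, species_id: str) -> str:
        try:
            return self.species_to_label[species_id]
        except KeyError:
            raise KeyError(f"species {species_id!r} has no lineage label") from None

    def is_green(self, species_id: str) -> bool:
        return self.label(species_id) in self.green_labels

    def green_species(self, species: Iterable[str]) -> list[str]:
        return [s for s in species if self.is_green(s)]

    def nongreen_species(self, species: Iterable[str]) -> list[str]:
        return [s for s in species if not self.is_green(s)]


@dataclass(frozen=True)
class ExperimentalProteomeSet:
    """Experimentally verified organelle proteins of one reference species."""

    organelle: str  # "plastid" | "mitochondrion"
    reference_species: str
    protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.organelle not in ("plastid", "mitochondrion"):
            raise ValueError(f"unknown organelle {self.organelle!r}")


@dataclass(frozen=True)
class DomainHitTable:
    """Deduplicated (protein_id, domain_accession) pairs."""

    pairs: frozenset[tuple[str, str]]

    def proteins_with_any(self, accessions: Iterable[str]) -> frozenset[str]:
        wanted = {strip_accession_version(a) for a in accessions}
        return frozenset(p for p, a in self.pairs if a in wanted)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class Parameters:
    """All thresholds of the pipeline; serialized into every results manifest."""

    min_green_species: int = 3
    max_nongreen_species_exclusive: int = 3
    core_fraction: float = 0.90
    gain_threshold: float = 0.75
    gain_threshold_sweep: tuple[float, ...] = (0.65, 0.75, 0.85)
    domain_fraction_threshold: float = 0.60
    domain_fraction_strict: bool = True
    nterm_window: int = 20
    rate_bounds: tuple[float, float] = (1e-6, 100.0)
    copy_number_display_cap: int = 50
    gain_parent_reading: str = "confident_absence"  # or "lax"

    def __post_init__(self) -> None:
        if not 0 < self.gain_threshold < 1:
            raise ValueError("gain_threshold must be in (0,1)")
        if not 0 < self.domain_fraction_threshold < 1:
            raise ValueError("domain_fraction_threshold must be in (0,1)")
        if self.rate_bounds[0] <= 0 or self.rate_bounds[1] <= self.rate_bounds[0]:
            raise ValueError("rate_bounds must satisfy 0 < q_min < q_max")
        if self.gain_parent_reading not in ("confident_absence", "lax"):
            raise ValueError("gain_parent_reading: 'confident_absence' or 'lax'")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def strip_accession_version(accession: str) -> str:
    """PF01535.20 -> PF01535; accessions without a version pass through."""
    return accession.split(".", 1)[0]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_orthogroups_tsv(
    path, species_of: Callable[[str], str] | None = None
) -> OrthogroupTable:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    First column is the orthogroup id; remaining columns are per-species,
    comma-separated protein lists. Species identity is taken from the column
    header (authoritative); ``species_of`` is only consulted for single-column
    files without species headers.
    """
    groups: dict[str, set[tuple[str, str]]] = {}
    seen_protein: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        species_cols = cols[1:]
        if not species_cols and species_of is None:
            raise FormatError(f"{path}: no species columns and no resolver given")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            og_id = cells[0].strip()
            if not og_id:
                raise FormatError(f"{path}:{lineno}: missing orthogroup id")
            if og_id in groups:
                raise FormatError(f"{path}:{lineno}: duplicate orthogroup id {og_id!r}")
            members: set[tuple[str, str]] = set()
            cells = cells[1:] + [""] * (len(species_cols) - len(cells) + 1)
            for sp, cell in zip(species_cols, cells):
                for token in cell.split(","):
                    pid = token.strip()
                    if not pid:
                        continue
                    species = sp if sp else species_of(pid)  # type: ignore[misc]
                    if pid in seen_protein:
                        prev_og, prev_sp = seen_protein[pid]
                        raise FormatError(
                            f"{path}:{lineno}: protein {pid!r} listed under "
                            f"{prev_sp!r} (in {prev_og!r}) and {species!r}"
                        )
                    seen_protein[pid] = (og_id, species)
                    members.add((pid, species))
            groups[og_id] = members
    return OrthogroupTable(groups)


def read_fasta(
    path,
    species_id: str | None = None,
    species_of: Callable[[str], str] | None = None,
    ko_of: Callable[[str], str | None] | None = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA; id token before first whitespace is protein_id.

    Sequences are uppercased and a single trailing ``*`` is stripped. Species
    comes from ``species_id`` (whole file) or from ``species_of(protein_id)``.
    """
    if species_id is None and species_of is None:
        raise ValueError("provide species_id or species_of")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise FormatError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FormatError(f"{path}: empty sequence for {pid!r}")
        sp = species_id if species_id is not None else species_of(pid)  # type: ignore[misc]
        koid = ko_of(pid) if ko_of is not None else None
        records.append(ProteinRecord(pid, sp, seq, koid))
    return records


def read_domain_tblout(path, accepted_accessions: Iterable[str]) -> DomainHitTable:
    """Read domain hits from HMMER3 ``--tblout`` or a plain two-column TSV.

    For tblout lines, the target name is field 1 and the query (profile)
    accession is taken from field 4, falling back to field 5 when field 4 is
    not a Pfam-style accession (some dialects shift the column). Accession
    version suffixes are stripped before filtering against
    ``accepted_accessions``; duplicate hits collapse to a single pair.
    """
    accepted = {strip_accession_version(a) for a in accepted_accessions}
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            if len(f) == 2:
                target, acc = f
                if not _PFAM_RE.match(acc):
                    raise FormatError(
                        f"{path}:{lineno}: second column {acc!r} is not a "
                        f"Pfam-style accession"
                    )
            elif len(f) >= 5:
                target = f[0]
                if _PFAM_RE.match(f[3]):
                    acc = f[3]
                elif _PFAM_RE.match(f[4]):
                    acc = f[4]
                else:
                    raise FormatError(
                        f"{path}:{lineno}: no Pfam-style query accession "
                        f"in fields 4/5: {f[3]!r}, {f[4]!r}"
                    )
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 or >=5 whitespace-separated "
                    f"fields, got {len(f)}"
                )
            acc = strip_accession_version(acc)
            if acc in accepted:
                pairs.add((target, acc))
    return DomainHitTable(frozenset(pairs))


def read_lineage_map(path, green_labels: Iterable[str] | None = None) -> LineageMap:
    """Read a species->lineage TSV with columns species_id, lineage[,is_green]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError(f"{path}: need at least species and lineage columns")
    mapping = dict(zip(df[cols[0]], df[cols[1]]))
    if green_labels is not None:
        greens = frozenset(green_labels)
    elif len(cols) >= 3:
        flags = df[cols[2]].astype(str).str.lower().isin({"1", "true", "yes"})
        greens = frozenset(df[cols[1]][flags])
    else:
        greens = DEFAULT_GREEN_LABELS
    return LineageMap(mapping, greens)


def read_experimental_sets(path) -> list[ExperimentalProteomeSet]:
    """Read a TSV with columns organelle, reference_species, protein_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected organelle/species/protein columns")
    org_c, sp_c, pid_c = df.columns[:3]
    out = []
    for (org, sp), grp in sorted(df.groupby([org_c, sp_c], sort=True)):
        out.append(
            ExperimentalProteomeSet(org, sp, frozenset(grp[pid_c].astype(str)))
        )
    return out


def read_ko_map(path) -> dict[str, str]:
    """protein_id -> KO id; empty and literal N/A cells mean "no annotation"."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and not header.startswith(("protein", "#")):
            fh.seek(0)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            pid = parts[0].strip()
            ko = parts[1].strip() if len(parts) > 1 else ""
            if ko and ko.upper() != "N/A":
                out[pid] = ko
    return out


def read_category_map(path) -> dict[str, str]:
    """Two-column TSV mapping (KO id -> category, or raw -> final category)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first and not first.lower().startswith(("koid", "raw", "#")):
            fh.seek(0)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            k, _, v = line.partition("\t")
            if k and v:
                out[k.strip()] = v.strip()
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "id") -> None:
    """Write a labeled matrix; floats get 17 significant digits (round-trip safe)."""
    m = matrix.sort_index(axis=0)
    m.to_csv(
        path,
        sep="\t",
        index_label=index_label,
        float_format="%.17g",
        lineterminator="\n",
    )


def read_matrix_tsv(path, dtype=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if dtype is not None:
        df = df.astype(dtype)
    return df


def write_orthogroups_tsv(ogs: OrthogroupTable, path, species_order=None) -> None:
    """Write the OrthoFinder-dialect table datamodel_io.read_orthogroups_tsv reads."""
    species = sorted(ogs.all_species()) if species_order is None else list(species_order)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for og_id in ogs.og_ids:
            by_sp: dict[str, list[str]] = {s: [] for s in species}
            for pid, sp in sorted(ogs.members(og_id)):
                by_sp[sp].append(pid)
            cells = [", ".join(by_sp[s]) for s in species]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in sorted(records, key=lambda r: r.protein_id):
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
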