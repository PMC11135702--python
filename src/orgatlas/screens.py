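"""Domain-fraction screens (PPR/mTERF-style) and N-terminal charge."""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel_io import DomainHitTable, OrthogroupTable, strip_accession_version

#: Pfam accessions of the PPR and mTERF screen profiles.
DEFAULT_SCREEN_ACCESSIONS = ("PF01535", "PF12854", "PF13041", "PF13812", "PF02536")

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")


def domain_fraction(
    member_proteins: Iterable[str],
    hits: DomainHitTable,
    screen_accessions: Iterable[str] = DEFAULT_SCREEN_ACCESSIONS,
    threshold: float = 0.60,
    strict: bool = True,
) -> tuple[float, bool]:
    """Fraction of an OG's members with >=1 screen-domain hit, and the flag.

    A member counts on a single hit to any screen accession, regardless of hit
    count or score. The flag is fraction > threshold with the strict default
    comparator, or >= threshold when ``strict`` is False.
    """
    members = sorted(set(member_proteins))
    if not members:
        raise ValueError("empty orthogroup")
    positive = hits.proteins_with_any(screen_accessions)
    n_hit = sum(1 for p in members if p in positive)
    frac = n_hit / len(members)
    flagged = frac > threshold if strict else frac >= threshold
    return frac, flagged


def screen_orthogroups(
    ogs: OrthogroupTable,
    og_ids: Iterable[str],
    hits: DomainHitTable,
    screen_accessions: Iterable[str] = DEFAULT_SCREEN_ACCESSIONS,
    threshold: float = 0.60,
    strict: bool = True,
) -> pd.DataFrame:
    """Apply the domain-fraction rule to each OG of a set."""
    rows = []
    positive = hits.proteins_with_any(screen_accessions)
    for og_id in sorted(set(og_ids)):
        members = ogs.protein_ids(og_id)
        if not members:
            raise ValueError(f"orthogroup {og_id!r} has no members")
        n_hit = len(members & positive)
        frac = n_hit / len(members)
        flagged = frac > threshold if strict else frac >= threshold
        rows.append((og_id, len(members), n_hit, frac, flagged))
    return pd.DataFrame(
        rows, columns=["og_id", "n_members", "n_with_domain", "fraction", "flagged"]
    ).set_index("og_id")


def domain_presence_matrix(
    flagged_ogs: Iterable[str],
    ogs: OrthogroupTable,
    hits: DomainHitTable,
    species: Sequence[str],
    screen_accessions: Iterable[str] = DEFAULT_SCREEN_ACCESSIONS,
) -> pd.DataFrame:
    """species x OG boolean matrix of domain-bearing presence.

    A cell is True only when that species has a member of the OG that itself
    carries a screen-domain hit — an OG may be present in a species while all
    of its local members lack the domain.
    """
    flagged = sorted(set(flagged_ogs))
    positive = hits.proteins_with_any(screen_accessions)
    data = pd.DataFrame(False, index=list(species), columns=flagged)
    for og_id in flagged:
        for pid, sp in ogs.members(og_id):
            if pid in positive and sp in data.index:
                data.loc[sp, og_id] = True
    return data


def nterm_charge(sequence: str, window: int = 20) -> int:
    """Net charge of the first ``window`` residues: (#K + #R) - (#D + #E).

    Histidine is neutral; the initiator Met counts toward the window; shorter
    sequences are scored over their whole length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    head = sequence[:window]
    pos = sum(1 for aa in head if aa in POSITIVE)
    neg = sum(1 for aa in head if aa in NEGATIVE)
    return pos - neg


def dual_targeting_report(
    pogs: Iterable[str],
    mogs: Iterable[str],
    ogs: OrthogroupTable,
    charges: Mapping[str, int],
) -> pd.DataFrame:
    """OGs classified as both POG and MOG, with member N-terminal charge range."""
    both = sorted(set(pogs) & set(mogs))
    rows = []
    for og_id in both:
        vals = [charges[p] for p in sorted(ogs.protein_ids(og_id)) if p in charges]
        cmin = min(vals) if vals else 0
        cmax = max(vals) if vals else 0
        rows.append((og_id, len(ogs.protein_ids(og_id)), cmin, cmax))
    return pd.DataFrame(
        rows, columns=["og_id", "n_members", "charge_min", "charge_max"]
    ).set_index("og_id")
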