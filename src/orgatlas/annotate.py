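"""Majority-rule KO annotation of orthogroups and functional categories."""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from importlib import resources

import pandas as pd

from .datamodel_io import OrthogroupTable

UNANNOTATED = "unannotated"


def default_overrides() -> dict[str, str]:
    """The shipped raw-category -> final-category curation table."""
    text = (
        resources.files("orgatlas.data").joinpath("brite_overrides.tsv").read_text()
    )
    out = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        raw, _, final = line.partition("\t")
        if raw and final:
            out[raw] = final
    return out


def majority_koid(
    koids: Iterable[str | None],
) -> tuple[str | None, Counter]:
    """Plurality vote over member KO ids; missing labels never vote.

    Ties break to the lexicographically smallest KO id; an all-missing
    multiset yields None.
    """
    counts = Counter(k for k in koids if k is not None)
    if not counts:
        return None, counts
    best = max(counts.values())
    winner = min(k for k, c in counts.items() if c == best)
    return winner, counts


def categorize(
    koid: str | None,
    brite_map: Mapping[str, str],
    overrides: Mapping[str, str] | None = None,
) -> str:
    """Map a KO id to its final category, applying the manual override table."""
    if koid is None:
        return UNANNOTATED
    raw = brite_map.get(koid)
    if raw is None:
        return UNANNOTATED
    if overrides and raw in overrides:
        return overrides[raw]
    return raw


def annotate_orthogroups(
    ogs: OrthogroupTable,
    ko_map: Mapping[str, str],
    brite_map: Mapping[str, str],
    overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-OG table: assigned koid, vote count, total votes, category.

    Votes are per protein (not per species); proteins without a KO label are
    excluded from the vote.
    """
    rows = []
    for og_id in ogs.og_ids:
        labels = [ko_map.get(pid) for pid in sorted(ogs.protein_ids(og_id))]
        koid, counts = majority_koid(labels)
        cat = categorize(koid, brite_map, overrides)
        rows.append(
            (
                og_id,
                koid if koid is not None else "",
                counts[koid] if koid is not None else 0,
                sum(counts.values()),
                cat,
            )
        )
    return pd.DataFrame(
        rows, columns=["og_id", "koid", "votes", "total_votes", "category"]
    ).set_index("og_id")


def category_composition(
    og_ids: Iterable[str], annotations: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Category counts and proportions over the annotated OGs of a set.

    Proportions are taken over annotated OGs only and sum to 1; the second
    return value is the fraction of the set that is annotated at all.
    """
    ids = sorted(set(og_ids))
    if not ids:
        raise ValueError("empty orthogroup set")
    missing = set(ids) - set(annotations.index)
    if missing:
        raise ValueError(f"unannotated og ids: {sorted(missing)[:5]}")
    cats = annotations.loc[ids, "category"]
    annotated = cats[cats != UNANNOTATED]
    frac = len(annotated) / len(ids)
    if annotated.empty:
        comp = pd.DataFrame(columns=["count", "proportion"])
        comp.index.name = "category"
        return comp, frac
    counts = annotated.value_counts().sort_index()
    comp = pd.DataFrame(
        {"count": counts, "proportion": counts / counts.sum()}
    )
    comp.index.name = "category"
    return comp, frac
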