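"""Orthogroup sorting rules: GOGs, core GOGs, POGs/MOGs, per-species summaries.

All rules count distinct species, never protein copies: an orthogroup with 40
paralogs in one species still contributes a single species to every criterion.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel_io import (
    ExperimentalProteomeSet,
    LineageMap,
    OrthogroupTable,
    Parameters,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationResult:
    gog_ids: frozenset[str]
    core_gog_ids: frozenset[str]
    pog_ids: frozenset[str]
    mog_ids: frozenset[str]
    gog_counts: pd.DataFrame  # per-OG green / non-green species counts
    organelle_provenance: pd.DataFrame  # og_id, organelle, protein, species


def build_copy_number_matrix(
    ogs: OrthogroupTable, species: Sequence[str]
) -> pd.DataFrame:
    """OG x species matrix of member-protein counts."""
    species = list(species)
    if len(set(species)) != len(species):
        raise ValueError("species list contains duplicates")
    col = {s: j for j, s in enumerate(species)}
    og_ids = ogs.og_ids
    data = np.zeros((len(og_ids), len(species)), dtype=int)
    for i, og_id in enumerate(og_ids):
        for _, sp in ogs.members(og_id):
            if sp not in col:
                raise ValueError(
                    f"orthogroup {og_id!r} has member species {sp!r} "
                    f"not in the species list"
                )
            data[i, col[sp]] += 1
    return pd.DataFrame(data, index=og_ids, columns=species)


def build_presence_matrix(
    ogs: OrthogroupTable, species: Sequence[str]
) -> pd.DataFrame:
    """OG x species 0/1 matrix: 1 iff the OG has >=1 member in that species."""
    return (build_copy_number_matrix(ogs, species) > 0).astype(int)


def select_gogs(
    presence: pd.DataFrame, lineages: LineageMap, params: Parameters
) -> tuple[frozenset[str], pd.DataFrame]:
    """Green orthogroups: >= min_green green species and strictly fewer than
    max_nongreen_species_exclusive non-green species with presence."""
    green = [s for s in presence.columns if lineages.is_green(s)]
    nongreen = [s for s in presence.columns if not lineages.is_green(s)]
    g = (presence[green] > 0).sum(axis=1)
    n = (presence[nongreen] > 0).sum(axis=1)
    counts = pd.DataFrame({"n_green": g, "n_nongreen": n})
    mask = (g >= params.min_green_species) & (
        n < params.max_nongreen_species_exclusive
    )
    return frozenset(presence.index[mask]), counts


def select_core_gogs(
    gogs: Iterable[str],
    presence: pd.DataFrame,
    lineages: LineageMap,
    params: Parameters,
) -> frozenset[str]:
    """GOGs present in strictly more than ``core_fraction`` of green species."""
    green = [s for s in presence.columns if lineages.is_green(s)]
    if not green:
        raise ValueError("no green species in the presence matrix")
    gog_list = sorted(set(gogs))
    frac = (presence.loc[gog_list, green] > 0).sum(axis=1) / len(green)
    return frozenset(frac.index[frac > params.core_fraction])


def select_organelle_ogs(
    ogs: OrthogroupTable, experimental: Iterable[ExperimentalProteomeSet]
) -> tuple[frozenset[str], frozenset[str], pd.DataFrame]:
    """POGs/MOGs: OGs containing >=1 experimentally verified organelle protein.

    The two sets may overlap. Experimental protein ids with no orthogroup
    membership are logged and skipped (they are not fatal: proteomes and
    clusterings can legitimately be out of sync).
    """
    index = ogs.protein_index()
    pogs: set[str] = set()
    mogs: set[str] = set()
    rows = []
    for expset in experimental:
        target = pogs if expset.organelle == "plastid" else mogs
        for pid in sorted(expset.protein_ids):
            hit = index.get(pid)
            if hit is None:
                logger.warning(
                    "experimental protein %r (%s, %s) not found in any orthogroup",
                    pid, expset.organelle, expset.reference_species,
                )
                continue
            og_id, sp = hit
            target.add(og_id)
            rows.append((og_id, expset.organelle, pid, expset.reference_species))
    provenance = pd.DataFrame(
        rows, columns=["og_id", "organelle", "protein_id", "reference_species"]
    ).sort_values(["og_id", "organelle", "protein_id"]).reset_index(drop=True)
    return frozenset(pogs), frozenset(mogs), provenance


def species_summary(
    ogset: Iterable[str], presence: pd.DataFrame, copy: pd.DataFrame
) -> pd.DataFrame:
    """Per-species PN (total proteins), ON (OGs present), P/O (= PN/ON, 0 if ON=0)."""
    ids = sorted(set(ogset))
    missing = set(ids) - set(presence.index)
    if missing:
        raise ValueError(f"ogset ids not in matrix: {sorted(missing)[:5]}")
    pn = copy.loc[ids].sum(axis=0)
    on = (presence.loc[ids] > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ppo = np.where(on > 0, pn / on.replace(0, 1), 0.0)
    return pd.DataFrame(
        {"PN": pn.astype(int), "ON": on.astype(int), "P_per_O": ppo},
        index=presence.columns,
    )


def classify_all(
    ogs: OrthogroupTable,
    presence: pd.DataFrame,
    lineages: LineageMap,
    experimental: Iterable[ExperimentalProteomeSet],
    params: Parameters,
) -> ClassificationResult:
    gog_ids, counts = select_gogs(presence, lineages, params)
    core = select_core_gogs(gog_ids, presence, lineages, params)
    pogs, mogs, prov = select_organelle_ogs(ogs, experimental)
    return ClassificationResult(gog_ids, core, pogs, mogs, counts, prov)


def display_copy_numbers(copy: pd.DataFrame, cap: int = 50) -> pd.DataFrame:
    """Rendering helper: clamp copy numbers at the display cap (heat-map key)."""
    return copy.clip(upper=cap)
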