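"""Minimal assay batteries hosting qualifying agonist and antagonist models.

An assay battery is the full set of assays physically run at a testing step;
it may host one subset model tailored to agonism and another tailored to
antagonism.  The optimizer crosses every qualifying agonist model with every
qualifying antagonist model, computes the size of their assay union (the
battery the pair requires) and their Hamming distance, and keeps the pairs
achieving the minimal union.  Constrained variants search all assay sets of a
fixed size for the best agonist performance while guaranteeing a qualifying
antagonist submodel, and the exclusion analysis re-qualifies models after
removing assays (e.g. the discontinued receptor-binding assays).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Collection, Mapping

import numpy as np
import pandas as pd

from .model_eval import QualificationCriteria, qualify_models
from .subset_models import NUM_ASSAYS, SubsetModel, parse_model_name

PAIR_COLUMNS = [
    "agonist_model",
    "antagonist_model",
    "union_size",
    "hamming",
    "antagonist_sensitivity",
    "antagonist_specificity",
    "agonist_sensitivity",
    "agonist_specificity",
]

# popcount lookup for vectorized union/hamming over uint16 masks
_POPCOUNT16 = np.array([bin(i).count("1") for i in range(1 << 16)], dtype=np.uint8)


class InfeasibleBatteryError(ValueError):
    """No battery of the requested size can host a qualifying model."""


def _masks(names: Collection[str]) -> np.ndarray:
    return np.array([parse_model_name(n).mask for n in names], dtype=np.uint16)


def enumerate_pairs(
    agonist_qualifying: Collection[str],
    antagonist_qualifying: Collection[str],
    agonist_summaries: pd.DataFrame | None = None,
    antagonist_summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full cross product of qualifying agonist x antagonist models.

    Returns one row per ordered pair with the union size and Hamming distance
    populated; per-mode sensitivity/specificity columns are filled from the
    optional summary frames (NaN otherwise).  The row count is
    ``len(agonist_qualifying) * len(antagonist_qualifying)``.
    """
    ag = sorted(agonist_qualifying)
    ant = sorted(antagonist_qualifying)
    if not ag or not ant:
        raise ValueError("both qualifying sets must be non-empty")
    m_ag = _masks(ag)
    m_ant = _masks(ant)
    union = _POPCOUNT16[np.bitwise_or.outer(m_ag, m_ant)]
    ham = _POPCOUNT16[np.bitwise_xor.outer(m_ag, m_ant)]
    n_ag, n_ant = len(ag), len(ant)
    df = pd.DataFrame(
        {
            "agonist_model": np.repeat(ag, n_ant),
            "antagonist_model": np.tile(ant, n_ag),
            "union_size": union.ravel().astype(int),
            "hamming": ham.ravel().astype(int),
        }
    )
    for prefix, summaries, key in (
        ("antagonist", antagonist_summaries, "antagonist_model"),
        ("agonist", agonist_summaries, "agonist_model"),
    ):
        for metric in ("sensitivity", "specificity"):
            col = f"{prefix}_{metric}"
            if summaries is not None:
                df[col] = summaries[metric].reindex(df[key]).to_numpy()
            else:
                df[col] = np.nan
    return df[PAIR_COLUMNS]


@dataclass(frozen=True)
class MinimalBatteryResult:
    """Smallest pair-union size and every pair achieving it."""

    union_size: int
    pairs: pd.DataFrame  # sorted for presentation; all ties retained


def minimal_battery(pairs: pd.DataFrame) -> MinimalBatteryResult:
    """The minimal battery size over all pairs, with all achieving pairs.

    Ties are all reported; sorting (ascending Hamming distance, descending
    antagonist specificity, then model names) is applied only for
    presentation and the result is invariant to input row order.
    """
    if pairs.empty:
        raise ValueError("pairs collection is empty")
    best = int(pairs["union_size"].min())
    hits = pairs[pairs["union_size"] == best].copy()
    hits = hits.sort_values(
        by=["hamming", "antagonist_specificity", "agonist_model", "antagonist_model"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return MinimalBatteryResult(union_size=best, pairs=hits)


@dataclass(frozen=True)
class Battery:
    """An assay battery with the subset models it hosts for each mode."""

    assays: frozenset[int]
    antagonist_model: str
    agonist_model: str
    antagonist_sensitivity: float
    antagonist_specificity: float
    agonist_sensitivity: float
    agonist_specificity: float

    @property
    def name(self) -> str:
        return SubsetModel.from_assays(self.assays).name

    @property
    def size(self) -> int:
        return len(self.assays)


def _submasks(mask: int):
    """All non-empty submasks of ``mask`` (standard subset-lattice walk)."""
    sub = mask
    while sub:
        yield sub
        sub = (sub - 1) & mask


def constrained_battery_search(
    antagonist_summaries: pd.DataFrame,
    agonist_summaries: pd.DataFrame,
    battery_size: int,
    criteria: QualificationCriteria | None = None,
) -> Battery:
    """Best battery of a fixed size that still hosts a qualifying antagonist model.

    Searches all C(14, battery_size) assay sets by direct enumeration.  A set
    is feasible when at least one qualifying antagonist submodel fits inside
    it; among feasible sets the battery maximizing the sensitivity of its
    best contained agonist submodel wins (ties broken by agonist specificity,
    then lexicographically smallest battery name).  The hosted antagonist
    model reported is the qualifying submodel with the best
    (sensitivity, specificity).
    """
    criteria = criteria or QualificationCriteria()
    if not 5 <= battery_size <= NUM_ASSAYS:
        raise ValueError(f"battery_size must be in 5..{NUM_ASSAYS}, got {battery_size}")
    qualifying_ant = qualify_models(antagonist_summaries, criteria)
    qual_masks = {parse_model_name(n).mask: n for n in qualifying_ant}
    if not any(m.bit_count() <= battery_size for m in qual_masks):
        raise InfeasibleBatteryError(
            f"no qualifying antagonist model fits in a battery of {battery_size} assays"
        )
    ag_lookup: dict[int, tuple[float, float, str]] = {}
    for name, row in agonist_summaries.iterrows():
        ag_lookup[parse_model_name(name).mask] = (
            float(row["sensitivity"]),
            float(row["specificity"]),
            name,
        )
    qual_mask_list = list(qual_masks)

    best_key: tuple | None = None
    best_battery: Battery | None = None
    for combo in combinations(range(1, NUM_ASSAYS + 1), battery_size):
        bmask = 0
        for i in combo:
            bmask |= 1 << (NUM_ASSAYS - i)
        fits = [m for m in qual_mask_list if (m & ~bmask) == 0]
        if not fits:
            continue
        # best agonist submodel inside this battery
        best_ag: tuple[float, float, str] | None = None
        for sub in _submasks(bmask):
            entry = ag_lookup.get(sub)
            if entry is None:
                continue
            if best_ag is None or (entry[0], entry[1]) > (best_ag[0], best_ag[1]):
                best_ag = entry
        if best_ag is None:
            continue
        bname = SubsetModel.from_mask(bmask).name
        # maximize sensitivity, then specificity; lexicographically smallest name wins ties
        key = (best_ag[0], best_ag[1], tuple(-ord(c) for c in bname))
        if best_key is None or key > best_key:
            ant_choice = max(
                fits,
                key=lambda m: (
                    float(antagonist_summaries.loc[qual_masks[m], "sensitivity"]),
                    float(antagonist_summaries.loc[qual_masks[m], "specificity"]),
                    qual_masks[m],
                ),
            )
            ant_name = qual_masks[ant_choice]
            best_key = key
            best_battery = Battery(
                assays=SubsetModel.from_mask(bmask).assays,
                antagonist_model=ant_name,
                agonist_model=best_ag[2],
                antagonist_sensitivity=float(antagonist_summaries.loc[ant_name, "sensitivity"]),
                antagonist_specificity=float(antagonist_summaries.loc[ant_name, "specificity"]),
                agonist_sensitivity=best_ag[0],
                agonist_specificity=best_ag[1],
            )
    if best_battery is None:
        raise InfeasibleBatteryError(
            f"no battery of {battery_size} assays hosts both a qualifying antagonist "
            "model and any scored agonist model"
        )
    return best_battery


@dataclass(frozen=True)
class ExclusionReport:
    """Qualification landscape for one mode after removing assays."""

    mode: str
    excluded: frozenset[int]
    n_models: int
    max_sensitivity: float
    max_sensitivity_models: tuple[str, ...]
    max_specificity: float
    qualifying: tuple[str, ...]


def exclude_assay_analysis(
    summaries_by_mode: Mapping[str, pd.DataFrame],
    excluded: Collection[int],
    criteria: QualificationCriteria | None = None,
) -> dict[str, ExclusionReport]:
    """Re-qualify subset models once the excluded assays are unavailable.

    For each mode, restricts the summaries to models disjoint from the
    excluded set and reports the best sensitivity/specificity there plus the
    models still passing the criteria.  With ``excluded`` empty this is the
    global qualification landscape.
    """
    criteria = criteria or QualificationCriteria()
    excluded_set = frozenset(excluded)
    if not excluded_set <= set(range(1, NUM_ASSAYS + 1)):
        raise ValueError(f"excluded assay indices out of range: {sorted(excluded_set)}")
    excl_mask = 0
    for i in excluded_set:
        excl_mask |= 1 << (NUM_ASSAYS - i)
    reports: dict[str, ExclusionReport] = {}
    for mode, summaries in summaries_by_mode.items():
        keep = [n for n in summaries.index if (parse_model_name(n).mask & excl_mask) == 0]
        sub = summaries.loc[keep]
        if sub.empty:
            raise ValueError(f"excluding assays {sorted(excluded_set)} leaves no models for mode {mode!r}")
        sens = sub["sensitivity"]
        best_sens = float(sens.max())
        reports[mode] = ExclusionReport(
            mode=mode,
            excluded=excluded_set,
            n_models=len(sub),
            max_sensitivity=best_sens,
            max_sensitivity_models=tuple(sorted(sens.index[sens == best_sens])),
            max_specificity=float(sub["specificity"].max()),
            qualifying=tuple(sorted(qualify_models(sub, criteria))),
        )
    return reports
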