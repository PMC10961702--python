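"""Scoring subset models against the full-model reference.

Pathway AUC scores are binarized at a cutoff (0.1 by default: values at or
above the cutoff are active calls) and every subset model's calls are
tabulated against the 14-assay reference model's calls for the same
chemicals.  Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) are
computed with the reference as truth; models qualify for battery building
when sensitivity exceeds 95% and specificity exceeds 85% (strict comparison
at full floating precision, configurable).

Also provided: the model-agreement 2x2 tabulation with Matthews correlation
coefficient (MCC), per-assay prevalence across a qualifying set, and the
leave-one-assay-out maximum-sensitivity analysis that identifies assays
indispensable for detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Iterable, Sequence

import numpy as np
import pandas as pd

from .subset_models import NUM_ASSAYS, Mode, parse_model_name


class AlignmentError(ValueError):
    """Raised when two call vectors do not cover the same chemical set."""


SUMMARY_COLUMNS = [
    "mode",
    "tp",
    "fp",
    "tn",
    "fn",
    "sensitivity",
    "specificity",
    "mcc",
    "balanced_accuracy",
]


@dataclass(frozen=True)
class QualificationCriteria:
    """Thresholds a subset model must beat to qualify for battery building.

    Defaults follow the screening-oriented choice of weighting sensitivity
    over specificity: sensitivity > 0.95 and specificity > 0.85.  ``strict``
    selects exclusive (>) comparison; with ``strict=False`` the comparison is
    inclusive (>=).
    """

    min_sensitivity: float = 0.95
    min_specificity: float = 0.85
    strict: bool = True

    def __post_init__(self) -> None:
        for v, label in ((self.min_sensitivity, "min_sensitivity"), (self.min_specificity, "min_specificity")):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{label} must be in (0, 1), got {v}")

    def passes(self, sensitivity: float, specificity: float) -> bool:
        if self.strict:
            return sensitivity > self.min_sensitivity and specificity > self.min_specificity
        return sensitivity >= self.min_sensitivity and specificity >= self.min_specificity


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts with the derived agreement metrics.

    ``sensitivity``/``specificity`` are NaN when their denominator is zero;
    MCC is defined as 0 when any marginal is zero (common convention).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def mcc(self) -> float:
        denom = (
            (self.tp + self.fp)
            * (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tn + self.fn)
        )
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(denom)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "balanced_accuracy": self.balanced_accuracy,
        }


@dataclass(frozen=True)
class AgreementTable:
    """2x2 model-agreement cells between two call vectors (a vs b)."""

    both_active: int
    both_inactive: int
    a_only: int
    b_only: int

    @property
    def n(self) -> int:
        return self.both_active + self.both_inactive + self.a_only + self.b_only

    @property
    def agreement(self) -> int:
        return self.both_active + self.both_inactive

    @property
    def mcc(self) -> float:
        # MCC is symmetric in which vector is taken as reference.
        return ConfusionSummary(
            tp=self.both_active, fp=self.a_only, tn=self.both_inactive, fn=self.b_only
        ).mcc


def binarize_auc(auc, cutoff: float = 0.1):
    """Binarize pathway AUC value(s): 1 iff auc >= cutoff ("at or above").

    Accepts a scalar or an array-like; negative AUC values are rejected.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    arr = np.asarray(auc, dtype=float)
    if np.any(arr < 0):
        raise ValueError("AUC values must be non-negative")
    calls = (arr >= cutoff).astype(int)
    if np.isscalar(auc) or arr.ndim == 0:
        return int(calls)
    return calls


def _align(predicted: pd.Series, reference: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    pred_ids = set(predicted.index)
    ref_ids = set(reference.index)
    if pred_ids != ref_ids:
        missing_in_pred = sorted(ref_ids - pred_ids)[:10]
        missing_in_ref = sorted(pred_ids - ref_ids)[:10]
        raise AlignmentError(
            "chemical sets differ between predicted and reference calls; "
            f"missing from predicted: {missing_in_pred}; missing from reference: {missing_in_ref}"
        )
    if predicted.index.has_duplicates or reference.index.has_duplicates:
        raise AlignmentError("duplicate chemical ids in call vector")
    order = reference.index
    return (
        predicted.reindex(order).to_numpy().astype(bool),
        reference.to_numpy().astype(bool),
    )


def align_calls(a: pd.Series, b: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Explicitly intersect two call vectors on their common chemicals.

    Chemicals present in only one vector are dropped *deliberately* here;
    :func:`confusion` and :func:`agreement_table` treat mismatched sets as an
    error, so intersection must be requested through this step.
    """
    common = a.index.intersection(b.index).sort_values()
    return a.reindex(common), b.reindex(common)


def confusion(predicted: pd.Series, reference: pd.Series) -> ConfusionSummary:
    """Tabulate predicted vs reference binary calls (reference as truth).

    Both inputs are 0/1 Series indexed by chemical id over the same chemical
    set; a mismatch raises :class:`AlignmentError` listing missing ids.
    """
    p, r = _align(predicted, reference)
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    tn = int(np.sum(~p & ~r))
    fn = int(np.sum(~p & r))
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def agreement_table(calls_a: pd.Series, calls_b: pd.Series) -> AgreementTable:
    """2x2 agreement cells between two models' calls on aligned chemicals."""
    a, b = _align(calls_a, calls_b)
    return AgreementTable(
        both_active=int(np.sum(a & b)),
        both_inactive=int(np.sum(~a & ~b)),
        a_only=int(np.sum(a & ~b)),
        b_only=int(np.sum(~a & b)),
    )


def _metrics_frame(
    model_names: Sequence[str],
    mode: str,
    tp: np.ndarray,
    fp: np.ndarray,
    tn: np.ndarray,
    fn: np.ndarray,
) -> pd.DataFrame:
    tp = tp.astype(float)
    fp = fp.astype(float)
    tn = tn.astype(float)
    fn = fn.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(np.where(denom > 0, denom, 1.0)), 0.0)
    df = pd.DataFrame(
        {
            "mode": mode,
            "tp": tp.astype(int),
            "fp": fp.astype(int),
            "tn": tn.astype(int),
            "fn": fn.astype(int),
            "sensitivity": sens,
            "specificity": spec,
            "mcc": mcc,
            "balanced_accuracy": (sens + spec) / 2,
        },
        index=pd.Index(model_names, name="model_name"),
    )
    return df


def evaluate_call_matrix(
    calls: np.ndarray,
    model_names: Sequence[str],
    reference_calls: np.ndarray,
    mode: str,
) -> pd.DataFrame:
    """Confusion summaries for many models at once.

    Parameters
    ----------
    calls
        Binary array of shape (n_chemicals, n_models), one column per model.
    model_names
        Column labels, in order.
    reference_calls
        Binary reference vector of length n_chemicals.
    mode
        Pathway mode label echoed into the output.

    Returns
    -------
    DataFrame indexed by model_name with the same columns as
    :data:`SUMMARY_COLUMNS`.
    """
    C = np.asarray(calls).astype(bool)
    r = np.asarray(reference_calls).astype(bool)
    if C.shape[0] != r.shape[0]:
        raise AlignmentError(
            f"call matrix has {C.shape[0]} chemicals but reference has {r.shape[0]}"
        )
    if C.shape[1] != len(model_names):
        raise ValueError("model_names length does not match call matrix width")
    tp = r.astype(np.int64) @ C
    fp = (~r).astype(np.int64) @ C
    fn = int(r.sum()) - tp
    tn = int((~r).sum()) - fp
    return _metrics_frame(list(model_names), mode, tp, fp, tn, fn)


def evaluate_all_models(
    auc_table: pd.DataFrame,
    reference_model: str,
    mode: Mode,
    cutoff: float = 0.1,
) -> pd.DataFrame:
    """Score every subset model in a long-format AUC table against a reference.

    ``auc_table`` has columns chemical_id, model_name, mode, auc (one row per
    key).  Calls are binarized at ``cutoff`` and each model's calls are
    tabulated against the binarized calls of ``reference_model``.
    """
    required = {"chemical_id", "model_name", "mode", "auc"}
    missing = required - set(auc_table.columns)
    if missing:
        raise ValueError(f"auc table missing columns: {sorted(missing)}")
    sub = auc_table[auc_table["mode"] == mode]
    if reference_model not in set(sub["model_name"]):
        raise ValueError(f"reference model {reference_model!r} not present in AUC table for mode {mode!r}")
    wide = sub.pivot(index="chemical_id", columns="model_name", values="auc")
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()[:10]
        raise AlignmentError(f"AUC table is not complete over chemicals x models; gaps in {bad}")
    calls = binarize_auc(wide.to_numpy(), cutoff)
    names = list(wide.columns)
    ref = calls[:, names.index(reference_model)]
    others = [n for n in names if n != reference_model]
    cols = [names.index(n) for n in others]
    return evaluate_call_matrix(calls[:, cols], others, ref, mode)


def qualify_models(
    summaries: pd.DataFrame,
    criteria: QualificationCriteria | None = None,
) -> set[str]:
    """Model names passing both qualification thresholds.

    Tightening the criteria never grows the returned set (monotonicity).
    """
    criteria = criteria or QualificationCriteria()
    sens = summaries["sensitivity"]
    spec = summaries["specificity"]
    if criteria.strict:
        mask = (sens > criteria.min_sensitivity) & (spec > criteria.min_specificity)
    else:
        mask = (sens >= criteria.min_sensitivity) & (spec >= criteria.min_specificity)
    return set(summaries.index[mask.fillna(False)])


def assay_prevalence(qualifying: Collection[str]) -> pd.Series:
    """Fraction of qualifying models containing each assay.

    Returns a Series indexed A1..A14 with values in [0, 1].  An empty
    qualifying set is an error (prevalence would be undefined).
    """
    names = list(qualifying)
    if not names:
        raise ValueError("assay prevalence is undefined for an empty qualifying set")
    counts = np.zeros(NUM_ASSAYS, dtype=int)
    for name in names:
        counts += np.array(parse_model_name(name).membership)
    return pd.Series(
        counts / len(names),
        index=pd.Index([f"A{i}" for i in range(1, NUM_ASSAYS + 1)], name="assay"),
        name="prevalence",
    )


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Maximum sensitivity among models avoiding an excluded assay set."""

    excluded: frozenset[int]
    max_sensitivity: float
    models: tuple[str, ...]  # argmax model name(s), sorted


def leave_one_out_max_sensitivity(
    summaries: pd.DataFrame,
    excluded: int | Iterable[int],
) -> LeaveOneOutResult:
    """Best achievable sensitivity once the excluded assay(s) are unavailable.

    Restricts the summaries to models containing none of the excluded assays
    and reports the maximum sensitivity with the model(s) achieving it.  If
    the exclusion leaves no models, an error is raised.
    """
    if isinstance(excluded, int):
        excluded_set = frozenset({excluded})
    else:
        excluded_set = frozenset(excluded)
    if not excluded_set <= set(range(1, NUM_ASSAYS + 1)):
        raise ValueError(f"excluded assay indices out of range: {sorted(excluded_set)}")
    excl_mask = 0
    for i in excluded_set:
        excl_mask |= 1 << (NUM_ASSAYS - i)
    keep = [name for name in summaries.index if (parse_model_name(name).mask & excl_mask) == 0]
    if not keep:
        raise ValueError(f"excluding assays {sorted(excluded_set)} leaves no subset models")
    sens = summaries.loc[keep, "sensitivity"]
    best = float(sens.max())
    argmax = tuple(sorted(sens.index[sens == best]))
    return LeaveOneOutResult(excluded=excluded_set, max_sensitivity=best, models=argmax)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, for reporting percentages (e.g. 43.125 -> 43.13)."""
    scale = 10**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)
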