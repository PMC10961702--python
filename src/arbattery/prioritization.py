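"""Testing-scenario cost accounting and the multi-stage testing simulation.

The cost unit of a testing scenario is the chemical-assay pair: the number of
chemicals run through a stage times the number of assays run at that stage,
summed over stages.  Scenario costs are compared as a percentage of the
maximal cost (every chemical through the full 14-assay battery).

The multi-stage workflow runs every chemical through a small first-stage
battery whose antagonist submodel already meets the qualification criteria
but whose agonist submodel is deliberately weak (~71% sensitivity).  Stage-1
agonist positives (true and false) select structural clusters; every chemical
in a selected cluster is then re-tested with the additional stage-2 assays,
whose agonist submodel is strong (~96% sensitivity).  The Monte-Carlo
simulation samples stage outcomes at the configured sensitivity/specificity
and reports the distribution of stage-2 load, total chemical-assay pairs and
agonist detection sensitivity over many runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd


def scenario_cost(
    stage_chemical_counts: Sequence[int],
    stage_battery_sizes: Sequence[int],
) -> int:
    """Total chemical-assay pairs: sum of chemicals_i * assays_i over stages."""
    if len(stage_chemical_counts) != len(stage_battery_sizes):
        raise ValueError(
            f"stage lists differ in length: {len(stage_chemical_counts)} vs {len(stage_battery_sizes)}"
        )
    if any(c < 0 for c in stage_chemical_counts) or any(s < 0 for s in stage_battery_sizes):
        raise ValueError("stage counts and battery sizes must be non-negative")
    return int(sum(c * s for c, s in zip(stage_chemical_counts, stage_battery_sizes)))


def percent_of_max(
    pairs: int,
    n_chemicals: int,
    full_battery: int = 14,
    round_to_int: bool = True,
) -> float:
    """Scenario cost as a percentage of testing every chemical in the full battery.

    Reported rounded to the nearest integer by default (pass
    ``round_to_int=False`` for the raw percentage).
    """
    if n_chemicals <= 0:
        raise ValueError("n_chemicals must be positive")
    pct = 100.0 * pairs / (n_chemicals * full_battery)
    if round_to_int:
        return float(int(np.floor(pct + 0.5)))
    return pct


def overall_sensitivity(
    s_antagonist: float,
    s_agonist: float,
    antagonist_weight: float = 0.9,
) -> float:
    """Prevalence-weighted overall sensitivity.

    Antagonists dominate the active calls (~90%), so overall sensitivity is
    ``w * s_antagonist + (1 - w) * s_agonist`` with ``w = 0.9`` by default.
    Inputs and output share whatever scale is supplied (percent or fraction).
    """
    if not 0.0 <= antagonist_weight <= 1.0:
        raise ValueError("antagonist_weight must be in [0, 1]")
    return antagonist_weight * s_antagonist + (1.0 - antagonist_weight) * s_agonist


def cluster_based_assignment(
    cluster_labels: pd.Series,
    agonist_predictions: pd.Series,
    large_battery: int = 9,
    small_battery: int = 5,
) -> tuple[pd.Series, int]:
    """Per-chemical battery size under the cluster-based scenario.

    Chemicals in clusters containing at least one agonist prediction get the
    large battery; everyone else gets the small one.  Chemicals without a
    cluster id are flagged and conservatively assigned the large battery.
    Returns the per-chemical assignment and the resulting scenario cost.
    """
    preds = agonist_predictions.reindex(cluster_labels.index).astype("boolean").fillna(False).astype(bool)
    unclustered = cluster_labels.isna()
    flagged_clusters = set(cluster_labels[preds & ~unclustered])
    in_flagged = cluster_labels.isin(flagged_clusters)
    sizes = pd.Series(
        np.where(in_flagged | unclustered, large_battery, small_battery),
        index=cluster_labels.index,
        name="battery_size",
    )
    return sizes, int(sizes.sum())


@dataclass(frozen=True)
class StageSpec:
    """Assays run at one testing stage and the rates of its agonist submodel.

    ``battery_size`` counts the assays physically run at this stage (for
    stage 2 that means the *additional* assays beyond stage 1).  The default
    rates correspond to the 3-assay agonist submodel of the 6-assay battery
    (stage 1) and are overridden per stage.
    """

    battery_size: int
    agonist_sensitivity: float
    agonist_specificity: float
    antagonist_sensitivity: float | None = None
    antagonist_specificity: float | None = None
    selector: Literal[
        "all-chemicals",
        "clusters-with-stage1-agonist-positives",
        "clusters-with-prior-agonist-prediction",
    ] = "all-chemicals"

    def __post_init__(self) -> None:
        if not 1 <= self.battery_size <= 14:
            raise ValueError("battery_size must be in 1..14")
        for v, label in (
            (self.agonist_sensitivity, "agonist_sensitivity"),
            (self.agonist_specificity, "agonist_specificity"),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")


#: Stage rates of the published two-stage design: stage 1 = 3-assay agonist
#: submodel inside the 6-assay battery; stage 2 = 6-assay agonist submodel of
#: the 9-assay battery, run as 3 additional assays.
DEFAULT_STAGE1 = StageSpec(
    battery_size=6,
    agonist_sensitivity=0.714,
    agonist_specificity=0.989,
    antagonist_sensitivity=0.952,
    antagonist_specificity=0.934,
    selector="all-chemicals",
)
DEFAULT_STAGE2 = StageSpec(
    battery_size=3,
    agonist_sensitivity=0.96,
    agonist_specificity=0.977,
    selector="clusters-with-stage1-agonist-positives",
)


@dataclass(frozen=True)
class SimulationResult:
    """Per-run outcomes and aggregates of the multi-stage simulation."""

    per_run: pd.DataFrame  # columns: n_stage2_chemicals, chemical_assay_pairs, agonist_detection_sensitivity
    n_runs: int
    seed: int | None
    settings: dict = field(compare=False)

    def aggregate(self) -> pd.DataFrame:
        """mean/median/min/max of each per-run quantity (NaN-aware)."""
        return self.per_run.agg(["mean", "median", "min", "max"])


def _round_half_even(x: float) -> int:
    # sampled-count rounding: nearest integer, ties to even
    return int(np.round(x))


def simulate_multistage(
    chemicals: pd.DataFrame,
    stage1: StageSpec = DEFAULT_STAGE1,
    stage2: StageSpec = DEFAULT_STAGE2,
    n_runs: int = 1000,
    seed: int | None = None,
    sampling: Literal["exact", "bernoulli"] = "exact",
) -> SimulationResult:
    """Monte-Carlo simulation of the two-stage agonist testing workflow.

    Parameters
    ----------
    chemicals
        DataFrame with columns chemical_id, cluster_id, is_agonist.  The
        is_agonist column marks the confirmed agonist designations the
        simulation treats as truth.
    stage1, stage2
        Stage batteries and agonist submodel rates.  Stage 2's
        ``battery_size`` is the number of additional assays run on the
        selected clusters.
    n_runs, seed
        Number of runs and the master seed; per-run generators are spawned
        from the master seed, so identical inputs give identical results.
    sampling
        ``"exact"`` draws exactly round(rate * n) chemicals without
        replacement (ties rounded to even); ``"bernoulli"`` flips an
        independent coin per chemical.

    Notes
    -----
    Antagonist detection is complete at stage 1 by design (its antagonist
    submodel already qualifies), so only agonist detection is simulated.
    Within selected clusters the stage-2 call supersedes stage 1; a stage-1
    false positive still selects its cluster for stage 2.  Detection
    sensitivity is NaN when the input has no true agonists.
    """
    required = {"chemical_id", "cluster_id", "is_agonist"}
    if not required <= set(chemicals.columns):
        raise ValueError(f"chemicals table requires columns {sorted(required)}")
    if chemicals["chemical_id"].duplicated().any():
        raise ValueError("duplicate chemical ids in simulation input")
    n_total = len(chemicals)
    clusters = chemicals["cluster_id"].to_numpy()
    truth = chemicals["is_agonist"].to_numpy().astype(bool)
    pos_idx = np.flatnonzero(truth)
    neg_idx = np.flatnonzero(~truth)
    n_pos, n_neg = len(pos_idx), len(neg_idx)
    cluster_sizes = pd.Series(clusters).value_counts()

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_runs)

    rows = []
    for run_seq in child_seeds:
        rng = np.random.default_rng(run_seq)
        if sampling == "exact":
            n_tp = min(_round_half_even(stage1.agonist_sensitivity * n_pos), n_pos)
            n_fp = min(_round_half_even((1.0 - stage1.agonist_specificity) * n_neg), n_neg)
            tp1 = rng.choice(pos_idx, size=n_tp, replace=False) if n_tp else np.array([], dtype=int)
            fp1 = rng.choice(neg_idx, size=n_fp, replace=False) if n_fp else np.array([], dtype=int)
        elif sampling == "bernoulli":
            tp1 = pos_idx[rng.random(n_pos) < stage1.agonist_sensitivity]
            fp1 = neg_idx[rng.random(n_neg) < (1.0 - stage1.agonist_specificity)]
        else:
            raise ValueError(f"unknown sampling mode {sampling!r}")
        stage1_pos = np.concatenate([tp1, fp1])
        selected_clusters = np.unique(clusters[stage1_pos]) if stage1_pos.size else np.array([])
        in_selected = np.isin(clusters, selected_clusters)
        n_stage2 = int(in_selected.sum())

        # stage 2 re-tests everyone in the selected clusters at stage-2 rates
        pos2 = np.flatnonzero(truth & in_selected)
        if sampling == "exact":
            n_det = min(_round_half_even(stage2.agonist_sensitivity * len(pos2)), len(pos2))
            detected = n_det
        else:
            detected = int(np.sum(rng.random(len(pos2)) < stage2.agonist_sensitivity))
        sensitivity = detected / n_pos if n_pos else np.nan
        pairs = stage1.battery_size * n_total + stage2.battery_size * n_stage2
        rows.append((n_stage2, pairs, sensitivity))

    per_run = pd.DataFrame(
        rows,
        columns=["n_stage2_chemicals", "chemical_assay_pairs", "agonist_detection_sensitivity"],
        index=pd.RangeIndex(n_runs, name="run"),
    )
    settings = {
        "stage1": stage1.__dict__ | {},
        "stage2": stage2.__dict__ | {},
        "sampling": sampling,
        "n_chemicals": n_total,
        "n_true_agonists": int(n_pos),
        "n_clusters": int(cluster_sizes.size),
        "final_call_semantics": "stage-2 call supersedes stage 1 inside selected clusters",
    }
    return SimulationResult(per_run=per_run, n_runs=n_runs, seed=seed, settings=settings)
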