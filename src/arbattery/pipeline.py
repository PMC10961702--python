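"""End-to-end composition of the analysis stages on one dataset.

Ties the generator, model evaluation, battery optimization, clustering and
simulation together the way a full study run uses them.  The evaluation path
works on in-memory surrogate-AUC matrices (16,368 subset models x all
chemicals is far too large for a long-format interchange file) and is shared
by the CLI, the tests and the acceptance run.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .battery_optimizer import MinimalBatteryResult, enumerate_pairs, minimal_battery
from .clustering import cut_tree, pairwise_tanimoto, ward_cluster
from .model_eval import QualificationCriteria, evaluate_call_matrix, qualify_models
from .subset_models import NUM_ASSAYS, Mode, enumerate_subset_models
from .synthetic_data import SyntheticDataset

FULL_MODEL = "A" + "1" * NUM_ASSAYS


def evaluate_dataset(
    dataset: SyntheticDataset,
    mode: Mode,
    cutoff: float = 0.1,
    min_size: int = 2,
) -> pd.DataFrame:
    """Score all enumerated subset models against the full-model reference."""
    models = enumerate_subset_models(min_size=min_size, include_full=True)
    names = [m.name for m in models]
    auc = dataset.auc_matrix(models, mode)
    calls = auc >= cutoff
    ref = calls[:, names.index(FULL_MODEL)]
    sub_cols = [i for i, n in enumerate(names) if n != FULL_MODEL]
    sub_names = [names[i] for i in sub_cols]
    return evaluate_call_matrix(calls[:, sub_cols], sub_names, ref, mode)


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the full workflow produces on one dataset."""

    summaries: dict[str, pd.DataFrame]  # mode -> per-model confusion summaries
    qualifying: dict[str, set[str]]
    pairs: pd.DataFrame
    battery: MinimalBatteryResult
    cluster_labels: pd.Series


def run_full_analysis(
    dataset: SyntheticDataset,
    criteria: QualificationCriteria | None = None,
    cutoff: float = 0.1,
    cut_height: float = 1.0,
) -> AnalysisResult:
    """Evaluate, qualify, optimize and cluster one dataset end to end."""
    criteria = criteria or QualificationCriteria()
    summaries = {mode: evaluate_dataset(dataset, mode, cutoff=cutoff) for mode in ("agonist", "antagonist")}
    qualifying = {mode: qualify_models(summaries[mode], criteria) for mode in summaries}
    pairs = enumerate_pairs(
        qualifying["agonist"],
        qualifying["antagonist"],
        agonist_summaries=summaries["agonist"],
        antagonist_summaries=summaries["antagonist"],
    )
    battery = minimal_battery(pairs)
    tree = ward_cluster(pairwise_tanimoto(dataset.fingerprints), dataset.fingerprints.ids)
    labels = cut_tree(tree, height=cut_height)
    return AnalysisResult(
        summaries=summaries,
        qualifying=qualifying,
        pairs=pairs,
        battery=battery,
        cluster_labels=labels,
    )
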