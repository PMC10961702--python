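"""Synthetic inputs with the statistical structure the analysis assumes.

The real workflow consumes four externally produced inputs: pathway-AUC
tables from the AR network model run against curated screening data, a
chemical x 14-assay hit-call matrix, ToxPrint structural fingerprints, and
QSAR predictions with physico-chemical properties.  None of those sources is
required here: this module generates all four with planted ground truth so
every downstream operation can be exercised and checked end to end.

Generated structure
-------------------
* **Chemicals** carry a ground-truth class (agonist-only, antagonist-only,
  both, inactive) at prevalences mirroring the screening setting where
  antagonists dominate the actives (~13%) and agonists are rare (~1%).
* **Hit calls**: active classes fire their mode's pathway assays at a
  configurable true-positive rate; inactives fire any assay at a small
  false-positive rate.  A configurable fraction of each active class are
  *narrow* detectors that fire only a single mode-specific signature assay —
  these plant the "indispensable assay" structure in which removing one
  signature assay caps the achievable sensitivity.
* **Fingerprints** are cluster prototypes with independent per-bit flip
  noise; agonists are placed only in a designated small set of clusters,
  reproducing the concentration of agonists in few structural clusters.
* **Surrogate AUC**: ``potency * (active pathway assays in model / pathway
  assays in model)``.  This is deliberately simple — the pipeline only
  consumes binarized AUCs and rankings — and is NOT the published network
  deconvolution model; it must not be used as a stand-in for it.  Per-chemical
  potency is drawn >= 0.2 for truly active classes and below the 0.1 call
  cutoff for inactives, so the full 14-assay model binarizes correctly on
  noiseless inputs.

Printed-table fixtures (model-agreement cells, the 9-assay-battery pair
names, the constrained batteries, and the costed testing scenarios) are
exposed as small constructor functions for tests and reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import FingerprintSet
from .subset_models import (
    NUM_ASSAYS,
    AssayRoster,
    Mode,
    SubsetModel,
    default_roster,
    pathway_assays,
)

CLASSES = ("inactive", "agonist", "antagonist", "both")

#: Signature assays available to narrow detectors, per mode.
NARROW_SIGNATURES = {"agonist": (9, 11), "antagonist": (12, 13, 14)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-data generator.

    Defaults mirror the screening setting: 1,820 chemicals of which ~238 are
    antagonist-only, ~16 agonist-only and ~6 both (prevalences 0.131 / 0.009 /
    0.003), clustered into 91 structural clusters with agonists confined to a
    small fraction of them.
    """

    n_chemicals: int = 1820
    prevalence_antagonist: float = 0.131
    prevalence_agonist: float = 0.009
    prevalence_both: float = 0.003
    n_clusters: int = 91
    agonist_cluster_fraction: float = 0.03  # fraction of clusters allowed to hold agonists
    fingerprint_length: int = 729
    bit_density: float = 0.30
    flip_noise: float = 0.02
    tpr_broad: float = 0.70  # per-assay hit rate of broad actives on their pathway
    fpr: float = 0.01  # per-assay hit rate off-pathway / for inactives
    narrow_fraction_antagonist: float = 0.30
    narrow_fraction_agonist: float = 0.35
    potency_active: tuple[float, float] = (0.2, 1.0)
    # narrow detectors concentrate all their evidence in one assay, so their
    # potency must exceed cutoff * pathway_size (0.1 * 11) for the full model
    # to call them active at all
    potency_narrow: tuple[float, float] = (1.15, 1.45)
    potency_inactive: tuple[float, float] = (0.0, 0.095)
    qsar_sensitivity: float = 0.90
    qsar_false_positive_rate: float = 0.05
    henry_log10_range: tuple[float, float] = (-9.0, -1.0)

    def __post_init__(self) -> None:
        total = self.prevalence_antagonist + self.prevalence_agonist + self.prevalence_both
        if total > 1.0:
            raise ValueError(f"class prevalences sum to {total} > 1")
        if self.n_chemicals < 4:
            raise ValueError("need at least 4 chemicals (one per class)")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")
        for rate, label in (
            (self.tpr_broad, "tpr_broad"),
            (self.fpr, "fpr"),
            (self.flip_noise, "flip_noise"),
            (self.bit_density, "bit_density"),
            (self.qsar_sensitivity, "qsar_sensitivity"),
            (self.qsar_false_positive_rate, "qsar_false_positive_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {rate}")


@dataclass(frozen=True)
class SyntheticDataset:
    """All pipeline inputs for one generated chemical universe."""

    chemicals: pd.DataFrame  # chemical_id, truth_class, cluster_truth, signature_assay,
    #                          potency_agonist, potency_antagonist,
    #                          qsar_agonist, qsar_antagonist, henrys_law_constant
    fingerprints: FingerprintSet
    hit_calls: pd.DataFrame  # index chemical_id, columns A1..A14, values 0/1
    config: GeneratorConfig
    seed: int | None
    roster: AssayRoster = field(default_factory=default_roster)

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.chemicals["chemical_id"])

    def truth_calls(self, mode: Mode) -> pd.Series:
        """Ground-truth activity indicator for one mode (class-level truth)."""
        cls = self.chemicals.set_index("chemical_id")["truth_class"]
        active = {"agonist": ("agonist", "both"), "antagonist": ("antagonist", "both")}[mode]
        return cls.isin(active).astype(int)

    def potency(self, mode: Mode) -> np.ndarray:
        return self.chemicals[f"potency_{mode}"].to_numpy()

    def auc_matrix(self, models: Sequence[SubsetModel], mode: Mode) -> np.ndarray:
        """Surrogate AUC for every chemical (rows) x model (columns)."""
        return surrogate_auc_matrix(
            self.hit_calls.to_numpy(), self.potency(mode), models, mode, self.roster
        )

    def auc_table(self, models: Sequence[SubsetModel], modes: Iterable[Mode] = ("agonist", "antagonist")) -> pd.DataFrame:
        """Long-format AUC table (chemical_id, model_name, mode, auc)."""
        frames = []
        ids = self.chemical_ids
        for mode in modes:
            mat = self.auc_matrix(models, mode)
            frames.append(
                pd.DataFrame(
                    {
                        "chemical_id": np.repeat(ids, len(models)),
                        "model_name": np.tile([m.name for m in models], len(ids)),
                        "mode": mode,
                        "auc": mat.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def surrogate_auc(
    hit_calls: Sequence[int],
    model: SubsetModel,
    mode: Mode,
    potency: float,
    roster: AssayRoster | None = None,
) -> float:
    """Surrogate pathway AUC for one chemical under one subset model.

    ``potency * (active pathway assays in the model / pathway assays in the
    model)``; 0 when the model's mode pathway is empty.  Monotone
    non-decreasing in the number of active pathway assays.  This is scaffold
    plumbing, not the published AUC deconvolution.
    """
    pathway = pathway_assays(model, mode, roster)
    if not pathway:
        return 0.0
    hits = np.asarray(hit_calls)
    active = sum(int(hits[i - 1]) for i in pathway)
    return float(potency) * active / len(pathway)


def surrogate_auc_matrix(
    hit_calls: np.ndarray,
    potency: np.ndarray,
    models: Sequence[SubsetModel],
    mode: Mode,
    roster: AssayRoster | None = None,
) -> np.ndarray:
    """Vectorized :func:`surrogate_auc` over chemicals x models."""
    roster = roster or default_roster()
    H = np.asarray(hit_calls, dtype=np.float32)
    if H.shape[1] != NUM_ASSAYS:
        raise ValueError(f"hit-call matrix must have {NUM_ASSAYS} columns")
    P = np.zeros((len(models), NUM_ASSAYS), dtype=np.float32)
    for j, m in enumerate(models):
        for i in pathway_assays(m, mode, roster):
            P[j, i - 1] = 1.0
    counts = P.sum(axis=1)
    frac = H @ P.T
    nonzero = counts > 0
    frac[:, nonzero] /= counts[nonzero]
    frac[:, ~nonzero] = 0.0
    return np.asarray(potency, dtype=np.float32)[:, None] * frac


def generate(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset; deterministic under ``seed``."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_chemicals

    ids = [f"SYN{i:06d}" for i in range(1, n + 1)]
    p_inactive = 1.0 - cfg.prevalence_antagonist - cfg.prevalence_agonist - cfg.prevalence_both
    truth = rng.choice(
        CLASSES,
        size=n,
        p=[p_inactive, cfg.prevalence_agonist, cfg.prevalence_antagonist, cfg.prevalence_both],
    )

    # narrow detectors: a fraction of each single-mode class fires only one
    # signature assay; round-robin over signatures guarantees coverage
    signature = np.zeros(n, dtype=int)  # 0 = broad
    for mode, frac in (("antagonist", cfg.narrow_fraction_antagonist), ("agonist", cfg.narrow_fraction_agonist)):
        sigs = NARROW_SIGNATURES[mode]
        members = np.flatnonzero(truth == mode)
        if len(members) == 0:
            continue
        n_narrow = min(len(members), max(len(sigs), int(np.round(frac * len(members))))) if frac > 0 else 0
        chosen = rng.permutation(members)[:n_narrow]
        for k, idx in enumerate(chosen):
            signature[idx] = sigs[k % len(sigs)]

    roster = default_roster()
    ag_path = sorted(roster.agonist_pathway)
    ant_path = sorted(roster.antagonist_pathway)

    hits = (rng.random((n, NUM_ASSAYS)) < cfg.fpr).astype(np.uint8)
    broad_ag = np.flatnonzero(((truth == "agonist") | (truth == "both")) & (signature == 0))
    broad_ant = np.flatnonzero(((truth == "antagonist") | (truth == "both")) & (signature == 0))
    cols_ag = np.array(ag_path) - 1
    cols_ant = np.array(ant_path) - 1
    hits[np.ix_(broad_ag, cols_ag)] = (
        rng.random((len(broad_ag), len(cols_ag))) < cfg.tpr_broad
    ).astype(np.uint8)
    hits[np.ix_(broad_ant, cols_ant)] = (
        rng.random((len(broad_ant), len(cols_ant))) < cfg.tpr_broad
    ).astype(np.uint8)
    narrow = np.flatnonzero(signature > 0)
    hits[narrow, signature[narrow] - 1] = 1

    def _draw_potency(active_mask: np.ndarray, narrow_mask: np.ndarray) -> np.ndarray:
        p = rng.uniform(*cfg.potency_inactive, size=n)
        p[active_mask] = rng.uniform(*cfg.potency_active, size=int(active_mask.sum()))
        p[narrow_mask] = rng.uniform(*cfg.potency_narrow, size=int(narrow_mask.sum()))
        return p

    ag_active = (truth == "agonist") | (truth == "both")
    ant_active = (truth == "antagonist") | (truth == "both")
    potency_ag = _draw_potency(ag_active, ag_active & (signature > 0))
    potency_ant = _draw_potency(ant_active, ant_active & (signature > 0))

    # structural clusters: agonists confined to designated clusters
    n_ag_clusters = max(1, int(np.round(cfg.agonist_cluster_fraction * cfg.n_clusters)))
    agonist_clusters = np.arange(1, n_ag_clusters + 1)
    cluster = rng.integers(1, cfg.n_clusters + 1, size=n)
    cluster[ag_active] = rng.choice(agonist_clusters, size=int(ag_active.sum()))

    prototypes = (rng.random((cfg.n_clusters, cfg.fingerprint_length)) < cfg.bit_density).astype(np.uint8)
    flips = (rng.random((n, cfg.fingerprint_length)) < cfg.flip_noise).astype(np.uint8)
    bits = prototypes[cluster - 1] ^ flips

    qsar_ag = np.where(
        ag_active,
        rng.random(n) < cfg.qsar_sensitivity,
        rng.random(n) < cfg.qsar_false_positive_rate,
    )
    qsar_ant = np.where(
        ant_active,
        rng.random(n) < cfg.qsar_sensitivity,
        rng.random(n) < cfg.qsar_false_positive_rate,
    )
    henry = 10.0 ** rng.uniform(*cfg.henry_log10_range, size=n)

    chemicals = pd.DataFrame(
        {
            "chemical_id": ids,
            "truth_class": truth,
            "cluster_truth": cluster,
            "signature_assay": signature,
            "potency_agonist": potency_ag,
            "potency_antagonist": potency_ant,
            "qsar_agonist": qsar_ag.astype(int),
            "qsar_antagonist": qsar_ant.astype(int),
            "henrys_law_constant": henry,
        }
    )
    hit_calls = pd.DataFrame(
        hits,
        index=pd.Index(ids, name="chemical_id"),
        columns=[f"A{i}" for i in range(1, NUM_ASSAYS + 1)],
    )
    fps = FingerprintSet(ids=tuple(ids), bits=bits)
    return SyntheticDataset(
        chemicals=chemicals, fingerprints=fps, hit_calls=hit_calls, config=cfg, seed=seed, roster=roster
    )


def noiseless_config(**overrides) -> GeneratorConfig:
    """Config for the deterministic limit: perfect hits, no structure noise."""
    base = GeneratorConfig(
        tpr_broad=1.0,
        fpr=0.0,
        flip_noise=0.0,
        narrow_fraction_antagonist=0.0,
        narrow_fraction_agonist=0.0,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# Printed-table fixtures
# ---------------------------------------------------------------------------

#: 2x2 model-agreement cells between the expanded 14-assay model and the
#: original 11-assay model over their 1,817 shared chemicals:
#: (both active, 14-assay only, 11-assay only, both inactive).
TABLE1_CELLS = {
    "antagonist": (173, 74, 10, 1560),
    "agonist": (21, 7, 12, 1777),
}


def table1_calls(mode: Mode) -> tuple[pd.Series, pd.Series]:
    """Call vectors (14-assay model, 11-assay model) realizing the agreement cells."""
    both, only14, only11, neither = TABLE1_CELLS[mode]
    n = both + only14 + only11 + neither
    ids = [f"CHEM{i:05d}" for i in range(1, n + 1)]
    calls14 = np.zeros(n, dtype=int)
    calls11 = np.zeros(n, dtype=int)
    calls14[: both + only14] = 1
    calls11[:both] = 1
    calls11[both + only14 : both + only14 + only11] = 1
    idx = pd.Index(ids, name="chemical_id")
    return (
        pd.Series(calls14, index=idx, name="model_14"),
        pd.Series(calls11, index=idx, name="model_11"),
    )


#: The 13 antagonist subset models pairing with the single agonist subset
#: model in the published 9-assay battery, with their printed antagonist
#: sensitivity/specificity.
TABLE4_AGONIST_MODEL = "A00101011101000"
TABLE4_ANTAGONIST_ROWS = (
    ("A00101000000111", 0.952, 0.952),
    ("A00001010000111", 0.952, 0.934),
    ("A00001000001111", 0.952, 0.934),
    ("A00001001000111", 0.952, 0.934),
    ("A00101000001111", 0.952, 0.955),
    ("A00101010000111", 0.952, 0.954),
    ("A00001001001111", 0.952, 0.936),
    ("A00001011000111", 0.952, 0.936),
    ("A00001010001111", 0.952, 0.934),
    ("A00101010001111", 0.952, 0.955),
    ("A00001011001111", 0.952, 0.936),
    ("A00101010101111", 0.952, 0.957),
    ("A00101011101111", 0.952, 0.959),
)


def table4_pairs() -> pd.DataFrame:
    """The 9-assay-battery model pairs with their printed antagonist metrics."""
    return pd.DataFrame(
        {
            "agonist_model": TABLE4_AGONIST_MODEL,
            "antagonist_model": [r[0] for r in TABLE4_ANTAGONIST_ROWS],
            "antagonist_sensitivity": [r[1] for r in TABLE4_ANTAGONIST_ROWS],
            "antagonist_specificity": [r[2] for r in TABLE4_ANTAGONIST_ROWS],
        }
    )


def table5_batteries() -> pd.DataFrame:
    """Constrained minimal batteries (5-9 assays) with their hosted models."""
    rows = [
        (5, "A00001000001111", "A00000000001001", 64.30, 92.60),
        (6, "A00001011000111", "A00001011000000", 71.40, 98.90),
        (7, "A00001011001111", "A00001011001001", 71.40, 99.00),
        (8, "A00101010101111", "A00101010101101", 85.0, 99.0),
        (9, "A00101011101111", "A00101011101000", 96.0, 97.70),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "battery_size",
            "antagonist_model",
            "agonist_model",
            "agonist_sensitivity_pct",
            "agonist_specificity_pct",
        ],
    )


def table6_scenarios() -> pd.DataFrame:
    """Costed testing scenarios over the 4,235-chemical prediction universe.

    ``chemical_counts`` and ``battery_sizes`` are per-stage tuples; the
    multi-stage row uses the published mean stage-2 load.
    """
    rows = [
        ("13-assay single model", (4235,), (13,)),
        ("9-assay battery", (4235,), (9,)),
        ("6-assay battery", (4235,), (6,)),
        ("cluster-based", (387, 3848), (9, 5)),
        ("multi-stage", (4235, 988), (6, 3)),
    ]
    return pd.DataFrame(rows, columns=["scenario", "chemical_counts", "battery_sizes"])
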