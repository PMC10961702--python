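"""CSV/TOML interchange formats, schema validation, and run manifests.

All tabular interchange is comma-separated UTF-8 with a mandatory header row.
Readers validate required columns (schema errors name the missing column),
reject duplicate keys, and preserve unknown columns; write-then-read round
trips are stable up to column order.  Scenario configuration is TOML
(stdlib ``tomllib``).  Every CLI run emits a JSON manifest with the tool
version, input digests, config echo and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
import tomllib

import pandas as pd

from . import __version__
from .clustering import FingerprintSet
from .prioritization import SimulationResult, StageSpec


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _read_csv(path, required: list[str], key: list[str] | None, name: str, dtype=None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=dtype)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing required column(s): {', '.join(missing)}")
    if key:
        dup = df.duplicated(subset=key)
        if dup.any():
            examples = df.loc[dup, key].head(5).to_dict("records")
            raise SchemaError(f"{name} table has duplicate key rows on {key}: {examples}")
    return df


# --- AUC and call tables ----------------------------------------------------

AUC_KEY = ["chemical_id", "model_name", "mode"]


def read_auc_table(path) -> pd.DataFrame:
    return _read_csv(path, AUC_KEY + ["auc"], AUC_KEY, "auc")


def write_auc_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_calls(path) -> pd.DataFrame:
    return _read_csv(path, AUC_KEY + ["call"], AUC_KEY, "calls")


def write_calls(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_call_vector(path) -> pd.Series:
    """Single-model call vector: columns chemical_id, call."""
    df = _read_csv(path, ["chemical_id", "call"], ["chemical_id"], "call vector")
    return df.set_index("chemical_id")["call"].astype(int)


def write_call_vector(calls: pd.Series, path) -> None:
    calls.rename("call").rename_axis("chemical_id").reset_index().to_csv(path, index=False)


# --- model summaries --------------------------------------------------------

SUMMARY_REQUIRED = [
    "model_name",
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


def read_summaries(path) -> pd.DataFrame:
    df = _read_csv(path, SUMMARY_REQUIRED, ["model_name", "mode"], "summaries")
    return df.set_index("model_name")


def write_summaries(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, index=False)


# --- fingerprints, clusters, cluster labels ---------------------------------


def read_fingerprints(path) -> FingerprintSet:
    # bits must be read as strings: leading zeros are significant
    df = _read_csv(path, ["chemical_id", "bits"], ["chemical_id"], "fingerprints", dtype={"bits": str})
    lengths = df["bits"].str.len().unique()
    if len(lengths) > 1:
        raise SchemaError(f"fingerprint bitstrings have inconsistent lengths: {sorted(lengths)}")
    if not df["bits"].str.fullmatch("[01]+").all():
        raise SchemaError("fingerprint bitstrings must contain only 0/1")
    return FingerprintSet.from_frame(df)


def write_fingerprints(fps: FingerprintSet, path) -> None:
    fps.to_frame().to_csv(path, index=False)


def read_clusters(path) -> pd.Series:
    df = _read_csv(path, ["chemical_id", "cluster_id"], ["chemical_id"], "clusters")
    return df.set_index("chemical_id")["cluster_id"].astype(int)


def write_clusters(labels: pd.Series, path) -> None:
    labels.rename("cluster_id").reset_index().to_csv(path, index=False)


def read_cluster_labels(path) -> pd.DataFrame:
    df = _read_csv(
        path,
        ["cluster_id", "label", "n_agonist", "n_antagonist", "n_both", "n_inactive"],
        ["cluster_id"],
        "cluster labels",
    )
    return df.set_index("cluster_id")


def write_cluster_labels(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, index=False)


# --- hit calls and chemicals (generator outputs) ----------------------------


def read_hit_calls(path) -> pd.DataFrame:
    assay_cols = [f"A{i}" for i in range(1, 15)]
    df = _read_csv(path, ["chemical_id"] + assay_cols, ["chemical_id"], "hit calls")
    return df.set_index("chemical_id")[assay_cols]


def write_hit_calls(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, index=False)


def read_chemicals(path) -> pd.DataFrame:
    return _read_csv(path, ["chemical_id"], ["chemical_id"], "chemicals")


def write_chemicals(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# --- scenario configuration (TOML) -------------------------------------------


def read_scenario_config(path) -> dict:
    """Scenario config: [stage1]/[stage2] tables plus top-level simulation keys.

    Recognized stage keys mirror :class:`~arbattery.prioritization.StageSpec`;
    top-level keys: n_runs, seed, sampling, antagonist_weight.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    for stage in ("stage1", "stage2"):
        if stage not in cfg:
            raise SchemaError(f"scenario config missing [{stage}] table")
    return cfg


def stage_from_config(table: dict) -> StageSpec:
    known = {
        "battery_size",
        "agonist_sensitivity",
        "agonist_specificity",
        "antagonist_sensitivity",
        "antagonist_specificity",
        "selector",
    }
    unknown = set(table) - known
    if unknown:
        raise SchemaError(f"unknown stage config key(s): {sorted(unknown)}")
    return StageSpec(**table)


# --- simulation results -------------------------------------------------------


def write_simulation_result(result: SimulationResult, csv_path, json_path) -> None:
    result.per_run.reset_index().to_csv(csv_path, index=False)
    agg = result.aggregate()
    payload = {
        "n_runs": result.n_runs,
        "seed": result.seed,
        "settings": result.settings,
        "aggregates": {col: agg[col].to_dict() for col in agg.columns},
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def read_simulation_runs(path) -> pd.DataFrame:
    return _read_csv(
        path,
        ["run", "n_stage2_chemicals", "chemical_assay_pairs", "agonist_detection_sensitivity"],
        ["run"],
        "simulation runs",
    ).set_index("run")


# --- roster -------------------------------------------------------------------


def read_roster(path):
    from .subset_models import Assay, AssayRoster

    df = _read_csv(
        path,
        ["index", "endpoint_name", "role", "in_agonist_pathway", "in_antagonist_pathway"],
        ["index"],
        "roster",
    )
    df["idx"] = df["index"].astype(str).str.lstrip("A").astype(int)
    df = df.sort_values("idx")
    assays = tuple(Assay(int(r.idx), r.endpoint_name, r.role) for r in df.itertuples())
    return AssayRoster(
        assays=assays,
        agonist_pathway=frozenset(df.loc[df["in_agonist_pathway"] == 1, "idx"]),
        antagonist_pathway=frozenset(df.loc[df["in_antagonist_pathway"] == 1, "idx"]),
    )


def write_roster(roster, path) -> None:
    rows = [
        {
            "index": a.label,
            "endpoint_name": a.endpoint_name,
            "role": a.role,
            "in_agonist_pathway": int(a.index in roster.agonist_pathway),
            "in_antagonist_pathway": int(a.index in roster.antagonist_pathway),
        }
        for a in roster.assays
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- run manifest -------------------------------------------------------------


@dataclass(frozen=True)
class RunManifest:
    tool_version: str
    command: str
    inputs: dict[str, str]  # path -> sha256
    config: dict
    seed: int | None
    timestamp: str


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    inputs: dict[str, str | Path],
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    manifest = RunManifest(
        tool_version=__version__,
        command=command,
        inputs={name: _digest(p) for name, p in inputs.items()},
        config=config or {},
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
    return path
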