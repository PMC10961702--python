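"""Chemical-structure clustering and cluster activity labeling.

Chemicals are described by fixed-length binary structural fingerprints
(ToxPrint-style bit vectors).  Pairwise Tanimoto distances
``D = 1 - |a AND b| / |a OR b|`` feed Ward's hierarchical clustering; the tree
is cut at a fixed height (1.0 by default) to define the final clusters, and
new chemicals are assigned to existing clusters by 1-nearest-neighbor search.
Clusters are then labeled by the activity of the chemicals they contain, and
a Henry's-law-constant filter removes chemicals too volatile for reliable in
vitro screening.

Ward linkage here is the squared-distance (D2) update applied directly to the
Tanimoto distance matrix.  Tanimoto distances are not Euclidean, so this is a
standard approximation rather than an exact minimum-variance criterion; the
``method`` argument of :func:`ward_cluster` accepts any scipy linkage method
if a different criterion is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist, squareform


@dataclass(frozen=True)
class FingerprintSet:
    """Binary fingerprints for a set of chemicals (rows) over fixed bit length."""

    ids: tuple[str, ...]
    bits: np.ndarray  # (n_chemicals, n_bits), entries 0/1

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 2 or bits.shape[0] != len(self.ids):
            raise ValueError("bits must be a (n_chemicals, n_bits) array matching ids")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate chemical ids in fingerprint set")
        object.__setattr__(self, "bits", bits.astype(np.uint8))

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chemical_id": self.ids, "bits": ["".join(map(str, row)) for row in self.bits]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FingerprintSet":
        ids = tuple(df["chemical_id"].astype(str))
        bits = np.array([[int(c) for c in s] for s in df["bits"]], dtype=np.uint8)
        return cls(ids=ids, bits=bits)


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) distance between two equal-length bit vectors.

    Two all-zero fingerprints are treated as identical (distance 0); an
    all-zero against a non-empty fingerprint has distance 1.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return 1.0 - int(np.sum(a & b)) / union


def pairwise_tanimoto(fps: FingerprintSet) -> np.ndarray:
    """Square symmetric Tanimoto distance matrix over a fingerprint set."""
    # scipy's 'jaccard' on boolean vectors is exactly the Tanimoto distance,
    # with the same 0-for-empty-pair convention.
    return squareform(pdist(fps.bits.astype(bool), metric="jaccard"))


@dataclass(frozen=True)
class ClusterModel:
    """Hierarchical merge tree over a fixed chemical set.

    ``linkage`` is a scipy linkage matrix (merge heights non-decreasing);
    ``ids`` gives the leaf order.
    """

    ids: tuple[str, ...]
    linkage: np.ndarray
    method: str = "ward"
    cut_height: float = 1.0
    labels: pd.Series = field(default=None, compare=False)  # populated by cut()

    def cut(self, height: float | None = None) -> pd.Series:
        return cut_tree(self, self.cut_height if height is None else height)


def ward_cluster(
    distances: np.ndarray,
    ids: Sequence[str],
    method: str = "ward",
) -> ClusterModel:
    """Agglomerate a precomputed distance matrix into a merge tree.

    ``distances`` must be square, symmetric, non-negative, with a zero
    diagonal.  The default ``method='ward'`` applies the D2-style Ward update
    directly to the supplied distances.  Deterministic given input order.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] != len(ids):
        raise ValueError("distance matrix size does not match ids")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix entries must be non-negative")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return ClusterModel(ids=tuple(ids), linkage=Z, method=method)


def cut_tree(tree: ClusterModel, height: float = 1.0) -> pd.Series:
    """Flat clusters from merges below ``height``.

    Returns a Series mapping chemical_id -> integer cluster id.  Cluster ids
    are canonicalized so that cluster 1 is the cluster containing the
    lexicographically smallest chemical id, making the labeling invariant to
    input order of chemicals with identical structure.
    """
    if height < 0:
        raise ValueError(f"cut height must be non-negative, got {height}")
    raw = hierarchy.fcluster(tree.linkage, t=height, criterion="distance")
    labels = pd.Series(raw, index=pd.Index(tree.ids, name="chemical_id"), name="cluster_id")
    # canonical relabeling: clusters numbered by their smallest member id
    order = {}
    for chem in sorted(labels.index):
        c = labels[chem]
        if c not in order:
            order[c] = len(order) + 1
    return labels.map(order).astype(int)


def assign_knn(
    query: np.ndarray,
    reference: FingerprintSet,
    labels: pd.Series,
    k: int = 1,
) -> int:
    """Cluster id for a query fingerprint by k-nearest-neighbor vote (k=1 default).

    Distance is Tanimoto.  Ties (equal distance at k=1, or tied votes at
    k>1) are broken deterministically by lowest cluster id, then
    lexicographically smallest chemical id.
    """
    if len(reference) == 0:
        raise ValueError("reference fingerprint set is empty")
    if not 1 <= k <= len(reference):
        raise ValueError(f"k must be in 1..{len(reference)}")
    q = np.asarray(query, dtype=bool).reshape(1, -1)
    if q.shape[1] != reference.n_bits:
        raise ValueError(f"query length {q.shape[1]} != reference bit length {reference.n_bits}")
    d = cdist(q, reference.bits.astype(bool), metric="jaccard").ravel()
    lab = labels.reindex(reference.ids)
    if lab.isna().any():
        missing = [i for i in reference.ids if pd.isna(labels.get(i))][:10]
        raise ValueError(f"labels missing for reference chemicals: {missing}")
    # order neighbors by (distance, cluster id, chemical id) for determinism
    keys = sorted(
        range(len(reference)),
        key=lambda i: (d[i], int(lab.iloc[i]), reference.ids[i]),
    )
    nearest = keys[:k]
    votes: dict[int, int] = {}
    for i in nearest:
        votes[int(lab.iloc[i])] = votes.get(int(lab.iloc[i]), 0) + 1
    top = max(votes.values())
    return min(c for c, v in votes.items() if v == top)


CLUSTER_CATEGORIES = ("agonist-active", "antagonist-active", "both-effect", "no-effect")


def label_clusters(
    labels: pd.Series,
    agonist_calls: pd.Series,
    antagonist_calls: pd.Series,
) -> pd.DataFrame:
    """Activity label and per-category chemical counts for each cluster.

    A cluster is *both-effect* iff it contains at least one agonist-positive
    and at least one antagonist-positive chemical (possibly the same one);
    otherwise it is agonist-active / antagonist-active / no-effect by simple
    containment.  Chemicals missing from a call vector are treated as
    inactive for that mode and reported in the ``n_missing_calls`` column.

    Returns a DataFrame indexed by cluster_id with columns label, n_agonist
    (agonist-only chemicals), n_antagonist (antagonist-only), n_both,
    n_inactive, n_missing_calls.
    """
    chems = labels.index
    ag = agonist_calls.reindex(chems)
    ant = antagonist_calls.reindex(chems)
    n_missing = (ag.isna() | ant.isna()).groupby(labels).sum().astype(int)
    ag = ag.fillna(0).astype(bool)
    ant = ant.fillna(0).astype(bool)
    grp = pd.DataFrame(
        {
            "cluster_id": labels,
            "both": (ag & ant),
            "agonist_only": (ag & ~ant),
            "antagonist_only": (~ag & ant),
            "inactive": (~ag & ~ant),
        }
    ).groupby("cluster_id").sum()
    has_ag = (grp["both"] + grp["agonist_only"]) > 0
    has_ant = (grp["both"] + grp["antagonist_only"]) > 0
    label = np.select(
        [has_ag & has_ant, has_ag, has_ant],
        ["both-effect", "agonist-active", "antagonist-active"],
        default="no-effect",
    )
    out = pd.DataFrame(
        {
            "label": label,
            "n_agonist": grp["agonist_only"].astype(int),
            "n_antagonist": grp["antagonist_only"].astype(int),
            "n_both": grp["both"].astype(int),
            "n_inactive": grp["inactive"].astype(int),
            "n_missing_calls": n_missing.reindex(grp.index).fillna(0).astype(int),
        },
        index=grp.index,
    )
    return out


@dataclass(frozen=True)
class VolatilityThresholds:
    """Henry's-law-constant cutoffs (atm*m3/mol) between volatility categories.

    ``high`` > high cutoff; ``moderate`` in (moderate, high]; ``slight`` in
    (slight, moderate]; ``none`` at or below the slight cutoff.  The defaults
    are configurable placeholders, not regulatory values.
    """

    high: float = 1e-3
    moderate: float = 1e-5
    slight: float = 1e-7

    def __post_init__(self) -> None:
        if not self.high > self.moderate > self.slight > 0:
            raise ValueError("thresholds must be strictly decreasing and positive")

    def category(self, h: float) -> str:
        if pd.isna(h):
            return "unknown"
        if h > self.high:
            return "high"
        if h > self.moderate:
            return "moderate"
        if h > self.slight:
            return "slight"
        return "none"


@dataclass(frozen=True)
class VolatilityResult:
    retained: tuple[str, ...]
    removed: tuple[str, ...]
    flagged_missing: tuple[str, ...]
    table: pd.DataFrame  # chemical_id index, columns henrys_law_constant, category, retained


def volatility_filter(
    records: pd.DataFrame,
    thresholds: VolatilityThresholds | None = None,
) -> VolatilityResult:
    """Drop chemicals categorized as high/moderate volatility.

    ``records`` needs columns chemical_id and henrys_law_constant.  Chemicals
    with a missing constant are retained but flagged (never silently
    dropped).
    """
    thresholds = thresholds or VolatilityThresholds()
    if not {"chemical_id", "henrys_law_constant"} <= set(records.columns):
        raise ValueError("records require columns chemical_id and henrys_law_constant")
    tab = records.set_index("chemical_id").copy()
    tab["category"] = tab["henrys_law_constant"].map(thresholds.category)
    tab["retained"] = ~tab["category"].isin(("high", "moderate"))
    return VolatilityResult(
        retained=tuple(tab.index[tab["retained"]]),
        removed=tuple(tab.index[~tab["retained"]]),
        flagged_missing=tuple(tab.index[tab["category"] == "unknown"]),
        table=tab,
    )
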