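"""Clustering of daily rest profiles within a shift group.

Each subject is represented by the concatenation of their work-day and
free-day rest profiles, both anchored 20:00 -> 19:59 at 5-min resolution
(2 x 288 = 576 elements).  Subjects are grouped by agglomerative
clustering with Ward's linkage on the Euclidean distance; the number of
clusters is chosen by the elbow of the within-cluster sum of squares

    W_k = sum_m (1 / (2 n_m)) * sum_{i,j in C_m} d(x_i, x_j)^2,

with d the Euclidean distance — the squared-distance reading makes W_k the
within-cluster sum of squares (about cluster centroids) that Ward's method
minimizes.  Profiles are probabilities already and are not standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import kruskal

from .metrics import N_SLOTS, RestProfile

__all__ = [
    "ProfileVector",
    "ClusterResult",
    "profile_vector",
    "within_cluster_ss",
    "ward_cluster",
    "elbow_select",
    "cluster_summary",
]

CLUSTER_ANCHOR_H = 20.0


@dataclass
class ProfileVector:
    """576-element work||free rest-profile vector, anchored at 20:00."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (2 * N_SLOTS,):
            raise ValueError(f"profile vector must have {2 * N_SLOTS} elements")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("profile vector entries must lie in [0, 1]")


def profile_vector(work: RestProfile, free: RestProfile,
                   subject_id: str | None = None) -> ProfileVector:
    """Concatenate the work-day and free-day profiles (work first); both
    must already be anchored at 20:00."""
    for prof, name in ((work, "work"), (free, "free")):
        if abs(prof.anchor_h - CLUSTER_ANCHOR_H) > 1e-9:
            raise ValueError(f"{name} profile must be anchored at 20:00, "
                             f"got {prof.anchor_h:g}:00")
    sid = subject_id or work.subject_id or "?"
    return ProfileVector(subject_id=sid,
                         values=np.concatenate([work.values, free.values]))


def within_cluster_ss(X: np.ndarray, labels: np.ndarray) -> float:
    """W_k with d = squared Euclidean distance; equals the summed squared
    deviations from cluster centroids."""
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


@dataclass
class ClusterResult:
    subject_ids: list[str]
    linkage_matrix: np.ndarray
    wk: np.ndarray  # W_k for k = 1..kmax
    chosen_k: int
    labels: np.ndarray  # 1..k, for the chosen cut
    elbow_flag: str = ""
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "cluster": self.labels})


def elbow_select(wk: np.ndarray, tol: float = 1e-9) -> tuple[int, str]:
    """Largest-flattening elbow: argmax over k = 2..kmax-1 of the second
    difference W_{k-1} - 2 W_k + W_{k+1}; ties break to the smaller k.
    Monotone-linear W_k (no positive curvature) -> k = 1, flagged."""
    wk = np.asarray(wk, dtype=float)
    if len(wk) < 3:
        raise ValueError("elbow selection needs W_k for at least k = 1..3")
    second = wk[:-2] - 2 * wk[1:-1] + wk[2:]  # indexed by k = 2..kmax-1
    if np.max(second) <= tol:
        return 1, "no elbow"
    return int(np.argmax(second)) + 2, ""


def ward_cluster(vectors: list[ProfileVector], kmax: int = 8) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering with elbow-selected k."""
    if len(vectors) < 3:
        raise ValueError("clustering needs at least 3 subjects")
    # order-independent: sort by subject id before building the matrix
    vecs = sorted(vectors, key=lambda v: v.subject_id)
    ids = [v.subject_id for v in vecs]
    X = np.stack([v.values for v in vecs])
    Z = linkage(X, method="ward", metric="euclidean")
    kmax = min(kmax, len(vecs))
    wk = np.empty(kmax)
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, kmax + 1):
        labels_by_k[k] = fcluster(Z, t=k, criterion="maxclust")
        wk[k - 1] = within_cluster_ss(X, labels_by_k[k])
    chosen, flag = elbow_select(wk)
    chosen = max(chosen, 1)
    return ClusterResult(
        subject_ids=ids, linkage_matrix=Z, wk=wk, chosen_k=chosen,
        labels=labels_by_k[max(chosen, 1)], elbow_flag=flag,
        labels_by_k=labels_by_k,
    )


def cluster_summary(result: ClusterResult, params: pd.DataFrame,
                    value_cols: list[str] | None = None) -> pd.DataFrame:
    """Kruskal-Wallis comparison of circadian parameters across clusters.

    ``params`` is a per-subject table with a subject_id column, an optional
    scope column, and numeric parameter columns.  Returns one row per
    (scope, parameter) with the K-W p-value; singleton clusters are
    included but flagged.
    """
    labels = result.to_frame()
    if result.chosen_k < 2 and len(np.unique(result.labels)) < 2:
        raise ValueError("cluster comparison needs at least 2 clusters")
    merged = params.merge(labels, on="subject_id", how="inner")
    if value_cols is None:
        value_cols = [c for c in merged.columns
                      if c not in ("subject_id", "scope", "cluster", "flags")
                      and pd.api.types.is_numeric_dtype(merged[c])]
    sizes = merged.groupby("cluster")["subject_id"].nunique()
    flag = "singleton-cluster" if (sizes == 1).any() else ""
    scopes = merged["scope"].unique() if "scope" in merged else [None]
    rows = []
    for scope in scopes:
        sub = merged if scope is None else merged[merged["scope"] == scope]
        for col in value_cols:
            groups = [g[col].dropna().to_numpy()
                      for _, g in sub.groupby("cluster") if g[col].notna().any()]
            if len(groups) < 2:
                continue
            try:
                stat, p = kruskal(*groups)
            except ValueError:  # all values identical
                stat, p = np.nan, 1.0
            rows.append({"scope": scope or "all", "parameter": col,
                         "kw_statistic": stat, "p_value": p, "flags": flag})
    return pd.DataFrame(rows)
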