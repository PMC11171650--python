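"""Unsupervised stage: label encoding, PCA and iterated K-means.

The feature space mirrors the published procedure: each lesion contributes
(dx_code, fd), where dx_code integer-encodes the diagnosis (or a coarser
group label) in sorted label order and fd is the box-counting dimension.
Because dx_code (0..L-1) and fd (~1.6-1.9) live on incommensurate scales,
both columns are standardized by default; ``scaling="none"`` reproduces the
raw-scale behaviour of the original analysis.  Note that clustering on an
encoded *label* column leaks the classification into the features — the
cluster report flags this; ``fd_only=True`` clusters on FD alone.

K-means is run as best-of-``restarts`` Lloyd optimizations (greedy k-means++
seeding per restart, seeded RNG) keeping the lowest inertia; silhouette and
inertia quantify cluster quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score as _sk_silhouette

from .errors import DegenerateInputError
from .grouping import GroupingScheme, LesionRecord, assign_groups


@dataclass
class FeatureMatrix:
    """Rows = lesions; columns = (dx_code, fd) or (fd,) in fd-only mode."""

    X: np.ndarray  # float, shape (n, n_features)
    ids: list[str]
    labels: list[str]
    encoder: dict[str, int]  # label -> code, bijective over labels present
    scaling: str  # "none" | "standardized"
    feature_names: tuple[str, ...] = ("dx_code", "fd")

    def decode(self, code: int) -> str:
        for label, c in self.encoder.items():
            if c == code:
                return label
        raise KeyError(code)


def encode_labels(
    records: list[LesionRecord],
    scheme: GroupingScheme | None = None,
    scaling: str = "standardized",
    fd_only: bool = False,
) -> FeatureMatrix:
    """Build the (dx_code, fd) feature matrix.

    Codes 0..L-1 are assigned in lexicographic order of the labels present.
    With ``scheme`` given, the encoded label is the record's group under that
    scheme rather than the raw diagnosis.
    """
    if not records:
        raise ValueError("no records to encode")
    if scaling not in ("none", "standardized"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if scheme is not None:
        labels = [g for _, g in assign_groups(records, scheme)]
    else:
        labels = [r.diagnosis for r in records]
    encoder = {lab: i for i, lab in enumerate(sorted(set(labels)))}
    codes = np.array([encoder[lab] for lab in labels], dtype=float)
    fds = np.array([r.fd for r in records], dtype=float)
    X = fds[:, None] if fd_only else np.column_stack([codes, fds])
    names = ("fd",) if fd_only else ("dx_code", "fd")
    if scaling == "standardized":
        sd = X.std(axis=0)
        if np.any(sd == 0):
            bad = names[int(np.argmin(sd))]
            raise DegenerateInputError(f"zero-variance feature column {bad!r}")
        X = (X - X.mean(axis=0)) / sd
    return FeatureMatrix(
        X, [r.id for r in records], labels, encoder, scaling, names
    )


@dataclass
class ClusterModel:
    """Best-of-restarts K-means output with its quality metrics."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    silhouette: float
    restarts: int
    seed: int

    def summary(self) -> str:
        sizes = np.bincount(self.assignments, minlength=self.k)
        lines = [
            f"K-means (k={self.k}, {self.restarts} restarts, seed {self.seed})",
            f"inertia    : {self.inertia:.4f}",
            f"silhouette : {self.silhouette:.4f}",
            f"sizes      : {list(map(int, sizes))}",
        ]
        return "\n".join(lines)


def kmeans_stage(
    m: FeatureMatrix, k: int, restarts: int = 100, seed: int = 0
) -> ClusterModel:
    """Best-of-``restarts`` Lloyd runs by inertia, deterministic under seed.

    Each restart seeds with greedy k-means++ and iterates Lloyd to
    convergence (tol 1e-6, max 300 sweeps).
    """
    if k < 2:
        raise ValueError("k must be >= 2 (silhouette undefined for k=1)")
    n = m.X.shape[0]
    if n < k:
        raise ValueError(f"{n} rows < k={k}")
    if np.unique(m.X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct rows")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(m.X)
    sil = float(_sk_silhouette(m.X, km.labels_))
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        assignments=km.labels_.copy(),
        inertia=float(km.inertia_),
        silhouette=sil,
        restarts=restarts,
        seed=seed,
    )


def silhouette_score(m: FeatureMatrix | np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette coefficient (Euclidean) of an assignment.

    Per row, s = (b - a) / max(a, b) with a = mean intra-cluster distance and
    b = minimal mean distance to another cluster.
    """
    X = m.X if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=float)
    assignments = np.asarray(assignments)
    if np.unique(assignments).size < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    return float(_sk_silhouette(X, assignments))


@dataclass
class PcaResult:
    """Principal components of the standardized feature matrix."""

    loadings: np.ndarray  # (components, features), orthonormal rows
    explained_variance_fraction: np.ndarray

    def summary(self) -> str:
        lines = ["PCA (standardized features)"]
        for i, (load, frac) in enumerate(
            zip(self.loadings, self.explained_variance_fraction), start=1
        ):
            lines.append(
                f"PC{i}: explained {100 * frac:.2f}%  loadings "
                + np.array2string(load, precision=4)
            )
        return "\n".join(lines)


def pca_stage(m: FeatureMatrix) -> PcaResult:
    """Eigendecomposition of the correlation structure of the features.

    Columns are standardized before decomposition regardless of the matrix's
    scaling mode; components are ordered by explained variance.
    """
    X = m.X
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 rows and >= 2 columns")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = m.feature_names[int(np.argmin(sd))]
        raise DegenerateInputError(f"zero-variance feature column {bad!r}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=X.shape[1]).fit(Z)
    return PcaResult(
        loadings=pca.components_.copy(),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def cluster_report(
    model: ClusterModel,
    records: list[LesionRecord],
    scheme: GroupingScheme | None = None,
) -> pd.DataFrame:
    """Per-cluster composition: dominant class, purity and size.

    With ``scheme`` given, composition is measured against group labels;
    otherwise against raw diagnoses.  Purity is the largest class fraction
    within the cluster.  When the encoded label was itself a clustering
    feature, purity overstates unsupervised performance (label leakage).
    """
    if len(records) != model.assignments.size:
        raise ValueError("model and records are not aligned")
    if scheme is not None:
        truth = [g for _, g in assign_groups(records, scheme)]
    else:
        truth = [r.diagnosis for r in records]
    rows = []
    for cid in range(model.k):
        members = [t for t, a in zip(truth, model.assignments) if a == cid]
        counts = pd.Series(members, dtype="object").value_counts()
        dominant = counts.index[0] if len(counts) else None
        purity = float(counts.iloc[0] / len(members)) if members else float("nan")
        rows.append(
            {
                "cluster": cid,
                "dominant": dominant,
                "purity": purity,
                "size": len(members),
            }
        )
    return pd.DataFrame(rows)
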