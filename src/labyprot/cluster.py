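"""Temporal clustering and ordination of protein profiles.

Profiles are clustered with k-means under Pearson distance: each protein's
profile is z-scored (mean 0, sd 1 across samples), after which the Pearson
distance 1 - r between two rows equals their squared Euclidean distance
divided by 2p (p = number of samples), so Lloyd iterations on the z-scored
rows minimize total Pearson distance up to that constant.  Constant
(zero-variance) profiles carry no correlation information and are excluded
before clustering with a reason code.

Cluster labels from k-means are arbitrary, so fitted clusters are renamed
C1..Ck by a fixed convention: descending centroid value at the reference
timepoint, ties broken by ascending timepoint of the centroid maximum.
For a settlement time course this names the zoospore-high clusters C1 and
C2, the late-rising cluster C3 and the early-rising cluster C4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

from .errors import ValidationError
from .io import IntensityMatrix, SampleDesign

logger = logging.getLogger(__name__)


def center_profiles(m: IntensityMatrix) -> pd.DataFrame:
    """Subtract each protein's mean over all samples (log2-centered profiles)."""
    v = m.values
    return v.sub(v.mean(axis=1, skipna=True), axis=0)


# ---------------------------------------------------------------------------
# PCA of samples


@dataclass
class PcaResult:
    variance_fraction: np.ndarray
    sample_scores: pd.DataFrame

    def __post_init__(self) -> None:
        vf = self.variance_fraction
        if np.any(vf < -1e-12) or vf.sum() > 1 + 1e-9:
            raise ValidationError("variance fractions must be nonnegative and sum to <= 1")
        if np.any(np.diff(vf) > 1e-9):
            raise ValidationError("variance fractions must be nonincreasing")


def pca_samples(m: IntensityMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples over complete protein rows (proteins are the variables)."""
    complete = m.complete_rows()
    if complete.n_proteins < 2:
        raise ValidationError("need >=2 complete protein rows for PCA")
    X = complete.values.to_numpy().T  # samples x proteins; PCA centers the columns
    k = min(X.shape) if n_components is None else n_components
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        variance_fraction=model.explained_variance_ratio_,
        sample_scores=pd.DataFrame(scores, index=complete.values.columns, columns=cols),
    )


# ---------------------------------------------------------------------------
# Pearson-distance k-means


def pearson_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation of two profiles."""
    return 1.0 - float(np.corrcoef(a, b)[0, 1])


def zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValidationError("constant profile has no Pearson distance; filter first")
    return (X - mu) / sd


class PearsonKMeans(BaseEstimator, ClusterMixin):
    """Lloyd k-means on z-scored profiles (= k-means under Pearson distance).

    Parameters
    ----------
    n_clusters : int (default 4)
    n_restarts : int (default 25) random initializations; the restart with
        the lowest inertia is kept.
    random_state : int seed; fits are deterministic given it.

    Attributes
    ----------
    labels_ : ndarray of int, cluster index per row
    cluster_centers_ : ndarray (n_clusters x n_samples), centroids in
        z-score space
    inertia_ : float, total Pearson distance of rows to their centroids
    n_iter_ : int, Lloyd iterations of the winning restart
    inertia_path_ : list of float, objective after each Lloyd iteration of
        the winning restart (nonincreasing)
    """

    def __init__(self, n_clusters: int = 4, n_restarts: int = 25,
                 max_iter: int = 300, tol: float = 1e-9, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _assign(Z: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # squared Euclidean to each center; ties go to the lower cluster index
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        return labels, d2[np.arange(len(Z)), labels]

    def _lloyd(self, Z: np.ndarray, rng: np.random.Generator):
        n, p = Z.shape
        k = self.n_clusters
        centers = Z[rng.choice(n, size=k, replace=False)].copy()
        path = []
        labels, d2 = self._assign(Z, centers)
        for it in range(1, self.max_iter + 1):
            for j in range(k):
                sel = labels == j
                if sel.any():
                    centers[j] = Z[sel].mean(axis=0)
                else:
                    # re-seed an empty cluster at the point farthest from its centroid
                    far = int(np.argmax(d2))
                    centers[j] = Z[far]
                    logger.info("re-seeded empty cluster %d at row %d", j, far)
            labels, d2 = self._assign(Z, centers)
            inertia = float(d2.sum())
            path.append(inertia)
            if len(path) > 1 and path[-2] - path[-1] <= self.tol:
                break
        return labels, centers, path[-1], len(path), path

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.n_clusters:
            raise ValidationError(
                f"need >= {self.n_clusters} profiles, got {X.shape[0]}"
            )
        Z = zscore_rows(X)
        p = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            cand = self._lloyd(Z, rng)
            if best is None or cand[2] < best[2]:
                best = cand
        labels, centers, inertia_e, n_iter, path = best
        self.labels_ = labels
        self.cluster_centers_ = centers
        # convert squared-Euclidean objective to total Pearson distance
        self.inertia_ = inertia_e / (2.0 * p)
        self.n_iter_ = n_iter
        self.inertia_path_ = [v / (2.0 * p) for v in path]
        return self

    def predict(self, X):
        Z = zscore_rows(np.asarray(X, dtype=float))
        return self._assign(Z, self.cluster_centers_)[0]


@dataclass
class ClusterModel:
    """Named temporal clusters of protein profiles."""

    k: int
    assignments: pd.Series          # protein_id -> 'C1'..'Ck'
    centroids: pd.DataFrame         # cluster name x sample (z-score space)
    inertia: float
    seed: int
    n_restarts: int
    excluded: dict[str, str] = field(default_factory=dict)  # protein -> reason

    def members(self, name: str) -> list[str]:
        return list(self.assignments.index[self.assignments == name])

    def sizes(self) -> dict[str, int]:
        return self.assignments.value_counts().sort_index().to_dict()


def _relabel(centers: np.ndarray, timepoints: np.ndarray) -> list[int]:
    """Order cluster indices by (centroid at earliest timepoint descending,
    then timepoint of centroid maximum ascending); returns old indices in
    C1..Ck order."""
    tps = sorted(set(timepoints.tolist()))
    t0 = tps[0]
    tp_means = np.stack([
        centers[:, timepoints == t].mean(axis=1) for t in tps
    ], axis=1)  # clusters x timepoints
    at_t0 = tp_means[:, tps.index(t0)]
    peak_time = np.array([tps[int(np.argmax(row))] for row in tp_means])
    order = sorted(range(len(centers)), key=lambda j: (-at_t0[j], peak_time[j]))
    return order


def kmeans_pearson(profiles: pd.DataFrame, design: SampleDesign, k: int = 4,
                   seed: int = 0, n_restarts: int = 25) -> ClusterModel:
    """Cluster centered profiles into k temporal clusters named C1..Ck.

    Constant rows are excluded (reason ``zero_variance``) before clustering.
    """
    sd = profiles.std(axis=1, ddof=0)
    excluded = {pid: "zero_variance" for pid in profiles.index[(sd == 0) | sd.isna()]}
    if excluded:
        logger.info("excluded %d constant/NaN profiles before clustering", len(excluded))
    keep = profiles.drop(index=list(excluded))
    keep = keep.dropna(axis=0)
    est = PearsonKMeans(n_clusters=k, n_restarts=n_restarts, random_state=seed)
    est.fit(keep.to_numpy())
    timepoints = design.frame.loc[list(profiles.columns), "timepoint"].to_numpy()
    order = _relabel(est.cluster_centers_, timepoints)
    name_of = {old: f"C{i + 1}" for i, old in enumerate(order)}
    assignments = pd.Series([name_of[j] for j in est.labels_], index=keep.index)
    centroids = pd.DataFrame(
        est.cluster_centers_[order], index=[f"C{i + 1}" for i in range(k)],
        columns=profiles.columns,
    )
    return ClusterModel(k=k, assignments=assignments, centroids=centroids,
                        inertia=est.inertia_, seed=seed, n_restarts=n_restarts,
                        excluded=excluded)


# ---------------------------------------------------------------------------
# cluster x significance accounting


def cluster_pattern_stats(model: ClusterModel, contrasts: pd.DataFrame,
                          unions: dict[str, tuple[str, ...]] | None = None) -> pd.DataFrame:
    """Per cluster (and optional cluster unions): size and count/fraction of
    members significantly up or down at each timepoint contrast."""
    sig = contrasts[contrasts["significant"]]
    tps = list(contrasts["contrast"].unique())
    groups: dict[str, list[str]] = {name: model.members(name) for name in model.centroids.index}
    for uname, parts in (unions or {}).items():
        groups[uname] = [p for part in parts for p in model.members(part)]
    rows = []
    for name, members in groups.items():
        mset = set(members)
        row: dict[str, object] = {"cluster": name, "size": len(members)}
        for c in tps:
            for direction in ("up", "down"):
                n = int(((sig["contrast"] == c) & (sig["direction"] == direction)
                         & sig["protein_id"].isin(mset)).sum())
                row[f"n_{direction}_{c}"] = n
                row[f"frac_{direction}_{c}"] = n / len(members) if members else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
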