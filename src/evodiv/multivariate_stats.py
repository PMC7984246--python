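"""Distance-based multivariate comparison of population variant profiles.

Populations are embedded as rows of a feature matrix (columns = union of
variant keys, entries = variant proportions, 0 where absent); treatment
groups are then compared on the Euclidean distance matrix with:

* PERMANOVA — pseudo-F from the partition of squared inter-point
  distances, with a permutation p-value obtained by reshuffling group
  labels over whole samples:

      SS_total  = (1/n)   sum_{i<j} d_ij^2
      SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
      pseudo-F  = ((SS_total - SS_within)/(a-1)) / (SS_within/(n-a))

  p = (1 + #{F_perm >= F_obs}) / (n_perm + 1), so p > 0 always.
* beta-dispersion — distances from each sample to its group centroid in
  principal-coordinate space, compared between groups by one-way ANOVA
  (a homogeneity-of-multivariate-dispersion test).
* NMDS — non-metric multidimensional scaling for visualisation, with
  Kruskal stress-1 reported (delegated to scikit-learn's SMACOF
  optimiser with seeded random restarts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .pool_diversity import VariantTable
from .stats_core import FTestResult, lm_f_test

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "DispersionResult",
    "NMDSResult",
    "variant_feature_matrix",
    "euclidean_distances",
    "permanova",
    "betadisper",
    "nmds",
    "plot_ordination",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled samples."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    seed: int | None


@dataclass(frozen=True)
class DispersionResult:
    labels: list[str]
    distance_to_centroid: np.ndarray
    group_means: dict[str, float]
    anova: FTestResult


@dataclass(frozen=True)
class NMDSResult:
    labels: list[str]
    coordinates: np.ndarray
    stress: float  # Kruskal stress-1


def variant_feature_matrix(tables: Iterable[VariantTable]) -> pd.DataFrame:
    """Populations x variants proportion matrix (absent variant = 0).

    Columns are the union of variant keys across populations, labelled
    ``chrom:pos:ref:alt`` and sorted; rows are population ids in input
    order.  Duplicate population ids are an error.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least two populations")
    ids = [t.population_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate population ids")
    all_keys = sorted(set().union(*(t.keys for t in tables)))
    columns = [f"{c}:{p}:{r}:{a}" for c, p, r, a in all_keys]
    mat = pd.DataFrame(0.0, index=pd.Index(ids, name="population_id"), columns=columns)
    for t in tables:
        for rec in t.records:
            mat.loc[t.population_id, f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}"] = (
                rec.proportion
            )
    return mat


def euclidean_distances(features: pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise Euclidean distances between feature-matrix rows."""
    if isinstance(features, pd.DataFrame):
        labels = [str(i) for i in features.index]
        values = features.to_numpy(dtype=float)
    else:
        values = np.asarray(features, dtype=float)
        labels = [str(i) for i in range(values.shape[0])]
    return DistanceMatrix(labels, squareform(pdist(values, metric="euclidean")))


def _permanova_ss(d2: np.ndarray, group_idx: np.ndarray, n_groups: int) -> float:
    """Within-group sum of squared distances, each group scaled by 1/n_g."""
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(group_idx == g)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub.sum() / 2.0 / len(members)
    return ss_within


def permanova(
    dist: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Group labels are permuted over whole samples (no strata); the observed
    statistic is included in both numerator and denominator of the
    permutation p-value.  A degenerate SS_within of 0 yields pseudo-F
    = +inf with the p-value still taken from the permutations.
    """
    groups = np.asarray(groups)
    if len(groups) != len(dist):
        raise ValueError("one group label per sample required")
    labels, idx = np.unique(groups, return_inverse=True)
    a, n = len(labels), len(dist)
    if a < 2:
        raise ValueError("need at least two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = dist.d**2
    ss_total = d2.sum() / 2.0 / n

    def pseudo_f(perm_idx: np.ndarray) -> float:
        ss_within = _permanova_ss(d2, perm_idx, a)
        if ss_within == 0.0:
            return np.inf
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(idx)
    ss_within_obs = _permanova_ss(d2, idx, a)
    r2 = (ss_total - ss_within_obs) / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(idx)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, seed)


def principal_coordinates(dist: DistanceMatrix, tol: float = 1e-9) -> np.ndarray:
    """Classical PCoA embedding of a distance matrix.

    Gower-centres -d^2/2 and keeps the eigenvectors of positive eigenvalue
    scaled to sqrt(eigenvalue).  For Euclidean input this reproduces the
    original configuration up to rotation; negative eigenvalues (possible
    for non-Euclidean input) are dropped.
    """
    d2 = dist.d**2
    n = len(dist)
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh(gower)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > tol * max(eigval.max(), 1.0)
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def betadisper(dist: DistanceMatrix, groups: Sequence) -> DispersionResult:
    """Homogeneity-of-dispersion test: distance to group centroid + ANOVA.

    Samples are embedded by principal-coordinate decomposition; each
    sample's distance to its own group centroid is computed there, and the
    per-group mean dispersions are compared with a one-way ANOVA F test.
    """
    groups = np.asarray(groups)
    if len(groups) != len(dist):
        raise ValueError("one group label per sample required")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    coords = principal_coordinates(dist)
    d_to_centroid = np.empty(len(dist))
    for lab in labels:
        members = groups == lab
        centroid = coords[members].mean(axis=0)
        d_to_centroid[members] = np.linalg.norm(coords[members] - centroid, axis=1)
    anova = lm_f_test(d_to_centroid, groups)
    means = {str(lab): float(d_to_centroid[groups == lab].mean()) for lab in labels}
    return DispersionResult(list(dist.labels), d_to_centroid, means, anova)


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    seed: int | None = None,
    n_init: int = 8,
    max_iter: int = 500,
) -> NMDSResult:
    """Non-metric multidimensional scaling with Kruskal stress-1.

    Runs scikit-learn's non-metric SMACOF optimiser from ``n_init`` seeded
    random starts and keeps the best configuration.  Stress-1 near 0 means
    the embedding preserves the rank order of the input distances.
    """
    from sklearn.manifold import MDS

    if k >= len(dist):
        raise ValueError("embedding dimension must be below the sample count")
    if not np.any(dist.d > 0):
        raise ValueError("degenerate all-zero distance matrix")
    mds = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
    )
    coords = mds.fit_transform(dist.d)
    return NMDSResult(list(dist.labels), coords, float(mds.stress_))


def plot_ordination(result: NMDSResult, groups: Sequence, path: str) -> None:
    """NMDS scatter with group centroids, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 5))
    for marker, lab in zip("ov^sd*", np.unique(groups)):
        members = groups == lab
        xy = result.coordinates[members]
        ax.scatter(xy[:, 0], xy[:, 1], marker=marker, label=str(lab), alpha=0.8)
        cx, cy = xy[:, 0].mean(), xy[:, 1].mean()
        ax.scatter([cx], [cy], marker=marker, color="black", s=90)
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.legend()
    ax.set_title(f"stress = {result.stress:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
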