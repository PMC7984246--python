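"""Variance decomposition of clone x substrate catabolic profiles.

Each evolved population is assayed as a grid of growth endpoints (OD660):
G clones grown on S single-carbon-source substrates.  The decomposition
splits the phenotypic variation among clones into:

* ``V_P`` — total phenotypic variation, the mean Euclidean distance between
  the catabolic profiles of all clone pairs (OD units);
* ``V_G`` — genotypic variation between clones (OD^2);
* ``V_E`` — environmental variation between substrates (OD^2);
* the genotype-by-environment components
  responsiveness ``R = sum_{i != j} (sigma_i - sigma_j)^2 / 2 / (G(G-1))``
  and inconsistency ``I = sum_{i != j} sigma_i sigma_j (1 - rho_ij) / (G(G-1))``,
  where ``sigma_i`` is clone i's standard deviation of growth across
  substrates and ``rho_ij`` the Pearson correlation of the two clones'
  profiles.

High R means the population mixes generalists (flat profiles) with
specialists (peaky profiles); high I means clones rank-switch across
substrates — the signature of resource specialisation.  Sums run over
ordered pairs i != j, consistent with the G(G-1) denominator.

Sample (n-1) variances and standard deviations are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "ODMatrix",
    "ClonalProfileStats",
    "VarianceComponents",
    "filter_substrates",
    "phenotypic_variance",
    "genotypic_variance",
    "environmental_variance",
    "responsiveness",
    "inconsistency",
    "clonal_profile_stats",
    "decompose",
    "plot_reaction_norms",
]

Treatment = Literal["heterogeneous", "homogeneous"]


@dataclass
class ODMatrix:
    """One population's clone x substrate growth endpoint matrix.

    ``values[i, j]`` is the OD660 of clone ``clone_ids[i]`` on substrate
    ``substrate_ids[j]``.  All values must be non-negative.
    """

    values: np.ndarray
    clone_ids: list[str]
    substrate_ids: list[str]
    population_id: str = ""
    treatment: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.clone_ids = [str(c) for c in self.clone_ids]
        self.substrate_ids = [str(s) for s in self.substrate_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D clone x substrate grid")
        g, s = self.values.shape
        if g != len(self.clone_ids) or s != len(self.substrate_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.clone_ids)} clones x {len(self.substrate_ids)} substrates"
            )
        if np.any(np.isnan(self.values)):
            raise ValueError("missing OD values are not allowed")
        if np.any(self.values < 0):
            raise ValueError("OD values must be non-negative")

    @property
    def n_clones(self) -> int:
        return self.values.shape[0]

    @property
    def n_substrates(self) -> int:
        return self.values.shape[1]

    def subset_substrates(self, substrate_ids: Sequence[str]) -> "ODMatrix":
        """Return a copy restricted to ``substrate_ids`` (order preserved)."""
        index = {s: j for j, s in enumerate(self.substrate_ids)}
        cols = [index[s] for s in substrate_ids]
        return ODMatrix(
            self.values[:, cols],
            list(self.clone_ids),
            list(substrate_ids),
            self.population_id,
            self.treatment,
        )


@dataclass(frozen=True)
class ClonalProfileStats:
    """Per-clone profile spread and pairwise profile correlations."""

    sigma: np.ndarray  # per-clone SD across substrates, OD units
    rho: np.ndarray  # G x G Pearson correlations across substrates


@dataclass(frozen=True)
class VarianceComponents:
    """All variance components of one population's catabolic profiles.

    ``V_G`` holds the clone-mean estimator; ``V_G_substrate`` the
    alternative estimator (mean over substrates of the between-clone
    variance on each substrate) — see :func:`genotypic_variance`.
    """

    V_P: float
    V_G: float
    V_E: float
    R: float
    I: float
    V_G_substrate: float = field(default=math.nan)


def _require(matrix: ODMatrix, min_clones: int = 2, min_substrates: int = 1) -> None:
    if matrix.n_clones < min_clones:
        raise ValueError(f"need at least {min_clones} clones, got {matrix.n_clones}")
    if matrix.n_substrates < min_substrates:
        raise ValueError(
            f"need at least {min_substrates} substrates, got {matrix.n_substrates}"
        )


def filter_substrates(
    matrices: Iterable[ODMatrix], threshold: float = 0.1
) -> tuple[list[ODMatrix], list[str]]:
    """Keep only substrates on which every clone in every population grew.

    A substrate is retained iff the minimum OD over all clones of all
    populations is strictly greater than ``threshold`` (default 0.1).  The
    filter is global across the experiment, producing one common substrate
    panel; column order is preserved.

    Returns the filtered matrices and the retained substrate id list.

    Raises
    ------
    ValueError
        If the matrices do not share a substrate id set, or no substrate
        survives (review the threshold or the assay).
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices supplied")
    panel = matrices[0].substrate_ids
    for m in matrices[1:]:
        if set(m.substrate_ids) != set(panel):
            raise ValueError(
                f"population {m.population_id!r} has a different substrate set"
            )
    # min over all clones of all populations, substrate by substrate
    mins = np.full(len(panel), np.inf)
    for m in matrices:
        aligned = m.subset_substrates(panel)
        mins = np.minimum(mins, aligned.values.min(axis=0))
    retained = [s for s, lo in zip(panel, mins) if lo > threshold]
    if not retained:
        raise ValueError(
            f"no substrate exceeds OD {threshold} in every clone; "
            "review the filtering threshold"
        )
    return [m.subset_substrates(retained) for m in matrices], retained


def phenotypic_variance(matrix: ODMatrix) -> float:
    """Mean Euclidean distance between the profiles of all clone pairs."""
    _require(matrix, min_clones=2)
    return float(pdist(matrix.values, metric="euclidean").mean())


def genotypic_variance(
    matrix: ODMatrix, estimator: Literal["clone-means", "per-substrate"] = "clone-means"
) -> float:
    """Between-clone variance of growth.

    ``clone-means`` (default): sample variance of the per-clone mean growth
    across substrates — variation in overall catabolic ability between
    clones.  ``per-substrate``: the between-clone variance computed on each
    substrate separately and averaged over substrates.  Both are reported
    by :func:`decompose`.
    """
    _require(matrix, min_clones=2)
    if estimator == "clone-means":
        return float(np.var(matrix.values.mean(axis=1), ddof=1))
    if estimator == "per-substrate":
        return float(np.var(matrix.values, axis=0, ddof=1).mean())
    raise ValueError(f"unknown estimator {estimator!r}")


def environmental_variance(matrix: ODMatrix) -> float:
    """Sample variance across substrates of the mean clone growth."""
    _require(matrix, min_clones=1, min_substrates=2)
    return float(np.var(matrix.values.mean(axis=0), ddof=1))


def clonal_profile_stats(matrix: ODMatrix) -> ClonalProfileStats:
    """Per-clone profile SDs and the pairwise profile correlation matrix.

    A clone with a constant profile (sigma = 0) has undefined correlations;
    its off-diagonal rho entries are set to 1 so that the corresponding
    inconsistency pair terms vanish (the limit of a vanishing signal).
    """
    _require(matrix, min_clones=2, min_substrates=2)
    sigma = matrix.values.std(axis=1, ddof=1)
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (matrix.n_substrates - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = cov / np.outer(sigma, sigma)
    rho[~np.isfinite(rho)] = 1.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    # snap rounding-error correlations to exactly +/-1 so that identical
    # (or exactly opposite) profiles yield exact pair terms
    rho[np.abs(1.0 - rho) < 1e-12] = 1.0
    rho[np.abs(rho + 1.0) < 1e-12] = -1.0
    return ClonalProfileStats(sigma=sigma, rho=rho)


def responsiveness(matrix: ODMatrix) -> float:
    """R: spread of the clones' environmental variances.

    ``R = sum_{i != j} (sigma_i - sigma_j)^2 / 2, divided by G(G-1)``.
    Zero when every clone responds to the substrate panel with the same
    variance; large when flat generalists coexist with peaky specialists.
    """
    stats = clonal_profile_stats(matrix)
    g = matrix.n_clones
    diff = stats.sigma[:, None] - stats.sigma[None, :]
    return float((diff**2).sum() / 2.0 / (g * (g - 1)))


def inconsistency(matrix: ODMatrix) -> float:
    """I: rank-switching of clone performance across substrates.

    ``I = sum_{i != j} sigma_i sigma_j (1 - rho_ij), divided by G(G-1)``.
    Zero when all profiles are perfectly correlated; large when clones
    specialise on different substrates (negative cross-correlations).
    Pairs involving a constant clone contribute 0.
    """
    stats = clonal_profile_stats(matrix)
    g = matrix.n_clones
    terms = np.outer(stats.sigma, stats.sigma) * (1.0 - stats.rho)
    np.fill_diagonal(terms, 0.0)
    return float(terms.sum() / (g * (g - 1)))


def decompose(
    matrix: ODMatrix,
    v_g_estimator: Literal["clone-means", "per-substrate"] = "clone-means",
) -> VarianceComponents:
    """Full variance decomposition of one population's profiles.

    Expects an already-filtered matrix with G >= 2 clones and S >= 2
    substrates.  ``V_G`` carries the estimator selected by
    ``v_g_estimator``; the other estimator is always available in
    ``V_G_substrate``/``V_G`` respectively.
    """
    _require(matrix, min_clones=2, min_substrates=2)
    vg_means = genotypic_variance(matrix, "clone-means")
    vg_sub = genotypic_variance(matrix, "per-substrate")
    primary, secondary = (
        (vg_means, vg_sub) if v_g_estimator == "clone-means" else (vg_sub, vg_means)
    )
    return VarianceComponents(
        V_P=phenotypic_variance(matrix),
        V_G=primary,
        V_E=environmental_variance(matrix),
        R=responsiveness(matrix),
        I=inconsistency(matrix),
        V_G_substrate=secondary,
    )


def plot_reaction_norms(matrix: ODMatrix, path: str) -> None:
    """Reaction-norm diagnostic: each clone's growth across substrates.

    Substrates are ordered by the population mean; grey lines are clones,
    the black line the population mean profile.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(-matrix.values.mean(axis=0))
    fig, ax = plt.subplots(figsize=(8, 4))
    for row in matrix.values:
        ax.plot(row[order], color="0.6", lw=0.8)
    ax.plot(matrix.values.mean(axis=0)[order], color="black", lw=2)
    ax.set_xlabel("substrate (ranked by mean growth)")
    ax.set_ylabel("OD660")
    ax.set_title(f"population {matrix.population_id} ({matrix.treatment or 'n/a'})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
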