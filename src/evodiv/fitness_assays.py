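"""Relative fitness from mixed-culture competition assays.

An evolved clone mix (white colonies) is competed 50:50 against a
LacZ-marked ancestor (blue colonies); samples at the start (T0) and end
(T7) of the competition are plated and colony-counted.  The focal strain's
relative fitness is the odds ratio of its mixture fractions,

    w = [f_T7 (1 - f_T0)] / [f_T0 (1 - f_T7)],

which is dilution-invariant (only fractions enter).  The log-ratio of the
two strains' absolute growth, ln(N_A7/N_A0) / ln(N_B7/N_B0) — the ratio of
Malthusian parameters — is computed alongside for reference; the two
statistics agree only approximately in general, and no equivalence is
asserted.

Treatment comparisons follow the contrast structure of a two-factor
(evolution environment x competition environment) design: contrasts where
the same populations appear in both cells use a paired t test, contrasts
between disjoint population sets use Welch's t, with Holm-Bonferroni
adjustment across the requested family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats_core import holm_adjust

__all__ = [
    "CompetitionAssay",
    "FitnessResult",
    "FixationError",
    "relative_fitness",
    "malthusian_ratio",
    "assay_fitness",
    "fitness_table",
    "pairwise_contrasts",
]


class FixationError(ValueError):
    """One strain reached fixation/extinction: relative fitness undefined."""


@dataclass(frozen=True)
class CompetitionAssay:
    """Colony counts of one competition (white = evolved mix, blue = ancestor)."""

    population_id: str
    evolution_env: str
    competition_env: str
    white_T0: int
    blue_T0: int
    white_T7: int
    blue_T7: int

    def __post_init__(self) -> None:
        for name in ("white_T0", "blue_T0", "white_T7", "blue_T7"):
            count = getattr(self, name)
            if count < 0 or count != int(count):
                raise ValueError(f"{name} must be a non-negative integer, got {count}")
        if self.white_T0 + self.blue_T0 == 0 or self.white_T7 + self.blue_T7 == 0:
            raise ValueError("zero total colony count at a timepoint")


@dataclass(frozen=True)
class FitnessResult:
    relative_fitness: float
    fraction_T0: float
    fraction_T7: float
    malthusian_ratio: float | None = None


def relative_fitness(f0: float, f7: float) -> float:
    """Odds-ratio relative fitness of the focal strain.

    ``f0`` and ``f7`` are the focal strain's mixture fractions at the start
    and end of the competition; both must lie strictly inside (0, 1).

    Raises
    ------
    FixationError
        If either fraction is 0 or 1 (the odds ratio degenerates; no
        silent infinity is returned).
    """
    for name, f in (("f0", f0), ("f7", f7)):
        if not 0.0 < f < 1.0:
            raise FixationError(
                f"{name}={f}: fixation/extinction, relative fitness undefined"
            )
    return (f7 * (1.0 - f0)) / (f0 * (1.0 - f7))


def malthusian_ratio(n_A0: float, n_A7: float, n_B0: float, n_B7: float) -> float:
    """Ratio of Malthusian parameters ln(N_A7/N_A0) / ln(N_B7/N_B0).

    Assumes both strains grew (or declined) exponentially between the
    timepoints; undefined when strain B's count did not change.
    """
    if min(n_A0, n_A7, n_B0, n_B7) <= 0:
        raise ValueError("all counts must be positive")
    denom = math.log(n_B7 / n_B0)
    if denom == 0.0:
        raise ValueError("reference strain count unchanged: ratio undefined")
    return math.log(n_A7 / n_A0) / denom


def assay_fitness(assay: CompetitionAssay) -> FitnessResult:
    """Fractions and both fitness statistics for one competition assay.

    The Malthusian ratio is computed from the raw colony counts (a valid
    proxy only when both timepoints were plated at the same dilution); it
    is set to None when any count is zero or the reference is unchanged.
    """
    f0 = assay.white_T0 / (assay.white_T0 + assay.blue_T0)
    f7 = assay.white_T7 / (assay.white_T7 + assay.blue_T7)
    w = relative_fitness(f0, f7)
    try:
        m = malthusian_ratio(assay.white_T0, assay.white_T7, assay.blue_T0, assay.blue_T7)
    except ValueError:
        m = None
    return FitnessResult(w, f0, f7, m)


def fitness_table(assays: Sequence[CompetitionAssay]) -> pd.DataFrame:
    """Per-assay fitness results as a tidy table."""
    rows = []
    for a in assays:
        res = assay_fitness(a)
        rows.append(
            {
                "population_id": a.population_id,
                "evolution_env": a.evolution_env,
                "competition_env": a.competition_env,
                "fraction_T0": res.fraction_T0,
                "fraction_T7": res.fraction_T7,
                "relative_fitness": res.relative_fitness,
                "malthusian_ratio": res.malthusian_ratio,
            }
        )
    return pd.DataFrame(rows)


def _group(table: pd.DataFrame, label: tuple[str, str]) -> pd.DataFrame:
    evo, comp = label
    sel = table[(table["evolution_env"] == evo) & (table["competition_env"] == comp)]
    if sel.empty:
        raise ValueError(f"no observations for group {label!r}")
    return sel


def pairwise_contrasts(
    table: pd.DataFrame,
    comparisons: Sequence[tuple[tuple[str, str], tuple[str, str]]],
    value_col: str = "relative_fitness",
) -> pd.DataFrame:
    """Targeted contrasts between (evolution env, competition env) cells.

    Each comparison is a pair of cell labels.  When both cells contain the
    same populations (the typical "same evolved mix competed in both
    environments" contrast) a paired t test on population-matched values is
    used; otherwise Welch's t.  Raw p-values are Holm-adjusted across the
    requested family.

    Returns a table with columns contrast, estimate (mean of group1 minus
    group2), SE, df, t_ratio, p_value, p_adjusted.
    """
    rows = []
    for label1, label2 in comparisons:
        g1 = _group(table, label1)
        g2 = _group(table, label2)
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError("need at least two observations per group")
        pops1, pops2 = set(g1["population_id"]), set(g2["population_id"])
        paired = pops1 == pops2 and len(g1) == len(g2)
        if paired:
            x = g1.set_index("population_id")[value_col].sort_index().to_numpy()
            y = g2.set_index("population_id")[value_col].sort_index().to_numpy()
            diff = x - y
            n = len(diff)
            se = diff.std(ddof=1) / math.sqrt(n)
            df = float(n - 1)
            if se == 0.0 and np.mean(diff) == 0.0:  # no signal, no noise
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(x, y)
        else:
            x = g1[value_col].to_numpy()
            y = g2[value_col].to_numpy()
            se = math.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
            if se == 0.0 and np.mean(x) == np.mean(y):
                t, p, df = 0.0, 1.0, float(len(x) + len(y) - 2)
            else:
                res = stats.ttest_ind(x, y, equal_var=False)
                t, p = res.statistic, res.pvalue
                df = float(res.df)
        rows.append(
            {
                "contrast": f"{label1[0]},{label1[1]} - {label2[0]},{label2[1]}",
                "estimate": float(np.mean(x) - np.mean(y)),
                "SE": float(se),
                "df": df,
                "t_ratio": float(t),
                "paired": paired,
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_adjust(out["p_value"].to_numpy())
    return out
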