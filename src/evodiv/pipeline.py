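"""End-to-end pipeline driver: simulate -> analyse -> summarise.

Stage functions operate on in-memory domain objects and return tidy
DataFrames/result objects; the CLI and the reproduction script are thin
wrappers around them.  The simulated experiment mirrors the emulated
study design: 6 populations per treatment, 10 clones each, a 96-substrate
catabolic panel, a two-factor competition assay, and pooled variant tables
whose treatment structure includes one variant carried by every
homogeneous-environment population and one carried by 4 of 6
heterogeneous-environment populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import phenotype_gxe, pool_diversity, stats_core, synthetic_data
from .cli_io import RunConfig
from .fitness_assays import CompetitionAssay, fitness_table, pairwise_contrasts
from .multivariate_stats import (
    DispersionResult,
    NMDSResult,
    PermanovaResult,
    betadisper,
    euclidean_distances,
    nmds,
    permanova,
    variant_feature_matrix,
)
from .phenotype_gxe import ODMatrix
from .pool_diversity import VariantTable
from .synthetic_data import (
    BiologScenario,
    CompetitionScenario,
    SharedVariant,
    VariantScenario,
)

__all__ = [
    "SimulatedExperiment",
    "simulate_experiment",
    "run_gxe",
    "run_fitness",
    "run_pooldiv",
    "run_ordination",
]

# true relative fitness by (evolution env, competition env): home-environment
# advantage for heterogeneous-evolved populations, none for homogeneous-evolved
DEFAULT_TRUE_FITNESS = {
    ("heterogeneous", "heterogeneous"): 1.90,
    ("heterogeneous", "homogeneous"): 1.17,
    ("homogeneous", "homogeneous"): 1.36,
    ("homogeneous", "heterogeneous"): 1.39,
}


@dataclass
class SimulatedExperiment:
    od_matrices: list[ODMatrix]
    variant_tables: list[VariantTable]
    assays: list[CompetitionAssay]
    seeds: dict[str, int]


def simulate_experiment(config: RunConfig | None = None) -> SimulatedExperiment:
    """Simulate every input stream of one specialist-vs-generalist study."""
    config = config or RunConfig()
    root = np.random.default_rng(config.seed)
    seeds = {
        name: int(root.integers(2**31))
        for name in ("biolog_specialist", "biolog_generalist", "variants_het",
                     "variants_hom", "competition")
    }

    base = BiologScenario(
        n_populations_per_treatment=config.n_populations_per_treatment,
        n_clones=config.n_clones,
        n_substrates=config.n_substrates,
    )
    spec = synthetic_data.generate_biolog(
        BiologScenario(**{**_asdict(base), "seed": seeds["biolog_specialist"]}),
        "specialist",
    )
    gen = synthetic_data.generate_biolog(
        BiologScenario(**{**_asdict(base), "seed": seeds["biolog_generalist"]}),
        "generalist",
    )

    n_total = 2 * config.n_populations_per_treatment
    # heterogeneous-environment populations: more variants, incl. a shared
    # indel in 4 of 6 populations; homogeneous: fewer, incl. a SNP in all
    het = VariantScenario(
        n_populations=n_total,
        mean_variants_per_population=2.5,
        shared_variant_spec=(
            SharedVariant("shared_indel_het", "heterogeneous", 4 / 6, 0.95, "indel"),
        ),
        seed=seeds["variants_het"],
    )
    hom = VariantScenario(
        n_populations=n_total,
        mean_variants_per_population=1.0,
        shared_variant_spec=(
            SharedVariant("shared_snp_hom", "homogeneous", 1.0, 0.95, "SNP"),
        ),
        seed=seeds["variants_hom"],
    )
    tables = [
        t for t in synthetic_data.generate_variant_tables(het)
        if t.treatment == "heterogeneous"
    ] + [
        t for t in synthetic_data.generate_variant_tables(hom)
        if t.treatment == "homogeneous"
    ]

    assays = synthetic_data.generate_competition_experiment(
        DEFAULT_TRUE_FITNESS,
        n_populations_per_treatment=config.n_populations_per_treatment,
        base_scenario=CompetitionScenario(),
        seed=seeds["competition"],
    )
    return SimulatedExperiment(spec + gen, tables, assays, seeds)


def _asdict(scenario) -> dict:
    import dataclasses

    return dataclasses.asdict(scenario)


def run_gxe(
    matrices: Sequence[ODMatrix], threshold: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter the substrate panel, decompose every population, compare treatments.

    Returns (per-population variance components, per-component F tests of
    treatment differences).  The F tests require both treatments present.
    """
    filtered, retained = phenotype_gxe.filter_substrates(matrices, threshold)
    rows = []
    for m in filtered:
        comp = phenotype_gxe.decompose(m)
        rows.append(
            {
                "population_id": m.population_id,
                "treatment": m.treatment,
                "n_substrates_retained": len(retained),
                "V_P": comp.V_P,
                "V_G": comp.V_G,
                "V_G_substrate": comp.V_G_substrate,
                "V_E": comp.V_E,
                "R": comp.R,
                "I": comp.I,
            }
        )
    components = pd.DataFrame(rows)

    tests = []
    if components["treatment"].nunique() == 2:
        for col in ("V_P", "V_G", "V_E", "R", "I"):
            res = stats_core.lm_f_test(components[col], components["treatment"])
            tests.append(
                {
                    "component": col,
                    "F": res.statistic,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p,
                }
            )
    return components, pd.DataFrame(tests)


def run_fitness(
    assays: Sequence[CompetitionAssay],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-assay fitness plus the three targeted treatment contrasts.

    Contrasts (evolution env, competition env): home-vs-away for each
    evolution environment (paired within population), and the two
    home-environment cells against each other (Welch).
    """
    table = fitness_table(assays)
    envs = sorted(table["evolution_env"].unique())
    if len(envs) == 2:
        e1, e2 = envs
        comparisons = [
            ((e1, e1), (e1, e2)),
            ((e1, e1), (e2, e2)),
            ((e2, e1), (e2, e2)),
        ]
        contrasts = pairwise_contrasts(table, comparisons)
    else:
        contrasts = pd.DataFrame()
    return table, contrasts


def run_pooldiv(
    tables: Sequence[VariantTable], detection_floor: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diversity metrics per population and rank-sum treatment comparisons."""
    rows = []
    for t in tables:
        m = pool_diversity.diversity_metrics(t, detection_floor)
        rows.append(
            {
                "population_id": m.population_id,
                "treatment": t.treatment,
                "genetic_distance": m.genetic_distance,
                "n_variants": m.n_variants,
                "alpha": m.alpha,
            }
        )
    metrics = pd.DataFrame(rows)

    tests = []
    treatments = sorted(metrics["treatment"].dropna().unique())
    if len(treatments) == 2:
        t1, t2 = treatments
        for col in ("genetic_distance", "n_variants", "alpha"):
            w, p = stats_core.ranksum_w(
                metrics.loc[metrics["treatment"] == t1, col],
                metrics.loc[metrics["treatment"] == t2, col],
            )
            tests.append({"metric": col, "W": w, "p": p, "group_x": t1, "group_y": t2})
    return metrics, pd.DataFrame(tests)


def run_ordination(
    tables: Sequence[VariantTable],
    n_perm: int = 9999,
    seed: int | None = None,
    clonal_whitelist: set | None = None,
) -> tuple[pd.DataFrame, PermanovaResult, DispersionResult, NMDSResult]:
    """Feature matrix -> Euclidean distances -> PERMANOVA, dispersion, NMDS.

    When a clonal whitelist is given, pooled tables are filtered to it
    first (the conservative default of the analysis).
    """
    if clonal_whitelist is not None:
        tables = [pool_diversity.whitelist_filter(t, clonal_whitelist) for t in tables]
    features = variant_feature_matrix(tables)
    groups = [t.treatment or "unknown" for t in tables]
    dist = euclidean_distances(features)
    perm = permanova(dist, groups, n_perm=n_perm, seed=seed)
    disp = betadisper(dist, groups)
    ord_res = nmds(dist, k=2, seed=seed)
    return features, perm, disp, ord_res
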