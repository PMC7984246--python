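"""Synthetic inputs with the statistical structure the pipeline assumes.

Generators for every data stream the analysis consumes, emulating an
experiment in which replicate bacterial populations evolve either in a
spatially heterogeneous environment (favouring coexisting resource
specialists) or a homogeneous one (favouring generalists):

* :func:`generate_biolog` — clone x substrate growth matrices.  In
  specialist mode each clone is assigned one of several disjoint substrate
  niches and grows at ``baseline + gain`` there but ``baseline - loss``
  elsewhere (a trade-off), producing the negative cross-clone correlations
  that the inconsistency statistic detects; generalist mode gives every
  clone the same flat profile.  I.i.d. Gaussian noise is added and the
  result truncated at 0 (OD cannot be negative).
* :func:`generate_variant_tables` — per-population variant-proportion
  tables: a Poisson number of private variants with Beta-distributed
  proportions, plus treatment-structured shared variants (e.g. one variant
  carried by every population of one treatment).
* :func:`generate_competition` — colony counts for a competition assay:
  growth between timepoints is deterministic with the final mixture
  fraction chosen so the odds ratio equals the true relative fitness; all
  stochasticity is binomial plating noise.
* :func:`generate_clone_reads` — tiny clone genomes and FASTQ reads
  carrying planted SNPs, plus a truth table of carrier fractions, for
  validating the pseudo-pool mixer.

Every generator is deterministic given its scenario seed; per-population
sub-streams are spawned from one root RNG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .fitness_assays import CompetitionAssay
from .phenotype_gxe import ODMatrix
from .pool_diversity import VariantRecord, VariantTable

__all__ = [
    "BiologScenario",
    "VariantScenario",
    "CompetitionScenario",
    "ReadScenario",
    "generate_biolog",
    "generate_variant_tables",
    "generate_competition",
    "generate_competition_experiment",
    "generate_clone_reads",
    "serial_transfer_generations",
]

_BASES = np.array(list("ACGT"))


def serial_transfer_generations(n_transfers: int, fold_dilution: float) -> int:
    """Minimum doublings implied by a serial-transfer design.

    Each transfer dilutes the culture ``fold_dilution``-fold (e.g. moving
    one third of the culture into fresh medium is a 3-fold dilution), so
    regrowth to the pre-transfer density takes log2(fold_dilution)
    doublings; over ``n_transfers`` transfers the population completes at
    least ``floor(n_transfers * log2(fold_dilution))`` generations —
    more if there is turnover at equilibrium density.
    """
    if n_transfers < 0 or fold_dilution <= 1:
        raise ValueError("need n_transfers >= 0 and fold_dilution > 1")
    return math.floor(n_transfers * math.log2(fold_dilution))


# ---------------------------------------------------------------------------
# catabolic profiles


@dataclass(frozen=True)
class BiologScenario:
    """Design of a synthetic clone x substrate growth experiment.

    OD-scale parameters (baseline, gain, loss, generalist mean, noise SD)
    are free choices; defaults keep off-niche growth well above the 0.1
    filtering floor so the default panel survives filtering.
    """

    n_populations_per_treatment: int = 6
    n_clones: int = 10
    n_substrates: int = 96
    baseline_mean: float = 0.6
    specialist_gain: float = 0.5
    specialist_loss: float = 0.3
    niche_size: int = 8
    n_specialist_types: int = 4
    generalist_mean: float = 0.6
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.niche_size * self.n_specialist_types > self.n_substrates:
            raise ValueError(
                f"niche capacity exceeded: {self.n_specialist_types} types x "
                f"{self.niche_size} substrates > {self.n_substrates} substrates"
            )
        if self.n_clones < 2 or self.n_substrates < 2:
            raise ValueError("need at least 2 clones and 2 substrates")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_biolog(
    scenario: BiologScenario, mode: Literal["specialist", "generalist"]
) -> list[ODMatrix]:
    """Growth matrices for all populations of one treatment.

    Specialist mode: clones are assigned niche types cyclically (so every
    type is represented); niches are disjoint random substrate blocks drawn
    per population.  Treatment labels follow the emulated design:
    specialist -> "heterogeneous", generalist -> "homogeneous".
    """
    if mode not in ("specialist", "generalist"):
        raise ValueError(f"unknown mode {mode!r}")
    treatment = "heterogeneous" if mode == "specialist" else "homogeneous"
    root = np.random.default_rng(scenario.seed)
    streams = root.spawn(scenario.n_populations_per_treatment)
    substrate_ids = [f"S{j + 1:03d}" for j in range(scenario.n_substrates)]
    clone_ids = [f"c{i + 1:02d}" for i in range(scenario.n_clones)]
    matrices = []
    for p, rng in enumerate(streams):
        mean = np.full(
            (scenario.n_clones, scenario.n_substrates),
            scenario.generalist_mean if mode == "generalist" else scenario.baseline_mean,
        )
        if mode == "specialist":
            mean -= scenario.specialist_loss
            shuffled = rng.permutation(scenario.n_substrates)
            niches = [
                shuffled[t * scenario.niche_size : (t + 1) * scenario.niche_size]
                for t in range(scenario.n_specialist_types)
            ]
            for i in range(scenario.n_clones):
                niche = niches[i % scenario.n_specialist_types]
                mean[i, niche] = scenario.baseline_mean + scenario.specialist_gain
        values = mean + rng.normal(0.0, scenario.noise_sd, size=mean.shape)
        matrices.append(
            ODMatrix(
                np.clip(values, 0.0, None),
                clone_ids,
                substrate_ids,
                population_id=f"{treatment[:3]}_{p + 1}",
                treatment=treatment,
            )
        )
    return matrices


# ---------------------------------------------------------------------------
# variant tables


@dataclass(frozen=True)
class SharedVariant:
    """A variant shared by a fraction of one treatment's populations.

    ``proportion`` fixes the within-population allele proportion; None
    draws it from the scenario's Beta distribution.
    """

    variant_id: str
    treatment: str
    fraction: float
    proportion: float | None = None
    type: str = "SNP"


@dataclass(frozen=True)
class VariantScenario:
    """Design of a synthetic pooled-variant experiment.

    ``n_populations`` is the total across both treatments; the first half
    is labelled "heterogeneous", the second "homogeneous".  Private
    variants are Poisson in number with Beta(alpha, beta) proportions.
    """

    n_populations: int = 12
    mean_variants_per_population: float = 2.0
    proportion_alpha: float = 1.0
    proportion_beta: float = 2.0
    shared_variant_spec: tuple[SharedVariant, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportion_alpha <= 0 or self.proportion_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.mean_variants_per_population < 0:
            raise ValueError("mean_variants_per_population must be >= 0")
        if self.n_populations % 2:
            raise ValueError("n_populations must be even (two equal treatments)")
        for sv in self.shared_variant_spec:
            if not 0.0 <= sv.fraction <= 1.0:
                raise ValueError(f"shared fraction out of [0,1]: {sv}")


def _draw_proportion(rng: np.random.Generator, a: float, b: float) -> float:
    # Beta(a, b) support is (0, 1); guard the measure-zero endpoints anyway
    for _ in range(100):
        p = float(rng.beta(a, b))
        if 0.0 < p <= 1.0:
            return p
    raise RuntimeError("could not draw a proportion in (0, 1]")


def generate_variant_tables(scenario: VariantScenario) -> list[VariantTable]:
    """Variant-proportion tables for all populations.

    Private variants get unique positions per (population, index) on a
    single synthetic chromosome; shared variants occupy dedicated low
    positions so their keys coincide across carrier populations.
    """
    rng = np.random.default_rng(scenario.seed)
    half = scenario.n_populations // 2
    treatments = ["heterogeneous"] * half + ["homogeneous"] * half
    pop_ids = [
        f"{t[:3]}_{i + 1}" for t in ("heterogeneous", "homogeneous") for i in range(half)
    ]

    # decide carrier sets for shared variants up front
    shared_records: dict[str, list[tuple[str, VariantRecord]]] = {pid: [] for pid in pop_ids}
    for s_idx, sv in enumerate(scenario.shared_variant_spec):
        members = [pid for pid, t in zip(pop_ids, treatments) if t == sv.treatment]
        n_carriers = int(round(sv.fraction * len(members)))
        carriers = rng.choice(members, size=n_carriers, replace=False)
        pos = s_idx + 1  # reserved positions 1..n_shared
        ref, alt = ("A", "G") if sv.type == "SNP" else ("A", "AT")
        for pid in carriers:
            p = (
                sv.proportion
                if sv.proportion is not None
                else _draw_proportion(rng, scenario.proportion_alpha, scenario.proportion_beta)
            )
            shared_records[pid].append(
                (pid, VariantRecord(sv.variant_id, "chr1", pos, ref, alt, sv.type, p))
            )

    offset = len(scenario.shared_variant_spec) + 100  # private positions start here
    tables = []
    for k, (pid, treatment) in enumerate(zip(pop_ids, treatments)):
        records = [rec for _, rec in shared_records[pid]]
        n_private = int(rng.poisson(scenario.mean_variants_per_population))
        for j in range(n_private):
            pos = offset + k * 10_000 + j  # unique per population and index
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            vtype = "SNP" if rng.random() < 0.75 else "indel"
            if vtype == "indel":
                alt = ref + "".join(rng.choice(_BASES, size=rng.integers(1, 4)))
            p = _draw_proportion(rng, scenario.proportion_alpha, scenario.proportion_beta)
            records.append(
                VariantRecord(f"{pid}_v{j + 1}", "chr1", pos, str(ref), str(alt), vtype, p)
            )
        tables.append(VariantTable(population_id=pid, records=records, treatment=treatment))
    return tables


# ---------------------------------------------------------------------------
# competition assays


@dataclass(frozen=True)
class CompetitionScenario:
    """Design of one synthetic competition assay.

    The focal (evolved) mix starts at fraction ``n0_focal / n0_total``
    (default 50:50 of 1e8 CFU); growth to the final timepoint is
    deterministic, with the final fraction solving the odds-ratio equation
    for ``true_relative_fitness``; plating draws binomial colony counts.
    """

    true_relative_fitness: float = 1.5
    n0_total: float = 1e8
    n0_focal: float = 5e7
    doublings: float = 12.0
    plated_colonies_mean: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_relative_fitness <= 0:
            raise ValueError("true_relative_fitness must be positive")
        if not 0 < self.n0_focal < self.n0_total:
            raise ValueError("n0_focal must split n0_total strictly")
        if self.plated_colonies_mean < 2:
            raise ValueError("plated_colonies_mean must be >= 2")


def final_fraction(f0: float, w: float) -> float:
    """Final mixture fraction whose odds ratio relative to ``f0`` is ``w``."""
    odds = w * f0 / (1.0 - f0)
    return odds / (1.0 + odds)


def generate_competition(
    scenario: CompetitionScenario,
    population_id: str = "pop_1",
    evolution_env: str = "heterogeneous",
    competition_env: str = "heterogeneous",
    max_retries: int = 100,
) -> CompetitionAssay:
    """One competition assay with binomial plating noise.

    Counts at each timepoint are Binomial(plated_colonies_mean, fraction)
    whites out of a fixed plate total; draws that would put a fraction at
    0 or 1 are resampled (bounded retries, then an error).
    """
    rng = np.random.default_rng(scenario.seed)
    f0 = scenario.n0_focal / scenario.n0_total
    f7 = final_fraction(f0, scenario.true_relative_fitness)
    n_plate = scenario.plated_colonies_mean

    def sample(fraction: float) -> int:
        for _ in range(max_retries):
            white = int(rng.binomial(n_plate, fraction))
            if 0 < white < n_plate:
                return white
        raise RuntimeError(
            f"fraction {fraction} produced fixation in {max_retries} plating draws"
        )

    white0 = sample(f0)
    white7 = sample(f7)
    return CompetitionAssay(
        population_id=population_id,
        evolution_env=evolution_env,
        competition_env=competition_env,
        white_T0=white0,
        blue_T0=n_plate - white0,
        white_T7=white7,
        blue_T7=n_plate - white7,
    )


def generate_competition_experiment(
    true_fitness: dict[tuple[str, str], float],
    n_populations_per_treatment: int = 6,
    base_scenario: CompetitionScenario = CompetitionScenario(),
    seed: int = 0,
) -> list[CompetitionAssay]:
    """A full two-factor competition experiment.

    ``true_fitness`` maps (evolution_env, competition_env) to the true
    relative fitness of populations evolved in that environment when
    competed in that environment.  Each treatment contributes
    ``n_populations_per_treatment`` populations, each assayed in every
    competition environment present in the mapping.
    """
    root = np.random.default_rng(seed)
    assays = []
    for evo_env in sorted({evo for evo, _ in true_fitness}):
        for i in range(n_populations_per_treatment):
            pid = f"{evo_env[:3]}_{i + 1}"
            for comp_env in sorted({c for e, c in true_fitness if e == evo_env}):
                sub_seed = int(root.integers(2**31))
                scenario = CompetitionScenario(
                    true_relative_fitness=true_fitness[(evo_env, comp_env)],
                    n0_total=base_scenario.n0_total,
                    n0_focal=base_scenario.n0_focal,
                    doublings=base_scenario.doublings,
                    plated_colonies_mean=base_scenario.plated_colonies_mean,
                    seed=sub_seed,
                )
                assays.append(
                    generate_competition(scenario, pid, evo_env, comp_env)
                )
    return assays


# ---------------------------------------------------------------------------
# clone genomes and reads


@dataclass(frozen=True)
class PlantedVariant:
    pos: int  # 1-based
    ref: str
    alt: str
    carriers: frozenset[int] = field(default_factory=frozenset)  # clone indices


@dataclass(frozen=True)
class ReadScenario:
    """Design of a tiny pseudo-pool sequencing validation experiment."""

    genome_length: int = 10_000
    n_clones: int = 10
    planted_variants: tuple[PlantedVariant, ...] = ()
    read_length: int = 100
    coverage_per_clone: float = 20.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        positions = [v.pos for v in self.planted_variants]
        if len(set(positions)) != len(positions):
            raise ValueError("planted variant positions must be unique")
        for v in self.planted_variants:
            if not 1 <= v.pos <= self.genome_length:
                raise ValueError(f"position {v.pos} outside genome (1-based)")
            if any(not 0 <= c < self.n_clones for c in v.carriers):
                raise ValueError(f"carrier index out of range for variant at {v.pos}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


def generate_clone_reads(
    scenario: ReadScenario, out_dir: str | Path
) -> tuple[list[Path], "pd.DataFrame"]:
    """Per-clone FASTQ files with planted SNPs, plus a truth table.

    The ancestral genome is random; each carrier clone's genome substitutes
    the alt base at its planted sites.  Reads start uniformly, carry the
    clone's alleles, and are corrupted per-base at ``error_rate`` (errors
    substitute a uniformly random different base).  The truth table lists
    each planted variant's carrier fraction — the proportion an ideal
    equal-weight pool would observe.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    genome = rng.choice(_BASES, size=scenario.genome_length)
    for v in scenario.planted_variants:
        genome[v.pos - 1] = v.ref  # ensure the declared ref is on the reference

    n_reads = int(round(scenario.coverage_per_clone * scenario.genome_length / scenario.read_length))
    qual_line = "I" * scenario.read_length  # Phred+33 Q40
    paths = []
    for clone in range(scenario.n_clones):
        clone_genome = genome.copy()
        for v in scenario.planted_variants:
            if clone in v.carriers:
                clone_genome[v.pos - 1] = v.alt
        path = out_dir / f"clone_{clone + 1:02d}.fastq"
        starts = rng.integers(0, scenario.genome_length - scenario.read_length + 1, size=n_reads)
        with path.open("w") as fh:
            for r, start in enumerate(starts):
                read = clone_genome[start : start + scenario.read_length].copy()
                if scenario.error_rate > 0:
                    err = rng.random(scenario.read_length) < scenario.error_rate
                    for j in np.flatnonzero(err):
                        choices = _BASES[_BASES != read[j]]
                        read[j] = rng.choice(choices)
                fh.write(
                    f"@clone{clone + 1:02d}_read{r + 1} pos={start + 1}\n"
                    f"{''.join(read)}\n+\n{qual_line}\n"
                )
        paths.append(path)

    truth = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": [v.pos for v in scenario.planted_variants],
            "ref": [v.ref for v in scenario.planted_variants],
            "alt": [v.alt for v in scenario.planted_variants],
            "carrier_fraction": [
                len(v.carriers) / scenario.n_clones for v in scenario.planted_variants
            ],
        }
    )
    return paths, truth
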