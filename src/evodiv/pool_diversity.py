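"""Diversity metrics from pooled-sequencing variant-proportion tables.

Pool-seq of an evolved population (equal-density mix of its clones) yields,
for each SNP or indel, the proportion ``p`` of reads carrying the derived
allele — an estimate of the clone carrier fraction.  Three per-population
metrics summarise these tables:

* genetic distance from the ancestral reference: ``sum p`` over variants;
* variant count: distinct variants at or above a detection floor
  (default 0.1, the pooled-detection proportion cut-off);
* alpha diversity: ``sum (1 - p^2 - q^2)`` with ``q = 1 - p``, i.e. summed
  expected heterozygosity ``2p(1-p)`` per site.

A conservative whitelist filter restricts pooled calls to variants seen in
clonal sequencing.  The pooled detection process itself (carrier fraction
-> binomially sampled read support -> proportion cut-off) is modelled at
the allele-count level by :func:`simulate_pool_detection`, and
:func:`mix_pseudo_pool` constructs in-silico pseudo-pools by subsampling a
fixed fraction of reads from each clone's FASTQ.

Variant identity is the VCF-style key (chrom, pos, ref, alt) with 1-based
positions; the SNP/indel type is annotation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VariantRecord",
    "VariantTable",
    "DiversityMetrics",
    "PoolDetectionResult",
    "genetic_distance",
    "variant_count",
    "alpha_diversity",
    "diversity_metrics",
    "whitelist_filter",
    "expected_pool_proportion",
    "simulate_pool_detection",
    "mix_pseudo_pool",
    "read_vcf",
]

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One SNP or indel segregating in a population at proportion p."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    type: str  # "SNP" or "indel"
    proportion: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError(
                f"variant proportion must lie in (0, 1], got {self.proportion}"
            )
        if self.type not in ("SNP", "indel"):
            raise ValueError(f"variant type must be 'SNP' or 'indel', got {self.type!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantTable:
    """All variants of one population. An empty table is valid."""

    population_id: str
    records: list[VariantRecord] = field(default_factory=list)
    treatment: str | None = None

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dup = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate variant keys in {self.population_id}: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([r.proportion for r in self.records], dtype=float)

    @property
    def keys(self) -> set[VariantKey]:
        return {r.key for r in self.records}


@dataclass(frozen=True)
class DiversityMetrics:
    population_id: str
    genetic_distance: float
    n_variants: int
    alpha: float


def genetic_distance(table: VariantTable) -> float:
    """Sum of variant proportions: distance from the ancestral reference."""
    return float(table.proportions.sum()) if len(table) else 0.0


def variant_count(table: VariantTable, min_prop: float = 0.1) -> int:
    """Number of distinct variants at proportion >= ``min_prop``."""
    if not 0.0 <= min_prop <= 1.0:
        raise ValueError("min_prop must lie in [0, 1]")
    if not len(table):
        return 0
    return int((table.proportions >= min_prop).sum())


def alpha_diversity(table: VariantTable) -> float:
    """Summed expected heterozygosity: sum over variants of 1 - p^2 - q^2."""
    if not len(table):
        return 0.0
    p = table.proportions
    return float((1.0 - p**2 - (1.0 - p) ** 2).sum())


def diversity_metrics(table: VariantTable, min_prop: float = 0.1) -> DiversityMetrics:
    """All three metrics for one population."""
    return DiversityMetrics(
        population_id=table.population_id,
        genetic_distance=genetic_distance(table),
        n_variants=variant_count(table, min_prop),
        alpha=alpha_diversity(table),
    )


def whitelist_filter(
    pool: VariantTable, clonal_variants: Iterable[VariantKey]
) -> VariantTable:
    """Keep only pooled variants also seen in clonal sequencing.

    The conservative cross-validation filter: pooled calls absent from the
    clonal whitelist are treated as artefacts and dropped.
    """
    allowed = set(clonal_variants)
    return VariantTable(
        population_id=pool.population_id,
        records=[r for r in pool.records if r.key in allowed],
        treatment=pool.treatment,
    )


def expected_pool_proportion(genotypes: np.ndarray) -> np.ndarray:
    """Carrier fraction per variant under equal-weight pooling.

    ``genotypes`` is a clones x variants binary matrix; the expected pooled
    proportion of each variant is the mean of its column.
    """
    g = np.asarray(genotypes)
    if not np.isin(g, (0, 1)).all():
        raise ValueError("genotypes must be binary")
    return g.mean(axis=0).astype(float)


@dataclass(frozen=True)
class PoolDetectionResult:
    """Outcome of one simulated pooled-detection experiment."""

    observed_proportion: np.ndarray
    detected: np.ndarray  # boolean per variant
    truth: np.ndarray  # boolean: variant truly present in the pool
    sensitivity: float
    n_false_negatives: int
    n_false_positives: int


def simulate_pool_detection(
    genotypes: np.ndarray,
    depth: int,
    error_rate: float = 0.0,
    cutoff: float = 0.1,
    seed: int | None = None,
) -> PoolDetectionResult:
    """Binomial model of pooled variant detection at a proportion cut-off.

    Each variant's alt-read count is Binomial(depth, p_eff) where
    ``p_eff = p (1 - e) + (1 - p) e`` folds the per-base error rate ``e``
    into the true carrier fraction ``p``; the variant is called detected
    iff the observed proportion alt/depth is >= ``cutoff``.  Sensitivity
    and false-negative/positive counts are reported against the planted
    truth (p > 0).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = expected_pool_proportion(genotypes)
    p_eff = p * (1.0 - error_rate) + (1.0 - p) * error_rate
    alt = rng.binomial(depth, p_eff)
    observed = alt / depth
    detected = observed >= cutoff
    truth = p > 0
    n_true = int(truth.sum())
    sensitivity = float((detected & truth).sum() / n_true) if n_true else float("nan")
    return PoolDetectionResult(
        observed_proportion=observed,
        detected=detected,
        truth=truth,
        sensitivity=sensitivity,
        n_false_negatives=int((truth & ~detected).sum()),
        n_false_positives=int((~truth & detected).sum()),
    )


def mix_pseudo_pool(
    clone_fastqs: Sequence[str | Path],
    out_path: str | Path,
    fraction: float = 0.1,
    seed: int | None = None,
) -> dict[str, int]:
    """Build a pseudo-pool FASTQ by subsampling each clone's reads.

    Every read of every input file is independently included with
    probability ``fraction``; outputs are concatenated in input-file order
    (read order within a file preserved).  Deterministic given ``seed``.
    Returns the per-file included read counts.
    """
    from Bio import SeqIO

    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    out_path = Path(out_path)
    with out_path.open("w") as out:
        for path in clone_fastqs:
            path = Path(path)
            kept = 0
            index = 0
            try:
                for record in SeqIO.parse(str(path), "fastq"):
                    if rng.random() < fraction:
                        SeqIO.write(record, out, "fastq")
                        kept += 1
                    index += 1
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record ~{index} in {path}: {exc}"
                ) from exc
            counts[str(path)] = kept
    return counts


def read_vcf(
    path: str | Path,
    population_id: str,
    proportion_info_key: str = "AF",
    treatment: str | None = None,
) -> VariantTable:
    """Read a minimal VCF into a VariantTable.

    Expects single-allele records with the pooled variant proportion in the
    INFO field under ``proportion_info_key`` (default ``AF``).  Variant
    type is inferred from allele lengths (equal length 1 -> SNP, otherwise
    indel); the ID column supplies the variant id, falling back to
    ``chrom:pos:ref:alt``.
    """
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        if len(v.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {v.CHROM}:{v.POS}; "
                "split alleles before import"
            )
        alt = v.ALT[0]
        prop = v.INFO.get(proportion_info_key)
        if prop is None:
            raise ValueError(
                f"{path}: record {v.CHROM}:{v.POS} lacks INFO/{proportion_info_key}"
            )
        vtype = "SNP" if len(v.REF) == 1 and len(alt) == 1 else "indel"
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
        records.append(
            VariantRecord(vid, v.CHROM, v.POS, v.REF, alt, vtype, float(prop))
        )
    return VariantTable(population_id=population_id, records=records, treatment=treatment)
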