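"""Configuration objects: stringency profiles, indel filter parameters, simulation settings.

The two built-in stringency tiers mirror the filters a high-coverage exome
study applies when calling diploid genotypes from pileups:

* ``HIGH`` — calls require 8X coverage, mean alternate base quality >= 40,
  site mapping quality >= 40, at least 20% of reads carrying the alternate
  allele, and alternate support on both strands.
* ``RESCUE`` — the relaxed tier used to re-examine discordant calls:
  coverage 8X -> 5X, alternate fraction 20% -> 15%, mapping quality 40 -> 30.
  Base quality and the both-strand requirement are not relaxed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# Ordered substitution types, strand-literal (12 classes, not collapsed to 6).
SUBSTITUTION_TYPES: tuple[str, ...] = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

BASES = "ACGT"


@dataclass(frozen=True)
class StringencyProfile:
    """A named bundle of hard genotype-call filters.

    All comparisons downstream are inclusive (``>=``), matching the
    "minimum X" semantics of each threshold.
    """

    name: str
    min_coverage: int = 8
    min_base_quality: float = 40.0
    min_mapping_quality: float = 40.0
    min_alt_fraction: float = 0.20
    require_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0.0 <= self.min_alt_fraction <= 1.0):
            raise ValueError("min_alt_fraction must lie in [0, 1]")

    def replace(self, **kwargs) -> "StringencyProfile":
        return dataclasses.replace(self, **kwargs)


HIGH = StringencyProfile("high", 8, 40.0, 40.0, 0.20, True)
RESCUE = StringencyProfile("rescue", 5, 40.0, 30.0, 0.15, True)


@dataclass(frozen=True)
class IndelFilterParams:
    """Hard filters for small-indel candidates.

    Candidates must map to both strands, with indel-read mapping quality
    >= 50, anchor (non-gapped) read mapping quality >= 20, a mean distance
    of >= 10 bp from the read end, and coverage >= 8X.  Accepted lengths
    default to insertions of 1-3 bp and deletions of 1-11 bp.
    """

    min_indel_mapping_quality: float = 50.0
    min_anchor_mapping_quality: float = 20.0
    min_mean_end_distance: float = 10.0
    min_coverage: int = 8
    require_both_strands: bool = True
    max_insertion_length: int = 3
    max_deletion_length: int = 11

    def __post_init__(self) -> None:
        for name in ("min_indel_mapping_quality", "min_anchor_mapping_quality",
                     "min_mean_end_distance", "min_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the diploid genotype model (see :mod:`lclfidelity.genotyper`)."""

    het_prior: float = 1e-3
    error_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.het_prior < 0.5):
            raise ValueError("het_prior must lie in (0, 0.5)")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")


# Default substitution spectrum: transition-heavy, with C>T the most common
# class (~25%) as is typical of spontaneous mutation spectra; the remaining
# transitions share 45% and the eight transversions split 30% evenly.
DEFAULT_SPECTRUM_WEIGHTS: tuple[float, ...] = (
    0.0375, 0.15, 0.0375,   # A>C A>G A>T
    0.0375, 0.0375, 0.25,   # C>A C>G C>T
    0.15, 0.0375, 0.0375,   # G>A G>C G>T
    0.0375, 0.15, 0.0375,   # T>A T>C T>G
)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for the synthetic tetrad-exome generator.

    The defaults describe a scaled-down exome: 250 capture regions of
    1,500 bp on a 30.75 Mb genome (1.22% targeted), sequenced to a mean
    depth of 125X, with a variant density matching ~19,354 called variants
    per 38 Mb exome and 0.18% of each lymphoblastoid cell line's calls
    being culture-derived de novo mutations.

    ``variant_density`` is the expected number of *called* variants per
    sample per targeted bp; the generator scales the number of segregating
    family sites by the mean per-sample carrier probability implied by
    ``maf_distribution`` so realised per-sample call counts match it.
    """

    seed: int = 0
    genome_length: int = 30_750_000
    n_target_regions: int = 250
    target_region_length: int = 1_500
    variant_density: float = 19_354 / 38_000_000
    maf_distribution: tuple = ("beta", 0.5, 0.5)
    de_novo_rate: float = 0.0018
    novel_fraction: float = 0.0275
    mean_depth: float = 125.0
    base_error_rate: float = 0.001
    strand_bias: float = 0.5
    spectrum_weights: Sequence[float] = DEFAULT_SPECTRUM_WEIGHTS
    # Two-point quality model.  The default places all reads at the high
    # value: with hard mean-quality thresholds equal to that value, any
    # low-quality admixture at high depth would reject essentially every
    # site, which is not the regime the filters are meant to probe.
    base_quality_high: float = 40.0
    base_quality_low: float = 20.0
    low_base_quality_fraction: float = 0.0
    mapping_quality_high: float = 40.0
    mapping_quality_low: float = 20.0
    low_mapping_quality_fraction: float = 0.0
    # Density (per targeted bp) of non-variant sites emitted so that false
    # positives are measurable; 1.0 emits every targeted position.
    invariant_site_density: float = 0.01
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        for name in ("de_novo_rate", "novel_fraction", "base_error_rate",
                     "strand_bias", "low_base_quality_fraction",
                     "low_mapping_quality_fraction", "invariant_site_density"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.variant_density < 0:
            raise ValueError("variant_density must be >= 0")
        w = np.asarray(self.spectrum_weights, dtype=float)
        if w.shape != (12,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("spectrum_weights must be 12 non-negative values summing to 1")
        if self.n_target_regions > 0 and self.target_region_length > 0:
            if self.genome_length < self.n_target_regions * self.target_region_length:
                raise ValueError(
                    "target regions cannot be packed into the genome: "
                    f"{self.n_target_regions} x {self.target_region_length} bp "
                    f"> genome_length {self.genome_length}"
                )

    @property
    def targeted_bp(self) -> int:
        return self.n_target_regions * self.target_region_length

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def mean_carrier_probability(self) -> float:
        """Mean P(an individual carries >=1 alt allele) under Hardy-Weinberg
        for the configured allele-frequency distribution: E[1 - (1-p)^2]."""
        kind = self.maf_distribution[0]
        if kind == "beta":
            a, b = float(self.maf_distribution[1]), float(self.maf_distribution[2])
            ep = a / (a + b)
            ep2 = a * (a + 1) / ((a + b) * (a + b + 1))
            return 2 * ep - ep2
        if kind == "fixed":
            p = float(self.maf_distribution[1])
            return 2 * p - p * p
        raise ValueError(f"unknown maf_distribution kind: {kind!r}")

    def sample_af(self, rng: np.random.Generator, n: int) -> np.ndarray:
        kind = self.maf_distribution[0]
        if kind == "beta":
            return rng.beta(float(self.maf_distribution[1]), float(self.maf_distribution[2]), size=n)
        if kind == "fixed":
            return np.full(n, float(self.maf_distribution[1]))
        raise ValueError(f"unknown maf_distribution kind: {kind!r}")


@dataclass
class PipelineConfig:
    """Fully-resolved configuration of an end-to-end pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    high_profile: StringencyProfile = HIGH
    rescue_profile: StringencyProfile = RESCUE
    model: ModelParams = field(default_factory=ModelParams)
    indel_params: IndelFilterParams = field(default_factory=IndelFilterParams)
    genotype_aware_concordance: bool = False
    splice_window: int = 2
    near_gene_bp: int = 50
    annotate_all_calls: bool = True
    outdir: Optional[str] = None
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        """Return a list of warnings (empty if the profile pair is sane)."""
        warnings = []
        if self.high_profile.min_coverage < self.rescue_profile.min_coverage:
            warnings.append("high profile has lower min_coverage than rescue profile")
        if self.high_profile.min_alt_fraction < self.rescue_profile.min_alt_fraction:
            warnings.append("high profile has lower min_alt_fraction than rescue profile")
        return warnings
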