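"""Paired-source concordance and threshold-relaxation rescue.

An individual's PBMC and LCL call sets are compared on variant keys
(chrom, pos, ref, alt).  The concordance rate is the percentage of keys
shared between the two sources relative to their union (zygosity-blind by
default).  Discordant keys are then re-examined in the source where the
variant was NOT called, under the relaxed RESCUE tier: if the same
alternate allele becomes callable there, the key is reclassified as
concordant — a threshold artifact rather than a biological difference.
Each rescue is attributed to the single minimal relaxation sufficient
(alternate fraction, then coverage, then mapping quality), or "combined".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from .config import ModelParams, StringencyProfile
from .genotyper import CallSet, call_site, pileup_from_row

RESCUE_REASONS = ("alt_fraction_relaxation", "coverage_relaxation",
                  "mapping_quality_relaxation", "combined", "none")


@dataclass
class PairComparison:
    """The PBMC/LCL comparison for one individual."""

    sample_id: str
    concordant: set = field(default_factory=set)
    discordant_pbmc_only: set = field(default_factory=set)
    discordant_lcl_only: set = field(default_factory=set)
    # Keys called in both sources with conflicting zygosity; populated only
    # in genotype-aware mode so the three key sets above stay disjoint.
    genotype_mismatch: set = field(default_factory=set)
    stage: str = "pre_rescue"

    @property
    def union_size(self) -> int:
        return (len(self.concordant) + len(self.discordant_pbmc_only)
                + len(self.discordant_lcl_only) + len(self.genotype_mismatch))

    @property
    def concordance_rate(self) -> float:
        """Percentage of shared keys over the union; NaN when both sets empty."""
        if self.union_size == 0:
            return math.nan
        return 100.0 * len(self.concordant) / self.union_size


@dataclass(frozen=True)
class RescueRecord:
    key: tuple
    missing_source: str  # the source in which the variant was NOT called
    rescued: bool
    rescue_reason: str

    def __post_init__(self) -> None:
        if self.rescue_reason not in RESCUE_REASONS:
            raise ValueError(f"unknown rescue reason {self.rescue_reason!r}")
        if self.rescued != (self.rescue_reason != "none"):
            raise ValueError("rescued flag inconsistent with rescue_reason")


def compare_pair(pbmc_calls: CallSet, lcl_calls: CallSet,
                 genotype_aware: bool = False) -> PairComparison:
    """Compare one individual's PBMC and LCL call sets on variant keys.

    With ``genotype_aware`` a key shared by both sources but with different
    zygosity counts as discordant on both sides.
    """
    if pbmc_calls.sample_id != lcl_calls.sample_id:
        raise ValueError(
            f"mismatched sample ids: {pbmc_calls.sample_id!r} vs {lcl_calls.sample_id!r}")
    pk, lk = pbmc_calls.keys(), lcl_calls.keys()
    shared = pk & lk
    pbmc_only, lcl_only = pk - lk, lk - pk
    mismatched: set = set()
    if genotype_aware:
        pg, lg = pbmc_calls.genotypes(), lcl_calls.genotypes()
        mismatched = {k for k in shared if pg[k] != lg[k]}
        shared -= mismatched
    return PairComparison(pbmc_calls.sample_id, shared, pbmc_only, lcl_only,
                          genotype_mismatch=mismatched, stage="pre_rescue")


def _single_relaxations(high: StringencyProfile,
                        rescue: StringencyProfile) -> list[tuple[str, StringencyProfile]]:
    """One-parameter relaxations of HIGH toward RESCUE, in attribution order."""
    return [
        ("alt_fraction_relaxation",
         replace(high, name="alt_only", min_alt_fraction=rescue.min_alt_fraction)),
        ("coverage_relaxation",
         replace(high, name="cov_only", min_coverage=rescue.min_coverage)),
        ("mapping_quality_relaxation",
         replace(high, name="mq_only", min_mapping_quality=rescue.min_mapping_quality)),
    ]


def rescue_discordant(pair: PairComparison, pileups: pd.DataFrame,
                      rescue_profile: StringencyProfile,
                      high_profile: StringencyProfile,
                      model: Optional[ModelParams] = None,
                      ) -> tuple[PairComparison, list[RescueRecord]]:
    """Re-call each discordant key's missing source under the RESCUE tier.

    ``pileups`` must cover both sources of the individual (pileup-table
    schema).  A discordant key with no pileup record in the missing source
    is counted as not rescued (reason "none").
    """
    model = model or ModelParams()
    sub = pileups[pileups["sample"] == pair.sample_id]
    index: dict[tuple, int] = {}
    for i, (src, chrom, pos) in enumerate(zip(sub["source"], sub["chrom"], sub["pos"])):
        index[(src, chrom, int(pos))] = i
    sub = sub.reset_index(drop=True)

    relaxations = _single_relaxations(high_profile, rescue_profile)
    records: list[RescueRecord] = []
    rescued_keys: set = set()

    work = [(k, "LCL") for k in sorted(pair.discordant_pbmc_only)] + \
           [(k, "PBMC") for k in sorted(pair.discordant_lcl_only)]
    for key, missing in work:
        chrom, pos, ref, alt = key
        row_i = index.get((missing, chrom, int(pos)))
        if row_i is None:
            records.append(RescueRecord(key, missing, False, "none"))
            continue
        sp = pileup_from_row(sub.iloc[row_i])
        call = call_site(sp, rescue_profile, model)
        if call is None or call["alt"] != alt:
            records.append(RescueRecord(key, missing, False, "none"))
            continue
        reason = "combined"
        for name, prof in relaxations:
            c = call_site(sp, prof, model)
            if c is not None and c["alt"] == alt:
                reason = name
                break
        records.append(RescueRecord(key, missing, True, reason))
        rescued_keys.add(key)

    post = PairComparison(
        pair.sample_id,
        concordant=pair.concordant | rescued_keys,
        discordant_pbmc_only=pair.discordant_pbmc_only - rescued_keys,
        discordant_lcl_only=pair.discordant_lcl_only - rescued_keys,
        genotype_mismatch=set(pair.genotype_mismatch),
        stage="post_rescue",
    )
    return post, records


def venn_counts(pair: PairComparison) -> tuple[int, int, int]:
    """(n_concordant, n_pbmc_only, n_lcl_only); sums to the union size."""
    return (len(pair.concordant), len(pair.discordant_pbmc_only),
            len(pair.discordant_lcl_only))
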