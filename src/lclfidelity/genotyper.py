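"""Diploid genotype calling from per-site pileups under hard stringency filters.

The genotype model is a three-state Bayesian classifier per site.  For the
best-supported non-reference allele with k supporting reads out of
n = ref + alt informative reads, the likelihoods are binomial with expected
alternate fractions {eps, 1/2, 1 - eps} for {hom-ref, het, hom-alt}, where
eps is the per-read error rate.  The prior is {1 - theta - theta^2, theta,
theta^2} with theta the heterozygosity prior, renormalised.  A variant is
emitted only when the MAP genotype is non-reference AND the site passes
every hard filter of the active stringency profile (coverage, mean alternate
base quality, site mapping quality, alternate-allele fraction, both-strand
support); all threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import BASES, IndelFilterParams, ModelParams, StringencyProfile
from .simulate import TargetRegion

GENOTYPES = ("hom-ref", "het", "hom-alt")

# Slack for inclusive float threshold comparisons (alt_fraction >= f means
# alt_count >= f * depth up to representation error).
_EPS = 1e-9

CALL_COLUMNS = ("chrom", "pos", "ref", "alt", "genotype", "depth", "alt_fraction",
                "alt_forward", "alt_reverse", "genotype_posterior", "tier",
                "variant_class")


@dataclass
class SitePileup:
    """Read evidence at one site: per-allele strand counts and quality summaries."""

    chrom: str
    pos: int
    ref: str
    counts: dict  # base -> (forward, reverse)
    base_quality: dict  # base -> mean Phred of reads supporting that base
    mapping_quality: float
    sample: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        for b, (f, r) in self.counts.items():
            if f < 0 or r < 0:
                raise ValueError(f"negative read count for allele {b}")
        if self.mapping_quality < 0:
            raise ValueError("mapping quality must be >= 0")

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())


@dataclass
class CallSet:
    """One sample-source's variant calls under a named stringency tier."""

    sample_id: str
    source: str
    tier: str
    calls: pd.DataFrame = field(default_factory=lambda: _empty_calls())

    def __post_init__(self) -> None:
        missing = set(CALL_COLUMNS) - set(self.calls.columns)
        if missing:
            raise ValueError(f"call table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.calls)

    def keys(self) -> set[tuple]:
        c = self.calls
        return set(zip(c["chrom"], c["pos"], c["ref"], c["alt"]))

    def __contains__(self, key: tuple) -> bool:
        return key in self.keys()

    def genotypes(self) -> dict[tuple, str]:
        c = self.calls
        return dict(zip(zip(c["chrom"], c["pos"], c["ref"], c["alt"]), c["genotype"]))


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in CALL_COLUMNS})


def _binom_logpmf(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(p > 0, k * np.log(max(p, 1e-300)), np.where(k == 0, 0.0, -np.inf))
        lq = np.where(p < 1, (n - k) * np.log(max(1 - p, 1e-300)),
                      np.where(n - k == 0, 0.0, -np.inf))
    return logc + lp + lq


def genotype_posterior_arrays(n_ref: np.ndarray, n_alt: np.ndarray,
                              het_prior: float, error_rate: float) -> np.ndarray:
    """Posterior over {hom-ref, het, hom-alt}; shape (n, 3).

    Rows with n_ref + n_alt == 0 are NaN (a no-posterior signal distinct
    from a confident hom-ref).
    """
    n_ref = np.asarray(n_ref, dtype=np.int64)
    n_alt = np.asarray(n_alt, dtype=np.int64)
    n = n_ref + n_alt
    theta = het_prior
    prior = np.array([1.0 - theta - theta ** 2, theta, theta ** 2])
    prior = prior / prior.sum()
    ps = (error_rate, 0.5, 1.0 - error_rate)
    loglik = np.stack([_binom_logpmf(n_alt, n, p) for p in ps], axis=-1)
    logpost = loglik + np.log(prior)
    logpost = logpost - logsumexp(logpost, axis=-1, keepdims=True)
    post = np.exp(logpost)
    post[n == 0] = np.nan
    return post


def genotype_posterior(pileup: SitePileup, het_prior: float = 1e-3,
                       error_rate: float = 1e-3) -> Optional[dict[str, float]]:
    """Posterior over the three diploid genotypes for the top non-ref allele.

    Returns None when the site has no reads (no-posterior signal).
    """
    if pileup.depth == 0:
        return None
    alt = _top_alt_allele(pileup)
    n_ref = sum(pileup.counts.get(pileup.ref, (0, 0)))
    n_alt = sum(pileup.counts.get(alt, (0, 0))) if alt is not None else 0
    post = genotype_posterior_arrays(np.array([n_ref]), np.array([n_alt]),
                                     het_prior, error_rate)[0]
    if np.any(np.isnan(post)):
        return None
    return dict(zip(GENOTYPES, post.tolist()))


def _top_alt_allele(pileup: SitePileup) -> Optional[str]:
    """Best-supported non-reference allele; ties break lexicographically."""
    best, best_count = None, 0
    for b in BASES:  # lexicographic order: first max wins ties
        if b == pileup.ref:
            continue
        c = sum(pileup.counts.get(b, (0, 0)))
        if c > best_count:
            best, best_count = b, c
    return best


def _call_kernel(depth: np.ndarray, n_ref: np.ndarray, n_alt: np.ndarray,
                 alt_fwd: np.ndarray, alt_rev: np.ndarray,
                 alt_bq: np.ndarray, mq: np.ndarray,
                 profile: StringencyProfile, model: ModelParams):
    """Vectorised filter + MAP-genotype evaluation.

    Returns (emit_mask, genotype_index, posterior_of_map).
    """
    post = genotype_posterior_arrays(n_ref, n_alt, model.het_prior, model.error_rate)
    with np.errstate(invalid="ignore"):
        map_idx = np.nanargmax(np.where(np.isnan(post), -1.0, post), axis=-1)
    map_post = np.take_along_axis(post, map_idx[:, None], axis=-1)[:, 0]

    has_reads = depth > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_frac = np.where(has_reads, n_alt / np.maximum(depth, 1), 0.0)
    ok = has_reads & (n_alt > 0) & (map_idx > 0)
    ok &= depth >= profile.min_coverage
    ok &= alt_bq >= profile.min_base_quality - _EPS
    ok &= mq >= profile.min_mapping_quality - _EPS
    ok &= n_alt >= profile.min_alt_fraction * depth - _EPS
    if profile.require_both_strands:
        ok &= (alt_fwd >= 1) & (alt_rev >= 1)
    return ok, map_idx, map_post, alt_frac


def call_site(pileup: SitePileup, profile: StringencyProfile,
              model: Optional[ModelParams] = None) -> Optional[dict]:
    """Call one site; returns a call record dict or None (no-call)."""
    model = model or ModelParams()
    alt = _top_alt_allele(pileup)
    if alt is None:
        return None
    n_ref = sum(pileup.counts.get(pileup.ref, (0, 0)))
    af, ar = pileup.counts.get(alt, (0, 0))
    n_alt = af + ar
    depth = pileup.depth
    ok, map_idx, map_post, alt_frac = _call_kernel(
        np.array([depth]), np.array([n_ref]), np.array([n_alt]),
        np.array([af]), np.array([ar]),
        np.array([pileup.base_quality.get(alt, 0.0)]),
        np.array([pileup.mapping_quality]), profile, model)
    if not ok[0]:
        return None
    return {
        "chrom": pileup.chrom, "pos": pileup.pos, "ref": pileup.ref, "alt": alt,
        "genotype": GENOTYPES[int(map_idx[0])], "depth": depth,
        "alt_fraction": float(alt_frac[0]), "alt_forward": int(af),
        "alt_reverse": int(ar), "genotype_posterior": float(map_post[0]),
        "tier": profile.name, "variant_class": "snv",
    }


def call_sample(pileups: pd.DataFrame, profile: StringencyProfile,
                model: Optional[ModelParams] = None,
                sample_id: Optional[str] = None,
                source: Optional[str] = None) -> CallSet:
    """Call every site of one sample-source pileup table (vectorised).

    ``pileups`` uses the pileup-table schema of :mod:`lclfidelity.simulate`
    and must contain a single (sample, source), be sorted by (chrom, pos)
    and free of duplicate sites.
    """
    model = model or ModelParams()
    if len(pileups) == 0:
        sid = sample_id or "NA"
        src = source or "NA"
        return CallSet(sid, src, profile.name, _empty_calls())

    samples = pileups["sample"].unique()
    sources = pileups["source"].unique()
    if len(samples) > 1 or len(sources) > 1:
        raise ValueError("call_sample expects a single sample-source pileup set")
    sid = sample_id or str(samples[0])
    src = source or str(sources[0])

    key = pileups[["chrom", "pos"]]
    if key.duplicated().any():
        raise ValueError("duplicate (chrom, pos) entries in pileup set")
    if not (key.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
            .equals(key.reset_index(drop=True))):
        raise ValueError("pileups must be sorted by (chrom, pos)")

    fwd = pileups[[f"{b}_fwd" for b in BASES]].to_numpy(dtype=np.int64)
    rev = pileups[[f"{b}_rev" for b in BASES]].to_numpy(dtype=np.int64)
    bq = pileups[[f"{b}_bq" for b in BASES]].to_numpy(dtype=float)
    tot = fwd + rev
    n = len(pileups)
    rows = np.arange(n)
    ref_idx = pileups["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    if np.any(pd.isna(ref_idx)):
        raise ValueError("pileup ref alleles must be one of A/C/G/T")
    ref_idx = ref_idx.astype(np.int64)

    masked = tot.copy()
    masked[rows, ref_idx] = -1
    alt_idx = np.argmax(masked, axis=1)  # first max -> lexicographic tie-break
    n_alt = tot[rows, alt_idx]
    n_ref = tot[rows, ref_idx]
    depth = tot.sum(axis=1)
    alt_fwd = fwd[rows, alt_idx]
    alt_rev = rev[rows, alt_idx]
    alt_bq = bq[rows, alt_idx]
    mq = pileups["mq"].to_numpy(dtype=float)

    ok, map_idx, map_post, alt_frac = _call_kernel(
        depth, n_ref, n_alt, alt_fwd, alt_rev, alt_bq, mq, profile, model)

    base_arr = np.array(list(BASES))
    calls = pd.DataFrame({
        "chrom": pileups["chrom"].to_numpy()[ok],
        "pos": pileups["pos"].to_numpy(dtype=np.int64)[ok],
        "ref": pileups["ref"].to_numpy()[ok],
        "alt": base_arr[alt_idx[ok]],
        "genotype": np.array(GENOTYPES, dtype=object)[map_idx[ok]],
        "depth": depth[ok],
        "alt_fraction": alt_frac[ok],
        "alt_forward": alt_fwd[ok],
        "alt_reverse": alt_rev[ok],
        "genotype_posterior": map_post[ok],
        "tier": profile.name,
        "variant_class": "snv",
    })
    return CallSet(sid, src, profile.name, calls.reset_index(drop=True))


@dataclass(frozen=True)
class IndelCandidate:
    """An imported/simulated small-indel candidate with its filter evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    indel_mapping_quality: float
    anchor_mapping_quality: float
    mean_end_distance: float
    depth: int
    alt_forward: int
    alt_reverse: int

    @property
    def variant_class(self) -> str:
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


def filter_indel(candidate: IndelCandidate,
                 params: Optional[IndelFilterParams] = None) -> tuple[bool, Optional[str]]:
    """Apply the hard indel filters; returns (passed, first_violated_rule)."""
    params = params or IndelFilterParams()
    checks = (
        ("indel_mapping_quality",
         candidate.indel_mapping_quality >= params.min_indel_mapping_quality),
        ("anchor_mapping_quality",
         candidate.anchor_mapping_quality >= params.min_anchor_mapping_quality),
        ("end_distance",
         candidate.mean_end_distance >= params.min_mean_end_distance),
        ("coverage", candidate.depth >= params.min_coverage),
        ("both_strands",
         (not params.require_both_strands)
         or (candidate.alt_forward >= 1 and candidate.alt_reverse >= 1)),
        ("length",
         (candidate.variant_class == "insertion"
          and 1 <= candidate.indel_length <= params.max_insertion_length)
         or (candidate.variant_class == "deletion"
             and 1 <= candidate.indel_length <= params.max_deletion_length)),
    )
    for rule, passed in checks:
        if not passed:
            return False, rule
    return True, None


@dataclass(frozen=True)
class CoverageSummary:
    mean_depth: float
    fraction_at_or_above_threshold: float
    threshold: int


def coverage_summary(pileups: pd.DataFrame, targets: Sequence[TargetRegion],
                     depth_threshold: int = 8) -> CoverageSummary:
    """Depth summary over all targeted positions of one sample-source.

    Positions without a pileup record count as depth 0, so with a sparse
    pileup emission this reports coverage of the *emitted* evidence over
    the full target space.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("targets must be non-empty")
    total_bp = sum(len(t) for t in targets)
    if len(pileups) == 0:
        return CoverageSummary(0.0, 0.0, depth_threshold)
    if pileups[["sample", "source"]].drop_duplicates().shape[0] > 1:
        raise ValueError("coverage_summary expects a single sample-source pileup set")
    count_cols = [f"{b}_{s}" for b in BASES for s in ("fwd", "rev")]
    depth = pileups[count_cols].to_numpy(dtype=np.int64).sum(axis=1)
    return CoverageSummary(
        mean_depth=float(depth.sum()) / total_bp,
        fraction_at_or_above_threshold=float((depth >= depth_threshold).sum()) / total_bp,
        threshold=depth_threshold,
    )


def pileup_from_row(row) -> SitePileup:
    """Build a scalar :class:`SitePileup` from one pileup-table row."""
    counts = {b: (int(row[f"{b}_fwd"]), int(row[f"{b}_rev"])) for b in BASES}
    bq = {b: float(row[f"{b}_bq"]) for b in BASES}
    return SitePileup(chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
                      counts=counts, base_quality=bq,
                      mapping_quality=float(row["mq"]),
                      sample=row.get("sample"), source=row.get("source"))
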