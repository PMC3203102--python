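"""Diploid genotype caller: posterior model, hard filters, indels, coverage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lclfidelity.config import (HIGH, RESCUE, IndelFilterParams, ModelParams,
                                SimulationConfig)
from lclfidelity.genotyper import (GENOTYPES, IndelCandidate, SitePileup,
                                   call_sample, call_site, coverage_summary,
                                   filter_indel, genotype_posterior,
                                   genotype_posterior_arrays)
from lclfidelity.simulate import TargetRegion, simulate_tetrad

from conftest import make_pileup, make_pileup_frame, oracle_genotype_posterior


class TestPosterior:
    def test_deep_hom_ref_is_confident(self):
        p = make_pileup(ref_fwd=10, ref_rev=10, alt_fwd=0, alt_rev=0)
        post = genotype_posterior(p, het_prior=0.001, error_rate=0.001)
        assert post["hom-ref"] > 0.99

    def test_balanced_het_is_map(self):
        p = make_pileup(ref_fwd=5, ref_rev=5, alt_fwd=5, alt_rev=5)
        post = genotype_posterior(p, het_prior=0.001, error_rate=0.001)
        assert max(post, key=post.get) == "het"

    def test_zero_depth_gives_no_posterior(self):
        p = SitePileup("chr1", 1, "A", {}, {}, 40.0)
        assert genotype_posterior(p) is None

    def test_het_posterior_symmetric_in_alt_count(self):
        """The het likelihood is symmetric in k vs n-k; with a symmetric
        prior (theta=0.5 gives {1/4, 1/2, 1/4}) the posterior is too."""
        for k in range(0, 21):
            a = genotype_posterior_arrays(np.array([20 - k]), np.array([k]),
                                          0.5, 1e-3)[0][1]
            b = genotype_posterior_arrays(np.array([k]), np.array([20 - k]),
                                          0.5, 1e-3)[0][1]
            assert a == pytest.approx(b, rel=1e-9)

    @given(n_ref=st.integers(0, 400), n_alt=st.integers(0, 400),
           theta=st.floats(1e-6, 0.4), eps=st.floats(1e-6, 0.4))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_independent_enumeration(self, n_ref, n_alt, theta, eps):
        if n_ref + n_alt == 0:
            return
        got = genotype_posterior_arrays(np.array([n_ref]), np.array([n_alt]),
                                        theta, eps)[0]
        want = oracle_genotype_posterior(n_ref, n_alt, theta, eps)
        np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-12)


class TestCallSite:
    def test_coverage_below_8_no_call_under_high(self):
        p = make_pileup(ref_fwd=2, ref_rev=1, alt_fwd=2, alt_rev=2)  # depth 7
        assert call_site(p, HIGH) is None

    def test_15_8_percent_called_only_under_rescue(self):
        # depth 19 with 3 alt reads (15.8%), both strands, qualities 40
        p = make_pileup(ref_fwd=8, ref_rev=8, alt_fwd=2, alt_rev=1)
        assert call_site(p, HIGH) is None
        call = call_site(p, RESCUE)
        assert call is not None and call["genotype"] == "het"

    def test_no_alt_reads_never_called(self):
        p = make_pileup(ref_fwd=50, ref_rev=50)
        assert call_site(p, HIGH) is None
        assert call_site(p, RESCUE) is None

    def test_single_strand_alt_rejected_when_both_strands_required(self):
        p = make_pileup(ref_fwd=5, ref_rev=5, alt_fwd=10, alt_rev=0)
        assert call_site(p, HIGH) is None
        assert call_site(p, HIGH.replace(require_both_strands=False)) is not None

    def test_low_base_quality_rejected(self):
        p = make_pileup(ref_fwd=5, ref_rev=5, alt_fwd=5, alt_rev=5, alt_bq=39.0)
        assert call_site(p, HIGH) is None

    def test_low_mapping_quality_rejected_high_but_not_rescue(self):
        p = make_pileup(ref_fwd=5, ref_rev=5, alt_fwd=5, alt_rev=5, mq=35.0)
        assert call_site(p, HIGH) is None
        assert call_site(p, RESCUE) is not None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_pileup(ref_fwd=-1)

    def test_triallelic_tie_breaks_lexicographically(self):
        p = make_pileup(ref="A", alt="G", ref_fwd=5, ref_rev=5, alt_fwd=3,
                        alt_rev=3, C=(3, 3))
        call = call_site(p, HIGH.replace(min_alt_fraction=0.0))
        assert call["alt"] == "C"


class TestCallSample:
    def test_empty_pileups_empty_callset(self):
        import pandas as pd
        from lclfidelity.simulate import PILEUP_COLUMNS
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in PILEUP_COLUMNS})
        assert len(call_sample(empty, HIGH)) == 0

    def test_duplicate_sites_rejected(self):
        df = make_pileup_frame([(100, "A", {"A": (5, 5), "C": (5, 5)}, 40, 40),
                                (100, "A", {"A": (5, 5), "C": (5, 5)}, 40, 40)])
        with pytest.raises(ValueError, match="duplicate"):
            call_sample(df, HIGH)

    def test_unsorted_sites_rejected(self):
        df = make_pileup_frame([(200, "A", {"A": (5, 5)}, 40, 40),
                                (100, "A", {"A": (5, 5)}, 40, 40)])
        with pytest.raises(ValueError, match="sorted"):
            call_sample(df, HIGH)

    def test_truth_recovery_at_zero_error(self):
        """Error-free deep pileups recover truth genotypes with no false calls."""
        cfg = SimulationConfig(seed=3, base_error_rate=0.0, de_novo_rate=0.0,
                               invariant_site_density=0.05)
        sim = simulate_tetrad(cfg)
        v = sim.truth.variants
        for sample in ("father", "child2"):
            sub = sim.pileups[(sim.pileups["sample"] == sample)
                              & (sim.pileups["source"] == "PBMC")]
            cs = call_sample(sub.reset_index(drop=True), HIGH)
            got = cs.genotypes()
            truth_gt = {}
            for _, row in v[v[f"gt_{sample}_PBMC"] > 0].iterrows():
                key = (row["chrom"], row["pos"], row["ref"], row["alt"])
                truth_gt[key] = GENOTYPES[int(row[f"gt_{sample}_PBMC"])]
            assert set(got) == set(truth_gt)
            mismatches = {k for k in got if got[k] != truth_gt[k]}
            assert not mismatches

    def test_high_calls_subset_of_rescue_calls(self, rng):
        """Threshold monotonicity on random pileups: HIGH subset of RESCUE."""
        rows = []
        for i in range(400):
            depth = int(rng.integers(1, 40))
            alt = int(rng.integers(0, depth + 1))
            af = int(rng.integers(0, alt + 1))
            rf = int(rng.integers(0, depth - alt + 1))
            rows.append((100 + i, "A",
                         {"A": (rf, depth - alt - rf), "G": (af, alt - af)},
                         float(rng.choice([20, 40])), float(rng.choice([20, 30, 40]))))
        df = make_pileup_frame(rows)
        high = call_sample(df, HIGH)
        rescue = call_sample(df, RESCUE)
        assert high.keys() <= rescue.keys()

    def test_relaxing_single_threshold_never_removes_calls(self, rng):
        rows = []
        for i in range(200):
            depth = int(rng.integers(4, 30))
            alt = int(rng.integers(0, depth + 1))
            rows.append((100 + i, "T",
                         {"T": (depth - alt, 0), "C": (alt // 2, alt - alt // 2)},
                         40.0, float(rng.choice([30, 40]))))
        df = make_pileup_frame(rows)
        base = call_sample(df, HIGH).keys()
        for relaxed in (HIGH.replace(min_coverage=5),
                        HIGH.replace(min_alt_fraction=0.15),
                        HIGH.replace(min_mapping_quality=30.0),
                        HIGH.replace(require_both_strands=False)):
            assert base <= call_sample(df, relaxed).keys()

    def test_false_call_rate_below_binomial_tail(self, rng):
        """At eps=0.01 and depth 8, hom-ref false calls are rarer than the
        two-of-eight binomial tail (the strand and fraction rules bite)."""
        n = 20_000
        alt = rng.binomial(8, 0.01, size=n)
        af = rng.binomial(alt, 0.5)
        rows = [(100 + i, "A", {"A": (4, 4 - int(a)), "C": (int(f), int(a) - int(f))},
                 40.0, 40.0)
                for i, (a, f) in enumerate(zip(alt, af))]
        df = make_pileup_frame(rows)
        false_rate = len(call_sample(df, HIGH)) / n
        from scipy.stats import binom
        tail = binom.sf(1, 8, 0.01)  # P(alt reads >= 2 of 8)
        assert false_rate < tail


class TestIndelFilter:
    def _candidate(self, **kw):
        base = dict(chrom="chr1", pos=100, ref="AT", alt="A",
                    indel_mapping_quality=50, anchor_mapping_quality=20,
                    mean_end_distance=10, depth=8, alt_forward=2, alt_reverse=2)
        base.update(kw)
        return IndelCandidate(**base)

    def test_low_indel_mapping_quality_fails_first(self):
        ok, reason = filter_indel(self._candidate(indel_mapping_quality=45))
        assert (ok, reason) == (False, "indel_mapping_quality")

    def test_short_end_distance_fails(self):
        ok, reason = filter_indel(self._candidate(mean_end_distance=8))
        assert (ok, reason) == (False, "end_distance")

    def test_exact_thresholds_pass(self):
        ok, reason = filter_indel(self._candidate())
        assert (ok, reason) == (True, None)

    def test_single_strand_fails(self):
        ok, reason = filter_indel(self._candidate(alt_reverse=0))
        assert (ok, reason) == (False, "both_strands")

    def test_overlong_deletion_fails_length(self):
        ok, reason = filter_indel(self._candidate(ref="A" + "T" * 12, alt="A"))
        assert (ok, reason) == (False, "length")

    def test_insertion_length_bounds(self):
        ok, _ = filter_indel(self._candidate(ref="A", alt="ATTT"))
        assert ok
        ok, reason = filter_indel(self._candidate(ref="A", alt="ATTTT"))
        assert (ok, reason) == (False, "length")


class TestCoverageSummary:
    def test_uniform_depth_above_threshold(self):
        targets = [TargetRegion("chr1", 0, 10)]
        rows = [(p, "A", {"A": (5, 5)}, 40, 40) for p in range(1, 11)]
        cov = coverage_summary(make_pileup_frame(rows), targets, 8)
        assert cov.fraction_at_or_above_threshold == 1.0
        assert cov.mean_depth == 10.0

    def test_no_pileups_zero_coverage(self):
        import pandas as pd
        from lclfidelity.simulate import PILEUP_COLUMNS
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in PILEUP_COLUMNS})
        cov = coverage_summary(empty, [TargetRegion("chr1", 0, 100)], 8)
        assert cov.mean_depth == 0.0 and cov.fraction_at_or_above_threshold == 0.0

    def test_poisson_125_nearly_all_above_8(self):
        cfg = SimulationConfig(seed=9, genome_length=1_000_000, n_target_regions=4,
                               target_region_length=1_000, variant_density=0.0,
                               invariant_site_density=1.0)
        sim = simulate_tetrad(cfg)
        sub = sim.pileups[(sim.pileups["sample"] == "father")
                          & (sim.pileups["source"] == "PBMC")]
        cov = coverage_summary(sub, sim.targets, 8)
        assert cov.fraction_at_or_above_threshold > 0.999
        assert cov.mean_depth == pytest.approx(125.0, rel=0.05)
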