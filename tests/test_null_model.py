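"""Monte-Carlo null machinery: resampling, determinism, calibration."""

import numpy as np
import pytest

from syndinuc import (
    CodingSequence,
    FramePosition,
    UndefinedMetricError,
    null_distribution,
    null_distributions,
    record_rng,
    resample_synonymous,
    sdu,
    significance_call,
)


class TestResampling:
    def test_translation_preserved(self, make_random_cds):
        seq = make_random_cds(80, seed=4)
        rng = np.random.default_rng(0)
        for _ in range(5):
            new = resample_synonymous(seq, rng)
            assert new.aa_seq == seq.aa_seq
            assert len(new.codons) == len(seq.codons)

    def test_all_met_unchanged(self):
        seq = CodingSequence.from_string("m", "AUG" * 6)
        new = resample_synonymous(seq, np.random.default_rng(1))
        assert new.codons == seq.codons

    def test_uniform_codon_frequencies(self):
        """Each Thr codon drawn ~1/4 of the time over many resamples."""
        from scipy.stats import chisquare

        seq = CodingSequence.from_string("t", "ACG")
        rng = np.random.default_rng(123)
        n = 10000
        counts = {}
        for _ in range(n):
            codon = resample_synonymous(seq, rng).codons[0]
            counts[codon] = counts.get(codon, 0) + 1
        observed = [counts.get(c, 0) for c in ("ACU", "ACC", "ACA", "ACG")]
        assert chisquare(observed).pvalue > 1e-4

    def test_ambiguous_codons_kept(self):
        seq = CodingSequence.from_string("a", "AUGNNNACG")
        new = resample_synonymous(seq, np.random.default_rng(2))
        assert new.codons[1] == "NNN"


class TestNullDistribution:
    def test_mean_near_one(self, make_random_cds):
        seq = make_random_cds(300, seed=8)
        dist = null_distribution(seq, "CG", "bridge", n_iter=1000, seed=5)
        se = dist.sd / np.sqrt(dist.n_iter)
        assert dist.mean == pytest.approx(1.0, abs=3 * se)

    def test_seeded_reproducibility(self, make_random_cds):
        seq = make_random_cds(100, seed=1)
        a = null_distribution(seq, "CG", "pos2", n_iter=200, seed=77)
        b = null_distribution(seq, "CG", "pos2", n_iter=200, seed=77)
        assert np.array_equal(a.samples, b.samples)
        assert a.summary() == b.summary()

    def test_record_substreams_order_independent(self):
        r1 = record_rng(9, "alpha").random(3)
        r2 = record_rng(9, "beta").random(3)
        r1_again = record_rng(9, "alpha").random(3)
        assert np.array_equal(r1, r1_again)
        assert not np.array_equal(r1, r2)

    def test_vectorized_matches_scalar_route(self, make_random_cds):
        """Fast engine is bit-identical to resample + recompute per draw."""
        seq = make_random_cds(60, seed=6)
        n = 20
        fast = null_distribution(
            seq, "CG", "bridge", n_iter=n, rng=np.random.default_rng(42)
        )
        rng = np.random.default_rng(42)
        slow = [sdu(resample_synonymous(seq, rng), "CG", "bridge") for _ in range(n)]
        assert np.array_equal(fast.samples, np.array(slow))

    def test_shared_resamples_consistent_with_single_cell(self, make_random_cds):
        seq = make_random_cds(60, seed=6)
        multi = null_distributions(
            seq, [("CG", "bridge"), ("UA", "pos2")], n_iter=50, seed=3
        )
        single = null_distribution(seq, "CG", "bridge", n_iter=50, seed=3)
        assert np.array_equal(
            multi[("CG", FramePosition.BRIDGE)].samples, single.samples
        )

    def test_undefined_cell_raises(self):
        seq = CodingSequence.from_string("t", "ACGACG")
        with pytest.raises(UndefinedMetricError):
            null_distribution(seq, "CG", "pos1", n_iter=10, seed=0)

    def test_rsdu_null_bounded(self, make_random_cds):
        seq = make_random_cds(120, seed=10)
        dist = null_distribution(
            seq, "CG", "bridge", n_iter=200, seed=1, metric="rsdu"
        )
        assert 0.0 <= dist.min and dist.max <= 1.0

    def test_summary_recomputable(self, make_random_cds):
        seq = make_random_cds(50, seed=2)
        dist = null_distribution(seq, "UA", "pos2", n_iter=100, seed=4)
        assert dist.min == float(np.min(dist.samples))
        assert dist.max == float(np.max(dist.samples))
        assert dist.sd == pytest.approx(float(np.std(dist.samples, ddof=1)))
        assert dist.quantile(0.5) == np.quantile(dist.samples, 0.5)


class TestSignificance:
    def test_range_rule(self, make_random_cds):
        seq = make_random_cds(200, seed=12)
        dist = null_distribution(seq, "CG", "bridge", n_iter=500, seed=9)
        assert significance_call(1.0, dist) == "within"
        assert significance_call(dist.min - 0.01, dist) == "under"
        assert significance_call(dist.max + 0.01, dist) == "over"

    def test_quantile_rule_is_tighter(self, make_random_cds):
        seq = make_random_cds(200, seed=12)
        dist = null_distribution(seq, "CG", "bridge", n_iter=500, seed=9)
        edge = dist.min + 1e-9  # inside the range but below the 2.5% quantile
        assert significance_call(edge, dist, rule="range") == "within"
        assert significance_call(edge, dist, rule="quantile") == "under"

    def test_null_calibration_coverage(self, make_random_cds):
        """Observed values drawn under the null fall within the resampled
        range in roughly the nominal fraction 1 - 2/(n_iter + 1)."""
        seq = make_random_cds(150, seed=20)
        rng = np.random.default_rng(30)
        n_iter = 99
        reps = 200
        hits = 0
        for _ in range(reps):
            observed = sdu(resample_synonymous(seq, rng), "CG", "bridge")
            dist = null_distribution(seq, "CG", "bridge", n_iter=n_iter, rng=rng)
            hits += significance_call(observed, dist) == "within"
        nominal = 1 - 2 / (n_iter + 1)
        se = np.sqrt(nominal * (1 - nominal) / reps)
        assert hits / reps >= nominal - 4 * se
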