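"""Overlap sensitivity, PPV, curve averaging and PWM motif scanning."""

import numpy as np
import pytest

from ctrlpool.enrichment import Region, RegionSet
from ctrlpool.evaluation import (
    PWM,
    OverlapCurve,
    average_curves,
    overlap_sensitivity,
    ppv,
    scan_motif,
)


def _set(intervals, label="x"):
    """RegionSet from (start, end) tuples on chr1, ranked in given order."""
    regions = [
        Region("chr1", s, e, float(len(intervals) - i), rank=i + 1)
        for i, (s, e) in enumerate(intervals)
    ]
    return RegionSet(regions, caller_label=label)


def _brute_ppv(candidate, gold):
    hits = 0
    for c in candidate.regions:
        if any(
            c.chrom == g.chrom and min(c.end, g.end) - max(c.start, g.start) >= 1
            for g in gold.regions
        ):
            hits += 1
    return hits / len(candidate.regions)


def _brute_sensitivity(candidate, gold, k):
    ng = int(np.ceil(k / 100 * len(gold.regions)))
    nc = int(np.ceil(k / 100 * len(candidate.regions)))
    g_top = gold.sorted_by_rank()[:ng]
    c_top = candidate.sorted_by_rank()[:nc]
    hits = 0
    for g in g_top:
        if any(
            g.chrom == c.chrom and min(g.end, c.end) - max(g.start, c.start) >= 1
            for c in c_top
        ):
            hits += 1
    return hits / ng


class TestOverlapSensitivity:
    def test_identity_is_one_everywhere(self):
        gold = _set([(0, 100), (200, 300), (400, 500), (600, 700)])
        curve = overlap_sensitivity(gold, gold)
        assert np.all(curve.sensitivity == 1.0)

    def test_disjoint_is_zero_everywhere(self):
        gold = _set([(0, 100), (200, 300)])
        cand = _set([(1000, 1100), (1200, 1300)])
        assert np.all(overlap_sensitivity(cand, gold).sensitivity == 0.0)

    def test_four_peak_hand_case(self):
        """Top 2 coincide, bottom 2 disjoint: k=50 -> 1.0, k=100 -> 0.5."""
        gold = _set([(0, 100), (200, 300), (400, 500), (600, 700)])
        cand = _set([(0, 100), (200, 300), (1000, 1100), (1200, 1300)])
        curve = overlap_sensitivity(cand, gold, k_grid=np.array([50.0, 100.0]))
        assert curve.sensitivity[0] == 1.0
        assert curve.sensitivity[1] == 0.5

    def test_superset_candidate_at_k100(self):
        gold = _set([(0, 100), (200, 300)])
        cand = _set([(500, 600), (0, 100), (200, 300)])  # contains gold spatially
        curve = overlap_sensitivity(cand, gold, k_grid=np.array([100.0]))
        assert curve.sensitivity[0] == 1.0

    def test_empty_candidate_gives_zero_curve(self):
        gold = _set([(0, 100)])
        curve = overlap_sensitivity(RegionSet([]), gold)
        assert np.all(curve.sensitivity == 0.0)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError, match="gold"):
            overlap_sensitivity(_set([(0, 100)]), RegionSet([]))

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(5):
            gold_iv = sorted(rng.choice(5000, size=20, replace=False))
            cand_iv = sorted(rng.choice(5000, size=30, replace=False))
            gold = _set([(int(s) * 10, int(s) * 10 + 8) for s in gold_iv])
            cand = _set([(int(s) * 10, int(s) * 10 + 8) for s in cand_iv])
            for k in (10.0, 35.0, 70.0, 100.0):
                got = overlap_sensitivity(cand, gold, k_grid=np.array([k])).sensitivity[0]
                assert got == pytest.approx(_brute_sensitivity(cand, gold, k), abs=1e-12)

    def test_equal_depth_mode_not_rewarding_bloat(self):
        """A candidate padded with junk peaks gains nothing under equal_depth."""
        gold = _set([(i * 100, i * 100 + 50) for i in range(10)])
        # candidate ranks 5 junk peaks above the true ones
        cand = _set(
            [(10_000 + i * 100, 10_050 + i * 100) for i in range(5)]
            + [(i * 100, i * 100 + 50) for i in range(10)]
        )
        k = np.array([50.0])
        sym = overlap_sensitivity(cand, gold, k_grid=k, mode="symmetric").sensitivity[0]
        eq = overlap_sensitivity(cand, gold, k_grid=k, mode="equal_depth").sensitivity[0]
        # symmetric truncation keeps ceil(0.5*15)=8 candidates (3 true), equal
        # depth keeps 5 (0 true)
        assert eq <= sym
        assert eq == 0.0

    def test_candidate_only_mode_uses_full_gold(self):
        gold = _set([(0, 100), (200, 300), (400, 500), (600, 700)])
        cand = _set([(0, 100), (200, 300)])
        got = overlap_sensitivity(
            cand, gold, k_grid=np.array([100.0]), mode="candidate_only"
        ).sensitivity[0]
        assert got == 0.5


class TestPPV:
    def test_subset_is_one(self):
        gold = _set([(0, 100), (200, 300), (400, 500)])
        cand = _set([(0, 100), (200, 300)])
        assert ppv(cand, gold) == 1.0

    def test_disjoint_is_zero(self):
        assert ppv(_set([(1000, 1100)]), _set([(0, 100)])) == 0.0

    def test_two_of_three(self):
        gold = _set([(0, 100), (200, 300)])
        cand = _set([(0, 50), (250, 350), (900, 950)])
        assert ppv(cand, gold) == pytest.approx(2 / 3)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            gold = _set([(int(s) * 10, int(s) * 10 + 9)
                         for s in sorted(rng.choice(3000, 40, replace=False))])
            cand = _set([(int(s) * 10, int(s) * 10 + 9)
                         for s in sorted(rng.choice(3000, 50, replace=False))])
            assert ppv(cand, gold) == pytest.approx(_brute_ppv(cand, gold), abs=1e-12)

    def test_empty_candidate_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            assert np.isnan(ppv(RegionSet([]), _set([(0, 100)])))


class TestAverageCurves:
    def test_identical_curves(self):
        k = np.array([50.0, 100.0])
        c = OverlapCurve(k, np.array([0.5, 1.0]))
        avg = average_curves([c, c, c])
        assert np.allclose(avg.sensitivity, [0.5, 1.0])
        assert np.allclose(avg.sd, 0.0)
        assert avg.n_repeats == 3

    def test_zero_one_pair(self):
        k = np.array([50.0])
        avg = average_curves(
            [OverlapCurve(k, np.array([0.0])), OverlapCurve(k, np.array([1.0]))]
        )
        assert avg.sensitivity[0] == pytest.approx(0.5)
        assert avg.sd[0] == pytest.approx(np.sqrt(0.5), abs=1e-12)  # ~0.707

    def test_grid_mismatch_rejected(self):
        a = OverlapCurve(np.array([50.0]), np.array([1.0]))
        b = OverlapCurve(np.array([25.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="grid"):
            average_curves([a, b])


def _degenerate_pwm(consensus="ACGTAC"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, idx[b]] = 100
    return PWM.from_counts("synthetic_consensus", counts)


class TestPWM:
    def test_rows_validated(self):
        with pytest.raises(ValueError, match="sum"):
            PWM("bad", np.full((4, 4), 0.3))

    def test_from_jaspar_round_trip(self, tmp_path):
        # synthetic JASPAR-format matrix (not a database entry)
        p = tmp_path / "synthetic_motif.jaspar"
        p.write_text(
            ">SYN0001.1 synthetic_test_motif\n"
            "A [ 10  0 20  5 ]\n"
            "C [  0 30  0  5 ]\n"
            "G [ 20  0 10  5 ]\n"
            "T [  0  0  0 15 ]\n"
        )
        pwm = PWM.from_jaspar(p)
        assert pwm.width == 4
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
        # column 1 is all-C up to pseudocount
        assert pwm.matrix[1, 1] > 0.99

    def test_consensus_sequence_is_hit(self):
        pwm = _degenerate_pwm("ACGTAC")
        peaks = _set([(0, 30)])
        genome = {"chr1": "T" * 10 + "ACGTAC" + "T" * 14}
        res = scan_motif(peaks, genome, pwm, p_threshold=0.01)
        assert res.hits == [True]
        assert res.occurrence_rate == 1.0

    def test_background_rate_matches_p_threshold(self, rng):
        """Forward-strand per-position hit rate ~ p under the background model.

        Uses an informative but non-degenerate matrix so the null score
        distribution is close to continuous and the realized rate can sit
        near the nominal p rather than at a sparse attainable level.
        """
        counts = rng.dirichlet(np.full(4, 0.8), size=10) * 100
        pwm = PWM.from_counts("synthetic_smooth", counts)
        thr = pwm.score_threshold(0.01)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, size=120_000)])
        scores = pwm.scan(seq, both_strands=False)
        rate = float(np.mean(scores >= thr))
        # binomial MC error at n=120k, p=0.01 is ~0.0003; allow 5 sigma + DP grain
        assert rate == pytest.approx(0.01, abs=0.004)

    def test_threshold_never_exceeds_nominal_p(self):
        """Exact enumeration: P(score >= threshold) <= p, even for a matrix
        whose attainable tail probabilities straddle p."""
        for consensus, p in [("ACGT", 0.05), ("ACGT", 0.01), ("ACGTA", 0.01)]:
            pwm = _degenerate_pwm(consensus)
            thr = pwm.score_threshold(p)
            lo = pwm.log_odds()
            w = pwm.width
            scores = []
            for word in range(4**w):
                idx = [(word >> (2 * i)) & 3 for i in range(w)]
                scores.append(sum(lo[i, b] for i, b in enumerate(idx)))
            exact_p = np.mean(np.array(scores) >= thr)
            assert exact_p <= p + 1e-9

    def test_n_heavy_peak_excluded(self):
        pwm = _degenerate_pwm("ACGTAC")
        peaks = _set([(0, 30), (40, 60)])
        genome = {"chr1": "T" * 4 + "ACGTAC" + "T" * 30 + "N" * 60}
        res = scan_motif(peaks, genome, pwm)
        assert res.n_excluded == 1
        assert res.hits[1] is None
        assert res.occurrence_rate == 1.0  # denominator excludes the N peak

    def test_empty_peak_set_rejected(self):
        pwm = _degenerate_pwm()
        with pytest.raises(ValueError, match="empty"):
            scan_motif(RegionSet([]), {"chr1": "ACGT"}, pwm)
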