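"""PWM scanning, occupancy scoring, hypergeometric machinery and PMET."""

import math
from itertools import combinations

import numpy as np
import pytest

from primedpeaks.intervals import annotate_closest_tss, filter_tss_window
from primedpeaks.motifs import (
    OccupancyScore,
    PositionWeightMatrix,
    bh_adjust,
    binomial_occupancy_score,
    logodds_scan,
    paired_enrichment,
    rank_and_top,
    run_pmet,
    set_overlap_test,
    single_motif_enrichment,
)
from primedpeaks import simulate as sim

REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(REVCOMP)[::-1]


class TestLogoddsScan:
    def test_consensus_single_hit_at_max_score(self, sharp_pwm):
        hits = logodds_scan(sharp_pwm, sharp_pwm.consensus, "p", sharp_pwm.max_score)
        assert len(hits) == 1
        h = hits[0]
        assert (h.offset, h.strand) == (0, "+")
        assert h.score == pytest.approx(sharp_pwm.max_score)

    def test_reverse_complement_hit_reported_forward(self, sharp_pwm):
        seq = "T" * 5 + revcomp(sharp_pwm.consensus) + "T" * 5
        hits = logodds_scan(sharp_pwm, seq, "p", sharp_pwm.max_score)
        assert [(h.offset, h.strand) for h in hits] == [(5, "-")]

    def test_short_sequence_empty(self, sharp_pwm):
        assert logodds_scan(sharp_pwm, "ACG", "p", 0.0) == []

    def test_windows_with_n_skipped(self, sharp_pwm):
        seq = sharp_pwm.consensus[:3] + "N" + sharp_pwm.consensus[4:]
        assert logodds_scan(sharp_pwm, seq, "p", -100.0) == []

    def test_matches_bruteforce_enumeration(self, sharp_pwm):
        rng = np.random.default_rng(42)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        hits = logodds_scan(sharp_pwm, seq, "p", 0.0)
        lom = np.log2(sharp_pwm.probs / sharp_pwm.background)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = []
        for off in range(40 - 6 + 1):
            win = seq[off : off + 6]
            fwd = sum(lom[j, idx[b]] for j, b in enumerate(win))
            rev = sum(lom[j, idx[b]] for j, b in enumerate(revcomp(win)))
            if fwd >= 0:
                expected.append((off, "+", fwd))
            if rev >= 0:
                expected.append((off, "-", rev))
        got = [(h.offset, h.strand, h.score) for h in hits]
        assert len(got) == len(expected)
        for g, e in zip(sorted(got), sorted(expected)):
            assert g[:2] == e[:2] and g[2] == pytest.approx(e[2])


class TestBinomialOccupancyScore:
    def test_zero_hits_zero_score(self):
        assert binomial_occupancy_score(0, 100, 0.01) == 0.0

    def test_all_hits_closed_form(self):
        # P(X >= 3) with k=n=3 is p^3 = 1e-3 -> score 3
        assert binomial_occupancy_score(3, 3, 0.1) == pytest.approx(3.0)

    def test_matches_term_summation(self):
        from math import comb

        p = 0.05
        tail = sum(comb(10, i) * p**i * (1 - p) ** (10 - i) for i in range(2, 11))
        assert binomial_occupancy_score(2, 10, p) == pytest.approx(
            -math.log10(tail), rel=1e-12
        )

    def test_monotone_in_k_and_pbg(self):
        scores_k = [binomial_occupancy_score(k, 50, 0.1) for k in range(0, 51)]
        assert all(a <= b for a, b in zip(scores_k, scores_k[1:]))
        scores_p = [binomial_occupancy_score(5, 50, p) for p in (0.01, 0.05, 0.2, 0.5)]
        assert all(a >= b for a, b in zip(scores_p, scores_p[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_occupancy_score(5, 3, 0.1)
        with pytest.raises(ValueError):
            binomial_occupancy_score(1, 3, 0.0)


class TestRankAndTop:
    def _scores(self, pairs):
        return [OccupancyScore(pid, "m", 0, 10, s) for pid, s in pairs]

    def test_tie_broken_by_peak_id(self):
        top = rank_and_top(self._scores([("c", 5.0), ("b", 1.0), ("a", 1.0)]), 2)
        assert top == ["c", "a"]

    def test_top_n_exceeding_size_returns_all_ordered(self):
        top = rank_and_top(self._scores([("b", 1.0), ("a", 2.0)]), 10)
        assert top == ["a", "b"]

    def test_matches_full_sort_prefix(self):
        rng = np.random.default_rng(5)
        scores = self._scores(
            [(f"p{i:04d}", float(rng.integers(0, 100))) for i in range(1000)]
        )
        top = rank_and_top(scores, 100)
        full = sorted(scores, key=lambda s: (-s.score, s.peak_id))
        assert top == [s.peak_id for s in full[:100]]


def hyper_upper_oracle(N, K, n, k):
    """Upper-tail hypergeometric by direct combination counting."""
    denom = math.comb(N, n)
    num = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return num / denom


class TestPairedEnrichment:
    def test_zero_overlap_p_one(self):
        r = paired_enrichment({"a", "b", "c"}, {"a"}, {"b"}, {"c"})
        assert r.p_value == 1.0

    def test_hand_computed_example(self):
        # N=10, K=4, n=5, k=3 -> 66/252
        universe = {f"u{i}" for i in range(10)}
        both = {f"u{i}" for i in range(4)}
        test = {"u0", "u1", "u2", "u5", "u6"}
        r = paired_enrichment(universe, test, both, both)
        assert (r.both_in_universe, r.both_in_test) == (4, 3)
        assert r.p_value == pytest.approx(66 / 252)

    def test_test_set_equal_universe_certain(self):
        universe = {f"u{i}" for i in range(6)}
        both = {"u0", "u1"}
        r = paired_enrichment(universe, universe, both, both)
        assert r.both_in_test == r.both_in_universe and r.p_value == pytest.approx(1.0)

    def test_test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            paired_enrichment({"a"}, {"z"}, set(), set())

    def test_small_lattice_against_enumeration(self):
        # spot lattice here; the full N <= 15 sweep runs in the acceptance suite
        for N in (5, 9, 12):
            universe = {f"u{i}" for i in range(N)}
            for K in range(N + 1):
                both = {f"u{i}" for i in range(K)}
                for n in range(1, N + 1):
                    test = {f"u{i}" for i in range(n)}
                    r = paired_enrichment(universe, test, both, both)
                    k = len(test & both)
                    assert r.p_value == pytest.approx(
                        hyper_upper_oracle(N, K, n, k), rel=1e-10
                    )


class TestSingleMotifAndOverlap:
    def test_single_motif_matches_enumeration(self):
        universe = {f"u{i}" for i in range(20)}
        top = {f"u{i}" for i in range(5)}
        test = {f"u{i}" for i in range(3, 11)}  # n=8, k=2
        r = single_motif_enrichment(universe, test, top)
        k = len(test & top)
        assert r.motif_b is None
        assert r.p_value == pytest.approx(hyper_upper_oracle(20, 5, 8, k), rel=1e-10)

    def test_set_overlap_disjoint_and_full(self):
        universe = {f"g{i}" for i in range(12)}
        assert set_overlap_test({"g0"}, {"g1"}, universe) == 1.0
        assert set_overlap_test(universe, universe, universe) == pytest.approx(1.0)

    def test_set_overlap_matches_enumeration(self):
        universe = {f"g{i}" for i in range(12)}
        a = {f"g{i}" for i in range(4)}
        b = {f"g{i}" for i in range(1, 7)}  # overlap 3
        assert set_overlap_test(a, b, universe) == pytest.approx(
            hyper_upper_oracle(12, 4, 6, 3), rel=1e-10
        )


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_step_up_by_hand(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1.0, size=50)
        q = bh_adjust(p)
        perm = rng.permutation(50)
        q_perm = bh_adjust(p[perm])
        assert q_perm == pytest.approx(q[perm])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1.0, size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(q_sm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.2])


@pytest.fixture(scope="module")
def planted():
    genome = sim.make_genome_fixture(seed=1)
    fix = sim.make_motif_peak_fixture(genome, seed=1)
    ann = filter_tss_window(annotate_closest_tss(fix.peaks, genome.tss), 8000)
    return fix, ann


class TestRunPmet:
    def test_planted_pair_attains_minimum_q(self, planted):
        fix, ann = planted
        res = run_pmet(fix.sequences, fix.motifs, ann, fix.test_genes, top_n=150)
        best = res.best_pair()
        assert {best.motif_a, best.motif_b} == set(fix.planted_pair)

    def test_all_unordered_pairs_no_self(self, planted):
        fix, ann = planted
        res = run_pmet(fix.sequences, fix.motifs, ann, fix.test_genes, top_n=150)
        ids = sorted(m.motif_id for m in fix.motifs)
        expected = set(map(frozenset, combinations(ids, 2)))
        got = {frozenset((e.motif_a, e.motif_b)) for e in res.pairs}
        assert got == expected and len(res.pairs) == len(expected)

    def test_empty_test_gene_set_all_p_one(self, planted):
        fix, ann = planted
        res = run_pmet(fix.sequences, fix.motifs, ann, ["no_such_gene"], top_n=150)
        assert all(e.p_value == 1.0 for e in res.pairs)

    def test_fewer_than_two_motifs_rejected(self, planted):
        fix, ann = planted
        with pytest.raises(ValueError):
            run_pmet(fix.sequences, fix.motifs[:1], ann, fix.test_genes)

    def test_qvalues_are_bh_of_pvalues(self, planted):
        fix, ann = planted
        res = run_pmet(fix.sequences, fix.motifs, ann, fix.test_genes, top_n=150)
        qs = bh_adjust([e.p_value for e in res.pairs])
        assert [e.q_value for e in res.pairs] == pytest.approx(list(qs))

    def test_matrix_symmetric(self, planted):
        fix, ann = planted
        res = run_pmet(fix.sequences, fix.motifs, ann, fix.test_genes, top_n=150)
        mat = res.neglog10_q_matrix()
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
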