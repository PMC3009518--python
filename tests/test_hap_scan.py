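import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhapminer.founder_score import ScoredFounderHaplotype
from fhapminer.hap_scan import (
    DensityParams,
    SimilarityParams,
    cluster,
    max_similarity,
    q_score,
    q_score_one_sample,
    scan,
    similarity,
)

from oracles import allele_groups_at


def records(haps, scores):
    return [
        ScoredFounderHaplotype(
            family_id=f"F{i}",
            label=(f"F{i}", 0),
            haplotype=tuple(h),
            score=float(s),
            carrier_copies={},
        )
        for i, (h, s) in enumerate(zip(haps, scores))
    ]


class TestSimilarity:
    def test_identical_five_mers_score_ten(self):
        p = SimilarityParams(window=5)
        assert similarity([1, 1, 2, 1, 1], [1, 1, 2, 1, 1], 2, p) == 10

    def test_hand_counted_example(self):
        # "11011" vs "11001": 4 matches; run through the middle position
        # covers positions 1-3 -> L=3, S = 3 + 4 = 7
        p = SimilarityParams(window=5)
        h1 = [1, 1, 0, 1, 1]
        h2 = [1, 1, 0, 0, 1]
        assert similarity(h1, h2, 2, p) == 7

    def test_focal_mismatch_zeroes_run(self):
        p = SimilarityParams(window=5)
        h1 = [1, 1, 1, 1, 1]
        h2 = [1, 1, 2, 1, 1]
        assert similarity(h1, h2, 2, p) == 4  # N=4, L=0

    def test_window_clipping_at_ends(self):
        p = SimilarityParams(window=5)
        h = [1, 2, 1]
        assert similarity(h, h, 0, p) == max_similarity(0, 3, p) == 6
        assert similarity(h, h, 2, p) == 6

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            similarity([1], [1, 2], 0, SimilarityParams())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(1, 2), min_size=5, max_size=5),
        st.lists(st.integers(1, 2), min_size=5, max_size=5),
        st.integers(0, 4),
        st.integers(0, 2),
    )
    def test_symmetry_and_self_maximality(self, a, b, focal, halfw):
        p = SimilarityParams(window=2 * halfw + 1)
        assert similarity(a, b, focal, p) == similarity(b, a, focal, p)
        assert similarity(a, b, focal, p) <= similarity(a, a, focal, p)
        assert similarity(a, a, focal, p) == max_similarity(focal, 5, p)


class TestCluster:
    def test_clone_set_forms_single_cluster(self):
        rng = np.random.default_rng(0)
        clones = [[1, 1, 1, 1, 1]] * 10
        distinct = []
        while len(distinct) < 10:
            h = list(rng.integers(1, 4, size=5))
            if h != clones[0] and h not in distinct:
                distinct.append(h)
        haps = np.array(clones + distinct)
        params = SimilarityParams(window=5)
        got = cluster(haps, 2, params, DensityParams(min_pts=3, eps=0.0))
        # oracle: exhaustive pairwise distance matrix at eps=0 connects only
        # identical segments
        s_max = max_similarity(2, 5, params)
        n = len(haps)
        d = np.array(
            [[s_max - similarity(haps[i], haps[j], 2, params) for j in range(n)] for i in range(n)]
        )
        for i in range(10):
            assert all(d[i, j] == 0 for j in range(10))
            assert all(d[i, j] > 0 for j in range(10, n))
        assert len(got) == 1
        assert sorted(got[0]) == list(range(10))

    def test_all_identical_single_cluster(self):
        haps = np.ones((6, 3), dtype=int)
        got = cluster(haps, 1, SimilarityParams(window=3), DensityParams(min_pts=2))
        assert got == [list(range(6))]

    def test_min_pts_above_n_gives_no_cluster(self):
        haps = np.ones((4, 3), dtype=int)
        got = cluster(haps, 1, SimilarityParams(window=3), DensityParams(min_pts=5))
        assert got == []

    def test_window_one_equals_allele_groups(self):
        rng = np.random.default_rng(42)
        haps = rng.integers(1, 3, size=(60, 7))
        params = SimilarityParams(window=1)
        for focal in range(7):
            got = {
                frozenset(c)
                for c in cluster(haps, focal, params, DensityParams(min_pts=3))
            }
            assert got == allele_groups_at(haps, focal, min_pts=3)


class TestQScore:
    def test_equal_means_equal_variances(self):
        q, p = q_score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(1)
        cl = 2.0 + rng.normal(0, 1e-6, size=4)
        rest = rng.normal(0, 1e-6, size=4)
        q, p = q_score(list(cl), list(cl) + list(rest))
        assert p < 1e-6
        assert q > 0

    def test_sign_flip_negates_q_keeps_p(self):
        cl = [1.0, 2.0, 1.5]
        all_ = cl + [0.0, 0.3, -0.2, 0.1]
        q1, p1 = q_score(cl, all_)
        q2, p2 = q_score([-x for x in cl], [-x for x in all_])
        assert q2 == pytest.approx(-q1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_distinct_means(self):
        q, p = q_score([2.0, 2.0], [2.0, 2.0, 0.0, 0.0])
        assert math.isinf(q) and q > 0
        assert p == 0.0

    def test_degenerate_sizes_raise(self):
        with pytest.raises(ValueError):
            q_score([1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            q_score([1.0, 2.0], [1.0, 2.0])

    def test_matches_scipy_welch(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        cl = list(rng.normal(1, 1, size=6))
        rest = list(rng.normal(0, 2, size=9))
        q, p = q_score(cl, cl + rest)
        ref = stats.ttest_ind(cl, rest, equal_var=False)
        assert q == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_one_sample_variant(self):
        rng = np.random.default_rng(8)
        cl = list(rng.normal(1, 1, size=5))
        rest = list(rng.normal(0, 1, size=10))
        q, p = q_score_one_sample(cl, cl + rest)
        mu = np.mean(cl + rest)
        ref = (np.mean(cl) - mu) / np.sqrt(np.var(cl, ddof=1) / 5)
        assert q == pytest.approx(ref)


class TestScan:
    def test_single_marker_bonferroni_identity(self):
        rng = np.random.default_rng(0)
        haps = rng.integers(1, 3, size=(30, 1))
        scores = rng.normal(size=30)
        res = scan(records(haps, scores), SimilarityParams(window=1))
        (best,) = res.best
        if best is not None:
            assert best.p_adjusted == pytest.approx(best.p_raw)

    def test_planted_signal_dominates_every_marker(self):
        rng = np.random.default_rng(3)
        carrier = np.array([1, 1, 1, 1, 1])
        n_carrier, n_bg = 40, 160
        bg = rng.integers(1, 3, size=(n_bg, 5))
        haps = np.vstack([np.tile(carrier, (n_carrier, 1)), bg])
        scores = np.concatenate(
            [3.0 + rng.normal(0, 1, n_carrier), rng.normal(0, 1, n_bg)]
        )
        res = scan(records(haps, scores), SimilarityParams(window=5))
        for best in res.best:
            assert best is not None
            members = set(best.members)
            # the shifted clone set drives the top cluster at every marker
            # (similar background segments may join as border points)
            assert set(range(n_carrier)) <= members
            assert best.q > 0
        assert res.any_significant

    def test_adjusted_p_monotone_in_raw(self):
        rng = np.random.default_rng(5)
        haps = rng.integers(1, 3, size=(50, 6))
        scores = rng.normal(size=50)
        res = scan(records(haps, scores), SimilarityParams(window=1))
        pairs = [(b.p_raw, b.p_adjusted) for b in res.best if b is not None]
        assert all(padj >= praw for praw, padj in pairs)
        pairs.sort()
        assert all(
            a[1] <= b[1] + 1e-12 for a, b in zip(pairs, pairs[1:])
        )

    def test_permutation_correction_detects_planted_signal(self):
        rng = np.random.default_rng(9)
        carrier = np.array([2, 1, 2])
        bg = rng.integers(1, 3, size=(60, 3))
        haps = np.vstack([np.tile(carrier, (30, 1)), bg])
        scores = np.concatenate([2.5 + rng.normal(0, 1, 30), rng.normal(0, 1, 60)])
        res = scan(
            records(haps, scores),
            SimilarityParams(window=1),
            correction="permutation",
            permutations=200,
            rng=11,
        )
        assert res.any_significant
        for b in res.best:
            if b is not None:
                assert b.p_adjusted >= b.p_raw

    def test_oversized_window_warns_and_clips(self):
        rng = np.random.default_rng(2)
        haps = rng.integers(1, 3, size=(20, 3))
        scores = rng.normal(size=20)
        with pytest.warns(UserWarning, match="clipping"):
            scan(records(haps, scores), SimilarityParams(window=9))

    def test_null_scan_rarely_significant(self):
        # family-wise error under the null stays near the nominal level;
        # checked loosely here (the calibrated check runs at study scale)
        rng = np.random.default_rng(12)
        hits = 0
        n_scans = 60
        for _ in range(n_scans):
            haps = rng.integers(1, 3, size=(80, 5))
            scores = rng.normal(size=80)
            res = scan(records(haps, scores), SimilarityParams(window=1), alpha=0.05)
            hits += res.any_significant
        se = math.sqrt(0.05 * 0.95 / n_scans)
        assert hits / n_scans <= 0.05 + 3 * se
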