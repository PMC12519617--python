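"""Association statistics: Spearman, KW/Dunn, chi-square, adjustments."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from quadstrat.assoc_stats import (
    StatsError,
    bh_adjust,
    bonferroni_adjust,
    chi_square,
    correlation_matrix,
    dunn_posthoc,
    kruskal_wallis,
    pairwise_chi_square,
    spearman,
)


def _midranks(v):
    """Brute-force mid-rank assignment."""
    v = np.asarray(v, dtype=float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        tied = np.sum(v == x)
        out[i] = less + (tied + 1) / 2.0
    return out


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).r == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [5.0, 3.0, 8.0, 8.0, 1.0, 9.0]
        rx, ry = _midranks(x), _midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(StatsError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_exact_mode_agrees_with_asymptotic_on_strong_signal(self):
        x = np.arange(8.0)
        y = np.array([0.5, 1.2, 1.9, 3.1, 4.0, 4.9, 6.2, 7.1])
        exact = spearman(x, y, method="exact")
        approx = spearman(x, y)
        assert exact.r == pytest.approx(approx.r)
        assert exact.p < 0.05 and approx.p < 0.05

    def test_highlight_rule(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        res = spearman(x, x + rng.normal(size=200))
        assert res.highlight == (abs(res.r) > 0.1 and res.p < 0.05)


class TestCorrelationMatrix:
    def test_self_correlation_highlighted(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(30, 2)),
                          columns=["a", "b"])
        out = correlation_matrix(df)
        self_row = out[(out.a == "a") & (out.b == "a")].iloc[0]
        assert self_row.r == 1.0 and self_row.highlight

    def test_null_highlight_rate_small(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(2000, 12)),
                          columns=[f"c{i}" for i in range(12)])
        out = correlation_matrix(df)
        off = out[out.a != out.b]
        assert off["highlight"].mean() < 0.10

    def test_planted_block_all_positive_with_score(self, study_cohort):
        from quadstrat import scoring
        _, matrix = study_cohort
        z = scoring.zscore(matrix, scoring.PI_PROTEINS)
        df = matrix.data[list(scoring.PI_PROTEINS)].copy()
        df["PI_Score"] = scoring.pi_score(z)
        out = correlation_matrix(df)
        with_score = out[(out.b == "PI_Score") & (out.a != "PI_Score")]
        assert (with_score["r"] > 0).all()


class TestKruskalWallis:
    def test_two_identical_groups(self):
        res = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_h(self):
        # ranks 1..6: H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 27/7
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.H == pytest.approx(27.0 / 7.0, abs=1e-9)

    def test_all_tied_returns_h0_p1(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert (res.H, res.p) == (0.0, 1.0)

    def test_rank_invariance(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=n) for n in (8, 12, 9)]
        from scipy.stats import rankdata
        pooled = np.concatenate(groups)
        ranks = rankdata(pooled)
        bounds = np.cumsum([0, 8, 12, 9])
        ranked_groups = [ranks[bounds[i]:bounds[i + 1]] for i in range(3)]
        assert kruskal_wallis(groups).H == pytest.approx(
            kruskal_wallis(ranked_groups).H
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(StatsError):
            kruskal_wallis([[1.0], []])


class TestDunn:
    def test_identical_groups_capped_at_one(self):
        res = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.adjusted_p[0] == 1.0

    def test_all_tied_gives_p_one(self):
        res = dunn_posthoc([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert (res.adjusted_p == 1.0).all()

    def test_pair_ordering_matches_permutation_oracle(self):
        # exhaustive relabelings of 9 points across 3 groups of 3
        from scipy.stats import rankdata
        data = np.array([1.0, 2.0, 3.0, 2.5, 6.0, 7.0, 9.0, 10.0, 12.0])
        groups = [data[:3], data[3:6], data[6:]]
        res = dunn_posthoc(groups)

        ranks = rankdata(data)
        observed = {}
        for (i, j), _ in zip(itertools.combinations(range(3), 2), res.raw_p):
            idx = {0: slice(0, 3), 1: slice(3, 6), 2: slice(6, 9)}
            observed[(i, j)] = abs(ranks[idx[i]].mean() - ranks[idx[j]].mean())
        perm_counts = {k: 0 for k in observed}
        n_perm = 0
        for first in itertools.combinations(range(9), 3):
            rest = [i for i in range(9) if i not in first]
            for second in itertools.combinations(rest, 3):
                third = [i for i in rest if i not in second]
                n_perm += 1
                parts = {0: list(first), 1: list(second), 2: third}
                for (i, j) in observed:
                    diff = abs(ranks[parts[i]].mean() - ranks[parts[j]].mean())
                    if diff >= observed[(i, j)] - 1e-12:
                        perm_counts[(i, j)] += 1
        perm_p = np.array([perm_counts[k] / n_perm for k in observed])
        assert list(np.argsort(perm_p)) == list(np.argsort(res.raw_p))

    def test_planted_pair_detected(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            groups = [rng.normal(size=15) for _ in range(3)] + [
                rng.normal(loc=2.0, size=15)
            ]
            res = dunn_posthoc(groups, labels=list("abcd"))
            frame = res.as_frame()
            sig = frame[frame.adjusted_p < 0.05]
            hits += int(
                len(sig) >= 1 and all("d" in (r.group_a, r.group_b)
                                      for r in sig.itertuples())
            )
        assert hits >= 15


class TestChiSquare:
    def test_printed_epilepsy_status_statistic(self, table3):
        res = chi_square(table3["epilepsy_status"])
        assert res.statistic == pytest.approx(13.47, abs=0.005)
        assert res.df == 6

    def test_exact_independence(self):
        res = chi_square(np.array([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chi_square(np.array([[0, 0], [1, 2]]))

    @settings(max_examples=50, derandomize=True)
    @given(
        counts=arrays(np.int64, (3, 4), elements=st.integers(1, 40)),
    )
    def test_permutation_and_transpose_invariance(self, counts):
        base = chi_square(counts).statistic
        rng = np.random.default_rng(0)
        perm = counts[rng.permutation(3)][:, rng.permutation(4)]
        assert chi_square(perm).statistic == pytest.approx(base, rel=1e-9)
        assert chi_square(counts.T).statistic == pytest.approx(base, rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(counts=arrays(np.int64, (3, 3), elements=st.integers(1, 30)))
    def test_residuals_sum_to_zero(self, counts):
        c = counts.astype(float)
        expected = np.outer(c.sum(1), c.sum(0)) / c.sum()
        assert abs((c - expected).sum()) < 1e-8


class TestPairwiseChiSquare:
    def test_high_high_vs_normal_low_raw_p(self, table3):
        res = pairwise_chi_square(table3["epilepsy_status"])
        frame = res.as_frame().set_index(["group_a", "group_b"])
        assert frame.loc[("High-High", "Normal-Low"), "raw_p"] == pytest.approx(
            0.005, abs=0.0005
        )

    def test_identical_rows_give_p_one(self):
        t = pd.DataFrame([[5, 5], [5, 5], [1, 9]], index=list("abc"))
        res = pairwise_chi_square(t)
        frame = res.as_frame().set_index(["group_a", "group_b"])
        assert frame.loc[("a", "b"), "raw_p"] == pytest.approx(1.0)

    def test_zero_margin_column_dropped_not_fatal(self):
        t = pd.DataFrame([[5, 0, 3], [7, 0, 1], [2, 4, 2]], index=list("abc"))
        res = pairwise_chi_square(t)
        assert np.isfinite(res.raw_p).all()

    def test_needs_three_rows(self):
        with pytest.raises(StatsError):
            pairwise_chi_square(pd.DataFrame([[1, 2], [3, 4]]))


class TestAdjustments:
    def test_bh_hand_executed_stepup(self):
        p = [0.005, 0.008, 0.16, 0.63, 0.74, 0.76]
        assert np.allclose(
            bh_adjust(p), [0.024, 0.024, 0.32, 0.76, 0.76, 0.76], atol=1e-9
        )

    def test_singletons_unchanged(self):
        assert bh_adjust([0.01])[0] == pytest.approx(0.01)
        assert bonferroni_adjust([0.01])[0] == pytest.approx(0.01)

    def test_bonferroni_basic(self):
        assert np.allclose(bonferroni_adjust([0.01, 0.5]), [0.02, 1.0])

    def test_all_equal_collapse(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(
        p=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20)
    )
    def test_dominance_and_monotonicity(self, p):
        p = np.array(p)
        bh = bh_adjust(p)
        bonf = bonferroni_adjust(p)
        assert (bh >= p - 1e-12).all() and (bh <= 1.0 + 1e-12).all()
        assert (bonf >= bh - 1e-9).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(bh[order]) >= -1e-12).all()
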