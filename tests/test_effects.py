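"""Normality screen, fixed-effects ANOVA, Duncan grouping, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lactofit.effects import (anova_fixed_effects, correlation_matrix,
                              duncan_critical_range, duncan_mrt, ks_normality)
from lactofit.exceptions import DegenerateLactation, InsufficientData


class TestKsNormality:
    def test_accepts_large_normal_sample(self):
        x = np.random.default_rng(1).normal(10.0, 2.0, 10_000)
        assert ks_normality(x).normal

    def test_rejects_exponential_sample(self):
        x = np.random.default_rng(2).exponential(1.0, 10_000)
        assert not ks_normality(x).normal

    def test_rejection_rate_near_alpha_under_the_null(self):
        rng = np.random.default_rng(3)
        rejections = sum(
            not ks_normality(rng.normal(0, 1, 200)).normal for _ in range(200)
        )
        assert 0.01 <= rejections / 200 <= 0.10

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateLactation):
            ks_normality(np.full(50, 3.14))

    def test_small_sample_is_insufficient(self):
        with pytest.raises(InsufficientData):
            ks_normality([1.0, 2.0, 3.0])


def _toy_two_factor_balanced():
    """8-row balanced 2x2 design with 2 replicates per cell."""
    herd = np.repeat([1, 2], 4)
    litter = np.tile(np.repeat(["single", "twin"], 2), 2)
    y = np.array([10.0, 12.0, 20.0, 22.0, 14.0, 16.0, 24.0, 26.0])
    return pd.DataFrame({"herd": herd, "litter_size": litter, "TP": y})


class TestAnova:
    def test_balanced_toy_matches_hand_computed_sums_of_squares(self):
        """Classical two-way balanced ANOVA reproduced from first principles."""
        df = _toy_two_factor_balanced()
        y = df["TP"].to_numpy()
        grand = y.mean()
        # hand calculation: factor SS from marginal means, residual by subtraction
        ss_herd = sum(4 * (y[df["herd"] == h].mean() - grand) ** 2 for h in (1, 2))
        ss_lit = sum(4 * (y[df["litter_size"] == l].mean() - grand) ** 2
                     for l in ("single", "twin"))
        ss_tot = float(np.sum((y - grand) ** 2))
        ss_res = ss_tot - ss_herd - ss_lit  # no interaction in the model
        res = anova_fixed_effects(df, "TP", ["herd", "litter_size"])
        tab = res.table.set_index("factor")
        assert tab.loc["herd", "sum_sq"] == pytest.approx(ss_herd, abs=1e-8)
        assert tab.loc["litter_size", "sum_sq"] == pytest.approx(ss_lit, abs=1e-8)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(ss_res, abs=1e-8)
        f_herd = (ss_herd / 1) / (ss_res / 5)
        assert tab.loc["herd", "F"] == pytest.approx(f_herd, abs=1e-8)
        assert res.rsquared == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_ss_decomposition_on_balanced_design(self):
        df = _toy_two_factor_balanced()
        res = anova_fixed_effects(df, "TP", ["herd", "litter_size"])
        ss = res.table.set_index("factor")["sum_sq"]
        total = float(np.sum((df["TP"] - df["TP"].mean()) ** 2))
        assert ss.sum() == pytest.approx(total, rel=1e-8)

    def test_overwhelming_effect_is_highly_significant(self):
        rng = np.random.default_rng(4)
        n = 120
        herd = rng.integers(1, 6, n)
        y = rng.normal(0, 1, n) + np.where(herd == 1, 5.0, 0.0)  # 5-SD shift
        df = pd.DataFrame({"herd": herd, "kidding_year": rng.choice([1998, 1999, 2000], n),
                           "A": y})
        res = anova_fixed_effects(df, "A", ["herd", "kidding_year"])
        tab = res.table.set_index("factor")
        assert tab.loc["herd", "p"] < 0.01
        assert tab.loc["herd", "flag"] == "HS"

    def test_aliased_factor_reported_inestimable(self):
        rng = np.random.default_rng(5)
        n = 40
        herd = rng.integers(1, 3, n)
        df = pd.DataFrame({
            "herd": herd,
            "kidding_year": np.where(herd == 1, 1998, 1999),  # perfect alias
            "A": rng.normal(700, 50, n),
        })
        res = anova_fixed_effects(df, "A", ["herd", "kidding_year"])
        assert "kidding_year" in res.inestimable or "herd" in res.inestimable
        flagged = res.table.set_index("factor")["flag"]
        assert (flagged == "inestimable").any()

    def test_significance_flags_follow_thresholds(self):
        df = _toy_two_factor_balanced()
        res = anova_fixed_effects(df, "TP", ["herd", "litter_size"])
        for row in res.table.itertuples():
            if row.factor == "Residual" or not np.isfinite(row.p):
                continue
            expected = "HS" if row.p < 0.01 else ("S" if row.p < 0.05 else "NS")
            assert row.flag == expected


def _duncan_oracle(means, ns, ms_error, df_error, alpha=0.05):
    """Exhaustive pairwise oracle: every ordered pair tested against the
    explicit Duncan critical range, with the containment protection applied
    by brute force over all enclosing spans."""
    order = np.argsort(-np.asarray(means))
    m = np.asarray(means)[order]
    n = np.asarray(ns)[order]
    k = len(m)
    raw = {}
    for i in range(k):
        for j in range(i + 1, k):
            p = j - i + 1
            n_h = 2.0 / (1.0 / n[i] + 1.0 / n[j])
            rp = duncan_critical_range(p, df_error, ms_error, n_h, alpha)
            raw[(i, j)] = (m[i] - m[j]) > rp
    sig = {}
    # widest spans first; a pair inside a homogeneous span is homogeneous
    homogeneous = set()
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            contained = any(a <= i and j <= b for (a, b) in homogeneous)
            s = raw[(i, j)] and not contained
            sig[(i, j)] = s
            if not s:
                homogeneous.add((i, j))
    return order, sig


class TestDuncan:
    def test_identical_means_share_one_letter(self):
        values = np.tile([10.0, 10.0], 6)
        groups = np.repeat([1, 2, 3], 4)
        g = duncan_mrt(values, groups, ms_error=1.0, df_error=20)
        assert set(g.table["letters"]) == {"a"}

    def test_huge_separation_gets_distinct_letters(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(100, 1, 10)])
        groups = np.repeat(["lo", "hi"], 10)
        g = duncan_mrt(values, groups, ms_error=1.0, df_error=18)
        letters = g.letters()
        assert letters["hi"] != letters["lo"]
        assert g.table.iloc[0]["level"] == "hi"  # sorted descending

    def test_single_level_is_insufficient(self):
        with pytest.raises(InsufficientData):
            duncan_mrt([1.0, 2.0], ["a", "a"], 1.0, 5)

    @pytest.mark.parametrize("seed", range(50))
    def test_grouping_matches_exhaustive_pairwise_oracle(self, seed):
        """4-level synthetic cases across 50 seeds: the stepwise grouping
        separates exactly the pairs the explicit critical-range oracle does."""
        rng = np.random.default_rng(1000 + seed)
        k, n_per = 4, 8
        effects = rng.normal(0, rng.uniform(0.3, 3.0), k)
        values = np.concatenate([rng.normal(e, 1.0, n_per) for e in effects])
        groups = np.repeat(np.arange(k), n_per)
        df_err = k * n_per - k
        ms_err = float(np.mean([values[groups == g].var(ddof=1) for g in range(k)]))
        g = duncan_mrt(values, groups, ms_err, df_err)
        means = [values[groups == i].mean() for i in range(k)]
        order, oracle = _duncan_oracle(means, [n_per] * k, ms_err, df_err)
        lv = g.table["level"].to_numpy()
        for i in range(k):
            for j in range(i + 1, k):
                assert g.significant[(lv[i], lv[j])] == oracle[(i, j)], (i, j)
        # letters consistent with separation: shared letter iff not separated
        letters = g.letters()
        for i in range(k):
            for j in range(i + 1, k):
                shared = bool(set(letters[lv[i]]) & set(letters[lv[j]]))
                assert shared == (not oracle[(i, j)])

    def test_invariant_to_level_relabelling(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(m, 1.0, 6) for m in (0.0, 1.5, 4.0)])
        groups = np.repeat(["x", "y", "z"], 6)
        g1 = duncan_mrt(values, groups, 1.0, 15)
        relabel = {"x": "c3", "y": "c1", "z": "c2"}
        g2 = duncan_mrt(values, np.vectorize(relabel.get)(groups), 1.0, 15)
        l1, l2 = g1.letters(), g2.letters()
        for old, new in relabel.items():
            assert l1[old] == l2[new]

    def test_scaling_effects_never_merges_groups(self):
        rng = np.random.default_rng(10)
        base = np.array([0.0, 1.0, 2.5])
        noise = rng.normal(0, 1.0, (3, 8))
        def n_groups(scale):
            values = np.concatenate([scale * b + noise[i] for i, b in enumerate(base)])
            groups = np.repeat([1, 2, 3], 8)
            g = duncan_mrt(values, groups, 1.0, 21)
            return len(set(g.table["letters"]))
        assert n_groups(5.0) >= n_groups(1.0)


class TestCorrelations:
    def _table(self, n=1000, seed=12):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"A": rng.normal(730, 100, n),
                             "B": rng.normal(0.26, 0.04, n),
                             "C": rng.normal(0.09, 0.01, n)})

    def test_duplicated_trait_has_unit_correlation(self):
        df = self._table(50)
        df["A2"] = df["A"]
        r, p, flags = correlation_matrix(df, ["A", "A2", "B"])
        assert r.loc["A", "A2"] == pytest.approx(1.0)
        assert flags.loc["A", "A2"] == "**"

    def test_negated_trait_has_minus_one(self):
        df = self._table(50)
        df["negA"] = -df["A"]
        r, _, _ = correlation_matrix(df, ["A", "negA"])
        assert r.loc["A", "negA"] == pytest.approx(-1.0)

    def test_independent_traits_are_uncorrelated(self):
        r, _, _ = correlation_matrix(self._table(1000))
        off = r.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_matrix_symmetric_unit_diagonal_and_psd(self):
        r, _, _ = correlation_matrix(self._table(300))
        m = r.to_numpy()
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.linalg.eigvalsh(m).min() > -1e-10

    def test_zero_variance_trait_reported_missing(self):
        df = self._table(30)
        df["const"] = 5.0
        r, p, flags = correlation_matrix(df, ["A", "const"])
        assert np.isnan(r.loc["A", "const"])
        assert flags.loc["A", "const"] == "n/a"

    def test_too_few_rows_is_insufficient(self):
        with pytest.raises(InsufficientData):
            correlation_matrix(self._table(2))


def test_duncan_critical_values_match_classical_tables():
    """Spot-check q-based Duncan ranges against the classical significant-
    range tables (alpha = 0.05): r_p = q_Duncan(p, df) values."""
    # classical Duncan significant ranges (standardised), Harter (1960)
    classical = {(2, 10): 3.151, (3, 10): 3.293, (2, 20): 2.950,
                 (4, 20): 3.190, (2, 60): 2.829, (5, 60): 3.143}
    for (p, df), expected in classical.items():
        alpha_p = 1 - (1 - 0.05) ** (p - 1)
        q = stats.studentized_range.ppf(1 - alpha_p, p, df)
        assert q == pytest.approx(expected, abs=1.5e-2)
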