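"""Repeated-measures ANOVA, effect sizes, LSD contrasts, Q-Q screening."""

import itertools

import numpy as np
import pandas as pd
import pytest

from smo2kinetics.stats import (
    _effect_arrays,
    _subset_ss,
    adjusted_partial_eta_squared,
    classify_effect,
    fisher_lsd,
    qq_points,
    rm_anova,
    rm_anova_array,
)


def long_table(data, factors):
    """Array (subjects x levels...) -> long DataFrame."""
    rows = []
    for idx in np.ndindex(data.shape):
        row = {"subject": f"s{idx[0]}", "y": data[idx]}
        for name, lev in zip(factors, idx[1:]):
            row[name] = f"{name}{lev}"
        rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_by_two_hand_oracle(self):
        # grand mean 3, condition means 1.5/4.5, subject means 2/4:
        # SS_cond = 9, SS_err = 1 -> F(1,1) = 9
        tbl = pd.DataFrame(
            {"subject": ["s1", "s1", "s2", "s2"],
             "cond": ["a", "b", "a", "b"],
             "y": [1.0, 3.0, 2.0, 6.0]}
        )
        res = rm_anova(tbl, "y", "subject", ["cond"])[0]
        assert res.ss_effect == pytest.approx(9.0)
        assert res.ss_error == pytest.approx(1.0)
        assert res.F == pytest.approx(9.0)
        assert (res.df_effect, res.df_error) == (1, 1)
        assert res.adj_pes == pytest.approx(0.8)

    def test_identical_condition_means_give_zero_F(self):
        tbl = pd.DataFrame(
            {"subject": ["s1", "s1", "s2", "s2"],
             "cond": ["a", "b", "a", "b"],
             "y": [1.0, 1.0, 4.0, 4.0]}
        )
        res = rm_anova(tbl, "y", "subject", ["cond"])[0]
        assert res.F == 0.0

    def test_level_relabelling_changes_no_statistic(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 3, 2))
        tbl = long_table(data, ["A", "B"])
        base = {r.effect: (r.F, r.p) for r in rm_anova(tbl, "y", "subject", ["A", "B"])}
        relabel = tbl.assign(A=tbl["A"].map({"A0": "zz", "A1": "mm", "A2": "aa"}))
        swapped = {r.effect: (r.F, r.p)
                   for r in rm_anova(relabel, "y", "subject", ["A", "B"])}
        for eff in base:
            assert base[eff] == pytest.approx(swapped[eff])

    def test_ss_decomposition_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            shape = (int(rng.integers(3, 7)), int(rng.integers(2, 5)),
                     int(rng.integers(2, 4)))
            data = rng.normal(size=shape)
            eff = _effect_arrays(data)
            total = float(np.sum((data - data.mean()) ** 2))
            parts = sum(
                _subset_ss(eff, shape, frozenset(T))
                for r in range(1, data.ndim + 1)
                for T in itertools.combinations(range(data.ndim), r)
            )
            assert parts == pytest.approx(total, rel=1e-12, abs=1e-10)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(9)
        data = rng.normal(size=(8, 3, 2)) + np.arange(3)[None, :, None] * 0.4
        tbl = long_table(data, ["A", "B"])
        sm = AnovaRM(tbl, "y", "subject", within=["A", "B"]).fit().anova_table
        mine = {r.effect: r for r in rm_anova(tbl, "y", "subject", ["A", "B"])}
        for eff in ("A", "B", "A:B"):
            assert mine[eff].F == pytest.approx(sm.loc[eff, "F Value"], rel=1e-9)
            assert mine[eff].p == pytest.approx(sm.loc[eff, "Pr > F"], rel=1e-9)
            assert mine[eff].df_effect == int(sm.loc[eff, "Num DF"])
            assert mine[eff].df_error == int(sm.loc[eff, "Den DF"])

    def test_incomplete_design_names_offender(self):
        tbl = pd.DataFrame(
            {"subject": ["s1", "s1", "s2"],
             "cond": ["a", "b", "a"],
             "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="s2"):
            rm_anova(tbl, "y", "subject", ["cond"])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_array(np.zeros((1, 3)), ["A"])


class TestAdjustedPartialEtaSquared:
    @pytest.mark.parametrize(
        "F, dfe, dferr, expected",
        [
            (1.0, 1, 10, 0.0),           # null expectation removed
            (1.0, 4, 3, 0.0),
            (9.0, 1, 1, 0.8),            # matches the 2x2 oracle
            (4.0, 2, 18, 6.0 / 26.0),    # reconstructed-SS cross-check
            (0.2, 3, 12, 0.0),           # clipped below at zero
        ],
    )
    def test_formula(self, F, dfe, dferr, expected):
        assert adjusted_partial_eta_squared(F, dfe, dferr) == pytest.approx(expected)

    def test_bounded_above_by_partial_eta_squared(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            F = rng.uniform(1.0, 30.0)
            dfe = int(rng.integers(1, 6))
            dferr = int(rng.integers(2, 40))
            pes = dfe * F / (dfe * F + dferr)
            assert adjusted_partial_eta_squared(F, dfe, dferr) <= pes + 1e-12

    def test_invalid_dfs_rejected(self):
        with pytest.raises(ValueError):
            adjusted_partial_eta_squared(2.0, 0, 5)


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.00, "trivial"),
            (0.009, "trivial"),
            (0.01, "small"),
            (0.059, "small"),
            (0.06, "moderate"),
            (0.09, "moderate"),
            (0.137, "moderate"),
            (0.14, "large"),
            (0.21, "large"),
        ],
    )
    def test_bands(self, value, expected):
        assert classify_effect(value) == expected


class TestFisherLsd:
    def test_closed_form_t_and_p(self):
        c = fisher_lsd({"x": 10.0, "y": 12.0}, ms_error=2.0, df_error=9,
                       n_per_level=4)[0]
        assert c.t == pytest.approx(-2.0)
        assert c.p == pytest.approx(0.0766, abs=2e-4)

    def test_identical_means(self):
        c = fisher_lsd({"x": 5.0, "y": 5.0}, 1.0, 10, 3)[0]
        assert c.t == 0.0 and c.p == pytest.approx(1.0)

    def test_antisymmetric_in_level_order(self):
        fwd = fisher_lsd({"x": 10.0, "y": 12.0}, 2.0, 9, 4)[0]
        rev = fisher_lsd({"y": 12.0, "x": 10.0}, 2.0, 9, 4)[0]
        assert rev.t == pytest.approx(-fwd.t)
        assert rev.p == pytest.approx(fwd.p)

    def test_underpowered_rejected(self):
        with pytest.raises(ValueError):
            fisher_lsd({"x": 1.0, "y": 2.0}, 1.0, 5, 1)


class TestQQPoints:
    def test_plotting_positions_n3(self):
        from scipy.stats import norm

        qq = qq_points(np.array([3.0, 1.0, 2.0]))
        np.testing.assert_allclose(
            qq.theoretical, norm.ppf([1 / 6, 3 / 6, 5 / 6])
        )
        np.testing.assert_allclose(qq.sample, [1.0, 2.0, 3.0])

    def test_normal_sample_slope_near_unity(self):
        x = np.random.default_rng(12).normal(size=10_000)
        qq = qq_points(x)
        slope = np.polyfit(qq.theoretical, qq.sample, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_affine_transform_preserves_ordering(self):
        x = np.random.default_rng(13).normal(size=50)
        base = qq_points(x)
        trans = qq_points(3.0 * x + 7.0)
        np.testing.assert_allclose(trans.sample, 3.0 * base.sample + 7.0)
        np.testing.assert_allclose(trans.theoretical, base.theoretical)

    def test_constant_sample_flagged_degenerate(self):
        assert qq_points(np.full(5, 2.0)).degenerate
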