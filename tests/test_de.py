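"""NB-LRT differential expression: factors, dispersion, test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from pirnaflow import de, synthgen


def _matrix(rows, columns=None):
    arr = np.asarray(rows)
    columns = columns or [f"s{j+1}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=columns)


class TestSizeFactors:
    def test_total_method_equal_totals(self):
        m = _matrix([[10, 10], [20, 20]])
        f = de.size_factors(m, method="total")
        assert np.allclose(f, 1.0)

    def test_total_method_direct_arithmetic(self):
        m = _matrix([[100, 400]])
        f = de.size_factors(m, method="total")
        assert np.allclose(f.to_numpy(), [0.5, 2.0])

    def test_total_method_homogeneity(self):
        # scaling one sample x10 scales its factor x10 relative to the rest
        # (absolute values shift by the geometric-mean renormalization)
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(1, 100, size=(50, 3)))
        f1 = de.size_factors(m, method="total")
        m2 = m.copy()
        m2["s1"] *= 10
        f2 = de.size_factors(m2, method="total")
        assert (f2["s1"] / f2["s2"]) == pytest.approx(
            10 * f1["s1"] / f1["s2"], rel=1e-9)
        assert np.exp(np.log(f2).mean()) == pytest.approx(1.0)

    def test_zero_total_sample_raises(self):
        with pytest.raises(ValueError):
            de.size_factors(_matrix([[0, 5], [0, 5]]))

    @pytest.mark.parametrize("method", ["mode", "median_ratio", "tmm"])
    def test_duplicated_columns_give_unit_factors(self, method):
        rng = np.random.default_rng(1)
        col = rng.integers(5, 200, size=300)
        m = _matrix(np.column_stack([col] * 4))
        f = de.size_factors(m, method=method)
        assert np.allclose(f, 1.0, atol=1e-6)

    def test_mode_resists_one_sided_composition_bias(self):
        # 25% of features 8x up in sample 2: null features must stay ~1:1
        rng = np.random.default_rng(2)
        n = 2000
        base = rng.poisson(100, size=(n, 2)).astype(float)
        base[: n // 4, 1] *= 8
        f_mode = de.size_factors(_matrix(base), method="mode")
        f_total = de.size_factors(_matrix(base), method="total")
        assert abs(f_mode["s2"] / f_mode["s1"] - 1.0) < 0.1
        assert f_total["s2"] / f_total["s1"] > 2.0  # the naive failure mode


class TestDispersion:
    def test_poisson_hits_floor(self):
        plan = synthgen.DEPlan(n_features=500, de_fraction=0, dispersion=1e-9,
                               seed=1)
        counts, _ = synthgen.simulate_counts(plan)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        phi = de.estimate_dispersion(counts, de.size_factors(counts), groups)
        assert phi == 0.01

    def test_parameter_recovery(self):
        plan = synthgen.DEPlan(n_features=2000, de_fraction=0, dispersion=0.2,
                               baseline_mean=100, seed=2)
        counts, _ = synthgen.simulate_counts(plan)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        phi = de.estimate_dispersion(counts, de.size_factors(counts), groups)
        assert 0.1 <= phi <= 0.3

    def test_duplicated_columns_floor(self):
        rng = np.random.default_rng(3)
        col = rng.integers(5, 200, size=100)
        m = _matrix(np.column_stack([col] * 4))
        groups = pd.Series(["A", "A", "B", "B"], index=m.columns)
        phi = de.estimate_dispersion(m, de.size_factors(m), groups)
        assert phi == 0.01


def _grid_loglik(y, s, phi, mu):
    r = 1 / phi
    m = s * mu
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + m)) + y * np.log(m / (r + m))))


class TestNbLrt:
    def test_identical_groups_are_null(self):
        res = de.nb_lrt(np.array([10, 10, 10, 10, 10, 10]),
                        np.ones(6), 0.05,
                        np.array(["A"] * 3 + ["B"] * 3))
        assert res["log2fc"] == pytest.approx(0.0, abs=1e-6)
        assert res["p"] == pytest.approx(1.0)

    def test_strong_signal_detected_up(self):
        res = de.nb_lrt(np.array([0, 0, 0, 50, 55, 60]),
                        np.ones(6), 0.05,
                        np.array(["A"] * 3 + ["B"] * 3))
        assert res["p"] < 1e-6
        assert res["log2fc"] > 0

    def test_fit_matches_brute_force_grid(self):
        # independent oracle: profile the likelihood on a dense mu grid
        rng = np.random.default_rng(4)
        y = rng.negative_binomial(10, 10 / (10 + 80), size=6).astype(float)
        s = np.array([0.8, 1.1, 1.05, 0.9, 1.2, 0.95])
        phi = 0.1
        groups = np.array(["A"] * 3 + ["B"] * 3)
        res = de.nb_lrt(y, s, phi, groups)
        grid = np.linspace(1, 300, 12000)
        ll0 = max(_grid_loglik(y, s, phi, m) for m in grid)
        lla = (max(_grid_loglik(y[:3], s[:3], phi, m) for m in grid)
               + max(_grid_loglik(y[3:], s[3:], phi, m) for m in grid))
        stat_grid = max(0.0, 2 * (lla - ll0))
        assert res["stat"] == pytest.approx(stat_grid, abs=1e-3)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        y = rng.poisson([20, 22, 18, 60, 55, 70]).astype(float)
        s = np.ones(6)
        g = np.array(["A"] * 3 + ["B"] * 3)
        g_swapped = np.array(["B"] * 3 + ["A"] * 3)
        r1 = de.nb_lrt(y, s, 0.1, g)
        r2 = de.nb_lrt(y, s, 0.1, g_swapped)
        assert r1["log2fc"] == pytest.approx(-r2["log2fc"], rel=1e-6)
        assert r1["p"] == pytest.approx(r2["p"], rel=1e-9)

    def test_invalid_phi(self):
        with pytest.raises(ValueError):
            de.nb_lrt(np.ones(4), np.ones(4), 0.0,
                      np.array(["A", "A", "B", "B"]))


class TestBH:
    def test_single_p_unchanged(self):
        assert de.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_direct_stepup_example(self):
        q = de.bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            de.bh_adjust(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=60))
    def test_q_dominates_p_and_matches_statsmodels(self, ps):
        p = np.array(ps)
        q = de.bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        from statsmodels.stats.multitest import multipletests

        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)


class TestRunDe:
    def test_direction_calls_respect_alpha_mode(self):
        plan = synthgen.DEPlan(n_features=300, de_fraction=0.2,
                               down_fraction_among_de=1.0, seed=6)
        counts, truth = synthgen.simulate_counts(plan)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        table = de.run_de(counts, groups,
                          de.DESettings(alpha_mode="fdr", alpha=0.05))
        sig = table[table["direction"] != "ns"]
        assert (sig["q"] <= 0.05).all()
        assert set(sig["direction"]) <= {"up", "down"}
        # planted all-down: the clear majority of calls must be down
        assert (sig["direction"] == "down").mean() > 0.9

    def test_power_and_direction_recovery_brain_preset(self):
        plan = synthgen.preset_deplan("brain", seed=7)
        counts, truth = synthgen.simulate_counts(plan)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        table = de.run_de(counts, groups,
                          de.DESettings(alpha_mode="pvalue", alpha=0.01))
        detected = (table["p"] < 0.01).reindex(truth.index)
        true_de = truth != "null"
        assert detected[true_de].mean() >= 0.90
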