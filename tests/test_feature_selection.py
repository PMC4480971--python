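"""Fisher transform, permutation null calibration, BH and event association."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import drugresp as dr
from drugresp.containers import PipelineError


def _series_arctanh(r: float, tol: float = 1e-14) -> float:
    """Independent high-precision oracle: sum r^(2k+1)/(2k+1)."""
    total, k, term = 0.0, 0, r
    while abs(term) > tol * max(1.0, abs(total)):
        total += term
        k += 1
        term = r ** (2 * k + 1) / (2 * k + 1)
    return total


class TestFisherZ:
    def test_matches_definition_formula(self):
        for r in [-0.9, -0.5, 0.0, 0.3, 0.4621, 0.8]:
            assert dr.fisher_z(r) == pytest.approx(0.5 * math.log((1 + r) / (1 - r)), abs=1e-12)
        assert dr.fisher_z(0.4621) == pytest.approx(0.5003, abs=5e-4)

    def test_odd_function(self):
        for r in np.arange(0.1, 1.0, 0.1):
            assert dr.fisher_z(-r) == -dr.fisher_z(r)

    def test_agrees_with_series_oracle_on_grid(self):
        for r in np.linspace(-0.99, 0.99, 41):
            assert abs(dr.fisher_z(r) - _series_arctanh(float(r))) < 1e-10

    def test_domain_error(self):
        with pytest.raises(ValueError):
            dr.fisher_z(1.0)
        with pytest.raises(ValueError):
            dr.fisher_z(-1.2)


def _bh_oracle(p):
    """Brute-force step-up: adj(i) = min over j>=i of p_(j)*m/j, capped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestBHAdjust:
    def test_hand_example(self):
        assert np.allclose(dr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_and_singleton(self):
        assert np.allclose(dr.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        assert np.allclose(dr.bh_adjust([0.7]), [0.7])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(dr.bh_adjust(p), _bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=15))
    def test_permutation_invariance_and_monotonicity(self, p):
        adj = dr.bh_adjust(p)
        perm = np.random.default_rng(1).permutation(len(p))
        adj_perm = dr.bh_adjust([p[i] for i in perm])
        assert np.allclose(adj_perm, [adj[i] for i in perm])
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(np.asarray(adj)[order]) >= -1e-12).all()
        assert (np.asarray(adj) >= np.asarray(p) - 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dr.bh_adjust([0.5, 1.2])


def _null_panel(n_genes, n_samples, seed):
    cfg = dr.SimulationConfig(
        n_genes=n_genes,
        n_driver_genes=1,
        n_cell_lines=n_samples,
        driver_effect_size=0.0,
        seed=seed,
    )
    expr, panel, _ = dr.simulate_panel(cfg)
    return expr, panel


class TestPermutationFeatureTest:
    def test_null_sd_close_to_fisher_asymptotic(self):
        """Permutation SD of f tracks 1/sqrt(n-3) within 15% at n=60."""
        expr, panel = _null_panel(80, 60, seed=3)
        stats = dr.permutation_feature_test(expr, panel, n_perm=1000, seed=5)
        expected = 1.0 / math.sqrt(60 - 3)
        ratio = stats["null_sd"].mean() / expected
        assert 0.85 < ratio < 1.15

    def test_type_i_error_near_nominal(self):
        """Fraction of p_raw < 0.05 under the global null stays in [0.02, 0.09]."""
        fractions = []
        for seed in range(20):
            expr, panel = _null_panel(100, 50, seed=100 + seed)
            stats = dr.permutation_feature_test(expr, panel, n_perm=500, seed=seed)
            fractions.append((stats["p_raw"] < 0.05).mean())
        assert 0.02 <= np.mean(fractions) <= 0.09

    def test_null_p_values_uniform(self):
        """Pooled p_raw under the null passes a KS uniformity check."""
        from scipy.stats import kstest

        expr, panel = _null_panel(500, 100, seed=42)
        stats = dr.permutation_feature_test(expr, panel, n_perm=500, seed=1)
        assert kstest(stats["p_raw"], "uniform").pvalue > 0.01

    def test_noiseless_driver_has_smallest_p(self):
        cfg = dr.SimulationConfig(
            n_genes=60, n_driver_genes=1, n_cell_lines=50, noise_sd=1e-9, seed=8
        )
        expr, panel, truth = dr.simulate_panel(cfg)
        stats = dr.permutation_feature_test(expr, panel, n_perm=300, seed=2)
        (driver,) = truth.driver_gene_ids
        assert stats["p_raw"].idxmin() == driver
        assert stats.loc[driver, "p_raw"] < 1e-10

    def test_direction_labels_follow_correlation_sign(self, small_study):
        stats = dr.permutation_feature_test(
            small_study["expr"], small_study["panel"], n_perm=200, seed=0
        )
        assert (stats.loc[stats["r"] < 0, "direction"] == "sensitivity").all()
        assert (stats.loc[stats["r"] > 0, "direction"] == "resistance").all()
        assert (stats["p_adj"] >= stats["p_raw"] - 1e-12).all()

    def test_zero_variance_gene_excluded(self, small_study):
        expr = small_study["expr"]
        flat = expr.values.copy()
        flat.iloc[0] = 5.0
        stats = dr.permutation_feature_test(
            dr.ExpressionMatrix(flat, "p1"), small_study["panel"], n_perm=100, seed=0
        )
        assert flat.index[0] not in stats.index


class TestSelectFeatures:
    def test_cutoff_boundary(self):
        stats = pd.DataFrame(
            {"p_raw": [0.009, 0.011], "r": [0.5, 0.6]}, index=["a", "b"]
        )
        assert dr.select_features(stats, 0.01) == ["a"]

    def test_cutoff_one_keeps_all_sorted_by_abs_r(self):
        stats = pd.DataFrame(
            {"p_raw": [0.5, 0.2, 0.9], "r": [0.1, -0.8, 0.3]}, index=["a", "b", "c"]
        )
        assert dr.select_features(stats, p_cutoff=1.0) == ["b", "c", "a"]

    def test_empty_selection_halts(self):
        stats = pd.DataFrame({"p_raw": [0.5], "r": [0.1]}, index=["a"])
        with pytest.raises(PipelineError):
            dr.select_features(stats, 0.01)

    def test_driver_recovery_on_reference_panel(self):
        """>=70% of 30 planted drivers pass the p<0.01 gate at n=200."""
        cfg = dr.SimulationConfig(seed=13)
        expr, panel, truth = dr.simulate_panel(cfg)
        stats = dr.permutation_feature_test(expr, panel, n_perm=1000, seed=13)
        selected = set(dr.select_features(stats, 0.01))
        recovered = len(selected & truth.driver_gene_ids) / len(truth.driver_gene_ids)
        assert recovered >= 0.70


def _fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher p by exact enumeration over the fixed margins."""
    n, row1, col1 = a + b + c + d, a + b, a + c

    def prob(x):
        return Fraction(
            math.comb(col1, x) * math.comb(n - col1, row1 - x), math.comb(n, row1)
        )

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs))


class TestGeneticEvents:
    def _panel(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        panel = dr.ResponsePanel.from_linear(
            pd.Series(np.exp2(y), index=[f"S{i}" for i in range(n)])
        )
        return panel.assign_labels(float(np.median(y)))

    def test_perfect_association_with_resistance(self):
        panel = self._panel(seed=1)
        resistant = (panel.labels == "resistant").astype(int)
        events = pd.DataFrame([resistant.to_numpy()], index=["EV"], columns=panel.sample_ids)
        out = dr.associate_genetic_events(events, panel, n_perm=200, seed=0)
        assert out.loc["EV", "r"] > 0
        assert out.loc["EV", "direction"] == "resistance"
        assert out.loc["EV", "fisher_exact_p"] < 1e-6

    def test_fisher_exact_matches_enumeration_oracle(self):
        assert _fisher_exact_oracle(6, 2, 2, 6) == pytest.approx(0.13193473, abs=1e-8)
        from scipy.stats import fisher_exact

        assert fisher_exact([[6, 2], [2, 6]])[1] == pytest.approx(
            _fisher_exact_oracle(6, 2, 2, 6), abs=1e-10
        )

    def test_independent_event_gives_moderate_p(self):
        pvals = []
        for seed in range(10):
            panel = self._panel(seed=seed, n=60)
            rng = np.random.default_rng(1000 + seed)
            events = pd.DataFrame(
                [rng.integers(0, 2, size=60)], index=["EV"], columns=panel.sample_ids
            )
            out = dr.associate_genetic_events(events, panel, n_perm=200, seed=seed)
            pvals.append(out.loc["EV", "p_perm"])
        assert 0.15 < np.mean(pvals) < 0.85  # roughly uniform under the null

    def test_constant_event_rows_excluded(self):
        panel = self._panel()
        events = pd.DataFrame(
            [np.ones(40), np.zeros(40), np.r_[np.ones(20), np.zeros(20)]],
            index=["all1", "all0", "ok"],
            columns=panel.sample_ids,
        )
        out = dr.associate_genetic_events(events, panel, n_perm=100, seed=0)
        assert list(out.index) == ["ok"]
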