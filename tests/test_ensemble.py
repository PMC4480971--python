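"""Ensemble criteria, overlap filtering, SVD consensus and forward selection."""

import numpy as np
import pandas as pd
import pytest

import drugresp as dr
from drugresp.containers import PipelineError
from drugresp.ensemble import SplitModelRecord
from drugresp.plsr import PerformanceRecord


def _metrics_table(rows):
    return pd.DataFrame(
        rows, columns=["outer_index", "inner_index", "corr_rv", "auc_rv", "corr_bv", "auc_bv"]
    )


def _spread_rows(outer, center_rv, spread_rv, center_bv, spread_bv, n=11):
    """Inner-split metrics with controlled medians and IQRs."""
    offsets = np.linspace(-0.5, 0.5, n)
    rows = []
    for i, o in enumerate(offsets):
        rows.append(
            (
                outer,
                i,
                center_rv + spread_rv * o,
                0.7 + 0.1 * o,
                center_bv + spread_bv * o,
                0.7 + 0.05 * o,
            )
        )
    return rows


class TestScoreBalancedSets:
    def test_wide_balance_spread_excluded(self):
        rows = _spread_rows(0, 0.6, 0.1, 0.6, 0.4)  # bv spread wider than rv
        rows += _spread_rows(1, 0.6, 0.4, 0.6, 0.1)  # bv spread narrower: ok
        ranked = dr.score_balanced_sets(_metrics_table(rows))
        by_outer = ranked.set_index("outer_index")
        assert not by_outer.loc[0, "passed"]
        assert by_outer.loc[1, "passed"]

    def test_overfit_set_excluded_by_non_inferiority(self):
        rows = _spread_rows(0, 0.8, 0.4, 0.5, 0.1)  # bv median far below rv
        rows += _spread_rows(1, 0.6, 0.4, 0.62, 0.1)
        ranked = dr.score_balanced_sets(_metrics_table(rows))
        by_outer = ranked.set_index("outer_index")
        assert not by_outer.loc[0, "passed"]
        assert by_outer.loc[1, "passed"]

    def test_survivors_ranked_by_c5(self):
        rows = _spread_rows(0, 0.5, 0.4, 0.55, 0.1)
        rows += _spread_rows(1, 0.6, 0.4, 0.70, 0.1)
        ranked = dr.score_balanced_sets(_metrics_table(rows))
        passed = ranked[ranked["passed"]]
        assert passed["outer_index"].tolist() == [1, 0]
        assert (passed["c5"].diff().dropna() <= 0).all()

    def test_real_signal_yields_surviving_sets(self, small_study):
        panel = dr.label_panel(small_study["panel"], method="median")
        stats = dr.permutation_feature_test(small_study["expr"], panel, n_perm=200, seed=1)
        genes = dr.select_features(stats, 0.05)
        cfg = dr.SplitConfig(n_outer=4, n_inner=25, seed=1)
        metrics = dr.run_ensemble(small_study["expr"], panel, genes, cfg)
        ranked = dr.score_balanced_sets(metrics)
        assert ranked["passed"].sum() >= 1


class TestPickRepresentatives:
    def test_top_k_and_best_inner(self):
        rows = _spread_rows(0, 0.6, 0.4, 0.65, 0.1) + _spread_rows(1, 0.6, 0.4, 0.60, 0.1)
        metrics = _metrics_table(rows)
        ranked = dr.score_balanced_sets(metrics)
        chosen = dr.pick_representatives(metrics, ranked, k=2)
        assert len(chosen) == 2
        for o, i in chosen:
            g = metrics[metrics["outer_index"] == o]
            assert g["corr_bv"].max() == g.set_index("inner_index").loc[i, "corr_bv"]

    def test_tie_broken_by_auc_then_index(self):
        rows = [
            (0, 0, 0.5, 0.6, 0.70, 0.60),
            (0, 1, 0.5, 0.6, 0.70, 0.65),
            (0, 2, 0.5, 0.6, 0.70, 0.65),
        ]
        metrics = _metrics_table(rows)
        ranked = pd.DataFrame({"outer_index": [0], "passed": [True]})
        assert dr.pick_representatives(metrics, ranked, k=1) == [(0, 1)]

    def test_k_one_gives_single_argmax(self):
        rows = _spread_rows(0, 0.6, 0.4, 0.65, 0.1)
        metrics = _metrics_table(rows)
        ranked = dr.score_balanced_sets(metrics)
        assert len(dr.pick_representatives(metrics, ranked, k=1)) == 1


class TestJaccardAndOverlap:
    def test_hand_values(self):
        assert dr.jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert dr.jaccard({"a"}, {"b"}) == 0.0
        assert dr.jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_empty_union_rejected(self):
        with pytest.raises(PipelineError):
            dr.jaccard(set(), set())

    def test_null_quantile_forced_identity(self):
        assert dr.overlap_null_quantile(20, 20, n_perm=50, seed=0) == 1.0

    def test_null_quantile_self_consistent_across_seeds(self):
        a = dr.overlap_null_quantile(300, 126, n_perm=4000, seed=1)
        b = dr.overlap_null_quantile(300, 126, n_perm=4000, seed=2)
        assert abs(a - b) < 0.03

    def test_null_quantile_monotone_in_q(self):
        qs = [
            dr.overlap_null_quantile(100, 40, n_perm=2000, q=q, seed=3)
            for q in (0.5, 0.8, 0.9, 0.99)
        ]
        assert qs == sorted(qs)


def _record(outer, inner, train_ids, corr_bv=0.5):
    return SplitModelRecord(
        outer_index=outer,
        inner_index=inner,
        model=None,
        random_val=PerformanceRecord(0.5, 0.7),
        balance_val=PerformanceRecord(corr_bv, 0.7),
        random_train=list(train_ids),
    )


class TestFilterOverlapping:
    def test_all_below_cutoff_retained(self):
        recs = [_record(0, 0, "abc"), _record(1, 0, "def"), _record(2, 0, "ghi")]
        assert len(dr.filter_overlapping(recs, 0.5)) == 3

    def test_duplicate_dropped(self):
        recs = [_record(0, 0, "abc"), _record(1, 0, "abc")]
        kept = dr.filter_overlapping(recs, 0.99)
        assert [(r.outer_index) for r in kept] == [0]

    def test_greedy_chain_keeps_first_and_third(self):
        a = _record(0, 0, ["1", "2", "3", "4"])
        b = _record(1, 0, ["1", "2", "3", "5"])  # J(a,b)=3/5 above cutoff
        c = _record(2, 0, ["1", "6", "7", "8"])  # J(a,c)=1/7, J(b,c)=1/7 below
        kept = dr.filter_overlapping([a, b, c], 0.5)
        assert [r.outer_index for r in kept] == [0, 2]


def _model_with_weights(genes, l1, l2, train=("s1", "s2"), corr_bv=0.5):
    loadings = pd.DataFrame({"comp_1": l1, "comp_2": l2}, index=genes)
    model = dr.PLSRModel(
        gene_ids=list(genes),
        n_components=2,
        x_loadings=loadings,
        coef=pd.Series(0.0, index=genes),
        x_mean=pd.Series(0.0, index=genes),
        x_std=pd.Series(1.0, index=genes),
        y_mean=0.0,
        training_sample_ids=list(train),
        fitted=pd.Series(dtype=float),
    )
    return SplitModelRecord(0, 0, model, PerformanceRecord(0.5, 0.7),
                            PerformanceRecord(corr_bv, 0.7), list(train))


class TestConsensusWeights:
    def test_identical_models_give_rank_one_consensus(self):
        genes = ["g1", "g2", "g3"]
        recs = [_model_with_weights(genes, [1.0, 2.0, 2.0], [0.0, 0.0, 1.0]) for _ in range(3)]
        cons = dr.consensus_weights(recs)
        w = dr.gene_weights(recs[0].model)
        w = w / np.linalg.norm(w)
        cosine = float(np.abs(cons.weights @ w))
        assert cosine > 1 - 1e-10

    def test_single_model_consensus_is_its_weights(self):
        genes = ["g1", "g2"]
        rec = _model_with_weights(genes, [3.0, 0.0], [4.0, 1.0])
        cons = dr.consensus_weights([rec])
        w = dr.gene_weights(rec.model)
        w = w / np.linalg.norm(w)
        assert np.allclose(np.abs(cons.weights), w, atol=1e-12)

    def test_union_gene_space_zero_fill(self):
        a = _model_with_weights(["g1", "g2"], [1.0, 1.0], [0.0, 0.0])
        b = _model_with_weights(["g2", "g3"], [1.0, 1.0], [0.0, 0.0])
        cons = dr.consensus_weights([a, b])
        assert list(cons.weights.index) == ["g1", "g2", "g3"]
        assert cons.weights["g2"] > cons.weights["g1"]

    def test_order_invariance_up_to_sign(self):
        genes = ["g1", "g2", "g3"]
        a = _model_with_weights(genes, [1.0, 0.2, 0.1], [0.0, 0.1, 0.0])
        b = _model_with_weights(genes, [0.9, 0.3, 0.2], [0.1, 0.0, 0.1])
        c1 = dr.consensus_weights([a, b]).weights
        c2 = dr.consensus_weights([b, a]).weights
        assert np.allclose(np.abs(c1), np.abs(c2), atol=1e-12)


class TestRepresentativeSelection:
    def test_model_matching_consensus_direction_wins(self):
        genes = ["g1", "g2", "g3"]
        aligned = _model_with_weights(genes, [2.0, 1.0, 0.5], [0.0, 0.0, 0.0], corr_bv=0.1)
        noisy = _model_with_weights(genes, [0.1, 2.0, 0.1], [0.0, 0.0, 0.0], corr_bv=0.9)
        third = _model_with_weights(genes, [2.1, 1.1, 0.4], [0.0, 0.0, 0.0], corr_bv=0.2)
        cons = dr.consensus_weights([aligned, third])
        best = dr.select_representative_model([aligned, noisy, third], cons)
        assert best is aligned or best is third

    def test_identical_models_tie_broken_by_balance_corr(self):
        genes = ["g1", "g2"]
        a = _model_with_weights(genes, [1.0, 0.5], [0.0, 0.0], corr_bv=0.4)
        b = _model_with_weights(genes, [1.0, 0.5], [0.0, 0.0], corr_bv=0.6)
        cons = dr.consensus_weights([a, b])
        assert dr.select_representative_model([a, b], cons) is b


class TestForwardSelection:
    def _study(self):
        cfg = dr.SimulationConfig(
            n_genes=120, n_driver_genes=8, n_cell_lines=80, seed=21
        )
        expr, panel, truth = dr.simulate_panel(cfg)
        panel = dr.label_panel(panel, method="median")
        return expr, panel, truth

    def test_plateau_found_and_core_reasonable(self):
        expr, panel, truth = self._study()
        stats = dr.permutation_feature_test(expr, panel, n_perm=200, seed=0)
        genes = dr.select_features(stats, 0.05)
        scfg = dr.SplitConfig(n_outer=2, n_inner=20, seed=3)
        metrics = dr.run_ensemble(expr, panel, genes, scfg)
        ranked = dr.score_balanced_sets(metrics)
        chosen = dr.pick_representatives(metrics, ranked, k=2)
        recs = [dr.materialize_record(expr, panel, genes, scfg, o, i) for o, i in chosen]
        cons = dr.consensus_weights(recs)
        rep = dr.select_representative_model(recs, cons)
        core, core_model, curve = dr.forward_select_core(
            expr, panel, rep, cons, scfg, start=5, eps=0.01, window=5
        )
        assert curve["k"].iloc[0] == 5
        assert 5 <= len(core) <= len(genes)
        assert list(core_model.gene_ids) == core  # core model refit at the plateau size

    def test_first_evaluated_size_is_start(self):
        expr, panel, truth = self._study()
        stats = dr.permutation_feature_test(expr, panel, n_perm=100, seed=0)
        genes = dr.select_features(stats, 0.05)
        scfg = dr.SplitConfig(n_outer=1, n_inner=5, seed=4)
        metrics = dr.run_ensemble(expr, panel, genes, scfg)
        ranked = dr.score_balanced_sets(metrics)
        chosen = dr.pick_representatives(metrics, ranked, k=1)
        rec = dr.materialize_record(expr, panel, genes, scfg, *chosen[0])
        cons = dr.consensus_weights([rec])
        _, _, curve = dr.forward_select_core(expr, panel, rec, cons, scfg, start=5)
        assert curve["k"].min() == 5


class TestEndToEndRecovery:
    def test_core_signature_enriched_for_drivers(self, reference_run):
        """Core gene list holds >=50% of drivers; top consensus ranks are clean."""
        truth = reference_run["truth"]
        result = reference_run["result"]
        core = set(result.core_genes)
        recovered = len(core & truth.driver_gene_ids) / len(truth.driver_gene_ids)
        assert recovered >= 0.50
        top30 = result.consensus.ranked_genes()[:30]
        non_driver_frac = np.mean([g not in truth.driver_gene_ids for g in top30])
        assert non_driver_frac <= 0.20

    def test_filter_overlapping_deterministic(self, reference_run):
        result = reference_run["result"]
        models = result.top_models
        again = dr.filter_overlapping(models, null_q=1.1)  # no-op threshold
        assert [(m.outer_index, m.inner_index) for m in again] == [
            (m.outer_index, m.inner_index) for m in models
        ]
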