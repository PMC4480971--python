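"""Split-ensemble scoring, consensus weighting and core-signature selection.

Every (outer, inner) split yields a PLSR model fitted on its random-
training lines and scored on both held-out parts.  Outer balanced-split
sets are then ranked by five criteria: good random-validation performance,
correlated AUC and correlation measures across inner splits (C2), a
narrower balance-validation than random-validation performance spread (C3),
balance-validation medians not inferior to random-validation medians --
inferiority indicates over-fitting (C4), and high absolute balance-
validation performance (C5).  One best inner model is taken from each
surviving top set; models whose random-training line sets overlap more
than the 90% quantile of a same-size random-subset Jaccard null are
dropped greedily in rank order.  The remaining top models are summarized
by an SVD consensus of their gene-weight vectors; the model most similar
to the consensus becomes the representative, and forward selection over
the consensus-ranked genes (starting from the five highest-weighted, one
gene at a time, stopping at an early plateau of both the correlation and
AUC curves) yields the core signature.

Only per-split metrics are kept in memory during the sweep; any individual
model is re-fitted on demand from its (outer, inner) indices, which are
sufficient because the split seeds are counter-derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .containers import ExpressionMatrix, PipelineError, ResponsePanel
from .plsr import (
    PerformanceRecord,
    PLSRModel,
    design_matrix,
    evaluate_performance,
    fit_plsr,
    gene_weights,
    predict,
)
from .splitting import SplitConfig, balanced_split, inner_random_split

logger = logging.getLogger("drugresp")


@dataclass
class SplitModelRecord:
    """One split's fitted model plus its held-out performance."""

    outer_index: int
    inner_index: int
    model: PLSRModel
    random_val: PerformanceRecord
    balance_val: PerformanceRecord
    random_train: list[str]


@dataclass
class ConsensusWeights:
    """First-singular-vector summary of the top models' gene weights."""

    weights: pd.Series  # unit-norm, indexed by the union gene universe
    contributing: list[tuple[int, int]]  # (outer_index, inner_index) per model
    oriented_positive: bool = True

    def ranked_genes(self) -> list[str]:
        return list(self.weights.abs().sort_values(ascending=False, kind="mergesort").index)


def _safe_perf(scores, observed, labels) -> PerformanceRecord:
    """Performance record; AUC is NaN when a held-out part is single-class."""
    corr = float(pearsonr(np.asarray(scores, float), np.asarray(observed, float))[0])
    try:
        from .plsr import roc_auc

        auc = roc_auc(scores, labels)
    except PipelineError:
        auc = float("nan")
    return PerformanceRecord(corr=corr, auc=auc)


def _fit_and_score(
    expr: ExpressionMatrix,
    resp: ResponsePanel,
    genes,
    random_train,
    random_val,
    balance_val,
    n_components: int,
):
    y = resp.ic50_log2
    labels = resp.labels
    model = fit_plsr(
        design_matrix(expr, random_train, genes), y.loc[random_train], n_components
    )
    rv = _safe_perf(
        predict(model, design_matrix(expr, random_val, genes)),
        y.loc[random_val],
        labels.loc[random_val],
    )
    bv = _safe_perf(
        predict(model, design_matrix(expr, balance_val, genes)),
        y.loc[balance_val],
        labels.loc[balance_val],
    )
    return model, rv, bv


def run_ensemble(
    expr: ExpressionMatrix,
    resp: ResponsePanel,
    genes,
    cfg: SplitConfig,
    n_components: int = 2,
) -> pd.DataFrame:
    """Sweep all n_outer x n_inner splits; return the per-split metric table.

    Columns: ``outer_index, inner_index, corr_rv, auc_rv, corr_bv, auc_bv``.
    The response panel must carry sensitive/resistant labels.
    """
    resp.labels  # raises if a cutoff has not been assigned
    rows = []
    for o in range(cfg.n_outer):
        train, balance_val = balanced_split(resp, cfg, [cfg.seed, o])
        for i in range(cfg.n_inner):
            random_train, random_val = inner_random_split(train, cfg, [cfg.seed, o, i])
            _, rv, bv = _fit_and_score(
                expr, resp, genes, random_train, random_val, balance_val, n_components
            )
            rows.append((o, i, rv.corr, rv.auc, bv.corr, bv.auc))
        logger.debug("ensemble: outer set %d/%d done", o + 1, cfg.n_outer)
    return pd.DataFrame(
        rows,
        columns=["outer_index", "inner_index", "corr_rv", "auc_rv", "corr_bv", "auc_bv"],
    )


def materialize_record(
    expr: ExpressionMatrix,
    resp: ResponsePanel,
    genes,
    cfg: SplitConfig,
    outer_index: int,
    inner_index: int,
    n_components: int = 2,
) -> SplitModelRecord:
    """Re-fit the model of one (outer, inner) split from its counter seeds."""
    train, balance_val = balanced_split(resp, cfg, [cfg.seed, outer_index])
    random_train, random_val = inner_random_split(train, cfg, [cfg.seed, outer_index, inner_index])
    model, rv, bv = _fit_and_score(
        expr, resp, genes, random_train, random_val, balance_val, n_components
    )
    return SplitModelRecord(outer_index, inner_index, model, rv, bv, random_train)


def _iqr(x: pd.Series) -> float:
    q = np.nanpercentile(x, [25, 75])
    return float(q[1] - q[0])


def score_balanced_sets(metrics: pd.DataFrame, delta: float = 0.02) -> pd.DataFrame:
    """Rank outer balanced-split sets by the five selection criteria.

    Per outer set: C2 = Spearman correlation between inner-split random-
    validation correlation and AUC; C3 = IQR(balance-val corr) /
    IQR(random-val corr), required < 1 (narrower balance-validation
    spread); C4 = balance-validation medians within ``delta`` of (or above)
    random-validation medians on both metrics (non-inferiority; failure
    indicates over-fitting); C5 = median balance-val corr + median
    balance-val AUC.  Sets failing C3 or C4 are excluded; survivors are
    ranked by C5, ties by C2.  Criterion 1 (good random-validation
    performance) enters through the C5 ranking and the later
    best-inner-model choice rather than a separate hard threshold.
    """
    rows = []
    for o, g in metrics.groupby("outer_index"):
        # a constant metric (e.g. AUC pinned at 1 in every inner split)
        # carries no ranking information; score the agreement as 0
        if g["corr_rv"].nunique() < 2 or g["auc_rv"].nunique(dropna=True) < 2:
            c2 = 0.0
        else:
            c2 = float(spearmanr(g["corr_rv"], g["auc_rv"], nan_policy="omit")[0])
        iqr_rv = _iqr(g["corr_rv"])
        c3 = _iqr(g["corr_bv"]) / iqr_rv if iqr_rv > 0 else np.inf
        med = g.median(numeric_only=True)
        c4 = (med["corr_bv"] >= med["corr_rv"] - delta) and (
            med["auc_bv"] >= med["auc_rv"] - delta
        )
        c5 = float(med["corr_bv"] + med["auc_bv"])
        rows.append((o, c2, c3, c4, c5))
    table = pd.DataFrame(rows, columns=["outer_index", "c2", "c3", "c4_ok", "c5"])
    table["passed"] = (table["c3"] < 1.0) & table["c4_ok"]
    survivors = int(table["passed"].sum())
    if survivors < 2:
        logger.warning("only %d balanced sets survive criteria C3/C4", survivors)
    return table.sort_values(
        ["passed", "c5", "c2"], ascending=[False, False, False], kind="mergesort"
    ).reset_index(drop=True)


def pick_representatives(
    metrics: pd.DataFrame, ranked_sets: pd.DataFrame, k: int = 5
) -> list[tuple[int, int]]:
    """Best inner model of each of the top-k surviving outer sets.

    The best inner split maximizes balance-validation correlation; ties go
    to higher balance-validation AUC, then lower inner index.
    """
    surviving = ranked_sets[ranked_sets["passed"]]["outer_index"].tolist()
    if k > len(surviving):
        logger.warning("requested %d top sets but only %d survive; using all", k, len(surviving))
    chosen = []
    for o in surviving[:k]:
        g = metrics[metrics["outer_index"] == o].sort_values(
            ["corr_bv", "auc_bv", "inner_index"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        chosen.append((int(o), int(g.iloc[0]["inner_index"])))
    if not chosen:
        raise PipelineError("no balanced-split sets survive the selection criteria")
    return chosen


def jaccard(a, b) -> float:
    """|a n b| / |a u b| between two sample-id sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise PipelineError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(union)


def overlap_null_quantile(
    panel_size: int,
    set_size: int,
    n_perm: int = 10000,
    q: float = 0.90,
    seed: int = 0,
) -> float:
    """q-quantile of Jaccard between two random same-size subsets of the panel."""
    if set_size > panel_size:
        raise PipelineError("set_size exceeds panel_size")
    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm)
    idx = np.arange(panel_size)
    for i in range(n_perm):
        a = rng.choice(idx, size=set_size, replace=False)
        b = rng.choice(idx, size=set_size, replace=False)
        inter = len(np.intersect1d(a, b, assume_unique=True))
        sims[i] = inter / (2 * set_size - inter)
    return float(np.quantile(sims, q))


def filter_overlapping(records: list[SplitModelRecord], null_q: float) -> list[SplitModelRecord]:
    """Greedy retention in rank order, dropping significantly overlapping models.

    A model is dropped if the Jaccard similarity of its random-training
    line set with any already-retained model exceeds the permutation null
    quantile.
    """
    retained: list[SplitModelRecord] = []
    for rec in records:
        if all(jaccard(rec.random_train, kept.random_train) <= null_q for kept in retained):
            retained.append(rec)
        else:
            logger.info(
                "dropping model (outer %d, inner %d): training set overlaps a retained model",
                rec.outer_index,
                rec.inner_index,
            )
    return retained


def consensus_weights(records: list[SplitModelRecord]) -> ConsensusWeights:
    """SVD consensus of the top models' gene-weight vectors.

    Each model's sqrt(L1^2+L2^2) weight vector is normalized to unit norm
    and zero-filled onto the union gene universe; the consensus is the
    first right singular vector of the stacked matrix, oriented so its mean
    correlation with the rows is non-negative.
    """
    if not records:
        raise PipelineError("consensus requires at least one model")
    weight_vectors = [gene_weights(r.model) for r in records]
    universe = sorted(set().union(*[w.index for w in weight_vectors]))
    mat = np.vstack(
        [w.reindex(universe, fill_value=0.0).to_numpy() for w in weight_vectors]
    )
    norms = np.linalg.norm(mat, axis=1)
    if np.all(norms == 0):
        raise PipelineError("all model weight vectors are zero")
    mat = mat / norms[:, None]
    _, s, vt = np.linalg.svd(mat, full_matrices=False)
    v = vt[0]
    if s[0] == 0:
        raise PipelineError("rank-0 weight matrix")
    mean_corr = float(np.mean(mat @ v))
    if mean_corr < 0:
        v = -v
    return ConsensusWeights(
        weights=pd.Series(v, index=pd.Index(universe, name="gene"), name="consensus_weight"),
        contributing=[(r.outer_index, r.inner_index) for r in records],
        oriented_positive=mean_corr >= 0,
    )


def select_representative_model(
    records: list[SplitModelRecord], consensus: ConsensusWeights
) -> SplitModelRecord:
    """The model whose weight vector correlates best with the consensus."""
    best, best_key = None, None
    for rec in records:
        w = gene_weights(rec.model).reindex(consensus.weights.index, fill_value=0.0)
        corr = float(pearsonr(w.to_numpy(), consensus.weights.to_numpy())[0])
        key = (round(corr, 12), rec.balance_val.corr)
        if best_key is None or key > best_key:
            best, best_key = rec, key
    return best


def forward_select_core(
    expr: ExpressionMatrix,
    resp: ResponsePanel,
    representative: SplitModelRecord,
    consensus: ConsensusWeights,
    cfg: SplitConfig,
    start: int = 5,
    eps: float = 0.005,
    window: int = 10,
    n_components: int = 2,
) -> tuple[list[str], PLSRModel, pd.DataFrame]:
    """Forward selection over consensus-ranked genes to the core signature.

    Genes are ordered by |consensus weight| descending; at each size k >=
    ``start`` the model is retrained on the representative split's random-
    training lines and scored (correlation, AUC) on its balance-validation
    lines.  The plateau size k* is the smallest k such that neither metric
    improves by more than ``eps`` anywhere within the next ``window``
    additions; the core model is refit at k*.  If no plateau occurs the
    full gene set is returned with a warning.
    """
    train, balance_val = balanced_split(resp, cfg, [cfg.seed, representative.outer_index])
    random_train = representative.random_train
    ranked = [g for g in consensus.ranked_genes() if g in set(expr.feature_ids)]
    sizes = list(range(min(start, len(ranked)), len(ranked) + 1))
    y, labels = resp.ic50_log2, resp.labels
    curve = []
    for k in sizes:
        genes_k = ranked[:k]
        model = fit_plsr(design_matrix(expr, random_train, genes_k), y.loc[random_train], n_components)
        perf = _safe_perf(
            predict(model, design_matrix(expr, balance_val, genes_k)),
            y.loc[balance_val],
            labels.loc[balance_val],
        )
        curve.append((k, perf.corr, perf.auc))
    curve_df = pd.DataFrame(curve, columns=["k", "corr", "auc"]).set_index("k")

    k_star = None
    for k in sizes:
        future = curve_df.loc[k + 1 : k + window]
        if future.empty:
            break
        gain_corr = (future["corr"] - curve_df.loc[k, "corr"]).max()
        gain_auc = (future["auc"] - curve_df.loc[k, "auc"]).max()
        if gain_corr <= eps and gain_auc <= eps:
            k_star = k
            break
    if k_star is None:
        logger.warning("no performance plateau found; returning the full gene set")
        k_star = sizes[-1]
    core_genes = ranked[:k_star]
    core_model = fit_plsr(
        design_matrix(expr, random_train, core_genes), y.loc[random_train], n_components
    )
    return core_genes, core_model, curve_df.reset_index()
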