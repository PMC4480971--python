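"""Correlation-based feature selection with a permutation null.

Each gene's Pearson correlation with log2 IC50 is Fisher-transformed
(f = 0.5 * ln((1+r)/(1-r))); a permutation null is built by repeatedly
shuffling the response vector over the cell-line panel (one shared
permutation schedule for all genes, which preserves gene-gene correlation
under the null), the permuted f-values are summarized by their sample mean
and SD, and a two-sided normal p-value is computed for the observed f.
Benjamini-Hochberg adjusted p-values are reported alongside, but the
selection gate is the raw p-value (default cutoff 0.01).

Also provides the binary genetic-event association analysis: Pearson
correlation of the event vector with log2 IC50 (positive = resistance-
associated), a permutation p-value, and Fisher's exact test against the
sensitive/resistant class labels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, PipelineError, ResponsePanel, SENSITIVE

logger = logging.getLogger("drugresp")

DIRECTION_SENSITIVITY = "sensitivity"  # r < 0: high expression, low IC50
DIRECTION_RESISTANCE = "resistance"  # r > 0: high expression, high IC50


def fisher_z(r):
    """Fisher's variance-stabilizing transform, f = 0.5*ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _center_rows(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=-1, keepdims=True)


def permutation_feature_test(
    expr: ExpressionMatrix,
    resp: ResponsePanel,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene correlation statistics against a permutation null.

    Returns a DataFrame indexed by gene with columns ``r, f, null_mean,
    null_sd, p_raw, p_adj, direction``.  Zero-variance genes are excluded
    (logged).  The same ``n_perm`` shuffles of the response vector are used
    for every gene.
    """
    common = expr.sample_ids.intersection(resp.sample_ids)
    if len(common) < 10:
        raise PipelineError("permutation feature test needs at least 10 samples")
    x = expr.values[common].to_numpy(dtype=float)
    y = resp.ic50_log2.loc[common].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise PipelineError("response vector has zero variance")

    xc = _center_rows(x)
    x_norm = np.linalg.norm(xc, axis=1)
    keep = x_norm > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("feature test: excluded %d zero-variance genes", n_excluded)
    xn = xc[keep] / x_norm[keep, None]

    yc = y - y.mean()
    yn = yc / np.linalg.norm(yc)
    r_obs = xn @ yn

    rng = np.random.default_rng(seed)
    n = len(yn)
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = yn[rng.permutation(n)]
    r_null = xn @ perms  # genes x n_perm

    clip = 1.0 - 1e-12
    f_obs = np.arctanh(np.clip(r_obs, -clip, clip))
    f_null = np.arctanh(np.clip(r_null, -clip, clip))
    null_mean = f_null.mean(axis=1)
    null_sd = f_null.std(axis=1, ddof=1)
    z = np.abs(f_obs - null_mean) / null_sd
    p_raw = 2.0 * sps.norm.sf(z)
    p_adj = bh_adjust(p_raw)

    genes = expr.feature_ids[keep]
    return pd.DataFrame(
        {
            "r": r_obs,
            "f": f_obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(r_obs < 0, DIRECTION_SENSITIVITY, DIRECTION_RESISTANCE),
        },
        index=genes,
    )


def select_features(stats: pd.DataFrame, p_cutoff: float = 0.01) -> list[str]:
    """Genes passing the raw p-value gate, ordered by |r| descending."""
    passed = stats[stats["p_raw"] < p_cutoff]
    if passed.empty:
        raise PipelineError(
            f"no features pass p_raw < {p_cutoff}; "
            "the panel may carry no expression-response signal"
        )
    order = passed.reindex(passed["r"].abs().sort_values(ascending=False).index)
    return list(order.index)


def associate_genetic_events(
    events: pd.DataFrame,
    resp: ResponsePanel,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Associate binary genetic events (genes x samples) with drug response.

    Per event: Pearson r with log2 IC50 (positive = resistance-associated),
    a two-sided permutation p over ``n_perm`` shuffles of the IC50 vector,
    and Fisher's exact test of the 2x2 table event x sensitive/resistant
    class.  All-zero or all-one event rows are excluded (logged).
    """
    common = events.columns.intersection(resp.sample_ids)
    y = resp.ic50_log2.loc[common].to_numpy(dtype=float)
    labels = (resp.labels.loc[common] == SENSITIVE).to_numpy()
    e = events[common].to_numpy(dtype=float)

    informative = (e.sum(axis=1) > 0) & (e.sum(axis=1) < e.shape[1])
    n_excluded = int((~informative).sum())
    if n_excluded:
        logger.info("event association: excluded %d constant event rows", n_excluded)
    e = e[informative]
    names = events.index[informative]

    ec = _center_rows(e)
    e_norm = np.linalg.norm(ec, axis=1)
    en = ec / e_norm[:, None]
    yc = y - y.mean()
    yn = yc / np.linalg.norm(yc)
    r_obs = en @ yn

    rng = np.random.default_rng(seed)
    n = len(yn)
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = yn[rng.permutation(n)]
    r_null = en @ perms
    p_perm = (1.0 + (np.abs(r_null) >= np.abs(r_obs)[:, None]).sum(axis=1)) / (n_perm + 1.0)

    fisher_p = np.empty(len(names))
    for i in range(len(names)):
        has_event = e[i] > 0
        table = [
            [int((has_event & labels).sum()), int((has_event & ~labels).sum())],
            [int((~has_event & labels).sum()), int((~has_event & ~labels).sum())],
        ]
        fisher_p[i] = sps.fisher_exact(table, alternative="two-sided")[1]

    return pd.DataFrame(
        {
            "r": r_obs,
            "p_perm": p_perm,
            "fisher_exact_p": fisher_p,
            "direction": np.where(r_obs < 0, DIRECTION_SENSITIVITY, DIRECTION_RESISTANCE),
        },
        index=names,
    )
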