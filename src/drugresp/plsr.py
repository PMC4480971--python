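"""PLSR fitting, prediction, gene weights and score-cutoff machinery.

Models are standard PLS1 regressions of log2 IC50 on autoscaled (centered,
unit-variance) expression columns.  The per-gene weight used for consensus
ranking and forward selection is sqrt(L1^2 + L2^2), the Euclidean norm of
the gene's loadings on the first two latent components.  Performance of a
model on held-out lines is summarized by the Pearson correlation between
predicted and experimental log2 IC50 and by the ROC AUC for recovering the
experimental sensitive/resistant labels from the predicted scores (lower
predicted IC50 = predicted sensitive).

Response cutoffs separating sensitive from resistant are data-driven: the
sample median for a normal-like distribution, or the density valley between
the two major modes of a kernel density estimate for a bimodal one; a
manual override is supported for distributions without a clear separation
point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, pearsonr
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score

from .containers import ExpressionMatrix, PipelineError, ResponsePanel, SENSITIVE

logger = logging.getLogger("drugresp")

CUTOFF_MEDIAN = "median"
CUTOFF_VALLEY = "density_valley"
CUTOFF_MANUAL = "manual"


@dataclass
class ScoreCutoff:
    """A sensitive/resistant boundary on the log2 IC50 (score) scale."""

    value: float
    method: str

    def classify(self, scores: pd.Series) -> pd.Series:
        """Sensitive iff score strictly below the cutoff (boundary = resistant)."""
        return pd.Series(
            np.where(scores < self.value, SENSITIVE, "resistant"), index=scores.index
        )


@dataclass
class PerformanceRecord:
    corr: float
    auc: float


@dataclass
class PLSRModel:
    """A fitted PLS1 model restricted to its signature genes."""

    gene_ids: list[str]
    n_components: int
    x_loadings: pd.DataFrame  # genes x components
    coef: pd.Series  # per-gene regression coefficient (on scaled X)
    x_mean: pd.Series
    x_std: pd.Series
    y_mean: float
    training_sample_ids: list[str]
    fitted: pd.Series  # fitted values on the training samples
    cutoff: ScoreCutoff | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "gene_ids": self.gene_ids,
            "n_components": self.n_components,
            "x_loadings": {
                c: self.x_loadings[c].tolist() for c in self.x_loadings.columns
            },
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "training_sample_ids": self.training_sample_ids,
            "cutoff": None
            if self.cutoff is None
            else {"value": self.cutoff.value, "method": self.cutoff.method},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSRModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        genes = d["gene_ids"]
        cutoff = d.get("cutoff")
        return cls(
            gene_ids=genes,
            n_components=d["n_components"],
            x_loadings=pd.DataFrame(d["x_loadings"], index=genes),
            coef=pd.Series(d["coef"], index=genes),
            x_mean=pd.Series(d["x_mean"], index=genes),
            x_std=pd.Series(d["x_std"], index=genes),
            y_mean=d["y_mean"],
            training_sample_ids=d["training_sample_ids"],
            fitted=pd.Series(dtype=float),
            cutoff=None if cutoff is None else ScoreCutoff(**cutoff),
        )


def design_matrix(expr: ExpressionMatrix, samples, genes) -> pd.DataFrame:
    """Samples x genes design matrix for a given signature and sample set."""
    return expr.values.loc[list(genes), list(samples)].T


def fit_plsr(X: pd.DataFrame, y: pd.Series, n_components: int = 2) -> PLSRModel:
    """Fit a PLS1 regression of y on autoscaled columns of X.

    Zero-variance columns are dropped (logged).  Requires at least
    ``n_components + 2`` samples.
    """
    if X.isna().any().any():
        raise PipelineError("design matrix contains missing values")
    if X.shape[0] < n_components + 2:
        raise PipelineError(
            f"need at least {n_components + 2} samples to fit {n_components} components"
        )
    y = pd.Series(y).loc[X.index]
    std = X.std(ddof=1)
    dropped = std.index[std == 0]
    if len(dropped):
        logger.info("fit_plsr: dropped %d zero-variance genes", len(dropped))
        X = X.drop(columns=dropped)
        std = std.drop(dropped)
    if X.shape[1] == 0:
        raise PipelineError("no genes with positive variance")
    mean = X.mean()
    Xs = (X - mean) / std
    ncomp = min(n_components, X.shape[0] - 1, X.shape[1])
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(Xs.to_numpy(), (y - y.mean()).to_numpy())
    coef = pd.Series(pls.coef_.ravel(), index=X.columns)
    loadings = pd.DataFrame(
        pls.x_loadings_,
        index=X.columns,
        columns=[f"comp_{k + 1}" for k in range(ncomp)],
    )
    fitted = pd.Series(
        Xs.to_numpy() @ coef.to_numpy() + y.mean(), index=X.index, name="fitted"
    )
    return PLSRModel(
        gene_ids=list(X.columns),
        n_components=ncomp,
        x_loadings=loadings,
        coef=coef,
        x_mean=mean,
        x_std=std,
        y_mean=float(y.mean()),
        training_sample_ids=list(X.index),
        fitted=fitted,
    )


def predict(model: PLSRModel, X: pd.DataFrame) -> pd.Series:
    """Predicted log2 IC50 for each row of X (samples x genes)."""
    missing = [g for g in model.gene_ids if g not in X.columns]
    if missing:
        raise PipelineError(f"prediction input lacks {len(missing)} model genes: {missing[:10]}")
    Xm = X[model.gene_ids]
    if not np.isfinite(Xm.to_numpy(dtype=float)).all():
        raise PipelineError("prediction input contains non-finite values")
    Xs = (Xm - model.x_mean) / model.x_std
    return pd.Series(
        Xs.to_numpy() @ model.coef.to_numpy() + model.y_mean,
        index=X.index,
        name="predicted_log2_ic50",
    )


def predict_expression(model: PLSRModel, expr: ExpressionMatrix) -> pd.Series:
    return predict(model, expr.values.T)


def gene_weights(model: PLSRModel) -> pd.Series:
    """Per-gene weight sqrt(L1^2 + L2^2) from the first two components."""
    if model.n_components < 2:
        raise PipelineError("gene weights require at least 2 PLS components")
    l1 = model.x_loadings.iloc[:, 0]
    l2 = model.x_loadings.iloc[:, 1]
    return np.sqrt(l1**2 + l2**2).rename("weight")


def roc_auc(scores: pd.Series, labels: pd.Series) -> float:
    """ROC AUC for recovering sensitive labels from predicted IC50 scores.

    Equals the Mann-Whitney pair statistic with ties counted 1/2; lower
    predicted scores indicate the sensitive class.
    """
    is_sensitive = np.asarray(labels) == SENSITIVE
    if is_sensitive.all() or not is_sensitive.any():
        raise PipelineError("ROC AUC requires both classes")
    return float(roc_auc_score(is_sensitive, -np.asarray(scores, dtype=float)))


def evaluate_performance(
    scores: pd.Series, observed: pd.Series, labels: pd.Series
) -> PerformanceRecord:
    """Correlation with observed log2 IC50 plus label-recovery AUC."""
    corr = float(pearsonr(np.asarray(scores, float), np.asarray(observed, float))[0])
    return PerformanceRecord(corr=corr, auc=roc_auc(scores, labels))


# ---------------------------------------------------------------------------
# response cutoffs
# ---------------------------------------------------------------------------


def _kde_modes(values: np.ndarray, grid_size: int = 512):
    kde = gaussian_kde(values, bw_method="silverman")
    pad = 0.05 * (values.max() - values.min() or 1.0)
    grid = np.linspace(values.min() - pad, values.max() + pad, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    peaks = interior[(dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])]
    return grid, dens, peaks


def response_cutoff(
    values,
    method: str = "auto",
    manual_value: float | None = None,
    min_minor_mass: float = 0.10,
) -> ScoreCutoff:
    """Data-driven sensitive/resistant cutoff on IC50 (or predicted) scores.

    ``median`` uses the sample median; ``valley`` the argmin of a
    Silverman-bandwidth Gaussian KDE between the two highest-density modes;
    ``auto`` picks valley when the KDE is bimodal with at least
    ``min_minor_mass`` of the data on the minor side, else median;
    ``manual`` returns the supplied value.
    """
    if method == CUTOFF_MANUAL or method == "manual":
        if manual_value is None:
            raise PipelineError("manual cutoff requires manual_value")
        return ScoreCutoff(float(manual_value), CUTOFF_MANUAL)
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise PipelineError("data-driven cutoffs need at least 10 values")
    if method == "median":
        return ScoreCutoff(float(np.median(values)), CUTOFF_MEDIAN)
    if method not in ("valley", "auto"):
        raise PipelineError(f"unknown cutoff method {method!r}")

    grid, dens, peaks = _kde_modes(values)
    if len(peaks) < 2:
        if method == "valley":
            raise PipelineError(
                "density is unimodal: no valley cutoff; use method='median' or manual"
            )
        return ScoreCutoff(float(np.median(values)), CUTOFF_MEDIAN)
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top2)
    valley_idx = lo + int(np.argmin(dens[lo : hi + 1]))
    valley = float(grid[valley_idx])
    minor_mass = min((values < valley).mean(), (values >= valley).mean())
    if method == "auto" and minor_mass < min_minor_mass:
        return ScoreCutoff(float(np.median(values)), CUTOFF_MEDIAN)
    return ScoreCutoff(valley, CUTOFF_VALLEY)


def label_panel(resp: ResponsePanel, method: str = "auto", manual_value=None) -> ResponsePanel:
    """Assign sensitive/resistant labels from a data-driven IC50 cutoff."""
    cut = response_cutoff(resp.ic50_log2.to_numpy(), method=method, manual_value=manual_value)
    return resp.assign_labels(cut.value)
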