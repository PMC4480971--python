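"""Dose-response QC, expression data reduction and cross-platform normalization.

Dose-response curves are handled as tidy tables with columns
``cell_line_id, dose, response, cv`` (one row per dose point; ``response``
is mean percent inhibition, NaN where the point is missing; ``cv`` is the
replicate coefficient of variation in percent).

The expression side implements the standard reduction funnel applied before
feature selection -- keep the top fraction of features by mean intensity,
then drop low-variance features, then collapse probesets to one
representative per gene -- plus the two steps needed to carry a model onto
a second array platform: best-match probe mapping and quantile
normalization of the test cohort against the training panel's reference
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PipelineError

logger = logging.getLogger("drugresp")

FLAG_OK = "pass"
FLAG_TOO_FEW = "too_few_points"
FLAG_MISSING = "missing_points"
FLAG_HIGH_CV = "high_cv"
FLAG_NON_MONOTONE = "non_monotone"
FLAG_LAST_DOSE_ONLY = "last_dose_only"


@dataclass
class ProbeMap:
    """Best-match probe pairs: test-platform source id -> training-platform id."""

    table: pd.DataFrame  # columns source_id, target_id

    def __post_init__(self) -> None:
        required = {"source_id", "target_id"}
        if not required.issubset(self.table.columns):
            raise PipelineError(f"probe map must have columns {sorted(required)}")
        if self.table["source_id"].duplicated().any():
            raise PipelineError("probe map: a source id maps to more than one target")

    @classmethod
    def from_tsv(cls, path) -> "ProbeMap":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dose-response QC
# ---------------------------------------------------------------------------


def qc_dose_response(
    curves: pd.DataFrame,
    cv_limit: float = 30.0,
    max_missing: int = 3,
    max_high_cv: int = 4,
    inversion_tolerance: float = 20.0,
    low_dose_floor: float = 10.0,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the four dose-response QC rules; return retained ids and flags.

    A curve is removed if (1) it has ``max_missing`` or more missing points,
    (2) ``max_high_cv`` or more points with CV above ``cv_limit``, (3) some
    lower dose inhibits more than a higher dose by over
    ``inversion_tolerance`` percentage points, or (4) it shows inhibition
    only at the highest tested dose (all lower doses below
    ``low_dose_floor`` while the top dose is active).  Each removed curve is
    flagged with the first rule it violates; curves with fewer than two
    valid points are flagged unconditionally.
    """
    if "response" not in curves.columns and "mean_response" in curves.columns:
        curves = curves.rename(columns={"mean_response": "response"})
    flags = []
    for cl, grp in curves.groupby("cell_line_id", sort=False):
        grp = grp.sort_values("dose")
        resp = grp["response"].to_numpy(dtype=float)
        cv = grp["cv"].to_numpy(dtype=float)
        valid = np.isfinite(resp)
        n_missing = int((~valid).sum())
        flag = FLAG_OK
        if valid.sum() < 2:
            flag = FLAG_TOO_FEW
        elif n_missing >= max_missing:
            flag = FLAG_MISSING
        elif int((cv[valid] > cv_limit).sum()) >= max_high_cv:
            flag = FLAG_HIGH_CV
        else:
            r = resp[valid]
            # rule 3: running maximum of earlier (lower) doses vs later doses
            if len(r) >= 2 and np.max(np.maximum.accumulate(r)[:-1] - r[1:]) > inversion_tolerance:
                flag = FLAG_NON_MONOTONE
            elif (r[:-1] < low_dose_floor).all() and r[-1] >= low_dose_floor:
                flag = FLAG_LAST_DOSE_ONLY
        flags.append((cl, flag))
    flag_table = pd.DataFrame(flags, columns=["cell_line_id", "flag"])
    retained = flag_table.loc[flag_table["flag"] == FLAG_OK, "cell_line_id"].tolist()
    logger.info(
        "dose-response QC: retained %d of %d curves", len(retained), len(flag_table)
    )
    return retained, flag_table


# ---------------------------------------------------------------------------
# expression data reduction
# ---------------------------------------------------------------------------


def reduce_by_intensity(m: ExpressionMatrix, keep_fraction: float = 0.40) -> ExpressionMatrix:
    """Keep the ``keep_fraction`` of features with highest mean intensity.

    Intensity is the mean log2 value across samples; ties are broken by
    feature-id lexical order.
    """
    if not 0 < keep_fraction <= 1:
        raise PipelineError("keep_fraction must lie in (0, 1]")
    if m.shape[0] == 0:
        raise PipelineError("empty expression matrix")
    n_keep = max(1, int(round(keep_fraction * m.shape[0])))
    order = (
        m.values.mean(axis=1)
        .rename("intensity")
        .rename_axis("feature_id")
        .reset_index()
        .sort_values(["intensity", "feature_id"], ascending=[False, True], kind="mergesort")
    )
    keep = set(order["feature_id"].head(n_keep))
    out = ExpressionMatrix(m.values.loc[m.feature_ids.isin(keep)], m.platform)
    logger.info("intensity filter: %d -> %d features", m.shape[0], out.shape[0])
    return out


def reduce_by_variance(m: ExpressionMatrix, min_variance: float = 1.0) -> ExpressionMatrix:
    """Keep features with sample variance (n-1 denominator) >= ``min_variance``."""
    if m.shape[1] < 2:
        raise PipelineError("variance filter needs at least two samples")
    var = m.values.var(axis=1, ddof=1)
    out = ExpressionMatrix(m.values.loc[var >= min_variance], m.platform)
    logger.info("variance filter: %d -> %d features", m.shape[0], out.shape[0])
    return out


def _representative_probes(values: pd.DataFrame, groups: pd.Series) -> list:
    """One probe per group: highest mean, ties by higher variance then id."""
    stats = pd.DataFrame(
        {
            "group": groups,
            "mean": values.mean(axis=1),
            "var": values.var(axis=1, ddof=1) if values.shape[1] > 1 else 0.0,
        },
        index=values.index,
    )
    stats = stats.rename_axis("probe").reset_index()
    stats = stats.sort_values(
        ["group", "mean", "var", "probe"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return stats.groupby("group", sort=False).first()["probe"].tolist()


def collapse_probesets(m: ExpressionMatrix, probe_to_gene) -> ExpressionMatrix:
    """Collapse probesets to one representative row per gene.

    The representative is the probeset with the highest mean intensity;
    ties fall back to higher variance, then lexical probe id.  Probes
    without a gene mapping are dropped (count logged).
    """
    mapping = pd.Series(probe_to_gene)
    mapped = m.feature_ids.intersection(mapping.index)
    n_dropped = m.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probesets: dropped %d unmapped probes", n_dropped)
    if len(mapped) == 0:
        raise PipelineError("no probes map to a gene symbol")
    values = m.values.loc[mapped]
    genes = mapping.loc[mapped]
    chosen = _representative_probes(values, genes)
    chosen_in_order = [p for p in values.index if p in set(chosen)]
    out = values.loc[chosen_in_order]
    out.index = pd.Index(genes.loc[chosen_in_order], name="feature_id")
    return ExpressionMatrix(out, m.platform)


def map_probes(m: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Rename test-platform features to training-platform identifiers.

    Unmapped features are dropped (count logged); several sources mapping
    to the same target are resolved by the probeset-collapsing rule.
    """
    mapping = probe_map.table.set_index("source_id")["target_id"]
    out = collapse_probesets(m, mapping)
    if out.shape[0] == 0:
        raise PipelineError("probe map shares no features with the matrix")
    return out


# ---------------------------------------------------------------------------
# reference quantile normalization
# ---------------------------------------------------------------------------


def reference_distribution(reference: ExpressionMatrix) -> np.ndarray:
    """Sorted per-rank means across reference samples (ascending)."""
    return np.sort(reference.values.to_numpy(dtype=float), axis=0).mean(axis=1)


def reference_quantile_normalize(
    test: ExpressionMatrix, reference: ExpressionMatrix
) -> ExpressionMatrix:
    """Quantile-normalize each test sample onto the reference distribution.

    Each test sample's values are replaced rank-by-rank with the reference
    distribution (the sorted per-rank means over reference samples); tied
    values receive the mean of the tied ranks' reference values.  When the
    feature counts differ (best-match mapping can drop features) the
    reference distribution is linearly interpolated at the test quantile
    positions.  Normalization is meant to run on the whole shared feature
    space before any signature subsetting.
    """
    if test.shape[0] == 0 or reference.shape[0] == 0:
        raise PipelineError("cannot quantile normalize an empty matrix")
    target = reference_distribution(reference)
    n = test.shape[0]
    if len(target) != n:
        pos = np.linspace(0.0, 1.0, n)
        ref_pos = np.linspace(0.0, 1.0, len(target))
        target = np.interp(pos, ref_pos, target)
    out = np.empty((n, test.shape[1]))
    x_all = test.values.to_numpy(dtype=float)
    for j in range(test.shape[1]):
        x = x_all[:, j]
        order = np.argsort(x, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = target
        # ties: average the reference values over tied positions
        if len(np.unique(x)) < n:
            s = pd.Series(assigned).groupby(x).transform("mean").to_numpy()
            assigned = s
        out[:, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=test.feature_ids, columns=test.sample_ids),
        platform=reference.platform,
    )
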