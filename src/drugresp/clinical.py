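"""Clinical evaluation of a trained signature on a patient cohort.

Patients are scored with the final PLSR model and called sensitive when
the predicted score falls strictly below the panel-calibrated cutoff.
Calls are judged two ways: against progression-free survival dichotomized
at a drug-specific cutoff (confusion matrix and the derived accuracy /
sensitivity / specificity / PPV / NPV), and by survival stratification
(Kaplan-Meier medians, log-rank test, univariate Cox hazard ratio of
predicted-sensitive vs predicted-resistant with a Wald 95% CI).  A
cross-drug check runs the identical computations for a signature applied
to a cohort treated with the other drug, tagged "cross".  An indication
scan reports the percentage of predicted-sensitive samples per cancer
indication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .containers import ClinicalCohort, PipelineError, SENSITIVE
from .pathway import FunctionalSignature
from .plsr import predict

logger = logging.getLogger("drugresp")


@dataclass
class PfsCutoff:
    """Drug-specific responder threshold on progression-free survival."""

    months: float
    drug: str = ""

    def __post_init__(self) -> None:
        if self.months <= 0:
            raise PipelineError("PFS cutoff must be positive")


@dataclass
class StratificationResult:
    """Classification + survival summary of one model-on-cohort evaluation."""

    tag: str  # "matched" or "cross"
    scores: pd.Series
    classes: pd.Series
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    median_pfs_sensitive: float | None = None
    median_pfs_resistant: float | None = None
    logrank_p: float | None = None
    hazard_ratio: float | None = None
    hr_ci_low: float | None = None
    hr_ci_high: float | None = None
    extras: dict = field(default_factory=dict)

    def metrics_percent(self) -> dict[str, float | None]:
        """The five confusion metrics on the 0-100 scale (None where undefined)."""
        return {
            name: (None if v is None else 100.0 * v)
            for name, v in {
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "ppv": self.ppv,
                "npv": self.npv,
            }.items()
        }


def classify_patients(
    signature: FunctionalSignature, cohort: ClinicalCohort
) -> pd.DataFrame:
    """Per-patient predicted score and sensitive/resistant call.

    The cohort expression must already be mapped onto the training feature
    space and quantile-normalized against the training panel.
    """
    missing = [g for g in signature.model.gene_ids if g not in set(cohort.expression.feature_ids)]
    if missing:
        raise PipelineError(f"cohort lacks signature genes: {missing[:10]}")
    scores = predict(signature.model, cohort.expression.values.T)
    classes = signature.cutoff.classify(scores)
    return pd.DataFrame({"score": scores, "class": classes})


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_vs_pfs(
    classes: pd.Series, pfs: pd.Series, cutoff: PfsCutoff
) -> StratificationResult:
    """Confusion metrics of the sensitive call against dichotomized PFS.

    Responder = PFS >= cutoff months (the boundary counts as responder).
    Undefined ratios (zero denominators) are reported as None, never 0.
    """
    pfs = pfs.loc[classes.index]
    responder = pfs >= cutoff.months
    pred_sens = classes == SENSITIVE
    tp = int((pred_sens & responder).sum())
    fp = int((pred_sens & ~responder).sum())
    fn = int((~pred_sens & responder).sum())
    tn = int((~pred_sens & ~responder).sum())
    n = tp + fp + fn + tn
    return StratificationResult(
        tag="",
        scores=pd.Series(dtype=float),
        classes=classes,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=_ratio(tp + tn, n),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def survival_stratify(
    classes: pd.Series, pfs: pd.Series, events: pd.Series
) -> dict:
    """KM medians, log-rank p and univariate Cox HR (sensitive vs resistant)."""
    pfs = pfs.loc[classes.index]
    events = events.loc[classes.index]
    is_sens = (classes == SENSITIVE).to_numpy()
    if is_sens.all() or not is_sens.any():
        raise PipelineError("survival stratification requires both predicted classes")

    medians = {}
    for label, mask in (("sensitive", is_sens), ("resistant", ~is_sens)):
        km = KaplanMeierFitter().fit(pfs[mask], events[mask])
        medians[label] = float(km.median_survival_time_)

    lr = logrank_test(pfs[is_sens], pfs[~is_sens], events[is_sens], events[~is_sens])

    df = pd.DataFrame(
        {"pfs": pfs.to_numpy(), "event": events.to_numpy(), "sensitive": is_sens.astype(int)}
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="pfs", event_col="event")
    summary = cph.summary.loc["sensitive"]
    return {
        "median_pfs_sensitive": medians["sensitive"],
        "median_pfs_resistant": medians["resistant"],
        "logrank_p": float(lr.p_value),
        "hazard_ratio": float(np.exp(summary["coef"])),
        "hr_ci_low": float(np.exp(summary["coef lower 95%"])),
        "hr_ci_high": float(np.exp(summary["coef upper 95%"])),
    }


def evaluate_cohort(
    signature: FunctionalSignature,
    cohort: ClinicalCohort,
    pfs_cutoff: PfsCutoff,
    tag: str = "matched",
) -> StratificationResult:
    """Full evaluation: classification, confusion vs PFS, survival split."""
    calls = classify_patients(signature, cohort)
    classes = calls["class"].loc[cohort.patient_ids]
    result = confusion_vs_pfs(classes, cohort.clinical["pfs_months"], pfs_cutoff)
    result.tag = tag
    result.scores = calls["score"].loc[cohort.patient_ids]
    try:
        surv = survival_stratify(
            classes, cohort.clinical["pfs_months"], cohort.clinical["event"]
        )
        for k, v in surv.items():
            setattr(result, k, v)
    except PipelineError as exc:
        logger.warning("survival stratification skipped: %s", exc)
    return result


def cross_drug_check(
    signature: FunctionalSignature, cohort_other_drug: ClinicalCohort, pfs_cutoff: PfsCutoff
) -> StratificationResult:
    """Apply a signature to a cohort treated with the other drug (tag 'cross')."""
    return evaluate_cohort(signature, cohort_other_drug, pfs_cutoff, tag="cross")


def indication_scan(
    signature: FunctionalSignature, cohort: ClinicalCohort, group_col: str = "indication"
) -> pd.DataFrame:
    """Percent predicted-sensitive samples per indication, to 2 decimals."""
    calls = classify_patients(signature, cohort)
    rows = []
    for name, grp in cohort.clinical.groupby(group_col):
        idx = grp.index
        if len(idx) == 0:
            continue
        n_sens = int((calls.loc[idx, "class"] == SENSITIVE).sum())
        rows.append((name, len(idx), round(100.0 * n_sens / len(idx), 2)))
    return pd.DataFrame(rows, columns=[group_col, "n", "percent_sensitive"])
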