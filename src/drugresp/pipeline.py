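"""End-to-end orchestration: reduction -> features -> ensemble -> signature.

``run_train`` executes the full model-building workflow on in-memory
inputs and returns every intermediate artifact plus a gene/sample funnel
(counts surviving each stage).  ``run_evaluate`` carries a trained
signature onto a second-platform cohort: best-match probe mapping,
whole-feature-space quantile normalization against the training panel,
classification, confusion metrics against dichotomized PFS and survival
stratification.  A single master seed fans out to per-stage seeds through
a fixed counter scheme, so identical configurations reproduce identical
artifacts bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .containers import ClinicalCohort, ExpressionMatrix, PipelineError, ResponsePanel
from .clinical import PfsCutoff, StratificationResult, evaluate_cohort, indication_scan
from .ensemble import (
    consensus_weights,
    filter_overlapping,
    forward_select_core,
    materialize_record,
    overlap_null_quantile,
    pick_representatives,
    run_ensemble,
    score_balanced_sets,
    select_representative_model,
)
from .feature_selection import permutation_feature_test, select_features
from .panel_sim import NORMAL_LIKE
from .pathway import (
    FunctionalSignature,
    PathwayCollection,
    enrich_pathways,
    fit_final_model,
    select_functional_genes,
)
from .plsr import response_cutoff
from .preprocess import (
    ProbeMap,
    map_probes,
    reduce_by_intensity,
    reduce_by_variance,
    reference_quantile_normalize,
)
from .splitting import SplitConfig, remove_middle_tertile

logger = logging.getLogger("drugresp")


@dataclass
class PipelineConfig:
    """All stage parameters of the training/evaluation workflow."""

    keep_fraction: float = 0.40
    min_variance: float = 1.0
    n_perm: int = 1000
    p_cutoff: float = 0.01
    ic50_mode: str = NORMAL_LIKE
    middle_tertile: bool = True  # remove middle third for normal-like IC50s
    n_outer: int = 150
    n_inner: int = 1000
    top_sets: int = 5
    n_components: int = 2
    overlap_n_perm: int = 10000
    overlap_quantile: float = 0.90
    forward_start: int = 5
    forward_eps: float = 0.005
    forward_window: int = 10
    pathway_p_cutoff: float = 0.01
    cutoff_method: str = "auto"
    manual_cutoff: float | None = None
    pfs_cutoff_months: float = 2.4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass
class TrainResult:
    """Artifacts of a full training run."""

    signature: FunctionalSignature
    core_genes: list[str]
    core_model: object
    consensus: object
    feature_stats: pd.DataFrame
    selected_genes: list[str]
    ensemble_metrics: pd.DataFrame
    ranked_sets: pd.DataFrame
    top_models: list
    enrichment: pd.DataFrame
    performance_curve: pd.DataFrame
    funnel: dict = field(default_factory=dict)
    labeled_panel: ResponsePanel | None = None
    reduced_expression: ExpressionMatrix | None = None


def run_train(
    expr: ExpressionMatrix,
    resp: ResponsePanel,
    pathways: PathwayCollection,
    config: PipelineConfig,
) -> TrainResult:
    """Execute the full training workflow and return all artifacts."""
    funnel: dict[str, int] = {"input_features": expr.shape[0], "input_samples": expr.shape[1]}

    # stage 1: data reduction on the expression side
    reduced = reduce_by_intensity(expr, config.keep_fraction)
    funnel["after_intensity"] = reduced.shape[0]
    reduced = reduce_by_variance(reduced, config.min_variance)
    funnel["after_variance"] = reduced.shape[0]

    # stage 2: response labels from a data-driven cutoff; middle-tertile
    # removal sharpens the contrast for normal-like IC50 distributions
    common = reduced.sample_ids.intersection(resp.sample_ids)
    panel = resp.subset(common)
    cut = response_cutoff(
        panel.ic50_log2.to_numpy(),
        method="median" if config.ic50_mode == NORMAL_LIKE else config.cutoff_method,
    )
    panel = panel.assign_labels(cut.value)
    if config.middle_tertile:
        panel = remove_middle_tertile(panel, ic50_mode=config.ic50_mode)
    funnel["panel_cell_lines"] = len(panel.sample_ids)
    train_expr = reduced.subset_samples(panel.sample_ids)

    # stage 3: correlation feature selection with a permutation null
    stats = permutation_feature_test(
        train_expr, panel, n_perm=config.n_perm, seed=[config.seed, 11]
    )
    selected = select_features(stats, config.p_cutoff)
    funnel["selected_features"] = len(selected)

    # stage 4: split ensemble, top-set criteria, consensus and core signature
    split_cfg = SplitConfig(
        n_outer=config.n_outer, n_inner=config.n_inner, seed=config.seed
    )
    metrics = run_ensemble(train_expr, panel, selected, split_cfg, config.n_components)
    ranked = score_balanced_sets(metrics)
    chosen = pick_representatives(metrics, ranked, k=config.top_sets)
    top_models = [
        materialize_record(train_expr, panel, selected, split_cfg, o, i, config.n_components)
        for o, i in chosen
    ]
    null_q = overlap_null_quantile(
        panel_size=len(panel.sample_ids),
        set_size=len(top_models[0].random_train),
        n_perm=config.overlap_n_perm,
        q=config.overlap_quantile,
        seed=[config.seed, 13],
    )
    top_models = filter_overlapping(top_models, null_q)
    funnel["top_models"] = len(top_models)
    consensus = consensus_weights(top_models)
    representative = select_representative_model(top_models, consensus)
    core_genes, core_model, curve = forward_select_core(
        train_expr,
        panel,
        representative,
        consensus,
        split_cfg,
        start=config.forward_start,
        eps=config.forward_eps,
        window=config.forward_window,
        n_components=config.n_components,
    )
    funnel["core_genes"] = len(core_genes)

    # stage 5: pathway filtering and the final calibrated model
    background = list(train_expr.feature_ids)
    enrichment = enrich_pathways(core_genes, background, pathways)
    functional_genes = select_functional_genes(
        core_genes, enrichment, pathways, consensus.weights, config.pathway_p_cutoff
    )
    funnel["functional_genes"] = len(functional_genes)
    signature = fit_final_model(
        functional_genes,
        train_expr,
        panel,
        stats,
        enrichment=enrichment[enrichment["p"] < config.pathway_p_cutoff],
        cutoff_method=config.cutoff_method,
        manual_cutoff=config.manual_cutoff,
        n_components=config.n_components,
        provenance={"seed": config.seed, "config_hash": config.config_hash()},
    )
    logger.info("funnel: %s", funnel)
    return TrainResult(
        signature=signature,
        core_genes=core_genes,
        core_model=core_model,
        consensus=consensus,
        feature_stats=stats,
        selected_genes=selected,
        ensemble_metrics=metrics,
        ranked_sets=ranked,
        top_models=top_models,
        enrichment=enrichment,
        performance_curve=curve,
        funnel=funnel,
        labeled_panel=panel,
        reduced_expression=train_expr,
    )


def normalize_cohort(
    cohort_expr: ExpressionMatrix,
    probe_map: ProbeMap | None,
    reference: ExpressionMatrix,
) -> ExpressionMatrix:
    """Map a test cohort onto the training feature space and quantile-normalize.

    Normalization runs on the whole shared feature space (never on the
    signature subset alone), so the training-panel score cutoffs transfer.
    """
    mapped = map_probes(cohort_expr, probe_map) if probe_map is not None else cohort_expr
    shared = mapped.feature_ids.intersection(reference.feature_ids)
    if len(shared) == 0:
        raise PipelineError("no shared features between cohort and reference")
    mapped = mapped.subset_features(shared)
    ref = reference.subset_features(shared)
    return reference_quantile_normalize(mapped, ref)


def run_evaluate(
    signature: FunctionalSignature,
    cohort: ClinicalCohort,
    probe_map: ProbeMap | None,
    reference: ExpressionMatrix,
    pfs_cutoff: PfsCutoff,
    tag: str = "matched",
) -> tuple[StratificationResult, pd.DataFrame]:
    """Normalize, classify and evaluate a cohort; returns (result, indication scan)."""
    normalized = normalize_cohort(cohort.expression, probe_map, reference)
    norm_cohort = ClinicalCohort(normalized, cohort.clinical, truth=cohort.truth)
    result = evaluate_cohort(signature, norm_cohort, pfs_cutoff, tag=tag)
    scan = indication_scan(signature, norm_cohort) if "indication" in cohort.clinical else pd.DataFrame()
    return result, scan
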