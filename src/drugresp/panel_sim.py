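"""Synthetic training panels, dose-response curves and clinical cohorts.

The generator emulates the statistical structure of a cell-line
drug-sensitivity screen: a log2 expression matrix in which a small set of
"driver" genes is co-regulated along a latent pathway axis, a per-cell-line
IC50 whose log2 value is a weighted sum of driver-gene expression plus
noise (optionally bimodal, i.e. a sensitive and a resistant subpopulation),
a second-platform patient cohort whose progression-free survival is coupled
to the true sensitivity score, and 10-dose dilution-series response curves
with planted QC violations.  Ground truth (driver identities, true weights,
true per-sample scores) is returned alongside, so every downstream stage of
the pipeline can be checked for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalCohort, ExpressionMatrix, ResponsePanel

NORMAL_LIKE = "normal_like"
BIMODAL = "bimodal"

#: planted dose-response QC violation tags
QC_CLEAN = "none"
QC_MISSING = "missing_points"
QC_HIGH_CV = "high_cv"
QC_NON_MONOTONE = "non_monotone"
QC_LAST_DOSE_ONLY = "last_dose_only"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen.

    The defaults define the reference simulation used throughout the test
    suite: 2,000 genes of which 30 are correlated drivers, 200 cell lines,
    a per-driver contribution of 0.5 log2-IC50 units per log2 expression
    unit and residual IC50 noise of 1 log2 unit.
    """

    n_genes: int = 2000
    n_driver_genes: int = 30
    n_cell_lines: int = 200
    driver_effect_size: float = 0.5  # per-gene weight on log2 IC50
    noise_sd: float = 1.0  # residual SD of log2 IC50
    ic50_mode: str = NORMAL_LIKE
    bimodal_gap: float = 5.0  # log2 units between subpopulation modes
    n_patients: int = 200
    platform_shift: float = 1.0  # additive log2 offset of platform 2
    map_fraction: float = 1.0  # fraction of probes with a best-match entry
    pfs_link: float = 1.5  # log hazard per unit standardized true score
    censor_rate: float = 0.2
    baseline_pfs_median: float = 3.0  # months, at average true score
    seed: int = 0
    # expression structure: drivers are well-expressed, pathway-co-regulated
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    driver_baseline_mean: float = 9.0
    driver_baseline_sd: float = 1.0
    gene_noise_low: float = 0.6
    gene_noise_high: float = 1.4
    latent_loading: float = 0.8  # driver loading on the shared pathway factor
    ic50_log2_intercept: float = 0.0
    indications: tuple[str, ...] = ("lung", "liver", "kidney", "breast")

    def validate(self) -> None:
        if self.n_driver_genes > self.n_genes:
            raise ValueError("n_driver_genes exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.ic50_mode not in (NORMAL_LIKE, BIMODAL):
            raise ValueError(f"unknown ic50_mode {self.ic50_mode!r}")
        if not 0 <= self.map_fraction <= 1:
            raise ValueError("map_fraction must lie in [0, 1]")

    def expected_ic50_moments(self) -> tuple[float, float]:
        """Analytic mean and SD of log2 IC50 under this configuration."""
        d, e, l = self.n_driver_genes, self.driver_effect_size, self.latent_loading
        beta = d * e * l  # coherent latent contribution
        lo, hi = self.gene_noise_low, self.gene_noise_high
        mean_sd2 = (lo * lo + lo * hi + hi * hi) / 3.0  # E[sd^2], sd ~ U(lo,hi)
        var = beta**2 + d * e**2 * mean_sd2 + self.noise_sd**2
        mean = self.ic50_log2_intercept
        if self.ic50_mode == BIMODAL:
            mean += self.bimodal_gap / 2.0
            var += self.bimodal_gap**2 / 4.0
        return mean, float(np.sqrt(var))


@dataclass
class GroundTruth:
    """Generating parameters of one simulated drug response.

    ``weights`` holds each gene's true contribution to log2 IC50 (exactly 0
    for non-drivers); ``true_score`` is the noiseless log2 IC50 per panel
    cell line; the remaining fields record the expression model so patient
    cohorts can be drawn from the same distribution.
    """

    driver_gene_ids: frozenset
    weights: pd.Series  # per-gene true weight on log2 IC50
    true_score: pd.Series  # per-sample noiseless log2 IC50
    baseline_means: pd.Series = field(repr=False, default=None)
    gene_noise_sd: pd.Series = field(repr=False, default=None)
    loadings: pd.DataFrame = field(repr=False, default=None)  # genes x factors
    factor_index: int = 0  # which latent factor this drug's score rides on
    factor_shift: float = 0.0  # bimodal shift applied to that factor
    direct_shift: float = 0.0  # bimodal shift applied directly to log2 IC50
    intercept: float = 0.0
    score_mean: float = 0.0
    score_sd: float = 1.0
    score_cutoff: float = 0.0  # true sensitive/resistant boundary
    subpopulation: pd.Series | None = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n)], name="feature_id")


def _draw_expression(
    rng: np.random.Generator,
    mu: np.ndarray,
    gene_sd: np.ndarray,
    loadings: np.ndarray,
    z: np.ndarray,
    sample_ids,
    gene_index: pd.Index,
) -> pd.DataFrame:
    noise = rng.normal(0.0, gene_sd[:, None], size=(len(mu), z.shape[1]))
    values = mu[:, None] + loadings @ z + noise
    return pd.DataFrame(values, index=gene_index, columns=sample_ids)


def _build_gene_model(config: SimulationConfig, rng: np.random.Generator, n_factors: int = 1):
    """Draw per-gene baselines, noise SDs, weights and factor loadings."""
    genes = _gene_ids(config.n_genes)
    d = config.n_driver_genes
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    gene_sd = rng.uniform(config.gene_noise_low, config.gene_noise_high, size=config.n_genes)
    loadings = np.zeros((config.n_genes, n_factors))
    weights = np.zeros((config.n_genes, n_factors))
    driver_sets = []
    for f in range(n_factors):
        lo, hi = f * d, (f + 1) * d
        if hi > config.n_genes:
            raise ValueError("not enough genes for the requested driver blocks")
        mu[lo:hi] = rng.normal(
            config.driver_baseline_mean, config.driver_baseline_sd, size=d
        )
        signs = np.where(np.arange(d) % 2 == 0, 1.0, -1.0)  # mix of directions
        weights[lo:hi, f] = signs * config.driver_effect_size
        loadings[lo:hi, f] = signs * config.latent_loading
        driver_sets.append(frozenset(genes[lo:hi]))
    return genes, mu, gene_sd, loadings, weights, driver_sets


def _simulate_study(config: SimulationConfig, n_drugs: int):
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, mu, gene_sd, loadings, weights, driver_sets = _build_gene_model(
        config, rng, n_factors=n_drugs
    )
    n = config.n_cell_lines
    samples = pd.Index([f"CL{i:04d}" for i in range(n)], name="sample_id")

    z = rng.standard_normal((n_drugs, n))
    subpop = pd.Series(rng.integers(0, 2, size=n), index=samples, name="subpopulation")
    beta = config.n_driver_genes * config.driver_effect_size * config.latent_loading
    factor_shift = direct_shift = 0.0
    if config.ic50_mode == BIMODAL:
        if beta > 1e-12:
            factor_shift = config.bimodal_gap / beta
            z = z + factor_shift * subpop.to_numpy()[None, :]
        else:
            direct_shift = config.bimodal_gap

    expr_df = _draw_expression(rng, mu, gene_sd, loadings, z, samples, genes)
    expression = ExpressionMatrix(expr_df, platform="platform1")

    truths, panels = [], []
    for f in range(n_drugs):
        w = weights[:, f]
        signal = w @ (expr_df.to_numpy() - mu[:, None])
        score = config.ic50_log2_intercept + signal + direct_shift * subpop.to_numpy()
        y = score + rng.normal(0.0, config.noise_sd, size=n)
        panel = ResponsePanel(
            pd.DataFrame(
                {"ic50_linear": np.exp2(y), "ic50_log2": y}, index=samples
            )
        )
        true_score = pd.Series(score, index=samples, name="true_score")
        if config.ic50_mode == BIMODAL:
            cutoff = float(true_score.groupby(subpop).mean().mean())
        else:
            cutoff = float(true_score.median())
        truths.append(
            GroundTruth(
                driver_gene_ids=driver_sets[f],
                weights=pd.Series(w, index=genes, name="true_weight"),
                true_score=true_score,
                baseline_means=pd.Series(mu, index=genes),
                gene_noise_sd=pd.Series(gene_sd, index=genes),
                loadings=pd.DataFrame(
                    loadings, index=genes, columns=[f"factor_{k}" for k in range(n_drugs)]
                ),
                factor_index=f,
                factor_shift=factor_shift,
                direct_shift=direct_shift,
                intercept=config.ic50_log2_intercept,
                score_mean=float(true_score.mean()),
                score_sd=float(true_score.std(ddof=1)) or 1.0,
                score_cutoff=cutoff,
                subpopulation=subpop,
            )
        )
        panels.append(panel)
    return expression, panels, truths


def simulate_panel(config: SimulationConfig) -> tuple[ExpressionMatrix, ResponsePanel, GroundTruth]:
    """Simulate one drug screen: expression, IC50 panel and ground truth."""
    expression, panels, truths = _simulate_study(config, n_drugs=1)
    return expression, panels[0], truths[0]


def simulate_two_drug_study(config: SimulationConfig):
    """Two drugs with disjoint driver blocks on the same cell-line panel.

    Returns ``(expression, (panel_a, truth_a), (panel_b, truth_b))``.  The
    drugs share the expression matrix but ride on independent latent
    factors, so each signature should predict only its own drug.
    """
    expression, panels, truths = _simulate_study(config, n_drugs=2)
    return expression, (panels[0], truths[0]), (panels[1], truths[1])


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------


def simulate_clinical_cohort(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[ClinicalCohort, pd.DataFrame]:
    """Draw a second-platform patient cohort from the panel's model.

    Patient expression follows the same generative model as the panel,
    shifted by ``platform_shift`` and renamed to platform-2 feature ids.
    PFS is exponential with log hazard ``pfs_link`` x standardized true
    score (higher score = more resistant = shorter PFS for positive links),
    with independent uniform administrative censoring.  Returns the cohort
    and the probe best-match table (source platform-2 id -> panel id).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    genes = truth.baseline_means.index
    n_factors = truth.loadings.shape[1]
    n = config.n_patients
    patients = pd.Index([f"PT{i:04d}" for i in range(n)], name="sample_id")

    z = rng.standard_normal((n_factors, n))
    subpop = rng.integers(0, 2, size=n)
    if truth.factor_shift:
        z[truth.factor_index] += truth.factor_shift * subpop

    expr_df = _draw_expression(
        rng,
        truth.baseline_means.to_numpy(),
        truth.gene_noise_sd.to_numpy(),
        truth.loadings.to_numpy(),
        z,
        patients,
        genes,
    )
    score = (
        truth.intercept
        + truth.weights.to_numpy() @ (expr_df.to_numpy() - truth.baseline_means.to_numpy()[:, None])
        + truth.direct_shift * subpop
    )

    # platform 2: additive shift + renamed features, with a best-match table
    p2_ids = pd.Index(["P2_" + g for g in genes], name="feature_id")
    cohort_expr = ExpressionMatrix(
        pd.DataFrame(
            expr_df.to_numpy() + config.platform_shift, index=p2_ids, columns=patients
        ),
        platform="platform2",
    )
    n_mapped = int(round(config.map_fraction * len(genes)))
    mapped = rng.choice(len(genes), size=n_mapped, replace=False)
    mapped.sort()
    probe_map = pd.DataFrame(
        {"source_id": p2_ids[mapped], "target_id": genes[mapped]}
    )

    # survival: exponential PFS, uniform administrative censoring
    s_std = (score - truth.score_mean) / truth.score_sd
    hazard = (np.log(2.0) / config.baseline_pfs_median) * np.exp(config.pfs_link * s_std)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=n) < config.censor_rate
    t_cens = rng.uniform(0.0, np.maximum(t_event, 1e-6))
    pfs = np.where(censored, np.minimum(t_cens, t_event), t_event)
    pfs = np.maximum(pfs, 0.02)
    event = (~censored).astype(int)

    indications = [config.indications[i % len(config.indications)] for i in range(n)]
    clinical = pd.DataFrame(
        {
            "pfs_months": pfs,
            "event": event,
            "arm": "matched",
            "indication": indications,
        },
        index=patients,
    )
    patient_truth = pd.DataFrame(
        {
            "true_score": score,
            "true_label": np.where(score < truth.score_cutoff, "sensitive", "resistant"),
        },
        index=patients,
    )
    cohort = ClinicalCohort(cohort_expr, clinical, truth=patient_truth)
    return cohort, probe_map


# ---------------------------------------------------------------------------
# dose-response curves
# ---------------------------------------------------------------------------


def dose_series(top_dose: float = 30.0, n_doses: int = 10, fold: float = 3.0) -> np.ndarray:
    """Ascending dilution series: ``n_doses`` doses, ``fold``-fold apart."""
    return top_dose / fold ** np.arange(n_doses - 1, -1, -1)


def _sigmoid_inhibition(doses: np.ndarray, ic50: float, hill: float = 1.5) -> np.ndarray:
    return 100.0 / (1.0 + (ic50 / doses) ** hill)


def simulate_dose_response(
    config: SimulationConfig, violation_fraction: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell-line 10-dose inhibition curves with planted QC violations.

    Returns ``(curves, truth)``: *curves* is tidy with columns
    ``cell_line_id, dose, response, cv`` (``response`` NaN where the point
    is missing), *truth* records which QC rule each curve was planted to
    violate (``none`` for clean curves).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    doses = dose_series()
    kinds = [QC_MISSING, QC_HIGH_CV, QC_NON_MONOTONE, QC_LAST_DOSE_ONLY]
    rows, planted = [], []
    for i in range(config.n_cell_lines):
        cl = f"CL{i:04d}"
        ic50 = float(np.exp2(rng.normal(0.0, 1.5)))
        resp = _sigmoid_inhibition(doses, ic50) + rng.normal(0.0, 2.0, size=len(doses))
        resp = np.clip(resp, 0.0, 100.0)
        cv = rng.uniform(5.0, 15.0, size=len(doses))
        kind = QC_CLEAN
        if rng.uniform() < violation_fraction:
            kind = kinds[rng.integers(0, len(kinds))]
            if kind == QC_MISSING:
                drop = rng.choice(len(doses), size=3, replace=False)
                resp[drop] = np.nan
            elif kind == QC_HIGH_CV:
                bad = rng.choice(len(doses), size=4, replace=False)
                cv[bad] = rng.uniform(35.0, 60.0, size=4)
            elif kind == QC_NON_MONOTONE:
                # strong inhibition at a low dose that vanishes at high doses
                resp = _sigmoid_inhibition(doses, ic50)
                resp[1] = min(resp[-2] + 40.0, 100.0)
            elif kind == QC_LAST_DOSE_ONLY:
                resp = np.full(len(doses), 0.0)
                resp[:-1] = rng.uniform(0.0, 8.0, size=len(doses) - 1)
                resp[-1] = rng.uniform(60.0, 95.0)
        for d, r, c in zip(doses, resp, cv):
            rows.append((cl, d, r, c))
        planted.append((cl, kind))
    curves = pd.DataFrame(rows, columns=["cell_line_id", "dose", "response", "cv"])
    truth = pd.DataFrame(planted, columns=["cell_line_id", "planted_violation"])
    return curves, truth


# ---------------------------------------------------------------------------
# synthetic pathways and on-disk layout
# ---------------------------------------------------------------------------


def make_pathways(
    truth: GroundTruth,
    n_pathways: int = 20,
    pathway_size: int = 30,
    seed: int = 0,
) -> dict[str, tuple[str, list[str]]]:
    """Synthetic gene sets: one holds the drivers, the rest are random."""
    rng = np.random.default_rng([seed, 303])
    genes = list(truth.weights.index)
    non_drivers = [g for g in genes if g not in truth.driver_gene_ids]
    sets: dict[str, tuple[str, list[str]]] = {
        "PW_DRIVERS": ("synthetic driver pathway", sorted(truth.driver_gene_ids))
    }
    for i in range(1, n_pathways):
        members = rng.choice(non_drivers, size=min(pathway_size, len(non_drivers)), replace=False)
        sets[f"PW_{i:03d}"] = ("synthetic random pathway", sorted(members))
    return sets


def write_simulation(
    out_dir,
    expression: ExpressionMatrix,
    panel: ResponsePanel,
    truth: GroundTruth,
    config: SimulationConfig,
    cohort: ClinicalCohort | None = None,
    probe_map: pd.DataFrame | None = None,
) -> None:
    """Write the simulated study as the pipeline's TSV/GMT/JSON inputs."""
    from .pathway import write_gmt  # local import to keep module order acyclic

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expression.to_tsv(out / "expression.tsv")
    panel.table[["ic50_linear"]].rename_axis("sample_id").to_csv(
        out / "ic50.tsv", sep="\t"
    )
    write_gmt(make_pathways(truth, seed=config.seed), out / "pathways.gmt")
    if cohort is not None:
        cohort.expression.to_tsv(out / "cohort_expression.tsv")
        cohort.clinical.rename_axis("sample_id").to_csv(out / "clinical.tsv", sep="\t")
    if probe_map is not None:
        probe_map.to_csv(out / "probe_map.tsv", sep="\t", index=False)
    truth_payload = {
        "driver_gene_ids": sorted(truth.driver_gene_ids),
        "weights": {g: w for g, w in truth.weights.items() if w != 0.0},
        "true_score": truth.true_score.round(6).to_dict(),
        "score_cutoff": truth.score_cutoff,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
        },
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))
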