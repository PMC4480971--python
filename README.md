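# drugresp

Builds **cell-line-derived drug-sensitivity signatures** — gene-expression
models trained on an in vitro screening panel that predict whether a patient's
tumor will respond to a targeted drug — and evaluates them on clinical
cohorts profiled on a different array platform.

## Who this is for

Translational-medicine and biomarker teams who have (a) a panel of cancer
cell lines with baseline log2 expression and per-line IC50 values for a
compound, and (b) an independent patient cohort with expression and
progression-free survival (PFS), and who want a reproducible pipeline from
raw dose-response QC to Kaplan-Meier stratification of predicted
responders. A fully synthetic study generator with known ground truth is
included, so every stage can be exercised and benchmarked without access to
proprietary screen data.

## The method

The response variable is log2(IC50); the predictors are autoscaled log2
expression values. The pipeline:

1. **Dose-response QC** — curves are dropped if they have ≥3 missing dose
   points, ≥4 points with CV > 30%, a non-monotone inversion, or inhibition
   only at the highest tested dose.
2. **Data reduction** — keep the top 40% of features by mean intensity,
   then features with variance ≥ 1; collapse probesets to the
   highest-intensity representative per gene.
3. **Feature selection** — per-gene Pearson correlation *r* with log2 IC50,
   Fisher-transformed (*f* = ½·ln((1+*r*)/(1−*r*))), tested against a
   permutation null (shared response shuffles, normal fit of permuted *f*);
   genes pass at raw p < 0.01 (BH-adjusted values reported alongside).
4. **Split ensemble** — an outer "balanced split" stratified by IC50
   tertile puts 70% of lines in training and 30% in balance validation;
   an inner random 60/40 split of the training part gives random training
   (42% of the panel) and random validation (28%). A 2-component PLS
   regression is fitted on every one of n_outer × n_inner splits and scored
   on both held-out parts by Pearson correlation and ROC AUC.
5. **Model selection** — outer sets are ranked by five criteria (correlated
   validation metrics, narrower balance-validation spread, non-inferior
   balance-validation medians, high absolute balance performance); the best
   inner model of each top set is kept, and models whose random-training
   line sets overlap beyond the 90% quantile of a random-subset Jaccard
   null are removed.
6. **Consensus and core signature** — per-gene weights
   w = √(PLS1² + PLS2²) from the surviving top models are summarized by the
   first right singular vector (SVD consensus); forward selection over
   consensus-ranked genes (starting from the top five, one gene at a time)
   stops at an early plateau of both validation metrics, giving the core
   model.
7. **Pathway filter** — core genes on gene sets enriched at hypergeometric
   p < 0.01 form the functional signature, refit on the full retained panel
   and calibrated with a data-driven score cutoff (median for normal-like
   score distributions, KDE density valley for bimodal ones, manual
   override supported).
8. **Clinical evaluation** — the patient cohort is mapped through a
   best-match probe table, quantile-normalized against the training panel
   on the whole shared feature space, scored, and classed sensitive when
   the predicted score falls below the panel cutoff. Calls are summarized
   against PFS dichotomized at a drug-specific cutoff (accuracy,
   sensitivity, specificity, PPV, NPV) and by survival analysis (KM
   medians, log-rank, univariate Cox hazard ratio).

## Worked example

```python
import drugresp as dr

cfg = dr.SimulationConfig(n_genes=500, n_driver_genes=20, n_cell_lines=150,
                          n_patients=200, seed=42)
expr, panel, truth = dr.simulate_panel(cfg)
pathways = dr.PathwayCollection(dr.make_pathways(truth, seed=cfg.seed))
pipe = dr.PipelineConfig(n_outer=5, n_inner=50, n_perm=500, seed=cfg.seed)
result = dr.run_train(expr, panel, pathways, pipe)
print("funnel:", result.funnel)

cohort, probe_map = dr.simulate_clinical_cohort(truth, cfg)
res, scan = dr.run_evaluate(result.signature, cohort, dr.ProbeMap(probe_map),
                            expr, dr.PfsCutoff(2.4))
print("metrics %:", res.metrics_percent())
print("HR:", res.hazard_ratio, "log-rank p:", res.logrank_p)
```

Output:

```
funnel: {'input_features': 500, 'input_samples': 150, 'after_intensity': 200,
         'after_variance': 106, 'panel_cell_lines': 100,
         'selected_features': 21, 'top_models': 3, 'core_genes': 14,
         'functional_genes': 12}
metrics %: {'accuracy': 74.0, 'sensitivity': 81.7, 'specificity': 65.6,
            'ppv': 72.0, 'npv': 76.8}
HR: 0.23 (95% CI 0.16-0.33)  log-rank p: 9.2e-17
```

Reading: of 500 simulated genes the reduction funnel keeps 106; 21 pass the
permutation gate; the forward-selected core has 14 genes of which 12 sit on
a significant pathway and form the final signature (12 of the 20 planted
drivers). On a fresh 200-patient second-platform cohort the calibrated
model calls responders with 74% accuracy against PFS dichotomized at 2.4
months, and the predicted-sensitive group has a hazard ratio of 0.23 —
markedly longer progression-free survival.

The same workflow is available from the shell:

```sh
drugresp simulate --out sim/ --seed 42
drugresp train --expr sim/expression.tsv --ic50 sim/ic50.tsv \
    --gmt sim/pathways.gmt --seed 42 --out model/
drugresp evaluate --model model/signature.json --expr sim/cohort_expression.tsv \
    --clinical sim/clinical.tsv --probe-map sim/probe_map.tsv \
    --reference sim/expression.tsv --pfs-cutoff 2.4 --out eval/
```

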