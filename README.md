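# cordmrs

Cord-blood DNA methylation risk scores (MRS) for maternal smoking.

Maternal smoking during pregnancy leaves a reproducible methylation
signature in newborn cord blood. Because self-reported smoking is
under-reported, an aggregated methylation score is a useful biomarker of
in-utero exposure — and it can be built **without individual-level
discovery data**, from published EWAS summary statistics alone. `cordmrs`
implements that construction end to end for epigenetic epidemiologists
working with birth-cohort β-value matrices:

* β-matrix quality control (missingness filters, mean imputation,
  cross-reactive/SNP probe masks, non-informative probe removal, sex
  mismatch and duplicate detection);
* reference-based cord-blood cell-type deconvolution (CD8T, CD4T, NK,
  B cells, monocytes, granulocytes, nucleated RBC) by constrained least
  squares;
* per-CpG "reverse regression" EWAS of smoking phenotypes (logistic for
  current/ever smoking, linear for weekly exposure hours with a
  rank-inverse-normal transform), with BH-FDR and genomic-inflation λ;
* inverse-variance fixed-effect meta-analysis with Cochran's Q;
* the core contribution: a **summary-statistics elastic net** (lassosum-style).
  With `X` the column-standardized β-matrix, discovery effects reduced to
  pseudo-correlations `b` and a reference correlation matrix `R ≈ X′X/(n−1)`,
  the CpG weights γ minimize

  ```
  f(γ) = γ′(R + λ₂I)γ − 2 b′γ + 2 λ₁‖γ‖₁
  ```

  by cyclic coordinate descent with soft-threshold updates
  `γⱼ ← S(bⱼ − Σ_{k≠j} R_{jk}γ_k, λ₁)/(R_{jj} + λ₂)`. The (λ₁, λ₂) pair is
  tuned on a 50 × 10 grid (λ₂ = α(1 − λ₁)) against untransformed smoking
  history (0–3) in a validation cohort;
* score transfer with partial CpG overlap, AUC with 2000-resample
  bootstrap CIs, dose–response ANOVA/t-tests, and MRS–outcome association
  with cross-cohort meta-analysis and FDR;
* a synthetic two-population birth-cohort generator (a ~5%-current-smoker
  European-like design and a ~0%-smoker South-Asian-like design) so every
  stage is testable without access to restricted cohort data.

## Worked example

```python
import dataclasses
from cordmrs.simulate import SimConfig, simulate_cohort, simulate_discovery_sumstats
from cordmrs.qc import run_qc
from cordmrs.mrs import (TuningGrid, prepare_b, reference_correlation,
                         score_samples, standardize, tune)
from cordmrs.evaluate import auc_mw

base = dict(n_samples=400, n_cpgs=1000, n_causal=20, structure_seed=601)
validation = simulate_cohort(SimConfig(seed=602, **base))
target = simulate_cohort(SimConfig(seed=603, **base))
sumstats = simulate_discovery_sumstats(SimConfig(seed=602, **base),
                                       validation.truth, n_discovery=5000, seed=605)

sex = validation.phenotypes.set_index("sample_id")["newborn_sex"]
clean, report = run_qc(validation.beta, validation.manifest, sex)
panel = reference_correlation(standardize(clean)[0])
b = prepare_b(sumstats, panel.probe_ids)
model, trace = tune(b, panel, dataclasses.replace(validation, beta=clean),
                    grid=TuningGrid.default(b))

clean_t, _ = run_qc(target.beta, target.manifest,
                    target.phenotypes.set_index("sample_id")["newborn_sex"])
scores, n_used = score_samples(model, clean_t)
labels = target.phenotypes.set_index("sample_id").loc[scores.index, "current_smoker"]
print(len(model.probe_ids), n_used, round(auc_mw(scores, labels.astype(int)), 3))
```

prints

```
21 21 0.983
```

meaning the tuned model kept 21 CpGs (all present in the target matrix,
so all 21 were used for scoring) and the transferred score separates
current smokers from the rest of an independent cohort with AUC 0.983
under this strong-signal synthetic design.

The same flow is available from the shell:

```bash
mrs-smoke run --config config.yaml        # full pipeline, one config
mrs-smoke simulate --n-samples 400 --out fix/
mrs-smoke qc --beta fix/beta.tsv --manifest fix/manifest.tsv --out qc/
mrs-smoke build-mrs --sumstats ss.tsv --beta qc/beta_clean.tsv \
    --pheno fix/phenotypes.csv --cells fix/cells.csv \
    --out-model model.json --out-trace trace.tsv
mrs-smoke score --model model.json --beta other_beta.tsv --out scores.csv
```

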