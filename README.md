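# soilfusion

Multiblock spectra fusion for proximal soil sensing: predict soil
fertility attributes (pH, organic carbon, P, K, Mg, Ca, moisture) from
paired mid-infrared (MIR) absorbance spectra and X-ray fluorescence
(XRF) count spectra, and quantify what fusing the two sensors buys over
either one alone.

The package is aimed at chemometricians and soil-sensing researchers
who want a tested, reproducible implementation of the standard
two-block calibration workflow:

* **Preprocessing** — moving average, max-normalization, SNV, MSC,
  Savitzky–Golay, asymmetric-least-squares baseline correction and
  Compton normalization, composed into per-attribute recipes with
  train-only statistics.
* **Kennard–Stone partitioning** — deterministic max–min selection of a
  representative calibration set (196 samples at 80% → 156/40).
* **PLS (NIPALS)** — `X = TPᵀ + E`, `Y = UQᵀ + F`, latent-variable
  count chosen by k-fold cross-validated RMSE.
* **SOPLS** — sequential orthogonalized PLS for two blocks:
  `Y = X₁B₁ + X₂C₂ + E`. Fit block 1, orthogonalize block 2 against the
  block-1 scores, fit the residuals, sum the stage predictions. The
  contribution of each block is incremental and block-scale-invariant;
  `(a₁, a₂)` come from an exhaustive cross-validated grid search.
* **VIP selection** — per-channel importance
  `VIPⱼ = √(p·Σₐ w²ⱼₐ·SSYₐ/SSY_tot)`, normalized so mean(VIP²) = 1;
  channels above threshold 1 feed a reduced SOPLS model.
* **Evaluation** — R², RMSE, RPD = SD/RMSE and RPIQ = (Q3−Q1)/RMSE.

A synthetic paired-spectra generator with known latent structure and a
tunable cross-block *complementarity* (the fraction of attribute
variance carried only by the XRF block) supports method studies and
makes every claim in the test suite checkable against ground truth.

## Worked example

`examples/05_sequential_fusion_sopls.py` generates 196 synthetic
samples at complementarity 0.5, splits them 156/40 with Kennard–Stone
and compares single-sensor PLS with sequential fusion for pH:

```
MIR alone  (3 LVs):        R2 = 0.524, RMSE = 0.352, RPD = 1.47
XRF alone  (5 LVs):        R2 = 0.577, RMSE = 0.332, RPD = 1.56
SOPLS fusion (a1=4, a2=6): R2 = 0.859, RMSE = 0.192, RPD = 2.70
```

Each sensor sees only part of the latent chemistry driving pH, so each
single-block model tops out near R² ≈ 0.55; the sequential fusion model
recovers both parts (R² 0.86, RPD 2.7 — well above the RPD ≈ 2
rule-of-thumb for quantitative usefulness). Adding VIP selection
(`examples/06_vip_variable_selection.py`) keeps 637 of the 2948 fused
channels with no loss of accuracy. The other examples cover generation,
preprocessing, splitting, CV-based model selection and the full
five-model comparison harness (`run_comparison`), which mirrors the
standard calibration-paper report: R²cv/RMSEC on training
cross-validation, R²p/RMSEP/RPD/RPIQ on the common test set, and the
variable count per model.

A thin CLI wraps the same operations:

```sh
soilfusion simulate --n 196 --seed 7 --out data/
soilfusion split data/mir.csv --fraction 0.8 --out split.csv
soilfusion compare --seed 7 --out run/
```

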