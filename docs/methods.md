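# Methods

## The problem

Proximal soil sensing estimates fertility attributes from fast,
non-destructive spectra instead of wet chemistry. MIR absorbance
(4000–650 cm⁻¹) responds to molecular vibrations of organic matter,
water and minerals; XRF (0–30 keV) counts element emission lines.
Neither sensor sees everything: MIR reads primary organic/water
chemistry directly, XRF reads elemental composition. Low-level fusion
concatenates the two channel sets; the question this package
operationalizes is whether, and by how much, a fused calibration beats
either sensor alone, and whether a sequential multiblock model uses the
second sensor more efficiently than plain concatenation.

## Models

**PLS (NIPALS).** Mean-centered `X (n×p)` and `Y` are decomposed as
`X = TPᵀ + E`, `Y = UQᵀ + F` with unit-norm weight vectors `wₐ`,
scores `tₐ = X wₐ` mutually orthogonal, and regression coefficients
`B = W(PᵀW)⁻¹Qᵀ`. NIPALS is used rather than SIMPLS because VIP is
defined on the per-component weights `W` and because NIPALS component
paths are exactly nested — the first `a` components of a long fit equal
the `a`-component fit — which makes cross-validation over component
counts cheap and exact. Channels are not autoscaled (spectral channels
share units); centering only. Responses are modeled one attribute at a
time, matching how the model families are compared.

**Latent-variable selection.** k-fold CV (default 10-fold; contiguous
fold blocks after one seeded shuffle) picks the component count with
the lowest RMSECV; exact ties go to the smaller count. The searched cap
defaults to 15 and is truncated by rank and fold size.

**SOPLS.** For blocks `X₁` (MIR first — the more informative sensor by
default, configurable) and `X₂` (XRF): (1) PLS of `Y` on `X₁` with `a₁`
components; (2) orthogonalize centered `X₂` against the stage-1 scores,
`X₂orth = X₂c − T₁(T₁ᵀT₁)⁻¹T₁ᵀX₂c`, implemented by a pseudo-inverse
least-squares projection with rcond 1e-10 for robustness to
near-collinear scores; (3) PLS of the stage-1 residuals on `X₂orth`
with `a₂` components; (4) prediction is the sum of the two stages. New
data reuse the stored centering and the stored `T₁ → X₂` projection
map. Consequences verified in tests: stage-2 information is exactly
incremental (`a₂ = 0` reproduces the block-1 PLS bit-for-bit), and the
fit is invariant to rescaling either block.

**(a₁, a₂) grid search.** Exhaustive grid (defaults 0–10 × 0–10,
5-fold CV), with centering, orthogonalization and both stage fits redone
inside every training fold — no test-fold leakage. Selection is
parsimonious: among grid points whose RMSECV is within 1% (relative,
configurable) of the minimum, the smallest `a₁ + a₂` wins, then the
smaller `a₁`. Without this tolerance an uninformative second block
would pick up chance slivers of CV improvement and `a₂ = 0` would
almost never be selected; 1% is small against the CV noise observed at
the package's working sample sizes. The empty model (0, 0) is excluded.

**VIP.** `VIPⱼ = √(p Σₐ w²ⱼₐ SSYₐ / SSY_tot)` with
`SSYₐ = ‖tₐ‖²‖qₐ‖²`. With unit-norm weight columns this makes
mean(VIP²) exactly 1, which the tests assert to 1e-8 and which
motivates the default threshold of 1. "Above the threshold" is read as
strict `>` (configurable to `≥`); scores exactly at 1 are dropped.
VIP is computed per block from that block's own CV-selected PLS model
(not from the fused model); the two masks then feed a fresh SOPLS grid
search on the reduced blocks. An empty selection in either block is an
error rather than a silent fallback.

**Metrics.** `RMSE = √(1/n Σ(yᵢ−ŷᵢ)²)`; `R² = 1 − SS_res/SS_tot`
(the complementary ratio `SS_res/SS_tot` is available as
`residual_ratio`; the two sum to 1 by construction); `RPD = SD/RMSE`
with the n−1 SD denominator (affects the 2nd decimal at n = 40);
`RPIQ = (Q3−Q1)/RMSE` with linear-interpolation quantiles. Zero RMSE
yields an `inf` sentinel with a warning rather than an exception.

## Preprocessing

Operators never change sample count or order. Moving average (window 5,
shrinking at the edges), max-normalization (each spectrum divided by
its own maximum), SNV (per-spectrum centering/scaling, n−1 sd), MSC
(per-spectrum OLS regression on a reference; the reference is the mean
training spectrum, learned once and frozen for test data),
Savitzky–Golay (window 11, order 2), asymmetric-least-squares baseline
correction (second-difference penalty 1e5, asymmetry 0.01, solved by
banded Cholesky; both parameters configurable), and Compton
normalization (division by the trapezoidal integral over a scatter
window, default 18–22 keV around the Rh source-scatter region). A
channel-masking operator for the 2.5 keV detector spike exists but is
not in the default recipes, because the standard fused variable count
(2948 = 900 + 2048) assumes the full XRF axis.

Per-attribute preset recipes: MIR gets moving average then an
attribute-specific tail (max-normalize for pH/OC/Mg/MC, SNV for P,
nothing for K, MSC for Ca); XRF prepends baseline correction and
Compton normalization to the same tails. Savitzky–Golay is provided as
an operator but appears in no preset.

## Sampling

Kennard–Stone max–min selection on Euclidean distances, seeded by the
globally most distant pair; ties break to the lowest sample index, so
the split is bit-reproducible and permutation-invariant up to ties.
Training size is `floor(fraction·n)`, so 196 samples at 0.8 give the
canonical 156/40 partition. The pipeline computes distances on a
stateless reference preprocessing (moving average + max-normalize) of
the concatenated blocks, so all five model families and all seven
attributes share one split while stateful recipe statistics can still
be learned train-only afterwards.

## The synthetic generator

The generator emulates the statistical structure the workflow assumes,
not instrument physics. `k` latent factors per sample (uniform,
nonnegative, exchangeable across samples — no spatial correlation is
modeled). The last `k_x` factors are XRF-exclusive; the remaining MIR
factors render Gaussian absorption bands at classic soil wavenumbers
(3800–3000 O–H, 3000–2820 C–H, 1873/1730 C=O, 1632–1530 O–H/C–H bend,
1409, 1157 cm⁻¹); a configurable subset of MIR factors is also visible
to XRF (redundant signal). XRF renders element emission peaks (P, K,
Ca, Mn, Fe, Zn, Sr, Sn lines; K-Kα 3.31 and Ca-Kα 3.69 keV fall in the
3–5 keV region, Fe in 5–8 keV) over a bremsstrahlung-like continuum
with a broad Rh-scatter bump near 20 keV, plus a fixed detector spike
at 2.5 keV.

Artifacts: MIR gets per-sample multiplicative gain and additive offset
(scatter) and white noise in absorbance units; XRF gets a per-sample
gain (the matrix effect Compton normalization corrects) and
variance-proportional noise as a Poisson surrogate, keeping closed-form
expectations. Both families are clipped nonnegative. `noise_sd = 0`
switches the whole dataset (spectra and attributes) to the
deterministic noise-free limit, in which every attribute is an exact
linear function of the latents and the clean MIR block has rank equal
to its factor count.

Attributes mix standardized latent combinations:
`y = mean + sd·(√(1−c)·s_MIR + √c·s_XRF + ε)`, so `complementarity` c
is exactly the fraction of signal variance carried only by the XRF
block, and `attr_snr` (default 10) the signal-to-noise variance ratio.
Marginal means/sds default to values patterned on a European
agricultural field survey (e.g. pH 8.02 ± 0.50, Ca 1380 ± 957 mg/100 g).
Because marginals are symmetric latent mixtures, heavy-spread
attributes (P, Ca) can occasionally graze negative values; real soil
attribute distributions are skewed and bounded, which the generator
does not reproduce. Passing tests therefore demonstrate correct model
behaviour under the assumed latent-linear structure — they do not
certify accuracy levels on real field spectra.

All randomness flows from one integer seed through a single
`numpy` Generator in a fixed draw order; identical configs reproduce
datasets bit-identically.

## Problem sizes used in the checks

The behavioural suites run the full workflow at reduced scale — 120
samples, 240 MIR / 360 XRF channels for the replicated
structure-recovery checks, full 196/900/2048 scale for the partition,
concatenation and VIP-identity checks — sizes chosen so the whole suite
runs comfortably on a laptop while leaving the statistical conclusions
unchanged. The no-gain limit (fusion ≈ MIR alone when XRF carries no
attribute signal) is asserted on the run-level mean RMSE ratio over the
seven attributes, since single-attribute CV model selection at n = 120
has a few percent of irreducible choice noise.

## Known limitations

* Two blocks only; no three-block or PO-PLS variants.
* Single-response fits per attribute in the comparison harness
  (multi-response NIPALS exists in the core but is not exercised there).
* The generator treats samples as exchangeable: no spatial structure,
  no skewed/bounded attribute marginals, no instrument drift.
* The AsLS baseline and the Compton window are sensible defaults, not
  instrument calibrations; both are configurable and should be tuned
  for real spectrometers.
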