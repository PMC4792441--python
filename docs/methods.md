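# Methods

This note documents the models, parameter choices and numerical decisions
behind `oemri`, and what the synthetic benchmark does and does not show.

## Signal model and fitting

Each pixel's magnitude inversion-recovery series is modelled as

    S(TI) = | S0 · (1 − B · exp(−R1 · TI)) |

with three free parameters: the signal at full relaxation S0 (arbitrary
units), the inversion-efficiency factor B (dimensionless, 2 for an ideal
global inversion), and the longitudinal relaxation rate R1. Units are fixed
package-wide: TI and TE in ms, R1 and ΔR1 in s⁻¹ (the fitter converts TIs
to seconds internally), ΔR2* in ms⁻¹. A single-pixel unit test pins the
ms↔s conversion in both conventions.

The folded (magnitude) curve is fitted directly — no polarity-restoration
step rewrites the data. With only seven samples, flipping points by
heuristic is fragile; the absolute value inside the model handles the fold
and the optimizer sees the data untouched. Initialization is a coarse
variable-projection scan: for 24 log-spaced trial R1 values the model is
linear in (S0, −S0·B) and solved in closed form, under both polarity
hypotheses of the pre-minimum samples; the best triple seeds a bounded
trust-region least-squares solve (analytic Jacobian, default tolerances
1e-10). `n_multistart` (default 2) adds deterministic restarts with R1
scaled by {1/4, 4, …}; ties in the final cost break toward the lower R1.
A noiseless 5×5×5 parameter-grid suite verifies recovery to better than
1e-4 relative error.

Default bounds: R1 ∈ [0.01, 20] s⁻¹, B ∈ [0, 2.1], S0 > 0. A fit that
stops on a finite bound is flagged invalid rather than clipped and kept, so
the derived maps never mix converged and saturated estimates. At the
default noise level this discards roughly a quarter of pixels — mostly
fits pushed past B = 2.1 by noise — which is the intended conservative
behaviour; the RMS-residual ceiling (0.5 · S0) additionally rejects
garbage fits. Degenerate inputs: an all-zero signal yields
`fit_ok = False`; NaN or negative samples are an error.

The derived maps are ΔR1 = R1_O2 − R1_air (oxygen uptake) and
ΔR2* = ln(S0_air / S0_O2) / TE (oxygen delivery). Negative ΔR2* values
are reported, not erased — they indicate S0_O2 > S0_air and are flagged.
Because the simulator attenuates only the oxygen-state S0 by
exp(−ΔR2*·TE), the ΔR2* operation is its exact inverse in the noiseless
case, which an identity test asserts at 1e-12.

At the default SNR (≈20 at S0 = 3.29) the measured per-pixel R1 precision
is ~0.05 s⁻¹, with roughly ±0.008 spread across phantom realizations; the
noisy-recovery test freezes its RMSE threshold at 0.065 s⁻¹ accordingly.
ΔR2* is intrinsically noisy at TE = 0.5 ms: a ~1–2% error in each fitted
S0 propagates through the log-ratio divided by half a millisecond, so the
fitted within-animal ΔR2* SD is visibly inflated above its generating
value even though the animal means stay unbiased. This is a genuine
property of short-TE delivery mapping (precision falls as TE shrinks), not
an implementation artifact.

## Synthetic phantoms

Each animal is an ellipse-pair lung mask (default ~1,200 pixels on a
64×64 grid) carrying four spatially correlated fields (Gaussian-smoothed
white noise, correlation length 3 pixels — enough to give patchy
heterogeneity without a tissue model). Fields are standardized *exactly*
to the requested in-mask mean and population SD, so a phantom's
within-animal moments equal the template values by construction:

| parameter | control mean (SD) | challenged mean (SD) |
|---|---|---|
| S0_air (a.u.) | 3.29 (0.62) | 2.90 (0.66) |
| R1_air (s⁻¹) | 0.557 (0.067) | 0.549 (0.081) |
| ΔR1 (s⁻¹) | 0.024 (0.094) | 0.025 (0.110) |
| ΔR2* (ms⁻¹) | 0.071 (0.205) | 0.090 (0.267) |

Structure between the fields:

* R1_air is independent of density (baseline R1 is flat across densities).
* ΔR1 = mean + slope·(S0_air − mean_S0) + residual, with the residual
  orthogonalized against density and sized so the total SD is exact. The
  density→uptake slope is 0.03 s⁻¹ per a.u. in controls and 0.08 in the
  challenged template. These slopes are a package choice: the steeper,
  left-shifted challenged line crosses the control line near 2.6 a.u., so
  pooled low-density bins show an uptake deficit in the challenged group
  and high-density bins an excess, while both groups keep matched global
  means — the regional-vs-global dissociation the analysis is designed to
  detect.
* ΔR2* is linearly coupled to ΔR1 (delivery tracks uptake) with per-group
  coupling 0.46 / 0.42 s⁻¹ per ms⁻¹. The values keep the per-group
  ΔR1–ΔR2* correlation above 0.9 while leaving the residual variance
  nonnegative given the SDs above; no single shared slope can do both, so
  the coupling is per-template.

Between-animal variation enters as Gaussian jitter of the four template
means (SDs 0.16/0.23 for S0_air, 0.015/0.019 for R1_air, 0.015/0.018 for
ΔR1, 0.065/0.058 for ΔR2*, control/challenged). Within-animal SDs are
*not* jittered: each animal reproduces its group's heterogeneity exactly.
This makes the SD-level group contrast nearly deterministic — stronger
than real data, where the heterogeneity itself varies between animals —
and is the main caveat when reading the heterogeneity-test power results.

The forward simulator computes the noiseless magnitude signal per gas
state (oxygen state: R1 + ΔR1 and S0 attenuated by exp(−ΔR2*·TE)), zeroes
the background, and adds Gaussian noise on the magnitude (σ = 0.165,
giving SNR ≈ 20 at the control S0; a Rician option exists and matters
little at this SNR). The simulator deliberately does not assume full
relaxation at the longest TI — at TI = 6 s a control-lung curve reaches
only ~93% of S0 — so S0 must come from the fit. Radial sampling, gridding
artifacts, motion and atelectasis are out of scope. The default study is
9 control vs 8 challenged animals, all randomness derived deterministically
from one master seed.

## ROI and group statistics

Per animal, mean and sample SD (n−1 throughout) of the five parameters
(S0_air, R1_air, R1_O2, ΔR1, ΔR2*) over in-mask pixels with both gas-state
fits valid. Group contrasts are two-sample t-tests on the per-animal means
(global level) or per-animal SDs (heterogeneity), Welch by default —
safe under the unequal group variances this model produces — with a
pooled-variance Student option. No multiple-testing correction across the
five parameters. Zero-variance edge: two groups with no within-group
variance compare as t = 0, p = 1 when their means agree and p = 0
otherwise.

## Bin analysis

All valid pixels of all animals are pooled and rank-assigned to 20
equal-count bins (counts differ by ≤1; ties break by record order via a
stable sort; when the count is not divisible, lower bins take the extra
records). Bin edges come from the pooled two-group distribution — this is
what makes "the group mean difference in bin b" well-defined for the
permutation test; a per-group quantile mode exists for plotting per-group
curves. Bins are value-defined, not spatial. Per-bin group means of any
response parameter are then compared.

## Resampling inference

Pixels within an animal are correlated, so the exchangeable unit is the
animal. The permutation test permutes group labels across animals (all of
an animal's pixels move together), with bins and the observed differences
fixed beforehand; p per bin is the fraction of N relabelings (default
10,000, drawn with replacement from the assignment space) whose |difference|
strictly exceeds the observed one. No +1 smoothing: the minimum reportable
p is 0 and the resolution is 1/N. The test suite validates the Monte-Carlo
p against exhaustive enumeration on a 3-vs-2 design and its null
calibration over 500 simulated null studies. Report outputs flag bins with
p < 0.1.

The bootstrap resamples animals with replacement within each group
(default 2,000 replicates) and recomputes per-bin group means against the
fixed bins; the SD over replicates estimates the sampling spread of each
binned mean. Resampling animals rather than pixels keeps the
exchangeability assumption consistent with the permutation test; pixel
resampling would understate the spread by ignoring within-animal
correlation. Replicates that leave a bin empty for a group are ignored for
that bin. Both procedures are bit-reproducible given a seed; internally
they reduce to weighted combinations of per-animal-per-bin sums and
counts, which is what makes repeated-study calibration experiments cheap.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks run at reduced scale, chosen as the smallest sizes
at which the targeted effects are unambiguous: calibration experiments use
16×16 grids with ~60-pixel masks (500 null studies) and 32×32 grids with
~300-pixel masks (100-study power checks); fitting tests use one animal
with a ~200-pixel mask. The acceptance script fits a full 17-animal study
at 48×48 with ~600-pixel masks (~20,000 pixel fits) and uses 2,000
permutations. The full-size defaults (64×64, ~1,200 pixels, N = 10,000)
remain the package defaults.

## Known limitations

* The exact-moment construction makes within-animal SDs noiseless study
  conditions, so heterogeneity contrasts pass more decisively than real
  data would allow; power numbers for the SD-level t-tests should be read
  as upper bounds.
* The inversion-efficiency bound at 2.1 rejects a noticeable fraction of
  noisy pixels whose true B is 2.0; widening the bound trades validity
  flags for occasional saturated estimates.
* Fitted within-animal SDs of R1-derived parameters include fit noise on
  top of the generating heterogeneity (≈+25% for R1_air and ΔR1 at default
  SNR); comparisons of fitted SDs against generating SDs must account for
  this.
* The bootstrap's animal-resampling choice and the replicate count (2,000)
  are package assumptions where several defensible options exist.
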