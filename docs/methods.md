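# Methods

This note documents the models, numerical choices and limitations of the
package. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from external data.

## Data model

A spectrum is a vector of diffuse-reflectance fractions on a uniform
wavelength grid, by default 450–760 nm at 1 nm (311 bands). Sets of spectra
share one grid and optionally carry per-sample labels: wet-basis moisture
content in percent (`100·(m₁ − m₂)/m₁` from fresh and oven-dry masses),
browning grade 1–4, and a continuous whiteness value. Train/test splitting
is a seeded random 4:1 partition with the test size `round(n/5)` (giving
160/40 at n = 200 and 128/32 at n = 160).

R² is the coefficient of determination `1 − SS_res/SS_tot`, not squared
Pearson correlation; the two differ for biased predictions, and the
determination form is the one that matches the RMSE-based ranking.

## Synthetic population

The generator emulates the structure the analysis assumes:

```
clean_i(λ)    = base(λ) · (1 − d_grade · brown(λ)) − Σ_k c_k(m_i) g_k(λ)
observed_i(λ) = a_i + b_i · (clean_i(λ) + nuisance_i(λ)) + ε_i(λ)
```

* `base` — a nearly flat, high (≈0.78–0.82) cap-reflectance curve.
* `brown` — a logistic dip toward short wavelengths (browning removes blue
  reflectance, making caps yellower). The per-grade depths `d_grade`
  (≈0.051/0.290/0.366/0.441 for grades 1–4) were calibrated once by root
  finding so the clean whiteness of a median-moisture spectrum of each
  grade sits at the center of that grade's calibrated whiteness range; the
  calibration routine ships in `synthetic.calibrate_grade_depths` and a
  test checks the frozen constants reproduce it.
* `g_k` — six Gaussian absorption bumps (σ 7–8 nm) at 475, 490, 650, 690,
  730 and 740 nm whose depths are affine in moisture (optionally mildly
  quadratic). On clean spectra, moisture is therefore an exact affine
  function of the six bump-band reflectances — the regression stages have
  a signal that is recoverable in principle.
* scatter — `b_i ~ LogNormal(0, 0.06)`, `a_i ~ Normal(0, 0.025)`: the
  multiplicative/additive effects MSC is designed to remove.
* `nuisance_i` — eight smooth Gaussian absorbers (σ 12 nm, centers kept
  away from the informative bumps) with iid per-sample coefficients
  (sd 0.02), representing pigment/texture/stray-light variation
  uncorrelated with moisture. This term is what limits full-spectrum
  models: with only iid band noise, a 311-band model can average the noise
  away and always beats a six-band model, which is the opposite of how
  band selection behaves on real reflectance data. Setting
  `nuisance_sd = 0` recovers the plain scatter+noise model used by the
  exactness tests.
* `ε` — iid Gaussian band noise, sd 0.003.

Default amplitudes were chosen once so that the full-spectrum BP model
lands near test-R² ≈ 0.8 at n = 200 — the regime in which the
band-selection comparison is meaningful — and were not tuned further.

What the generator does **not** emulate: radiative transfer or tissue
optics, wavelength-axis misregistration between instruments, detector
nonlinearity, temperature drift, or any real covariance between moisture
and browning. Passing tests therefore demonstrate correctness of the
algorithms and the claimed orderings under these assumptions, not
instrument-grade performance on real mushrooms.

## Calibration

Offset-only: `P̄` is the per-band mean of `reference − device` over paired
samples and is added to device spectra. The printed-literature sign variant
(`paper_literal`, ΔP = device − reference with P′ = device + P̄) is provided
for fidelity but moves device spectra away from the reference; the default
convention is the one under which fit∘apply converges to the reference
(exactly, for jitter-free pairs). With measurement jitter the offset error
shrinks as 1/√n_pairs. No gain term and no wavelength registration are
attempted.

## Preprocessing

* **Savitzky–Golay** — window 7, order 2 by default (a gentle smoother at
  1 nm sampling); edge bands evaluate the terminal window's fitted
  polynomial, preserving length.
* **Normalization** — per-spectrum min–max to [0, 1]; unit-vector scaling
  available behind a flag.
* **SNV** — population (1/N) standard deviation, stated so tests are exact.
* **MSC** — per-spectrum OLS fit against a reference spectrum, then
  inversion `(s − a)/b`. The reference is the mean of the fitting
  (training) set and is frozen in an `MscModel` for reuse on test spectra;
  re-estimating it on test data would leak information.

## Wavelength reduction

**SPA.** From each possible starting band a chain is grown by repeatedly
projecting the remaining band-columns onto the orthogonal complement of
the selected set (centered data) and taking the largest residual norm,
with exact ties broken toward the lower band index. Every chain prefix is
scored by 5-fold cross-validated RMSE of an intercepted MLR against the
response; the globally best (start, size) wins, with the first minimum
taken on ties. A brute-force projection recursion (explicit least-squares
residuals) serves as the oracle in tests. Duplicated columns have zero
residual norm after their twin is selected and can never enter a chain
twice.

**PCA.** Mean-centered, unscaled (chemometric convention for reflectance);
components retained up to 95% cumulative explained variance by default.
Note that with strong nuisance variance the leading components need not
contain the moisture signal — the PCA-BP rows of the comparison table show
exactly this failure mode, which is a property of variance-ranked
compression, not a bug.

## Regression models

**PLS1.** Standard deflation: weight = covariance direction of the
residual blocks, score deflation of X and y, collapsed coefficients
`B = W(PᵀW)⁻¹c`. The implementation is authored here because generic
two-block NIPALS codes lose precision at full rank; this one agrees with
OLS to machine precision on orthonormal designs, and the sequential
factor path and collapsed coefficients agree to < 1e-8. Factor count by
minimum 5-fold CV RMSE.

**BP network.** One tanh hidden layer (5–10 units; 8 default), linear
output. Inputs are min–max scaled to [−1, 1] per feature, the target is
standardized. Training is damped Gauss–Newton (Levenberg–Marquardt) on the
full residual Jacobian; when parameters outnumber samples the normal
equations are solved in sample space via the push-through identity, so
full-spectrum networks stay cheap. Stopping: target MSE 0.001 (standardized
scale), 100-epoch budget (1000 for the SSA-refined final fit), damping
overflow, or early stopping — a held-out 20% slice of the fitting data is
monitored and training returns the best-validation weights after 6
consecutive non-improvements, the standard toolbox behavior without which
these small LM-trained networks interpolate their training data. Hidden
size can be scanned over 5–10 with selection by held-out R² (smallest size
wins ties).

**SSA.** Canonical producer/scrounger/scout population rules (population
10, 20 iterations, 70% producers, 20% scouts, safety threshold 0.6),
positions clipped to box bounds, best-so-far tracking makes the fitness
history monotone. The optimizer's known contraction toward the origin is
acceptable here because network weights are sought in a symmetric box
around zero.

**SSA-BP.** SSA searches the flattened initial weight/bias vector in
[−1, 1]; the fitness of a candidate is the validation MSE (inner seeded
4:1 split of the training data) after a 100-epoch LM refinement — the same
budget a plain training run gets. The plain seeded initialization is
member 0 of the initial population, and the final model is chosen
elitistically between the SSA winner and the plain initialization (both
trained with the 1000-epoch budget) by inner-validation MSE, so the
optimizer can refine but never degrade the baseline on its own objective.
With `n_iter = 0` the procedure reduces exactly to plain training.

## Whiteness

Tristimulus values follow the equal-interval summation over 450–760 nm
with the standard normalization `K = 100/Σ R(λ)ȳ₁₀(λ)Δλ`, so a perfect
reflector has Y₁₀ = 100 and real samples vary — the alternative of folding
the sample reflectance into K (available as `paper_literal_k`) forces
Y₁₀ ≡ 100 for every sample and is kept only for comparison. The sums use
composite-trapezoid endpoint weights: the color-matching functions are
sharply truncated at the 450 nm range edge, where a plain rectangle sum
over-weights the endpoint by several tenths of a percent of Z₁₀.

The CIE 1964 10° color-matching functions are generated from published
single/multi-lobe lognormal analytic fits (accurate to roughly 1–2% of
peak) and the illuminant is a 6504 K Planckian daylight stand-in
normalized to 100 at 560 nm — synthetic approximations of the official
tables, adequate because every whiteness quantity in the package
(white point, generator calibration, regression targets, grade medians)
is computed self-consistently against the same tables. Anyone replacing
them with the official CIE tabulations should re-run
`synthetic.calibrate_grade_depths` and refreeze the browning depths.

Ganz whiteness is the unclamped affine index with the 800/1700
coefficients; the default whiteboard chromaticity is the white point of
the configured illuminant/observer pair. Grading uses fixed thresholds
55.375 / 34.445 / 23.945 — midpoints between the calibrated whiteness
ranges of adjacent grades (the grade-2 and grade-3 ranges overlap
slightly; the midpoint of the overlap is the threshold there). Values in
the gaps between ranges are graded but flagged `gap region`; values beyond
the calibrated extremes are graded to the nearest level and flagged
`out of calibration`.

## Pipelines and reproducibility

`run_moisture` wires the stages together: seeded 4:1 split, MSC reference
frozen on the training split, SPA/PCA fitted on training data only, then
every configured model. `run_whiteness` computes per-sample whiteness,
per-grade min/median/max, a Kruskal–Wallis rank test across grades (chosen
over ANOVA because four small grade groups need no normality assumption;
the test is skipped with a notice when fewer than two grades are present)
and an optional BP whiteness regression. Replicate scans sharing a
`sample_id` can be averaged by `average_replicates` before analysis.

Every run emits a manifest (config hash, seed, package version). All
randomness flows through explicit integer seeds into
`numpy.random.default_rng`; per-stage seeds are derived with a stable CRC
of the stage name, so repeated runs are bit-identical across processes.

Problem sizes used by the shipped studies: 200 samples for the moisture
comparison, 4 × 40 for whiteness grading, 10 paired seeds for the
model-ordering checks — small enough to run in seconds while leaving the
claimed orderings clearly resolved.

## Known limitations

* The spectral model is phenomenological; coefficients have no literature
  provenance, so absolute RMSEs are not comparable to instrument studies.
* SPA's all-starts scan is O(bands² · max_size) and becomes slow beyond a
  few hundred bands; a fixed starting band is available.
* The BP trainer is exact Gauss–Newton and is not suited to networks with
  more than a few thousand parameters.
* The approximate CIE tables shift absolute tristimulus values by up to a
  few percent relative to the official tabulations; rankings, grades and
  all self-consistent comparisons are unaffected.
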