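# Methods

## The statistics

**PLV and Rayleigh significance.** The phase locking value is the mean
resultant length of the per-trial phase-difference unit vectors. Its
large-sample significance uses the conventional Rayleigh approximation
p ≈ exp(−n·PLV²), valid for n ≳ 50 draws. A published variant prints this
approximation as exp(−PLV); that form is dimensionally inconsistent with a
sample-size-dependent tail (it never drops below e⁻¹ ≈ 0.368) and is kept
only behind `rayleigh_pvalue(..., formula="as_printed")` for comparability.
The default is the n-dependent form.

**USTPL.** Two angle populations are pooled and ranked from 0 in the
positive direction; rank r maps to the uniform score β = 2πr/n (rank 1 maps
to 2π/n, not 0 — the statistic is rotation invariant, so this anchoring is
cosmetic but fixed for reproducibility). The squared resultant R² of one
population's scores is normalized as R\* = 2(n−1)R²/(n₁n₂). We read the
normalization's "R" as the *squared* resultant: only that reading has the
asymptotic χ²(2) null (its exact null mean is 2 for every n₁, n₂ — a
two-line combinatorial identity: E[cos(βᵢ−βⱼ)] = −1/(n−1) over distinct
equally spaced scores). The square-root reading is available as
`ust_statistic(..., root_normalization=True)` but has no χ² limit and is not
used for inference. Significance modes:

- *asymptotic* — upper tail of χ²(2) at R\*; selected by `mode="auto"` when
  n > 40 (the stated validity bound of the approximation);
- *exact* — full enumeration of the choose(n, n₁) label assignments whenever
  that count is ≤ `exact_cap` (default 10⁵); the p-value is the exact
  fraction of assignments with R\* at least the observed one (the identity
  assignment is included, so p > 0 without any add-one adjustment);
- *permutation* — Monte-Carlo relabeling with the add-one estimator
  (1 + #{null ≥ observed}) / (1 + n_perm), never zero, 1000 permutations by
  default.

Exactly tied angles (possible with quantized phases) are ordered by a seeded
random shuffle. A deterministic mid-rank convention would perturb the equal
spacing of the scores, which the null distribution assumes; random
tie-breaking preserves spacing at the cost of a seed dependence that is
recorded in the result.

**PLI / WPLI.** PLI is the magnitude of the mean sign of sin θ. Trials with
sin θ exactly 0 contribute sign 0 and stay in the average (dropping them
would silently change n). PLI is deliberately not rotation invariant — its
whole point is asymmetry about the real axis, where instantaneous crosstalk
(phase 0 or π) lives. The signed mean is available via `pli(s, signed=True)`
and in the significance wrapper's metadata. WPLI weights each trial by the
magnitude of the imaginary cross-spectrum and reduces algebraically to
|⟨ℑX⟩|/⟨|ℑX|⟩; it is undefined (0/0) when every ℑX is exactly zero and
raises in that case. WPLI is implemented for completeness but excluded from
the default benchmark, which compares the unweighted PLI.

**PBI.** (PLV₁ − PLV_all)(PLV₂ − PLV_all), with PLV_all computed from the
two partial resultant vectors so that the index is bit-exactly symmetric in
its arguments. Permutation significance uses |PBI| as the permuted
statistic; for PLI the permuted statistic is |PLI₁ − PLI₂|. Both wrappers
default to 1000 permutations.

## Morlet phase extraction

One complex coefficient per (trial, channel) at a requested time and
frequency: the inner product of the per-trial demeaned signal with an
L2-normalized Gaussian-windowed complex exponential, truncated at ±4σ_t
(tail mass ~3·10⁻⁴). The envelope is parameterized by the number of cycles,
σ_t = cycles/(2πf), default 7 cycles at the 40-Hz analysis frequency. A
bandwidth stated in fractions of an octave does not invert uniquely to a
cycles count (it depends on whether it names the Gaussian σ or the FWHM in
log-frequency), so the cycles convention is used and recorded verbatim in
`bandwidth_spec`. Demodulation is referenced to absolute recording time, so
a stationary cos(2πft + φ) yields phase φ; the simulator's sine carriers
therefore read back as φ − π/2, a fixed quadrature offset that cancels in
every pairwise difference. Evaluation times closer than the truncated
half-support to an edge raise an error naming the minimum margin.
L2-normalization of the wavelet is cosmetic: only phases feed the
statistics, and amplitude-scaling invariance is asserted by test.

## The simulator

Each region of interest carries a unit-amplitude 40-Hz sinusoid per trial.
Locked trials share a fixed per-ROI phase (one uniform draw per simulation)
perturbed trial-by-trial by von Mises(0, κ) noise, κ ∈ {20, 50} being the
reference concentrations (default 50); unlocked trials redraw all phases
uniformly each trial. Defaults: 20 locked + 20 unlocked trials, 1 s at
1000 Hz, analysis at 0.5 s.

The anatomical route to source leakage (forward model, inverse operator) is
collapsed into one explicit mixing matrix M = I + sO: O has zero diagonal,
off-diagonal weights decaying exponentially with a random ROI spacing on a
unit interval (decay length 0.05, so leakage concentrates on nearest
neighbours the way inverse-solution blur mixes adjacent parcels), and each
row of sO sums to the crosstalk strength s < 1, keeping M strictly
diagonally dominant. What matters for testing the statistics is the leakage
phenomenon — instantaneous mixing inflating apparent phase locking between
independent sources — not the anatomical path to it.

Additive noise is Gaussian, white in time and colored across channels by an
equicorrelation-plus-jitter SPD covariance (mean off-diagonal correlation
0.3 by default, eigenvalues floored at 10⁻³). "Noise level" is the ratio of
mean per-channel noise RMS to mean per-channel signal RMS; the reference
conditions are 0.1% and 1%. Noise is regenerated independently per trial.
The full recording is reproducible from the config seed alone (stage seeds
for plan, mixing, and noise are derived from it).

## The benchmark harness

Per condition (noise level × trial count × κ), the harness runs
`n_replicate_sets × iterations_per_set` positive simulations (locked trials
plus an unlocked baseline) and as many negative simulations (unlocked trials
only, split in half into surrogate baseline/stimulus populations), all
through one fixed mixing matrix (the "anatomy" of the run). Each method
yields one detection statistic per ROI pair per simulation: −p for USTPL
and PLV (more significant = larger), the raw statistic magnitude for PLI
and |PBI|, which carry no analytic significance level. Statistics are pooled
within each replicate set into a per-method ROC (methods never pooled
together); the AUC, computed by trapezoid (equivalently Mann–Whitney with
ties counted ½), is reported as mean ± sd across the sets — the default is
5 sets of 4 iterations. The benchmark applies the asymptotic USTPL p-value
at all trial counts; at 20+20 trials this sits at the edge of the stated
n > 40 bound, but ROC ordering depends only on the p↔R\* monotonicity, and
the type-I calibration of the asymptotic tail is verified separately.

For USTPL and PLV the harness additionally reports classification
rates at α = 0.05, with and without Bonferroni correction
over the number of simultaneous ROI pairs. Both the proportion-correct
(TP+TN)/(P+N) and its complement are emitted under separate names
(`correct_rate_*`, `error_rate_*`), since "error rate" in the literature
sometimes names either quantity.

Desk-scale problem sizes: the package's reference benchmark runs use 2–6
ROIs, 20 trials per population, 600–1000 Hz sampling, and 20 iterations per
condition. The heavy-crosstalk comparison (strength 0.9 between a channel
pair, κ = 50, n = 20, noise 0.1%) is the regime in which the contaminated
baseline defeats the Rayleigh/PLV test while the rank test retains power;
at mild crosstalk both tests saturate and the comparison is uninformative,
so the strength is chosen to actually produce the confound under the
abstracted mixing model.

## What the synthetic data does and does not show

The generator reproduces the mechanisms the statistics must face — trialwise
phase concentration, instantaneous linear leakage, spatially correlated
additive noise — but not the anatomy behind them: no cortical geometry, no
distributed forward/inverse operators, no sign-flip ROI averaging, no
broadband or multi-frequency structure (all sources share one carrier), and
amplitudes are constant by construction (which is also why WPLI degenerates
to PLI here). Passing benchmarks therefore validate the statistics'
calibration and relative ordering under leakage, not absolute AUC values on
real recordings, which depend on subject-specific leakage geometry.

## Known limitations

- USTPL is omnibus: it detects that two phase-difference distributions
  differ, not which is more strongly locked or whether the lag changed.
- The χ²(2) tail is an approximation; below n = 40 the implementation
  upgrades to exact/permutation inference automatically, but user-forced
  asymptotic mode at very small n is anticonservative in the extreme tail.
- The permutation wrappers treat trials as exchangeable between populations;
  trial-order dependence (drift, adaptation) violates that assumption.
- ROC pooling across ROI pairs ignores their dependence through the shared
  mixing, as in the reference evaluation design.
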