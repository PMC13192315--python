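# Methods

## The measurement model

A single endolysosomal SERS acquisition samples the few-nanometer
neighborhood of a gold nanoprobe. The package treats each spectrum as

    y(x) = b(x) + Σ_k  o_k · a_k · L_k(x) + ε(x) + spikes,

where `x` is the wavenumber (cm⁻¹), `b` a smooth baseline, `L_k` a unit-height
Lorentzian at band position `c_k` with width `fwhm_k`, `o_k ∈ {0, 1}` a
per-spectrum occurrence indicator, `a_k` a positive amplitude and `ε` white
detector noise. The scientific signal is in the occurrence statistics: the
probability `P(o_k = 1)` depends on the experimental condition, and
correlated occurrence of two bands across spectra indicates that the two
molecular species visit the probe's near field together (colocalization).

## Synthetic data generator

`sers_cooccur.synthetic` draws from exactly this model.

* **Occurrence.** Per condition, indicators are generated from a Gaussian
  copula: latent standard normals with correlation `rho` on designated band
  pairs (identity elsewhere) are thresholded at the normal quantile of each
  band's occurrence probability. Marginals are therefore exact while the
  pairwise dependence is tunable; a non-positive-definite pair matrix is a
  configuration error.
* **Amplitudes** are lognormal with mean `mean_amplitude` and coefficient
  of variation `amplitude_cv` (default 0.3; degenerate at the mean when 0).
* **Baseline** is a polynomial on the normalized axis coordinate, default
  `120 − 40u + 25u²` counts — a gently curved background of the magnitude
  typical for cell SERS at short integration times.
* **Noise** is Gaussian, default sd 1 count; default band heights are
  10–20 counts, i.e. 10–20× the noise, so band presence is unambiguous and
  test outcomes measure the statistics, not the detection limit.
* **Spikes** are Poisson-distributed per spectrum (default rate 0.05),
  single-channel, +200 counts: the artifact the spike-removal stage must
  defeat.
* **Default band table**: 24 bands at literature Raman positions of
  cellular spectra (phenylalanine 1006/1028, amide I/II/III, tryptophan,
  tyrosine, disulfide 465/503/553, adenine 725, nucleic-acid backbone 810,
  lipid CH₂/C–C modes, …) with two conditions (`control`,
  `saclac_10um`) whose occurrence probabilities differ by ≥ 0.3 for 14
  bands. The disulfide pair 465/503 carries a planted occurrence
  correlation of 0.8 — the structure the MAA analysis is meant to recover.
* The default axis is 400–1800 cm⁻¹ in 2 cm⁻¹ steps (p = 701).

What the generator does **not** emulate: band-shape changes and peak
shifts, amplitude correlation beyond shared occurrence, heteroscedastic or
correlated noise, multiplicative enhancement drift, and any physical
plasmonics. Passing tests therefore demonstrate that the chain recovers
planted occurrence structure under idealized band shapes, not that it is
robust to every distortion of real cell spectra.

## Preprocessing

Fixed order: spike removal → AsLS baseline → subtract + vector-normalize →
detectable-signal filter → crop to 400–1800 cm⁻¹ (closed interval).

* **Spike removal.** Modified z-score (0.6745·(d − median)/MAD) of the
  first differences; a channel is flagged on an upward step above
  `spike_z_threshold` (default 8) into it or a downward step below the
  negative threshold out of it, so an isolated positive spike is flagged
  without touching its neighbors. Flagged channels are replaced by the
  median of unflagged channels within ±5 channels; the operation is
  idempotent. The z-score is relative to the spectrum's own
  difference MAD, so a strictly noise-free spectrum with a sharp band can
  trigger false flags; detector noise at realistic levels sets the scale
  the detector needs.
* **AsLS baseline.** Minimizes `Σ w_i (y_i − z_i)² + λ Σ (Δ²z_i)²` with
  `w_i = p` above the baseline and `1 − p` below, iterated to a stable
  weight assignment (defaults λ = 1e5, p = 0.01, ≤ 10 iterations — the
  commonly recommended range for Raman backgrounds; both config-exposed).
  The pentadiagonal system is solved in banded Cholesky form; tests verify
  agreement with a dense solve of the same objective to 1e−6 and the
  ordinary-least-squares limit (λ → ∞, p = 0.5) to 1e−3.
  A known artifact worth remembering when reading selections: around a
  band that is present in only part of the spectra, the fitted baseline
  rises slightly, so band *flank* channels acquire occurrence-correlated
  dips and can be picked up as informative.
* **Detectable-signal filter.** A spectrum is kept when its maximum
  corrected intensity exceeds `signal_snr_min` (default 5) times the noise
  sd, robustly estimated as `1.4826·median|Δy|/√2`; the rule is
  scale-invariant, hence valid after normalization. At 701 channels the
  false-keep rate for pure noise is ≈ 4·10⁻⁴ and spectra carrying any
  default band at ≥ 10× noise pass with ≥ 99% probability. Reference
  (signal-free) spectra are preprocessed identically *minus* this filter,
  which would reject them by construction.

## Band occurrence

Windows are closed intervals of ±10 cm⁻¹ around centers 400, 405, …,
1800 cm⁻¹ (281 centers); integrals are trapezoidal on the physical axis
(exact for linear segments, spacing-aware); edge windows use their covered
part. A band is detected when the integral strictly exceeds the reference
mean plus `k_sigma` (default 3) reference standard deviations at that
center; the per-center detection fraction over a condition's spectra is
its relative occurrence histogram. Strict inequality makes the
all-reference case unambiguous, and raising `k_sigma` can only lower
counts.

## Forest, SMD and MAA

Trees are grown with scikit-learn (Gini impurity, bootstrap with
replacement, `mtry = ⌊p^{3/4}⌋` random candidates per split, nodes below
`min_node_size = 5` become leaves); `num_trees` defaults to 1000 at desk
scale (the study-scale setting is 10000). Predictions are majority votes;
accuracy is reported on the held-out stratified 20% and, since the
convention is ambiguous, out-of-bag accuracy is available as well.

The surrogate layer is computed on the in-bag samples of each node: for
every other variable the best mimicking cut (orientation flips allowed,
CART convention) is found by scanning the sorted values with cumulative
counts; quality is the adjusted agreement `A = (a − m)/(1 − m)` with
`m = max(left fraction, right fraction)`; the top `s = ⌊0.10·p⌋` with
`A > 0` are stored. For an independent candidate at a balanced node the
best-cut agreement behaves like the supremum of an absolute Brownian
bridge, so the null mean is ≈ `2·√(π/2)·ln2/√m` (0.12 at m = 200) — small
but not negligible, which is why relation maps are read relative to their
own background, not in absolute units.

**SMD.** Per tree, a variable's depth is the minimal depth where it is
primary or stored surrogate; absent variables contribute the tree's
deepest node depth + 1 (penalty convention, config-visible through the
tree records). The mean over trees is the SMD importance; lower is more
important.

**Selection threshold.** Thresholding needs care because neighboring
spectral channels are strongly correlated: under label permutation the
across-variable SMD spread is structural (band neighborhoods recur as
surrogates) and does not shrink with more trees, so any per-variable tail
quantile of a matched null selects roughly that tail fraction — measured
2–3 false selections per run at p = 176. The default is therefore
familywise-conservative: the threshold is the *minimum* of the pooled SMD
values from `n_null = 8` forests fitted on label-permuted copies, each
with `num_trees/8` (≥ 25) trees. Fewer trees widen the null's lower tail,
pushing the threshold further down, while the analysis forest's SMD values
concentrate; in 20-repetition simulations the selection on permuted data
is empty in 20/20 runs, and truly separating variables (whose SMD sits
near 0–1, far below the threshold of ≈ 1.2–1.4) are still selected. The
percentile and null tree count are config-exposed.

**Representatives and MAA.** Selected variables within 2 channels of each
other (≈ 4 cm⁻¹ at native spacing) form one signal; the lowest-SMD member
represents it (ties toward lower wavenumber). MAA(i, j) is the mean stored
adjusted agreement of j over all nodes with primary split i (zero when j
is unstored, 1 for i = j by convention, 0 if i is never primary); it is
computed on the same 80% training forest as the classification. Because
only the top `s` surrogates are stored, MAA is a slightly truncated
estimate — another reason to read maps relatively.

## Numerical and design choices

* Calibration is an affine map (gain + offset) fitted by least squares to
  matched peaks of the packaged toluene–acetonitrile standard; a fitted
  gain further than 10% from unity is rejected as implausible.
* PCA is mean-centered, signs fixed so each loading's largest-magnitude
  element is positive.
* Relation maps keep, per representative, partners above the row's 0.95
  quantile (display cutoff only; the CSV of the full matrix is also
  written). Row order defaults to descending wavenumber.
* All stochastic steps (generation, splitting, bootstrap, feature
  sampling, permutations) derive from explicit integer seeds; identical
  (config, seed) pairs give byte-identical CSV outputs.
* Degenerate inputs: constant spectra cannot be normalized and are
  rejected; constant candidate variables yield no surrogate; singleton
  classes cannot be stratified.

## Simulation scales

The repeated-simulation properties (null calibration of the threshold,
planted co-occurrence recovery) run on a coarsened axis (8 cm⁻¹ steps,
p = 176) with 100 spectra per condition and 150–300 trees; the
classification benchmark runs at the native axis (p = 701) with 400
spectra per condition and 1000 trees. These sizes were fixed once as
desk-scale study conditions; enlarging them sharpens, not changes, the
reported behavior.

## Known limitations

* The permutation-null threshold compares forests with different tree
  counts; if real-label trees are much shallower than permuted-label trees
  (very strong signal), the penalty scale shifts and selection becomes
  more liberal. Inspect the SMD histogram against the threshold when in
  doubt.
* AsLS flank artifacts (above) can promote band-flank channels into the
  selected set; group representatives mitigate but do not remove this.
* The generator's independence assumptions mean MAA findings on real data
  should be treated as colocalization *candidates*, not proof.
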