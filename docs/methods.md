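# Methods

## Scope and model

midquant quantifies mass isotopomer distributions (MIDs) of *targeted*
ions from stable-isotope labeling experiments. The core model is linear:
a molecule whose tracer-derived label distribution is the simplex vector
`x` over label states 0..n is observed, after convolution with natural
isotopic background, as channel fractions `M·x`. All quantification
reduces to (i) measuring the observed channel fractions accurately and
(ii) constructing and inverting `M` correctly for the instrument mode.

## Peak finding and integration

**Composite trace.** All quantified isotopologue EICs of one target are
summed pointwise into a composite; the peak is located and bounded on the
composite (after Savitzky–Golay smoothing), and the resulting bounds are
stored once per isotopic cluster and applied to every channel. This is
the central design commitment: with shared bounds, two channels with the
same elution profile integrate to areas in exactly their intensity ratio,
regardless of how poorly a weak channel's own peak would bound. The
channel EICs share one RT grid by construction (same scans); mixing scan
populations (e.g. MS1 with MS2 channels) in one cluster is a
method-validation error.

**Probabilistic matching.** Candidate apexes are local maxima of the
smoothed composite within `expected_rt ± rt_window` above
`baseline + k·noise`. Each is scored
`S = exp(−Δrt²/2σ²) · (h − b)/max(h − b)` with `σ = rt_window/2`; when
characteristic sibling ions are matched, candidates are further weighted
by proximity to the nearest characteristic apex, and characteristic-ion
apexes anchor a piecewise-linear RT warp (expected → observed, constant
offset beyond the outermost anchors). The Gaussian-kernel-times-height
form is this package's declared interpretation of "probabilistic"
matching; it is scale-invariant in intensity and reduces to
nearest-in-RT for equal heights.

**Noise.** `1.4826 · median|Δy| / √2` over successive differences of the
raw composite — the MAD-to-σ rescaling with the differencing variance
removed. Successive differences need no peak-free region and are nearly
blind to smooth peaks; the estimator is within 5% of truth for Gaussian
noise at n = 10⁴ (tested) and reads ≪1% of apex on noiseless peaks.

**Baseline.** A straight line between the minimum smoothed intensity in
the leading and trailing 10% of the window, clamped at zero. This
deliberately models only constant + linear drift; curved baselines are a
known limitation.

**Bounds.** Walk outward from the apex until the smoothed intensity
drops below `baseline + k·noise` (default k = 3), a local minimum below
5% of apex height is hit (shoulder guard), or the window ends. If the
longer apex-to-edge width exceeds `asymmetry_cap` (default 2.0) times
the shorter, the longer side is clipped to exactly the cap — clipping,
not near-edge extension, so integration never reaches beyond detected
signal. Cap arithmetic is in scan-index units on the (uniform) grid.
Bounds are monotone in k: a higher threshold never widens them.

**Integration.** Raw (unsmoothed) intensities are summed between the
bounds after subtracting the channel's own straight line between its two
edge intensities, clamped at zero. Smoothing is used only to *locate*
peaks. Edge-to-edge subtraction scales with the channel, so it preserves
between-channel ratios exactly for congruent shapes; this was chosen
over a composite-derived baseline for that reason. Records whose total
area falls below `10 · noise · width` are flagged `low_signal`.

## Natural-abundance correction

Column `j` of the correction matrix is the natural isotopologue
distribution of the "correction formula" shifted by `j` nominal tracer
shifts (+1 for ²H/¹³C/¹⁵N, +2 for ¹⁸O/³⁴S):

- `low_res_ms1`: the full ion formula minus the `j` labeled atoms —
  at unit resolution every element's heavy isotopes share the tracer's
  nominal channels.
- `high_res_ms1`: only the tracer element's remaining atoms — the mass
  defect of other elements' isotopes (e.g. ¹⁵N at +0.99704 vs ¹³C at
  +1.00336 Da) is resolved away from the tracer channels. Resolution is
  modeled as a binary resolved/unresolved choice, not a numeric
  resolving-power curve.
- `tandem`: the product-ion formula only; neutral-loss atoms never reach
  the detector.
- dual tracers, high resolution: the Kronecker product of the two
  single-tracer matrices over row-major (tracer1, tracer2) channel pairs.
  A tracer declared with zero labelable positions contributes a trivial
  identity factor — it is not a tracer, and its element's background is
  resolved away like any non-tracer element — so the dual construction
  reduces exactly to the single-tracer matrix. At unit resolution,
  distinct label pairs with equal combined nominal shift are isobaric and
  rejected unless the method declares summed channels.

Natural distributions are computed by per-element polynomial convolution
(binary exponentiation of the single-atom isotope polynomial), truncated
at the tracked channels with the cut-off tail mass reported. Abundances
are IUPAC representative values (¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364,
¹⁷O 0.00038, ¹⁸O 0.00205, ³³S 0.0075, ³⁴S 0.0421, ³⁶S 0.0001),
overridable per method via an `isotopes` section. Rows beyond the
tracked channels are dropped, so column sums may be < 1; this is correct
(mass escaping to untracked channels is simply unobserved) and tested.

Inversion is non-negative least squares followed by renormalization to
the simplex — negative label fractions are unphysical, and for square
well-conditioned systems with an interior solution NNLS coincides with
direct inversion. Matrices with condition number above 1e12 raise and
the record is flagged `correction_failed`. Tracer impurity (the labeled
substrate not being 100% enriched) is not modeled.

## Average percent enrichment

`APE = 100 · Σᵢ i·Mᵢ / n` over label counts 0..n; for dual tracers,
computed per tracer by marginalizing the 2-D MID over the other axis.

## Reporting

Group summaries are arithmetic mean and sample SD (ddof = 1) of corrected
MIDs and APEs per (target, group, time point). Group comparisons use
Welch's two-sample t-test per channel and per APE with Benjamini–Hochberg
adjustment across the channels of a target — a pluggable default chosen
for robustness to unequal variances, not a claim of optimality. Unlabeled
controls are scored by the RMSE of their *raw* MID against the
mode-appropriate theoretical distribution (the zero-label matrix column,
renormalized to the tracked channels); the uncorrected MID is compared
because correction would trivially zero the residual.

## Synthetic data

The generator emulates: Gaussian or exponentially-modified-Gaussian
(τ > 0) elution at known RT/width/apex, per-channel amplitudes equal to
apex × observable fraction with the observable fractions produced by the
*same* correction matrices the corrector inverts, constant + linear
baseline drift, and noise `I → I·(1 + N(0, σ_mult)) + N(0, σ_add)`
clamped at zero. Runs are written as real mzML (or mzXML/netCDF) files
with a CSV ground-truth sidecar, deterministic per seed.

It does **not** emulate electrospray ionization physics, detector
saturation, isotopic fine structure within a nominal channel, co-eluting
interferences, or retention-time drift within a run. Passing tests on
synthetic data therefore demonstrate the correctness of the algorithms
under the stated noise model, not instrument-specific performance.

Default study conditions used throughout tests and the acceptance script:
glutamine [M+H]⁺ (C₅H₁₁N₂O₃, base m/z 147.07642), apex 10⁶ counts,
σ = 4 s on a 0.5 s scan grid over 0–120 s, 10 ppm tolerance, and for the
benchmark standards the five label states unlabeled, [1-¹³C],
[1,2-¹³C₂], [¹⁵N₂] and [U-¹³C₅] on the dual-tracer (¹³C₅ × ¹⁵N₂,
18-channel) method. Noisy studies use σ_mult = 2% and σ_add = 1% of
apex over 100 replicates. These sizes keep any single study under a few
seconds while leaving Monte-Carlo standard errors well below the effects
being measured.

## Numerical notes and known limitations

- Clamping noisy intensities at zero biases near-zero channels slightly
  upward; in the 100-replicate noise study the resulting raw-MID bias is
  ≈0.5 Monte-Carlo SD (≲0.01 absolute) on the strongest channel. It
  vanishes as noise → 0 and is inherent to non-negative intensity data.
- Savitzky–Golay edges use polynomial fits on the truncated window
  (scipy `mode="interp"`); signals shorter than the window are returned
  unsmoothed with a warning.
- EMG apex placement: the generator shifts the analytic EMG so its mode
  sits at the requested apex RT and normalizes the mode to the requested
  apex intensity.
- mzML/mzXML parsing covers the encodings in practical use (base64,
  zlib or none, 32/64-bit floats, both byte orders, CV-param RT units,
  ISO-8601 durations); SRM/MRM chromatogram objects, ion mobility and
  vendor-proprietary formats are out of scope. Non-ANDI netCDF layouts
  are rejected, never guessed.
- Untargeted peak discovery and deconvolution of overlapping compounds
  beyond the shoulder guard are out of scope; absolute concentration
  calibration and flux estimation are downstream of this package.
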