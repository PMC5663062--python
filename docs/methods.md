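# Methods

## The measurement model

A raw SERS trace of a corolla extract is modelled as

    y(ν) = b(ν) + Σᵢ Iᵢ · A · g(ν − νᵢ; Γ) + ε(ν),   ν ∈ [400, 1800] cm⁻¹

on a uniform 1 cm⁻¹ grid (1401 points): a smooth fluorescence background
`b`, sharp Raman bands at positions νᵢ with relative intensities Iᵢ ∈ (0, 1]
scaled by a base amplitude `A`, and additive noise ε. The background is a
fifth-order polynomial in the wavenumber axis rescaled to [−1, 1] (the
rescaling conditions the least-squares fits); the default lineshape `g` is a
unit-apex Gaussian of FWHM Γ = 12 cm⁻¹, well under the 100 cm⁻¹ width filter
and fully resolved on the 1 cm⁻¹ grid. A Lorentzian is available; real SERS
bands lie between the two, and nothing downstream depends on the choice
beyond the wings' overlap.

## Baseline removal

`correct_baseline` implements the iterative modified-polynomial scheme: fit
a degree-5 polynomial by least squares, build a working signal in which
every point above the clipping level is replaced by it, refit, and stop when
the relative RMS change of the fitted curve drops below 1e-4 (or after 100
iterations, in which case the result is returned with `converged=False` and
a warning — never an exception).

The clipping level is `fit + margin`. With `margin = 0` (plain peak
clipping) two biases appear on noisy spectra: the fit creeps toward the
noise *minima*, because each pass shaves the upper half of the noise band,
and contiguous peak wings pinned at the fit drag it locally below the true
background, leaving ripple of up to ~5% of the strongest peak near band
clusters — enough to distort weak-band intensities and spawn shoulder
artifacts. The default (`noise_margin=None`) therefore re-estimates the
margin each iteration as the standard deviation of (working − fit), the
standard cure: the fit then settles in the middle of the noise band, the
iteration converges in ~12 passes on typical synthetic spectra, and
residual ripple drops an order of magnitude. `noise_margin=0` keeps the
plain scheme available; a positive value fixes the margin by hand.

Corrected values are *not* clipped at zero: peak heights are measured
relative to zero, and clipping residual noise would bias them upward.

Floating-point note: the corrected spectrum is `input − fit` and the stored
baseline is `input − corrected`, so the reconstruction identity
`input − corrected == baseline` holds bit-for-bit; the additive form
`corrected + baseline == input` holds to one ulp (exact bitwise additivity
is unattainable in fixed precision where |corrected| ≫ |input|, e.g. at
near-zero signal points).

## Peak extraction

Replicates (default 6 per sample, matching parallel measurements from
different spots) are baseline-corrected individually and averaged pointwise
into the mean spectrum, cutting the noise floor √6-fold. Characteristic
peaks are local maxima of the (optionally smoothed) mean spectrum with

* apex height above `min_height` (default 400 a.u.) — height is the apex of
  the *unsmoothed* corrected spectrum above zero, not prominence relative
  to neighbouring valleys, because the corrected baseline sits at ≈ 0;
* FWHM below `max_width` (default 100 cm⁻¹), measured by linear
  interpolation of the two half-height crossings;
* apexes closer than `min_separation` (default 5 cm⁻¹) merged keeping the
  higher, suppressing noise-split maxima.

Positions are snapped to the grid (integer cm⁻¹ at default resolution).
Detected heights are max-normalized into the pattern; exactly one peak
reads 1 (ties all read 1).

### Scale-matched detection profile

The 400 a.u. height floor is an instrument-scale convention: the weakest
relative intensity in the reference library is 0.0422, so the floor
presumes strongest-peak heights of roughly 10 000 a.u. For spectra whose
strongest peak is known to reach `A` (synthetic sets in particular),
`scaled_detection_config(A)` sets the floor to `A/40` — below the weakest
library band (0.0422·A) yet an order of magnitude above both the averaged
noise floor (20/√6 ≈ 8 a.u. at the default noise) and baseline-residual
ripple — with a merge radius of one FWHM (ripple shoulders appear within a
linewidth of a true apex, while genuinely distinct library bands are never
closer than 16 cm⁻¹) and a 5-point moving average that stabilizes apex
positions of the weakest bands (a ~190 a.u. Gaussian apex drops only ~4
a.u. one grid point away, below the 8 a.u. noise). This profile is what the
round-trip experiments and the acceptance script use at A = 4000.

## The synthetic generator

`generate_replicate_set` emulates what the instrument would have produced
for a known pattern: the analytic peak sum scaled per replicate by
`(1 + jitter)` with jitter ~ N(0, 0.05) — spot-to-spot focusing differences
act mainly on overall signal level and cancel under max-normalization —
plus the polynomial background (clipped at 0) and i.i.d. Gaussian noise of
SD 20 a.u. Randomness comes from a generator seeded by
`(seed, replicate_index)`, so sets are bit-reproducible and replicates are
independent. Defaults: A = 4000 a.u., Γ = 12 cm⁻¹, 6 replicates.

What it deliberately does not model: SERS enhancement physics and its
concentration dependence, Poisson photon statistics, cosmic-ray spikes,
wavenumber calibration drift, and band-shape asymmetry. Passing round-trip
tests therefore show the *processing chain* is faithful (background removal
does not distort patterns; detection recovers what the model put in); they
do not certify performance on real instrument data, where calibration drift
and non-polynomial backgrounds add error sources.

## Matching and assignment

Identification scores a query pattern against each library pattern by
pairing peaks greedily, one-to-one, in order of increasing position
difference, admitting pairs within 4 cm⁻¹, and computing
`Σ_pairs qᵢ rᵢ / (‖q‖‖r‖)` with the norms over *all* peaks — a cosine in
which unmatched peaks dilute but never contribute. Self-match is exactly 1;
the score is symmetric; raising the tolerance can only add pairs and so
never lowers it. Ranking is by score, then by smaller summed position
deviation (which separates the single-peak cultivars at 732 vs 733 cm⁻¹),
then by name. The 4 cm⁻¹ window covers the position scatter observed within
one chemical band across cultivars (e.g. 731–734, 1017–1023) without
bridging distinct bands.

Compound assignment checks each peak against a reference-band table: point
references match within the table's tolerance (default 3 cm⁻¹ — the window
that attributes the 1017–1023 cm⁻¹ peaks of seven further cultivars to the
1020 cm⁻¹ crocetin band, while at tolerance 0 only the exact 1020 cm⁻¹ peak
matches), interval references by containment with deviation 0. Entries
quoted at an identical reference (1,8-cineol and sabinene, both 652 cm⁻¹)
are all returned, flagged ambiguous.

## Band clustering and the pattern map

`find_common_bands` pools all peak positions across cultivars, sorts them,
and starts a new cluster wherever consecutive positions differ by more than
`gap_threshold` (default 8 cm⁻¹ — small enough to keep the isolated 624
cm⁻¹ band of Golden Queen out of the 647–657 run, large enough not to
fragment contiguous bands). Support counts distinct cultivars per cluster;
the 731–734 cm⁻¹ cluster has support 26. The pattern map draws one row per
cultivar (library order) on the 400–1800 cm⁻¹ axis, each peak a colored
block whose hue sweeps linearly from violet (270°, intensity → 0) to red
(0°, intensity 1) at full saturation and value — a single monotone,
bit-testable parameter.

## Library records and fixtures

The bundled reference library stores each cultivar's peak positions
(integers, cm⁻¹) and normalized intensities exactly as published, with no
re-normalization on load (validation only); one intensity (White Jade at
1022 cm⁻¹, 0.0422) is recorded at four decimal places in the source and
kept verbatim. Absolute heights and widths are not part of the published
records, so those fields are optional and populated only for patterns this
pipeline extracts itself. Library files are versioned JSON
(`{schema_version, name, created, notes, patterns: [{cultivar, peaks:
[{position, normalized_intensity, height?, width?}]}]}`) with a flat CSV
export; spectra are two-column text with `#` metadata headers, linearly
interpolated onto the default grid on read when the native axis differs.

## Problem sizes and determinism

Round-trip experiments process 26 cultivars × 6 replicates × 1401 points;
the baseline iteration converges in ~12 passes per replicate, so a full
rebuild (synthesis → correction → extraction → identification for all 26)
completes in seconds. All stochastic steps flow from a single integer seed.

## Known limitations

* Sub-grid peak positions (parabolic apex interpolation) are not computed;
  positions are quoted at grid resolution, as the reference records are.
* Overlapping bands are not deconvolved; a shoulder within one merge radius
  of a stronger apex is absorbed into it.
* The width filter measures FWHM relative to zero; on strongly curved
  residual backgrounds a band's apparent width can exceed its true FWHM.
* The identification score has no calibrated probability interpretation; it
  ranks candidates but does not test whether the query belongs to the
  library at all.
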