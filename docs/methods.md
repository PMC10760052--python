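# Methods

This note documents the models, algorithms, defaults and known
limitations of `smassay`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Generative models (the simulators)

### Photobleaching traces (`simulate_traces`)

Each complex carries `copies_n` fluorophore sites. Site visibility is
Bernoulli(`p_mature`), a single probability that absorbs chromophore
maturation, antibody/Fab occupancy and photoactivity — these are not
separable from step-count data, so the simulator does not separate them.
Visible fluorophores bleach at independent Exponential(`bleach_rate`)
times; the trace value at frame `t` is
`unit_intensity × (fluorophores alive at the frame start) +
background_level`, plus Poisson shot noise (optional) and Gaussian read
noise. Complexes with zero visible fluorophores are flagged
undetectable: a dark complex yields no spot, which is exactly why all
downstream stoichiometry fits condition on `k ≥ 1`.

Defaults: `copies_n = 2`, `p_mature = 0.8` (the dimer benchmark),
`bleach_rate = 1/30 s⁻¹` so the mean bleach time is one quarter of the
default two-minute movie (`n_frames = 1200` at `frame_interval_s =
0.1`); most bleaching completes in-movie without making dwells too short
to resolve. Intensities are in photons (unit 400/frame/fluorophore,
background 20/px/frame, read noise 2), giving extracted-trace step SNR
near 10.

Two simplifications matter for interpretation:

- Activity is sampled at frame starts, so steps are sharp; a real camera
  integrates within frames and produces partial-step transition frames.
- Blinking/dark-state kinetics are not simulated; the analysis likewise
  does not model them.

### Image fields (`simulate_field`, `simulate_two_channel`)

Spots are placed by rejection sampling with a minimum separation
(refusing configurations with `n·π·r²` above half the usable area, where
the sampler would thrash) and rendered as 2-D Gaussians
(`psf_sigma_px`, amplitude convention `A·exp(-r²/2σ²)`, so one spot
integrates to `2πσ²A`; window truncation at 4.5σ loses < 0.005%). Pixel
noise is Poisson(signal + background) plus Gaussian read noise — EMCCD
excess noise is ignored as unnecessary for SNR-controlled tests.
Coordinates are 0-based pixel indices; a spot at integer (x, y) is
centered on that pixel's center; truth is stored at sub-pixel precision.

Two-channel fields label each complex in channel A/B independently with
`p_label_A`/`p_label_B` — one number per channel standing in for
antibody binding, fluorophore labeling and complex dissociation, which
colocalization data cannot distinguish. Channel B positions add a
constant registration offset plus per-channel Gaussian localization
jitter (`jitter_px`, default 0.25 px); `independent_fraction` adds
unpaired free molecules per channel. `two_channel_truth_spotsets`
exposes the truth as spot lists directly, for matching-stage tests at
sizes where rendering would only re-add the jitter already modeled.

### Bead populations (`simulate_simoa`)

Molecules in the sample volume are captured and enzyme-labeled with
combined efficiency `capture_efficiency × detect_label_efficiency`
(binomial thinning), scattered uniformly over `n_beads` (multinomial, so
per-bead counts are Poisson in the large-number limit), and a
Binomial(`n_beads`, `bead_load_fraction`) subset — capped by the well
count — is analyzed. A loaded bead reads "on" iff it carries ≥ 1 enzyme;
enzyme kinetics, substrate turnover and well imaging are not simulated.
Defaults (25 µL sample, 500k beads, 5% loading ≈ 25k analyzed,
efficiencies 0.1 × 0.1) put a 3 pM top standard at AEB ≈ 0.9, inside the
digital range. The simulator has **no non-specific binding**: blanks are
truly dark, so simulated blank SDs and hence LODs are optimistic;
passing tests say nothing about real-world blanks.

## Analyses

### Spot detection (`detect_spots`)

Band-pass (difference of Gaussians, σ₁ = max(1, size/3), σ₂ = 2σ₁) →
3×3 local maxima → significance threshold → merge within
`approx_size_px` (brighter peak wins; exact ties to lower (y, x)) →
intensity-weighted centroid and background-subtracted sum over a
(2·size+1)² window. Spots whose window would be truncated by the border
are discarded; saturated peaks are flagged, not dropped.

The significance test is applied to the *filtered* response against a
robust SD (1.4826 × MAD) of the filtered image. Thresholding the raw
peak pixel instead would make the advertised SNR threshold meaningless:
at peak SNR 5 the raw peak fluctuates a full SD around 5, capping recall
near 50%, while the matched filter concentrates the spot and averages
the noise down. `Spot.snr` records the detection statistic, so the
invariant "every emitted spot has snr ≥ threshold" holds exactly.
Defaults `approx_size_px = 4`, `snr_threshold = 5` mirror the
particle-size/intensity-SD knobs of ComDet-class detectors.

### Colocalization (`match_spots`, `estimate_chance`)

Object-based, one-to-one, globally greedy: candidate pairs within
`max_distance_px` (default 4) are accepted nearest-first. Greedy
matching is deterministic and matches the behavior class of the standard
plugins; a Hungarian assignment serves as the oracle in tests (pair
counts agree to within a couple on sparse fields). Both directional
fractions are always reported — published colocalization numbers differ
depending on which channel is the reference, so neither direction is
privileged. A constant registration offset is estimated as the median
displacement of mutual nearest neighbors and applied when it exceeds
0.5 px. The chance control re-runs the matching after random cyclic
translations (≥ 10 px) of one channel and reports the mean matched
fraction; on a sparse field it approaches the spatial-Poisson rate
`1 - exp(-ρπr²)`. Pixel-intensity correlation metrics (Pearson/Manders)
are out of scope: the assay's colocalization is object-based.

### Step counting (`fit_steps`)

Recursive binary segmentation on the background-subtracted trace: the
split maximizing the RSS reduction is accepted iff the reduction exceeds
`penalty` × a local noise-variance estimate, recursing into both halves.
Plain binary segmentation leaves two artifacts — change points that were
optimal for a parent segment but are redundant once the true steps on
either side are found, and misaligned positions for closely spaced
steps — so each change is then refined within its final neighbors and
changes that no longer clear the penalty are pruned, iterating to a
fixed point.

Noise estimation is the delicate part. Under shot noise the bright
beginning of a trace is ~3× noisier than the post-bleach baseline, so a
single trace-wide SD (dominated by the quiet tail) badly understates
early-segment noise. The fit therefore runs twice: pass 1 uses a rolling
median of |first differences| (step-immune) floored by the trace-wide
robust SD; pass 2 re-estimates noise per pass-1 segment — within a
segment there are no steps, so a 20%-trimmed mean of squared differences
(de-biased for the trim) gives a much tighter estimate than the median —
builds a per-frame SD map (segments too short to estimate inherit their
noisier neighbor), and re-segments against it. On noiseless traces every
estimate is zero and the fit is exact.

`penalty = 30` by default: on flat noise traces the false-step rate is
well under the 5% design ceiling (measured ≈ 0 over hundreds of traces),
while a 5-SD step lasting two frames reduces the RSS by ~50 variance
units and is never missed. `min_dwell_frames` merges segments shorter
than the given dwell; the default 1 performs no merging, because the
penalty already suppresses single-frame outliers and merging discards
genuine fast double-bleach events — use ≥ 2 for camera-integrated data
with transition frames. Levels must be weakly decreasing; any increase
flags `upward-step`.

Trace classification: accepted traces have ≥ 1 step, no upward step, and
a final level within 2 residual SDs of zero (the complex must finish
bleaching); rejections are tallied by reason. These rules are standard
practice rather than a published recipe. Rejecting unresolved traces
slightly depletes multi-fluorophore complexes (a dimer has two chances
to outlive the movie), which is why measured two-step fractions sit a
point or two below the model's 2/3 at the default movie length.

### Stoichiometry (`fit_stoichiometry`)

For each candidate `n`, the multinomial log-likelihood of the step
histogram under the zero-truncated binomial is maximized over
`p ∈ (0, 1]` (bounded scalar optimization; `1-(1-p)^n` computed via
`expm1`/`log1p` to avoid cancellation at small p); `n` is selected by
BIC with a parsimony tie-break at numerical precision. The open top bin
(`k ≥ k_max`, default 4) contributes its full tail mass ("tail" mode) or
is renormalized away ("truncate"). Candidates smaller than the largest
populated closed bin are structurally infeasible. A likelihood-ratio
test against the saturated multinomial flags poor fits at the 1% level.
`fixed_p` supports the assumed-p comparison (e.g. p = 0.8 taken a
priori) alongside the free MLE — which of the two a published comparison
used is often unstated, so both are provided.

### Digital ELISA (`simoa` module)

`compute_aeb` is the Poisson zero-class inversion `-ln(1 - f_on)`
(instruments apply it internally; it is rarely printed). A fully-on
array raises rather than returning infinity. Standard curves are
weighted least squares of mean AEB vs concentration over levels with
mean `f_on < 0.7` (the digital ceiling; saturated levels are excluded
and flagged), with per-level weights from the delta-method binomial
variance `f/((1-f)n)` when bead counts are available and equal weights
otherwise. A straight line rather than 4PL: the generative model is
linear in AEB by construction and the digital range of a real curve is
too. LOD = (blank mean + 3 SD − intercept)/slope, floored at zero — "3
SD above blank" being the conventional operationalization of "reliably
detect". Quantification back-calculates concentration, converts to
attomoles (`conc × volume × dilution × 1e18`), flags below-LOD readings
rather than silently reporting them, and summarizes replicates as
mean/SD/CV. Calibration can run in molar units or attomoles-per-assay;
the conversion volume must be supplied explicitly.

## Pipeline and reproducibility

`run_simpull` and `run_simoa` execute the stages from a single
`RunConfig` (lossless YAML round-trip). One global seed fans out to
per-stage seeds via `SeedSequence([seed, crc32(stage_name)])`, so any
stage can be rerun in isolation and identical configs produce
byte-identical output files (checked by checksum in the tests). Every
run writes a provenance record: config hash (excluding the output path),
seed, package version, per-stage seeds. Movies are multi-page uint16
TIFF with `_chA`/`_chB` suffixes; tables are CSV; results are JSON.

## Problem sizes used in the checks

The acceptance-style checks run at desk scale, chosen to keep each
statistical bound a few SE wide: 600 detectable traces per replicate and
a 10-replicate seed list for the two-step fraction (binomial SE ≈ 1.9
points per replicate); 10 fields of 100 spots at peak SNR 5 for
detection; 2000 complexes × 10 seeds per labeling probability for
colocalization; 3 movies × 100 spots × 480 frames × 10 seeds for the
image-pipeline recovery; 10⁴ beads per λ for the Poisson inversion.

## Known limitations

- No drift, no optical aberrations, no TIRF evanescent-depth profile;
  the PSF is a plain Gaussian.
- No blinking model; hidden-Markov or Bayesian step counting is out of
  scope, as is correction for fluorophores bleached before acquisition.
- TIRF camera parameters (pixel size, frame rate) are stated
  assumptions, not reproductions of any instrument.
- The SiMoA simulator's dark blank makes simulated LODs optimistic (see
  above); absolute reproduction of instrument AEB values is not claimed,
  since bead counts analyzed and internal corrections vary by platform.
- Greedy matching can differ from optimal assignment on dense fields;
  the tests bound the gap only in the sparse regime the assay uses.
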