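# Methods

## The measurement

An energy proxy trait (EPT) reduces a short video of a developing
embryo to a spectrum of temporal-frequency energy. Every visible
process — ciliary rotation, muscular crawling, the heartbeat — moves
pixels, and the per-frame mean pixel intensity of the region containing
the embryo fluctuates accordingly. The power spectral density of that
one-dimensional signal is an organism-agnostic, continuously measurable
phenotype: broadband energy tracks overall movement, narrowband peaks
track periodic organs such as the heart.

Spectra are estimated with Welch's method (`scipy.signal.welch`). The
default segment length is the **full 30-s record**, so Welch degenerates
to a single Hann-windowed periodogram. Rationale: the lowest analysis
band starts at 0.03 Hz, and only a full-length segment resolves
1/30 s ≈ 0.033 Hz; the native grid is then k/30 Hz, which places exactly
three native frequencies in every 0.1 Hz band regardless of whether the
recording was made at 30 or 48 frames/s. Window, overlap, detrending
(default: constant) and segment length are all configurable
(`SpectralConfig`). The DC bin is dropped and the spectrum truncated at
6 Hz, above which no biologically meaningful signal is expected from
these embryos.

**Total energy** is the plain sum of PSD values across the analysed
frequencies — a proxy, not a calibrated signal power, so no Δf
weighting is applied; multiply by the frequency step (1/30 Hz) for an
integral, variance-like quantity.

## Developmental time series

Embryos develop at different absolute rates, so all comparison happens
on relative developmental time: hours are mapped linearly onto [0, 1]
between the 4-cell stage and hatching. Total energy is min-max
normalised within each individual before averaging, so cohort means
describe trajectory shape rather than scale. Per-embryo series are
resampled by linear interpolation onto a common grid of G = 101 points
(1% resolution, finer than the hourly sampling of any embryo); grid
points outside an embryo's observed range take the nearest observation
rather than extrapolating. Cohorts are summarised pointwise as
mean ± sd (n−1 denominator; a single-member cohort reports sd = 0 with
a warning), and event timings by their cohort median. Embryos without a
recorded hatch (mortalities) are excluded when series are assembled.

## Spectral reduction

Native spectral grids differ with frame rate, so spectra are compared
only after binning into 60 contiguous half-open bands
[0.03 + 0.1k, 0.03 + 0.1(k+1)) Hz, k = 0..59. The top edge is 6.03 Hz
so that the 6.00 Hz native frequency is included; the band value is the
arithmetic mean of the native energies inside the band.

Species-mean time × band matrices are natural-log transformed with an
offset ε = 10⁻¹² (silent bands exist in synthetic data; ε is
configurable) and then min-max scaled per band across the time axis.
The alternative order (scale before log) is available via
`log_first=False`; log-first is the default because scaling last
guarantees every band occupies [0, 1] when it enters the PCA. A band
constant over all time carries no trajectory information and is set to
zero with a warning.

PCA is computed on centred, *unscaled* columns via SVD — per-band 0–1
scaling has already equalised ranges, and variance-scaling would
amplify noise in near-silent bands. Component sign is fixed by making
the largest-magnitude loading entry positive, so scores and loadings
are reproducible across runs and platforms. PCA is fitted per species
by default (each species' trajectory lives in its own component
space); a pooled fit is possible by passing a stacked matrix.

## Event statistics

*Band tests.* For each developmental event, the 5 hourly timepoints
immediately before onset (exclusive) are compared against the 5 at or
after onset with a Kruskal–Wallis test per band
(`scipy.stats.kruskal`, tie-corrected, χ² p-values). Observations are
pooled per-embryo per-timepoint values (5 × n per group) by default;
per-embryo window means are available (`pool="embryo_mean"`). Embryos
with fewer than 5 timepoints on either side are excluded with a
warning. Bonferroni correction uses family size m = 30 by default —
the adjusted threshold then equals 0.05/30 ≈ 0.00167, matching the
convention of the analyses this package reimplements — with m = 60
(one per band) available; neither choice affects directions or raw
p-values, only the correction.

*Percent change.* Between consecutive inter-event intervals the
percent change of cohort-mean band energy is
100·(after − before)/before, undefined (reported missing) when the
reference mean is zero.

*Species comparison.* A mixed repeated-measures ANOVA
(`pingouin.mixed_anova`) with species between subjects and relative
time within; the reported F is the between-subjects species effect.

## The counterfactual model

Whether an event onset *changed* the total-energy series is asked with
a Bayesian structural time-series counterfactual. The model is a
Gaussian local level — observation noise around a random-walk level —
which is the minimal structural model for this design: there is no
control series to regress on, and pre-event windows are short and
aperiodic, so trend and seasonal blocks would not be identifiable.

Fitting is by Gibbs sampling: the level path is drawn by forward
filtering, backward sampling; the two variances from their
inverse-gamma full conditionals. Priors are IG(1, 0.01·s²) on both
variances, with s² the pre-period sample variance — weakly informative
and scale-matched, which makes the whole procedure equivariant under
rescaling of the series. Defaults: 1000 draws after 200 burn-in; the
seed is mandatory.

For each event, the **pre-period runs from the previous event's onset**
(back-extended to a minimum of 10 points; from the series start for the
first event) and the post-period to the next event's onset or hatch.
Fitting from the series start is available (`pre_from_series_start`)
but not the default: a local-level model fitted across earlier
developmental regimes inherits their level shifts — notably the
rotation jump — as innovation variance, and the resulting
counterfactual spread (credible intervals ~20× the effect on the
species-mean series) swamps genuine post-onset changes. Keeping the fit
local to the preceding developmental phase is the standard practice of
choosing a stable pre-intervention window.

The effect summary compares the observed cumulative post-period total
against the distribution of cumulative counterfactual forecasts:
absolute effect (actual − predicted, with 95% credible interval),
relative effect (absolute/predicted), and a one-sided posterior
tail-area probability `tail_p` — the probability mass of the
counterfactual on the far side of the observation, not doubled, floored
at 1/D (a report of 0.001 at D = 1000 is a resolution floor). The
complementary "posterior probability of a causal effect" is
100·(1 − tail_p). Because `tail_p` is a min-tail statistic its null
distribution is uniform on (0, 0.5]; calibration is checked on
2·tail_p.

## The synthetic cohorts

No public dataset of hourly embryo video exists for the target species,
so the generator emulates the statistical structure the analysis
assumes. Each embryo's hourly 30-s mean-pixel signal is a baseline
(100 intensity units) plus:

- **rotation**: band-limited (0.03–6 Hz) Gaussian noise — ciliary
  rotation is broadband, raising energy across all analysed bands —
  with amplitude following a piecewise-linear envelope over relative
  time: zero before rotation onset, rising to a peak between rotation
  and crawling, declining into crawling, a step down at crawling
  (foot attachment ends free swimming), and a taper after radula
  onset;
- **cardiac**: a sinusoid (amplitude 1.2) at the template's fundamental,
  zero before heart onset, random phase per recording;
- white Gaussian noise (sd 0.5).

The envelope is anchored to each embryo's *realised* event times by a
monotone piecewise-linear warp of relative time, so amplitude steps
coincide with the recorded onsets rather than the template's nominal
times.

Three templates: two lymnaeid-like itineraries (heart onset before
crawling; development 288 h and 336 h; cardiac 1.7 and 1.4 Hz; 48 and
30 frames/s) and one heterochronic physid-like itinerary (crawling
0.37 < heart 0.45 in relative time; 168 h; 2.5 Hz; 48 frames/s).
Event times and the envelope peaks (0.35, 0.50, 0.33 of relative time)
follow the qualitative structure of pulmonate embryogenesis — earlier
events and a compressed pre-crawling decline in the physid — with no
claim of matching any real species quantitatively. Default cohort
sizes are 28, 40 and 43 embryos. Intraspecific timing variation is
multiplicative lognormal jitter (cv = 0.05) on hatch and on each event
time, with order violations rejected and resampled (bounded retries).

What the generator does **not** emulate: spatial structure (a single
region-of-interest mean is synthesised directly), slow drifts in
illumination, embryo growth and optical-density changes, non-stationary
heart rate, behavioural intermittency within a 30-s record, and
mortality. Passing tests therefore demonstrate that the pipeline
recovers programmed spectral/timing structure from signal-level data,
not that it is robust to every artefact of real microscopy video.

## Problem sizes and numerical choices

End-to-end checks in the test suite and the acceptance script run
cohorts of 10–12 embryos per species rather than the full 28/40/43, and
the byte-level determinism check uses 2: the properties asserted at
that scale (effect signs, all-band significance patterns, trajectory
marker order, reproducibility) are size-independent, and the reduced
cohorts keep a complete run to a few minutes. Calibration simulations
for the counterfactual machinery use pre-periods of 120–200 points, at
which the two variances are well identified; variance recovery is
averaged over several independent realisations because a single
realisation's apparent level variance fluctuates by tens of percent on
its own (verified against a maximum-likelihood fit of the same model).

Other numerical conventions: event markers snap to the nearest grid
point with ties to the earlier one; all pipeline CSV output is written
at 9 significant digits so identical runs are byte-identical; per-stage
and per-embryo random streams are spawned from the master seed via
`numpy.random.SeedSequence`, so cohorts are reproducible and mutually
independent.

## Known limitations

- Table-2-style magnitudes are not comparable to any published values:
  they depend on unpublished raw video, unknown pre-period conventions
  and unknown sampler settings; only the schema, sign structure and
  significance pattern are meaningful here.
- The Kruskal–Wallis χ² p-value is asymptotic; at the default group
  sizes (5 × n pooled) it is adequate, but for per-embryo means with
  tiny cohorts an exact test would be preferable.
- The mixed ANOVA treats grid points as exchangeable repeated measures;
  no sphericity correction is applied to the between-subjects effect
  (none is needed for it), and autocorrelation along the grid inflates
  the nominal within-subject resolution rather than the species F.
- The local-level counterfactual assumes the pre-event regime would
  have continued unchanged; developmental trajectories trend, so
  effects at events that sit on steep slopes are conservative (part of
  the slope is absorbed into the forecast spread).
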