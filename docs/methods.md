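# Methods

This note documents the models and procedures implemented in `whalesong`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Acoustic song metrics

**Spectral reduction.** The pipeline works from power-spectral-density
frames: 5-second spectra on an integer 1-Hz grid in dB re 1 µPa²/Hz
(`spectra.FrameSet`). Frames are averaged into one mean spectrum per UTC
calendar day. Whether a long-term monitoring system averages spectra in dB
or in linear power is often left unstated; we default to **linear power**
(the physically meaningful energy average, dominated by louder intervals)
and expose `domain="db"` for sensitivity checks. Day coverage is
`frames × 5 s / 86 400 s`; only days with **coverage ≥ 0.75** enter
analyses, and a `CoverageAccounting` object tracks period, sampled,
retained and complete days with the rounded percentages recomputed from
counts. The spectrogram recipe for 16 kHz audio uses nfft = 16 000 (1 Hz
bins), a Hann window and 50 % overlap; the "background-subtracted" variant
removes, per frequency bin, the 1st percentile of levels over time.

**Call index (CI).** For blue and fin whale song the detection statistic is

    CI = max(dB over peak bins) / mean(dB over background bins)

with fin peak {20, 21} Hz / background {19, 22} Hz, and blue (B-call third
harmonic) peak {42, 43} Hz / background {41, 44} Hz. CI is a **ratio of dB
values**, not of linear powers: that is the only reading consistent with a
no-signal value of 1.0 and daily maxima near 1.2 at realistic ocean
spectrum levels (~100 dB). Spectrum levels must be positive dB;
non-positive mean backgrounds are rejected rather than silently producing
negative indices. CI applies both to daily mean spectra (daily series) and
to single 5-s frames (diel analyses).

**Humpback song fraction.** Humpback song is scored by an external
classifier producing a 1-s stream in [0, 1]; the daily metric is the
percent of recorded seconds with score **strictly >** 0.7. Other
biological sources produce moderate scores (~0.3–0.6), so the 0.7 floor
rejects them by construction.

**Smoothing and presence.** Daily metric series are smoothed with a
centered **5-day running mean** defined on the calendar-day grid; at edges
and next to gaps the mean is over available days in the window. Presence
is read from the smoothed series: CI ≥ 1.01 for blue/fin, song fraction
≥ 3 % for humpback. A "minimum value applied to define presence" is
interpreted as inclusive (≥) at exact equality; the comparator is
config-exposed. Smoothing before thresholding clarifies the temporal
boundaries of persistent song seasons; its known cost is a one-to-two-day
halo of false positives at sharp season edges, which lowers precision
slightly but not recall.

## Phenology and diel behavior

Because song emerges annually between July and August in all three
species, an **analysis year** spans July 1–June 30. Seasonality is
summarized by a monthly climatology (percent of retained days with
detection per month, pooled across years — months with no retained days
are reported missing, not zero) and by the percent of days with detection
per analysis year. Interannual change is expressed as the ratio of two
annual percentages.

Diel structure uses apparent solar elevation (SE) from a Meeus/NOAA
low-precision ephemeris with the standard refraction correction (accuracy
a few hundredths of a degree; the requirement is only ≤ 0.5° against a
12°-wide band structure). Day is SE > 0°, night SE < −12°; the twilight
band between them belongs to neither bin and is excluded. The
**day:night ratio** is the ratio of song-positive sample fractions
(score > 0.7 per second, or frame CI ≥ 1.01 per 5 s) in the day bin versus
the night bin, pooled over the period by default (`method="daily"`
averages per-day fractions first). Because both numerator and denominator
are per-unit-time rates, the statistic is invariant to integer thinning of
the stream. When the night bin has no positive samples the ratio is
undefined and reported as NaN, never infinity. Solar elevation is
evaluated on a 60-s grid and broadcast to samples: the sun moves
< 0.25°/min, so the induced binning error is negligible.

## Photo-identification metrics

`uid_per_day` counts distinct individuals per day. Days with no
identifications are **absent, not zero**: survey effort does not cover
every day, and zero-filling unsurveyed days would bias monthly medians
downward (a config flag restores zeros for sensitivity).

**Migration timing** sets a threshold at the **33rd percentile** (linear
interpolation between closest ranks; method exposed) of all daily UID
values pooled across years, then scans monthly medians: arrival is the
first month in the spring window (Feb–Jun) whose median rises above the
threshold with every subsequent month through the persistence horizon
(September) also above; departure is the symmetric first persistent drop
in the Oct–Feb window, with persistence through February, the annual
minimum month. The persistence horizon is truncated at the end of the
record (otherwise the final study year could never register an arrival).
A month without survey data reads as below threshold. `months_above`
counts months of the analysis year whose median exceeds the threshold and
is monotone non-increasing in the threshold.

**Site fidelity** is the per-individual count of distinct identification
days within an analysis year, screened at a minimum of 1–4 days to probe
sensitivity to transient individuals. Distributions are compared with
Wilcoxon rank-sum tests: exact enumeration when the smaller sample has
≤ 8 values and no ties, otherwise the normal approximation with tie and
continuity corrections; two all-identical samples give p = 1 by
convention.

## Isotopic niche geometry

For each (species, year) group of (δ13C, δ15N) samples: the **standard
ellipse area** SEA = π√(λ₁λ₂) over the eigenvalues of the bivariate
covariance (unbiased n−1 divisor, the SIBER convention; ML divisor behind
a flag), its small-sample correction **SEAc = SEA·(n−1)/(n−2)** (for the
five-sample groups the factor is exactly 4/3), and the **total area** TA
of the convex hull. Probability ellipses scale the semi-axes by
√χ²₂(p) for p ∈ {0.40, 0.95}. Overlap between two ellipses is computed by
exact polygon clipping of 1024-gon boundary approximations (relative area
error ~6 × 10⁻⁶, far below the 0.5 % verification band of the circle-lens
closed form) and reported as percent of the **union** of the two areas
("the jointly occupied isotopic space"); sum- and per-ellipse
denominators are available since the field reports several conventions.

## Upwelling aggregation

Daily BEUTI (kmol nitrate m⁻¹ d⁻¹ at 37°N) is smoothed with the same
5-day running mean and the annual total is the sum of positive smoothed
values — downwelling periods contribute nothing. The anomaly is reported
against the long-term mean of annual totals, 174 kmol/m. Accumulation
windows may be calendar years (upwelling context) or July–June analysis
years (song metrics); gaps > 5 days inside a window trigger a warning.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure each analysis stage
assumes, with bookkeeping sufficient to validate the stage against truth.

- **PSD frames**: background = base spectrum (flat 95 dB default) + an
  AR(1) day-level offset (lag-1 coefficient 0.6, SD 1.5 dB — common to all
  bins, as broadband noise weather is) + independent per-frame, per-bin
  Gaussian jitter (SD 0.5 dB). During scheduled bouts the peak-band bins
  are raised by `call_energy_db` (default 6 dB) above the realized
  background; background bins are untouched. Truth records per-frame song
  flags; the daily presence flag is true iff at least one frame that day
  is song-flagged.
- **Diel bout placement**: bouts are allocated to the night bin with
  probability ρ·T_night / (ρ·T_night + (1−ρ)·T_day), where T are the
  day's bin durations. This duration weighting makes the singing *rate*
  ratio night:day exactly ρ:(1−ρ), so the day:night metric recovers
  (1−ρ)/ρ at any latitude and season; a plain Bernoulli(ρ) allocation
  would bias the recovered ratio by T_night/T_day (≈ 0.82 annually at the
  study site). ρ is therefore documented as the equal-duration night
  share. Bouts occupy non-overlapping `bout_length` blocks chosen
  uniformly within each bin, so realized song time matches the configured
  duty cycle to within one block.
- **Score stream**: song seconds exceed 0.7 with probability 0.9 (the
  classifier's score distribution during song is not published; this is a
  free modeling choice), otherwise fall in [0.4, 0.7); background follows
  Beta(1.5, 25); confuser events (Poisson, default 5/day, ~5-minute
  exponential durations) score uniform [0.3, 0.6] — below threshold by
  construction.
- **Photo-ID**: per individual and year, arrival ~ N(Apr 15, 6 d) and
  departure ~ N(Nov 16, 10 d); surveys occur per day with monthly effort
  probability (0.6 default) and each present individual is detected with
  probability 0.5. A `resident_fraction` (0.08) of individuals remains
  year-round: overwintering animals are a documented feature of coastal
  humpback aggregations, and without the low-UID winter sighting days
  they produce, the pooled daily-UID distribution has no lower third for
  the 33rd-percentile threshold to separate and the timing statistic is
  structurally undefined. Under these defaults the threshold's median
  value is 4 UID/day.
- **Isotopes**: bivariate-normal draws per (species, year) group from
  configured means and covariances (n = 5 default per group, matching the
  biopsy design).
- **BEUTI**: an annual cosine peaking in late spring plus AR(1) noise,
  going negative in winter.

Not emulated: waveform-level song structure, propagation and masking,
noise nonstationarity beyond AR(1), inter-individual heterogeneity in
detectability, observation clustering of ecotourism effort, and isotope
non-normality. Passing tests therefore demonstrate correctness of the
*computation chain* under the stated statistical assumptions, not
robustness of the field method to real-ocean complications.

## Problem sizes and numerical choices

Year-scale spectral simulations run at the 5-s cadence on a 15–50 Hz grid
(36 bins, covering both analysis bands) via a streaming path that reduces
each day's 17 280 frames to its daily spectrum and per-frame CI before
discarding them, keeping memory flat; the bundled demo configuration is
one analysis year. Score streams run at full 1-s resolution (31.5 M
samples/year). All generators draw from a single seeded
`numpy.random.Generator`; the pipeline derives per-stage seeds from one
root seed via `SeedSequence.spawn`, so reruns are byte-identical. CSV
output uses a fixed `%.6g` float format for determinism. Degenerate
inputs are handled explicitly: rank-1 isotope covariances give SEA = 0
with a warning, collinear hulls give TA = 0 with a warning, empty score
days are excluded rather than zero, and a presence series with no flagged
days reports NaN precision.

## Known limitations

- The 5-day smoother's edge halo caps presence precision slightly below
  1 at sharp season boundaries (recall is unaffected).
- The day:night ratio uses a 60-s solar grid; samples within ~30 s of a
  bin edge may be misbinned (error orders of magnitude below the
  sampling noise of the ratio).
- The exact rank-sum path is limited to min(n) ≤ 8 without ties; beyond
  that the normal approximation is used even for moderately small
  samples.
- Ellipse overlap is polygonal; for near-tangent ellipses the reported
  overlap can be off by the vertex-discretization error (increase
  `n_vertices` if that matters).
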