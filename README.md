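# whalesong

Metrics for long-term passive acoustic monitoring of baleen whale song,
with the companion statistics used to interpret interannual change:
photo-identification population metrics, isotopic trophic-niche geometry,
and upwelling-index aggregation. A synthetic-data module emulates every
input with known ground truth, so each stage of the pipeline can be
validated end to end.

## Who this is for

Bioacousticians and statistical ecologists working with cabled-observatory
or autonomous hydrophone records who need reproducible, tested
implementations of the standard song-detection chain — and a way to verify
it recovers known answers before pointing it at real data.

## What it computes

**Call index (CI).** Blue and fin whale song appear as narrowband peaks in
daily mean power spectra (fin 20-Hz pulses at 20–21 Hz; the blue whale
B-call third harmonic at 42–43 Hz). The detection statistic is

    CI = max(peak-band spectrum level) / mean(flanking background levels)

computed on dB spectrum levels; CI = 1.0 means no call energy, and daily
presence of song is CI ≥ 1.01 after 5-day smoothing.

**Humpback song fraction.** From an external classifier's 1-s score
stream: the percent of recorded seconds with score > 0.7; daily presence
at ≥ 3 % of the day.

**Phenology & diel behavior.** Monthly climatologies and July–June annual
percentages of days with detection; apparent solar elevation (SE) from a
low-precision ephemeris; the day:night ratio of song-positive fractions in
the SE > 0° vs SE < −12° bins.

**Photo-ID metrics.** Unique individuals per surveyed day (UID/day), the
33rd-percentile migration-timing threshold with persistent
rise/fall month detection, per-individual site fidelity, and Wilcoxon
rank-sum comparisons (exact for small samples).

**Isotopic niche.** Standard ellipse area SEA = π√(λ₁λ₂), its small-sample
correction SEAc = SEA·(n−1)/(n−2), convex-hull total area, 40 %/95 %
probability ellipses, and percent overlap of jointly occupied space.

**Upwelling.** Annual cumulative positive BEUTI after 5-day smoothing, and
its anomaly against the 174 kmol/m long-term mean.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate one analysis year of 5-s spectral frames with a 60-day blue whale
song season (6 dB injected call energy), then run the detection chain:

```python
import numpy as np, pandas as pd
from whalesong import (BLUE_BAND, AnalysisYear, annual_detection,
                       call_index_daily, day_night_ratio,
                       detection_performance, presence, smooth_5day)
from whalesong.synthetic import (NoiseModel, SongScenario,
                                 simulate_ci_experiment)

scenario = SongScenario(species="blue", season_start_doy=244,
                        season_end_doy=303, call_energy_db=6.0)
dates = pd.date_range("2021-07-01", periods=365, freq="D")
daily, frame_ci, truth = simulate_ci_experiment(
    scenario, NoiseModel(), BLUE_BAND, dates, seed=1,
    freqs=np.arange(15, 51))

ci = call_index_daily(daily, BLUE_BAND)
pres = presence(smooth_5day(ci), 1.01)
precision, recall = detection_performance(pres, truth.daily_presence)
print(f"song-day mean CI  : {ci[truth.daily_presence].mean():.3f}")
print(f"silent-day mean CI: {ci[~truth.daily_presence].mean():.4f}")
print(f"percent of days with detection: "
      f"{annual_detection(pres, AnalysisYear(2021)):.1f}%")
print(f"precision / recall vs truth   : {precision:.2f} / {recall:.2f}")
```

prints

```
song-day mean CI  : 1.042
silent-day mean CI: 1.0000
percent of days with detection: 17.0%
precision / recall vs truth   : 0.97 / 1.00
```

The 6 dB injection at a 50 % duty cycle raises the daily CI to ~1.04 —
comfortably above the 1.01 presence floor — while silent days sit at
1.000; all 60 true song days are recovered (recall 1.00), and precision
0.97 reflects the two-day smoothing halo at the season edges. 17 % of the
year's days have detection (62 of 365, the 60-day season plus the halo).

## Command line

```bash
whalesong run-full --seed 1 --out-dir out/      # full synthetic pipeline
whalesong simulate --species blue --days 30 --seed 1 --out frames.csv
whalesong ci frames.csv --species blue --out ci.csv
whalesong niche biopsies.csv --out niche.csv
whalesong beuti beuti.csv --year 2021
```

`run-full` writes per-day metrics, monthly climatology, annual summary,
photo-ID, niche and upwelling CSVs plus a run log with the config hash;
reruns with the same seed are byte-identical.

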