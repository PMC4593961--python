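# emgmap

Spatial activation mapping for high-density surface EMG (HD-sEMG)
electrode grids.

`emgmap` turns multichannel surface-EMG recordings from a rows × columns
electrode grid (the reference configuration is 7 × 9 = 63 monopolar
channels over the forearm) into RMS activation maps expressed in
relative forearm coordinates, and quantifies them with two spatial
statistics:

* **activation centroid** — the RMS-weighted mean electrode position
  `(cx, cy)` in (% forearm circumference, % forearm length);
* **SSD** — a normalized sum-of-squared-differences between two
  max-normalized maps, in percent: 0 for identical maps, 100 for maps
  whose active channels do not overlap.

On top of that it provides repeated-measures condition contrasts
(within-subject ANOVA with Mauchly's sphericity test, per-effect
Greenhouse–Geisser correction, and Tukey pairwise comparisons), and a
synthetic compartmentalized-EMG generator with full ground truth so the
entire chain runs and is testable without any recorded data.

## Package layout

| module                 | contents |
|------------------------|----------|
| `emgmap.grid`          | electrode grid geometry, relative forearm coordinate system |
| `emgmap.preprocessing` | zero-phase band-pass, windowed RMS, rest-baseline subtraction, repetition averaging, per-subject effort normalization |
| `emgmap.maps`          | `RmsMap` construction, centroid, max-normalization, SSD, display-only bilinear upsampling |
| `emgmap.stats`         | repeated-measures ANOVA (1–3 within factors), Mauchly/GG, Tukey pairwise, cell contrasts |
| `emgmap.simulate`      | Gaussian compartment territories, enslaving matrix, band-limited stochastic carriers, cohort generation |
| `emgmap.io`            | plain-text recording/map/grid formats with provenance hashing |
| `emgmap.pipeline`      | end-to-end analysis producing tidy tables + report bundle |
| `emgmap.cli`           | `emgmap` command-line interface |

### Conventions

* `y` is % forearm length: 0 % proximal (olecranon), 100 % distal
  (ulnar styloid); row *r* of *R* rows sits at `100·(r − 0.5)/R`.
  Row 1 is the most proximal row.
* `x` is % forearm circumference on a linear `[0, 100)` axis with the
  seam at the medial forearm. The centroid is linear (no circular
  statistics); activation of interest sits mid-axis, far from the seam.
* Centroid and SSD always operate on the original un-interpolated grid;
  `interpolate_for_display` exists solely for figures.
* Negative rest-subtracted RMS values are floored at 0 by default
  (`floor_at_zero=False` retains them).
* The SSD denominator is `Σ(nA² + nB²)`, the quadratic normalization
  that yields exactly 0 for identical maps and exactly 100 for
  disjoint-support maps. "Two random maps give 100" holds in the
  disjoint-support sense; i.i.d. noise maps score below 100 under any
  quadratic normalization. Alternative denominators can be passed as a
  callable to `ssd`.

## Quick start (library)

```python
import emgmap as em

cfg = em.default_config(seed=1, noise_rms=0.05)   # 7x9 grid, 4 compartments
cond = em.Condition("index", "high", "static")
rec, truth = em.simulate_recording(cfg, cond)

filtered = em.bandpass(rec)                        # 20-400 Hz, zero phase
vec = em.condition_rms(filtered, cond)             # baseline-corrected RMS
m = em.build_map(vec, cfg.grid)
print(em.centroid(m))                              # activation barycenter

other = em.normalize_map(m)
print(em.ssd(other, other).ssd_percent)            # 0.0
```

## Command line

```bash
emgmap simulate   --out-dir sim --subjects 2 --seed 1      # write recordings
emgmap preprocess sim/s0_index-high-static.tsv --out-dir maps
emgmap map        maps/s0_index-high-static.tsv            # centroid (and SSD with 2 files)
emgmap stats      results/centroids.csv --dv cy --within finger --within effort
emgmap report     --out-dir results --subjects 10 --seed 1 # full pipeline + figures
```

Exit codes: 2 usage errors, 3 data/configuration errors, 1 internal
errors. Every report bundle contains `run_info.json` with the seed,
configuration hash and all analysis flags; re-running with the same
configuration reproduces all numeric tables byte-for-byte.

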