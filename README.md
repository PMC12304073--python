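# gazesat

**How many observers does a scene-viewing eye-tracking study need?**
`gazesat` answers the question empirically, by resampling: it treats
sample-size planning as a *data-saturation* problem and measures, on real or
synthetic multi-observer gaze data, how quickly the information contributed
by each additional participant diminishes.

The package is aimed at eye-tracking researchers planning free-viewing
experiments (single feature-rich stimuli viewed by many observers, or
multi-image laboratory studies) who want resampling-based sample-size
guidelines rather than rules of thumb.

## The method

**Distribution-map saturation.** Gaze samples (or fixation locations) of a
set of participants are pooled into a pixel-grid *distribution map*. For
each candidate sample size *n* (capped at ⌊N/2⌋), the engine repeatedly

1. draws *n* participants without replacement and pools their gaze into a
   *comparison* map;
2. pools a disjoint, half-sized (⌈N/2⌉) *benchmark* set drawn from the
   remaining participants;
3. scores the pair with two standard map-similarity metrics:
   * **NSS** — the comparison map is Gaussian-blurred (σ = 1° of visual
     angle) and z-scored; the benchmark map is z-scored but not blurred;
     NSS is the mean comparison *z* over the pixels where the benchmark
     received at least an average amount of gaze (*z* ≥ 0).
   * **AUC** — benchmark *z* ≥ 0 defines binary labels; the blurred,
     min–max-scaled comparison map defines predictions; the score is the
     full-grid rank-based (Mann–Whitney) ROC area. 0.5 = chance,
     1 = perfect correspondence.

Bootstrapping this comparison (e.g. 1000 iterations) yields, per *n*, a
mean and a 95% range — the *saturation curve*. Guideline tables read the
curve backwards: the sample sizes at which the mean metric first clears a
5% relative improvement over the previous row, and cross-reference matrices
of the relative change between arbitrary sample-size pairs.

**AOI variance.** A parallel analysis computes five per-participant
area-of-interest metrics (number of visits, percentage fixated, time to
first fixation, dwell time per visit, total dwell time) for named polygonal
AOIs, and tracks how the bootstrap dispersion (95% range) of their sample
means shrinks with *n* — with tables of the sample sizes achieving
successive 25% variance reductions.

**Synthetic observers.** A seeded generator produces gaze with the
statistical structure the analysis assumes — shared attention hotspots,
idiosyncratic per-observer hotspots, centre bias, and measurement jitter
calibrated to a target RMS-S2S precision. Two profiles emulate contrasting
study designs: `dataset1_profile()` (single 1920×1080 image, 60 Hz,
RMS-S2S 0.41°, high inter-observer variability) and `dataset2_profile()`
(multiple 1280×960 images, 500 Hz, RMS-S2S 0.006°).

## Worked example

```python
import gazesat as gs

config = gs.dataset1_profile(n_participants=60, seed=42)
fixations = gs.generate_fixations(config)
recordings = [gs.truncate_window(r, 0.0, 5.0)          # first 5 s only
              for r in gs.generate_gaze_samples(fixations, config)]

model = gs.SaturationAnalysis.from_recordings(
    recordings, n_grid=[1, 2, 4, 8, 16, 30], n_bootstrap=200, downscale=10)
result = model.fit(seed=0)
print(result.summary())
```

```
Leave-n-out bootstrap saturation analysis
=========================================================
participants:     60    bootstrap iterations: 200
blur sigma:     1.00 deg  downscale: 10   seed: 0

NSS (mean [2.5%, 97.5%] per sample size n)
---------------------------------------------------------
 n     mean       lo       hi
 1   0.4814   0.2720   0.7325
 2   0.6159   0.4439   0.7652
 4   0.7605   0.6366   0.8511
 8   0.8608   0.7804   0.9353
16   0.9471   0.8882   0.9998
30   0.9913   0.9278   1.0470

AUC (mean [2.5%, 97.5%] per sample size n)
---------------------------------------------------------
 n     mean       lo       hi
 1   0.7088   0.6228   0.7653
 2   0.7446   0.6918   0.7857
 4   0.7633   0.7309   0.7969
 8   0.7770   0.7514   0.8005
16   0.7977   0.7798   0.8148
30   0.8111   0.7936   0.8289
```

Reading the output: a single observer's map already predicts the held-out
benchmark far better than chance (AUC ≈ 0.71), but the curve flattens
rapidly — the jump from 1 to 2 observers gains more than the jump from 16
to 30, the law of diminishing returns that saturation-based sample-size
planning exploits. The 95% ranges narrow with *n*: larger samples give more
*predictable* generalizability, not just better averages. The 5%-step
guideline table derived from the same fit,

```python
print(result.threshold_table("NSS").to_frame().to_string(index=False))
```

```
metric    n  value
   NSS    1   0.48
   NSS    2   0.62
   NSS    4   0.76
   NSS    8   0.86
   NSS   16   0.95
   NSS > 30    NaN
```

lists the successive sample sizes at which mean NSS first improved by ≥ 5%
over the previous row; the final row marks that no further 5% step is
reachable within this grid.

The same pipeline runs from the shell:

```sh
gazesat simulate   --profile dataset1 --n 60 --seed 42 --out data/
gazesat saturation --profile dataset1 --n 60 --n-grid 1,2,4,8,16,30 \
                   --n-boot 200 --downscale 10 --seed 0 --out run/
gazesat aoi        --profile dataset1 --n 60 --aoi aois.json --out run_aoi/
```

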