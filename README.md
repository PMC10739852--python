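# pgccscope

Single-cell morphological analysis of **polyploid giant cancer cells
(PGCCs)** in multichannel fluorescence microscopy images.

PGCCs are cancer cells carrying extra chromosome sets, recognizable by their
oversized nuclei. They resist chemotherapy and can reseed tumors, but bulk
drug-screening assays (MTT/ATP) cannot see whether a compound eradicated the
small PGCC subpopulation. `pgccscope` provides the image-cytometry
alternative: count every cell in a well, classify each one as PGCC, non-PGCC
or dead, and turn the per-cell counts into screening statistics — for
high-content screening labs, imaging-core facilities, and anyone studying
polyploidy dynamics in culture.

## The method

For each field of view (Hoechst nuclear stain; Calcein-AM live and
ethidium-homodimer dead stains; optional CellROX ROS probe or nuclear RFP
for time-lapse):

1. **Segment nuclei.** The nuclear channel is flattened with morphological
   top-hat/bottom-hat filtering (`I + TH(I) − BH(I)`, structuring-element
   radius above the largest nucleus radius), contrast-stretched between its
   50th and 99th percentile, binarized by Otsu's threshold, and labeled into
   connected components. Objects below a size cutoff are flagged as debris.
2. **Gate viability.** A cell is *live* iff it is Calcein-bright **and**
   ethidium-dim (quadrant gate). Gates can be fixed in camera units or
   derived automatically from an Otsu split of the log-intensity population.
3. **Classify ploidy by nuclear area.** A live cell is a **PGCC** iff its
   nuclear area strictly exceeds the threshold

   *A* > 300 px (4× objective) ≡ 1875 px (10×) ≡ 817 µm²,

   i.e. a circle of diameter 2·√(817/π) ≈ 32 µm. Pixel thresholds scale with
   magnification squared; the physical-area mode is magnification-free.
4. **Quantify.** Per-well class counts; per-compound categorization against
   control wells with unprotected pooled-variance *t*-tests (Fisher's-LSD
   style, Benjamini–Hochberg optional); four-parameter-logistic (4PL) IC50
   fits `r(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)`; per-cell
   intensity contrasts (e.g. ROS in PGCCs vs non-PGCCs, Welch *t* on
   log-intensities). Time-lapse sequences (nuclear RFP, no viability
   stains) are counted per frame, linked into tracks by nearest-neighbor
   assignment, and scanned for non-PGCC→PGCC transitions.

A bundled synthetic-microscopy simulator renders fields, plates, and
time-lapse sequences of elliptical nuclei with class-dependent sizes and
stain intensities, smooth background, PSF blur and shot/read noise — with
exact per-nucleus ground truth, so the whole pipeline is testable without
real data.

## Worked example

```python
import numpy as np
from pgccscope import (SimParams, simulate_field, analyze_field,
                       summarize_well, threshold_for_magnification,
                       fit_dose_response)
from pgccscope.quantify import four_param_logistic

# a simulated 1024x1024 field at 10x: 90 non-PGCCs, 10 PGCCs, 5 dead, 10 debris
field, truth = simulate_field(SimParams(seed=1))
records = analyze_field(field)          # segment -> gate -> classify
s = summarize_well(records, well_id="demo")
print(f"threshold @10x: {threshold_for_magnification(300, 4, 10)} px")
print(f"non-PGCCs: {s.n_non_pgcc}  PGCCs: {s.n_pgcc}  dead: {s.n_dead}  debris: {s.n_debris}")
print(f"PGCC fraction: {s.pgcc_fraction:.3f}")

conc = np.geomspace(0.001, 100, 8)      # µM
resp = four_param_logistic(conc, 1.0, 0.05, 0.8, 1.2)
fit = fit_dose_response(conc, resp + np.random.default_rng(0).normal(0, 0.03, 8))
print(fit.summary())
```

prints

```
threshold @10x: 1875 px
non-PGCCs: 90  PGCCs: 10  dead: 5  debris: 10
PGCC fraction: 0.100
Four-parameter logistic dose-response fit
=========================================
n observations : 8
converged      : True
IC50           : 0.704994
Hill slope     : 1.254
top (0 dose)   : 1.006
bottom (sat.)  : 0.08764
residual SS    : 0.0003923
```

The recovered counts equal the simulator's ground truth exactly; the IC50
estimate sits within the noise of the true 0.8 µM. The per-cell record table
(`records`) is a pandas DataFrame with centroid, area (px and µm²),
per-channel mean intensities, viability and ploidy class per nucleus — see
`pgccscope.records` for the schema.

## Command line

```sh
pgccscope simulate plate --seed 1 --out plate/          # synthetic plate + layout + truth
pgccscope screen --layout plate/layout.yaml --images plate/ --out results/
pgccscope dose --table doses.csv
pgccscope timelapse --images frames/ --interval-min 30 --out tl/ --track
```

`screen` writes `records.csv`, `summaries.csv`, `effects.csv` (per-compound
category: `kills_both`, `kills_pgcc_only`, `kills_non_pgcc_only`,
`induces_pgcc`, `inactive`) and a `run_metadata.json` capturing every
parameter; reruns on identical inputs are byte-identical.

## Layout of the package

| module | contents |
|---|---|
| `pgccscope.io` | TIFF/plate-layout reading, record/summary CSV round-trips |
| `pgccscope.segmentation` | background correction, binarization, labeling, measurement, debris filter |
| `pgccscope.classify` | viability gates, area thresholds, PGCC calls |
| `pgccscope.quantify` | well summaries, compound effects, `DoseResponse` model, intensity contrasts, `process_plate` |
| `pgccscope.timelapse` | per-frame counts, track linking, transition detection |
| `pgccscope.simulate` | synthetic fields/plates/time-lapses with ground truth |
| `pgccscope.plotting` | dose curves, time series, gating and violin plots |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
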