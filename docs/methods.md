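# Methods

This note documents the models, defaults and numerical choices behind
`pgccscope`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before trusting results on real
images.

## Segmentation

**Background correction.** The nuclear channel is enhanced as
`I + tophat(I) − bottomhat(I)`: the top-hat passes bright features narrower
than the structuring element (nuclei), the bottom-hat subtraction deepens
dark artifacts, and broad illumination structure cancels between the two.
The structuring element is an octagon of radius `tophat_radius_px`
implemented as a separable square pass plus iterated 3×3 cross passes
(van-Herk-style linear-time grey morphology); the octagon approximates a
disk at a fraction of the cost, which matters at radius 50 on megapixel
fields. The radius must exceed the largest nucleus radius, otherwise
nuclei themselves are treated as background; the default is 50 px at 10×
(≈ 33 µm at 0.66 µm/px, above any plausible nucleus), scaled linearly with
magnification.

**Contrast stretch.** The enhanced image is mapped linearly so that its
50th percentile → 0 and 99th percentile → 1, clipped outside. The median
is the robust background anchor: nuclei cover far less than half of a
field, and a lower anchor (e.g. the 1st percentile) lands on the dark
halos that the bottom-hat subtraction creates around bright nuclei, which
compresses the usable range and can derail the threshold step. A guard
declares the field empty (all zeros) when the stretch span is below
`min_contrast_snr` (default 10) times the pixel-noise scale estimated from
the median absolute first difference — without it, an empty well would be
stretched until its residual illumination structure segments as objects.

**Binarization.** Otsu's threshold on a 256-bin histogram of the corrected
image (default), or a fixed threshold. Otsu keeps the pipeline insensitive
to staining concentration and exposure time, since both act approximately
as intensity scalings that the stretch-plus-Otsu combination absorbs; the
robustness sweep in the acceptance suite quantifies this (counts change by
0 under ×0.5–×2 amplitude and gain perturbations).

**Labeling and measurement.** Connected components under 8-connectivity
(configurable to 4). `exclude_border` (default on) removes components
touching the image edge, because partial nuclei bias areas downward —
which matters when area *is* the classifier. `split_touching` (default
off) watershed-splits components of solidity < 0.9 using
distance-transform maxima as markers; it is off by default because the
simulator keeps nuclei separated and undersplitting is easier to audit
than oversplitting (each record carries its solidity for exactly that
purpose). Per-nucleus intensity means are taken over the object mask
dilated by 2 px, the same dilated mask for every channel: the viability
and ROS stains are cytoplasmic, and the thin perinuclear rim captures them
without segmenting whole cells. Areas are pixel counts; physical areas use
`area_px × pixel_size_um²`.

**Debris.** Objects with `area_px < min_area_px` (default 50 px at 10×,
scaled with magnification²) are flagged `debris` and excluded from all
counts. 50 px ≈ 22 µm² ≈ a 5.3 µm circle, well below any intact nucleus.

## Classification

**Viability.** live ⇔ `mean_live > live_threshold` and
`mean_dead ≤ dead_threshold`. Auto-gating splits the pooled
log10(intensity+1) population per channel with Otsu, then places the gate
at the log-space midpoint of the two class medians; the midpoint step
keeps the gate clear of the majority class's tail when live and dead
populations are very unbalanced (a 100:5 ratio is typical of healthy
cultures). `process_plate` pools records across the whole plate before
gating so that sparse wells gate consistently; fixed gates override.
Dead is a terminal class — a dead cell's nuclear size is never
interpreted as ploidy.

**Ploidy.** Among live, non-debris cells: PGCC ⇔ area **strictly** exceeds
the threshold (an area exactly at the threshold is non-PGCC). The pixel
thresholds are 300 px at 4× and 1875 px at 10× (`300 × (10/4)²`), the
physical threshold 817 µm² (circle-equivalent diameter 32 µm). Physical
mode is preferred when the pixel size is known; pixel mode reproduces the
objective-dependent defaults otherwise. The threshold values themselves
are taken as given (they were calibrated against flow cytometry); this
package only guarantees their consistent application.

## Screening statistics

Per compound, two-sided unpaired *t*-tests with pooled variance compare
the non-PGCC and the PGCC counts of the compound's replicate wells against
the control wells — unprotected pairwise contrasts in the Fisher's-LSD
tradition, no multiplicity correction by default (Benjamini–Hochberg
behind a flag, applied across all compound × count tests). A change is
"significant" when p < α (default 0.05) *and* the treated mean moves in
the stated direction. Categories, in precedence order: decrease in both →
`kills_both`; decrease in PGCCs only → `kills_pgcc_only`; increase in
PGCCs → `induces_pgcc`; decrease in non-PGCCs only → `kills_non_pgcc_only`;
otherwise `inactive`. `induces_pgcc` outranks `kills_non_pgcc_only`
because the taxane phenotype — fewer non-PGCCs *and* more PGCCs — is
scientifically a PGCC-induction event, and ranking it as a kill would hide
exactly the compounds this assay exists to find. Zero-variance degenerate
groups are handled explicitly (identical groups → p = 1).

Counts, not normalized viabilities, are the default response; both counts
are tested because a PGCC-selective compound is invisible in the total.

**Calibration.** With 3 replicates and Poisson-distributed counts the
pooled *t*-test is only asymptotically exact, so the acceptance suite
measures the realized type-I error over 1000 simulated inactive compounds,
each against a fresh control draw (sharing one control triple across
compounds would correlate all comparisons and make the realized rate an
accident of that triple). The per-test rate lands near the nominal 5%.

## Dose–response

`DoseResponse(conc, resp).fit()` fits the four-parameter logistic
`r(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)` by least squares on
log10 concentration, multi-started over Hill slopes {0.5, 1, 2, 4} and
IC50 starting points at the concentration quartiles; the best of 12 starts
wins. The parameterization is normalized after fitting so `bottom ≤ top`
(the 4PL is invariant under swapping asymptotes and negating the slope).
`converged` is false when the optimizer fails, responses are flat, or the
fitted IC50 falls outside the tested concentration range by more than
×100 — an IC50 that far outside the data is an extrapolation, not an
estimate. Rescaling all concentrations by k rescales the IC50 by exactly k.

## Time-lapse

Viability stains are phototoxic over days, so time-lapse fields carry only
a nuclear-RFP marker: every non-debris nucleus counts as live and the PGCC
call is by area alone. Frame times come from metadata (the reference
acquisition interval is 30 min, never assumed). Tracking is greedy
nearest-neighbor: candidate links sorted by centroid distance, accepted
greedily, rejected beyond `max_disp` (µm if a pixel size is known, else
px); unmatched tracks persist `max_gap_frames` (default 1) then are
`lost`; ties break on the lower label, so linking is deterministic. Greedy
assignment is adequate at screening densities where the typical
inter-nucleus distance far exceeds the per-frame displacement; a global
(Hungarian) assignment is a noted upgrade, not implemented.

A **transition** is recorded at the first frame where a track's area
crosses from ≤ threshold to > threshold and stays above for
`persistence_frames` (default 3) consecutive frames. The persistence
requirement debounces single-frame flicker of near-threshold nuclei; 3
frames = 90 min at the reference interval, short against the multi-hour
growth of a polyploidizing nucleus. One event per track at most; tracks
already above threshold at birth are not transitions.

## The synthetic-data generator

`simulate_field` renders, in order: filled ellipses (rejection-placed with
a minimum separation and a border margin, so ground-truth objects never
clip or touch), per-class amplitudes added on the masks, Gaussian PSF blur
(σ = 1.5 px), a background plane plus broad Gaussian blobs, Poisson shot
noise, Gaussian read noise (σ = 8), and a [0, 65535] sensor clip. The
ground-truth table holds each object's class, centroid, rendered pixel
area (exact mask counts before blur/noise) and per-channel amplitude.
All randomness flows from one seed through PCG64; per-well and per-frame
substreams are derived by SHA-256 hashing of the master seed with the
well id / frame index, so plate and sequence output is reproducible
independent of iteration order.

Default study conditions (all configurable):

| parameter | default | rationale |
|---|---|---|
| field | 1024×1024 px, 0.66 µm/px, 10× | at this pixel size 1875 px ≈ 817 µm², so pixel and physical thresholds agree |
| population | 90 non-PGCC, 10 PGCC, 5 dead, 10 debris | a treated-culture composition with a ~10% PGCC fraction |
| non-PGCC diameter | log-normal, median 15 µm, σ_log 0.15, truncated to [6, 28] µm | typical interphase nuclei |
| PGCC diameter | log-normal, median 40 µm, σ_log 0.10, truncated to [36, 80] µm | clearly polyploid nuclei |
| nuclear amplitude | log-normal, median 3000, σ_log 0.1 | Hoechst binds DNA stoichiometrically, so per-nucleus brightness varies little |
| live/dead amplitudes | bright 2000 (σ_log 0.2) / dim 60 (σ_log 0.3) | cytoplasmic stains vary more than DNA stains |
| ROS | median 500, PGCC fold 3× | reproduces an elevated-ROS phenotype |
| debris | 1.8–3.5 µm specks at 3× nuclear amplitude | condensed-chromatin fragments are small and Hoechst-bright |

Ground-truth ploidy class follows the *operational* (area-based)
definition, which is why the class-conditional diameter distributions are
truncated away from the 32 µm boundary: a "true PGCC" is, by the method's
own definition, a nucleus above threshold. The truncation gap ([28, 36]
µm unpopulated by default) also gives the exact-recovery tests a margin
larger than the segmentation's area error (~a few percent); narrowing or
removing the gap is the intended way to study near-threshold behavior,
and the bounds are plain parameters.

In simulated time-lapses, transitioning nuclei grow exponentially in area
(×1.15 per frame through the boundary region, capped at a 45 µm target),
with the trajectory phased so the true crossing falls midway between two
frames — each adjacent frame is then ~7% away from the threshold, outside
measurement error, which makes "counted curve equals truth" a meaningful
check rather than a coin flip on boundary frames. Motion is Gaussian
(σ = 1 µm/frame) with step rejection against other nuclei **at their
maximal grown radii**, so growth can never merge two nuclei. Background
structure is static across the sequence; only noise is per-frame.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: multi-lobed or lobulated PGCC nuclei
(ellipses only), touching/overlapping nuclei (separation is enforced, so
the watershed splitter is never exercised by default), focus drift,
vignetting or aberrations beyond the smooth background model,
camera-specific noise calibration, cell division and PGCC budding, and
staining heterogeneity beyond independent log-normal amplitudes. On real
images the exact-recovery results should be read as upper bounds.

## Problem sizes in the validation suite

The acceptance checks run on one CPU in a few minutes total: the default
1024² field (105 objects) for recovery and the ×0.5–×2 robustness sweep; a
31-condition × 3-replicate plate of 768² wells (~60 cells each) for the
screen; 48 frames of 1100² for the time-lapse; 2500² at 4× with ~10,050
objects for the capacity run; 1000 null compounds for calibration; and the
exhaustive 2¹⁶ 4×4 masks plus 100 random 16×16 masks for the labeling
oracle. These sizes are the package's chosen validation conditions; all
generators accept larger values.

## Known limitations

- The area classifier counts a multinucleated PGCC with spatially separate
  nuclei as several small nuclei; resolving this needs per-cell (not
  per-nucleus) segmentation, which is out of scope.
- DNA-content (integrated Hoechst) ploidy calling is deliberately not
  implemented; intensity is recorded but never used for class assignment.
- Auto-gating assumes both live and dead populations are present; a plate
  with no dead cells at all will place the dead gate inside noise. Fixed
  gates are the remedy and override everything.
- The empty-field contrast guard trades a small amount of sensitivity
  (fields whose brightest real object is within ~10 noise SDs of
  background are declared empty) for robustness against segmenting
  illumination structure in cell-free wells.
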