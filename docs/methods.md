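# Methods

## The growth-and-division model

Each simulated cell is a rod (capsule) that elongates only from its two
tips. The cell is conceptually split at its (eventual) septum plane into
side A — toward pole A, the left pole in the rendered scene — and side B.
Each side grows exponentially at a pole-specific rate:

    side_x(t) = side_x(t_sep) · exp(r_x · (t − t_sep)),

where `t_sep` is the condensation time at which the septum position is
fixed. The two rates of one cell are drawn one each from a *fast* and a
*slow* normal distribution (defaults 1.66×10⁻⁴ ± 2.39×10⁻⁵ and
7.87×10⁻⁵ ± 8.80×10⁻⁶ min⁻¹); negative draws are redrawn, never clamped.
The fast rate lands on the side that is shorter at placement with
probability `fast_on_short_prob` (default 0.78), emulating the observed
trend that the shorter side grows faster.

The event sequence per cell is: birth → appearance of a diffuse internal
patch after a normal delay (default 30 ± 10 min) → `condensation_frames`
(default 3 ± 1 frames, min 1) of patch wandering → condensation at the
septum position → division after a fixed timer (`invagination_delay`,
default 160 min). Division is a **timer, not a length threshold**: cell
length is deliberately not a division cue, so septal spots appear over a
wide range of lengths. The septum position is `0.5 + N(0, σ_p)` clamped to
(0, 1); the default `σ_p = 0.066` is back-computed so that ~87% of true
positions fall within the central 20% band (`0.1/Φ⁻¹(0.935)`). At division
the two daughter birth lengths equal the parental side lengths exactly
(conservation is exact in ground truth). A daughter's old pole keeps its
parental rate and its new pole draws from the *other* rate class, keeping
one fast and one slow pole per cell; this inheritance rule is a modelling
choice (`inherit_old_pole_rate`) — nothing in the data constrains it — and
can be switched off to re-draw daughter rates afresh.

Pre-placement growth uses the same two rates on both sides of the eventual
septum plane, back-solving the side lengths at `t_sep` so that the total
at birth equals the drawn birth length. Birth lengths default to
6.5 ± 1.8 µm (truncated at 2 µm), which puts placement-time lengths in the
~3.5–12 µm range where septal spots are seen in live cells; static
snapshots instead draw truth lengths explicitly from the per-species
three-spot distributions (4.8 ± 1.37, 4.32 ± 1.10, 3.46 ± 0.34 µm).

The pre-condensation patch performs a reflected Gaussian random walk on
normalized position in [0.15, 0.85] with a large per-frame step
(`wander_step_sd = 0.6` of cell length), making successive patch positions
essentially uncorrelated — patches appear at variable locations and only
*temporarily* dwell anywhere. This matters for detection: a slowly
diffusing patch would satisfy any finite stability criterion by chance,
whereas the jumpy walk is reliably rejected by the condensation rule
below.

## Rendering

Scenes are laid out on a grid of non-overlapping slots, one per founder
lineage, all cells horizontal. Founders keep their image centre fixed;
after a division each daughter is anchored at the septum plane shifted
outward by half a `separation_gap` (default 0.5 µm — one cell width of
clear background between daughters, as after the post-division snap; a
narrower gap lets the daughters' PSF tails bias each other's boundary).
The phase channel draws each cell as a binary dark capsule
(`background − contrast`) before convolution with a Gaussian PSF
(σ = 0.10 µm) and additive Gaussian noise (SD 6 on a background of 200) —
binary-before-PSF keeps the forward model simple and exactly
deterministic at `noise_sd = 0`, at the cost of quantising tip positions
to the pixel grid (see *Numerical choices*). The fluorescence channel
carries 2-D Gaussian foci: one at each pole cap centre throughout
(amplitude 150), a broad dim patch pre-condensation (amplitude 90,
1.6× PSF width), and a tight septal spot after. The final
`invagination_frames` (3) before division render a local width
constriction at the septum. Pixel size defaults to 0.05 µm/px
(sCMOS-class sampling; the measurement noise floor scales directly with
this calibration). A single master seed drives simulation and the two
noise channels through separately derived streams, so identical config +
seed reproduces output byte-for-byte.

What the generator does **not** emulate: phase-contrast halos, shot
(Poisson) noise, photobleaching, cell crowding or touching, V-snapping
geometry, out-of-plane growth, and sub-pixel capsule rasterisation.
Passing tests therefore demonstrate the pipeline's correctness under an
idealised but noisy forward model, not robustness to every artefact of
real phase-contrast movies — in particular touching cells would require a
splitting step (watershed) that is intentionally out of scope.

## Measurement pipeline

**Segmentation.** Otsu threshold on the full frame (scenes are sparse and
bimodal; a fixed threshold can be supplied), inversion, radius-1 opening,
connected components; components under `min_area_px` (50) or touching the
border are discarded and logged with reason codes.

**Centerline length.** The mask is skeletonised; side branches are pruned
by keeping the longest endpoint-to-endpoint skeleton path (Dijkstra over
the 8-connected skeleton graph); the path is smoothed with a moving
average of about one cell width — a raw 8-connected staircase
overestimates the arclength of a 30°-tilted rod by ~7% — and resampled at
0.5-px spacing. Each end is extended along the terminal direction to the
cell boundary, located at sub-pixel precision as the crossing of the
half-level between the local interior and background medians. Because the
half-level contour of a PSF-blurred *convex* cap sits inside the true tip
by ≈ σ²/2R, the crossing is pushed outward by that offset, with σ
estimated per-edge from the 25%/75% crossings of the same profile —
without this correction every cell reads ~0.5 px short. Pole A is the
endpoint with the smaller coordinate along the cell's dominant axis
(comparing full lexicographic order lets sub-pixel row jitter flip the
side labels of a horizontal cell between frames). Objects whose skeleton
is a point, a loop, or shorter than 0.8× their width are flagged
unmeasurable and excluded downstream. Under default noise the median
absolute length error is ≈ 0.2 px.

**Foci.** The detection threshold is the frame median + k·MAD (k = 5, raw
MAD). Within each mask, each connected above-threshold region yields
exactly one focus at its maximal-intensity pixel (row-major tie-break);
maxima closer than 0.25 µm along the centerline are merged to the
brighter one (non-maximum suppression — noise occasionally splits one
spot's region in two for a frame). Foci are projected to the nearest
centerline vertex for arclength `s` and `p = s/L`, and classified polar
iff `min(s, L−s) ≤ d_pole` (0.5 µm ≈ one cell width, boundary inclusive;
the cutoff is a config knob).

**Focus tracking and condensation.** Internal foci of one cell track are
linked frame-to-frame by optimal assignment (Hungarian) on |Δs| with a
gate `max_step_um = 0.3` µm: a stationary septal spot jitters by
~0.03 µm/frame while patches jump >1 µm, so the gate links the former and
fragments the latter. Condensation is the earliest index from which the
track's `p` stays within ±ε (0.05) of its forward running median for
`k_frames` (3) consecutive observations — 30 min of stability at the
10-min cadence. When several focus tracks of one cell yield events, the
pipeline prefers events whose track persists to the end of the cell track
(the septal spot marks the division site, so its track survives until
division; patch tracks die early), then the earliest.

**Lineage.** Masks are linked across frames by maximal pixel overlap,
kept at IoU ≥ 0.3; a division is declared when one mask is succeeded by
two masks each with IoU ≥ 0.15 against the parent (the one-into-two
topology change). Tracks form binary forests; daughters are assigned to
parental sides by centroid proximity to the parent's poles.

**Growth rates.** For each divided cell, the parent length at the
condensation frame is split at the septum position into the two
septum-to-pole side lengths, and each side's rate is the two-point
estimator `r = ln(daughter_length / side_at_sep) / (t_div − t_sep)`. The
septum position used for the split is the *median* detected `p` over the
stable (post-condensation) segment of the septal track: the spot is
stationary, so averaging beats the single-frame pixel quantisation
(±0.5 px) that otherwise dominates the error budget. `r_fast`/`r_slow`
are the per-cell max/min; cells with a non-growing slow side (r ≤ 0) are
kept and flagged but excluded from ratio summaries. The summary reports
both the mean of per-cell fast:slow ratios and the ratio of means — the
two differ because estimator noise in the denominator inflates per-cell
ratios, and which one a published "mean ratio" denotes is ambiguous.

**Asymmetry and variability statistics.** The degree of asymmetry at
placement is formalised as the signed relative side-length difference
`(a − b)/(a + b)`; its correlation with `r_a − r_b` uses the Pearson
definitional sums with the two-sided p-value from the t-transform (zero
variance ⇒ undefined, reported as NaN). The length-variability comparison
is an unpaired rank-sum test on absolute deviations from each sample's
median — a paired signed-rank test is ill-defined for independent samples
of unequal size — with full enumeration of the null for combined n ≤ 12
and a tie-corrected, continuity-corrected normal approximation otherwise;
identical pooled deviations give p = 1.

## Numerical choices and limitations

- Binary rasterisation quantises capsule tips to the pixel grid, so a
  single cell's length carries a ±0.5 px phase error that no sub-pixel
  measurement can remove; it is zero-mean across a population. Likewise
  the septal spot's maximal pixel is quantised, which sets the noise
  floor of the side-length split. This noise propagates into per-cell
  `max/min` rate selection and, at coarse calibrations (≳0.065 µm/px),
  visibly inflates the fast mean and deflates the slow mean; at the
  default 0.05 µm/px the effect is within sampling error at n ≈ 60.
- Growth over one 160-min timer is only ~2.7% (fast side), so the
  two-point rate estimator operates at low signal-to-noise by
  construction; per-cell ratios are broad and their mean exceeds the
  ratio of means.
- The condensation rule can fire one frame early when the last wander
  position happens to land within ~2ε of the septum, adding ≈ +1–3 min
  to the mean detected delay.
- Degenerate inputs are contracts, not crashes: empty frames segment to
  empty lists, discs are flagged unmeasurable, masks with no bright pixel
  yield no foci, empty position lists make `central_fraction` raise, and
  all-tied variability samples return p = 1.
- Ties are deterministic throughout: row-major argmax in detection,
  cost-then-index in matching, False for faster-on-shorter at exact rate
  ties.

## Problem sizes

The test suite and the acceptance script use 200-cell static snapshots
per species, 24-founder movies (~26 frames) for the division timer, and
60-founder movies for rate recovery — sizes at which the 3-SE recovery
bands are a few percent of the target values and a full run completes in
well under a minute on one CPU.
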