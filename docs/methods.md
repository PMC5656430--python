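# Methods notes

This note records the models, parameter choices and numerical decisions
behind `vsdpipe`, in the order data flows through the pipeline. It states
no empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic recordings

The generator emulates double-sided VSD imaging of one leech segmental
ganglion: two cameras, one per cell-body surface, with the dorsal view
rendered left-right mirrored relative to canonical anatomical coordinates
(the cameras face opposite sides). Its purpose is statistical realism at
the level the analysis is sensitive to — amplitudes, noise floors,
timescales, geometry — not optical realism.

**Cell layout.** Neurons are placed inside an elliptical shell region of
460 × 110 µm, mostly as bilateral homolog pairs mirrored about the midline,
with soma radii drawn uniformly from 5–12 µm (leech somata are ~10–60 µm in
diameter). Dense layouts progressively relax the pair-separation criterion
rather than fail, since real cell bodies touch. Six glial packets are
assigned by position (anterior/middle/posterior × left/right). Cells are
rendered as 2-D Gaussian intensity profiles with σ = radius/2 on a dim
uniform background; smooth profiles are what makes the one-pixel-shift
linearization of the motion estimator valid.

**Voltage programs.** Each cell's membrane potential is baseline (−50 mV)
plus, depending on behavior, a sinusoidal rhythm (swim 1.5 Hz, crawl
0.2 Hz; amplitudes 4–8 mV for involved cells, homologs share phase) or
stimulus-locked boxcar depolarizations (0–6 mV per side for local bending),
plus Poisson spike trains (spikes briefer than a frame enter as their
frame-integrated area — brief spikes are undersampled at 50 Hz), Poisson
EPSPs of 2–4 mV with 0.3 s exponential decay, and Gaussian membrane noise
(default 1 mV sd). The swim/crawl reference cell (standing in for a DI-1
motor neuron or AE cell) is pinned to phase 0.

**Forward model.** Pixel values follow
`F = F0 · (1 + s·(V − V_rest)/100 mV)` with sensitivity `s` defaulting to
2.7 % per 100 mV, multiplied by a single-exponential bleach (default 5 %
amplitude, τ = 30 s). The sensitivity is exposed as a parameter; unitary
EPSP sizes in ΔF/F depend linearly on it (2 mV ↦ 0.054 % at 2.7, 0.02 % at
1.0).

**Noise and nuisance terms.**
- *Shot noise* is Gaussian with per-pixel variance proportional to
  intensity, with the gain calibrated so the frame-to-frame relative noise
  of a typical cell-sized area equals `shot_noise_ppm` (default 70 ppm,
  the photon-noise floor of a cooled CCD at these fluxes).
- *Global fluctuation* is one low-pass series shared by all pixels of both
  views, **added** as stray light with amplitude `global_sd` × mean
  brightness. Fluorescent crosstalk between the two images is additive
  light, and only an additive term can be cancelled by the analysis's
  additive non-ROI background subtraction; a multiplicative model would
  make that stage structurally unable to succeed.
- *Motion* is a low-pass random trajectory per view (`motion_amplitude_px`
  rms, bandwidth 1 Hz), applied by displacing the analytic cell profiles
  themselves rather than resampling rendered frames. Real motion
  translates light without blurring; frame resampling at render time would
  bake an interpolation artifact into the data that no correction could
  remove.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical PSF and depth-of-focus blur of the curved
cell layer, dye rundown and phototoxicity, non-rigid (per-packet)
deformation, electrode artifacts, non-Gaussian cell shapes, and ROI
outlines drawn by hand (synthetic ROIs are the true rendered disks). Ground
truth stores everything downstream stages estimate: trajectories, percent
ΔF/F per cell, oscillation phase relative to the reference, left/right
response differences, and identities.

## Motion correction

The shifted-reference estimator is exact on its linear family by
construction; its trajectory accuracy depends on two numerical choices:

- **Iterative refinement.** Independent single-pass per-axis estimates are
  biased for combined x+y displacements (a 2-D bilinear shift is a product
  of 1-D operators, so each axis sees a frame filtered along the other).
  Each frame is therefore re-estimated up to 3 rounds, resampling the
  *original* frame by the current total estimate each round (tolerance
  10⁻³ units). This also extends the usable range beyond one unit; frames
  whose first-round estimate exceeds one unit are flagged.
- **Cubic-spline resampling.** Sub-pixel resampling (basis construction,
  refinement, and stack correction) uses spline order 3 with edge
  replication. Bilinear interpolation modulates the apparent brightness of
  a cell-sized Gaussian by ≈ frac(1−frac)/(2σ²) of its peak — of order 1 %
  for σ of a few pixels — which exceeds typical VSD signals (~0.1 %); the
  spline keeps the round-trip error of an ROI mean orders of magnitude
  below the signal.

Rotation is estimated after removing the translation estimate, in units of
0.1°. Correction resamples frames (translation first, then rotation), so
ROI extraction downstream is agnostic to motion; correcting frames rather
than extracted ROI signals is this package's choice. The reference frame's trajectory entry is pinned
to zero.

## Trace conditioning

SALPA-style detrending is realized as a centered sliding-window cubic
least-squares fit — equivalently Savitzky–Golay smoothing (window =
2 × time constant, polynomial order 3, scipy's `interp` edge mode, which
fits the first/last full window's polynomial at the edges) — subtracted
from the trace. Any cubic-in-time input is annihilated to numerical
precision. The cited algorithm's event-triggered restart logic is not
needed here (no stimulus-artifact blanking) and is omitted.

The time constant is bounded to 1–15 s. A 15 s window cannot fit inside a
15 s trial, so the high-level conditioner clips the time constant to the
largest value whose window fits the trace and warns; the low-level
`salpa_detrend` raises instead, since silently shrinking a caller's window
would change its meaning.

The global background is the mean over all in-frame pixels outside every
ROI (optionally restricted to a ganglion outline), detrended with the same
parameters before subtraction; detrending the background first keeps the
subtraction from re-introducing the bleach trend into detrended traces. The ΔF/F normalizer is the mean of the *raw* (pre-detrend) trace, so
percent units refer to absolute brightness. The sensitivity calibration
(tests and acceptance script) renders with zero background so the ROI mean
is pure cell signal; any background in the ROI dilutes the recovered slope
below the dye's true sensitivity, exactly as it does in real recordings.

## Coherence and involvement

Coherence uses K = 5 Slepian tapers at NW = 3 over the full trial (15 s at
50 Hz for bend/swim, 50 s at 20 Hz for crawl), evaluated at the FFT bin
nearest the requested frequency; the evaluation frequency defaults to the
reference's multitaper spectral peak within the rhythm band. Phase
convention: positive phase means the cell leads the reference. The stimulus
reference for local bending is the 0.5 Hz binary on/off train at frame
resolution.

The null threshold is the closed form `sqrt(1 − α^(1/(K−1)))` for the
coherence magnitude of incoherent signals estimated with K independent
tapers; the test suite validates it by Monte Carlo (10⁴ independent noise
pairs) at the 1-percentage-point level. The magnitude confidence interval
is a leave-one-taper-out jackknife on the arctanh scale, a standard
multitaper construction.

Cross-animal involvement: a neuron is involved in a behavior if it exceeds
the 95 % bound in ≥ 4 of 6 animals. For the bilaterally symmetric behaviors
(swim, crawl) the homolog pair is the unit: a pair counts as exceeding in
an animal iff at least one member exceeds the 97.5 % bound, and an involved
pair marks both members. Neurons observed in fewer than 4 animals for a
behavior are flagged undetermined and excluded from the Venn tabulation.

## Stimulus-identity decoding

Windows relative to stimulus onset: stimulus [0, 0.5) s, control
[−1.0, −0.5) s, reference [−0.5, −0.1) s; responses are window means minus
the reference-phase mean. Trial indexing is 1-based so the odd/even partner
rule reads naturally. Ties (held-out response exactly equidistant from the
two class means) score as incorrect — conservative, and measure-zero under
continuous noise. Responses enter the distance comparison un-normalized;
no variance scaling is applied. The control-phase score reuses the
identical machinery with the control response substituted. A vectorized
batch scorer (exploiting the fact that removing a trial and its partner
removes exactly one trial per class) is verified against the per-cell
scorer and against a brute-force enumeration oracle.

## Canonical-map registration

The staged affine is fitted exactly in the stated order — T₁/T₂ center the
point sets, S₁ matches rms spreads, R is orthogonal Procrustes restricted
to det = +1 (mirrored views are handled upstream by per-aspect canonical
charts, never by reflections), S₂ is a per-coordinate least-squares
stretch — followed by a few alternating R ↔ S₂ refinements. Refinement is
needed because a stretch applied *after* a rotation biases the Procrustes
fit; alternating minimization converges to the exact factorization on
clean data. Packets with ≥ 3 non-collinear anchors get their own
transform; others inherit the whole-aspect fit.

Warp-field kernel scales use σₖ = √3 × the distance from the k-th anchor
ROI to its nearest neighbor among **all** ROIs of the view (not just the
anchors): the warp then stays local at the cell-spacing scale even when
confirmed anchors are sparse, and isolated anchors reproduce their
residuals. A single anchor falls back to the ROI cloud's median
nearest-neighbor spacing. Coincident anchors are an error.

The automatic-assignment conflict cost is
`‖displacement‖² · r_neuron / median_radius + λ (log r_neuron − log r_roi)²`
with λ the squared median nearest-neighbor ROI distance: size-similar
matches are most meritorious and displacing larger cells costs more.
Candidate edges are each neuron's 5 nearest ROIs; connected conflict
components with ≤ 8 members per side are solved by optimal (minimum-cost)
assignment, larger ones greedily lowest-cost-first. User-confirmed pairs
are never overridden; unresolvable neurons and ROIs are listed, not
dropped. The interactive confirm-and-refine workflow is emulated by a
batch loop accepting a callback that supplies extra confirmed pairs per
round (≤ 5 rounds or until the assignment is stable).

## Clustering and integration

Correlation distance is 1 − Pearson r of the percent-ΔF/F traces over the
analyzed episode; zero-variance cells are excluded with a warning. Linkage
is average, the tree cut a fixed distance threshold of 0.7 — both
both exposed as parameters; the planted-partition
recovery test pins the default behavior. Cells in clusters smaller than 3
are excluded from DVI/CI (the threshold is a parameter; the regime-ranking
test checks the qualitative conclusion is stable for 2, 3 and 5). Each
*cell* is one histogram entry, not each cluster.

## Pipeline and reproducibility

The `run` command derives all stage seeds from the single config seed, and
a config hash plus seed fully determine every output table. Validation
reports hard violations (α outside (0,1), SALPA constant outside [1, 15] s,
missing files) as errors and soft issues (e.g. 50 Hz for crawling, where
20 Hz is typical) as warnings.

**Problem sizes.** The bundled demo and CLI tests run 60-cell ganglia on
64 × 192–256 px dual views for 8–15 s; calibration quantities use 10⁴
replicates; registration recovery uses 30–60 cell point sets; clustering
recovery uses 15–25 cells × 300–400 samples. These sizes make every
quantity statistically resolvable at the tolerances tested while a full
suite run stays in the tens of seconds.

## Known limitations

- The frame-resampling correction degrades for features with σ ≲ 1.5 px
  (undersampled cells); at such scales no interpolation scheme can
  preserve sub-percent photometry. Realistic magnifications (σ ≥ 2.5 px)
  are unaffected.
- The analytic null bound assumes the evaluation frequency is fixed before
  testing; picking the reference's spectral peak makes the cell-level test
  mildly anticonservative in principle, though calibration at the tested
  settings is within a percentage point.
- The affine+warp registration assumes packet-scale smooth distortion; it
  has no outlier rejection for grossly misplaced user pairs.
- The generator's cells are isotropic Gaussians with disk ROIs; ROI
  mis-drawing, overlap ambiguity and segmentation error in real data are
  out of scope.
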