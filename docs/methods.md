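# Methods

`cvtspect` simulates quantitative ventilation SPECT of a synthetic thorax
and asks which combination of acquisition, reconstruction and analysis
parameters best separates healthy lungs from lungs with mild COPD, using a
kernel-based coefficient-of-variation statistic as the per-image score.
This note records the models, the parameter choices and their rationale,
the numerical decisions, and what the synthetic setting does and does not
establish about clinical data.

## The disease model and the phantom

Mild COPD presents as patchy ventilation loss. It is modelled as spherical
lesions of 1 cm diameter whose tracer concentration is 50% of the
surrounding lung, scattered quasi-uniformly until they occupy 10% of the
lung volume. Together the lesions remove 5% of the total lung activity —
small compared with the ~15–20% normal range of spirometric indices, so
the imaging task is genuinely hard. The healthy lung is a homogeneous
distribution; no activity exists outside the lungs. Lesions keep the lung
attenuation coefficient: airway obstruction removes tracer, not tissue.

The thorax is deliberately schematic: two ellipsoids (flattened at the
mediastinal plane) inside an elliptical-cylinder body. The heterogeneity
analysis depends on lung volume, edge gradients and lesion statistics, not
anatomy, so a geometric stand-in suffices where an anthropomorphic phantom
is not redistributable. The lung semi-axes are calibrated at build time by
bisection so the voxelised volume matches the 4.2 l target (a 65-year-old
male mid-respiration) to well under the 5% contract; scaled presets scale
the target with the cube of the linear scale.

Lesion centres are drawn by rejection sampling from the lung voxels with a
minimum centre-to-centre distance of one diameter (even coverage, no
overlap) and the whole sphere constrained inside the lung. Placement stops
when the target fraction is reached; the overshoot is at most one sphere
(~0.02 percentage points at the default scale). Placement is bit-for-bit
reproducible from the seed.

Attenuation at 140 keV: soft tissue 0.15 cm^-1, lung 0.04 cm^-1, air 0.
Bone is omitted (treated as soft tissue); for this task the dominant
contrast is lung-versus-soft-tissue.

Respiratory and cardiac motion are approximated by an anisotropic Gaussian
blur of the activity before projection — FWHM 1.0 cm craniocaudal, 0.3 cm
transverse by default — standing in for frame averaging over the
breathing cycle. Gated 4-D simulation is out of scope; the blur reproduces
the salient effect (lesions become broader and shallower).

## Acquisition model

The forward model is an analytic attenuated parallel-beam projector:
128 equally spaced angles over 360° (64 at the mini scale), a 128×128
detector with 0.33 cm bins, and a non-circular orbit following an ellipse
whose radius spans 17–25 cm (auto-contour stand-in). For each angle the
volume is rotated into the detector frame (linear interpolation), each
voxel attenuated by exp(−∫μ dl) along the ray (cumulative sum with a
half-voxel self term), blurred in-plane by the distance-dependent
collimator response, and summed along the ray.

The collimator-detector response is Gaussian with
FWHM(d) = sqrt(intrinsic² + (slope·d)²). The LEHR model (intrinsic
0.40 cm, slope 0.0688) is calibrated to a system resolution of 1.5 cm FWHM
at the 21 cm mean orbit radius. No LEGP resolution figure is available
from the same source, so LEGP uses 1.25× the LEHR FWHM at equal distance;
its relative sensitivity 1.68 is the ratio of the two collimators'
clinical count totals at equal activity (1.23/0.73 = 6.14/3.64 ≈ 1.68).

Photon-physics fidelity is deliberately limited: no scatter, septal
penetration or energy-window modelling. The reconstruction uses the
identical system model, so the model–data pair is internally consistent —
internal consistency beats partial realism for a parameter-ranking study.

Two implementation details matter for speed and exactness. Blur is
applied in distance bins (8 by default): planes at similar collimator
distance are summed and blurred once with the bin's mean-distance kernel.
And angles are grouped by their residue modulo 90°, since quarter-turn
rotations are exact array permutations; each residue group costs a single
interpolated rotation. The grouped path is bit-identical to the per-angle
path.

## Counts and noise

Noiseless projections are scaled so their total equals the clinical count
level for the (collimator, activity) pair — LEGP: 1.23e6 (25 MBq) and
6.14e6 (125 MBq); LEHR: 0.73e6 and 3.64e6 — then 40 (8 at the mini scale)
independent Poisson realisations are drawn, simulating repeat
acquisitions of the same distribution. Realisation seeds derive from
(base seed, stream label, index) through `numpy` seed sequences, so any
(design, realisation) pair is reproducible in isolation and the grid is
embarrassingly parallel. Reduced desk-scale grids keep the clinical count
totals by default (count density rises); an option scales totals by
detector-area ratio instead.

## Reconstruction

Standard OSEM: multiplicative EM updates over 16 interleaved angle
subsets processed in bit-reversed order, with attenuation and CDR
compensation in the system matrix (the true phantom μ map is used, as the
attenuation is known in a simulation study), uniform unit initialisation
inside a cylindrical field of view, and a fixed update count as the only
stopping rule. The update grid is 2, 4, …, 20 iterations × 16 subsets =
32…320 updates. Voxels with near-zero sensitivity are masked out of the
update rather than divided by. One reconstruction pass serves all update
counts of a design family via snapshots, which is the dominant cost
saving in the factorial grid (reconstructions are reused across every
cutoff/kernel/lung-volume design that shares collimator, activity and
update count).

Because rotation adjoints are exact only for quarter-turn angle sets, the
forward/backward pair is matched to interpolation accuracy in general.
Consequences, verified in the tests: MLEM likelihood is monotone
non-decreasing on quarter-turn geometries (exact-adjoint regime); on
realistic many-angle geometries the noiseless hot-sphere
contrast-recovery curve climbs over the update grid to a plateau and may
then drift downward by a fraction of a percent of its plateau value per
iteration — monotonicity holds within that drift. Global reprojected
counts match measured counts to well under 5% from 64 updates on.

## Post-filtering

3-D Butterworth low-pass, gain A(f) = [1 + (|f|/Q)^p]^(−1/2) at radial
frequency |f| in cycles/cm, power p = 6, cutoffs Q ∈ {0.4, 0.5, 0.6, 0.7}
or no filter. Applied by FFT without padding (the lungs are interior, so
circular wrap-around is negligible); the DC term — the image mean — is
preserved to 1e−6 relative. Negative ripples are clipped to zero at the
CV-analysis stage, not inside the filter, mirroring physical
non-negativity while keeping the filter itself mean-preserving. Nyquist
for 0.33 cm voxels is ≈1.515 cycles/cm, so all study cutoffs are valid.

## Analysis volumes

The whole-lung mask thresholds the mean of the healthy reconstructions at
half the "maximum lung value"; the robust maximum is the 99.5th
percentile of the positive voxels rather than the literal maximum, which
in a noisy reconstruction is an outlier. The two largest connected
components are kept. The reduced-lung mask erodes the boundary by one
voxel (3×3×3 structuring element), removing the steep edge-gradient shell
whose CV values reflect geometry, not disease. Masks are derived once per
(collimator, activity, updates, cutoff) cell from the healthy mean image
and reused unchanged for the diseased arm of the same design.

At the clinical lung size, the half-maximum mask covers ≥90% of the true
lung; at the half-size mini anatomy the ~1.5 cm PSF erodes proportionally
more of the lung (coverage ~88%), which is a physical scale effect, not a
segmentation artefact.

## The CV_T statistic

For every mask voxel whose cubic kernel (edge 1.0, 1.7, 2.3 or 3.0 cm =
3, 5, 7 or 9 voxels at 0.33 cm) lies inside the grid, CV = sample
standard deviation / mean over the kernel, in percent. Kernel voxels
outside the mask are included — edge kernels deliberately see the lung
boundary gradient, which is the behaviour that makes kernel size interact
with the whole-versus-reduced lung choice. Kernels with non-positive mean
are excluded.

Each image's CV values form a density curve on fixed 1%-wide bins over
[0, 200]% (area normalised to 100%; values beyond the range are clamped
into the end bins). Fixed bins make curves averageable across
realisations; 1% matches the precision at which thresholds are usefully
reported. The threshold CV_T is the centre of the highest bin of the
healthy group's mean curve (ties resolve to the lower CV). The per-image
score AUC(CV_T) is the percentage of CV values strictly above CV_T,
computed from the raw values rather than the binned curve to avoid
discretisation bias (the two agree within one bin's area, asserted in
tests). Diseased lungs shift CV mass upward, raising AUC(CV_T).

## Design comparison and ranking

Each design yields 40 (or 8) AUC(CV_T) values per arm. The arms are
compared with the Mann–Whitney U test: midranks for ties, tie-corrected
variance, Z signed positive when the diseased group tends higher, and
two-sided p = 2Φ(−|Z|) with no continuity correction — the convention
whose complete-separation floor at n = 40/40 is ≈1.4e−14, consistent in
magnitude with the smallest p values such a study can print. Designs with
Z ≤ 0 are excluded from ranking (the statistic moved the wrong way); the
rest are ordered by ascending p, ties broken on the design identifier for
determinism. Bonferroni over the 800-design family (α = 0.05/800 =
6.25e−5) gates significance claims.

## Problem scales

* `full_scale` — 256³ phantom at 0.165 cm, 128 angles, 40 realisations:
  the clinical dimensions. Supported but not exercised by the test suite.
* `desk_scale` — full anatomy on the 128³/0.33 cm reconstruction grid:
  used for phantom arithmetic and segmentation checks.
* `mini_scale` — half-size anatomy on 64³, 64 angles, 8 realisations:
  the end-to-end testing scale; a two-design separation study runs in
  about two minutes on one CPU.

At the mini scale with seed 1, the good design (LEHR, 125 MBq, 64
updates, Q = 0.6, 1 cm kernel, whole lung) separates the arms completely
(Z = 3.36, p = 7.8e−4, the n = 8/8 floor) while the same design at 25 MBq
reaches only p ≈ 0.03 — the count-level ordering expected of the method.
CV_T at this scale is ~6–10%, not the ~23% of a full anthropomorphic
simulation: the modal CV reflects phantom scale, count density and the
transport model, and no claim is made that the synthetic value transfers.

## What the synthetic setting does not show

The phantom has schematic anatomy, piecewise-constant tissues, no scatter
or septal penetration, Gaussian motion blur instead of gated breathing
motion, and a noise model that is exactly Poisson on the scaled
projections. Passing tests therefore establish the internal correctness
and calibration of the pipeline and the qualitative parameter orderings
(count level, collimator, update count, cutoff, kernel/volume
interaction) — not absolute p values, CV_T thresholds, or effect sizes
for clinical data.

## Known limitations

* The forward/adjoint pair is matched only to interpolation accuracy off
  quarter-turn angles; EM monotonicity guarantees weaken accordingly
  (quantified above and bounded in the tests).
* Detector grid must coincide with the transverse volume grid (one bin
  per voxel column); heterogeneous detector/voxel sizes would need a
  resampling stage.
* The distance-binned CDR (8 bins) trades a small PSF-width quantisation
  for a ~5× speedup; increase `n_distance_bins` to refine.
* Masks, like the statistic, are defined from the healthy arm; a clinical
  application would need a subject-independent segmentation rule.
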