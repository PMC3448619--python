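# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the open design decisions behind pulmoquant.

## Coordinate conventions

All volumes live on regular axis-aligned grids: arrays indexed
`[i, j, k]` along world `(x, y, z)`, right-handed, millimetres,
`world = origin + index × spacing`, 0-based indices. x is left–right,
y dorsal(−)–ventral(+), z caudal(−)–cranial(+). CT is in Hounsfield
units (HU), PET in count-rate units.

## Dose model

The absorbed dose of an ¹⁸F-FDG administration is split into a positron
and an annihilation-photon component, assuming the whole activity decays
inside the animal (no elimination — renal excretion of FDG is neglected,
which overestimates the dose slightly):

* cumulated decays `N(T) = (A0/λ)(1 − e^{−λT})`, with the `T → ∞` limit
  `A0/λ`;
* positron dose `D_β = p·E_β·N/m` with branching ratio `p = 0.9673` and
  mean positron energy `E_β = 0.2428 MeV`; the ~1.5 mm positron range is
  small against the body, so full local absorption is assumed;
* gamma dose `D_γ = a_γ·p·E_γ·N/m` with `E_γ = 2 × 511 keV`. Only the
  absorbed fraction `a_γ` of the photon energy deposits in a mouse-sized
  body; `a_γ` is linearly interpolated in body mass between Monte-Carlo
  values of 4.4% (20 g) and 5.5% (40 g), clamped (with a warning)
  outside that range. At 30 g the exact midpoint is 4.95%; the commonly
  quoted rounded value 4.9% changes `D_γ` by < 0.3 mGy and both are
  accepted in tests. The branching ratio appears in `D_γ` deliberately:
  annihilation photons exist only after a positron decay, and the
  resulting 24.5–24.8 mGy at the standard administration is consistent
  with independent Monte-Carlo estimates, while omitting `p` is not.

Two half-lives are configurable from one constants registry: the
physical ¹⁸F half-life of 109.77 min (used for the decay integrals of
the dose estimate) and the effective whole-body value of 110 min (used
for the TLD correction). Energy conversion uses the CODATA MeV→J
constant; doses are reported in mGy.

**TLD correction.** A thermoluminescence dosimeter taped to the skin
integrates dose only while attached (`T_TLD` = 75 min by default),
whereas the animal is exposed until complete decay. Assuming a purely
exponential dose rate and a spatially stationary activity distribution,
the mouse dose follows from the reading as

```
D_mouse = D_TLD · (1 − e^{−λ T_mouse}) / (1 − e^{−λ T_TLD}) / (1 − a_γ)
```

The attenuation correction is implemented as division by `(1 − a_γ)` —
the reading underestimates the unattenuated field by the fraction
absorbed in tissue; the alternative reading (multiplying by `1 + a_γ`)
differs by < 0.3% at these fractions. At the defaults the multiplier is
×2.79. Region summaries average the corrected doses; the default
grouping is chest = positions {2, 3, 8}, abdomen = {6, 7},
pelvis = {9}. The thoracoabdominal-junction positions 4 and 5 straddle
both regions and are left ungrouped by default; any grouping can be
supplied.

## Segmentation

CT volumes are calibrated with the unique affine map sending the air
reference to −1000 HU and the water reference to 0 HU. Region growing
expands from each seed through connected voxels whose intensity lies
within ± tolerance of the seed voxel's own intensity, and unions the
per-seed regions; seed order cannot affect the result, adding seeds can
only grow the mask, and raising the tolerance can only grow it (both
properties are tested).

The customary "2% threshold tolerance" is ambiguous; the default reads
it as 2% of the calibrated volume's full dynamic range (scale-free,
matching common region-growing tools), and 2% of the seed's absolute
value is available as an alternative. The choice is recorded in the mask
provenance. Connectivity defaults to 6 neighbours (faces only),
conservative against leakage through corner-touching voxels; 26 is
available. No morphological post-processing is applied.

## Registration

Landmark pairs (matched by name, ≥ 3 non-collinear) are fitted with the
closed-form Kabsch solution: centre both clouds, SVD the
cross-covariance, correct the determinant so a reflection is never
returned. This is exact and deterministic; no iterative optimizer is
involved. Per-landmark fiducial registration errors and their RMS are
reported. The study protocol this mirrors accepted registrations
visually and re-picked the worst-fitting landmark when borders
misaligned; here that gate is quantitative — refinement (re-pick or
exclusion, keeping ≥ 3 landmarks) is advised when the RMS exceeds a
configurable threshold, default 0.39 mm, one in-plane PET voxel of the
emulated scanner (0.39 × 0.39 × 0.76 mm). PET is always the moving
image: CT carries the morphology on which ROIs are drawn. Resampling
uses trilinear interpolation (count-rate fields are smooth; nearest
neighbour would quantize) with a constant fill outside the field of
view.

## Uptake quantification

ROIs are spheres of a target volume (lung quadrants 3.5 mm³, liver
11.9 mm³, lesions 11.6 mm³ — the study's mean ROI sizes; the original
ROI shapes were not recorded, and sphericity is an artifact choice kept
in provenance). Voxels belong to an ROI when their centre falls inside
the sphere; the realized volume (count × voxel volume) is reported next
to the target, and no partial-volume weighting or correction is applied.
On the emulated PET grid the centre-counting discretization leaves the
realized volume within ~5% of the target. Quadrant ROIs are constructed
by splitting the lung mask at its midsagittal and axial centroid planes
and centring one sphere per quadrant at the quadrant centroid, shrunk to
the quadrant's bounding box; the original study placed these manually.

Per-animal summaries are unweighted arithmetic means over the four
quadrants. Spearman correlation uses average ranks for ties; its p-value
is exact (full permutation enumeration) for n ≤ 8 and the t
approximation otherwise. Student and Welch two-sample tests are both
reported, as group variances in such small cohorts often differ.

## Synthetic phantom

Organs are analytic solids so every ground-truth quantity is exact and
closed-form: a soft-tissue elliptic-cylinder torso in air, two
aerated-lung ellipsoids, a spherical myocardium partly carved out of the
left lung, a liver ellipsoid caudal to the lungs, and a dorsal bone
spine with a slight kyphotic bow (giving the "dorsal maximum of the
spinal convexity" a unique position). Tumours are spheres inside the
lung fields: a "diffuse" model of many small nodules (default 12,
radius 0.4–0.8 mm, enforced surface separation so components stay
countable) emulating the multifocal phenotype, or a single
"circumscribed" 2 mm-radius sphere emulating the focal phenotype.
Nodules are sampled sequentially from one seeded stream, so a larger
nodule count extends a smaller one and tumour load grows monotonically
with the count — the property the aerated-volume surrogate tests rely
on.

CT assigns HU per tissue (air −1000, aerated lung −650, soft
tissue/liver +50, tumour +40, bone +700 — standard murine ranges, all
configurable). PET is the organ uptake map (defaults relative to
liver = 1.0: myocardium 2.0, aerated lung 0.4, resting soft tissue 0.25,
tumour = ratio × liver with ratio 3.0 — a fasted-FDG-like pattern chosen
so tumour-free lung ratios land near the sub-unity values seen in
healthy animals) convolved with a Gaussian point-spread function
(default FWHM 1.6 mm, typical small-animal PET resolution), corrupted by
counting noise, and resampled into a frame offset from the CT frame by a
known rigid transform (default a few degrees and 1–2 mm, the residual
misalignment of repositioning-free multimodality beds). Noise is drawn
per voxel as Poisson counts with expectation proportional to the blurred
activity — variance proportional to the local mean, the signature of
reconstructed-image counting noise — scaled so the liver expects 50
counts per voxel by default; no sinogram or reconstruction simulation is
attempted. Five landmarks are reported in both frames: left-ventricle
tip, right-ventricle lateral border, cranial and caudal liver pole, and
the dorsal spinal maximum. The liver poles substitute for the spleen
poles used clinically, since the phantom (like most small-animal CT at
soft-tissue contrast) has no delineable spleen. Optional Gaussian jitter
on the PET-frame picks models manual picking error (default 0).

The default grid is 96 × 96 × 110 voxels at 0.2 mm isotropic — the
anatomy has fixed physical size (~19 × 19 × 22 mm) and the grid must
contain it, so too-small grids raise a sizing error. The emulated CT
acquisition used 0.094 mm voxels; the default is coarsened for
tractable volume sizes, and the test suite coarsens further to 0.3 mm.
PET is generated on the CT grid rather than the scanner's
0.39 × 0.39 × 0.76 mm grid; this sidesteps a second resampling without
affecting any tested property, since blur, noise and the frame offset
are modelled explicitly.

What the phantom deliberately omits — anatomical texture, attenuation
and scatter, respiratory motion, reconstruction artifacts, partial
lobe/airway anatomy — bounds what passing tests show: they validate the
algorithms' correctness and calibration on known ground truth, not
performance on real reconstructions. In particular the piecewise-constant
CT makes region growing nearly exact; the 5% recovery bound is a
contract on the algorithm, not an accuracy claim for real lungs.

## Numerical choices and degenerate inputs

* Rigid fits reject < 3 pairs, collinear configurations (second singular
  value < 1e-9 of the first) and name mismatches; rotations are
  validated to det = +1.
* Region growing from a seed on a constant plateau is linear in accepted
  voxels (scikit-image flood fill); co-valued seeds already covered by an
  earlier region are skipped, which cannot change the union.
* Empty ROIs, zero/negative liver means, equal calibration references,
  zero TLD exposure times and constant rank-correlation inputs all raise
  typed errors rather than propagating NaNs.
* The exact Spearman p enumerates all n! permutations (≤ 40320 at
  n = 8); beyond that the t approximation is used.
* Pipeline reports embed a provenance block (version, seed, config
  hash); rerunning a completed run with `resume` and an unchanged config
  hash is a no-op.

## Known limitations

* The aerated-volume surrogate saturates once nodules coalesce; the
  generator enforces separation, so coalescent growth is untested.
* TLD region grouping of the junction positions (4, 5) is convention,
  not measurement.
* The CT dose of a combined examination (202 mGy for the emulated
  protocol) is an external input, not computed here.
* Landmark-based registration accuracy on real data depends on picking
  error, which the phantom models only as optional isotropic jitter.
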