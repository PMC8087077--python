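# Methods

## Frames and transforms

All geometry lives in named right-handed frames with lengths in mm; the
optical tracker's frame is the world frame. Transforms are stored
child→parent (tool→tracker, image→tracker, projector→sensor), matching how
optical trackers report poses; rotations are matrices internally, with
scalar-first quaternions accepted at the pose-CSV boundary (normalized on
read, rejected if the norm deviates from 1 by more than 1e-6). Rotation
validity is enforced at construction: `RᵀR = I` and `det R = +1` to 1e-9.

## Fiducial registration and FRE

Paired-point rigid fitting uses the closed-form SVD solution of the
centered cross-covariance with a determinant sign guard, the standard
solver for this problem; correspondence is by label order only (landmarks
are paired manually in practice). FRE is defined as the RMS — not the
mean — of residual norms, matching how the accuracy statistics elsewhere
in the package are reported. Fiducial sets must contain at least 3
non-collinear points; collinearity is tested on the second singular value
of the centered point matrix (> 1e-6 mm), so planar sets — like the
phantom's corner divots — are accepted, as they must be.

Pivot calibration solves the stacked linear system `[R_k −I][b; p] = −t_k`
by least squares. Orientation diversity is a hard requirement: a condition
number above 1e6 (e.g. near-constant rotation, which makes tip and pivot
inseparable) raises an error rather than returning the minimum-norm
pseudo-solution.

## Projector model and calibration

The projector is a zero-skew, distortion-free pinhole (laser
pico-projectors are focus-free and near-distortion-free at the error scale
of interest): pixels are 0-based, origin at the top-left pixel centre,
+u right, +v down, optical axis along +z. Calibration estimates the 3×4
projection matrix by the normalized DLT (isotropic Hartley normalization
of both point sets), requires ≥ 6 non-coplanar points, and decomposes via
RQ with positive-diagonal sign fixing. Because the DLT minimizes algebraic
error, a Levenberg–Marquardt refinement of the ten physical parameters
(f_u, f_v, c_u, c_v, rotation vector, translation) on the reprojection
residuals follows by default. The reported reprojection RMS is over the u
and v residual components. The sensor pose captured at calibration time
converts the extrinsics into the fixed projector→sensor mounting, which is
what makes the projector freely repositionable afterwards. Image
width/height are not observable from correspondences and are explicit
arguments (package default 800×600). The default model uses f = 1000 px
and a sensor mounted 30 mm above the optical centre.

## Volumes

A volume is an axis-aligned scalar grid: world = origin + spacing ∘ index,
voxel-centre convention. Oblique NIfTI direction matrices are rejected on
read — the rigid, scanner-aligned setting this package targets never
produces them, and silently resampling would hide geometry errors.
Resampling is trilinear on the world-aligned grid with output dims
`ceil(dim·spacing/new_spacing)` (output extent covers input extent; edge
samples clamp). Threshold segmentation is a closed interval on intensity
(HU for CT). Iso-surfaces are the 0.5 level of the mask by marching cubes
after padding (so border-touching structures close) and light Gaussian
smoothing (σ = 1 voxel), which moves the level set off the voxel
staircase; on a 10 mm sphere at 0.5 mm spacing the extracted area is
within ~1% of analytic instead of ~8% high.

Fused display follows the operating-room convention: the anatomical slice
in grayscale, the functional slice colormapped over it,
`(1−α)·gray(anat) + α·cmap(func)` per pixel, both volumes window-normalized
by their own global min/max. The colormaps (gray, hot, rainbow, purple)
are fixed 256-entry in-code tables: hot is the black→red→yellow→white
piecewise-linear ramp, rainbow an HSV hue sweep blue→red, purple a violet
ramp used for bone renderings.

## NMI registration

Multimodality rigid registration maximizes
`NMI = (H(A)+H(B))/H(A,B)` with a fixed 64×64 joint histogram, over 3
translations (mm) + 3 Euler angles (deg, about the fixed volume's world
centre). The optimizer is derivative-free: a 3-level coarse-to-fine 3×3×3
translation grid (halving steps from `max_shift/3`), then Nelder–Mead over
all six parameters with an explicit initial simplex (1 mm / 2° steps —
Nelder–Mead's default simplex collapses around near-zero starts and would
leave rotations unexplored). Samples falling outside the moving volume are
excluded; a candidate with under 25% overlap scores 0. The returned
transform maps fixed-frame to moving-frame world coordinates (resampling
convention). Identical inputs give NMI = 2 at the identity; independent
images give ≈ 1.

## Synthetic subject

`make_synthetic_subject` emulates the navigation-relevant features of a
small-animal CT + PET/SPECT study on one 0.3 mm isotropic grid (the
spacing used for navigation after downsampling; default FOV 64×48×100
voxels ≈ 19×14×30 mm): an ellipsoidal soft-tissue body (40 HU) in air
(−1000 HU), two rod-like high-intensity skeleton elements (1200 HU), a
4 mm-radius tumour sphere (120 HU) strictly inside the body, and a
functional hotspot exactly co-located with the tumour over a faint body
background, plus optional Gaussian noise (defaults 5 HU / 0.05 uptake
units). The tumour mask is the exact voxelized sphere, so thresholding the
noiseless CT at the tumour band reproduces it bit-exactly. The generator
does **not** emulate partial-volume blur, scanner PSF, reconstruction
artifacts, attenuation, or anatomy beyond "body + rods + sphere";
passing tests therefore validate the geometric chain, not robustness to
real image texture.

## Tracker simulation

Noise is applied to marker coordinates (iid Gaussian per axis), never
directly to poses; the pose is then re-estimated by the same rigid fit
used for registration. This reproduces the physically important couplings:
orientation jitter scales inversely with the marker-array baseline, and
tip/projection error grows linearly with the lever arm — the mechanism
behind distance-dependent projection error. Default marker σ = 0.10 mm
(typical of research-grade infrared trackers — a simulation parameter, not
a measured value), with 0.05 mm extra for handheld pointers (added in
quadrature). Tool geometry: pointer = 50 mm marker square with a 150 mm
tip offset; AR-device sensor = 90 mm marker square, sized to the projector
enclosure footprint rather than to a handheld instrument.

## Rendering

The virtual camera rasterizes in software at projector resolution with a
z-buffer: flat colors, no shading (the overlays are flat contours and
slices), per-structure opacity composited back-to-front, slices first and
then meshes ordered by centroid depth. Slice quads sit at their true world
plane (this is what pointer-driven depth scrolling means), with
perspective-correct (1/z-interpolated) texture lookup; draping onto curved
surfaces is out of scope. Triangles touching non-positive depth are
skipped rather than clipped. Bare point structures light the single
nearest pixel. Safety alerts use the Euclidean distance transform of the
margin mask (0 inside); tips outside the volume are measured against the
nearest margin voxel centre directly.

## Phantom accuracy protocol

The phantom is a 5×5 divot grid at 20 mm pitch over 10 mm checker squares
(the two pitches are independent parameters: divots occupy alternating
squares). Registration uses the 4 corner divots by default (configurable),
localized once per run with the simulated pointer; FRE is recorded from
that single registration since the phantom does not move between standoff
conditions. Per distance (200/300/400 mm) the projector is aimed at the
grid centre from the given standoff; per divot, 3 pointer localizations
give the "real" point (their mean), and per repetition the "virtual" point
is computed by projecting the registered divot estimate through the
*measured* (noisy) projector pose to a pixel, then intersecting that
pixel's ray — cast from the *true* pose, since the physical light leaves
the physical projector — with the true phantom plane. The drawn pixel is
kept at continuous coordinates: quantizing to the pixel grid would add a
~0.2 mm artifact unrelated to tracking error and would break the exactness
of the noiseless chain (which yields FRE = 0 and all Err = 0 to machine
precision). A `projector_angle_sigma_deg` option adds pure orientation
jitter about the optical centre, the mode in which error scales linearly
with distance (RMS(400)/RMS(200) ≈ 2).

Summary statistics: per distance, RMS and SD (ddof = 1) of the errors; the
overall value is the unweighted mean of the per-distance RMS values, with
the pooled SD and pooled RMS reported alongside for transparency.

## Problem sizes and determinism

Unit and property tests run on deliberately small instances — 24³–45³
voxel grids, hundreds of Monte-Carlo draws, a 200-run protocol sweep for
the distance-scaling checks — sizes at which every oracle (analytic sphere
volumes, exhaustive shift search, brute-force transform search,
closed-form noise statistics) is computable exactly. Every stochastic
routine takes an explicit seed and is bit-reproducible; reports embed the
seed and noise parameters.

## Known limitations

- Rigid world only: no tissue deformation, no non-rigid registration.
- Axis-aligned volumes only; no DICOM, no tomographic reconstruction.
- No lens distortion or keystone/radiometric compensation in the projector
  model; no draping onto curved surfaces.
- Tracker noise is isotropic and iid per marker; real infrared trackers
  have depth-anisotropic, pose-dependent noise and occlusion effects.
- Simulated accuracy figures characterize the model chain under the chosen
  noise parameters; they are not measurements of any physical device.
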