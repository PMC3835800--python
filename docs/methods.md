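# Methods

`gridstereo` reconstructs a 3D surface patch from one stereo image pair of a
projected gridline pattern and rigidly registers it to a reference surface
mesh. This note documents the model behind each stage, the parameters that
matter, what the synthetic scene generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Problem setting

A stereo endoscope observes a smooth, nearly featureless organ surface
(think of a liver lobe) onto which a small projector casts a lattice of `R`
horizontal and `C` vertical dark lines. The `R×C` line crossings are
artificial features: they can be detected in both views, matched, and
triangulated, giving a 3D point grid from which a smooth surface is fitted.
Registering that surface to a preoperative surface model (e.g. segmented
from MR) with the iterative closest point (ICP) algorithm links the live
endoscopic view to the preoperative coordinate frame. Accuracy is summarised
by the average surface distance (ASD) between the registered reconstruction
and the reference surface.

## Camera model and stereo geometry (`geometry`)

Cameras follow the pinhole model with radial (`k1`, `k2`) and tangential
(`p1`, `p2`) polynomial distortion applied to normalized image coordinates.
Undistortion inverts the polynomial by fixed-point iteration and verifies
the result through the forward model to a residual below 1e-10 normalized
units; divergence (physically meaningless coefficient settings) raises an
error rather than returning garbage.

The stereo rig stores the left camera, right camera and the left-to-right
rigid transform (`x_r = R x_l + t`, `t` in mm). The fundamental matrix for
undistorted pixel coordinates is `F = K_r^-T [t]x R K_l^-1`, normalized to
unit Frobenius norm with a deterministic sign. Triangulation uses the
midpoint of the common perpendicular of the two back-projected rays rather
than a linear (DLT) solve: the length of that perpendicular (the "ray gap",
in mm) is a physically interpretable quality score for a correspondence,
and the matching and reconstruction stages use it as such. Rigid fits use
the closed-form weighted SVD solution with a reflection guard.

All 3D quantities are in millimetres; pixels are 0-based, origin top-left,
x rightward, y downward.

## Synthetic scenes (`synthetic`)

The generator replaces the physical phantom experiment. Its defaults are the
package's study conditions:

| parameter | default | meaning |
|---|---|---|
| surface | `liver_like`, seed 1 | sum of 3–5 Gaussian bumps, amplitude ≲2.5 mm, on a base plane 30 mm from the endoscope; extent 28×22 mm |
| pattern | 7 rows × 11 cols | 77 crossings; 32 projector-px spacing, 5 px line width |
| projector | 848×480, f=800 px | reverse pinhole, mounted ~6.5 mm off-axis, fixed in the world |
| rig | 4 mm baseline, 2° convergence | 640×480 sensors, f=700 px, mild radial distortion (k1=-0.06, k2=0.004); ~27×21 mm field of view at 30 mm |
| illumination | spot, strength 0.35, σ=0.23·W | multiplicative Gaussian spot with ambient floor, centred off-axis — endoscope-style non-uniform lighting |
| projector falloff | σ=120 projector px | line/background contrast fades towards the pattern borders |
| noise | σ=3 gray levels | additive Gaussian, quantized to 8 bits |
| clutter | 4 X-shaped smudges | real 3D features outside the pattern footprint, for the ROI stage to reject |

Rendering is physically ordered: each camera pixel's ray is intersected with
the height field (fixed-point iteration on depth, valid for the near-nadir
geometry used), the surface point is projected into the projector to obtain
its distance to the nearest gridline, an anti-aliased line profile and the
two shading fields are applied, then noise and quantization. Ground truth
(3D crossings, exact projections in both views, grid indices, a dense
reference mesh, line-core masks) comes from the same forward model, so
detection, matching, triangulation and registration can each be scored
against truth. Rendering is a pure function of the scene and its seed.

The two shading fields were chosen so that the generator reproduces the
failure mode the intensity-correction stage exists for: because the viewing
light and the projector are separate sources with separate falloffs, line
*level* and line *contrast* vary independently across the image, and no
single global threshold separates all lines from all background in the
uncorrected image — while after correction a global threshold works. With
the defaults, skipping correction costs roughly a third of the crossings
and admits a patch of near-threshold background; with correction the
detection is essentially perfect.

Pose corpora (`make_experiment`) jitter the endoscope pose (default ≤1.5°,
≤1.2 mm) while projector and surface stay fixed, resampling any pose that
would push a crossing out of view. 19 poses is the default protocol size.

Not emulated: specular highlights, subsurface scattering, tissue texture,
deformation over time, rolling shutter, or calibration error (the rig used
for rendering is the rig given to reconstruction). Passing tests therefore
demonstrate correctness of the algorithmic chain under controlled
conditions, not robustness to every artefact of real endoscopic video.

## Preprocessing (`preprocess`)

1. **Inversion** — ITU-R 601 luma, then `v -> 255−v`, making the dark
   gridlines bright for thinning.
2. **Intensity correction** — `I_new = 255 − ((I_ave − I_c)/2 + 127)` with
   `I_ave` a 31×31 box mean (reflected borders). This pins background to
   ~127.5 and maps lines to 127.5 plus half their local contrast, making
   contrast spatially uniform. The divisor 2 keeps the full difference
   range inside byte range; the squared variant (`mode="squared"`), which
   saturates for local contrasts above ~11 gray levels, is retained for
   comparison. The window must be large relative to the line width so the
   local mean tracks background; 31 px ≈ 6 line widths at the default
   geometry.
3. **Thresholding** — three methods. `background` (pipeline default on
   corrected images) thresholds at `127.5 + max(3·σ̂, 3)` where `σ̂` is a
   robust noise scale from horizontal first differences; it exploits the
   flat background the correction establishes and, unlike Otsu, cannot
   migrate into the line class when the background is nearly constant.
   `otsu` is the conventional histogram threshold (and what the pipeline
   falls back to when correction is disabled — that ablation is precisely
   "conventional thresholding on the raw image"). `fixed` takes an explicit
   level.
4. **ROI detection** — threshold, drop specks below 25 px (a large closing
   element would otherwise chain isolated noise pixels image-wide), close
   with a Euclidean disk of radius 18 px (implemented with two distance
   transforms, O(N) in the radius; the radius must exceed half the
   inter-line spacing, ~31 px here, for the lattice to merge), keep the
   largest component, fill holes. All later stages work inside this mask.
5. **Cleanup** — closing with a 1 px disk, removal of components below
   25 px, filling of background holes below 100 px (the open lattice cells
   are ~900 px and stay open).

## Junction detection (`features`)

The cleaned binary image is thinned to a unit-width skeleton (two-pass
morphological thinning as implemented in scikit-image). For every skeleton
pixel two cross-point numbers are computed: half the count of 0/1
transitions around the 8-pixel ring of the 3×3 window (SCN) and around the
16-pixel perimeter of the 5×5 window (MCN), each traversed clockwise from
the top with ring closure (the (n+1)-th term reuses the first pixel). An
interior line pixel scores 2, an endpoint 1, an ideal 4-arm crossing 4.
A pixel is a junction candidate when *both* numbers reach the threshold
(default 3.0, valid range [3, 4]): thinning frequently splits a crossing
into two nearby 3-valent nodes, which the relaxed threshold plus cluster
merging (centroids closer than half the estimated line spacing are merged)
reassembles into one sub-pixel candidate. The transition count is invariant
to the ring's starting pixel and direction, so the ordering convention is
irrelevant; a test asserts this.

Merged candidates are refined to sub-pixel accuracy: nearby skeleton pixels
are split into the two line orientations (2-means on the doubled angle),
and perpendicular intensity profiles of the corrected image are sampled
along each arm (skipping the junction core); each profile's
intensity-weighted centroid gives a point on the true ridge, a total
least-squares line is fitted per arm family, and the two lines are
intersected. On clean renders this reduces the mean localization error from
~0.3 px (cluster centroids) to ~0.07 px, which the depth budget needs: at a
4 mm baseline and 30 mm working distance, 1 px of disparity error is
~0.32 mm of depth error. If the local geometry is unusable the refinement
falls back to skeleton line fits, then to the centroid.

## Matching (`matching`)

Crossings look alike, so correspondence rests on geometry only. Detections
(undistorted to ideal pixel coordinates) are organised into grid columns by
finding peaks of a smoothed 1-D density of x-coordinates — a column is a
*concentration* of x-values, so scattered spurious detections neither
create columns nor bridge the gaps between real ones; points far from every
peak get column index −1 and cannot shift the numbering between the views.
Within a column, y-order gives row indices; columns holding more than `R`
points are flagged. Left/right matching then walks each column in row
order: candidates must share the column index and lie within 2 px
(perpendicular pixel distance) of the left point's epipolar line;
ties prefer the matching row index, then the smaller residual; matching is
one-to-one and unmatched points are discarded and counted. This stage is
what eliminates spurious detections that survive the image-space filters.

## Surface reconstruction and ASD (`surface`)

Matched pairs are triangulated; a pair is dropped if its ray gap exceeds
2 mm *or* if its depth deviates from the median depth by more than 3.5
median absolute deviations (floored at 6 mm) — a false correspondence with
near-identical pixel coordinates in both views triangulates to a wildly
wrong depth while keeping a small ray gap, so the gap alone cannot catch
it. Surviving points are arranged on the (row, col) grid; duplicate cells
keep the smaller-gap point.

The smooth surface is an interpolating bicubic spline over the grid
parameter plane, one spline per coordinate, evaluated on an upsampled
lattice (default 8× per cell) and triangulated. Missing cells are first
filled with a thin-plate-spline prediction so the tensor spline has full
support; a pure thin-plate variant is available (`method="tps"`). The fit
passes through every present grid point (`upsample=1` returns the grid
itself).

ASD between a source surface and a reference mesh is the mean over source
vertices of the *exact* point-to-triangle distance to the reference,
computed with a KD-tree candidate search whose radius guarantee makes the
result identical to a brute-force scan over all triangles (asserted in
tests). The default direction is reconstruction → reference, because the
reconstruction covers only part of the organ surface and the reverse
direction would be inflated by uncovered area; a symmetric option averages
the two directional means.

## Registration (`register`)

Classic two-step ICP: exact closest points on the reference surface
(point-to-triangle, not nearest vertex), then the closed-form rigid update,
composed until the RMS closest-point distance changes by less than 1e-4 mm
or 100 iterations. The RMS trace is recorded and is non-increasing by
construction (each update is optimal for the current correspondences, and
new correspondences can only be closer); tests assert this on every run.
Non-convergence within the iteration budget is reported through a flag, not
an exception. An optional trimmed fraction robustifies the update; the
default is the untrimmed classic iteration.

`initial_align` provides a coarse start: centroid alignment plus principal
axes, with the four proper sign combinations disambiguated by the smallest
mean distance to the reference points. This works when source and reference
cover comparable areas; for a shallow surface *patch* against a larger
smooth reference, in-plane rotations and flips of the patch score nearly
alike and the choice is unreliable. The multi-pose experiment driver
therefore initializes ICP at the identity, which corresponds to the coarse
pre-alignment an image-guidance system obtains from tracking hardware;
`init="pca"` remains available.

`run_experiment` renders each scene, runs the full pipeline, registers the
fitted surface to the reference mesh (ICP on a ≤1200-vertex subsample — the
six-parameter rigid fit is grossly over-determined beyond that — with the
final ASD evaluated on all vertices) and aggregates mean ± standard
deviation of per-scene ASD along with mean detection sensitivity. Scene
failures are recorded per scene, excluded from aggregates, and never abort
the batch. Ablation switches disable intensity correction or ROI detection
to reproduce the degradation structure: with the default corpus the full
pipeline is best, skipping ROI detection is slightly worse (surviving
clutter points deform the fitted grid), and skipping intensity correction
is markedly worst (a third of the grid lost and near-threshold background
admitted).

## Problem sizes and runtimes

The validation protocol uses 19 poses per corpus at 640×480; a full
pipeline pass over one pair takes a few seconds on one CPU, and the whole
acceptance battery (one noise-free corpus, one noisy corpus under three
pipeline variants, plus analytic spot checks) runs in a few minutes. These
sizes are the package's test protocol, chosen to exercise every stage at
realistic image scale.

## Known limitations

* The renderer's ray casting assumes a near-nadir view of a gentle height
  field; grazing views or self-occluding geometry are out of scope.
* Column-based matching assumes the vertical gridlines map to roughly
  vertical image columns; a rig rolled by tens of degrees would need a
  rectification step (the epipolar gate itself is rotation-agnostic).
* ICP finds the local optimum nearest its initialization; a patch flipped
  or slid far along a smooth reference is a documented failure mode, not an
  error.
* The synthetic study conditions are favourable for sub-0.1 mm accuracy
  (exact calibration, static scene); real-image accuracy is dominated by
  calibration quality and tissue motion, which are not modelled.
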