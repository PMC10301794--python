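# Methods

This note documents the models, parameter choices and numerical decisions
behind the pipeline, what the synthetic validation scenes do and do not
emulate, and the known limitations.

## Color model and white balancing

Sensor frames are 8-bit gamma-compressed sRGB; linearization uses the
standard piecewise curve (linear slope 12.92 below 0.04045, exponent 2.4
above) through a 256-entry lookup table, and the inverse by left bisection
over the table's bin boundaries.  A pixel's chromaticity is its color
divided by the total linear intensity I = R+G+B ∈ [0, 3]; pixels with
I = 0 carry an explicit undefined flag rather than sentinel values.

Gray-pixel selection uses two *axis-aligned* ellipses around the neutral
5500 K gamut point with the published spreads (σ_r = 0.0723, σ_g = 0.0097,
σ_b = 0.0749) as standard deviations, i.e. squared denominators in the
ellipse test — the literal-σ variant can be configured but is not the
default, since the constants are documented as standard deviations.  The
exposure band (0.02 and 0.98 in the gamma domain) is applied to I after
linearization: (0.00155, 0.955) × I_max.

The gain model ties the single color-temperature setting K_W to channel
gains Γ_R = Γ_K, Γ_B = 1/Γ_K, Γ_K = √(2(K_W−K_min)/(K_max−K_min)), with
equal gains at the range centre.  The update scaler
γ = √(r̄·b̄_W/(r̄_W·b̄)) is converted to a new setting through the inverse
of the gain model (Γ_K′ = γ·Γ_K, then K_W′ from Γ_K′), which converges in
essentially one step on a uniform cast; the predicted post-update error E*
rescales the red mean by γ and the blue mean by 1/γ before renormalizing —
the physically consistent reading of the gain model (scaling both means the
same way would leave the red/blue balance untouched).  An update is
applied only when (E > 1.758×10⁻⁸) ∧ (E − E* > 10⁻¹⁵); the threshold is a
config constant with no deeper provenance.

The offline virtual camera stores an equal-gain internal image (red
divided by Γ_K at the recorded temperature on the virtual 2000–9000 K
range, blue multiplied by it), iterates the same controller from the
recorded setting, and stops on a ±1 K step, on a rejected update, or —
after ≥ 20 jittering repetitions — freezes at the mean of the three
smallest recent updates within 10 K of their predecessor (cap: 200
iterations).  Saturation rules on output: pixels overexposed in the input
stay untouched; a channel pushed above 1 saturates the whole pixel; a
channel below 10⁻⁸ zeroes it; everything is clipped to [0, 1].

Convergence from a strong cast needs *bootstrapping*: under a large cast
no truly gray pixel lands inside the tight selection ellipse, but pixels
of near-neutral surfaces under varied local illumination do, their mean is
biased toward the true grays, and the loop walks in.  Scenes without any
near-neutral content cannot be corrected — a real limitation of
gray-gamut white balancing, not of this implementation.

## Exposure scoring

The controller drives the skewness of the 256-bin gamma-domain gray-value
histogram about mid-gray (128) to zero, computing the histogram directly
from linear intensities by bisecting precomputed linearized bin
boundaries.  The skewness is the *standardized* third central moment
(bounded step sizes; the raw moment would scale steps with the histogram
width).  Defaults: τ_Δ = 1 ms hardware step, N_τ = 5 steps at |S| = 1,
reference exposure τ** = clamp(τ_frame = 100 ms) — τ** acts as the
gain-crossover point, so the gain engages only when the virtual exposure
exceeds one frame time.  Offline the controller only scores frame quality;
the trace is written per view.

## Depth segmentation

Smoothing is an edge-preserving (bilateral-style) filter: a 5×5 spatial
Gaussian (σ = 1.5 px) times a per-pixel gradient-magnitude weight
exp(−ΔD²/2σ_d²) with σ_d = 10 mm, so strong depth steps do not bleed.
Weights come from a precomputed table indexed by left bisection over
squared integer boundaries — no square roots or exponentials per pixel;
the table agrees with exact float evaluation to well under 1 mm.
Undefined pixels (0) are excluded from every average and copied through.

Edges are zero crossings of an octagonal Laplacian (4-neighbours weight 1,
diagonals 1/√2, centre −(4+2√2), so all eight neighbours act at unit
distance).  Edge strength is the largest opposing-neighbour difference,
doubled for one-sided neighbours at undefined depth.  Candidates above
12 mm — or bordering undefined depth — are primary; others are accepted
when (Δ > 3.5 mm) ∧ ((Δ > 12 mm) ∨ ((Δ−3.5)/(12−Δ) > 1)) and they connect
to a primary edge (hysteresis).

Patient selection: non-edge defined pixels, 3×3 grid, largest 4-connected
component in the central ninth touching its border (ties break toward the
centroid nearest the image centre), flood-filled across the frame; a
per-row depth band Dclose ≤ D ≤ Dfar (row maxima capped at one third of
the total spread or mean+3σ, row minima mirrored and floored at the 200 mm
sensor limit) strips background bleed.  The bounds are inclusive — a
perfectly flat component would otherwise produce an empty band.
Components under 200 px, or without a valid band, are rejected and the
next-largest tried; edge pixels adjacent to the final mask are kept in a
separate boundary set so the mask itself never contains an edge pixel.

## Meshing

Masked depth pixels backproject through the depth intrinsics; the pixel
grid is triangulated along a fixed top-left→bottom-right diagonal with
windings facing the camera, and any triangle touching an invalid vertex is
dropped.  Texture coordinates are the projections into the laterally
offset color sensor; a triangle whose texture-space winding flips while
its 3D normal faces the depth camera bridges a depth discontinuity (the
color sensor would see its back side) and is removed.  Degenerate
triangles (uv area < 0.25 px², shortest uv edge < 0.5 px, beyond the
texture's top/bottom rows) and skinny triangles (minimum angle < 13° with
both long edges beyond mean + 4 sd of the neighbourhood edge lengths
within max(0.9|e_b|, |e_a|) of the needle tip) are removed, with removal
cascading along the long edges of adjacent skinny triangles; duplicate
vertices merge on exact equality (depth quantization makes near-duplicates
legitimate), unreferenced vertices and patches under 100 triangles are
dropped.

The canonical patient frame permutes axes (+z head, +x patient-right →
patient-left, +y toward the back) and shifts the origin's y to the mean of
the median y of the outer two of five x-subgroups within the top vertical
third — the shoulder planes.  Surfaces record their frame so the
operation is idempotent.

## Registration

Pairwise symmetric point-to-plane ICP, hand-implemented (Gauss–Newton on
the 6-dof twist, cKDTree correspondences).  Initialization estimates the
relative shoulder-axis rotation about z and the centroid shift inside the
bounding-box overlap; the initial correspondence distance is l̄ + 2σ over
normal-compatible (≤ 30°) forward/backward nearest neighbours, floored at
the sampling pitch.  Because the shoulder-median estimate is coarse on
partial arcs and the clip heads form a near-regular bump lattice (false
lattice-shifted minima), a small fan of yaw offsets (0, ±8°, ±16°, ±24°)
is scored with one short coarse run and the best seed starts the full
schedule.

Each symmetric run performs a forward then a reverse point-to-plane fit
(reverse initialized with the forward inverse); a candidate is accepted
only if it strictly shrinks l_c, and among feasible candidates the lower
point-to-plane error wins (errors at different l_c are not comparable, so
l_c carries the progress test).  When the schedule stalls above
l_min = 1 mm after real progress, one final run at l_min is attempted.
Inner runs cap at 80 iterations with a 10⁻⁶ relative-error tolerance.

Two implementation details matter for accuracy on partially overlapping
scans: clouds are subsampled to 12 000 points per surface (deterministic
seed, so identical surfaces subsample identically and self-registration is
exact), and mesh-border vertices (3 eroded rings) plus grazing-incidence
vertices are excluded — border geometry is ragged and one-sided, and
points beyond the partner view's coverage would otherwise snap to its rim
and drag the fit sideways.  At these settings the accumulated orientation
drift across a 14-view, 270° sweep of the synthetic torso stays below
about half a degree, the level needed for ~1 mm electrode accuracy;
halving the sample count roughly triples the drift.

Global alignment chains the pairwise transforms; a failed pair flags all
downstream views unaligned.  Loop closure is explicitly out of scope.

## Markers, fitting, grid, labels

Classification uses two rotated ellipses in (r, g) with squared spreads;
ties go to red.  Lifting locates the uv triangle containing each marker
pixel (nearest-centroid candidates, barycentric test) and interpolates the
3D position and normal.  The opposite-color filter keeps red points with a
blue neighbour within the clip-head radius (9 mm) and blue points with a
red neighbour within the rim width (3 mm).  Clustering is HDBSCAN with
minimum cluster size max(count(red)/(4·N_clip), 20), minimum samples 20,
and a split-stopping distance equal to the clip-head radius.

The dominant cluster normal is the first right singular vector of the
normal bundle, sign-fixed toward the mean normal (ambiguous opposing
bundles raise an error).  The disk/ring fit minimizes, over X with
L-BFGS-B from the centroid (bounds ±4 head radii), the blue deviation from
the disk radius, the red excess beyond it, and the out-of-plane offset.
Clips split by cable shadows are re-joined when either piece has a
red/blue ratio outside (1/3, 3), the pieces' centroids lie within one head
diameter, and ≥ 10 points of each have their nearest out-of-cluster
neighbour in the other; the model is then fitted to the larger piece.

Grid construction estimates the mean 9-NN spacing x̄ (far-off centres are
excluded from the estimate but stay in the set — they become singles),
triangulates with an empty-ball criterion at radii x̄/2 and x̄ (a triple is
accepted when a ball of that radius resting on it contains no other
centre — the surface a pivoting ball would reach), collapses centres
closer than (2/3)·head-radius onto the larger cluster, and normalizes the
two largest connected meshes by diagonal edge swaps.  The frontal patch is
the one with the smaller mean y.  Rows are unions over horizontal edges,
where "horizontal" additionally requires |Δz| within half the vertical
grid pitch so lattice diagonals never merge adjacent rows.  Numbering:
frontal bottom-right → top-left ascending; dorsal continues top-right →
bottom-left.  Singles: lowest centre is LL; the outermost upper centres on
the correct side of the x-midline are RA/LA; the remaining two are the
right-side auxiliaries, front before back by y.

Marker geometry defaults — disk radius 6 mm, rim width 3 mm, 3 mm head
protrusion — are config values; the clip's physical dimensions are not
published.

## Calibration

Masked, properly exposed chromaticities accumulate into a 256×256 (r, g)
histogram, median-filtered 7×7.  Bins above mean + 1.9 sd of the nonzero
bins are labeled 4-connectedly; regions of ≥ 5 bins are peaks.  A
full-covariance Gaussian mixture initialized at the peak centroids is
fitted to the samples (fixed seed); the component with maximal mean r is
red, the one maximizing 1−r−g is blue, further components (highlights, raw
conversion artifacts) are discarded.  Spreads are the square roots of the
covariance eigenvalues and the angle maps the major axis onto the red
axis, matching the classification form exactly.  Note the 7×7 median
filter suppresses any color blob narrower than about four bins; a usable
calibration set needs enough chromaticity spread and pixel count per
color, which a handful of views of ~67 clips provides.

## Synthetic validation scenes

The generator emulates the recording conditions end to end: an elliptic
cylinder torso (rx = 160, ry = 110, height 600 mm) with smooth anatomical
relief — named features (spine groove, scapulae, pectorals, belly, waist)
plus a fixed pseudo-random field of centimetre-scale blobs standing in for
ribs and musculature.  The fine relief is not cosmetic: on a smooth
convex side surface, consecutive views can slide tangentially within the
depth noise and pairwise registration becomes ill-posed, exactly as it
would on a featureless mannequin.  Marker clip heads are flat disks
raised 3 mm above the skin and are ray-cast *exactly* (ray/disk-plane
intersection); an approximate depth offset would warp the bump field
view-dependently and bias the registration.

Views are rendered analytically (Newton refinement of the ray/implicit
surface intersection to < 0.01 mm): a 180×240 depth image (focal 208 px;
about 2.2 mm/px at the torso) and a 360×480 color image from a sensor
offset 25 mm laterally, so occlusion removal is exercised.  Depth gets
Gaussian noise (default 1 mm) and millimetre quantization; rays beyond
~80° incidence return no depth (infrared dropout); a gray room wall
(radius 900 mm, chromaticity jittered around the neutral point) surrounds
the torso and feeds the white-balance loop.  Per-view illuminants draw
uniformly from 2800–8500 K and are applied through the gain model, with
the recorded setting clamped to the physical 2500–6500 K range.  The
default 67-electrode layout is a 32-pad frontal patch (8×4), a 30-pad
dorsal patch (6×5), RA/LA at the shoulder fronts, LL at the left hip and
two right-side auxiliaries, all placed to respect the real layout's
separations (singles well clear of the patch lattice) and the camera's
vertical field of view.

These scenes do **not** emulate: breathing or postural motion, cloth,
specular skin highlights, cables and their shadows (the opposite-color
filter and split-merge logic are tested on constructed cases instead),
multi-illuminant scenes, or sensor-specific depth artifacts beyond
Gaussian noise plus quantization.  Passing the synthetic recovery
therefore demonstrates the geometric/color chain at realistic noise, not
robustness to every clinical nuisance.

Default scene sizes (14 views, 180×240 depth, 12 000 ICP samples) were
chosen so a full validation runs in minutes on one CPU while the recovered
accuracy sits in the same ~1–2 mm regime the hardware's depth quantization
permits.  Scene-to-scene variation (different illuminant/noise draws)
moves the mean recovered error between about 1 and 2.6 mm, driven mostly
by accumulated registration drift; the generator's default seed (1234)
yields ≈ 1 mm.  Evaluation matches electrodes by label and removes the
arbitrary global pose with a rigid Kabsch fit before computing residuals —
relative geometry, including chain drift, remains fully penalized.

## Known limitations

- Sequential pairwise chaining accumulates drift; the paper's protocol
  (and this implementation) has no loop closure by design.
- The shoulder-median yaw initializer is biased on partial arcs; the
  multi-start fan compensates but a pathological pair could still lock
  onto a clip-lattice-shifted minimum.
- The disk/ring objective measures blue deviation from the *disk* radius;
  with blue points spread over the rim width, a half-occluded ring biases
  the fitted centre by up to ~2 mm (full rings are unbiased by symmetry).
- Gray-gamut white balancing requires near-neutral content in view.
- The exposure controller assumes a brightness *distribution* on the
  patient; on a perfectly uniform surface its skewness score saturates at
  ±1 and it oscillates around mid-gray instead of settling.
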