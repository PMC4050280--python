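# Methods

`memtomo` implements the computational chain for determining the
oligomeric state and membrane orientation of an elongated membrane
fusogen from cryo-electron tomograms of protein-decorated vesicles:
synthetic ground-truthed tomogram generation, particle picking,
constrained iterative subtomogram alignment and averaging with Fourier
shell correlation, membrane-referenced orientation and packing
statistics, rigid plus hinge-restricted flexible fitting of a
multi-domain atomic model, and emPAI-based relative protein abundance.

## Conventions

Positions are in Å; voxel `(i,j,k)` is centred at
`origin + (index + 0.5) * voxel_size`. Orientations are intrinsic Z-Y-Z
Euler triplets in degrees; the rotation takes the template (reference)
frame into the tomogram frame. Density is dark: protein and membrane are
negative on a zero background, so particle picking is a local *minima*
search and isosurface thresholds select voxels at or below a level. Maps
are MRC2014 mode 2 with the pixel size in the cell dimensions.

## Synthetic scenes

The generator emulates the statistical structure the analysis rests on,
not image formation in full:

* **Protein phantom** — an ellipsoidal head (cross-section 60 x 40 Å,
  axial extent half the total length) on a cylindrical tail (radius
  10 Å), 130 Å long, anchored at the template origin with the long axis
  along +z. Edges are anti-aliased by coverage weighting. The interior
  volume (~103,000 Å^3) is close to the ~87,000 Å^3 expected for the
  monomer's molecular weight, so volume-thresholded isosurfaces enclose
  most of the phantom.
* **Scene** — anchors uniform on a sphere under a hard-core
  centre-to-centre constraint (default 100 Å) by rejection sampling
  (capped at 10,000 attempts per particle, with an explicit capacity
  error reporting the achieved count). Long axes are tilted from the
  outward normal by a Gaussian truncated to [0°, 90°) (default
  33° ± 17°) about a uniform tangent azimuth. The default vesicle radius
  is 1000 Å: with 500 particles this gives ~31% surface coverage, safely
  below the ~55% jamming limit of random sequential adsorption while
  keeping the neighbour spacing near the hard core, i.e. a densely but
  not pathologically packed layer. Ground-truth tilt and azimuth are
  recorded per particle.
* **Tomogram** — membrane as a dark spherical shell (45 Å thick; an
  optional flag renders two leaflet sub-shells), particles resampled at
  their poses by trilinear interpolation; a ±60° single-axis missing
  wedge applied as a hard Fourier mask (the wedge filter is treated as
  the sole reconstruction anisotropy); additive white Gaussian noise
  with variance = signal variance over the nonzero support / SNR.
  The default SNR of 0.5 is a moderate regime: per-voxel noise is about
  1.4x the protein contrast, while the ~200-voxel particle footprint
  still supports reliable correlation alignment. Real tomograms add
  CTF, dose-dependent damage and reconstruction artefacts that the
  generator does not model, so passing tests demonstrate the pipeline's
  statistical behaviour, not instrument-level realism.

`make_synthetic_chain` builds a small three-domain backbone model used
to validate the fitting operations with constructed hinge rotations and
residue-pair distances.

## Picking

Picking runs on a binned (default 2x for 7.6 Å voxels; 4x is the
natural choice at 3.8 Å), Gaussian-filtered (sigma 1 binned voxel)
tomogram. The vesicle sphere is fitted first (algebraic least squares on
shell samples, then geometric refinement); the sphere stands in for a
manual membrane segmentation. Each vesicle's rotationally symmetric
density (radial mean profile) is then subtracted before the minima
search: the membrane shell's noise ripple and wedge-induced angular
residuals otherwise dominate the minima, whereas the protein layer's
anisotropic part survives subtraction. Candidates are strict
26-neighbourhood minima below `mean - 2 SD` (whole-map statistics),
restricted to a 40-150 Å band above the membrane surface (the protein
layer; the inner bound excludes shell residuals), then non-maximum
suppressed (keep-deepest within 50 Å). Each detection is finally snapped
to its membrane anchor — the deepest membrane-band point nearby, where
tail and shell densities add — first on the binned map, then on a
lightly smoothed full-resolution map. Boxes are therefore anchor-centred
and initial orientations are the outward membrane normals.

## Alignment and averaging

Alignment is a deterministic angular grid search about each particle's
pose (delta rotations on cone rings crossed with in-plane spins; the
identity is always a candidate and ties go to the first candidate in
scan order) combined with a windowed FFT translation search, against a
reference re-averaged after every iteration. Three measures proved
necessary for an unbiased bootstrap from membrane-normal starting
orientations and are applied throughout:

* **Membrane subtraction** (above) — the symmetric vesicle density
  carries no pose information but biases the masked correlation of
  tilted particles toward the membrane-locked pose.
* **Wedge-compensated correlation** — each particle's comparison is
  restricted to the Fourier region its tilt range actually sampled
  (the pose-rotated wedge support), with per-candidate normalization
  over that region; without it orientations drift toward the common
  wedge direction.
* **Membrane anchoring** — after each iteration the collective rotation
  of the consensus frame away from the membrane-normal frame (chordal
  mean of the pose-relative-to-normal rotations, projected to SO(3)) is
  removed; the membrane is the external reference frame for tilt
  statistics and nothing else pins the consensus frame.

Stage A (five iterations) is translation-only (±4 Å) and unmasked: it
scores candidates against the global average and corrects small
centring errors while leaving the anchor-centred convention and normal
orientations intact. Duplicates closer than 80 Å keep the higher score.

Stage B (six iterations, angular half-ranges 30/20/15/10/6/4° with
steps of a third of the half-range, ±8 Å shifts, Gaussian reference
low-pass rising from 1/4 to 3/4 Nyquist) runs masked — a soft cylinder
(radius 60 Å, z from 10 to 145 Å, cosine edges) that excludes the
membrane slab and neighbouring particles — on the *full* deduplicated
candidate set. Running stage B on the full set is a deliberate
deviation from selecting first: with a few hundred particles at
moderate SNR the reference bootstrap is only stable above roughly three
hundred contributing particles; selecting first halves the set and the
refinement collapses into the membrane-normal attractor. Larger mask
radii admit neighbouring particles and inflate the orientation scatter;
smaller ones clip tilted heads and bias the tilt mean low; 60 Å
balances the two for a 100 Å-spaced layer. A residual 2-3° downward
bias of the recovered tilt mean remains, from the clipping of the most
strongly tilted heads.

Particles scoring above the mean correlation are then selected, split
even/odd by record index, and each half refined independently for three
further masked iterations (±10/6/4°) before the half-maps are rigidly
registered and their FSC computed (shells one Fourier voxel wide;
resolution at a threshold by linear interpolation of the first downward
crossing). Because the halves share the joint warm start, the FSC is a
consistency measure rather than a strictly independent gold-standard
estimate; full independence from the initial averages is unstable at
these particle counts (see above). The combined average uses all
selected particles and is low-pass filtered with a Gaussian fitted to
the FSC decay.

PCA classification (masked voxel vectors, k-means on the leading
component scores, fixed seed) is available for heterogeneity checks.

## Geometry statistics

Tilt is the angle between the particle's rotated long axis and the
outward sphere normal at its *anchor* — the axis traced back to the
membrane sphere (closest ray-sphere intersection; radial projection as
fallback) — not at its instantaneous centre. Azimuths are measured in a
deterministic tangent basis and tested for circular uniformity with the
Rayleigh statistic. Orientation statistics are reported over every
jointly aligned particle; selecting on correlation first would bias the
tilt distribution because strongly tilted particles score slightly
lower under any axial mask. Packing (nearest-neighbour centre-to-centre
distances, exact by k-d tree) is reported between the anchors of the
selected set. Volume thresholding picks the k-th darkest voxel so the
enclosed voxel-count volume matches the target within half a voxel;
extents are max-minus-min projections (plus one voxel, since voxels are
cubes) onto the principal axes of the largest 26-connected component,
with head cross-sections evaluated over the distal half when a membrane
direction is supplied.

## Model fitting

Model density is synthesized as mass-weighted dark Gaussians with
real-space SD `resolution / (2 pi sqrt 2)`. The CCC is the
about-the-mean correlation over the model's own footprint (|density| at
least 10% of its maximum); the choice is applied consistently to rigid
and flexible fitting. Rigid fitting is a grid search over rotations
about the model centroid and translations; zero ranges evaluate the
initial pose. Hinge-restricted flexible fitting alternately rotates
domains II and III as rigid bodies about their hinge pivots (midpoint
of the hinge residues' backbone atoms; hinge residues move with the
distal domain) on a shrinking rotation-vector grid, domain I fixed; the
zero rotation is always in the search space, so the flexible CCC can
never fall below the rigid one. No stereochemical regularization is
applied at the hinge junctions — validation is by CCC and recovered
angles, not geometry scores. Domain rotations between two conformations
are measured by superposing on the fixed domain's backbone and taking
the axis-angle magnitude of the residual moving-domain rotation
(invariant to global rigid motion; exact on constructed rotations).
Bilayer placement fits two Gaussians to the radial mean-density profile
and reports the leaflet peak radii and separation.

## Relative abundance

`empai = 10^(observed/observable) - 1`; the relative abundance of a
protein within one preparation is its emPAI as a percentage of the sum
over detected proteins (not-detected entries are excluded, not zeroed).
Reported integers round half-up; full precision is retained. The
packaged vesicle-proteomics table reproduces the AFF-1 preparation's
printed integer percentages exactly; in the EFF-1 preparation two
printed values are arithmetically inconsistent with any single
normalization of the printed emPAI values (they bound the denominator
on opposite sides), indicating they were derived from unrounded inputs;
the computed column matches the other eleven exactly and those two
within one point.

## Problem sizes and determinism

The shipped study conditions — one 1000 Å vesicle with 500 particles
(orientation statistics and packing) and one 800 Å vesicle with 300
particles (map metrology) at 7.6 Å voxels, box 40 voxels — were chosen
so a full chain runs in minutes on one CPU while keeping surface
coverage and spacing in the regime the analysis assumes. All
randomness flows from a single seed fanned out per stage
(`seed * 100 + stage counter`); identical config and seed give
identical tables and maps.

## Known limitations

* The wedge filter is the only reconstruction anisotropy modelled; no
  CTF, dose weighting or alignment errors of the tilt series.
* Spherical membranes only; tubular geometries are out of scope.
* The FSC after a joint warm start is a consistency measure, not a
  strictly independent half-set estimate (see above).
* The minimum nearest-neighbour distance is an extreme-value statistic:
  a single residual false pick or localization error shortens it, so it
  is reported alongside the median.
* Flexible fitting ignores stereochemistry at hinge junctions; fitted
  models are for interpretation at subnanometre-to-nanometre scale, not
  refinement.
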