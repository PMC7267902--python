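# Methods

## Problem and representations

A tractogram is an ordered list of streamlines; each streamline an ordered
polyline of 3-D points in world millimetres (RAS+), tied to a reference
voxel grid (shape + 4×4 affine, the pair a NIfTI header carries).  A
rater's bundle is modelled as a *selection*: a strictly increasing set of
indices into the parent tractogram.  This is well defined because every
rater in the supported study design segments the *same* parent dataset;
streamline identity is index identity.

Bundles returned as TRK/TCK files lose index information, so they are
resolved back to parent indices by coordinate identity: same point count,
same order, every point within a tolerance (default 1e-3 mm).  The fast
path hashes coordinates rounded to the tolerance lattice (O(n) overall); a
streamline whose float32-quantized coordinates straddle a rounding
boundary falls back to a tolerance scan over same-point-count candidates.
Duplicate geometries (identical streamlines do occur in tractograms) are
claimed greedily, lowest unclaimed parent index first — deterministic and
independent of bundle file order.  Any unmatched streamline is an error
reporting the failure count; nothing is dropped silently.

The voxel representation derives from selections: a **density map** counts
per voxel the number of *distinct* selected streamlines touching it (a
streamline contributes at most 1 per voxel), and a **binary mask** is its
support.  Two notions of "touches" are provided:

- `points`: a sampled point lies in the voxel.  This reproduces the
  didactic point-based construction exactly, but undercounts on
  sparsely-sampled (compressed) streamlines.
- `segments` (default): the polyline intersects the voxel cube, computed by
  exact Amanatides–Woo 3-D grid traversal of every segment (numba-jitted).

Voxel convention: centers at integer voxel coordinates, voxel *i* spanning
[i−0.5, i+0.5) per axis; a world point maps to `floor(inv(A)·x + 0.5)`.
Out-of-grid points clip silently (a count of fully out-of-grid streamlines
is logged): the flip/translate duplication can push edge voxels out, and
hard failure would be brittle.

## Measures

Pairwise: Dice 2|A∩B|/(|A|+|B|) and Jaccard |A∩B|/|A∪B| over either
universe; the identity D = 2J/(1+J) is property-tested.  Two empty inputs
score 1 (perfect agreement on nothing), empty vs non-empty 0 — this keeps
Dice(a,a)=1 unconditionally.  Density-map Pearson correlation is computed
over the union of the two supports by default (full-grid correlation is
inflated by the shared zeros; the support is configurable, including an
explicit mask).  Degenerate supports raise an explicit undefined-measure
error, never a silent NaN.

Against a vote-built average segmentation, confusion counts use as default
universe *all* streamlines of the parent (or all grid voxels) — with ~1e5+
elements and thousands selected, true negatives dominate, specificity and
accuracy sit near 1, and Cohen's κ = (p_o − p_e)/(1 − p_e) converges to
the Dice coefficient (the TN→∞ limit is asserted to <1e-3 at TN=1e6).
κ uses p_o = accuracy and p_e = ((TP+FP)(TP+FN)+(FN+TN)(FP+TN))/total².
Alternative universes are selectable because the TN/TP ratio differs
between representations.  Per-metric zero denominators are flagged
undefined rather than raising.

Bundle descriptives: streamline count; volume = support-voxel count ×
voxel volume, reported in cm³ (segments-mode voxelization by default);
mean polyline arc length in mm; mean scalar (e.g. FA) over support voxels,
unweighted by default with density weighting optional.

## Consensus

A vote map assigns each element the number of raters whose segmentation
contains it; thresholding at votes ≥ k yields the consensus.  k=1 is
exactly the union, k=N the intersection, and the thresholded sets nest
monotonically in k.  Ratio thresholds convert via ceil(r·N), so r=0.5 with
N=11 gives the 6-of-11 majority rule.  The streamline and voxel consensus
are built independently — the voxel consensus thresholds votes of the
per-rater masks, *not* the mask of the streamline consensus (raters can
share volume while sharing no streamlines).  Outputs are labelled
"average segmentation": the consensus is the raters' central tendency, not
ground-truth anatomy.  For the study harness the voxel votes use each
rater's fused-triplicate mask (one vote per rater, not per replicate).

## Blinded triplication harness

Each subject's tractogram is triplicated: untouched; mirrored about the
grid mid-X plane (voxel i → Nx−1−i, applied as a world-space affine whose
matrix square is exactly the identity); rigidly translated by whole voxels
(default (4,4,0)).  Copies get seeded random hex names; the manifest
stores the bijection name ↔ (subject, variant), the forward 4×4 transform
per copy (CSV + JSON sidecar) and the seed.  De-randomization inverts the
transform and resolves indices against the original parent; missing or
extra result files raise a reconciliation error listing the names.

Exactness: phantom coordinates are quantized to float32 values (exactly
what TRK/TCK storage imposes anyway).  For unit-spacing grids with integer
transform parameters, double-precision application of flip/translate and
their inverses is then bit-exact, so harness round trips recover planted
index sets with no tolerance at all.

Scoring: intra-rater compares the 3 unordered replicate pairs per subject
(5 subjects → 15 values per rater and measure); inter-rater first fuses
each rater's triplicates — union by default ("fused" is interpreted as
union to retain all evidence; majority-of-3 and intersection are
selectable) — then compares fused bundles across all rater pairs, each
rater's score averaging its N−1 comparisons (self-comparison excluded);
gold scores compare each fused bundle to the per-subject expert-vote
average segmentation, including classification metrics in both
representations.  Hemispheres are pooled into one distribution per measure
(the table keeps a hemisphere column for finer breakdowns).  Left/right
mirroring symmetry is what licenses the X-flip blinding.

Statistics: distributions are reported as median and IQR with
linear-interpolation quartiles (stated so results are bit-reproducible).
Group comparison is a two-sided Mann–Whitney U test: for n,m ≤ 8 the null
distribution of U is enumerated exactly over all C(n+m,n) assignments of
the observed (tie-aware) values, with two-sided p = P(min(U, nm−U) ≤
min(u_obs, nm−u_obs)) — identical samples give p = 1; larger samples use
the tie-corrected normal approximation.  The significance threshold
defaults to 0.01.  A per-rater intra-vs-inter Pearson correlation is
provided to ask whether self-consistent raters also agree with others.

## Synthetic phantoms and raters

`make_phantom` builds a vertically coherent, gently bending and fanning
tube of core streamlines through the grid center (offsets uniform over the
tube cross-section, default radius 2 voxels, fan factor 2× at the top,
smooth per-point jitter), plus distractors alternating between displaced
off-bundle tubes and horizontal streamlines crossing the core.  Defaults
(32³ grid at 1 mm, 10²–10³ streamlines, 24 points each) keep any test or
script run in seconds; counts scale to ~1e5 to approximate a realistic
hemisphere tractogram.  The core support forms a single 26-connected
component (tested).

The default rater model is independent Bernoulli: each core streamline
kept with probability p, each distractor picked up with probability q.
Independence gives closed forms used for calibration: the expected
pairwise streamline Dice of two raters at q=0 is exactly p, and after
3-replicate union fusion 1−(1−p)³; raising q lowers precision against the
core without touching sensitivity.  A spatially correlated `RoiJitterRater`
(jittered selection plane and radius — one local decision moving many
streamlines) is provided for realism but has no closed form.  The
deterministic `robot_rater` selects streamlines crossing a plane placed
relative to the dataset's own bounding box, symmetric in x, so it commutes
with flip/translation — the end-to-end identity oracle of the harness.

Simulated studies default to 5 subjects × 3 variants (15 blinded datasets
per rater) with 11 experts (p=0.9, q=0.01) and 13 nonexperts (p=0.9,
q=0.10): equal keep probability, differing spurious rate, which reproduces
the qualitative real-world signature — nonexperts produce larger bundles
with lower precision against the expert consensus while sensitivity stays
high.  All seeds derive from a single master seed via `SeedSequence`
spawning; identical seeds give bit-identical score tables.

What the simulator does *not* emulate: anatomically realistic bundle
geometry, spatially correlated rater errors as the default, rater drift
over time, registration error, or tractography variability.  Passing tests
therefore validate the *measurement machinery* — measures, consensus,
blinding round trips, statistics — not any claim about human rater
behaviour on real data.

## Numerical choices and limitations

- Resolution tolerance 1e-3 mm (well above float32 storage jitter, far
  below inter-streamline distances); TRK affine consistency checked at
  1e-3 (float32 headers), NIfTI affines at 1e-5.
- Acceptance-style simulations use n_core = 1000 with 30 seed pairs per
  keep probability, and a 5×(11+13) study at n_core = 300 — sizes chosen
  to make Monte-Carlo error comfortably smaller than the 0.02 calibration
  band while keeping runs in seconds.
- Voxel-grid traversal tie-breaks: points exactly on a voxel boundary
  belong to the higher voxel (half-open cubes); traversal steps are capped
  by the Manhattan distance between end voxels.
- Bundles whose parents differ, mixed grids, out-of-universe elements and
  empty-input statistics all raise typed errors instead of propagating
  NaNs.
- Streamline-wise measures require bundles drawn from the *same* parent;
  comparing bundles across subjects or tractography runs needs
  distance-based measures that are out of scope here.
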