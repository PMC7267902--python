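"""Synthetic phantoms and simulated raters.

Real reproducibility studies need whole-brain tractograms and many human
raters; for testing and calibration this module builds the whole study
in silico:

- :func:`make_phantom` generates a parent tractogram containing a known
  "true" bundle — a spatially coherent, gently fanning vertical tube of
  streamlines (loosely evoking a pyramidal-tract shape) — plus off-bundle
  and crossing distractor streamlines.
- :func:`simulate_rater` draws a rater's selection from a Bernoulli error
  model: each true-bundle streamline is kept with probability ``p`` and
  each distractor picked up with probability ``q``, independently.  The
  independence gives closed-form expectations (e.g. the expected pairwise
  streamline Dice of two raters at spurious rate q=0 is exactly ``p``),
  which the test-suite uses for parameter recovery.
- :class:`RoiJitterRater` is a spatially correlated alternative: the rater
  "draws" an axial selection plane whose position and radius jitter, and
  keeps the streamlines crossing it.  More realistic error structure, no
  closed form.
- :func:`robot_rater` is a deterministic coordinate-defined segmenter whose
  criterion depends only on the dataset's own bounding box; it returns the
  same bundle on the original, flipped and translated copies, which makes
  it the end-to-end identity oracle for the blinded harness.
- :func:`simulate_study` wires it all together: phantoms per subject,
  blinded triplicates, simulated raters in two groups, and the anonymized
  bundle files the study harness expects.

All phantom coordinates are quantized to float32 values (as tractogram
files store them), which also makes the integer-voxel rigid transforms of
the harness exactly invertible in double precision.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ReferenceGrid
from .study_harness import StudyManifest, make_triplicates
from .tract_io import Selection, Tractogram, subset_tractogram

__all__ = [
    "PhantomTruth", "RaterModel", "RoiJitterRater",
    "make_phantom", "simulate_rater", "robot_rater", "simulate_study",
    "StudyData",
]


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of a phantom: which parent indices form the true bundle
    (core) and which are clutter (distractors).  Core and distractors
    partition the parent tractogram."""

    core: Selection
    distractors: Selection
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RaterModel:
    """Independent Bernoulli rater error model."""

    keep_prob: float          # P(core streamline selected)
    spurious_prob: float = 0.0  # P(distractor selected)
    seed: int | None = None

    def __post_init__(self):
        for name in ("keep_prob", "spurious_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


def _quantize(a: np.ndarray) -> np.ndarray:
    return a.astype(np.float32).astype(np.float64)


def _smooth_noise(rng, n, scale):
    """Smooth per-point jitter: random walk minus its linear trend."""
    w = np.cumsum(rng.normal(0.0, scale, size=n))
    t = np.linspace(0.0, 1.0, n)
    return w - w[0] - t * (w[-1] - w[0])


def make_phantom(n_core: int = 200, n_distractor: int = 100,
                 grid: ReferenceGrid | None = None, seed: int = 0,
                 tube_radius: float = 2.0, fan: float = 1.0,
                 n_points: int = 24, id: str | None = None):
    """Phantom tractogram with a known coherent bundle.

    Core streamlines run bottom-to-top through the grid center, offset
    radially within ``tube_radius`` (voxels) and fanning out toward the top
    by a factor ``1 + fan``.  Distractors alternate between displaced
    off-bundle tubes and horizontal streamlines crossing the core.  Returns
    ``(tractogram, truth)``; deterministic given ``seed``.
    """
    if n_core < 0 or n_distractor < 0:
        raise ValueError("counts must be non-negative")
    if grid is None:
        grid = ReferenceGrid.isotropic((32, 32, 32))
    if min(grid.shape) < 20:
        raise ValueError(f"grid {grid.shape} too small for the phantom; "
                         "need >= 20 voxels per axis")
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    z0, z1 = 2.5, nz - 3.5
    z = np.linspace(z0, z1, n_points)
    u = (z - z0) / (z1 - z0)
    bend = 1.5 * np.sin(np.pi * u / 2.0)       # gentle anterior bend

    streamlines = []
    for _ in range(n_core):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        # uniform over the tube cross-section: bounded offsets keep the
        # core support one connected component even at small n
        r = tube_radius * np.sqrt(rng.uniform())
        spread = 1.0 + fan * u                  # fan opens toward the top
        ox = r * np.cos(theta) * spread + _smooth_noise(rng, n_points, 0.15)
        oy = r * np.sin(theta) * spread + _smooth_noise(rng, n_points, 0.15)
        vox = np.column_stack([cx + bend + ox, cy + oy, z])
        streamlines.append(vox)

    for j in range(n_distractor):
        if j % 2 == 0:
            # displaced off-bundle tube near a lateral border
            side = 1.0 if (j // 2) % 2 == 0 else -1.0
            dx = side * (cx - 4.0) + rng.normal(0.0, 1.0)
            dy = rng.normal(0.0, 2.0)
            ox = _smooth_noise(rng, n_points, 0.3)
            oy = _smooth_noise(rng, n_points, 0.3)
            vox = np.column_stack([cx + dx + ox, cy + dy + oy, z])
        else:
            # horizontal streamline crossing the core left-right
            zc = rng.uniform(z0 + 2.0, z1 - 2.0)
            y_line = np.linspace(2.5, ny - 3.5, n_points)
            vox = np.column_stack([
                np.full(n_points, cx + rng.normal(0.0, 2.0))
                + _smooth_noise(rng, n_points, 0.3),
                y_line,
                np.full(n_points, zc) + _smooth_noise(rng, n_points, 0.3)])
        streamlines.append(vox)

    world = []
    lo = np.array([0.0, 0.0, 0.0]) - 0.4
    hi = np.asarray(grid.shape, float) - 0.6
    for vox in streamlines:
        vox = np.clip(vox, lo, hi)              # keep everything in-grid
        world.append(_quantize(grid.voxel_to_world(vox)))

    tid = id or f"phantom-{seed}"
    parent = Tractogram(world, grid, tid)
    truth = PhantomTruth(
        Selection(tid, np.arange(n_core, dtype=np.int64)),
        Selection(tid, np.arange(n_core, n_core + n_distractor,
                                 dtype=np.int64)),
        params={"n_core": n_core, "n_distractor": n_distractor, "seed": seed,
                "tube_radius": tube_radius, "fan": fan, "n_points": n_points})
    return parent, truth


def simulate_rater(truth: PhantomTruth, model: RaterModel,
                   seed: int | None = None) -> Selection:
    """Draw one rater's selection under the Bernoulli error model."""
    s = seed if seed is not None else model.seed
    rng = np.random.default_rng(s)
    keep_core = truth.core.indices[
        rng.random(len(truth.core)) < model.keep_prob]
    keep_spur = truth.distractors.indices[
        rng.random(len(truth.distractors)) < model.spurious_prob]
    return Selection(truth.core.parent_id,
                     np.concatenate([keep_core, keep_spur]))


@dataclass(frozen=True)
class RoiJitterRater:
    """Spatially correlated rater: selects streamlines crossing a jittered
    axial plane within a jittered radius of the plane's bundle centroid.
    Mimics ROI-placement error (one local decision moving many streamlines
    at once); has no closed-form score expectations."""

    z_frac: float = 0.5
    radius: float = 6.0       # mm
    z_jitter: float = 1.5     # mm, sd of plane-position error
    radius_jitter: float = 1.0  # mm, sd of radius error

    def segment(self, t: Tractogram, seed: int) -> Selection:
        rng = np.random.default_rng(seed)
        pts = np.vstack(t.streamlines)
        zmin, zmax = pts[:, 2].min(), pts[:, 2].max()
        zc = zmin + self.z_frac * (zmax - zmin) + rng.normal(0.0, self.z_jitter)
        rad = max(0.5, self.radius + rng.normal(0.0, self.radius_jitter))
        hits = _crossing_indices(t, zc, rad)
        return Selection(t.id, hits)


def _crossing_indices(t: Tractogram, zc: float, radius: float) -> np.ndarray:
    """Streamlines crossing plane z=zc within `radius` of the in-plane
    centroid of all crossing points (symmetric in x and y, so invariant
    under flips/translations of the whole dataset)."""
    crossing = []
    xy = []
    for i, s in enumerate(t.streamlines):
        dz = s[:, 2] - zc
        sign_change = np.nonzero(dz[:-1] * dz[1:] <= 0)[0]
        if sign_change.size == 0:
            continue
        k = sign_change[0]
        denom = s[k + 1, 2] - s[k, 2]
        frac = 0.5 if denom == 0 else (zc - s[k, 2]) / denom
        p = s[k] + frac * (s[k + 1] - s[k])
        crossing.append(i)
        xy.append(p[:2])
    if not crossing:
        return np.empty(0, np.int64)
    xy = np.asarray(xy)
    center = xy.mean(axis=0)
    d = np.linalg.norm(xy - center, axis=1)
    return np.asarray(crossing, np.int64)[d <= radius]


def robot_rater(t: Tractogram, z_frac: float = 0.5,
                radius: float = 6.0) -> Selection:
    """Deterministic coordinate-defined segmenter.

    Selects streamlines crossing the axial plane at fraction ``z_frac`` of
    the dataset's own z-extent, within ``radius`` mm of the crossing-point
    centroid.  Because the criterion is relative to the data and symmetric
    in x, it commutes with the harness's flip and translation: the robot
    segments "the same bundle" on every blinded variant.
    """
    pts = np.vstack(t.streamlines) if len(t) else np.zeros((1, 3))
    zmin, zmax = pts[:, 2].min(), pts[:, 2].max()
    zc = zmin + z_frac * (zmax - zmin)
    return Selection(t.id, _crossing_indices(t, zc, radius))


# ---------------------------------------------------------------------------
# Full simulated study
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Everything the study harness consumes, generated in silico."""

    parents: dict             # subject -> original Tractogram
    truths: dict              # subject -> PhantomTruth
    grid: ReferenceGrid
    manifest: StudyManifest   # merged over subjects
    datasets: dict            # anon name -> blinded Tractogram
    rater_bundles: dict       # rater -> {anon name -> bundle Tractogram}
    groups: dict              # rater -> "expert" | "nonexpert"

    def collect(self, tol: float = 1e-3):
        """De-randomize every rater's bundles into RaterResults."""
        from .study_harness import deanonymize
        return [deanonymize(self.rater_bundles[r], self.manifest,
                            self.parents, r, group=self.groups[r], tol=tol)
                for r in sorted(self.rater_bundles)]


def simulate_study(n_subjects: int = 5, n_experts: int = 11,
                   n_nonexperts: int = 13,
                   expert_model: RaterModel = RaterModel(0.9, 0.01),
                   nonexpert_model: RaterModel = RaterModel(0.9, 0.10),
                   seed: int = 0, n_core: int = 200, n_distractor: int = 100,
                   grid: ReferenceGrid | None = None,
                   translation=(4, 4, 0)) -> StudyData:
    """Simulate the full blinded study.

    Per subject: a phantom and its three anonymized variants (so 5 subjects
    give each rater a 15-dataset task list).  Per rater and blinded dataset:
    a Bernoulli selection drawn with a fresh seed, returned as a bundle
    tractogram in the blinded copy's coordinates — exactly what a rater
    would send back.  Deterministic given ``seed``.
    """
    if n_subjects < 1 or n_experts + n_nonexperts < 2:
        raise ValueError("need >= 1 subject and >= 2 raters")
    root = np.random.SeedSequence(seed)
    subj_seeds, trip_seeds, rater_root = root.spawn(3)
    subj_children = subj_seeds.spawn(n_subjects)
    trip_children = trip_seeds.spawn(n_subjects)

    parents, truths, datasets = {}, {}, {}
    manifest = None
    for i in range(n_subjects):
        subject = f"subject-{chr(ord('A') + i)}" if i < 26 else f"subject-{i}"
        p, t = make_phantom(n_core=n_core, n_distractor=n_distractor,
                            grid=grid, id=subject,
                            seed=int(subj_children[i].generate_state(1)[0]
                                     % (2 ** 31)))
        parents[subject], truths[subject] = p, t
        ds, mf = make_triplicates(
            p, translation=translation, subject=subject,
            seed=int(trip_children[i].generate_state(1)[0] % (2 ** 31)))
        datasets.update(ds)
        manifest = mf if manifest is None else manifest.merge(mf)

    raters = ([(f"expert-{i+1:02d}", "expert", expert_model)
               for i in range(n_experts)]
              + [(f"nonexpert-{i+1:02d}", "nonexpert", nonexpert_model)
                 for i in range(n_nonexperts)])
    rater_children = rater_root.spawn(len(raters))
    rater_bundles, groups = {}, {}
    for (rater, group, model), rseq in zip(raters, rater_children):
        groups[rater] = group
        task_seeds = rseq.spawn(len(datasets))
        bundles = {}
        for (name, blinded), tseq in zip(sorted(datasets.items()), task_seeds):
            entry = manifest.lookup(name)
            truth = truths[entry.subject]
            # the rater "works on" the blinded copy: draw indices from the
            # truth, then hand back the blinded copy's streamlines
            sel = simulate_rater(
                truth, model,
                seed=int(tseq.generate_state(1)[0] % (2 ** 31)))
            blinded_sel = Selection(blinded.id, sel.indices)
            bundles[name] = subset_tractogram(blinded, blinded_sel,
                                              new_id=f"{name}:bundle")
        rater_bundles[rater] = bundles
    return StudyData(parents, truths, parents[next(iter(parents))].grid,
                     manifest, datasets, rater_bundles, groups)
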