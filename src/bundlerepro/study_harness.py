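"""Blinded triplication study machinery and reproducibility statistics.

Study design being emulated: each subject's tractogram is *triplicated* —
one copy untouched, one mirrored about the grid's mid-X plane (left/right
flip), one rigidly translated by a whole number of voxels.  All copies get
random names so raters segment them blindly, unaware of the duplication.
Afterwards the manifest de-randomizes the returned bundles: each is mapped
back to its (subject, variant), the rigid transform is inverted, and the
bundle is resolved to streamline indices of the original parent.

Scores follow the triplication logic:

- *intra*-rater: all 3 unordered replicate pairs per subject, so 5 subjects
  x 3 pairs = 15 values per rater and measure;
- *inter*-rater: each rater's three replicates are first fused (union by
  default) into one bundle per subject, to strip intra-rater noise, then
  fused bundles are compared across raters pairwise;
- *gold*: each rater's fused bundle against the vote-built average
  segmentation of the expert group.

Distributions are summarized as median and interquartile range; groups are
compared with a two-sided Mann-Whitney U test.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import GoldStandard
from .errors import StudyError, UndefinedMeasureError
from .grid import ReferenceGrid
from .measures import (classification_metrics, confusion, density_correlation,
                       dice, jaccard)
from .tract_io import Selection, Tractogram, resolve_selection
from .voxel_rep import binary_mask, density_map

__all__ = [
    "VARIANTS", "ManifestEntry", "StudyManifest", "RaterResult",
    "flip_transform", "translation_transform", "apply_transform",
    "make_triplicates", "deanonymize", "fuse_triplicates",
    "intra_rater_scores", "inter_rater_scores", "gold_scores",
    "per_rater_score", "summarize", "group_compare",
    "rater_score_correlation", "study_summary", "SummaryStats",
    "GroupComparison", "DEFAULT_MEASURES",
]

VARIANTS = ("original", "flipped", "translated")

DEFAULT_MEASURES = ("streamline_dice", "voxel_dice", "density_correlation")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def flip_transform(grid: ReferenceGrid) -> np.ndarray:
    """World-space affine mirroring about the grid's mid-X plane.

    In voxel coordinates the map is i -> Nx - 1 - i; composed with the grid
    affine it becomes an exact world-space involution (for integer-entry
    affines the matrix product flip @ flip is exactly the identity).
    """
    nx = grid.shape[0]
    m = np.eye(4)
    m[0, 0] = -1.0
    m[0, 3] = float(nx - 1)
    return grid.affine @ m @ np.linalg.inv(grid.affine)


def translation_transform(grid: ReferenceGrid, voxels) -> np.ndarray:
    """World-space rigid shift by a whole number of voxels per axis."""
    v = np.asarray(voxels, dtype=np.float64)
    if v.shape != (3,) or np.any(v != np.round(v)):
        raise ValueError(f"translation must be 3 whole voxel counts, got {voxels}")
    t = np.eye(4)
    t[:3, 3] = grid.affine[:3, :3] @ v
    return t


def apply_transform(t: Tractogram, transform: np.ndarray,
                    new_id: str | None = None) -> Tractogram:
    """Apply a 4x4 world-space affine to every streamline point."""
    T = np.asarray(transform, dtype=np.float64)
    lin, off = T[:3, :3], T[:3, 3]
    streamlines = [s @ lin.T + off for s in t.streamlines]
    return Tractogram(streamlines, t.grid, new_id or f"{t.id}:tx")


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    anon_name: str
    subject: str
    variant: str
    transform: np.ndarray     # forward world-space affine applied to the copy
    order: int                # position in the rater's task list


@dataclass
class StudyManifest:
    """Bijection anonymized name <-> (subject, variant) with the exact
    transforms needed to de-randomize."""

    entries: dict[str, ManifestEntry]
    seed: int

    def __post_init__(self):
        pairs = [(e.subject, e.variant) for e in self.entries.values()]
        if len(set(pairs)) != len(pairs):
            raise StudyError("manifest is not a bijection: duplicated "
                             "(subject, variant) pair")
        for subj in self.subjects():
            have = {e.variant for e in self.entries.values() if e.subject == subj}
            if have != set(VARIANTS):
                raise StudyError(f"subject {subj!r} has variants {sorted(have)}, "
                                 f"expected all of {VARIANTS}")

    def subjects(self) -> list[str]:
        return sorted({e.subject for e in self.entries.values()})

    @property
    def n_subjects(self) -> int:
        return len(self.subjects())

    def lookup(self, anon_name: str) -> ManifestEntry:
        try:
            return self.entries[anon_name]
        except KeyError:
            raise StudyError(f"anonymized name {anon_name!r} not in manifest")

    def merge(self, other: "StudyManifest") -> "StudyManifest":
        overlap = set(self.entries) & set(other.entries)
        if overlap:
            raise StudyError(f"duplicate anonymized names: {sorted(overlap)[:3]}")
        return StudyManifest({**self.entries, **other.entries}, self.seed)

    # CSV + JSON sidecar for the 4x4 transforms
    def to_csv(self, path, transforms_json=None) -> None:
        rows = []
        for e in sorted(self.entries.values(), key=lambda e: e.order):
            tx, ty, tz = e.transform[:3, 3]
            rows.append({"anonymized_name": e.anon_name, "subject": e.subject,
                         "variant": e.variant, "tx": tx, "ty": ty, "tz": tz,
                         "order": e.order})
        pd.DataFrame(rows).to_csv(path, index=False)
        if transforms_json is not None:
            side = {e.anon_name: e.transform.tolist()
                    for e in self.entries.values()}
            side["__seed__"] = self.seed
            with open(transforms_json, "w") as fh:
                json.dump(side, fh, indent=1)

    @classmethod
    def from_csv(cls, path, transforms_json) -> "StudyManifest":
        df = pd.read_csv(path)
        with open(transforms_json) as fh:
            side = json.load(fh)
        seed = int(side.pop("__seed__", 0))
        entries = {}
        for _, r in df.iterrows():
            name = str(r["anonymized_name"])
            entries[name] = ManifestEntry(
                name, str(r["subject"]), str(r["variant"]),
                np.asarray(side[name], dtype=np.float64), int(r["order"]))
        return cls(entries, seed)


def _anon_names(rng: np.random.Generator, n: int) -> list[str]:
    """UUID-like hex names from the seeded stream, collision-free."""
    names: set[str] = set()
    while len(names) < n:
        names.add("".join(f"{b:02x}" for b in rng.integers(0, 256, size=8)))
    return sorted(names)  # stable mapping given the seed


def make_triplicates(parent: Tractogram, translation=(4, 4, 0), seed: int = 0,
                     subject: str | None = None):
    """Triplicate one subject's tractogram: original / X-flip / translation.

    Returns ``(datasets, manifest)`` where ``datasets`` maps anonymized name
    -> transformed Tractogram.  Anonymized names and task order are drawn
    from a seeded RNG; the manifest records the exact forward transforms so
    :func:`deanonymize` can invert them.
    """
    rng = np.random.default_rng(seed)
    transforms = {
        "original": np.eye(4),
        "flipped": flip_transform(parent.grid),
        "translated": translation_transform(parent.grid, translation),
    }
    names = _anon_names(rng, 3)
    order = rng.permutation(3)
    datasets, entries = {}, {}
    subj = subject or parent.id
    for name, variant, pos in zip(names, VARIANTS, order):
        datasets[name] = apply_transform(parent, transforms[variant], new_id=name)
        entries[name] = ManifestEntry(name, subj, variant,
                                      transforms[variant], int(pos))
    return datasets, StudyManifest(entries, seed)


# ---------------------------------------------------------------------------
# De-randomization
# ---------------------------------------------------------------------------

@dataclass
class RaterResult:
    """One rater's de-randomized segmentations.

    ``selections`` maps (subject, variant) -> Selection on the subject's
    original parent tractogram."""

    rater: str
    group: str                # "expert" | "nonexpert"
    selections: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.selections})


def deanonymize(bundles: dict, manifest: StudyManifest,
                parents: dict, rater: str, group: str = "expert",
                tol: float = 1e-3, metadata: dict | None = None) -> RaterResult:
    """Map returned bundles back to (subject, variant) and parent indices.

    ``bundles`` maps anonymized name -> bundle Tractogram as segmented on
    the blinded copy; the inverse transform from the manifest is applied
    before resolving indices against ``parents[subject]``.  Missing or
    unexpected names raise a reconciliation error listing them.
    """
    missing = sorted(set(manifest.entries) - set(bundles))
    extra = sorted(set(bundles) - set(manifest.entries))
    if missing or extra:
        raise StudyError(f"result files do not reconcile with manifest: "
                         f"missing={missing} extra={extra}")
    result = RaterResult(rater, group, metadata=metadata or {})
    for name, bundle in bundles.items():
        entry = manifest.lookup(name)
        parent = parents[entry.subject]
        inv = np.linalg.inv(entry.transform)
        native = apply_transform(bundle, inv, new_id=f"{name}:native")
        result.selections[(entry.subject, entry.variant)] = \
            resolve_selection(parent, native, tol=tol)
    return result


def fuse_triplicates(r: RaterResult, subject: str,
                     method: str = "union") -> Selection:
    """Fuse a rater's three replicate selections of one subject into one
    bundle (union by default; "majority" keeps elements in >= 2 replicates,
    "intersection" in all 3)."""
    sels = []
    for variant in VARIANTS:
        if (subject, variant) not in r.selections:
            raise StudyError(f"rater {r.rater!r}: missing variant {variant!r} "
                             f"for subject {subject!r}")
        sels.append(r.selections[(subject, variant)])
    if method == "union":
        return sels[0].union(sels[1], sels[2])
    all_idx = np.concatenate([s.indices for s in sels])
    idx, cnt = np.unique(all_idx, return_counts=True)
    need = {"majority": 2, "intersection": 3}.get(method)
    if need is None:
        raise ValueError(f"unknown fusion method {method!r}")
    return Selection(sels[0].parent_id, idx[cnt >= need])


# ---------------------------------------------------------------------------
# Pairwise scoring
# ---------------------------------------------------------------------------

class _DensityCache:
    """Memoizes density maps/masks per selection key to avoid re-voxelizing."""

    def __init__(self, parents: dict, mode: str = "segments"):
        self.parents = parents
        self.mode = mode
        self._maps: dict = {}

    def density(self, key, subject: str, sel: Selection):
        if key not in self._maps:
            self._maps[key] = density_map(self.parents[subject], sel,
                                          mode=self.mode)
        return self._maps[key]

    def mask(self, key, subject, sel):
        return binary_mask(self.density(key, subject, sel))


def _score_pair(cache: _DensityCache, subject: str,
                key_a, sel_a: Selection, key_b, sel_b: Selection,
                measures) -> dict:
    out = {}
    for m in measures:
        if m == "streamline_dice":
            out[m] = dice(sel_a, sel_b)
        elif m == "streamline_jaccard":
            out[m] = jaccard(sel_a, sel_b)
        elif m == "voxel_dice":
            out[m] = dice(cache.mask(key_a, subject, sel_a),
                          cache.mask(key_b, subject, sel_b))
        elif m == "voxel_jaccard":
            out[m] = jaccard(cache.mask(key_a, subject, sel_a),
                             cache.mask(key_b, subject, sel_b))
        elif m == "density_correlation":
            try:
                out[m] = density_correlation(cache.density(key_a, subject, sel_a),
                                             cache.density(key_b, subject, sel_b))
            except UndefinedMeasureError:
                out[m] = float("nan")
        else:
            raise ValueError(f"unknown measure {m!r}")
    return out


_COLUMNS = ["rater", "group", "subject", "hemisphere", "comparison",
            "other", "measure", "value"]


def _rows_to_table(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_COLUMNS)


def intra_rater_scores(result: RaterResult, parents: dict,
                       measures=DEFAULT_MEASURES, mode: str = "segments",
                       hemisphere: str = "L") -> pd.DataFrame:
    """Score all 3 unordered replicate pairs per subject for one rater.

    With 5 subjects this yields the 5 x 3 = 15 values per measure whose mean
    is the rater's intra-rater reproducibility score."""
    cache = _DensityCache(parents, mode)
    rows = []
    for subject in result.subjects():
        for va, vb in itertools.combinations(VARIANTS, 2):
            if (subject, va) not in result.selections or \
                    (subject, vb) not in result.selections:
                continue
            sa = result.selections[(subject, va)]
            sb = result.selections[(subject, vb)]
            scores = _score_pair(cache, subject, (result.rater, subject, va), sa,
                                 (result.rater, subject, vb), sb, measures)
            for m, v in scores.items():
                rows.append((result.rater, result.group, subject, hemisphere,
                             "intra", f"{va}|{vb}", m, v))
    return _rows_to_table(rows)


def inter_rater_scores(results: list, parents: dict,
                       measures=DEFAULT_MEASURES, mode: str = "segments",
                       fusion: str = "union",
                       hemisphere: str = "L") -> pd.DataFrame:
    """Pairwise comparison of fused (per-subject) bundles across raters.

    Each unordered rater pair contributes one row per subject and measure;
    a rater's inter score is the mean over all its comparisons
    (self-comparison excluded)."""
    if len(results) < 2:
        raise StudyError("inter-rater scores need at least 2 raters")
    cache = _DensityCache(parents, mode)
    fused = {(r.rater, s): fuse_triplicates(r, s, method=fusion)
             for r in results for s in r.subjects()}
    rows = []
    for ra, rb in itertools.combinations(results, 2):
        for subject in sorted(set(ra.subjects()) & set(rb.subjects())):
            sa, sb = fused[(ra.rater, subject)], fused[(rb.rater, subject)]
            scores = _score_pair(cache, subject, ("fused", ra.rater, subject), sa,
                                 ("fused", rb.rater, subject), sb, measures)
            for m, v in scores.items():
                rows.append((ra.rater, ra.group, subject, hemisphere,
                             "inter", rb.rater, m, v))
                rows.append((rb.rater, rb.group, subject, hemisphere,
                             "inter", ra.rater, m, v))
    return _rows_to_table(rows)


_CLASSIFICATION = ("sensitivity", "specificity", "precision", "accuracy",
                   "youden", "kappa")


def gold_scores(results: list, golds: dict, parents: dict,
                measures=DEFAULT_MEASURES, mode: str = "segments",
                fusion: str = "union", classification: bool = True,
                hemisphere: str = "L") -> pd.DataFrame:
    """Each rater's fused bundle against the per-subject average
    segmentation (``golds``: subject -> GoldStandard), including binary
    classification metrics in both representations."""
    cache = _DensityCache(parents, mode)
    rows = []
    for r in results:
        for subject in r.subjects():
            if subject not in golds:
                raise StudyError(f"no gold standard for subject {subject!r}")
            g: GoldStandard = golds[subject]
            sel = fuse_triplicates(r, subject, method=fusion)
            gold_key = ("gold", subject)
            # pairwise measures vs the gold (voxel side vs the gold mask)
            for m in measures:
                if m == "streamline_dice":
                    v = dice(sel, g.streamline)
                elif m == "streamline_jaccard":
                    v = jaccard(sel, g.streamline)
                elif m == "voxel_dice":
                    v = dice(cache.mask(("fused", r.rater, subject), subject, sel),
                             g.voxel)
                elif m == "voxel_jaccard":
                    v = jaccard(cache.mask(("fused", r.rater, subject), subject,
                                           sel), g.voxel)
                elif m == "density_correlation":
                    try:
                        v = density_correlation(
                            cache.density(("fused", r.rater, subject), subject,
                                          sel),
                            cache.density(gold_key, subject, g.streamline))
                    except UndefinedMeasureError:
                        v = float("nan")
                else:
                    raise ValueError(f"unknown measure {m!r}")
                rows.append((r.rater, r.group, subject, hemisphere, "gold",
                             "gold", m, v))
            if classification:
                c_str = confusion(sel, g.streamline,
                                  universe=parents[subject])
                cm_str = classification_metrics(c_str)
                mask = cache.mask(("fused", r.rater, subject), subject, sel)
                c_vox = confusion(mask, g.voxel)
                cm_vox = classification_metrics(c_vox)
                for name in _CLASSIFICATION:
                    rows.append((r.rater, r.group, subject, hemisphere, "gold",
                                 "gold", f"streamline_{name}",
                                 getattr(cm_str, name)))
                    rows.append((r.rater, r.group, subject, hemisphere, "gold",
                                 "gold", f"voxel_{name}",
                                 getattr(cm_vox, name)))
    return _rows_to_table(rows)


def per_rater_score(table: pd.DataFrame, comparison: str,
                    measure: str) -> pd.Series:
    """Mean score per rater for one comparison type and measure (the paper's
    per-rater 'reproducibility score'), hemispheres pooled."""
    sub = table[(table["comparison"] == comparison)
                & (table["measure"] == measure)]
    return sub.groupby("rater")["value"].mean()


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    median: float
    iqr: float
    q1: float
    q3: float
    n: int


def summarize(values) -> SummaryStats:
    """Median and interquartile range with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=np.float64)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("summarize needs at least one non-NaN value")
    q1, q2, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return SummaryStats(float(q2), float(q3 - q1), float(q1), float(q3),
                        int(v.size))


@dataclass(frozen=True)
class GroupComparison:
    u: float                  # Mann-Whitney U for the first sample
    p_value: float
    method: str               # "exact" | "asymptotic"
    degenerate: bool = False  # all values tied across both samples


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a``: concordant pairs, ties counted 1/2."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[:a.size].sum() - a.size * (a.size + 1) / 2.0)


def group_compare(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U test for two independent samples.

    For n, m <= 8 the null distribution of U is enumerated exactly over all
    C(n+m, n) assignments of the observed (possibly tied) values, with the
    two-sided p defined as P(min(U, nm-U) <= min(u_obs, nm-u_obs)); this
    yields p = 1 for identical samples.  Larger samples use the
    tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    degenerate = bool(np.ptp(np.concatenate([a, b])) == 0)
    u_obs = _u_statistic(a, b)
    n, m = a.size, b.size
    if n <= 8 and m <= 8:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = n * (n + 1) / 2.0
        stat_obs = min(u_obs, n * m - u_obs)
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            u = ranks[list(combo)].sum() - offset
            if min(u, n * m - u) <= stat_obs + 1e-9:
                hits += 1
            total += 1
        return GroupComparison(u_obs, hits / total, "exact", degenerate)
    if degenerate:
        return GroupComparison(u_obs, 1.0, "asymptotic", True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    return GroupComparison(float(res.statistic), float(res.pvalue),
                           "asymptotic", degenerate)


def rater_score_correlation(intra_scores, inter_scores) -> float:
    """Pearson r between per-rater intra and inter reproducibility scores."""
    x = np.asarray(intra_scores, dtype=np.float64)
    y = np.asarray(inter_scores, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched score vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMeasureError("zero variance in a score vector")
    return float(stats.pearsonr(x, y).statistic)


def study_summary(table: pd.DataFrame, alpha: float = 0.01) -> dict:
    """JSON-ready summary: per measure/comparison, group medians + IQR and
    the expert-vs-nonexpert Mann-Whitney p-value (significance at alpha)."""
    out: dict = {"alpha": alpha, "measures": {}}
    for (comparison, measure), sub in table.groupby(["comparison", "measure"]):
        block: dict = {}
        for group, gsub in sub.groupby("group"):
            vals = gsub["value"].dropna()
            if len(vals) == 0:
                continue
            s = summarize(vals)
            block[group] = {"median": s.median, "iqr": s.iqr, "n": s.n}
        groups = sorted(block)
        if len(groups) == 2:
            va = sub[sub["group"] == groups[0]]["value"].dropna()
            vb = sub[sub["group"] == groups[1]]["value"].dropna()
            try:
                cmp = group_compare(va, vb)
                block["test"] = {"p_value": cmp.p_value, "u": cmp.u,
                                 "method": cmp.method,
                                 "significant": bool(cmp.p_value < alpha)}
            except ValueError:
                pass
        out["measures"].setdefault(measure, {})[comparison] = block
    return out
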