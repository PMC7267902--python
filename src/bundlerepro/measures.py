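"""Agreement and descriptive measures, in both representations.

Pairwise overlap (Dice, Jaccard) is defined identically over streamline
index sets and over voxel supports; only the universe differs, and the two
can give wildly different values for the same pair of bundles (two raters
may pick almost disjoint streamline subsets that still fill the same
volume).  Density-map Pearson correlation adds a spatial-distribution
comparison.  Against a vote-built average segmentation ("gold standard",
which by construction contains no false positives or negatives) binary
classification metrics apply: sensitivity, specificity, precision,
accuracy, Youden's J and Cohen's kappa.

Conventions (stated so results are reproducible):

- Dice/Jaccard of two empty inputs is 1.0 (perfect agreement on nothing);
  empty vs non-empty is 0.0.
- The default confusion universe is the whole parent tractogram
  (streamlines) or the whole reference grid (voxels); with ~1e5-1e6
  elements and only thousands selected, true negatives dominate and
  specificity/accuracy sit near 1, which in turn drives kappa toward Dice.
- Density correlation is computed over the union of the two supports by
  default; correlating over the full grid lets the shared zeros swamp r.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (ParentMismatchError, UndefinedMeasureError, UniverseError)
from .grid import ReferenceGrid
from .tract_io import Selection, Tractogram
from .voxel_rep import BinaryMask, DensityMap, density_map, binary_mask

__all__ = [
    "ConfusionCounts", "ClassificationMetrics", "BundleStats", "ComparisonReport",
    "streamline_dice", "voxel_dice", "dice", "jaccard",
    "density_correlation", "confusion", "classification_metrics",
    "bundle_stats", "pair_report",
]


# ---------------------------------------------------------------------------
# Dice / Jaccard
# ---------------------------------------------------------------------------

def _set_sizes(a, b):
    """(|A|, |B|, |A∩B|) for two Selections or two BinaryMasks."""
    if isinstance(a, Selection) and isinstance(b, Selection):
        if a.parent_id != b.parent_id:
            raise ParentMismatchError(
                f"different parents: {a.parent_id!r} vs {b.parent_id!r}")
        inter = np.intersect1d(a.indices, b.indices).size
        return len(a), len(b), int(inter)
    if isinstance(a, BinaryMask) and isinstance(b, BinaryMask):
        a.grid.require_compatible(b.grid)
        return (a.n_voxels, b.n_voxels,
                int(np.count_nonzero(a.support & b.support)))
    raise TypeError(f"cannot compare {type(a).__name__} with {type(b).__name__}")


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both inputs are empty."""
    na, nb, ni = _set_sizes(a, b)
    if na + nb == 0:
        return 1.0
    return 2.0 * ni / (na + nb)


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B|; 1.0 when both inputs are empty."""
    na, nb, ni = _set_sizes(a, b)
    union = na + nb - ni
    if union == 0:
        return 1.0
    return ni / union


def streamline_dice(a: Selection, b: Selection) -> float:
    """Dice over streamline index sets of a shared parent tractogram."""
    if not (isinstance(a, Selection) and isinstance(b, Selection)):
        raise TypeError("streamline_dice expects two Selections")
    return dice(a, b)


def voxel_dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice over voxel supports on a shared grid."""
    if not (isinstance(a, BinaryMask) and isinstance(b, BinaryMask)):
        raise TypeError("voxel_dice expects two BinaryMasks")
    return dice(a, b)


# ---------------------------------------------------------------------------
# Density-map correlation
# ---------------------------------------------------------------------------

def density_correlation(a: DensityMap, b: DensityMap,
                        support: str | np.ndarray = "union") -> float:
    """Pearson r between two density maps over a chosen voxel support.

    ``support`` is ``"union"`` (default: voxels nonzero in either map),
    ``"grid"`` (every voxel), or an explicit boolean array on the grid.
    Degenerate supports (fewer than 2 voxels, or zero variance in either
    map) raise :class:`UndefinedMeasureError` rather than returning NaN.
    """
    a.grid.require_compatible(b.grid)
    if isinstance(support, str):
        if support == "union":
            mask = (a.counts > 0) | (b.counts > 0)
        elif support == "grid":
            mask = np.ones(a.grid.shape, dtype=bool)
        else:
            raise ValueError(f"unknown support {support!r}")
    else:
        mask = np.asarray(support).astype(bool)
        if mask.shape != a.grid.shape:
            raise ValueError("support mask shape does not match grid")
    x = a.counts[mask].astype(np.float64)
    y = b.counts[mask].astype(np.float64)
    if x.size < 2:
        raise UndefinedMeasureError(
            f"correlation support has {x.size} voxel(s); need >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMeasureError("zero variance on the correlation support")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Confusion counts and classification metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred, gold, universe=None) -> ConfusionCounts:
    """Confusion counts of a prediction against a gold standard.

    For Selections, ``universe`` is the element count of the parent
    tractogram (an int or the Tractogram itself).  For BinaryMasks the
    default universe is every voxel of the grid; pass a BinaryMask to
    restrict it.  Elements outside the universe raise UniverseError.
    """
    if isinstance(pred, Selection) and isinstance(gold, Selection):
        if pred.parent_id != gold.parent_id:
            raise ParentMismatchError("prediction and gold have different parents")
        if universe is None:
            raise UniverseError(
                "streamline confusion needs a universe: pass the parent "
                "tractogram or its streamline count")
        n = len(universe) if isinstance(universe, Tractogram) else int(universe)
        for s in (pred, gold):
            if len(s) and s.indices[-1] >= n:
                raise UniverseError(
                    f"selection index {s.indices[-1]} outside universe of size {n}")
        tp = np.intersect1d(pred.indices, gold.indices).size
        fp = len(pred) - tp
        fn = len(gold) - tp
        return ConfusionCounts(int(tp), int(fp), int(fn), n - tp - fp - fn)

    if isinstance(pred, BinaryMask) and isinstance(gold, BinaryMask):
        pred.grid.require_compatible(gold.grid)
        if universe is None:
            uni = np.ones(pred.grid.shape, dtype=bool)
        elif isinstance(universe, BinaryMask):
            pred.grid.require_compatible(universe.grid)
            uni = universe.support
            if np.any(pred.support & ~uni) or np.any(gold.support & ~uni):
                raise UniverseError("mask contains voxels outside the universe")
        else:
            raise TypeError("voxel universe must be None or a BinaryMask")
        p, g = pred.support, gold.support
        tp = int(np.count_nonzero(p & g))
        fp = int(np.count_nonzero(p & ~g))
        fn = int(np.count_nonzero(~p & g & uni))
        n = int(np.count_nonzero(uni))
        return ConfusionCounts(tp, fp, fn, n - tp - fp - fn)

    raise TypeError(
        f"cannot build confusion from {type(pred).__name__}/{type(gold).__name__}")


@dataclass(frozen=True)
class ClassificationMetrics:
    """Binary classification metrics; a metric whose denominator is zero is
    None and listed in ``undefined``."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    youden: float | None
    kappa: float | None
    undefined: frozenset = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sensitivity", "specificity", "precision", "accuracy",
                 "youden", "kappa")}


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Sensitivity, specificity, precision, accuracy, Youden's J and Cohen's
    kappa from confusion counts.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o = accuracy
    and chance agreement p_e = ((TP+FP)(TP+FN) + (FN+TN)(FP+TN)) / total^2.
    When true negatives vastly outnumber everything else, p_e -> the
    proportion of negatives and kappa approaches the Dice coefficient.
    """
    if c.total == 0:
        raise UndefinedMeasureError("empty universe: no classification metrics")
    und = set()

    def ratio(num, den, name):
        if den == 0:
            und.add(name)
            return None
        return num / den

    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    acc = (c.tp + c.tn) / c.total
    youden = sens + spec - 1.0 if (sens is not None and spec is not None) else None
    if youden is None:
        und.add("youden")
    t2 = float(c.total) ** 2
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / t2
    if p_e == 1.0:
        und.add("kappa")
        kappa = None
    else:
        kappa = (acc - p_e) / (1.0 - p_e)
    return ClassificationMetrics(sens, spec, prec, acc, youden, kappa,
                                 frozenset(und))


# ---------------------------------------------------------------------------
# Per-bundle descriptive measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BundleStats:
    """File-level bundle attributes: count, volume (cm^3), mean streamline
    length (mm) and mean scalar (e.g. FA) over the support voxels."""

    streamline_count: int
    volume_cm3: float
    mean_length_mm: float | None
    mean_scalar: float | None = None


def _arc_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def bundle_stats(parent: Tractogram, sel: Selection,
                 scalar_map=None, mode: str = "segments",
                 density_weighted: bool = False) -> BundleStats:
    """Descriptive statistics of one bundle.

    ``scalar_map`` is a nibabel image or (array, grid) pair on the parent
    grid; the mean scalar is unweighted over support voxels by default, or
    weighted by streamline density with ``density_weighted=True``.  An empty
    selection reports count 0, volume 0 and None for the means.
    """
    sel.validate_against(parent)
    if len(sel) == 0:
        return BundleStats(0, 0.0, None, None)
    d = density_map(parent, sel, mode=mode)
    mask = binary_mask(d)
    volume_cm3 = mask.volume_mm3 / 1000.0
    mean_len = float(np.mean([_arc_length(parent.streamlines[i])
                              for i in sel.indices]))
    mean_scalar = None
    if scalar_map is not None:
        if isinstance(scalar_map, tuple):
            data, sgrid = scalar_map
            data = np.asarray(data, dtype=np.float64)
        else:
            sgrid = ReferenceGrid.from_nifti(scalar_map)
            data = np.asanyarray(scalar_map.dataobj).astype(np.float64)
        parent.grid.require_compatible(sgrid)
        if density_weighted:
            w = d.counts[mask.support].astype(np.float64)
            mean_scalar = float(np.average(data[mask.support], weights=w))
        else:
            mean_scalar = float(np.mean(data[mask.support]))
    return BundleStats(len(sel), volume_cm3, mean_len, mean_scalar)


# ---------------------------------------------------------------------------
# Combined pairwise report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonReport:
    representation: str
    dice: float
    jaccard: float
    density_correlation: float | None = None
    classification: ClassificationMetrics | None = None

    def as_dict(self) -> dict:
        out = {"representation": self.representation,
               "dice": self.dice, "jaccard": self.jaccard}
        if self.density_correlation is not None:
            out["density_correlation"] = self.density_correlation
        if self.classification is not None:
            out["classification"] = self.classification.as_dict()
        return out


def pair_report(parent: Tractogram, a: Selection, b: Selection,
                mode: str = "segments") -> dict:
    """One report block per representation for a pair of bundles."""
    da = density_map(parent, a, mode=mode)
    db = density_map(parent, b, mode=mode)
    ma, mb = binary_mask(da), binary_mask(db)
    try:
        corr = density_correlation(da, db)
    except UndefinedMeasureError:
        corr = None
    return {
        "streamline": ComparisonReport("streamline", dice(a, b), jaccard(a, b)),
        "voxel": ComparisonReport("voxel", dice(ma, mb), jaccard(ma, mb),
                                  density_correlation=corr),
    }
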