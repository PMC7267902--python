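"""Vote maps and thresholded average segmentations ("gold standards").

Given several raters' segmentations of the same tractogram, each element
(streamline of the parent, or voxel of the grid) gets a vote count: the
number of raters whose segmentation contains it.  Thresholding the votes at
``k`` keeps the elements at least ``k`` raters agreed on: ``k = 1`` is the
union of the segmentations, ``k = n_raters`` their intersection, and
``k > n/2`` a majority vote (e.g. 6 of 11 raters).

The thresholded result is labeled an *average segmentation*: it is the
central tendency of the raters, not ground-truth anatomy.  Streamline-wise
and voxel-wise averages are built independently — the voxel vote counts
come from each rater's own mask, never from voxelizing the streamline
consensus.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, ParentMismatchError
from .grid import ReferenceGrid
from .tract_io import Selection, Tractogram
from .voxel_rep import BinaryMask, selection_mask

__all__ = ["VoteMap", "vote_map", "threshold_vote", "build_gold_standard",
           "GoldStandard"]


@dataclass
class VoteMap:
    """Per-element rater vote counts over a streamline or voxel universe."""

    kind: str                 # "streamline" or "voxel"
    votes: np.ndarray         # 1-D over parent indices, or 3-D over the grid
    n_raters: int
    parent_id: str | None = None
    grid: ReferenceGrid | None = None

    def __post_init__(self):
        if self.kind not in ("streamline", "voxel"):
            raise ValueError(f"kind must be streamline|voxel, got {self.kind!r}")
        self.votes = np.asarray(self.votes, dtype=np.int32)
        if self.votes.size and (self.votes.min() < 0
                                or self.votes.max() > self.n_raters):
            raise ValueError("votes must lie in [0, n_raters]")

    def normalized(self) -> np.ndarray:
        """Votes as a probability map (fraction of raters)."""
        return self.votes / float(self.n_raters)


def vote_map(inputs, parent: Tractogram | None = None,
             grid: ReferenceGrid | None = None) -> VoteMap:
    """Count, per element, how many of the inputs contain it.

    ``inputs`` is a non-empty list of Selections (with ``parent`` giving the
    universe) or of BinaryMasks on a common grid.
    """
    if not inputs:
        raise ValueError("vote_map needs at least one input")
    first = inputs[0]
    if isinstance(first, Selection):
        if parent is None:
            raise ValueError("streamline vote_map needs the parent tractogram")
        votes = np.zeros(len(parent), dtype=np.int32)
        for s in inputs:
            if not isinstance(s, Selection) or s.parent_id != first.parent_id:
                raise ParentMismatchError("all inputs must share one parent")
            s.validate_against(parent)
            votes[s.indices] += 1
        return VoteMap("streamline", votes, len(inputs),
                       parent_id=parent.id)
    if isinstance(first, BinaryMask):
        g = grid or first.grid
        votes = np.zeros(g.shape, dtype=np.int32)
        for m in inputs:
            if not isinstance(m, BinaryMask):
                raise TypeError("mixed input types in vote_map")
            g.require_compatible(m.grid)
            votes += m.support.astype(np.int32)
        return VoteMap("voxel", votes, len(inputs), grid=g)
    raise TypeError(f"unsupported vote_map input type {type(first).__name__}")


def _resolve_k(min_vote, n_raters: int) -> int:
    """Integer -> absolute count; float -> rater fraction in (0,1], via ceil."""
    if isinstance(min_vote, (int, np.integer)):
        k = int(min_vote)
    elif isinstance(min_vote, float):
        if not 0.0 < min_vote <= 1.0:
            raise ValueError(f"ratio threshold must be in (0, 1], got {min_vote}")
        k = math.ceil(min_vote * n_raters)
    else:
        raise TypeError(f"min_vote must be int or float, got {type(min_vote)}")
    if not 1 <= k <= n_raters:
        raise ValueError(f"min_vote {min_vote!r} -> k={k} outside [1, {n_raters}]")
    return k


def threshold_vote(v: VoteMap, min_vote):
    """Elements with votes >= k.  ``min_vote`` is an absolute count (int) or
    a rater fraction (float in (0,1], converted via ceil)."""
    k = _resolve_k(min_vote, v.n_raters)
    if v.kind == "streamline":
        return Selection(v.parent_id, np.flatnonzero(v.votes >= k))
    return BinaryMask(v.grid, v.votes >= k)


@dataclass
class GoldStandard:
    """Vote-thresholded average segmentation in both representations.

    Explicitly *not* true anatomy — it is the average of the contributing
    raters, hence the ``label``."""

    streamline: Selection
    voxel: BinaryMask
    min_vote: int
    n_raters: int
    label: str = "average segmentation"


def build_gold_standard(inputs: list[Selection], parent: Tractogram,
                        min_vote, mode: str = "segments",
                        masks: list[BinaryMask] | None = None) -> GoldStandard:
    """Average segmentation from several raters' selections.

    The streamline gold thresholds streamline votes; the voxel gold
    thresholds voxel votes of the per-rater masks (supplied via ``masks`` or
    voxelized here) — the two are built independently.
    """
    sv = vote_map(inputs, parent=parent)
    if masks is None:
        masks = [selection_mask(parent, s, mode=mode) for s in inputs]
    if len(masks) != len(inputs):
        raise ValueError("masks must match inputs one-to-one")
    vv = vote_map(masks)
    k = _resolve_k(min_vote, len(inputs))
    return GoldStandard(threshold_vote(sv, k), threshold_vote(vv, k),
                        k, len(inputs))
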