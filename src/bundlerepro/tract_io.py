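"""Tractogram / bundle-selection containers and TRK/TCK file I/O.

All streamline coordinates are kept internally in world millimetres (RAS+).
TRK files store streamlines in their native voxel space; nibabel converts
them to/from world mm using the header affine, which is taken from the
:class:`~bundlerepro.grid.ReferenceGrid`.  TCK files are world mm by
definition.

A rater's bundle is a :class:`Selection`: a strictly increasing set of
indices into the shared parent tractogram.  Bundles that arrive as files
(the rater saved a subset of streamlines, order and identity lost) are
matched back to parent indices by coordinate identity within a tolerance
(:func:`resolve_selection`).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines import Tractogram as _NibTractogram
from nibabel.streamlines.header import Field

from .errors import FormatError, GridMismatchError, ResolutionError
from .grid import ReferenceGrid

__all__ = [
    "Tractogram", "Selection",
    "read_tractogram", "write_tractogram", "resolve_selection",
    "subset_tractogram",
]


@dataclass
class Tractogram:
    """Ordered list of streamlines (each an (n,3) float64 array, world mm)
    tied to a reference grid.  Streamline order is identity: index i always
    refers to the same streamline."""

    streamlines: list
    grid: ReferenceGrid
    id: str = "tractogram"

    def __post_init__(self):
        cleaned = []
        for i, s in enumerate(self.streamlines):
            arr = np.ascontiguousarray(np.asarray(s, dtype=np.float64))
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(
                    f"streamline {i}: expected (n>=2, 3) array, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i}: non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.streamlines[i]

    def all_indices(self) -> "Selection":
        return Selection(self.id, np.arange(len(self), dtype=np.int64))


@dataclass(frozen=True)
class Selection:
    """A bundle as a subset of parent-tractogram streamline indices."""

    parent_id: str
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self):
        raw = self.indices
        if isinstance(raw, (set, frozenset)):
            raw = sorted(raw)
        idx = np.unique(np.asarray(raw, dtype=np.int64))
        if idx.size and idx[0] < 0:
            raise ValueError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def as_set(self) -> set:
        return set(int(i) for i in self.indices)

    def union(self, *others: "Selection") -> "Selection":
        for o in others:
            _require_same_parent(self, o)
        return Selection(self.parent_id,
                         np.union1d(self.indices,
                                    np.concatenate([o.indices for o in others])
                                    if others else np.empty(0, np.int64)))

    def intersection(self, other: "Selection") -> "Selection":
        _require_same_parent(self, other)
        return Selection(self.parent_id, np.intersect1d(self.indices, other.indices))

    def validate_against(self, parent: Tractogram):
        if self.parent_id != parent.id:
            raise ValueError(
                f"selection parent {self.parent_id!r} != tractogram {parent.id!r}")
        if len(self) and self.indices[-1] >= len(parent):
            raise IndexError(
                f"selection index {self.indices[-1]} out of range for parent of "
                f"{len(parent)} streamlines")


def _require_same_parent(a: Selection, b: Selection):
    from .errors import ParentMismatchError
    if a.parent_id != b.parent_id:
        raise ParentMismatchError(
            f"selections have different parents: {a.parent_id!r} vs {b.parent_id!r}")


def subset_tractogram(t: Tractogram, sel: Selection, new_id: str | None = None
                      ) -> Tractogram:
    """Materialize a selection as its own tractogram (e.g. to save a bundle)."""
    sel.validate_against(t)
    return Tractogram([t.streamlines[i].copy() for i in sel.indices],
                      t.grid, new_id or f"{t.id}:subset")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _format_from_path(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".trk", ".tck"):
        return ext[1:]
    raise FormatError(f"unsupported tractogram extension {ext!r} (use .trk/.tck)")


def read_tractogram(path, grid: ReferenceGrid | None = None,
                    id: str | None = None) -> Tractogram:
    """Read a TRK or TCK file into world-mm coordinates.

    TRK headers carry their own grid; if ``grid`` is also given the two must
    agree (shape exactly, affine within 1e-3 — TRK stores float32 affines).
    TCK carries no grid, so ``grid`` is required for TCK files.
    """
    fmt = _format_from_path(path)
    try:
        f = nib.streamlines.load(str(path))
    except Exception as e:  # nibabel raises assorted errors on corrupt files
        raise FormatError(f"cannot read {path}: {e}") from e

    if fmt == "trk":
        hdr = f.header
        file_grid = ReferenceGrid(tuple(int(d) for d in hdr[Field.DIMENSIONS]),
                                  np.asarray(hdr[Field.VOXEL_TO_RASMM], float))
        if grid is not None:
            grid.require_compatible(file_grid, atol=1e-3)
        else:
            grid = file_grid
    elif grid is None:
        raise GridMismatchError(
            "TCK files carry no voxel grid; a ReferenceGrid is required")

    streamlines = [np.asarray(s, dtype=np.float64)
                   for s in f.tractogram.streamlines]
    return Tractogram(streamlines, grid,
                      id or os.path.splitext(os.path.basename(str(path)))[0])


def write_tractogram(t: Tractogram, path, format: str | None = None) -> None:
    """Write a tractogram as TRK or TCK (inferred from the extension).

    Coordinates are stored in the format's native convention (TRK voxel
    space via the grid affine, TCK world mm); re-reading recovers world-mm
    coordinates within float32 precision.
    """
    fmt = format or _format_from_path(path)
    nib_t = _NibTractogram(
        [s.astype(np.float64) for s in t.streamlines],
        affine_to_rasmm=np.eye(4))
    if fmt == "trk":
        hdr = TrkFile.create_empty_header()
        hdr[Field.DIMENSIONS] = np.asarray(t.grid.shape, dtype=np.int16)
        zooms = np.sqrt((t.grid.affine[:3, :3] ** 2).sum(axis=0))
        hdr[Field.VOXEL_SIZES] = zooms.astype(np.float32)
        hdr[Field.VOXEL_TO_RASMM] = t.grid.affine.astype(np.float32)
        hdr[Field.VOXEL_ORDER] = b"RAS"
        TrkFile(nib_t, header=hdr).save(str(path))
    elif fmt == "tck":
        TckFile(nib_t).save(str(path))
    else:
        raise FormatError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# Resolving file-based bundles against a parent tractogram
# ---------------------------------------------------------------------------

def _geometry_key(pts: np.ndarray, tol: float) -> bytes:
    # Round each coordinate to the tolerance lattice; O(1) lookup per streamline.
    q = np.round(pts / tol).astype(np.int64)
    return q.tobytes()


def resolve_selection(parent: Tractogram, bundle: Tractogram,
                      tol: float = 1e-3) -> Selection:
    """Match each bundle streamline to exactly one parent index.

    Matching is by coordinate identity: same point count, same order, every
    point within ``tol`` mm.  The fast path hashes coordinates rounded to the
    tolerance lattice; streamlines whose rounding straddles a lattice
    boundary (float32 storage jitter) fall back to a per-candidate scan over
    parent streamlines with the same point count.  Duplicate geometries are
    claimed greedily, lowest unclaimed parent index first, which is
    deterministic and independent of bundle file order.
    """
    table: dict[bytes, list[int]] = {}
    by_npts: dict[int, list[int]] = {}
    for i, s in enumerate(parent.streamlines):
        table.setdefault(_geometry_key(s, tol), []).append(i)
        by_npts.setdefault(s.shape[0], []).append(i)

    claimed = np.zeros(len(parent), dtype=bool)
    matched: list[int] = []
    n_failed = 0
    for b in bundle.streamlines:
        cand = table.get(_geometry_key(b, tol), ())
        hit = -1
        for i in cand:
            if not claimed[i]:
                hit = i
                break
        if hit < 0:
            # fallback: tolerance scan among same-point-count parents
            for i in by_npts.get(b.shape[0], ()):
                if claimed[i]:
                    continue
                if np.max(np.abs(parent.streamlines[i] - b)) <= tol:
                    hit = i
                    break
        if hit < 0:
            n_failed += 1
        else:
            claimed[hit] = True
            matched.append(hit)

    if n_failed:
        raise ResolutionError(
            f"{n_failed} of {len(bundle)} bundle streamlines have no match in "
            f"parent {parent.id!r} within {tol} mm", n_failed=n_failed)
    return Selection(parent.id, np.asarray(matched, dtype=np.int64))
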