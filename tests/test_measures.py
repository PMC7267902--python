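"""Agreement measures vs independent brute-force oracles."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bundlerepro import (BinaryMask, ConfusionCounts, ReferenceGrid,
                         Selection, Tractogram, bundle_stats,
                         classification_metrics, confusion,
                         density_correlation, dice, jaccard, streamline_dice,
                         voxel_dice)
from bundlerepro.errors import (ParentMismatchError, UndefinedMeasureError,
                                UniverseError)
from bundlerepro.voxel_rep import DensityMap


def sel(idx, parent="P"):
    return Selection(parent, np.asarray(sorted(idx), np.int64))


def mask_of(voxels, shape=(4, 4, 4)):
    g = ReferenceGrid.isotropic(shape)
    m = np.zeros(shape, bool)
    for v in voxels:
        m[v] = True
    return BinaryMask(g, m)


# -- worked example: 2x5 grid, two non-identical streamlines ---------------

def test_streamline_dice_of_distinct_streamlines_is_zero():
    # two single-streamline bundles with different geometry share no index
    assert streamline_dice(sel({2}), sel({3})) == 0.0


def test_voxel_dice_five_three_sharing_three():
    a = mask_of([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0), (0, 1, 0)])
    b = mask_of([(1, 0, 0), (2, 0, 0), (3, 0, 0)])
    assert voxel_dice(a, b) == pytest.approx(0.75, abs=0)
    assert jaccard(a, b) == pytest.approx(0.6, abs=0)


# -- Dice/Jaccard basics ----------------------------------------------------

@pytest.mark.parametrize("a,b,d,j", [
    ({1, 2, 3}, {2, 3, 4}, 2 * 2 / 6, 2 / 4),
    ({1, 2, 3}, {1, 2, 3}, 1.0, 1.0),
    ({1, 2}, {3, 4}, 0.0, 0.0),
    (set(), set(), 1.0, 1.0),
    (set(), {1}, 0.0, 0.0),
])
def test_dice_jaccard_set_oracle(a, b, d, j):
    assert streamline_dice(sel(a), sel(b)) == pytest.approx(d, abs=1e-15)
    assert jaccard(sel(a), sel(b)) == pytest.approx(j, abs=1e-15)


def test_parent_mismatch_rejected():
    with pytest.raises(ParentMismatchError):
        streamline_dice(sel({1}), sel({1}, parent="Q"))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(a=st.sets(st.integers(0, 30)), b=st.sets(st.integers(0, 30)))
def test_symmetry_and_dice_jaccard_identity(a, b):
    """m(a,b)=m(b,a) and D = 2J/(1+J) to 1e-12."""
    sa, sb = sel(a), sel(b)
    d1, d2 = streamline_dice(sa, sb), streamline_dice(sb, sa)
    j = jaccard(sa, sb)
    assert d1 == d2
    assert abs(d1 - 2 * j / (1 + j)) < 1e-12
    assert streamline_dice(sa, sa) == 1.0


# -- confusion + classification --------------------------------------------

def test_confusion_set_oracle():
    c = confusion(sel({3, 4, 5, 6}), sel({1, 2, 3, 4}), universe=10)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 2, 4)


def test_confusion_trivial_cases():
    g = sel({1, 2, 3})
    c = confusion(g, g, universe=10)
    assert c.fp == 0 and c.fn == 0
    c2 = confusion(sel(set()), g, universe=10)
    assert c2.tp == 0 and c2.fn == 3


def test_confusion_universe_violation():
    with pytest.raises(UniverseError):
        confusion(sel({11}), sel({1}), universe=10)
    with pytest.raises(UniverseError):
        confusion(sel({1}), sel({2}))  # streamlines need an explicit universe


def test_classification_hand_oracle():
    m = classification_metrics(ConfusionCounts(3, 1, 1, 5))
    assert m.accuracy == pytest.approx(0.8)
    # p_e = (4*4 + 6*6)/100 = 0.52 ; kappa = 0.28/0.48
    assert m.kappa == pytest.approx(0.28 / 0.48, abs=1e-12)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.precision == pytest.approx(0.75)
    assert m.youden == pytest.approx(0.75 + 5 / 6 - 1, abs=1e-12)


def test_perfect_prediction_all_ones():
    m = classification_metrics(ConfusionCounts(4, 0, 0, 6))
    for name in ("sensitivity", "specificity", "precision", "accuracy",
                 "kappa"):
        assert getattr(m, name) == pytest.approx(1.0)
    assert m.youden == pytest.approx(1.0)


def test_undefined_metrics_flagged():
    m = classification_metrics(ConfusionCounts(0, 0, 0, 10))
    assert m.sensitivity is None and "sensitivity" in m.undefined
    assert m.precision is None
    with pytest.raises(UndefinedMeasureError):
        classification_metrics(ConfusionCounts(0, 0, 0, 0))


def test_kappa_tends_to_dice_as_tn_grows():
    """With TN dominating, chance agreement collapses and kappa converges to
    the Dice coefficient of prediction vs gold."""
    tp, fp, fn = 30, 10, 15
    d = 2 * tp / (2 * tp + fp + fn)
    gaps = []
    for tn in (10**2, 10**4, 10**6):
        k = classification_metrics(ConfusionCounts(tp, fp, fn, tn)).kappa
        gaps.append(abs(k - d))
    assert gaps == sorted(gaps, reverse=True)
    assert gaps[-1] < 1e-3


# -- density correlation ----------------------------------------------------

def _dmap(counts, shape=(4, 4, 4)):
    arr = np.zeros(shape, np.int32)
    arr.reshape(-1)[:len(counts)] = counts
    return DensityMap(ReferenceGrid.isotropic(shape), arr)


def test_density_correlation_cases():
    a = _dmap([1, 2, 3])
    assert density_correlation(a, a) == pytest.approx(1.0)
    assert density_correlation(_dmap([1, 2, 3]), _dmap([3, 2, 1])) == \
        pytest.approx(-1.0)
    # hand formula oracle on union support
    x, y = np.array([1, 0, 2, 4.0]), np.array([2, 1, 1, 3.0])
    r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    got = density_correlation(_dmap(x.astype(int)), _dmap(y.astype(int)),
                              support="union")
    assert got == pytest.approx(r_oracle, abs=1e-12)


def test_density_correlation_degenerate_errors():
    with pytest.raises(UndefinedMeasureError):
        density_correlation(_dmap([1, 1, 1]), _dmap([1, 2, 3]))
    with pytest.raises(UndefinedMeasureError):
        density_correlation(_dmap([2]), _dmap([3]))


# -- bundle statistics -------------------------------------------------------

def test_bundle_stats(grid32):
    # one straight streamline of arc length 10 mm along x
    t = Tractogram([np.array([[5.0, 5, 5], [10, 5, 5], [15, 5, 5]])],
                   grid32, "t")
    s = bundle_stats(t, t.all_indices())
    assert s.streamline_count == 1
    assert s.mean_length_mm == pytest.approx(10.0)
    assert s.volume_cm3 == pytest.approx(11 * 1.0 / 1000.0)  # 11 voxels @1mm3
    # constant scalar map -> mean 0.5 regardless of the bundle
    scalar = (np.full(grid32.shape, 0.5), grid32)
    assert bundle_stats(t, t.all_indices(), scalar_map=scalar).mean_scalar \
        == pytest.approx(0.5)


def test_bundle_stats_empty(grid32):
    t = Tractogram([np.array([[1.0, 1, 1], [2, 1, 1]])], grid32, "t")
    s = bundle_stats(t, Selection(t.id, []))
    assert s.streamline_count == 0 and s.volume_cm3 == 0.0
    assert s.mean_length_mm is None and s.mean_scalar is None
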