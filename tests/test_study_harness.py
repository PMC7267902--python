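"""Blinded triplication harness, score aggregation, statistics."""
import itertools

import numpy as np
import pytest
from scipy import stats

import bundlerepro.study_harness as sh
from bundlerepro import (RaterResult, Selection, deanonymize,
                         fuse_triplicates, group_compare, make_triplicates,
                         rater_score_correlation, robot_rater,
                         simulate_study, subset_tractogram, summarize)
from bundlerepro.errors import StudyError, UndefinedMeasureError
from bundlerepro.study_harness import (VARIANTS, apply_transform,
                                       flip_transform, translation_transform)


# -- transforms --------------------------------------------------------------

def test_flip_is_exact_involution(phantom):
    parent, _ = phantom
    F = flip_transform(parent.grid)
    assert np.array_equal(F @ F, np.eye(4))
    flipped_twice = apply_transform(apply_transform(parent, F), F)
    for a, b in zip(parent.streamlines, flipped_twice.streamlines):
        assert np.array_equal(a, b)          # bit-exact (float32-valued coords)


def test_translate_roundtrip_bit_exact(phantom):
    parent, _ = phantom
    T = translation_transform(parent.grid, (4, 4, 0))
    back = apply_transform(apply_transform(parent, T), np.linalg.inv(T))
    for a, b in zip(parent.streamlines, back.streamlines):
        assert np.array_equal(a, b)


def test_translation_requires_whole_voxels(grid32):
    with pytest.raises(ValueError):
        translation_transform(grid32, (0.5, 0, 0))


# -- manifest ---------------------------------------------------------------

def test_five_subjects_fifteen_datasets_bijection():
    data = simulate_study(n_subjects=5, n_experts=1, n_nonexperts=1,
                          n_core=30, n_distractor=10, seed=3)
    assert len(data.datasets) == 15
    pairs = {(e.subject, e.variant) for e in data.manifest.entries.values()}
    assert len(pairs) == 15
    assert {v for _, v in pairs} == set(VARIANTS)
    # every rater's task list covers exactly the 15 anonymized names
    for bundles in data.rater_bundles.values():
        assert set(bundles) == set(data.datasets)


def test_manifest_csv_roundtrip(phantom, tmp_path):
    parent, _ = phantom
    _, mf = make_triplicates(parent, seed=9)
    mf.to_csv(tmp_path / "m.csv", transforms_json=tmp_path / "m.json")
    back = sh.StudyManifest.from_csv(tmp_path / "m.csv", tmp_path / "m.json")
    assert set(back.entries) == set(mf.entries)
    for name, e in mf.entries.items():
        assert np.array_equal(back.entries[name].transform, e.transform)
        assert back.entries[name].variant == e.variant


def test_deanonymize_reconciliation_error(phantom):
    parent, _ = phantom
    datasets, mf = make_triplicates(parent, seed=1)
    some = dict(list(datasets.items())[:2])
    with pytest.raises(StudyError, match="missing"):
        deanonymize(some, mf, {parent.id: parent}, "r1")


# -- end-to-end identity -----------------------------------------------------

def test_robot_rater_end_to_end_identity(phantom):
    """A deterministic coordinate-defined rater segmenting all three blinded
    variants, de-randomized and fused, equals its segmentation of the
    original (the harness round trip is lossless)."""
    parent, _ = phantom
    datasets, mf = make_triplicates(parent, translation=(4, 4, 0), seed=21)
    bundles = {name: subset_tractogram(t, robot_rater(t), new_id=name)
               for name, t in datasets.items()}
    result = deanonymize(bundles, mf, {parent.id: parent}, "robot")
    direct = robot_rater(parent)
    assert len(direct) > 5
    for variant in VARIANTS:
        got = result.selections[(parent.id, variant)]
        assert got.as_set() == direct.as_set()
    fused = fuse_triplicates(result, parent.id)
    assert fused.as_set() == direct.as_set()


def test_planted_selection_roundtrip(phantom):
    """make_triplicates -> subset by known indices -> deanonymize recovers
    the planted index set exactly on every variant."""
    parent, _ = phantom
    planted = Selection(parent.id, [0, 3, 17, 44, 61])
    datasets, mf = make_triplicates(parent, seed=5)
    bundles = {name: subset_tractogram(t, Selection(t.id, planted.indices),
                                       new_id=name)
               for name, t in datasets.items()}
    result = deanonymize(bundles, mf, {parent.id: parent}, "r")
    for variant in VARIANTS:
        assert result.selections[(parent.id, variant)].as_set() \
            == planted.as_set()


# -- fusion ------------------------------------------------------------------

def _result_with(parent, a, b, c):
    r = RaterResult("r", "expert")
    for v, s in zip(VARIANTS, (a, b, c)):
        r.selections[(parent.id, v)] = Selection(parent.id, s)
    return r


def test_fusion_union_majority_intersection(phantom):
    parent, _ = phantom
    r = _result_with(parent, {1, 2}, {2, 3}, {3, 4})
    assert fuse_triplicates(r, parent.id).as_set() == {1, 2, 3, 4}
    assert fuse_triplicates(r, parent.id, method="majority").as_set() == {2, 3}
    assert fuse_triplicates(r, parent.id,
                            method="intersection").as_set() == set()
    r2 = _result_with(parent, {5, 6}, {5, 6}, {5, 6})
    assert fuse_triplicates(r2, parent.id).as_set() == {5, 6}
    # |fused| >= max |replicate|
    assert len(fuse_triplicates(r, parent.id)) >= 2


def test_fusion_missing_variant_errors(phantom):
    parent, _ = phantom
    r = RaterResult("r", "expert")
    r.selections[(parent.id, "original")] = Selection(parent.id, [1])
    with pytest.raises(StudyError):
        fuse_triplicates(r, parent.id)


# -- score tables ------------------------------------------------------------

def test_intra_scores_count_and_identity(phantom):
    parent, _ = phantom
    r = _result_with(parent, {1, 2, 3}, {1, 2, 3}, {1, 2, 3})
    t = sh.intra_rater_scores(r, {parent.id: parent},
                              measures=("streamline_dice", "voxel_dice"))
    # 1 subject x 3 pairs x 2 measures
    assert len(t) == 6
    assert (t["value"] == 1.0).all()


def test_intra_fifteen_values_for_five_subjects():
    data = simulate_study(n_subjects=5, n_experts=1, n_nonexperts=1,
                          n_core=40, n_distractor=10, seed=8)
    r = data.collect()[0]
    t = sh.intra_rater_scores(r, data.parents, measures=("streamline_dice",))
    assert len(t) == 15                     # 5 subjects x 3 replicate pairs


def test_inter_scores_pairs_and_identity(phantom):
    parent, _ = phantom
    r1 = _result_with(parent, {1, 2}, {1, 2}, {1, 2})
    r2 = _result_with(parent, {1, 2}, {1, 2}, {1, 2})
    r2.rater = "r2"
    t = sh.inter_rater_scores([r1, r2], {parent.id: parent},
                              measures=("streamline_dice",))
    assert set(t["value"]) == {1.0}
    # 1 pair x 1 subject, mirrored into both raters' rows
    assert len(t) == 2
    with pytest.raises(StudyError):
        sh.inter_rater_scores([r1], {parent.id: parent})


def test_gold_scores_signatures(phantom):
    """Over-segmentation: sensitivity 1, precision < 1; under-segmentation
    mirrors it."""
    from bundlerepro import build_gold_standard
    parent, _ = phantom
    gold_sel = {10, 11, 12, 13}
    golds = {parent.id: build_gold_standard(
        [Selection(parent.id, gold_sel)] * 3, parent, 2)}
    over = _result_with(parent, gold_sel | {20, 21}, gold_sel | {20, 21},
                        gold_sel | {20, 21})
    under = _result_with(parent, {10, 11}, {10, 11}, {10, 11})
    under.rater = "under"
    t = sh.gold_scores([over, under], golds, {parent.id: parent},
                       measures=("streamline_dice",))
    def val(rater, m):
        s = t[(t["rater"] == rater) & (t["measure"] == m)]["value"]
        return float(s.iloc[0])
    assert val("r", "streamline_sensitivity") == 1.0
    assert val("r", "streamline_precision") < 1.0
    assert val("under", "streamline_precision") == 1.0
    assert val("under", "streamline_sensitivity") < 1.0
    # an expert whose bundle equals the gold: dice 1, kappa 1
    exact = _result_with(parent, gold_sel, gold_sel, gold_sel)
    exact.rater = "exact"
    t2 = sh.gold_scores([exact], golds, {parent.id: parent},
                        measures=("streamline_dice",))
    sub = t2[t2["measure"].isin(["streamline_dice", "streamline_kappa"])]
    assert (sub["value"] == 1.0).all()


def test_score_table_invariant_to_anonymized_names(phantom):
    """Different anonymization seeds (different names/order) produce the
    same de-randomized score table."""
    parent, _ = phantom
    tables = []
    for seed in (1, 2):
        datasets, mf = make_triplicates(parent, seed=seed)
        bundles = {n: subset_tractogram(t, robot_rater(t), new_id=n)
                   for n, t in datasets.items()}
        r = deanonymize(bundles, mf, {parent.id: parent}, "robot")
        tables.append(sh.intra_rater_scores(
            r, {parent.id: parent}, measures=("streamline_dice",)))
    assert np.allclose(tables[0]["value"], tables[1]["value"])


# -- statistics --------------------------------------------------------------

def test_summarize_examples_and_oracle():
    s = summarize([1, 2, 3, 4, 5])
    assert s.median == 3 and s.iqr == 2
    assert summarize([7, 7, 7]).iqr == 0
    rng = np.random.default_rng(0)
    v = rng.normal(size=101)
    s = summarize(v)
    q1, q2, q3 = np.quantile(np.sort(v), [0.25, 0.5, 0.75])
    assert abs(s.median - q2) < 1e-12 and abs(s.iqr - (q3 - q1)) < 1e-12


def test_mannwhitney_identical_samples_p1():
    c = group_compare([1, 2, 3, 4], [1, 2, 3, 4])
    assert c.method == "exact" and c.p_value == 1.0


def test_mannwhitney_u_matches_pair_counting():
    """Exact-branch U equals the brute-force count of concordant pairs
    (ties at 1/2) for all small samples tried."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        n, m = rng.integers(2, 9, size=2)
        a = rng.integers(0, 6, size=n).astype(float)
        b = rng.integers(0, 6, size=m).astype(float)
        u_brute = sum(1.0 if x > y else 0.5 if x == y else 0.0
                      for x in a for y in b)
        c = group_compare(a, b)
        assert c.method == "exact"
        assert c.u == pytest.approx(u_brute, abs=1e-12)


def test_mannwhitney_detects_shift():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 50)
    b = rng.normal(3, 1, 50)
    c = group_compare(a, b)
    assert c.method == "asymptotic" and c.p_value < 0.01
    # agrees with scipy on the same data
    ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    assert c.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)


def test_rater_score_correlation():
    intra = np.array([0.5, 0.7, 0.9, 0.8])
    assert rater_score_correlation(intra, intra) == pytest.approx(1.0)
    assert rater_score_correlation(intra, -intra + 1.0) == pytest.approx(-1.0)
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=10), rng.normal(size=10)
    oracle = np.corrcoef(x, y)[0, 1]
    assert rater_score_correlation(x, y) == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(UndefinedMeasureError):
        rater_score_correlation([1, 1, 1], [1, 2, 3])


def test_inter_dice_matches_union_fusion_expectation():
    """Independent Bernoulli raters at keep probability p, spurious rate 0:
    after 3-replicate union fusion each core streamline is retained with
    probability 1-(1-p)^3, so the expected fused pairwise streamline Dice
    is 1-(1-p)^3 (vs p for single replicates)."""
    from bundlerepro import RaterModel
    p = 0.6
    data = simulate_study(n_subjects=2, n_experts=4, n_nonexperts=0,
                          expert_model=RaterModel(p, 0.0),
                          nonexpert_model=RaterModel(p, 0.0),
                          n_core=800, n_distractor=0, seed=31)
    results = data.collect()
    table = sh.inter_rater_scores(results, data.parents,
                                  measures=("streamline_dice",))
    expected = 1 - (1 - p) ** 3
    assert table["value"].mean() == pytest.approx(expected, abs=0.03)


def test_study_summary_structure():
    data = simulate_study(n_subjects=2, n_experts=2, n_nonexperts=2,
                          n_core=40, n_distractor=20, seed=4)
    results = data.collect()
    table = sh.inter_rater_scores(results, data.parents,
                                  measures=("streamline_dice",))
    summary = sh.study_summary(table)
    block = summary["measures"]["streamline_dice"]["inter"]
    assert {"expert", "nonexpert"} <= set(block)
    assert 0 <= block["expert"]["median"] <= 1
    assert "p_value" in block["test"]
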