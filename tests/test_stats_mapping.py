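"""Normalization, Jaccard distances, PCoA (with an independent
scikit-bio cross-check), Venn region counts, and 'ili table assembly."""
import itertools
import warnings
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from plantcarto import stats_mapping as sm
from plantcarto.errors import DegenerateSampleError, ValidationError
from plantcarto.models import FeatureMatrix, Mesh, SampleMetadata


def _matrix(data, samples=None):
    data = np.asarray(data, dtype=float)
    samples = samples or [f"s{i}" for i in range(data.shape[1])]
    return FeatureMatrix(
        mz=200.0 + np.arange(data.shape[0]),
        rt=10.0 * (1.0 + np.arange(data.shape[0])),
        areas=pd.DataFrame(data, columns=samples,
                           index=[f"f{i:05d}" for i in
                                  range(data.shape[0])]))


# ---------------------------------------------------------------------------
# TIC normalization


def test_tic_uniform_split():
    m = sm.tic_normalize(_matrix([[2.0], [2.0]]))
    np.testing.assert_allclose(m.areas.to_numpy().ravel(), [0.5, 0.5])


def test_tic_idempotent_on_unit_sum():
    m = _matrix([[0.25], [0.75]])
    out = sm.tic_normalize(m)
    np.testing.assert_allclose(out.areas.to_numpy(), m.areas.to_numpy())


def test_tic_columns_sum_to_one():
    rng = np.random.default_rng(2)
    m = _matrix(rng.uniform(0.1, 5.0, size=(30, 8)))
    out = sm.tic_normalize(m)
    np.testing.assert_allclose(out.areas.sum(axis=0), np.ones(8),
                               atol=1e-12)


def test_tic_zero_column_names_sample():
    with pytest.raises(DegenerateSampleError, match="s1"):
        sm.tic_normalize(_matrix([[1.0, 0.0], [1.0, 0.0]]))


# ---------------------------------------------------------------------------
# Jaccard


def test_jaccard_identical_zero():
    d = sm.jaccard_distances(_matrix([[1.0, 2.0], [3.0, 4.0]]))
    assert d.d[0, 1] == 0.0


def test_jaccard_disjoint_one():
    d = sm.jaccard_distances(_matrix([[1.0, 0.0], [0.0, 1.0]]))
    assert d.d[0, 1] == 1.0


def test_jaccard_hand_enumeration():
    # P_i = {f1, f2}, P_j = {f1, f3} -> 1 - 1/3
    d = sm.jaccard_distances(_matrix([[1.0, 1.0], [1.0, 0.0], [0.0, 1.0]]))
    assert d.d[0, 1] == pytest.approx(2.0 / 3.0)


def test_jaccard_empty_pair_zero():
    d = sm.jaccard_distances(_matrix([[0.0, 0.0]]))
    assert d.d[0, 1] == 0.0


def test_jaccard_triangle_inequality():
    rng = np.random.default_rng(4)
    for _ in range(40):
        pres = rng.random((12, 6)) < rng.uniform(0.2, 0.8)
        d = sm.jaccard_distances(_matrix(pres.astype(float))).d
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_normalization_invariance_of_jaccard():
    rng = np.random.default_rng(6)
    data = (rng.uniform(0.1, 3.0, size=(25, 7))
            * (rng.random((25, 7)) < 0.6))
    data[0, :] = 1.0  # no all-zero column, so TIC normalization is defined
    m = _matrix(data)
    direct = sm.jaccard_distances(m).d
    after_tic = sm.jaccard_distances(sm.tic_normalize(m)).d
    np.testing.assert_array_equal(direct, after_tic)


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_two_point_closed_form():
    d = 0.8
    dm = sm.DistanceMatrix(["a", "b"], np.array([[0.0, d], [d, 0.0]]))
    res = sm.pcoa(dm, n_axes=1)
    np.testing.assert_allclose(np.sort(res.coordinates.ravel()),
                               [-d / 2, d / 2], atol=1e-12)
    assert res.eigenvalues[0] == pytest.approx(d * d / 2)


def test_pcoa_recovers_euclidean_configuration():
    rng = np.random.default_rng(13)
    pts = rng.normal(size=(10, 3))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    res = sm.pcoa(sm.DistanceMatrix([f"s{i}" for i in range(10)], d),
                  n_axes=3)
    emb = res.coordinates
    d_emb = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=-1)
    assert np.max(np.abs(d_emb - d)) < 1e-9
    # rank property: points from R^3 give at most 3 positive eigenvalues
    assert np.sum(res.eigenvalues > 1e-9) <= 3


def test_pcoa_simplex_equal_eigenvalues():
    n = 5
    d = np.ones((n, n)) - np.eye(n)
    res = sm.pcoa(sm.DistanceMatrix([f"s{i}" for i in range(n)], d),
                  n_axes=n - 1)
    pos = res.eigenvalues[res.eigenvalues > 1e-12]
    np.testing.assert_allclose(pos, pos[0], rtol=1e-9)


def test_pcoa_truncates_with_warning():
    dm = sm.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.warns(UserWarning, match="truncating"):
        res = sm.pcoa(dm, n_axes=3)
    assert res.coordinates.shape == (2, 1)


def test_pcoa_agrees_with_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(21)
    pres = (rng.random((30, 8)) < 0.5).astype(float)
    dm = sm.jaccard_distances(_matrix(pres))
    ours = sm.pcoa(dm, n_axes=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.d, ids=dm.sample_ids))
    ref_eig = np.sort(ref.eigvals.to_numpy())[::-1]
    np.testing.assert_allclose(np.sort(ours.eigenvalues)[::-1][:3],
                               ref_eig[:3], atol=1e-9)
    for k in range(3):
        np.testing.assert_allclose(
            np.abs(ours.coordinates[:, k]),
            np.abs(ref.samples.to_numpy()[:, k]), atol=1e-6)


# ---------------------------------------------------------------------------
# Venn counts


def _meta(samples, tissues, blanks=()):
    return [SampleMetadata(s, "p", t, s in blanks, 0.0, 0.0, 0.0, 1.0)
            for s, t in zip(samples, tissues)]


def test_venn_all_features_everywhere():
    m = _matrix(np.ones((10, 4)))
    meta = _meta(m.sample_ids, ["leaf", "leaf", "stem", "stem"])
    v = sm.venn_counts(m, meta)
    assert v.all_groups_count == 10
    assert v.all_groups_percent == pytest.approx(100.0)


def test_venn_block_diagonal_private_features():
    data = np.zeros((6, 3))
    for i in range(6):
        data[i, i % 3] = 1.0
    m = _matrix(data)
    meta = _meta(m.sample_ids, ["a", "b", "c"])
    v = sm.venn_counts(m, meta)
    assert all(len(region) == 1 for region in v.regions)
    assert v.total == 6


def test_venn_matches_brute_force_bucketing():
    rng = np.random.default_rng(17)
    tissues = ["leaf", "stem", "fruit", "flower"]
    samples = [f"s{i}" for i in range(8)]
    meta = _meta(samples, [tissues[i % 4] for i in range(8)],
                 blanks={"s7"})
    pres = rng.random((50, 8)) < 0.4
    m = _matrix(pres.astype(float), samples=samples)
    v = sm.venn_counts(m, meta)
    expected = Counter()
    for row in pres:
        groups = frozenset(tissues[i % 4] for i in range(8)
                           if row[i] and samples[i] != "s7")
        if groups:
            expected[groups] += 1
    assert v.regions == dict(expected)
    assert v.total == sum(expected.values())
    # permutation invariance over sample order
    perm = rng.permutation(8)
    m2 = _matrix(pres[:, perm].astype(float),
                 samples=[samples[i] for i in perm])
    assert sm.venn_counts(m2, meta).regions == v.regions


def test_venn_unmapped_sample_rejected():
    m = _matrix(np.ones((2, 2)))
    with pytest.raises(ValidationError):
        sm.venn_counts(m, _meta(["s0"], ["leaf"]))


# ---------------------------------------------------------------------------
# 'ili table


def _cube_mesh(side=10.0):
    v = np.array([[x, y, z] for x in (0, side) for y in (0, side)
                  for z in (0, side)], dtype=float)
    f = np.array([[0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5]])
    return Mesh(vertices=v, faces=f)


def test_eim_table_shape_and_blank_exclusion():
    m = _matrix(np.arange(6, dtype=float).reshape(2, 3) + 1.0)
    meta = [SampleMetadata("s0", "p", "leaf", False, 1, 1, 1, 0.5),
            SampleMetadata("s1", "p", "stem", False, 2, 2, 2, 0.5),
            SampleMetadata("s2", "none", "blank", True)]
    table = sm.build_eim_table(m, meta, _cube_mesh())
    assert table.sample_names == ["s0", "s1"]
    assert len(table.feature_names) == 2
    assert table.values.shape == (2, 2)
    assert table.feature_names[0] == "mz_200.0000_rt_10.0s"


def test_eim_table_coordinate_validation():
    m = _matrix(np.ones((1, 1)))
    meta = [SampleMetadata("s0", "p", "leaf", False, 99.0, 1.0, 1.0, 0.5)]
    with pytest.raises(ValidationError, match="s0"):
        sm.build_eim_table(m, meta, _cube_mesh())


def test_eim_localizes_tissue_exclusive_feature():
    """A fruit-only feature's column is non-zero exactly on fruit rows."""
    data = np.array([[5.0, 6.0, 0.0, 0.0],  # everywhere-but-fruit? no: rows
                     [0.0, 0.0, 3.0, 4.0]])  # fruit-only feature
    samples = ["leaf_0", "leaf_1", "fruit_0", "fruit_1"]
    m = _matrix(data, samples=samples)
    meta = [SampleMetadata(s, "p", s.split("_")[0], False, 1.0 + i, 1.0,
                           1.0, 0.5)
            for i, s in enumerate(samples)]
    table = sm.build_eim_table(m, meta, _cube_mesh())
    fruit_rows = [i for i, n in enumerate(table.sample_names)
                  if n.startswith("fruit")]
    col = table.values[:, 1]
    assert all(col[i] > 0 for i in fruit_rows)
    assert all(col[i] == 0 for i in range(4) if i not in fruit_rows)
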