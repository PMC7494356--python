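"""Coordinate system: enumeration, analysis, block-distribution duality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graytex as gt
from graytex import space as sp
from conftest import A_DIFF, D_DIFF, H_DIFF, H_SUM, V_SUM


@pytest.mark.parametrize(
    "G,order,n_groups",
    [(3, None, 33), (3, 1, 1), (3, 2, 8), (3, 3, 16), (3, 4, 8),
     (2, None, 10), (2, 1, 1), (2, 2, 4), (2, 3, 4), (2, 4, 1)],
)
def test_group_counts(G, order, n_groups):
    assert len(gt.enumerate_groups(G, order)) == n_groups


@pytest.mark.parametrize(
    "G,order,dim",
    [(3, None, 66), (2, None, 10), (3, 2, 16), (3, 3, 32), (3, 4, 16)],
)
def test_space_dimension(G, order, dim):
    assert gt.space_dimension(G, order) == dim


def test_pair_groups_are_four_orientations_times_sum_diff():
    pairs = gt.enumerate_groups(3, 2)
    supports = {g.support for g in pairs}
    assert len(supports) == 4  # horizontal, vertical, two diagonals
    for sup in supports:
        assert sum(g.support == sup for g in pairs) == 2  # sum and difference


def test_invalid_gray_levels():
    with pytest.raises(sp.InvalidParameterError):
        gt.enumerate_groups(1)
    with pytest.raises(sp.InvalidParameterError):
        gt.space_dimension(0)


def test_group_canonical_validation():
    with pytest.raises(sp.InvalidParameterError):
        gt.TextureGroup(3, (0, 0, 0, 0))
    with pytest.raises(sp.InvalidParameterError):
        gt.TextureGroup(3, (3, 0, 0, 0))


def test_analyze_constant_patch_all_groups():
    v = gt.analyze(np.zeros((8, 8), dtype=int))
    assert np.allclose(v.probs[:, 0], 1.0)
    assert np.allclose(v.probs[:, 1:], 0.0)


def test_analyze_hand_counts_periodic():
    # 2x2 periodic patch [[0,1],[2,0]]: horizontal sums over the 4 wrapped
    # placements are {1, 1, 2, 2}
    v = gt.analyze([[0, 1], [2, 0]], boundary="periodic")
    assert np.array_equal(v[H_SUM], [0.0, 0.5, 0.5])


def test_analyze_hand_counts_valid():
    # every horizontal difference is -1 = 2 (mod 3)
    v = gt.analyze([[0, 1, 2], [2, 0, 1]])
    assert np.array_equal(v[H_DIFF], [0.0, 0.0, 1.0])


def test_patch_size_guards():
    # a 2x2 patch accommodates every glider; anything thinner is rejected
    # at construction, so analysis never sees an undersized grid
    v = gt.analyze(np.zeros((2, 2), int), groups=[H_SUM], boundary="valid")
    assert np.array_equal(v[H_SUM], [1.0, 0.0, 0.0])
    with pytest.raises(sp.PatchSizeError):
        sp.GrayPatch(np.zeros((1, 5), int))
    with pytest.raises(sp.PatchSizeError):
        sp._stat_field(np.zeros((2, 1), dtype=np.int64), H_SUM, "valid")


def test_block_probabilities_point_mass_and_uniform(rng):
    P = gt.block_probabilities(np.zeros((6, 6), int))
    assert P[0] == 1.0 and P.sum() == 1.0
    big = rng.integers(0, 3, (400, 400))
    P = gt.block_probabilities(big)
    assert np.allclose(P, 1 / 81, atol=4 * np.sqrt((1 / 81) / big.size))


def test_block_probabilities_periodic_2x2():
    P = gt.block_probabilities([[0, 1], [2, 0]], boundary="periodic")
    assert np.isclose(P[P > 0].min(), 0.25) and (P > 0).sum() == 4


def test_coords_from_uniform_blocks_is_origin():
    v = gt.coords_from_block_probs(np.full(81, 1 / 81))
    assert np.allclose(v.probs, 1 / 3)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    G=st.sampled_from([2, 3]),
    h=st.integers(2, 6),
    w=st.integers(2, 6),
    seed=st.integers(0, 2**20),
)
def test_analyze_equals_block_marginalization_periodic(G, h, w, seed):
    """Gliding statistics and marginalizing the wrapped block histogram agree."""
    patch = np.random.default_rng(seed).integers(0, G, (h, w))
    a = gt.analyze(patch, boundary="periodic", G=G)
    b = gt.coords_from_block_probs(gt.block_probabilities(patch, "periodic", G), G)
    assert np.allclose(a.probs, b.probs, atol=1e-12)


def test_block_coords_round_trip_exact(rng):
    """coords -> blocks -> coords reproduces a translation-invariant P."""
    patch = rng.integers(0, 3, (5, 7))
    P = gt.block_probabilities(patch, boundary="periodic")
    v = gt.coords_from_block_probs(P)
    P2 = gt.block_probs_from_coords(v)
    assert np.allclose(P, P2, atol=1e-12)


def test_infeasible_coordinates_raise():
    # horizontal sums always 0 forces structure in the 4-point statistics;
    # demanding everything else uniform is inconsistent
    v = gt.origin_vector(3)
    probs = v.probs.copy()
    probs[v.group_index("beta(++)")] = [1, 0, 0]
    with pytest.raises(sp.InfeasibilityError):
        gt.block_probs_from_coords(sp.TextureVector(3, probs))


def test_level_relabeling_shifts_first_order_histogram(rng):
    patch = rng.integers(0, 3, (10, 10))
    gamma = gt.TextureGroup(3, (1, 0, 0, 0))
    v1 = gt.analyze(patch, boundary="periodic")[gamma]
    v2 = gt.analyze((patch + 1) % 3, boundary="periodic")[gamma]
    assert np.array_equal(np.roll(v1, 1), v2)


def test_large_iid_patch_converges_to_origin(rng):
    patch = rng.integers(0, 3, (200, 200))
    v = gt.analyze(patch)
    se = np.sqrt((1 / 3) * (2 / 3) / patch.size)
    assert np.abs(v.probs - 1 / 3).max() < 5 * se


def test_plane_point_origin_and_vertex():
    d = gt.PlaneDirection("simple", (H_SUM,), angle=0.0)
    assert np.allclose(d.point(0.0).probs, 1 / 3)
    vertex = d.point(np.sqrt(2 / 3))
    assert np.allclose(vertex[H_SUM], [1, 0, 0], atol=1e-12)
    # groups not named by the plane stay at the origin
    assert np.allclose(vertex[H_DIFF], 1 / 3)


def test_plane_point_simple_angles_hit_other_vertices():
    for k, h in [(1, 1), (2, 2)]:
        d = gt.PlaneDirection("simple", (H_SUM,), angle=2 * np.pi * k / 3)
        assert np.isclose(d.point(np.sqrt(2 / 3))[H_SUM][h], 1.0)


def test_plane_point_mixed_full_saturation():
    d = gt.PlaneDirection("mixed", (H_SUM, H_DIFF), angle=0.0, axes=(0, 1))
    v = d.point(1.0)
    assert np.isclose(v[H_SUM][0], 1.0)       # coordinate 1 = full saturation
    assert np.allclose(v[H_DIFF], 1 / 3)      # the other axis stays centered


def test_plane_point_negative_contrast_rejected():
    d = gt.PlaneDirection("simple", (H_SUM,), angle=0.0)
    with pytest.raises(sp.InvalidParameterError):
        d.point(-0.1)


def test_mixed_plane_requires_distinct_groups():
    with pytest.raises(sp.InvalidParameterError):
        gt.PlaneDirection("mixed", (H_SUM, H_SUM), angle=0.0, axes=(0, 1))


def test_texture_vector_io_round_trips(tmp_path, rng):
    v = gt.analyze(rng.integers(0, 3, (8, 8)))
    v.to_csv(tmp_path / "v.csv")
    v2 = sp.TextureVector.from_csv(tmp_path / "v.csv")
    assert v.allclose(v2)
    v3 = sp.TextureVector.from_json(v.to_json())
    assert v.allclose(v3)


def test_gray_patch_io_round_trips(tmp_path, rng):
    p = sp.GrayPatch(rng.integers(0, 3, (6, 6)))
    p.save_npy(tmp_path / "p.npy")
    p.save_txt(tmp_path / "p.txt")
    assert np.array_equal(sp.GrayPatch.load(tmp_path / "p.npy").values, p.values)
    assert np.array_equal(sp.GrayPatch.load(tmp_path / "p.txt").values, p.values)
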