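"""Symmetry group action on patches, coordinates and thresholds."""

from dataclasses import dataclass

import numpy as np
import pytest

import graytex as gt
from graytex import symmetry as sym
from graytex.space import InvalidParameterError, PlaneDirection
from conftest import A_DIFF, D_DIFF, H_DIFF, H_SUM, V_SUM


def test_apply_identity_and_involutions(rng):
    p = gt.GrayPatch(rng.integers(0, 3, (5, 7)))
    ident = sym.SymmetryTransformation("identity")
    assert np.array_equal(sym.apply_to_patch(ident, p).values, p.values)
    rot180 = sym.SymmetryTransformation("rot180")
    twice = sym.apply_to_patch(rot180, sym.apply_to_patch(rot180, p))
    assert np.array_equal(twice.values, p.values)


def test_exchange_black_white_on_zeros():
    t = sym.transformation_by_name("exch(B,W)")
    out = sym.apply_to_patch(t, np.zeros((4, 4), int))
    assert np.all(out.values == 2)


def test_value_map_names_cover_s3():
    names = {t.name for t in sym.all_transformations(3) if t.geometry == "identity"}
    assert names == {"identity", "exch(B,W)", "exch(B,G)", "exch(G,W)",
                     "cycle(BGW)", "cycle(BWG)"}


def test_non_affine_slope_rejected():
    with pytest.raises(InvalidParameterError):
        sym.SymmetryTransformation("identity", a=2, b=0, G=4)


def test_lrflip_on_horizontal_difference():
    """A left-right flip negates the horizontal difference statistic:
    h=1 and h=2 swap while h=0 is fixed."""
    t = sym.SymmetryTransformation("lrFlip")
    src, h_map = sym.transform_group(t, H_DIFF)
    assert src == H_DIFF and h_map == (0, 2, 1)


def test_lrflip_swaps_diagonal_orientations():
    t = sym.SymmetryTransformation("lrFlip")
    src, _ = sym.transform_group(t, D_DIFF)
    assert src.support == A_DIFF.support   # opposite diagonal
    src_back, _ = sym.transform_group(t, A_DIFF)
    assert src_back.support == D_DIFF.support


def test_rot90_maps_horizontal_to_vertical():
    t = sym.SymmetryTransformation("rot90")
    src, _ = sym.transform_group(t, H_SUM)
    assert src.support == V_SUM.support


def test_transform_coordinates_identity_and_origin(rng):
    v = gt.analyze(rng.integers(0, 3, (6, 6)), boundary="periodic")
    ident = sym.SymmetryTransformation("identity")
    assert sym.transform_coordinates(ident, v).allclose(v, atol=0)
    origin = gt.origin_vector(3)
    for t in sym.all_transformations(3):
        assert sym.transform_coordinates(t, origin).allclose(origin, atol=0)


def test_oracle_equality_patch_vs_coordinates(rng):
    """transform_coordinates exactly matches analyze(apply_to_patch)."""
    for t in sym.all_transformations(3):
        for _ in range(5):
            p = rng.integers(0, 3, (rng.integers(3, 7), rng.integers(3, 7)))
            lhs = gt.analyze(sym.apply_to_patch(t, gt.GrayPatch(p)),
                             boundary="periodic")
            rhs = sym.transform_coordinates(t, gt.analyze(p, boundary="periodic"))
            assert np.array_equal(lhs.probs, rhs.probs), t.name


def test_group_action_composition_and_inverse(rng):
    patch = rng.integers(0, 3, (6, 6))
    v = gt.analyze(patch, boundary="periodic")
    composable = [t for t in sym.all_transformations(3)
                  if t.geometry in ("identity", "rot90", "rot180", "rot270")]
    for t1 in composable[::5]:
        for t2 in composable[::7]:
            combined = t2.compose(t1)  # t1 first, then t2
            # patch-level oracle for the composition law
            via_pair_patch = sym.apply_to_patch(
                t2, sym.apply_to_patch(t1, gt.GrayPatch(patch)))
            direct_patch = sym.apply_to_patch(combined, gt.GrayPatch(patch))
            assert np.array_equal(via_pair_patch.values, direct_patch.values)
            # and the induced coordinate action respects it too
            via_pair = sym.transform_coordinates(
                t2, sym.transform_coordinates(t1, v))
            direct = sym.transform_coordinates(combined, v)
            assert np.array_equal(via_pair.probs, direct.probs)
    # inverses exist within the 36 and undo the action exactly
    for t in sym.all_transformations(3)[::4]:
        a_inv = pow(t.a, -1, 3)
        inv = sym.SymmetryTransformation(
            sym._GEOMETRY_INVERSE[t.geometry], a_inv, (-a_inv * t.b) % 3)
        back = sym.transform_coordinates(inv, sym.transform_coordinates(t, v))
        assert np.array_equal(back.probs, v.probs), t.name


def test_flip_rotation_composition_outside_set_rejected():
    t1 = sym.SymmetryTransformation("lrFlip")
    t2 = sym.SymmetryTransformation("rot90")
    with pytest.raises(InvalidParameterError):
        t1.compose(t2)


# -- threshold transport ----------------------------------------------------

@dataclass
class _Record:
    direction: PlaneDirection
    threshold: float


def _fan(group, thresholds):
    return [_Record(PlaneDirection("simple", (group,), 2 * np.pi * k / 12), t)
            for k, t in enumerate(thresholds)]


def test_threshold_change_identity_all_trivial():
    records = _fan(H_DIFF, np.full(12, 0.5))
    out = sym.threshold_change(sym.SymmetryTransformation("identity"), records)
    assert out["n_used"] == 0 and out["n_trivial"] == 12


def test_threshold_change_isotropic_thresholds_are_invariant():
    records = _fan(H_DIFF, np.full(12, 0.5)) + _fan(H_SUM, np.full(12, 0.5))
    t = sym.SymmetryTransformation("lrFlip")
    out = sym.threshold_change(t, records)
    assert out["n_used"] > 0
    assert np.allclose(out["log_differences"], 0.0)


def test_threshold_change_counts_unmatched():
    # lrFlip sends the diagonal-plane fan onto the (absent) anti-diagonal plane
    records = _fan(D_DIFF, np.full(12, 0.5))
    out = sym.threshold_change(sym.SymmetryTransformation("lrFlip"), records)
    assert out["n_unmatched"] == 12 and out["n_used"] == 0


def test_threshold_change_detects_asymmetry():
    # thresholds that vary around the fan change under a flip that reverses
    # the angle ordering
    vals = 0.5 * np.exp(0.3 * np.sin(2 * np.pi * np.arange(12) / 12))
    records = _fan(H_DIFF, vals)
    out = sym.threshold_change(sym.SymmetryTransformation("lrFlip"), records)
    assert out["n_used"] > 0
    assert np.abs(out["log_differences"]).max() > 0.1


def test_predicted_thresholds_invariant_for_symmetric_model(rng):
    """An isotropic Gaussian model predicts thresholds invariant under
    every geometric transformation (the blue-violin analogue)."""
    from graytex import prediction as pr

    model = pr.GaussianTextureModel(np.full(99, 1 / 3), np.eye(99))
    records = []
    for group in gt.enumerate_groups(3, 2):
        for k in range(12):
            d = PlaneDirection("simple", (group,), 2 * np.pi * k / 12)
            records.append(_Record(d, pr.predict_threshold(model, d)))
    for name in ("lrFlip", "udFlip", "rot90", "rot180"):
        out = sym.threshold_change(sym.SymmetryTransformation(name), records)
        assert out["n_used"] > 0
        assert np.abs(out["log_differences"]).max() < 1e-9, name
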