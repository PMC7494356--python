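"""Maximum-entropy synthesis: exactness, round trips, entropy, stimuli."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import graytex as gt
from graytex import space as sp
from graytex import synthesis as syn
from conftest import A_DIFF, D_DIFF, H_DIFF, H_SUM, V_SUM


@pytest.mark.parametrize("group,probs,h", [
    (H_SUM, (1, 0, 0), 0),
    (H_DIFF, (0, 0, 1), 2),   # 'mini-gradients' cycling through the levels
    (V_SUM, (0, 1, 0), 1),
    (D_DIFF, (1, 0, 0), 0),
    (A_DIFF, (0, 0, 1), 2),
])
def test_degenerate_targets_are_exact(group, probs, h):
    patch = gt.synthesize_single_group(group, probs, 16, seed=0)
    assert gt.analyze(patch)[group][h] == 1.0


def test_horizontal_sum_saturation_gives_constant_pair_sums():
    patch = gt.synthesize_single_group(H_SUM, (1, 0, 0), 16, seed=1)
    sums = (patch.values[:, :-1] + patch.values[:, 1:]) % 3
    assert np.all(sums == 0)


def test_seed_determinism():
    a = gt.synthesize_single_group(H_SUM, (0.5, 0.3, 0.2), 32, seed=9)
    b = gt.synthesize_single_group(H_SUM, (0.5, 0.3, 0.2), 32, seed=9)
    c = gt.synthesize_single_group(H_SUM, (0.5, 0.3, 0.2), 32, seed=10)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_invalid_target_distribution_rejected():
    with pytest.raises(sp.InfeasibilityError):
        gt.synthesize_single_group(H_SUM, (0.8, 0.8, -0.6), 16, seed=0)


@pytest.mark.parametrize("group", [H_DIFF, D_DIFF])
def test_single_group_round_trip(group):
    target = np.array([0.55, 0.25, 0.20])
    vals = [gt.analyze(gt.synthesize_single_group(group, target, 64, s),
                       groups=[group])[group] for s in range(5)]
    assert np.abs(np.mean(vals, axis=0) - target).max() < 0.02


def test_other_low_order_groups_stay_uniform():
    """Constraining one pair group leaves the histogram and the other pair
    groups at the unbiased point (the maximum-entropy property)."""
    patch = gt.synthesize_single_group(H_SUM, (0.7, 0.2, 0.1), 96, seed=4)
    v = gt.analyze(patch)
    n = 96 * 95
    tol = 5 * np.sqrt((1 / 3) * (2 / 3) / n)
    for g in gt.enumerate_groups(3, 1) + gt.enumerate_groups(3, 2):
        if g == H_SUM:
            continue
        assert np.abs(v[g] - 1 / 3).max() < tol, g.name


def test_unconstrained_origin_target_looks_iid():
    patch = gt.synthesize_single_group(H_SUM, (1 / 3, 1 / 3, 1 / 3), 128, seed=2)
    v = gt.analyze(patch)
    assert np.abs(v.probs - 1 / 3).max() < 5 * np.sqrt((2 / 9) / (127 * 127))


def test_small_patch_entropy_matches_iid_reference(rng):
    """Distribution of an unconstrained group's coordinate on 4x4 patches
    matches the i.i.d.-uniform reference (two-sample test, alpha=0.01)."""
    n = 2000
    counts_syn = np.zeros(17, dtype=int)
    counts_iid = np.zeros(17, dtype=int)
    for s in range(n):
        patch = gt.synthesize_single_group(H_SUM, (0.5, 0.3, 0.2), 4, seed=s)
        stat = sp._stat_field(patch.values, V_SUM, "periodic")
        counts_syn[int(np.sum(stat == 0))] += 1
        iid = rng.integers(0, 3, (4, 4))
        stat = sp._stat_field(iid, V_SUM, "periodic")
        counts_iid[int(np.sum(stat == 0))] += 1
    keep = (counts_syn + counts_iid) > 5
    _, p, *_ = chi2_contingency(np.vstack([counts_syn[keep], counts_iid[keep]]))
    assert p > 0.01


def test_mixed_round_trip_recovers_both_axes():
    vals_a, vals_b = [], []
    for s in range(10):
        patch = gt.synthesize_mixed(H_SUM, 0, 0.6, H_DIFF, 1, 1 / 3, 64, seed=s)
        v = gt.analyze(patch, groups=[H_SUM, H_DIFF])
        vals_a.append(v[H_SUM][0])
        vals_b.append(v[H_DIFF][1])
    assert abs(np.mean(vals_a) - 0.6) < 0.02
    assert abs(np.mean(vals_b) - 1 / 3) < 0.02


def test_mixed_origin_looks_iid():
    patch = gt.synthesize_mixed(H_SUM, 0, 1 / 3, V_SUM, 0, 1 / 3, 64, seed=0)
    v = gt.analyze(patch)
    assert np.abs(v.probs - 1 / 3).max() < 6 * np.sqrt((2 / 9) / (63 * 63))


def test_mixed_cross_orientation_constraints():
    patch = gt.synthesize_mixed(H_SUM, 0, 0.55, V_SUM, 1, 0.45, 64, seed=3)
    v = gt.analyze(patch, groups=[H_SUM, V_SUM])
    assert abs(v[H_SUM][0] - 0.55) < 0.035
    assert abs(v[V_SUM][1] - 0.45) < 0.035


def test_mixed_double_saturation_is_infeasible():
    with pytest.raises(sp.InfeasibilityError):
        gt.synthesize_mixed(H_SUM, 0, 1.0, H_DIFF, 1, 1.0, 32, seed=0)


def test_mixed_requires_distinct_groups():
    with pytest.raises(sp.InvalidParameterError):
        gt.synthesize_mixed(H_SUM, 0, 0.5, H_SUM, 1, 0.5, 32, seed=0)


def test_mixed_determinism():
    a = gt.synthesize_mixed(H_SUM, 0, 0.5, H_DIFF, 0, 0.4, 32, seed=11)
    b = gt.synthesize_mixed(H_SUM, 0, 0.5, H_DIFF, 0, 0.4, 32, seed=11)
    assert np.array_equal(a.values, b.values)


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


def test_stimulus_geometry_top_structured_target():
    spec = gt.SynthesisSpec(single=(H_SUM, (1, 0, 0)))
    stim = gt.make_stimulus(spec, "top", structured_target=True, seed=5)
    assert stim.shape == (64, 64)
    strip = stim.values[8:24, :]  # rows 9-24 in 1-based indexing
    assert np.all((strip[:, :-1] + strip[:, 1:]) % 3 == 0)
    rest = np.concatenate([stim.values[:8].ravel(), stim.values[24:].ravel()])
    # background is i.i.d. uniform
    frac = np.bincount(rest, minlength=3) / rest.size
    assert np.abs(frac - 1 / 3).max() < 5 * np.sqrt((2 / 9) / rest.size)


def test_stimulus_structured_background():
    spec = gt.SynthesisSpec(single=(H_SUM, (1, 0, 0)))
    stim = gt.make_stimulus(spec, "left", structured_target=False, seed=5)
    bg = stim.values[:, 30:]  # far from the left strip (cols 8:24)
    assert np.all((bg[:, :-1] + bg[:, 1:]) % 3 == 0)


@pytest.mark.parametrize("side,rows,cols", [
    ("top", (8, 24), (0, 64)), ("bottom", (40, 56), (0, 64)),
    ("left", (0, 64), (8, 24)), ("right", (0, 64), (40, 56)),
])
def test_strip_slices(side, rows, cols):
    rs, cs = gt.strip_slices(side)
    assert (rs.start, rs.stop) == rows and (cs.start, cs.stop) == cols


def test_stimulus_invalid_side():
    spec = gt.SynthesisSpec(single=(H_SUM, (1, 0, 0)))
    with pytest.raises(sp.InvalidParameterError):
        gt.make_stimulus(spec, "diagonal", True, seed=0)


def test_stimulus_determinism_and_origin_indistinguishable():
    spec = gt.SynthesisSpec(single=(H_SUM, (1 / 3, 1 / 3, 1 / 3)))
    a = gt.make_stimulus(spec, "top", True, seed=3)
    b = gt.make_stimulus(spec, "top", True, seed=3)
    assert np.array_equal(a.values, b.values)
    strip = gt.analyze(a.values[8:24, :])
    assert np.abs(strip.probs - 1 / 3).max() < 0.12  # strip ~ background


def test_synthesis_spec_validation():
    with pytest.raises(sp.InvalidParameterError):
        gt.SynthesisSpec()  # neither single nor mixed
    with pytest.raises(sp.InvalidParameterError):
        gt.SynthesisSpec(single=(H_SUM, (1, 0, 0)),
                         mixed=((H_SUM, 0, 0.5), (H_DIFF, 0, 0.5)))
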