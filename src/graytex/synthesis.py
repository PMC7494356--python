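"""Maximum-entropy texture synthesis and 4AFC stimulus rendering.

Single-group textures are generated by seeding the patch with i.i.d. uniform
levels and sweeping it in raster order: wherever a glider placement has its
last (raster-order) support cell at the current position, the modular
statistic ``h`` is drawn from the target distribution and the cell is solved
for, ``x = s_last^{-1} (h - sum_others s_i A_i) mod G``.  Every placement of
the minimal glider then carries an independent draw from the target
distribution, and all unconstrained degrees of freedom remain uniform — the
maximum-entropy texture with that group's coordinates fixed.

Textures constrained in two groups at once are generated by the same
sequential fill with *tilted* conditionals: each cell is sampled with weights
``prod_c w_c[h_c(x)]`` where ``w_c`` boosts the constrained value of group
``c``'s statistic by ``exp(lambda_c)``.  The tilt parameters are calibrated by
a damped fixed-point iteration until the realized axis probabilities match
the targets; combinations for which the iteration cannot reach the target
(deep saturation in both groups) raise :class:`InfeasibilityError`, mirroring
the fact that not all coordinate combinations are achievable in a real
texture.  Near the origin the calibration converges quickly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .space import (
    GrayPatch,
    InfeasibilityError,
    InvalidParameterError,
    TextureGroup,
    _stat_field,
)

__all__ = [
    "SynthesisSpec",
    "synthesize_single_group",
    "synthesize_mixed",
    "synthesize",
    "make_stimulus",
    "strip_slices",
    "STIMULUS_SIZE",
    "STRIP_THICKNESS",
    "STRIP_MARGIN",
]

STIMULUS_SIZE = 64
STRIP_THICKNESS = 16
STRIP_MARGIN = 8

_HARD = 1e-9


def _group_fill_info(group: TextureGroup):
    """Raster-order fill metadata: determined cell, other support cells."""
    support = [(pos, s) for pos, s in zip(
        ((0, 0), (0, 1), (1, 0), (1, 1)), group.coeffs) if s]
    (det_pos, det_coeff) = support[-1]
    others = support[:-1]
    inv = pow(det_coeff, -1, group.G)
    return det_pos, det_coeff, inv, others, group.bbox


def _validate_probs(probs, G: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (G,):
        raise InvalidParameterError(f"probs must have {G} entries")
    if p.min() < -1e-12 or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise InfeasibilityError(
            f"target probabilities must be a distribution, got {p.tolist()}"
        )
    return np.clip(p, 0.0, None) / p.sum()


def synthesize_single_group(group: TextureGroup, probs, size, seed) -> GrayPatch:
    """Maximum-entropy patch with one group's coordinates fixed at ``probs``.

    Parameters
    ----------
    group : TextureGroup
    probs : array of G probabilities for ``h = 0..G-1``
    size : int or (rows, cols)
    seed : int or numpy Generator

    The constrained group's empirical coordinates are an i.i.d. multinomial
    sample of the target (exact for degenerate targets); all other groups'
    coordinates converge to ``1/G`` as the patch grows.  Deterministic given
    the seed.
    """
    G = group.G
    p = _validate_probs(probs, G)
    H, W = (size, size) if np.isscalar(size) else size
    if H < 2 or W < 2:
        raise InvalidParameterError("size must be at least 2x2")
    rng = np.random.default_rng(seed)
    A = rng.integers(0, G, (H, W))
    (dr, dc), _, inv, others, (br, bc) = _group_fill_info(group)
    i_lo, i_hi = dr, H - br + dr          # inclusive constrained-row range
    j_lo, j_hi = dc, W - bc + dc          # inclusive constrained-col range
    if i_hi < i_lo or j_hi < j_lo:
        raise InvalidParameterError("patch too small for this group's glider")
    h_draws = rng.choice(G, size=(i_hi - i_lo + 1, j_hi - j_lo + 1), p=p)

    same_row = any(r == dr for (r, _), _ in others)
    past_cols_only = all(c < dc for (_, c), _ in others)
    if not same_row:
        # all context cells are in earlier rows: sweep rows, vector over cols
        for i in range(i_lo, i_hi + 1):
            acc = np.zeros(j_hi - j_lo + 1, dtype=np.int64)
            for (r, c), s in others:
                acc += s * A[i - dr + r, j_lo - dc + c : j_hi - dc + c + 1]
            A[i, j_lo : j_hi + 1] = (inv * (h_draws[i - i_lo] - acc)) % G
    elif past_cols_only:
        # all context cells are in earlier columns: sweep cols, vector over rows
        for j in range(j_lo, j_hi + 1):
            acc = np.zeros(i_hi - i_lo + 1, dtype=np.int64)
            for (r, c), s in others:
                acc += s * A[i_lo - dr + r : i_hi - dr + r + 1, j - dc + c]
            A[i_lo : i_hi + 1, j] = (inv * (h_draws[:, j - j_lo] - acc)) % G
    else:
        # wavefront dependency (some theta and the alpha group): per-cell fill
        for i in range(i_lo, i_hi + 1):
            for j in range(j_lo, j_hi + 1):
                acc = 0
                for (r, c), s in others:
                    acc += s * A[i - dr + r, j - dc + c]
                A[i, j] = (inv * (int(h_draws[i - i_lo, j - j_lo]) - acc)) % G
    return GrayPatch(A, G)


# ---------------------------------------------------------------------------
# Mixed-group synthesis
# ---------------------------------------------------------------------------


def _tilt_weights(value: float, lam: float, h_target: int, G: int) -> np.ndarray:
    w = np.ones(G)
    if value >= 1.0 - _HARD:
        w[:] = 0.0
        w[h_target] = 1.0
    elif value <= _HARD:
        w[h_target] = 0.0
    else:
        w[h_target] = np.exp(lam)
    return w


def _fill_tilted(constraints, size, rng, G: int) -> GrayPatch:
    """Sequential raster fill with per-constraint tilted conditionals.

    ``constraints``: list of (group, h_target, value, lam).
    """
    H, W = size
    A = rng.integers(0, G, (H, W))
    infos = []
    for group, h_target, value, lam in constraints:
        (dr, dc), det_coeff, _, others, (br, bc) = _group_fill_info(group)
        w = _tilt_weights(value, lam, h_target, G)
        infos.append(((dr, dc), det_coeff, others, (br, bc), w))
    uniforms = rng.random((H, W))
    levels = np.arange(G)
    for i in range(H):
        for j in range(W):
            weights = None
            for (dr, dc), det_coeff, others, (br, bc), w in infos:
                oi, oj = i - dr, j - dc
                if oi < 0 or oj < 0 or oi + br > H or oj + bc > W:
                    continue
                acc = 0
                for (r, c), s in others:
                    acc += s * A[oi + r, oj + c]
                h_of_x = (det_coeff * levels + acc) % G
                wc = w[h_of_x]
                weights = wc if weights is None else weights * wc
            if weights is None:
                continue  # unconstrained cell keeps its uniform seed
            total = weights.sum()
            if total <= 0.0:
                raise InfeasibilityError(
                    "conditional probabilities vanished during synthesis; "
                    "the requested coordinate combination is not achievable"
                )
            cdf = np.cumsum(weights) / total
            A[i, j] = int(np.searchsorted(cdf, uniforms[i, j], side="right"))
    return GrayPatch(A, G)


def _axis_probability(patch: GrayPatch, group: TextureGroup, h: int) -> float:
    stat = _stat_field(patch.values, group, "valid")
    return float(np.mean(stat == h))


def _spec_digest(parts) -> int:
    text = json.dumps(parts, sort_keys=True)
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


@lru_cache(maxsize=128)
def _calibrate_tilts(key: tuple, G: int) -> tuple[float, ...]:
    """Fixed-point calibration of the tilt parameters.

    Deterministic: the calibration RNG is derived from the constraint targets
    themselves, so the returned tilts are a pure function of the request.
    """
    constraints = [(TextureGroup(G, coeffs), h, v) for coeffs, h, v in key]
    soft = [k for k, (_, _, v) in enumerate(constraints) if _HARD < v < 1.0 - _HARD]
    lams = []
    for _, _, v in constraints:
        if _HARD < v < 1.0 - _HARD:
            lams.append(float(np.log(v * (G - 1) / (1.0 - v))))
        else:
            lams.append(0.0)
    if not soft:
        return tuple(lams)
    rng = np.random.default_rng(
        _spec_digest([[list(c), h, v] for c, h, v in key])
    )
    size = (72, 72)
    tol, max_iter = 0.012, 30
    for it in range(max_iter):
        packed = [
            (g, h, v, lam) for (g, h, v), lam in zip(constraints, lams)
        ]
        patch = _fill_tilted(packed, size, rng, G)
        resid = 0.0
        for k in soft:
            g, h, v = constraints[k]
            q = min(max(_axis_probability(patch, g, h), 1e-4), 1.0 - 1e-4)
            resid = max(resid, abs(q - v))
            step = np.log(v * (1.0 - q) / (q * (1.0 - v)))
            lams[k] += 0.7 * float(np.clip(step, -1.5, 1.5))
        if resid < tol:
            return tuple(lams)
        if max(abs(l) for l in lams) > 14.0:
            break
    raise InfeasibilityError(
        "tilt calibration did not converge; requested combination "
        f"{[(g.name, h, v) for g, h, v in constraints]} appears infeasible"
    )


def synthesize_mixed(group_a: TextureGroup, h_a: int, value_a: float,
                     group_b: TextureGroup, h_b: int, value_b: float,
                     size, seed) -> GrayPatch:
    """Maximum-entropy patch with one axis probability fixed in each of two groups.

    ``value_x`` is the probability that group ``x``'s statistic equals
    ``h_x``; the origin corresponds to ``value = 1/G``.  Raises
    :class:`InfeasibilityError` when the combination cannot be realized
    (e.g. full saturation in both groups simultaneously).
    """
    if group_a.G != group_b.G:
        raise InvalidParameterError("groups must share the same G")
    if group_a == group_b:
        raise InvalidParameterError("mixed synthesis requires two distinct groups")
    G = group_a.G
    for h, v in ((h_a, value_a), (h_b, value_b)):
        if not 0 <= h < G:
            raise InvalidParameterError(f"axis index {h} out of range")
        if not -1e-12 <= v <= 1.0 + 1e-12:
            raise InfeasibilityError(f"axis probability {v} outside [0, 1]")
    H, W = (size, size) if np.isscalar(size) else size
    key = (
        (group_a.coeffs, int(h_a), round(float(value_a), 12)),
        (group_b.coeffs, int(h_b), round(float(value_b), 12)),
    )
    lams = _calibrate_tilts(key, G)
    constraints = [
        (group_a, h_a, float(value_a), lams[0]),
        (group_b, h_b, float(value_b), lams[1]),
    ]
    rng = np.random.default_rng(seed)
    return _fill_tilted(constraints, (H, W), rng, G)


# ---------------------------------------------------------------------------
# Specs and stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthesisSpec:
    """Target for a synthesized patch.

    ``single``: ``(group, probs)`` fixing one group's full coordinate triplet.
    ``mixed``: ``((group_a, h_a, value_a), (group_b, h_b, value_b))``.
    Exactly one of the two must be given.
    """

    size: tuple[int, int] = (STIMULUS_SIZE, STIMULUS_SIZE)
    single: tuple | None = None
    mixed: tuple | None = None

    def __post_init__(self):
        if (self.single is None) == (self.mixed is None):
            raise InvalidParameterError("specify exactly one of single= or mixed=")


def synthesize(spec: SynthesisSpec, seed) -> GrayPatch:
    if spec.single is not None:
        group, probs = spec.single
        return synthesize_single_group(group, probs, spec.size, seed)
    (ga, ha, va), (gb, hb, vb) = spec.mixed
    return synthesize_mixed(ga, ha, va, gb, hb, vb, spec.size, seed)


def strip_slices(side: str) -> tuple[slice, slice]:
    """Row/column slices (0-based) of the 16x64 target strip for each side.

    The strip sits at an 8-check margin from the named side of the 64x64
    array; e.g. ``side='top'`` occupies rows 8..23 (1-based rows 9-24).
    """
    lo = STRIP_MARGIN
    hi = STRIP_MARGIN + STRIP_THICKNESS
    full = slice(0, STIMULUS_SIZE)
    far_lo = STIMULUS_SIZE - STRIP_MARGIN - STRIP_THICKNESS
    far_hi = STIMULUS_SIZE - STRIP_MARGIN
    if side == "top":
        return slice(lo, hi), full
    if side == "bottom":
        return slice(far_lo, far_hi), full
    if side == "left":
        return full, slice(lo, hi)
    if side == "right":
        return full, slice(far_lo, far_hi)
    raise InvalidParameterError(f"side must be left/right/top/bottom, got {side!r}")


def make_stimulus(texture: SynthesisSpec, side: str, structured_target: bool,
                  seed, G: int = 3) -> GrayPatch:
    """Render a 64x64-check 4AFC stimulus array.

    A 16x64 (or 64x16) strip at an 8-check margin from ``side`` is filled
    from one distribution and the remainder from the other: the structured
    texture follows ``texture``; the unstructured texture is i.i.d. uniform
    over the G levels.  ``structured_target=True`` puts the structured
    texture in the strip.  Deterministic given the seed.
    """
    rs, cs = strip_slices(side)
    ss = np.random.SeedSequence(seed)
    s_tex, s_iid = ss.spawn(2)
    rng = np.random.default_rng(s_iid)
    if structured_target:
        canvas = rng.integers(0, G, (STIMULUS_SIZE, STIMULUS_SIZE))
        shape = (rs.stop - rs.start, cs.stop - cs.start)
        spec = SynthesisSpec(size=shape, single=texture.single, mixed=texture.mixed)
        canvas[rs, cs] = synthesize(spec, s_tex).values
    else:
        spec = SynthesisSpec(size=(STIMULUS_SIZE, STIMULUS_SIZE),
                             single=texture.single, mixed=texture.mixed)
        canvas = synthesize(spec, s_tex).values.copy()
        canvas[rs, cs] = rng.integers(0, G, (rs.stop - rs.start, cs.stop - cs.start))
    return GrayPatch(canvas, G)


def save_png(patch: GrayPatch, path) -> None:
    """Write a patch as PNG, levels mapped linearly onto 0..255."""
    import imageio.v3 as iio

    lut = np.linspace(0, 255, patch.G).astype(np.uint8)
    iio.imwrite(path, lut[patch.values])
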