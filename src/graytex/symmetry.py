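"""Geometric and gray-level symmetries and their action on texture coordinates.

A transformation combines a geometric operation on the patch (flips and
clockwise rotations from the dihedral group of the square) with an affine
relabeling of the gray levels, ``v -> a*v + b (mod G)`` with ``a`` a unit.
For ``G = 3`` the six affine maps realize every permutation of the three
levels, so exchanges such as ``exch(B,W)`` (black/white swap, ``v -> 2 - v``)
are exact affine maps.

The induced action on texture coordinates is computed exactly: the geometry
permutes the glider stencil, translation invariance re-anchors its support,
re-canonicalization multiplies by a unit ``u``, and the affine value map sends
the statistic ``s.A`` to ``a*(s.A) + b*sum(s)``; composing these gives the
target canonical group together with a permutation of the ``h`` labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .space import (
    GrayPatch,
    InvalidParameterError,
    PlaneDirection,
    TextureGroup,
    TextureVector,
    _canonicalize,
    as_patch,
    enumerate_groups,
)

__all__ = [
    "GEOMETRIES",
    "SymmetryTransformation",
    "all_transformations",
    "transformation_by_name",
    "apply_to_patch",
    "transform_group",
    "transform_coordinates",
    "transform_direction",
    "threshold_change",
]

GEOMETRIES = ("identity", "lrFlip", "udFlip", "rot90", "rot180", "rot270")

_LEVEL_CHARS = {0: "B", 1: "G", 2: "W"}


def _value_map_name(a: int, b: int, G: int) -> str:
    if (a, b) == (1, 0):
        return "id"
    if G == 3:
        perm = tuple((a * v + b) % 3 for v in range(3))
        swaps = {(0, 2, 1): "exch(G,W)", (2, 1, 0): "exch(B,W)", (1, 0, 2): "exch(B,G)"}
        cycles = {(1, 2, 0): "cycle(BGW)", (2, 0, 1): "cycle(BWG)"}
        if perm in swaps:
            return swaps[perm]
        if perm in cycles:
            return cycles[perm]
    return f"affine({a},{b})"


@dataclass(frozen=True)
class SymmetryTransformation:
    """A geometric transform followed by an affine gray-level map."""

    geometry: str = "identity"
    a: int = 1
    b: int = 0
    G: int = 3

    def __post_init__(self):
        if self.geometry not in GEOMETRIES:
            raise InvalidParameterError(f"unknown geometry {self.geometry!r}")
        import math

        if math.gcd(self.a % self.G, self.G) != 1:
            raise InvalidParameterError(
                f"value-map slope {self.a} is not invertible mod {self.G}; "
                "only affine gray-level permutations are supported"
            )

    @property
    def name(self) -> str:
        vm = _value_map_name(self.a % self.G, self.b % self.G, self.G)
        if vm == "id":
            return self.geometry
        if self.geometry == "identity":
            return vm
        return f"{self.geometry}+{vm}"

    def compose(self, other: "SymmetryTransformation") -> "SymmetryTransformation":
        """``self`` applied after ``other`` (patch-level composition).

        Only defined when the two geometries compose to a supported geometry
        (the six listed ones do not form a closed subgroup of D4 by
        themselves only for flip*rotation products, which produce the two
        diagonal flips; those compositions raise).
        """
        geo = _compose_geometry(self.geometry, other.geometry)
        a = (self.a * other.a) % self.G
        b = (self.a * other.b + self.b) % self.G
        return SymmetryTransformation(geo, a, b, self.G)


def _compose_geometry(g1: str, g2: str) -> str:
    table = _geometry_matrices()
    m = table[g1] @ table[g2]
    for name, mat in table.items():
        if np.array_equal(m, mat):
            return name
    raise InvalidParameterError(
        f"composition of {g1} and {g2} is a diagonal flip, outside the supported set"
    )


@lru_cache(maxsize=None)
def _geometry_matrices() -> dict:
    """2x2 integer matrices acting on (row, col) offsets.

    ``rot90`` is a *clockwise* quarter turn of the image.
    """
    return {
        "identity": np.array([[1, 0], [0, 1]]),
        "lrFlip": np.array([[1, 0], [0, -1]]),
        "udFlip": np.array([[-1, 0], [0, 1]]),
        # clockwise rotation: new(row, col) = (col, n-1-row) -> offset map
        "rot90": np.array([[0, 1], [-1, 0]]),
        "rot180": np.array([[-1, 0], [0, -1]]),
        "rot270": np.array([[0, -1], [1, 0]]),
    }


def _geom_array(geometry: str, arr: np.ndarray) -> np.ndarray:
    if geometry == "identity":
        return arr.copy()
    if geometry == "lrFlip":
        return np.flip(arr, axis=1)
    if geometry == "udFlip":
        return np.flip(arr, axis=0)
    if geometry == "rot90":  # clockwise
        return np.rot90(arr, k=-1)
    if geometry == "rot180":
        return np.rot90(arr, k=2)
    if geometry == "rot270":  # clockwise 270 == counterclockwise 90
        return np.rot90(arr, k=1)
    raise InvalidParameterError(f"unknown geometry {geometry!r}")


_GEOMETRY_INVERSE = {
    "identity": "identity",
    "lrFlip": "lrFlip",
    "udFlip": "udFlip",
    "rot90": "rot270",
    "rot180": "rot180",
    "rot270": "rot90",
}


def all_transformations(G: int = 3) -> tuple[SymmetryTransformation, ...]:
    """All geometry x affine-value-map combinations (36 for G=3)."""
    import math

    out = []
    for geo in GEOMETRIES:
        for a in range(1, G):
            if math.gcd(a, G) != 1:
                continue
            for b in range(G):
                out.append(SymmetryTransformation(geo, a, b, G))
    return tuple(out)


def transformation_by_name(name: str, G: int = 3) -> SymmetryTransformation:
    for t in all_transformations(G):
        if t.name == name:
            return t
    raise KeyError(f"unknown transformation {name!r}")


def apply_to_patch(t: SymmetryTransformation, patch) -> GrayPatch:
    """Geometric transform of the grid followed by the gray-level map."""
    p = as_patch(patch, t.G)
    vals = _geom_array(t.geometry, p.values)
    return GrayPatch((t.a * vals + t.b) % t.G, t.G)


@lru_cache(maxsize=None)
def transform_group(t: SymmetryTransformation, group: TextureGroup):
    """Source group and h relabeling induced by ``t``.

    Returns ``(source, h_map)`` such that for any patch ``P`` (periodic
    boundary), ``analyze(apply_to_patch(t, P))[group][h] ==
    analyze(P)[source][h_map[h]]``.

    The h relabeling follows from ``s.(a*A + b) = a*(s.A) + b*sum(s)`` and
    from the unit ``u`` used to re-canonicalize the geometrically permuted
    stencil.
    """
    G = t.G
    # stencil of the statistic measured on the transformed patch, pulled back
    # to original-patch coordinates: apply the inverse geometry to the stencil
    sten = _geom_array(_GEOMETRY_INVERSE[t.geometry], group.stencil)
    canon, u = _canonicalize(tuple(int(x) for x in sten.ravel()), G)
    source = TextureGroup(G, canon)
    a_inv = pow(t.a % G, -1, G)
    sigma = group.coeff_sum()
    h_map = tuple((u * a_inv * (h - t.b * sigma)) % G for h in range(G))
    return source, h_map


def transform_coordinates(t: SymmetryTransformation, v: TextureVector) -> TextureVector:
    """Coordinates of the transformed patch, computed without touching pixels.

    Exactly equals ``analyze(apply_to_patch(t, p), boundary='periodic')`` when
    ``v = analyze(p, boundary='periodic')``.
    """
    if v.G != t.G:
        raise InvalidParameterError("transformation and vector disagree on G")
    groups = enumerate_groups(v.G)
    out = np.empty_like(v.probs)
    for i, g in enumerate(groups):
        source, h_map = transform_group(t, g)
        si = groups.index(source)
        out[i] = v.probs[si, list(h_map)]
    return TextureVector(v.G, out, strict=False)


def transform_vector_flat(t: SymmetryTransformation, flat: np.ndarray) -> np.ndarray:
    """Action of ``t`` on a flattened coordinate vector or offset (linear)."""
    G = t.G
    n = len(enumerate_groups(G))
    v = np.asarray(flat, dtype=float).reshape(n, G)
    groups = enumerate_groups(G)
    out = np.empty_like(v)
    for i, g in enumerate(groups):
        source, h_map = transform_group(t, g)
        out[i] = v[groups.index(source), list(h_map)]
    return out.ravel()


def transform_direction(t: SymmetryTransformation, direction: PlaneDirection) -> np.ndarray:
    """Unit-contrast displacement of the transformed direction (flattened)."""
    return transform_vector_flat(t, direction.displacement(1.0))


def threshold_change(t: SymmetryTransformation, records: Sequence) -> dict:
    """Log-threshold differences induced by a symmetry transformation.

    Each record must expose ``direction`` (a :class:`PlaneDirection`) and
    ``threshold``.  For every record, the direction is mapped through ``t``
    and paired with the record measured at the transformed direction.
    Directions on which ``t`` acts trivially are excluded, as are transformed
    directions with no available measurement.

    Returns a dict with ``log_differences`` (array of
    ``log t(transformed) - log t(original)``), and the counts ``n_used``,
    ``n_trivial``, ``n_unmatched``.
    """
    records = list(records)
    keys = [np.round(r.direction.displacement(1.0), 9).tobytes() for r in records]
    lookup = {k: r for k, r in zip(keys, records)}
    diffs, n_trivial, n_unmatched = [], 0, 0
    for r, k in zip(records, keys):
        mapped = np.round(transform_direction(t, r.direction), 9).tobytes()
        if mapped == k:
            n_trivial += 1
            continue
        target = lookup.get(mapped)
        if target is None:
            n_unmatched += 1
            continue
        diffs.append(np.log(target.threshold) - np.log(r.threshold))
    return {
        "log_differences": np.asarray(diffs),
        "n_used": len(diffs),
        "n_trivial": n_trivial,
        "n_unmatched": n_unmatched,
    }
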