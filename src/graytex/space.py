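"""Translation-invariant coordinates for local grayscale textures.

A texture with ``G`` gray levels is characterized by the joint statistics of
2x2 blocks of checks.  Translation invariance makes the ``G**4`` block
probabilities redundant; a non-redundant parameterization is obtained from the
characters of the additive group Z_G acting on linear combinations of the four
check values.  Each *texture group* is a coefficient vector
``s = (s1, s2, s3, s4)`` over the glider positions (row-major, A1 top-left),
taken modulo translation of its support and modulo multiplication by a unit of
Z_G.  The group's coordinates are the probabilities ``p_h`` that

    s1*A1 + s2*A2 + s3*A3 + s4*A4  =  h   (mod G)

for ``h = 0 .. G-1``.  For ``G = 3`` there are 33 canonical groups
(1 first-order, 8 second-order, 16 third-order, 8 fourth-order), each carrying
``G - 1`` independent probabilities, for a 66-dimensional texture space; the
binary case ``G = 2`` gives the familiar 10 dimensions.

Flattening convention (version 1, relied on by all downstream covariance
math): groups ordered by (order, support in raster order, coefficients
lexicographically); within each group ``h = 0, 1, ..., G-1``.  The full
flattened vector therefore has ``n_groups * G`` entries; each group's entries
sum to one, so the affine dimension is ``n_groups * (G - 1)``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GrayPatch",
    "TextureGroup",
    "TextureVector",
    "PlaneDirection",
    "enumerate_groups",
    "space_dimension",
    "analyze",
    "block_counts",
    "block_probabilities",
    "coords_from_block_probs",
    "block_probs_from_coords",
    "origin_vector",
    "plane_point",
    "COORDINATE_VERSION",
]

COORDINATE_VERSION = 1

#: Glider positions in row-major order: A1 top-left, A2 top-right,
#: A3 bottom-left, A4 bottom-right.
GLIDER_POSITIONS = ((0, 0), (0, 1), (1, 0), (1, 1))

_ORDER_LETTERS = {1: "gamma", 2: "beta", 3: "theta", 4: "alpha"}
_ORDER_GREEK = {1: "γ", 2: "β", 3: "θ", 4: "α"}


class InvalidParameterError(ValueError):
    """Raised for out-of-domain parameters (e.g. G < 2)."""


class PatchSizeError(ValueError):
    """Raised when a patch is too small for the requested operation."""


class InfeasibilityError(ValueError):
    """Raised when requested texture coordinates cannot be realized."""


def _check_gray_levels(G: int) -> None:
    if not isinstance(G, (int, np.integer)) or G < 2:
        raise InvalidParameterError(f"number of gray levels must be >= 2, got {G!r}")


def _units(G: int) -> tuple[int, ...]:
    return tuple(u for u in range(1, G) if math.gcd(u, G) == 1)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrayPatch:
    """A 2D grid of integer gray levels in ``{0, ..., G-1}``."""

    values: np.ndarray
    G: int = 3

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.shape[0] < 2 or vals.shape[1] < 2:
            raise PatchSizeError(f"patch must be at least 2x2, got shape {vals.shape}")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise InvalidParameterError("patch values must be integers")
            vals = np.round(vals).astype(np.int64)
        _check_gray_levels(self.G)
        if vals.min() < 0 or vals.max() >= self.G:
            raise InvalidParameterError(
                f"patch values must lie in 0..{self.G - 1}"
            )
        object.__setattr__(self, "values", vals.astype(np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def save_npy(self, path) -> None:
        np.save(path, self.values)

    def save_txt(self, path) -> None:
        np.savetxt(path, self.values, fmt="%d")

    @classmethod
    def load(cls, path, G: int = 3) -> "GrayPatch":
        path = str(path)
        if path.endswith(".npy"):
            return cls(np.load(path), G)
        return cls(np.loadtxt(path, dtype=np.int64), G)


def as_patch(patch, G: int = 3) -> GrayPatch:
    if isinstance(patch, GrayPatch):
        return patch
    return GrayPatch(np.asarray(patch), G)


@dataclass(frozen=True, order=True)
class TextureGroup:
    """One canonical coefficient vector over the 2x2 glider.

    ``coeffs`` holds (s1, s2, s3, s4) in row-major glider order.  Canonical
    form: the support's bounding box touches row 0 and column 0, and the
    vector is the lexicographic minimum of its orbit under multiplication by
    units of Z_G (for prime ``G`` this makes the first nonzero coefficient 1).
    """

    G: int
    coeffs: tuple[int, int, int, int]

    def __post_init__(self):
        _check_gray_levels(self.G)
        if len(self.coeffs) != 4 or any(not (0 <= c < self.G) for c in self.coeffs):
            raise InvalidParameterError(f"coefficients must lie in 0..{self.G - 1}")
        if all(c == 0 for c in self.coeffs):
            raise InvalidParameterError("coefficient vector must be nonzero")

    @property
    def order(self) -> int:
        return sum(c != 0 for c in self.coeffs)

    @property
    def support(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            pos for pos, c in zip(GLIDER_POSITIONS, self.coeffs) if c != 0
        )

    @property
    def bbox(self) -> tuple[int, int]:
        """Rows and columns of the minimal glider containing the support."""
        rows = max(r for r, _ in self.support) + 1
        cols = max(c for _, c in self.support) + 1
        return rows, cols

    @property
    def stencil(self) -> np.ndarray:
        out = np.zeros((2, 2), dtype=np.int64)
        for (r, c), s in zip(GLIDER_POSITIONS, self.coeffs):
            out[r, c] = s
        return out

    def coeff_sum(self) -> int:
        return sum(self.coeffs) % self.G

    @property
    def name(self) -> str:
        """Greek-letter name: order letter + one sign symbol per position.

        Coefficient symbols: ``+`` for 1, ``-`` for G-1, the digit otherwise,
        ``0`` for absent positions; trailing zeros are dropped.  Examples for
        G=3: ``beta(++)`` horizontal sum, ``beta(+0+)`` vertical sum,
        ``beta(+00-)`` main-diagonal difference, ``beta(0+-)`` anti-diagonal
        difference.
        """
        syms = []
        for c in self.coeffs:
            if c == 0:
                syms.append("0")
            elif c == 1:
                syms.append("+")
            elif c == self.G - 1 and self.G > 2:
                syms.append("-")
            else:
                syms.append(str(c))
        body = "".join(syms).rstrip("0") or "0"
        return f"{_ORDER_LETTERS[self.order]}({body})"

    @property
    def greek_name(self) -> str:
        return _ORDER_GREEK[self.order] + self.name.split("(")[1].rstrip(")")

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"TextureGroup(G={self.G}, {self.name})"


def _canonicalize(coeffs: Sequence[int], G: int) -> tuple[tuple[int, int, int, int], int]:
    """Translate support to the top-left and scale by a unit to canonical form.

    Returns ``(canonical_coeffs, u)`` where ``canonical = u * shifted mod G``.
    """
    sten = np.zeros((2, 2), dtype=np.int64)
    for (r, c), s in zip(GLIDER_POSITIONS, coeffs):
        sten[r, c] = s % G
    if not sten.any():
        raise InvalidParameterError("zero coefficient vector")
    rows = np.where(sten.any(axis=1))[0]
    cols = np.where(sten.any(axis=0))[0]
    shifted = np.zeros_like(sten)
    shifted[: 2 - rows.min(), : 2 - cols.min()] = sten[rows.min() :, cols.min() :]
    s0 = tuple(int(x) for x in shifted.ravel())
    best, best_u = None, 1
    for u in _units(G):
        cand = tuple((u * x) % G for x in s0)
        if best is None or cand < best:
            best, best_u = cand, u
    return best, best_u


@lru_cache(maxsize=None)
def enumerate_groups(G: int, order: int | None = None) -> tuple[TextureGroup, ...]:
    """All canonical texture groups for ``G`` gray levels.

    Parameters
    ----------
    G : int
        Number of gray levels (>= 2).
    order : int, optional
        Restrict to groups with this many nonzero coefficients (1-4).

    Returns
    -------
    tuple of TextureGroup
        Deterministically ordered: by order, then support (raster order),
        then coefficients lexicographically.  For G=3 this yields 1 + 8 + 16
        + 8 = 33 groups; for G=2, 10 groups.
    """
    _check_gray_levels(G)
    if order is not None and not 1 <= order <= 4:
        raise InvalidParameterError(f"order must be in 1..4, got {order}")
    seen = set()
    groups = []
    for coeffs in itertools.product(range(G), repeat=4):
        if all(c == 0 for c in coeffs):
            continue
        canon, _ = _canonicalize(coeffs, G)
        if canon in seen:
            continue
        seen.add(canon)
        g = TextureGroup(G, canon)
        if order is None or g.order == order:
            groups.append(g)
    groups.sort(key=lambda g: (g.order, g.support, g.coeffs))
    return tuple(groups)


def space_dimension(G: int, order: int | None = None) -> int:
    """Affine dimension of the texture space: ``G - 1`` per canonical group.

    ``space_dimension(3) == 66``; ``space_dimension(2) == 10``;
    ``space_dimension(3, order=2) == 16``.
    """
    return len(enumerate_groups(G, order)) * (G - 1)


# ---------------------------------------------------------------------------
# Texture vectors
# ---------------------------------------------------------------------------


class TextureVector:
    """Per-group probability triplets over the canonical groups of a given G.

    Stores a ``(n_groups, G)`` array of probabilities in the fixed flattening
    order (``COORDINATE_VERSION``).  When produced by :func:`analyze`, also
    retains the integer counts so that derived equalities are bit-exact.
    """

    def __init__(self, G: int, probs: np.ndarray, counts: np.ndarray | None = None,
                 totals: np.ndarray | None = None, strict: bool = True):
        _check_gray_levels(G)
        self.G = int(G)
        self.groups = enumerate_groups(self.G)
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (len(self.groups), self.G):
            raise InvalidParameterError(
                f"probs must have shape {(len(self.groups), self.G)}, got {probs.shape}"
            )
        if strict and probs.min() < -1e-9:
            raise InvalidParameterError("probabilities must be nonnegative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise InvalidParameterError("each group's probabilities must sum to 1")
        self.probs = probs
        self.counts = counts
        self.totals = totals

    # -- construction -------------------------------------------------
    @classmethod
    def origin(cls, G: int = 3) -> "TextureVector":
        n = len(enumerate_groups(G))
        return cls(G, np.full((n, G), 1.0 / G))

    @classmethod
    def from_flat(cls, flat: np.ndarray, G: int = 3) -> "TextureVector":
        n = len(enumerate_groups(G))
        return cls(G, np.asarray(flat, dtype=float).reshape(n, G))

    # -- access --------------------------------------------------------
    @property
    def flat(self) -> np.ndarray:
        return self.probs.ravel()

    def group_index(self, group) -> int:
        if isinstance(group, TextureGroup):
            return self.groups.index(group)
        for i, g in enumerate(self.groups):
            if g.name == group or g.greek_name == group:
                return i
        raise KeyError(f"unknown group {group!r}")

    def __getitem__(self, group) -> np.ndarray:
        return self.probs[self.group_index(group)]

    def allclose(self, other: "TextureVector", atol: float = 1e-12) -> bool:
        return self.G == other.G and np.allclose(self.probs, other.probs, atol=atol)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"TextureVector(G={self.G}, {len(self.groups)} groups)"

    # -- I/O -----------------------------------------------------------
    def to_frame(self):
        import pandas as pd

        rows = [
            {"group_name": g.name, "h": h, "probability": self.probs[i, h]}
            for i, g in enumerate(self.groups)
            for h in range(self.G)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, G: int = 3) -> "TextureVector":
        import pandas as pd

        df = pd.read_csv(path)
        groups = enumerate_groups(G)
        probs = np.zeros((len(groups), G))
        name_idx = {g.name: i for i, g in enumerate(groups)}
        for _, row in df.iterrows():
            probs[name_idx[row["group_name"]], int(row["h"])] = row["probability"]
        return cls(G, probs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "G": self.G,
                "coordinate_version": COORDINATE_VERSION,
                "groups": {g.name: self.probs[i].tolist() for i, g in enumerate(self.groups)},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TextureVector":
        data = json.loads(text)
        G = int(data["G"])
        groups = enumerate_groups(G)
        probs = np.array([data["groups"][g.name] for g in groups])
        return cls(G, probs)


def origin_vector(G: int = 3) -> TextureVector:
    return TextureVector.origin(G)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


def _stat_field(values: np.ndarray, group: TextureGroup, boundary: str) -> np.ndarray:
    """Field of ``sum_i s_i A_i mod G`` over glider placements."""
    G = group.G
    H, W = values.shape
    if boundary == "periodic":
        acc = np.zeros((H, W), dtype=np.int64)
        for (r, c), s in zip(GLIDER_POSITIONS, group.coeffs):
            if s:
                acc += s * np.roll(values, (-r, -c), axis=(0, 1))
        return acc % G
    if boundary != "valid":
        raise InvalidParameterError(f"boundary must be 'valid' or 'periodic', got {boundary!r}")
    br, bc = group.bbox
    Ho, Wo = H - br + 1, W - bc + 1
    if Ho < 1 or Wo < 1:
        raise PatchSizeError(
            f"patch {values.shape} smaller than glider bounding box {(br, bc)}"
        )
    acc = np.zeros((Ho, Wo), dtype=np.int64)
    for (r, c), s in zip(GLIDER_POSITIONS, group.coeffs):
        if s:
            acc += s * values[r : r + Ho, c : c + Wo]
    return acc % G


def analyze(patch, groups: Iterable[TextureGroup] | None = None,
            boundary: str = "valid", G: int = 3) -> TextureVector:
    """Texture coordinates of a patch: per-group histograms of the glider statistic.

    For each group, glides the *minimal* shape containing the nonzero
    coefficients over the patch (``boundary='valid'``, the default) or wraps
    periodically (``boundary='periodic'``, which makes coordinates exactly
    translation invariant), and counts the fraction of placements at which
    the modular linear combination equals each ``h``.

    Parameters
    ----------
    patch : GrayPatch or 2D integer array
    groups : iterable of TextureGroup, optional
        Defaults to every canonical group of the patch's ``G``.
    boundary : {'valid', 'periodic'}

    Returns
    -------
    TextureVector
        Probabilities are exact rationals (integer count / #placements).
    """
    p = as_patch(patch, G)
    all_groups = enumerate_groups(p.G)
    wanted = all_groups if groups is None else tuple(groups)
    probs = np.full((len(all_groups), p.G), 1.0 / p.G)
    counts = np.zeros((len(all_groups), p.G), dtype=np.int64)
    totals = np.zeros(len(all_groups), dtype=np.int64)
    index = {g: i for i, g in enumerate(all_groups)}
    for g in wanted:
        i = index[g]
        stat = _stat_field(p.values, g, boundary)
        cnt = np.bincount(stat.ravel(), minlength=p.G)
        counts[i] = cnt
        totals[i] = stat.size
        probs[i] = cnt / stat.size
    return TextureVector(p.G, probs, counts=counts, totals=totals)


def block_counts(patch, boundary: str = "valid", G: int = 3) -> np.ndarray:
    """Integer histogram over the ``G**4`` 2x2 block configurations.

    Indexing: configuration ``(A1, A2, A3, A4)`` row-major maps to flat index
    ``A1*G**3 + A2*G**2 + A3*G + A4``.
    """
    p = as_patch(patch, G)
    Gv = p.G
    H, W = p.shape
    if boundary == "periodic":
        parts = [np.roll(p.values, (-r, -c), axis=(0, 1)) for r, c in GLIDER_POSITIONS]
    elif boundary == "valid":
        if H < 2 or W < 2:
            raise PatchSizeError("patch smaller than the 2x2 glider")
        parts = [p.values[r : r + H - 1, c : c + W - 1] for r, c in GLIDER_POSITIONS]
    else:
        raise InvalidParameterError(f"unknown boundary {boundary!r}")
    code = ((parts[0] * Gv + parts[1]) * Gv + parts[2]) * Gv + parts[3]
    return np.bincount(code.ravel(), minlength=Gv**4)


def block_probabilities(patch, boundary: str = "valid", G: int = 3) -> np.ndarray:
    """Normalized distribution over the ``G**4`` block configurations."""
    cnt = block_counts(patch, boundary, G)
    return cnt / cnt.sum()


@lru_cache(maxsize=None)
def _block_stat_table(G: int) -> np.ndarray:
    """(n_groups, G**4) table of the glider statistic per block configuration."""
    groups = enumerate_groups(G)
    configs = np.array(list(itertools.product(range(G), repeat=4)))
    table = np.zeros((len(groups), G**4), dtype=np.int64)
    for i, g in enumerate(groups):
        table[i] = (configs @ np.array(g.coeffs)) % G
    return table


def coords_from_block_probs(P: np.ndarray, G: int = 3) -> TextureVector:
    """Marginalize a block distribution onto every canonical group.

    ``probs[g][h]`` is the total probability of block configurations whose
    glider statistic for group ``g`` equals ``h``.  Exactly equals
    ``analyze(patch, boundary='periodic')`` when ``P`` comes from
    :func:`block_probabilities` of the same periodic patch.
    """
    P = np.asarray(P, dtype=float).ravel()
    if P.size != G**4:
        raise InvalidParameterError(f"block distribution must have {G**4} entries")
    if not np.isclose(P.sum(), 1.0, atol=1e-6):
        raise InvalidParameterError("block distribution must be normalized")
    table = _block_stat_table(G)
    groups = enumerate_groups(G)
    probs = np.zeros((len(groups), G))
    for h in range(G):
        probs[:, h] = np.where(table == h, P[None, :], 0.0).sum(axis=1)
    return TextureVector(G, probs)


@lru_cache(maxsize=None)
def _character_decomposition(G: int):
    """For every s in Z_G^4: the canonical group index, unit u with
    ``canonical = u * shifted(s)``, or None for s == 0."""
    groups = enumerate_groups(G)
    index = {g.coeffs: i for i, g in enumerate(groups)}
    out = []
    for s in itertools.product(range(G), repeat=4):
        if all(c == 0 for c in s):
            out.append(None)
            continue
        canon, u = _canonicalize(s, G)
        out.append((index[canon], u))
    return tuple(out)


def block_probs_from_coords(v: TextureVector, tol: float = 1e-9) -> np.ndarray:
    """Reconstruct the translation-invariant block distribution from coordinates.

    Inverts the character sums: for every coefficient vector ``s`` (not only
    canonical ones) the Fourier coefficient of the block distribution is a
    character sum of one canonical group's probabilities, after undoing the
    translation and unit-scaling that relate ``s`` to its canonical form.

    Raises
    ------
    InfeasibilityError
        If the reconstruction has negative entries beyond ``tol`` (the given
        coordinates are not consistent with any translation-invariant block
        distribution).
    """
    G = v.G
    omega = np.exp(2j * np.pi / G)
    decomp = _character_decomposition(G)
    hs = np.arange(G)
    Phat = np.zeros(G**4, dtype=complex)
    for flat, info in enumerate(decomp):
        if info is None:
            Phat[flat] = 1.0
            continue
        gi, u = info
        pc = v.probs[gi]
        # event {s . A = h}  ==  {canonical . A = u*h}
        Phat[flat] = np.sum(pc[(u * hs) % G] * omega**hs)
    configs = np.array(list(itertools.product(range(G), repeat=4)))
    svecs = configs  # same enumeration order for s as for A
    phase = omega ** (-(svecs @ configs.T) % G).astype(float)
    P = (Phat @ phase).real / G**4
    if P.min() < -tol:
        raise InfeasibilityError(
            f"coordinates are infeasible: reconstructed probability {P.min():.3g} < 0"
        )
    P = np.clip(P, 0.0, None)
    return P / P.sum()


# ---------------------------------------------------------------------------
# Plane geometry
# ---------------------------------------------------------------------------


def _simplex_basis(G: int) -> np.ndarray:
    """Orthonormal basis of the sum-zero subspace of R^G (rows).

    For G=3: ``e_x = (2,-1,-1)/sqrt(6)`` points toward the ``p0`` vertex and
    ``e_y = (0,1,-1)/sqrt(2)``; angles 0, 120, 240 degrees point at the
    vertices ``p0, p1, p2``.
    """
    if G == 3:
        return np.array([[2.0, -1.0, -1.0] / np.sqrt(6.0), [0.0, 1.0, -1.0] / np.sqrt(2.0)])
    if G == 2:
        return np.array([[1.0, -1.0] / np.sqrt(2.0)])
    raise InvalidParameterError("simple-plane geometry implemented for G in {2, 3}")


@dataclass(frozen=True)
class PlaneDirection:
    """A direction within a simple or mixed texture plane.

    Simple plane: one group's probability simplex, embedded with the
    orthonormal basis of :func:`_simplex_basis`; ``contrast`` is Euclidean
    distance from the origin in probability space (the vertex ``p_h = 1``
    lies at contrast ``sqrt((G-1)/G)``).

    Mixed plane: two axes, each a single probability ``p_h`` of a distinct
    group, in *saturation units*: coordinate ``t`` means
    ``p_h = 1/G + t*(G-1)/G``, so ``t = 0`` is the unbiased texture and
    ``t = 1`` full saturation; the remaining probabilities of the group stay
    equal.  ``angle`` is measured in the (axis A, axis B) coordinate plane.
    """

    kind: str  # 'simple' | 'mixed'
    groups: tuple[TextureGroup, ...]
    angle: float = 0.0
    axes: tuple[int, ...] | None = None  # mixed: (h_A, h_B)

    def __post_init__(self):
        if self.kind not in ("simple", "mixed"):
            raise InvalidParameterError(f"unknown plane kind {self.kind!r}")
        if self.kind == "simple" and len(self.groups) != 1:
            raise InvalidParameterError("simple plane takes exactly one group")
        if self.kind == "mixed":
            if len(self.groups) != 2 or self.axes is None or len(self.axes) != 2:
                raise InvalidParameterError("mixed plane takes two groups and two h axes")
            if self.groups[0] == self.groups[1]:
                raise InvalidParameterError("mixed plane groups must be distinct")

    @property
    def G(self) -> int:
        return self.groups[0].G

    def label(self) -> str:
        if self.kind == "simple":
            return f"{self.groups[0].name}@{self.angle:.4f}"
        (ga, gb), (ha, hb) = self.groups, self.axes
        return f"{ga.name}[{ha}]x{gb.name}[{hb}]@{self.angle:.4f}"

    def displacement(self, contrast: float = 1.0) -> np.ndarray:
        """Flattened-coordinate offset from the origin at the given contrast."""
        G = self.G
        all_groups = enumerate_groups(G)
        out = np.zeros((len(all_groups), G))
        if self.kind == "simple":
            basis = _simplex_basis(G)
            if basis.shape[0] == 1:
                d = math.cos(self.angle) * basis[0]
            else:
                d = math.cos(self.angle) * basis[0] + math.sin(self.angle) * basis[1]
            out[all_groups.index(self.groups[0])] = contrast * d
        else:
            t = (contrast * math.cos(self.angle), contrast * math.sin(self.angle))
            for g, h, ti in zip(self.groups, self.axes, t):
                row = np.full(G, -ti / G)
                row[h] += ti
                # p_h moves by t*(G-1)/G, the others by -t/G each
                out[all_groups.index(g)] = row * (1.0)
        return out.ravel()

    def point(self, contrast: float) -> TextureVector:
        """Origin displaced by ``contrast`` along this direction (not clipped)."""
        if contrast < 0:
            raise InvalidParameterError("contrast must be >= 0")
        G = self.G
        flat = TextureVector.origin(G).flat + self.displacement(contrast)
        n = len(enumerate_groups(G))
        # feasibility (probabilities in [0, 1]) is the caller's concern
        return TextureVector(G, flat.reshape(n, G), strict=False)


def plane_point(direction: PlaneDirection, contrast: float) -> TextureVector:
    """Texture vector at the given contrast along a plane direction."""
    return direction.point(contrast)
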