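"""Prediction-measurement agreement statistics and significance tests.

Mismatch between two sets of positive thresholds is measured by the
difference of natural logarithms, ``log y - log x``, which approximates the
relative error for small mismatches (a median absolute log error of 0.13
means half the measurements are within about 13%).  Significance of the
match is assessed with a permutation test: measured thresholds are shuffled
across direction labels (globally, or within each plane to respect the
elliptical structure of the predictions) and the median absolute log error
is recomputed for each shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .space import InvalidParameterError

__all__ = [
    "ComparisonSet",
    "log_errors",
    "median_abs_log_error",
    "permutation_test",
    "fit_threshold_ellipse",
]


@dataclass
class ComparisonSet:
    """Paired predicted/measured thresholds with plane and direction labels."""

    labels: tuple
    planes: tuple
    predicted: np.ndarray
    measured: np.ndarray
    log_err: np.ndarray | None = None

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.measured = np.asarray(self.measured, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InvalidParameterError("direction labels must be unique")
        if not (len(self.planes) == self.predicted.size == self.measured.size == n):
            raise InvalidParameterError("field lengths differ")
        if np.any(self.predicted <= 0) or np.any(self.measured <= 0):
            raise InvalidParameterError("thresholds must be positive")

    def __len__(self):
        return len(self.labels)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"label": self.labels, "plane": self.planes,
             "predicted": self.predicted, "measured": self.measured,
             "log_error": log_errors(self.predicted, self.measured)}
        )

    def median_abs_log_error(self) -> float:
        return median_abs_log_error(self.predicted, self.measured)

    def by_plane_kind(self, kinds) -> dict:
        """Median log error per subset of planes (e.g. simple vs mixed)."""
        out = {}
        for kind, planes in kinds.items():
            m = np.isin(np.asarray(self.planes), list(planes))
            if m.any():
                out[kind] = float(np.median(
                    log_errors(self.predicted[m], self.measured[m])))
        return out


def log_errors(x, y) -> np.ndarray:
    """Elementwise ``log y - log x`` for positive inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise InvalidParameterError("inputs must be positive")
    return np.log(y) - np.log(x)


def median_abs_log_error(x, y) -> float:
    """Median of ``|log y - log x|``; symmetric in its arguments."""
    return float(np.median(np.abs(log_errors(x, y))))


def permutation_test(comparison: ComparisonSet, n_perm: int = 10_000,
                     mode: str = "global", seed=0) -> dict:
    """Permutation null for the median absolute log error.

    Shuffles the measured thresholds across direction labels — globally
    (``mode='global'``), testing the hypothesis that measurements were drawn
    from a single direction-independent distribution, or within each plane
    (``mode='within_plane'``), which preserves per-plane threshold ranges
    and is sensitive only to structure beyond them.

    Returns ``observed``, ``p`` (the fraction of null medians at or below
    the observed, with the +1 correction so p is never zero), and the
    central 95% range of the null distribution.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    if len(comparison) < 3:
        raise InvalidParameterError("need at least 3 pairs")
    if mode not in ("global", "within_plane"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    lx = np.log(comparison.predicted)
    ly = np.log(comparison.measured)
    observed = float(np.median(np.abs(ly - lx)))
    planes = np.asarray(comparison.planes)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = np.arange(ly.size)
        if mode == "global":
            rng.shuffle(perm)
        else:
            for pl in np.unique(planes):
                idx = np.flatnonzero(planes == pl)
                perm[idx] = rng.permutation(perm[idx])
        null[b] = np.median(np.abs(ly[perm] - lx))
    p = (1 + int(np.sum(null <= observed))) / (1 + n_perm)
    lo, hi = np.quantile(null, [0.025, 0.975])
    return {"observed": observed, "p": float(p), "n_perm": n_perm,
            "null_low": float(lo), "null_high": float(hi), "mode": mode}


def fit_threshold_ellipse(points: np.ndarray) -> dict:
    """Least-squares origin-centered conic fit constrained to an ellipse.

    ``points`` is ``(n, 2)`` in plane coordinates.  Fits
    ``A x^2 + B x y + C y^2 = 1`` by linear least squares (the natural form
    for threshold contours around the texture-space origin, where the
    efficient-coding predictions lie exactly on such an ellipse).  Raises if
    the best conic is not an ellipse (e.g. collinear or hyperbolic points).

    Returns the conic coefficients, the RMS residual of ``A x^2 + ... - 1``,
    and the semi-axes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidParameterError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    M = np.column_stack([x**2, x * y, y**2])
    if np.linalg.matrix_rank(M) < 3 and pts.shape[0] >= 3:
        # allow circles (rank 2 pattern) but reject truly degenerate input
        if np.linalg.matrix_rank(np.column_stack([x, y])) < 2:
            raise InvalidParameterError("points are collinear")
    coef, *_ = np.linalg.lstsq(M, np.ones_like(x), rcond=None)
    A, B, C = coef
    disc = B**2 - 4 * A * C
    if disc >= 0 or A <= 0:
        raise InvalidParameterError(
            f"best-fit conic is not an ellipse (discriminant {disc:.3g})"
        )
    resid = float(np.sqrt(np.mean((M @ coef - 1.0) ** 2)))
    Q = np.array([[A, B / 2], [B / 2, C]])
    evals = np.linalg.eigvalsh(Q)  # ascending; semi-axes come out descending
    axes = tuple(float(1.0 / np.sqrt(e)) for e in evals)
    return {"A": float(A), "B": float(B), "C": float(C),
            "residual": resid, "semi_axes": axes}
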