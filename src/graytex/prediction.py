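"""Efficient-coding threshold predictions from texture-space statistics.

In the sampling-limited regime, efficient coding predicts that detection
thresholds are *inversely* proportional to the standard deviation of the
stimulus statistic across natural inputs ("variance is salience").  This
module fits a multivariate Gaussian to an ensemble of texture coordinate
vectors and predicts the threshold along any plane direction as

    threshold(u)  =  scale * (u' Sigma u) ** (-eta / 2)

where ``u`` is the unit-contrast displacement of the direction in flattened
coordinate space, ``Sigma`` the fitted covariance, and ``eta`` a power-law
exponent (default 1, the linear efficient-coding prediction; ``eta = 0``
makes all thresholds equal, i.e. predictions independent of the data).  The
overall scale is not fixed by the theory and is fit to measurements as a
single parameter by weighted least squares in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .space import InvalidParameterError, PlaneDirection, TextureVector, enumerate_groups

__all__ = [
    "GaussianTextureModel",
    "fit_gaussian",
    "predict_threshold",
    "predict_thresholds",
    "fit_scale",
    "fit_eta",
]


class DegenerateDirectionError(ValueError):
    """Raised when the model has (numerically) zero variance along a direction."""


@dataclass
class GaussianTextureModel:
    """Mean and covariance of texture vectors over an image ensemble.

    Coordinates are the flattened per-group probabilities (coordinate-order
    version in :mod:`graytex.space`); each group's probabilities sum to one,
    so the covariance is rank-deficient by one per group.  Directions used
    for prediction live in the per-group sum-zero subspace, where the
    quadratic form is well-defined.
    """

    mean: np.ndarray
    covariance: np.ndarray
    G: int = 3
    n_samples: int = 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        d = self.mean.size
        if self.covariance.shape != (d, d):
            raise InvalidParameterError("covariance shape does not match mean")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise InvalidParameterError("covariance must be symmetric")

    def variance_along(self, direction) -> float:
        u = direction.displacement(1.0) if isinstance(direction, PlaneDirection) \
            else np.asarray(direction, dtype=float)
        if not np.any(u):
            raise InvalidParameterError("direction vector is zero")
        return float(u @ self.covariance @ u)

    def save_npz(self, path) -> None:
        np.savez(path, mean=self.mean, covariance=self.covariance,
                 G=self.G, n_samples=self.n_samples)

    @classmethod
    def load_npz(cls, path) -> "GaussianTextureModel":
        data = np.load(path)
        return cls(data["mean"], data["covariance"], int(data["G"]),
                   int(data["n_samples"]))


def fit_gaussian(vectors, G: int = 3, ridge: float = 0.0) -> GaussianTextureModel:
    """Sample mean and covariance of an ensemble of texture vectors.

    ``vectors`` may be TextureVectors or already-flattened arrays.  A ridge
    (added to the diagonal) stabilizes downstream quadratic forms when the
    sample is small relative to the dimension.
    """
    rows = [v.flat if isinstance(v, TextureVector) else np.asarray(v, float)
            for v in vectors]
    X = np.vstack(rows)
    if X.shape[0] < 2:
        raise InvalidParameterError("need at least two vectors to fit a Gaussian")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    if ridge > 0:
        cov = cov + ridge * np.eye(cov.shape[0])
    return GaussianTextureModel(mean, cov, G=G, n_samples=X.shape[0])


def predict_threshold(model: GaussianTextureModel, direction, eta: float = 1.0) -> float:
    """Unscaled predicted threshold ``(u' Sigma u)**(-eta/2)`` along a direction.

    ``direction`` is a :class:`PlaneDirection` (its unit-contrast
    displacement defines the quadratic form, so thresholds come out in the
    plane's contrast units) or a raw flattened offset vector.
    """
    var = model.variance_along(direction)
    if var <= 1e-300:
        raise DegenerateDirectionError(
            "zero variance along direction: predicted threshold is unbounded"
        )
    return float(var ** (-eta / 2.0))


def predict_thresholds(model: GaussianTextureModel, directions, eta: float = 1.0) -> np.ndarray:
    return np.array([predict_threshold(model, d, eta) for d in directions])


def fit_scale(predicted, measured, log_errors=None) -> float:
    """Single multiplicative factor aligning predictions with measurements.

    Minimizes ``(1/n) sum_i ((log(s * pred_i) - log(meas_i)) / eps_i)**2``
    over ``s``; the closed form is the weighted geometric mean of
    ``measured / predicted`` with weights ``1/eps**2``.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise InvalidParameterError("predicted and measured lengths differ")
    if np.any(predicted <= 0) or np.any(measured <= 0):
        raise InvalidParameterError("thresholds must be positive")
    if log_errors is None:
        w = np.ones_like(predicted)
    else:
        log_errors = np.asarray(log_errors, dtype=float)
        if np.any(log_errors <= 0):
            raise InvalidParameterError("log-space uncertainties must be positive")
        w = 1.0 / log_errors**2
    return float(np.exp(np.sum(w * (np.log(measured) - np.log(predicted))) / np.sum(w)))


def fit_eta(predicted_std, measured, log_errors=None) -> tuple[float, float]:
    """Power-law exponent linking natural-image variability to thresholds.

    Weighted least squares of ``log(measured)`` on ``-log(std)`` with an
    intercept: ``log t = log s - eta * log std``.  Returns ``(eta, scale)``.
    """
    std = np.asarray(predicted_std, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if std.size != measured.size:
        raise InvalidParameterError("lengths differ")
    if std.size < 3:
        raise InvalidParameterError("need at least 3 points to fit eta")
    if np.any(std <= 0) or np.any(measured <= 0):
        raise InvalidParameterError("inputs must be positive")
    if np.ptp(np.log(std)) < 1e-12:
        raise InvalidParameterError("degenerate regressor: constant std")
    if log_errors is None:
        w = np.ones_like(std)
    else:
        w = 1.0 / np.asarray(log_errors, dtype=float) ** 2
    X = np.column_stack([np.ones_like(std), -np.log(std)])
    y = np.log(measured)
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ y)
    return float(beta[1]), float(np.exp(beta[0]))


def second_order_planes(G: int = 3, n_mixed: int = 22):
    """The probed second-order planes: all simple planes plus mixed pairs.

    Returns a list of plane descriptors usable to build
    :class:`PlaneDirection` fans: ``('simple', group)`` for each of the 8
    pair groups and ``('mixed', (ga, ha), (gb, hb))`` for the first
    ``n_mixed`` distinct group pairs (h = 0 and 1 axes), mirroring the
    design of probing 4 simple and 22 mixed planes.
    """
    import itertools

    pairs = [g for g in enumerate_groups(G, order=2)]
    planes = [("simple", g) for g in pairs]
    mixed = []
    for (ga, gb) in itertools.combinations(pairs, 2):
        for ha, hb in ((0, 0), (0, 1)):
            mixed.append(("mixed", (ga, ha), (gb, hb)))
    return planes + mixed[:n_mixed]


def plane_directions(plane, n_directions: int = 12) -> list[PlaneDirection]:
    """Evenly spaced direction fan within one plane."""
    out = []
    for k in range(n_directions):
        angle = 2.0 * np.pi * k / n_directions
        if plane[0] == "simple":
            out.append(PlaneDirection("simple", (plane[1],), angle))
        else:
            (ga, ha), (gb, hb) = plane[1], plane[2]
            out.append(PlaneDirection("mixed", (ga, gb), angle, (ha, hb)))
    return out
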