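"""Synthetic inputs: natural-image surrogates and simulated 4AFC observers.

The image generator emulates the statistical structure that drives the
natural-scene analysis without requiring any external data: Gaussian random
fields with a power-law (1/f-type) spatial spectrum are exponentiated to
lognormal light intensities.  Scene-to-scene diversity — the feature that
gives natural images their large texture-space variance — is emulated by
drawing each image's contrast, spectral slope and correlation anisotropy
from distributions around the ensemble defaults; the anisotropy is
deliberately biased toward stronger horizontal correlations so that
predicted thresholds differ across texture planes and recovery tests are
non-trivial.  A labeled fraction of images is Gaussian-blurred to exercise
blur rejection.

The observer generator produces binomial 4AFC trial counts from a Weibull
observer with known thresholds, using the standard session geometry
(directions sampled at a few contrasts, a few hundred trials each).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .psychophysics import TrialBlock, weibull_fc
from .space import InvalidParameterError, PlaneDirection

__all__ = [
    "FixtureSpec",
    "generate_images",
    "generate_observer_data",
    "run_recovery_experiment",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Ensemble parameters for synthetic natural-image surrogates.

    ``spectral_exponent`` is the power-spectrum slope (2 gives the 1/f
    amplitude spectrum of natural scenes); ``log_sigma`` the standard
    deviation of log intensity (scene contrast); ``anisotropy`` the mean
    ratio of horizontal to vertical correlation length.  The ``*_jitter``
    fields control per-image lognormal/normal diversity around the means.
    ``blur_fraction`` of the images are blurred with a Gaussian of width
    ``blur_sigma`` pixels (in the raw image, before any preprocessing).
    """

    n_images: int = 24
    size: int = 512
    spectral_exponent: float = 2.0
    log_mu: float = 0.0
    log_sigma: float = 0.9
    anisotropy: float = 1.5
    exponent_jitter: float = 0.3
    sigma_jitter: float = 0.35
    anisotropy_jitter: float = 0.25
    blur_fraction: float = 0.25
    blur_sigma: float = 3.0

    def __post_init__(self):
        if self.n_images < 1 or self.size < 8:
            raise InvalidParameterError("need n_images >= 1 and size >= 8")
        if not 0.0 <= self.blur_fraction <= 1.0:
            raise InvalidParameterError("blur_fraction must be in [0, 1]")
        for name in ("spectral_exponent", "log_sigma", "anisotropy", "blur_sigma"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")


def _power_law_field(size: int, exponent: float, anisotropy: float, rng) -> np.ndarray:
    """Unit-variance Gaussian field with anisotropic power-law spectrum.

    Power ``~ k_eff**(-exponent)`` with ``k_eff = sqrt((kx/ax)^2 + ky^2)``;
    ``ax > 1`` stretches correlations along the horizontal axis.
    """
    ky = np.fft.fftfreq(size)[:, None]
    kx = np.fft.fftfreq(size)[None, :]
    k_eff = np.sqrt((kx / anisotropy) ** 2 + ky**2)
    amp = np.zeros_like(k_eff)
    nz = k_eff > 0
    amp[nz] = k_eff[nz] ** (-exponent / 2.0)
    noise = np.fft.fft2(rng.standard_normal((size, size)))
    field = np.fft.ifft2(noise * amp).real
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_images(spec: FixtureSpec, seed=0):
    """Synthetic luminance images plus ground-truth blur labels.

    Returns ``(images, blurred)``: a list of positive-valued lognormal
    intensity images and a boolean array marking the blurred ones.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_blur = int(round(spec.blur_fraction * spec.n_images))
    blurred = np.zeros(spec.n_images, dtype=bool)
    if n_blur:
        blurred[rng.choice(spec.n_images, size=n_blur, replace=False)] = True
    images = []
    for i in range(spec.n_images):
        expo = max(0.0, spec.spectral_exponent + spec.exponent_jitter * rng.standard_normal())
        aniso = spec.anisotropy * np.exp(spec.anisotropy_jitter * rng.standard_normal())
        sigma = spec.log_sigma * np.exp(spec.sigma_jitter * rng.standard_normal())
        field = _power_law_field(spec.size, expo, aniso, rng)
        image = np.exp(spec.log_mu + sigma * field)
        if blurred[i]:
            image = gaussian_filter(image, spec.blur_sigma, mode="reflect")
        images.append(image)
    return images, blurred


def generate_observer_data(directions, true_thresholds, k: float = 2.5,
                           n_contrasts: int = 3, trials_per_direction: int = 360,
                           contrast_spread: float = 1.6, seed=0,
                           subject: str | None = "S1"):
    """Binomial 4AFC trial counts from a Weibull observer with known thresholds.

    Each direction is probed at ``n_contrasts`` contrasts geometrically
    spaced by ``contrast_spread`` around its true threshold (the pilot-tuned
    placement that keeps performance between chance and ceiling), with
    ``trials_per_direction`` trials split evenly across contrasts.

    Returns a list of :class:`TrialBlock`; ground truth is the input.
    """
    directions = list(directions)
    lams = np.asarray(true_thresholds, dtype=float)
    if lams.size != len(directions):
        raise InvalidParameterError("directions and thresholds lengths differ")
    if np.any(lams <= 0):
        raise InvalidParameterError("true thresholds must be positive")
    rng = np.random.default_rng(seed)
    grid = contrast_spread ** np.linspace(-1, 1, n_contrasts)
    n_per = trials_per_direction // n_contrasts
    blocks = []
    for d, lam in zip(directions, lams):
        c = lam * grid
        p = weibull_fc(c, lam, k)
        n = np.full(n_contrasts, n_per, dtype=int)
        kk = rng.binomial(n, p)
        blocks.append(TrialBlock(tuple(c), tuple(n), tuple(kk),
                                 direction=d, subject=subject))
    return blocks


def run_recovery_experiment(seed=0, spec: FixtureSpec | None = None,
                            n_planes_simple: int = 4, n_planes_mixed: int = 4,
                            n_directions: int = 12, trials_per_direction: int = 360,
                            observer_k: float = 2.5, n_boot: int = 100,
                            n_perm: int = 10_000, eta: float = 1.0):
    """End-to-end chain: images -> pipeline -> predictions -> observers -> evaluation.

    Generates a synthetic ensemble, runs the full preprocessing pipeline,
    fits the Gaussian texture model, predicts thresholds in a set of
    second-order planes, simulates Weibull observers whose true thresholds
    equal the (scaled) predictions, refits thresholds from the simulated
    trials, and evaluates the prediction-measurement agreement.

    Returns a dict with the comparison set, the fitted scale, the median
    (signed and absolute) log errors and the permutation test result.
    """
    from .evaluation import ComparisonSet, permutation_test
    from .pipeline import PipelineConfig, run_pipeline
    from .prediction import (fit_gaussian, fit_scale, plane_directions,
                             predict_thresholds, second_order_planes)
    from .psychophysics import fit_threshold

    spec = spec or FixtureSpec()
    ss = np.random.SeedSequence(seed)
    s_img, s_pipe, s_obs, s_fit, s_perm = (s.generate_state(1)[0] % (2**31)
                                           for s in ss.spawn(5))
    images, _ = generate_images(spec, s_img)
    result = run_pipeline(images, PipelineConfig(), seed=s_pipe)
    model = fit_gaussian(result.vectors)

    planes = second_order_planes()
    chosen = planes[:n_planes_simple] + planes[8 : 8 + n_planes_mixed]
    directions, plane_ids = [], []
    for pi, plane in enumerate(chosen):
        for d in plane_directions(plane, n_directions):
            directions.append(d)
            plane_ids.append(pi)
    unscaled = predict_thresholds(model, directions, eta=eta)
    # place the simulated observer's thresholds at perceptually plausible
    # contrasts (the theory leaves the overall scale free)
    true = unscaled * (0.5 / np.median(unscaled))

    blocks = generate_observer_data(directions, true, k=observer_k,
                                    trials_per_direction=trials_per_direction,
                                    seed=s_obs)
    fits = [fit_threshold(b, n_boot=n_boot, seed=s_fit + i)
            for i, b in enumerate(blocks)]
    measured = np.array([f.threshold for f in fits])
    log_se = np.array([max(f.log_se, 1e-3) for f in fits])

    scale = fit_scale(unscaled, measured, log_se)
    comparison = ComparisonSet(
        labels=tuple(d.label() for d in directions),
        planes=tuple(plane_ids),
        predicted=scale * unscaled,
        measured=measured,
        log_err=log_se,
    )
    errs = np.log(measured) - np.log(scale * unscaled)
    perm = permutation_test(comparison, n_perm=n_perm, seed=s_perm)
    return {
        "comparison": comparison,
        "model": model,
        "scale": scale,
        "true_thresholds": true,
        "median_log_error": float(np.median(errs)),
        "median_abs_log_error": float(np.median(np.abs(errs))),
        "permutation": perm,
        "pipeline_kept_fraction": result.kept_fraction,
    }
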