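"""4AFC psychometric fitting: Weibull thresholds, bootstrap errors, averaging.

Fraction correct in the four-alternative forced-choice texture segregation
task is modeled as a Weibull function of texture contrast ``c``:

    fc(c) = 0.25 + 0.75 * (1 - 2 ** (-(c / lam) ** k))

with guess rate fixed at chance (0.25) and no lapse term.  The base-2
parameterization makes the scale ``lam`` exactly the contrast at which
performance is 0.625, halfway between chance and ceiling — the threshold
criterion.  Fits are maximum-likelihood under the binomial observation
model; uncertainties come from bootstrap resampling of the trials.  The fit
may extrapolate a threshold beyond the valid coordinate range (a
low-sensitivity direction); such fits are returned as-is and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .space import InvalidParameterError, PlaneDirection

__all__ = [
    "TrialBlock",
    "WeibullFit",
    "weibull_fc",
    "fit_threshold",
    "align_subjects",
    "combine_errorbars",
    "FitError",
]

CHANCE = 0.25
CEILING = 1.0
CRITERION = 0.625  # halfway between chance and ceiling


class FitError(RuntimeError):
    """Raised when the psychometric fit fails to converge."""


@dataclass(frozen=True)
class TrialBlock:
    """Binomial trial counts at each tested contrast for one direction."""

    contrasts: tuple
    n_trials: tuple
    n_correct: tuple
    direction: PlaneDirection | None = None
    subject: str | None = None

    def __post_init__(self):
        c = np.asarray(self.contrasts, float)
        n = np.asarray(self.n_trials, int)
        k = np.asarray(self.n_correct, int)
        if not (c.size == n.size == k.size):
            raise InvalidParameterError("contrasts/trials/correct lengths differ")
        if np.any(c <= 0):
            raise InvalidParameterError("contrasts must be positive")
        if np.any(k < 0) or np.any(k > n):
            raise InvalidParameterError("need 0 <= n_correct <= n_trials")
        object.__setattr__(self, "contrasts", tuple(float(x) for x in c))
        object.__setattr__(self, "n_trials", tuple(int(x) for x in n))
        object.__setattr__(self, "n_correct", tuple(int(x) for x in k))


@dataclass
class WeibullFit:
    """Fitted Weibull scale/shape with threshold and log-space uncertainty."""

    lam: float
    k: float
    log_se: float
    ci_low: float
    ci_high: float
    extrapolated: bool = False
    unbounded: bool = False

    @property
    def threshold(self) -> float:
        return self.lam


def weibull_fc(contrast, lam: float, k: float):
    """Fraction correct of the 4AFC Weibull observer.

    ``fc(0) = 0.25``, ``fc(lam) = 0.625``, ``fc(inf) = 1``.
    """
    c = np.asarray(contrast, dtype=float)
    out = CHANCE + (CEILING - CHANCE) * (1.0 - 2.0 ** (-((c / lam) ** k)))
    return float(out) if np.isscalar(contrast) else out


def _neg_log_likelihood(params, c, n, kk):
    lam, shape = np.exp(params)
    p = np.clip(weibull_fc(c, lam, shape), 1e-9, 1 - 1e-9)
    return -np.sum(kk * np.log(p) + (n - kk) * np.log1p(-p))


def _mle(c, n, kk, x0):
    res = minimize(_neg_log_likelihood, x0, args=(c, n, kk),
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
    return res


def fit_threshold(block: TrialBlock, n_boot: int = 1000, seed=0,
                  ci_level: float = 0.95) -> WeibullFit:
    """Maximum-likelihood Weibull fit with bootstrap log-space uncertainty.

    The threshold is the fitted scale ``lam`` (the 0.625-correct contrast).
    Bootstrap: trials at each contrast are resampled (binomially, from the
    observed fraction) and refit; the log-space standard error is half the
    central 68% percentile interval of ``log lam`` and the confidence
    interval the central ``ci_level`` interval.

    Performance at chance across all contrasts yields an ``unbounded`` flag;
    a threshold outside the tested contrast range is flagged
    ``extrapolated`` (it may also exceed the valid coordinate range — a
    low-sensitivity direction).
    """
    c = np.asarray(block.contrasts, float)
    n = np.asarray(block.n_trials, int)
    kk = np.asarray(block.n_correct, int)
    if np.unique(c).size < 2:
        raise InvalidParameterError("need at least 2 distinct contrasts")

    frac = kk / np.maximum(n, 1)
    # crude initialization: contrast nearest the criterion, slope 2
    x0 = np.array([np.log(c[np.argmin(np.abs(frac - CRITERION))]), np.log(2.0)])
    res = _mle(c, n, kk, x0)
    if not res.success:  # pragma: no cover - NM rarely fails outright
        raise FitError(f"Weibull fit did not converge: {res.message}")
    lam, shape = np.exp(res.x)

    # all-chance data: likelihood is flat in lam -> unbounded threshold
    binom_se = np.sqrt(np.maximum(frac * (1 - frac), 1e-9) / np.maximum(n, 1))
    unbounded = bool(np.all(frac <= CHANCE + 2 * binom_se))
    extrapolated = bool(lam > c.max() or lam < c.min())

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        kb = rng.binomial(n, frac)
        rb = _mle(c, n, kb, res.x)
        boot[b] = rb.x[0]
    lo, hi = np.quantile(boot, [(1 - ci_level) / 2, (1 + ci_level) / 2])
    p16, p84 = np.quantile(boot, [0.16, 0.84])
    return WeibullFit(
        lam=float(lam), k=float(shape), log_se=float((p84 - p16) / 2),
        ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        extrapolated=extrapolated, unbounded=unbounded,
    )


def align_subjects(per_subject: dict, tol: float = 1e-12, max_iter: int = 200):
    """Consensus thresholds and per-subject sensitivity multipliers.

    ``per_subject`` maps subject -> {direction_label: threshold}.  The model
    ``t[s, d] = m[s] * consensus[d]`` is fit by minimizing squared log
    deviations (alternating geometric means, which is the exact closed form
    for complete data).  Multipliers are normalized to geometric mean 1.

    Returns ``(consensus, multipliers, variance_explained)`` where
    ``variance_explained`` is the fraction of total log-threshold variance
    captured by the consensus-plus-multiplier model.
    """
    subjects = list(per_subject)
    if not subjects:
        raise InvalidParameterError("need at least one subject")
    directions = sorted({d for t in per_subject.values() for d in t})
    T = np.full((len(subjects), len(directions)), np.nan)
    for i, s in enumerate(subjects):
        for j, d in enumerate(directions):
            if d in per_subject[s]:
                T[i, j] = np.log(per_subject[s][d])
    if np.any(np.all(np.isnan(T), axis=0)):
        raise InvalidParameterError("a direction has no measurements")
    if np.any(np.all(np.isnan(T), axis=1)):
        raise InvalidParameterError("a subject has no measurements")

    # relative multipliers are only identifiable if the subject/direction
    # coverage graph is connected
    parent = list(range(len(subjects) + len(directions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(subjects)):
        for j in range(len(directions)):
            if not np.isnan(T[i, j]):
                parent[find(i)] = find(len(subjects) + j)
    if len({find(i) for i in range(len(parent))}) > 1:
        raise InvalidParameterError(
            "subjects have disjoint direction coverage; multipliers are not identifiable"
        )

    logm = np.zeros(len(subjects))
    prev = np.inf
    for _ in range(max_iter):
        cons = np.nanmean(T - logm[:, None], axis=0)
        resid = T - logm[:, None] - cons[None, :]
        logm = logm + np.nanmean(resid, axis=1)
        logm -= logm.mean()  # geometric-mean-1 normalization
        obj = np.nansum((T - logm[:, None] - cons[None, :]) ** 2)
        if prev - obj < tol:
            break
        prev = obj
    cons = np.nanmean(T - logm[:, None], axis=0)
    resid = T - logm[:, None] - cons[None, :]
    total = np.nansum((T - np.nanmean(T)) ** 2)
    var_expl = 1.0 if total == 0 else 1.0 - np.nansum(resid**2) / total
    consensus = {d: float(np.exp(cons[j])) for j, d in enumerate(directions)}
    multipliers = {s: float(np.exp(logm[i])) for i, s in enumerate(subjects)}
    return consensus, multipliers, float(var_expl)


def combine_errorbars(per_subject_log_errors) -> float:
    """Exponentiated root-mean-square of per-subject log-space error bars."""
    e = np.asarray(list(per_subject_log_errors), dtype=float)
    if e.size == 0:
        raise InvalidParameterError("no error bars given")
    return float(np.exp(np.sqrt(np.mean(e**2))))
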