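"""Parametric conditional score densities p(x_i | s_i = 1, y).

Each upstream prediction tool produces scores whose class-conditional
shape is modeled with one of five families:

* ``gamma`` — Gamma on ``x - shift`` (right-skewed positive scores);
* ``gamma_reflected`` — Gamma on ``r - x``: the histogram is flipped at
  its maximum so that left-skewed scores (e.g. TargetScan context scores,
  where more negative means a stronger target) get a Gamma-shaped tail;
* ``negative_binomial`` — NB on ``round(scale * (x - shift))`` for
  integer-like alignment scores;
* ``gaussian`` / ``gaussian_mixture_2`` — one or two normal components;
* ``exponential_shifted`` — Exponential on ``x - shift``.

All fits are maximum likelihood.  Densities are floored at a small
positive value so that a single out-of-support score at prediction time
cannot zero out an entire likelihood product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

from .errors import DegenerateDataError, FitError, InsufficientDataError

FAMILIES = (
    "gamma",
    "gamma_reflected",
    "negative_binomial",
    "gaussian",
    "gaussian_mixture_2",
    "exponential_shifted",
)

#: Default density floor: keeps log-likelihood factors finite for scores
#: outside the fitted support.
DENSITY_FLOOR = 1e-12

#: Offset fraction used when anchoring a support boundary at the sample
#: extremum, so the extremum itself has positive density.
_EDGE_EPS = 1e-9


@dataclass
class FittedConditional:
    """A fitted density for one tool and one class.

    ``params`` are the family parameters, ``transform`` records the
    support transform (reflection point, shift, discretization scale)
    needed to evaluate the density on the original score axis.
    """

    family: str
    params: dict
    transform: dict = field(default_factory=dict)
    n_fit: int = 0
    floor: float = DENSITY_FLOOR

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p, fam = self.params, self.family
        if fam in ("gamma", "gamma_reflected"):
            if not (p["shape"] > 0 and p["scale"] > 0):
                raise ValueError("gamma shape and scale must be positive")
        elif fam == "negative_binomial":
            if not (p["size"] > 0 and 0 < p["prob"] < 1):
                raise ValueError("NB requires size > 0 and prob in (0, 1)")
        elif fam == "gaussian":
            if not p["sd"] > 0:
                raise ValueError("gaussian sd must be positive")
        elif fam == "gaussian_mixture_2":
            w = np.asarray(p["weights"], dtype=float)
            if w.shape != (2,) or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
                raise ValueError("mixture weights must be two values summing to 1")
            if min(p["sds"]) <= 0:
                raise ValueError("mixture sds must be positive")
        elif fam == "exponential_shifted":
            if not p["rate"] > 0:
                raise ValueError("exponential rate must be positive")


def _clean(scores, min_n: int) -> np.ndarray:
    x = np.asarray(scores, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if np.isinf(x).any():
        raise ValueError("scores contain infinities")
    if len(x) < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} scores, got {len(x)}"
        )
    return x


def density(fc: FittedConditional, x, *, floored: bool = True):
    """Evaluate the (mass or density) function on the original score axis.

    Accepts scalars or arrays; values outside the fitted support get the
    configured floor (or 0 when ``floored=False``).
    """
    xa = np.asarray(x, dtype=float)
    fam, p, t = fc.family, fc.params, fc.transform
    if fam == "gamma":
        d = stats.gamma.pdf(xa - t["shift"], p["shape"], scale=p["scale"])
    elif fam == "gamma_reflected":
        d = stats.gamma.pdf(t["reflection"] - xa, p["shape"], scale=p["scale"])
    elif fam == "negative_binomial":
        c = np.rint(t["scale"] * (xa - t["shift"]))
        valid = c >= 0
        d = np.where(
            valid,
            stats.nbinom.pmf(np.where(valid, c, 0).astype(int), p["size"], p["prob"]),
            0.0,
        )
    elif fam == "gaussian":
        d = stats.norm.pdf(xa, p["mean"], p["sd"])
    elif fam == "gaussian_mixture_2":
        w, m, s = p["weights"], p["means"], p["sds"]
        d = w[0] * stats.norm.pdf(xa, m[0], s[0]) + w[1] * stats.norm.pdf(
            xa, m[1], s[1]
        )
    elif fam == "exponential_shifted":
        d = stats.expon.pdf(xa - t["shift"], scale=1.0 / p["rate"])
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(fam)
    d = np.nan_to_num(np.asarray(d, dtype=float), nan=0.0)
    if floored:
        d = np.maximum(d, fc.floor)
    return d if xa.ndim else float(d)


def log_density(fc: FittedConditional, x):
    return np.log(density(fc, x))


def fit_gamma_reflected(scores) -> FittedConditional:
    """Flip the sample at its maximum and fit a Gamma by MLE.

    The reflection point ``r = max + eps`` is stored so the same flip is
    applied at prediction time.
    """
    x = _clean(scores, 10)
    rng_width = float(np.ptp(x))
    if rng_width == 0:
        raise DegenerateDataError("all scores equal; cannot fit gamma")
    r = float(x.max()) + _EDGE_EPS * rng_width
    shape, _, scale = stats.gamma.fit(r - x, floc=0)
    return FittedConditional(
        "gamma_reflected",
        {"shape": float(shape), "scale": float(scale)},
        {"reflection": r},
        n_fit=len(x),
    )


def fit_gamma(scores) -> FittedConditional:
    """Fit a Gamma by MLE on ``x - shift``.

    Strictly positive scores keep their natural support (shift 0); when
    non-positive values occur the support is anchored just below the
    sample minimum instead.
    """
    x = _clean(scores, 10)
    rng_width = float(np.ptp(x))
    if rng_width == 0:
        raise DegenerateDataError("all scores equal; cannot fit gamma")
    shift = 0.0 if x.min() > 0 else float(x.min()) - _EDGE_EPS * rng_width
    shape, _, scale = stats.gamma.fit(x - shift, floc=0)
    return FittedConditional(
        "gamma",
        {"shape": float(shape), "scale": float(scale)},
        {"shift": shift},
        n_fit=len(x),
    )


def fit_negative_binomial(scores, scale: float = 1.0) -> FittedConditional:
    """Discretize to counts ``round(scale * (x - min))`` and fit NB by MLE.

    The mean is profiled out (the NB mean MLE is the sample mean for any
    dispersion), leaving a 1-D likelihood maximization over the size.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    x = _clean(scores, 10)
    shift = float(x.min())
    c = np.rint(scale * (x - shift))
    if (c < 0).any():
        raise ValueError("negative count after discretization")
    c = c.astype(int)
    if c.var() == 0:
        raise DegenerateDataError("no variation after discretization")
    mu = c.mean()

    def nll(log_size: float) -> float:
        k = math.exp(log_size)
        return -float(stats.nbinom.logpmf(c, k, k / (k + mu)).sum())

    res = optimize.minimize_scalar(
        nll, bounds=(math.log(1e-3), math.log(1e7)), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover
        raise FitError("negative-binomial likelihood maximization failed")
    size = math.exp(res.x)
    prob = size / (size + mu)
    return FittedConditional(
        "negative_binomial",
        {"size": float(size), "prob": float(prob)},
        {"shift": shift, "scale": float(scale)},
        n_fit=len(x),
    )


def fit_gaussian(scores) -> FittedConditional:
    x = _clean(scores, 10)
    sd = float(x.std(ddof=0))  # MLE (1/n) standard deviation
    if sd == 0:
        raise DegenerateDataError("zero variance; cannot fit gaussian")
    return FittedConditional(
        "gaussian", {"mean": float(x.mean()), "sd": sd}, {}, n_fit=len(x)
    )


def fit_gaussian_mixture_2(scores, seed: int = 0) -> FittedConditional:
    """Two-component Gaussian mixture by EM.

    Initialization: means at the 25th/75th percentiles, both sds at half
    the sample sd, weights 0.5/0.5; convergence when the log-likelihood
    improves by less than 1e-8 or after 500 iterations.  If a component
    collapses (sd below 1e-6 of the range) the fit restarts with jittered
    means, up to 5 attempts.  Components are reported by ascending mean.
    """
    x = _clean(scores, 20)
    n = len(x)
    rng_width = float(np.ptp(x))
    s0 = float(x.std(ddof=0))
    if s0 == 0:
        raise DegenerateDataError("zero variance; cannot fit mixture")
    rng = np.random.default_rng(seed)
    base_means = np.percentile(x, [25, 75]).astype(float)
    for attempt in range(5):
        m = base_means + (rng.normal(0, 0.1 * s0, 2) if attempt else 0.0)
        sd = np.full(2, s0 / 2)
        w = np.full(2, 0.5)
        prev_ll = -math.inf
        collapsed = False
        for _ in range(500):
            comp = w * stats.norm.pdf(x[:, None], m, sd)
            tot = np.maximum(comp.sum(axis=1), 1e-300)
            ll = float(np.log(tot).sum())
            resp = comp / tot[:, None]
            nk = np.maximum(resp.sum(axis=0), 1e-300)
            w = nk / n
            m = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - m) ** 2).sum(axis=0) / nk
            sd = np.sqrt(var)
            if sd.min() < 1e-6 * rng_width:
                collapsed = True
                break
            if ll - prev_ll < 1e-8:
                break
            prev_ll = ll
        if not collapsed:
            order = np.argsort(m)
            return FittedConditional(
                "gaussian_mixture_2",
                {
                    "weights": [float(w[i]) for i in order],
                    "means": [float(m[i]) for i in order],
                    "sds": [float(sd[i]) for i in order],
                },
                {},
                n_fit=n,
            )
    raise FitError("EM collapsed in all 5 restarts")


def fit_exponential_shifted(scores) -> FittedConditional:
    x = _clean(scores, 10)
    shift = float(x.min())
    mean_excess = float((x - shift).mean())
    if mean_excess == 0:
        raise DegenerateDataError("zero mean after shift; cannot fit exponential")
    return FittedConditional(
        "exponential_shifted",
        {"rate": 1.0 / mean_excess},
        {"shift": shift},
        n_fit=len(x),
    )


FITTERS = {
    "gamma": fit_gamma,
    "gamma_reflected": fit_gamma_reflected,
    "negative_binomial": fit_negative_binomial,
    "gaussian": fit_gaussian,
    "gaussian_mixture_2": fit_gaussian_mixture_2,
    "exponential_shifted": fit_exponential_shifted,
}


def sample(fc: FittedConditional, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw scores from a fitted conditional (inverse of the support transform)."""
    p, t = fc.params, fc.transform
    if fc.family == "gamma":
        return t["shift"] + rng.gamma(p["shape"], p["scale"], size)
    if fc.family == "gamma_reflected":
        return t["reflection"] - rng.gamma(p["shape"], p["scale"], size)
    if fc.family == "negative_binomial":
        c = rng.negative_binomial(p["size"], p["prob"], size)
        return t["shift"] + c / t["scale"]
    if fc.family == "gaussian":
        return rng.normal(p["mean"], p["sd"], size)
    if fc.family == "gaussian_mixture_2":
        idx = (rng.random(size) >= p["weights"][0]).astype(int)
        means = np.asarray(p["means"])[idx]
        sds = np.asarray(p["sds"])[idx]
        return means + sds * rng.standard_normal(size)
    if fc.family == "exponential_shifted":
        return t["shift"] + rng.exponential(1.0 / p["rate"], size)
    raise ValueError(fc.family)  # pragma: no cover


def normalization(fc: FittedConditional) -> float:
    """Numerically integrate (or sum) the un-floored density over its support.

    Used to verify that every fitted conditional is a proper distribution
    before flooring is applied.
    """
    p, t = fc.params, fc.transform
    if fc.family == "negative_binomial":
        kmax = int(stats.nbinom.ppf(1 - 1e-14, p["size"], p["prob"])) + 10
        return float(stats.nbinom.pmf(np.arange(kmax + 1), p["size"], p["prob"]).sum())
    if fc.family == "gamma":
        lo = t["shift"]
        hi = t["shift"] + stats.gamma.ppf(1 - 1e-13, p["shape"], scale=p["scale"])
    elif fc.family == "gamma_reflected":
        hi = t["reflection"]
        lo = t["reflection"] - stats.gamma.ppf(1 - 1e-13, p["shape"], scale=p["scale"])
    elif fc.family == "gaussian":
        lo, hi = p["mean"] - 10 * p["sd"], p["mean"] + 10 * p["sd"]
    elif fc.family == "gaussian_mixture_2":
        smax = max(p["sds"])
        lo = min(p["means"]) - 10 * smax
        hi = max(p["means"]) + 10 * smax
    elif fc.family == "exponential_shifted":
        lo = t["shift"]
        hi = t["shift"] + stats.expon.ppf(1 - 1e-13, scale=1.0 / p["rate"])
    else:  # pragma: no cover
        raise ValueError(fc.family)
    total, _ = integrate.quad(
        lambda v: density(fc, v, floored=False), lo, hi, limit=400, epsabs=1e-10
    )
    return float(total)
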