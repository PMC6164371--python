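"""Closed-form FRAP recovery models.

Three analytic recovery laws are provided, each for a uniform-disk read-out
of radius R after a Gaussian-profile bleach pulse of depth K:

* ``adm`` — anomalous diffusion (CTRW subdiffusion treated through a
  Gaussian propagator with dispersion D_alpha * t**alpha),
* ``bm`` — free Brownian motion (the classic Axelrod series),
* ``rbm`` — restricted Brownian motion, i.e. Brownian motion of a mobile
  fraction M plus an immobile fraction 1 - M that never recovers.

All three are alternating series in the bleach constant K; they are
evaluated with a running-term recurrence (no factorials) and truncated at
``n_terms`` (default 19), which is accurate to well below 1e-6 for K <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODEL_KEYS = ("adm", "bm", "rbm")

#: Number of free parameters per model (K counted as free).
N_FREE_PARAMS = {"adm": 3, "bm": 2, "rbm": 3}


@dataclass(frozen=True)
class AdmParams:
    """Anomalous-diffusion model parameters.

    D_alpha is the anomalous dispersion coefficient (length**2 / time**alpha),
    alpha the subdiffusion exponent in (0, 1], K the bleach constant.
    """

    D_alpha: float
    alpha: float
    K: float

    def __post_init__(self) -> None:
        if self.D_alpha < 0:
            raise ValueError("D_alpha must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.K < 0:
            raise ValueError("K must be >= 0")


@dataclass(frozen=True)
class BmParams:
    """Free-Brownian model parameters (D in length**2 / time)."""

    D: float
    K: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.K < 0:
            raise ValueError("K must be >= 0")


@dataclass(frozen=True)
class RbmParams:
    """Restricted-Brownian parameters; M is the mobile fraction in [0, 1]."""

    D: float
    K: float
    M: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if not 0 <= self.M <= 1:
            raise ValueError("M must be in [0, 1]")


@dataclass(frozen=True)
class SeriesSettings:
    """Series truncation control.

    n_terms counts the terms beyond n = 0; 19 reproduces a 200-term
    evaluation to < 1e-6 for K <= 3.  convergence_guard is the relative
    magnitude of the last term above which a truncation warning is flagged.
    """

    n_terms: int = 19
    convergence_guard: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")


DEFAULT_SETTINGS = SeriesSettings()


def bleach_profile(r, K: float, w: float):
    """Unbleached density exp(-K * exp(-2 r**2 / w**2)) left by a Gaussian
    bleach pulse of waist ``w`` and depth ``K`` at radial distance ``r``.

    Decreasing in K, increasing in r; equals exp(-K) at the centre.
    """
    if w <= 0:
        raise ValueError("waist w must be > 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    r = np.asarray(r, dtype=float)
    out = np.exp(-K * np.exp(-2.0 * r * r / (w * w)))
    return out if out.ndim else float(out)


def bleach_depth(K: float) -> float:
    """Spatially averaged post-bleach intensity of the Axelrod series,
    sum_{n>=0} (-K)^n / (n! (n+1)) = (1 - exp(-K)) / K.

    This is the t = 0 value of the Brownian series and the immobile-fraction
    plateau of the restricted-Brownian model.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if K == 0:
        return 1.0
    return float(-np.expm1(-K) / K)


def adm_recovery(t, R: float, params: AdmParams,
                 settings: SeriesSettings = DEFAULT_SETTINGS):
    """Anomalous-diffusion recovery for a uniform disk read-out of radius R.

    I_R(t) = 1 + sum_{n>=1} (-K)^n / n! * 1/(2n)
             * [1 - exp(-2 n R^2 / (R^2 + 4 n D_alpha t^alpha))]

    Bounded in (0, 1] and non-decreasing in t for K > 0; recovers to 1.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    spread = 4.0 * params.D_alpha * np.power(t, params.alpha)  # MSD*2 of the propagator
    out = np.ones_like(t)
    term = 1.0  # (-K)^n / n!
    R2 = R * R
    for n in range(1, settings.n_terms + 1):
        term *= -params.K / n
        out = out + term / (2.0 * n) * (1.0 - np.exp(-2.0 * n * R2 / (R2 + n * spread)))
    return out if out.ndim else float(out)


def bm_recovery(t, R: float, params: BmParams,
                settings: SeriesSettings = DEFAULT_SETTINGS):
    """Free-Brownian (Axelrod-type) recovery,

    I_R(t) = sum_{n>=0} (-K)^n / n! * 1 / (1 + n + 8 n D t / R^2),

    with the n = 0 term equal to 1.  The curve starts at the bleach depth
    (1 - exp(-K))/K at t = 0 and recovers to 1; t enters only through
    D t / R^2, so doubling R and quadrupling t leaves the value unchanged.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    x = 8.0 * params.D * t / (R * R)
    out = np.ones_like(t)
    term = 1.0
    for n in range(1, settings.n_terms + 1):
        term *= -params.K / n
        out = out + term / (1.0 + n + n * x)
    return out if out.ndim else float(out)


def rbm_recovery(t, R: float, params: RbmParams,
                 settings: SeriesSettings = DEFAULT_SETTINGS):
    """Restricted-Brownian recovery,

    I_R(t) = (1 - M) (1 - e^-K)/K + M * bm_recovery(t),

    i.e. a convex combination of the immobile plateau (the bleach depth)
    and the free-Brownian recovery, affine in the mobile fraction M.
    """
    bm = bm_recovery(t, R, BmParams(D=params.D, K=params.K), settings)
    return (1.0 - params.M) * bleach_depth(params.K) + params.M * bm


def dispersion_from_alpha(D: float, alpha: float) -> float:
    """Anomalous dispersion D_alpha = D * sin(pi alpha) / (pi alpha).

    This is the exact dispersion of the CTRW Gaussian-approximated
    propagator for Levy-law waiting times; it pairs D (the per-jump
    Gaussian variance parameter) with the t**alpha mean-squared
    displacement law.  Vanishes as alpha -> 1 only in the formal limit of
    the formula; alpha = 1 itself maps D_alpha = D (Brownian case).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if D < 0:
        raise ValueError("D must be >= 0")
    if alpha == 1.0:
        return float(D)
    return float(D * np.sin(np.pi * alpha) / (np.pi * alpha))


def dispersion_from_alpha_gamma(D: float, alpha: float) -> float:
    """Alternative dispersion convention D_alpha = D / Gamma(1 - alpha).

    Kept as an option; the sine form above is canonical here (the two are
    related through the reflection formula by a factor Gamma(1 + alpha)).
    """
    from scipy.special import gamma

    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(D / gamma(1.0 - alpha))


def alpha_aware_diffusion(D_alpha: float, alpha: float) -> float:
    """Invert the dispersion relation: D = D_alpha * (pi alpha) / sin(pi alpha).

    Undefined at alpha = 1, where sin(pi alpha) = 0 and the formula
    degenerates: an explicit error is raised there.
    """
    if not 0 < alpha < 1:
        if alpha == 1.0:
            raise ZeroDivisionError(
                "dispersion inverse undefined at alpha = 1 (sin(pi) = 0)")
        raise ValueError("alpha must be in (0, 1]")
    return float(D_alpha * np.pi * alpha / np.sin(np.pi * alpha))


def green_exponent(alpha: float) -> float:
    """Stretched-exponential tail exponent nu = 1 / (2 - alpha) of the
    subdiffusive propagator, interpolating between Gaussian (alpha = 1,
    nu = 1) and exponential (alpha -> 0, nu -> 1/2).  Diagnostic only.
    """
    if not 0 < alpha < 2:
        raise ValueError("alpha must be in (0, 2)")
    return 1.0 / (2.0 - alpha)


def evaluate(model_key: str, t, R: float, params: dict,
             settings: SeriesSettings = DEFAULT_SETTINGS):
    """Evaluate a registered model from a plain parameter dict."""
    if model_key == "adm":
        p = AdmParams(D_alpha=params["D_alpha"], alpha=params["alpha"], K=params["K"])
        return adm_recovery(t, R, p, settings)
    if model_key == "bm":
        p = BmParams(D=params["D"], K=params["K"])
        return bm_recovery(t, R, p, settings)
    if model_key == "rbm":
        p = RbmParams(D=params["D"], K=params["K"], M=params["M"])
        return rbm_recovery(t, R, p, settings)
    raise KeyError(f"unknown model key {model_key!r}; expected one of {MODEL_KEYS}")


def asymptote(model_key: str, params: dict) -> float:
    """t -> infinity limit of a model: 1 for adm and bm, and
    (1 - M) * bleach_depth(K) + M for rbm (the immobile part never refills).
    """
    if model_key in ("adm", "bm"):
        return 1.0
    if model_key == "rbm":
        return (1.0 - params["M"]) * bleach_depth(params["K"]) + params["M"]
    raise KeyError(f"unknown model key {model_key!r}")
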