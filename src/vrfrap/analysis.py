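"""Variable-radius FRAP inference.

Fitted parameters from recoveries bleached at several radii are regressed
against the inverse bleach radius 1/R.  Three pieces of physics hang off
that line:

* the intercept at 1/R = 0 (R -> infinity) extrapolates away finite-size
  and finite-time bias, recovering the true subdiffusion exponent alpha
  and diffusion coefficient D of a CTRW walker;
* the *sign* of the slope discriminates motion models — CTRW subdiffusion
  gives a negative alpha-vs-1/R slope, while trapping in spatial domains
  gives a positive mobile-fraction (and alpha) slope;
* a positive mobile-fraction slope feeds the empirical Schram relation
  M(R) = Mp + 0.63 L / R (valid for L < R), yielding the confinement
  domain radius L = slope / 0.63 and the free fraction Mp = intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np
from scipy.stats import linregress

from .fitting import FitResult

SCHRAM_COEFFICIENT = 0.63

#: regression-eligible parameter names per model
_PARAM_SOURCES = {
    "alpha": ("adm",),
    "D_alpha": ("adm",),
    "D": ("adm", "bm", "rbm"),
    "M": ("rbm",),
    "K": ("adm", "bm", "rbm"),
}


@dataclass
class VrFitSeries:
    """Per-radius fit results of a single model."""

    entries: list[tuple[float, FitResult]]
    model_key: str
    length_unit: str = "a.u."

    def __post_init__(self) -> None:
        if len({round(r, 12) for r, _ in self.entries}) < 3:
            raise ValueError("need fits at >= 3 distinct bleach radii")
        for _, fr in self.entries:
            if fr.model_key != self.model_key:
                raise ValueError("all entries must share the series model_key")

    @property
    def radii(self) -> np.ndarray:
        return np.array([r for r, _ in self.entries], dtype=float)


@dataclass
class RegressionResult:
    """OLS line of a fitted parameter against 1/R."""

    parameter_name: str
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float
    r_squared: float
    n_points: int
    R_min_used: float
    length_unit: str = "a.u."
    meta: dict[str, Any] = field(default_factory=dict)

    def slope_significant(self, z: float = 2.0) -> bool:
        return (np.isfinite(self.slope_stderr) and self.slope_stderr > 0
                and abs(self.slope) > z * self.slope_stderr)

    def to_dict(self) -> dict:
        return {
            "parameter_name": self.parameter_name,
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "slope_stderr": float(self.slope_stderr),
            "intercept_stderr": float(self.intercept_stderr),
            "r_squared": float(self.r_squared),
            "n_points": int(self.n_points),
            "R_min_used": float(self.R_min_used),
            "length_unit": self.length_unit,
        }


@dataclass
class DomainEstimate:
    """Confinement-domain size from the Schram relation.

    L is the domain radius, Mp the freely diffusing (plateau) fraction and
    1 - Mp the confined fraction; the estimate is only geometrically valid
    when L is smaller than the smallest bleach radius used.
    """

    L: float
    Mp: float
    confined_fraction: float
    valid: bool
    length_unit: str = "a.u."

    def to_dict(self) -> dict:
        return {"L": float(self.L), "Mp": float(self.Mp),
                "confined_fraction": float(self.confined_fraction),
                "valid": bool(self.valid), "length_unit": self.length_unit}


class CrossoverResult(NamedTuple):
    radius: float
    physical: bool


def regress_vs_inverse_radius(series: VrFitSeries, parameter_name: str,
                              R_min: float = 0.0,
                              weighted: bool = False) -> RegressionResult:
    """Ordinary least-squares line of a fitted parameter against 1/R,
    restricted to radii strictly above ``R_min``.

    With ``weighted=True`` and finite per-fit standard errors available,
    a 1/variance-weighted fit (statsmodels WLS) is used instead.
    """
    if parameter_name not in _PARAM_SOURCES:
        raise KeyError(f"unknown parameter {parameter_name!r}")
    if series.model_key not in _PARAM_SOURCES[parameter_name]:
        raise ValueError(
            f"parameter {parameter_name!r} is not produced by model "
            f"{series.model_key!r}")
    pts = [(r, fr) for r, fr in series.entries if r > R_min and fr.converged]
    if len(pts) < 3:
        raise ValueError("need >= 3 converged fits with R > R_min")
    radii = np.array([r for r, _ in pts])
    if np.unique(np.round(radii, 12)).size < 3:
        raise ValueError("need >= 3 distinct radii after filtering")
    x = 1.0 / radii
    y = np.array([fr.parameter(parameter_name) for _, fr in pts])
    if weighted:
        se = np.array([fr.stderr.get(parameter_name, np.nan) for _, fr in pts])
        if np.all(np.isfinite(se)) and np.all(se > 0):
            import statsmodels.api as sm

            X = sm.add_constant(x)
            res = sm.WLS(y, X, weights=1.0 / se**2).fit()
            return RegressionResult(
                parameter_name, float(res.params[1]), float(res.params[0]),
                float(res.bse[1]), float(res.bse[0]),
                float(res.rsquared), len(pts), float(radii.min()),
                series.length_unit, meta={"weighted": True})
    if np.allclose(y, y[0]):
        # exactly constant parameter: slope 0, intercept = that constant
        return RegressionResult(parameter_name, 0.0, float(y[0]), 0.0, 0.0,
                                1.0, len(pts), float(radii.min()),
                                series.length_unit)
    lr = linregress(x, y)
    return RegressionResult(
        parameter_name, float(lr.slope), float(lr.intercept),
        float(lr.stderr), float(lr.intercept_stderr),
        float(lr.rvalue**2), len(pts), float(radii.min()),
        series.length_unit)


def extrapolate_parameter(regression: RegressionResult) -> tuple[float, float]:
    """Finite-size-corrected parameter estimate: the regression intercept
    at 1/R = 0 (R -> infinity) and its standard error."""
    return regression.intercept, regression.intercept_stderr


def classify_motion(alpha_regression: RegressionResult | None = None,
                    M_regression: RegressionResult | None = None,
                    z: float = 2.0, unity_tol: float = 0.05) -> str:
    """Slope-sign model discrimination.

    * ``ctrw_like``       — alpha-vs-1/R slope significantly negative
      (finite-size signature of CTRW subdiffusion);
    * ``domain_confined`` — alpha slope significantly positive and/or
      mobile-fraction slope significantly positive (trapping domains);
    * ``brownian``        — no significant slope and extrapolated alpha
      and/or M within ``unity_tol`` of 1;
    * ``inconclusive``    — anything else.

    Significance is |slope| > z * slope_stderr (default z = 2).  Either
    regression may be None for a partial classification.
    """
    if alpha_regression is None and M_regression is None:
        return "inconclusive"
    a_sig = alpha_regression is not None and alpha_regression.slope_significant(z)
    m_sig = M_regression is not None and M_regression.slope_significant(z)
    if a_sig and alpha_regression.slope < 0:
        return "ctrw_like"
    if (a_sig and alpha_regression.slope > 0) or (m_sig and M_regression.slope > 0):
        return "domain_confined"
    if not a_sig and not m_sig:
        near_one = []
        if alpha_regression is not None:
            near_one.append(abs(alpha_regression.intercept - 1.0) <=
                            max(unity_tol, z * alpha_regression.intercept_stderr))
        if M_regression is not None:
            near_one.append(abs(M_regression.intercept - 1.0) <=
                            max(unity_tol, z * M_regression.intercept_stderr))
        if near_one and all(near_one):
            return "brownian"
    return "inconclusive"


def schram_domain_size(M_regression: RegressionResult) -> DomainEstimate:
    """Invert the Schram relation M(R) = Mp + 0.63 L / R.

    L = slope / 0.63 (slope carries units of length) and Mp is the
    intercept clipped to [0, 1].  The estimate is flagged invalid for a
    negative slope or when L is not below the smallest radius used.
    """
    if M_regression.parameter_name != "M":
        raise ValueError("domain size requires a mobile-fraction (M) regression")
    slope = M_regression.slope
    L = max(slope, 0.0) / SCHRAM_COEFFICIENT
    Mp = float(np.clip(M_regression.intercept, 0.0, 1.0))
    valid = slope >= 0 and L < M_regression.R_min_used
    return DomainEstimate(L=float(L), Mp=Mp, confined_fraction=1.0 - Mp,
                          valid=bool(valid), length_unit=M_regression.length_unit)


def alpha_crossover_radius(alpha_regression: RegressionResult) -> CrossoverResult:
    """Radius at which the fitted-alpha line crosses alpha = 1, i.e. the
    apparent transition from subdiffusive to normal diffusion.

    Solves intercept + slope / R = 1; intercept exactly 1 gives an
    infinite crossover radius, and a negative solution (e.g. intercept
    below 1 with a negative slope) is flagged non-physical.
    """
    slope = alpha_regression.slope
    intercept = alpha_regression.intercept
    if slope == 0:
        raise ValueError("slope is zero: no crossover radius")
    if intercept == 1.0:
        return CrossoverResult(np.inf, True)
    radius = slope / (1.0 - intercept)
    return CrossoverResult(float(radius), bool(radius > 0))


def build_series(fits: list[FitResult], model_key: str,
                 length_unit: str = "a.u.") -> VrFitSeries:
    """Assemble a VrFitSeries from fit results carrying their radii."""
    entries = [(fr.bleach_radius, fr) for fr in fits
               if fr.model_key == model_key and fr.bleach_radius is not None]
    return VrFitSeries(entries=entries, model_key=model_key,
                       length_unit=length_unit)
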