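"""Synthetic twin of the cell FRAP experiments.

Emulates the confocal acquisition protocol (150 samples over 100 s, 0.44 s
spacing early then 1 s late) and the four-objective instrument table
(bleach radii 0.32-0.74 um, laser waists 160-370 nm), and generates
variable-radius datasets from any generative model — the analytic
recovery laws with additive Gaussian noise, or the CTRW Monte-Carlo engine
— so the fitting and regression stages can be validated end to end
without cell data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from . import models
from .ctrw import CtrwConfig, simulate_recovery
from .curve import RecoveryCurve


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of one recovery acquisition.

    The camera samples every ``early_interval`` seconds right after the
    bleach, then every ``late_interval`` seconds (to limit monitoring
    photobleaching), for ``n_points`` samples over ``total_duration``.
    The bleach pulse length is metadata only (no diffusion during the
    pulse is modelled).
    """

    total_duration: float = 100.0
    n_points: int = 150
    early_interval: float = 0.44
    late_interval: float = 1.0
    bleach_pulse: float = 0.2


DEFAULT_PROTOCOL = AcquisitionProtocol()


def experimental_time_grid(protocol: AcquisitionProtocol = DEFAULT_PROTOCOL
                           ) -> np.ndarray:
    """Reconstruct the dual-rate sampling grid.

    The split between early and late samples is solved from the two
    published constraints (n_early + n_late = n_points and
    n_early * early + n_late * late = total_duration), rounded to whole
    samples, with the final sample forced to land on total_duration.
    For the default protocol this gives 89 early + 61 late samples.
    """
    p = protocol
    if p.early_interval <= 0 or p.late_interval <= 0 or p.n_points < 2:
        raise ValueError("invalid protocol")
    if p.late_interval == p.early_interval:
        n_early = p.n_points
    else:
        n_early = round((p.n_points * p.late_interval - p.total_duration)
                        / (p.late_interval - p.early_interval))
    n_late = p.n_points - n_early
    if n_early < 1 or n_late < 0:
        raise ValueError("no dual-rate switch point satisfies the protocol")
    # consistency within one sample of the stated duration
    dur = n_early * p.early_interval + n_late * p.late_interval
    if abs(dur - p.total_duration) > max(p.early_interval, p.late_interval):
        raise ValueError("protocol durations and counts are inconsistent")
    early = p.early_interval * np.arange(n_early)
    late = early[-1] + p.late_interval * np.arange(1, n_late + 1)
    grid = np.concatenate([early, late])
    grid[-1] = p.total_duration
    return grid


_INSTRUMENT_ROWS = [
    # objective, magnification, NA, R (um), dR (um), waist (nm)
    ("16x", 16, 1.0, 0.74, 0.04, 370.0),
    ("40x", 40, 1.3, 0.44, 0.03, 222.0),
    ("63x", 63, 1.4, 0.37, 0.01, 185.0),
    ("100x", 100, 1.4, 0.32, 0.01, 160.0),
]


def instrument_table() -> pd.DataFrame:
    """Measured bleach-disk radii and laser waists per objective.

    Every row satisfies R = 2 x waist (the bleached disk is about twice
    the 1/e**2 beam waist).
    """
    return pd.DataFrame(
        _INSTRUMENT_ROWS,
        columns=["objective", "magnification", "numerical_aperture",
                 "bleach_radius_um", "radius_uncertainty_um", "waist_nm"],
    )


def table_radii_um() -> list[float]:
    """The four instrument bleach radii in micrometres."""
    return [row[3] for row in _INSTRUMENT_ROWS]


@dataclass
class SyntheticDatasetSpec:
    """Recipe for a variable-radius synthetic dataset.

    ``generative_model`` is one of the analytic models ("adm", "bm",
    "rbm") or "ctrw-sim" (delegates to the Monte-Carlo engine).  For rbm,
    ``true_params`` may carry domain-confinement truth as ``Mp`` and ``L``
    instead of a fixed ``M``; the mobile fraction at each radius is then
    M(R) = Mp + 0.63 L / R (flagged when L >= the smallest radius, where
    the relation leaves its validity range).
    """

    generative_model: str = "rbm"
    true_params: dict[str, Any] = field(default_factory=dict)
    radii: list[float] = field(default_factory=table_radii_um)
    noise_sd: float = 0.03
    replicates_per_radius: int = 3
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL
    length_unit: str = "um"
    seed: int = 0
    ctrw_config: CtrwConfig | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates_per_radius < 1:
            raise ValueError("replicates_per_radius must be >= 1")


def generate_curve(model_key: str, params: dict[str, float], R: float,
                   protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
                   noise_sd: float = 0.03, seed: int = 0) -> RecoveryCurve:
    """One synthetic recovery: the analytic model on the acquisition grid
    plus iid Gaussian noise; the generative truth rides in the metadata."""
    times = experimental_time_grid(protocol)
    clean = models.evaluate(model_key, times, R, params)
    rng = np.random.default_rng(seed)
    noisy = clean + (rng.normal(0.0, noise_sd, times.size) if noise_sd > 0 else 0.0)
    return RecoveryCurve(
        times=times, intensities=noisy, bleach_radius=R,
        noise_sd=noise_sd if noise_sd > 0 else None,
        provenance="synthetic-model",
        meta={"generative_model": model_key, "truth": dict(params),
              "seed": seed},
    )


def _mobile_fraction_at(R: float, truth: dict[str, Any]) -> float:
    if "M" in truth:
        return float(truth["M"])
    return float(truth["Mp"]) + 0.63 * float(truth["L"]) / R


def generate_vrfrap_dataset(spec: SyntheticDatasetSpec) -> list[RecoveryCurve]:
    """Full variable-radius dataset: radii x replicates independent curves.

    Per-curve seeds derive deterministically from ``spec.seed``.  For
    "ctrw-sim" each curve is an independent Monte-Carlo run (intrinsic
    counting noise) with optional additive read-out noise on top.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_curves = len(spec.radii) * spec.replicates_per_radius
    seeds = [int(s) % 2**31 for s in ss.generate_state(n_curves)]
    curves: list[RecoveryCurve] = []
    truth = dict(spec.true_params)
    schram_truth = spec.generative_model == "rbm" and "Mp" in truth
    idx = 0
    for R in spec.radii:
        for _ in range(spec.replicates_per_radius):
            seed = seeds[idx]
            idx += 1
            if spec.generative_model == "ctrw-sim":
                cfg = spec.ctrw_config or CtrwConfig()
                curve = simulate_recovery(
                    replace(cfg, bleach_radius=float(R), seed=seed))
                if spec.noise_sd > 0:
                    rng = np.random.default_rng(seed + 1)
                    curve.intensities = curve.intensities + rng.normal(
                        0.0, spec.noise_sd, curve.times.size)
                    curve.noise_sd = spec.noise_sd
                curve.meta["truth"] = {"alpha": cfg.alpha,
                                       "D": cfg.diffusion_coefficient}
            else:
                params = dict(truth)
                flagged = False
                if schram_truth:
                    params = {"D": truth["D"], "K": truth["K"],
                              "M": min(_mobile_fraction_at(R, truth), 1.0)}
                    flagged = truth["L"] >= min(spec.radii)
                curve = generate_curve(spec.generative_model, params, float(R),
                                       spec.protocol, spec.noise_sd, seed)
                curve.meta["truth"] = dict(truth)
                if schram_truth and flagged:
                    curve.meta["schram_validity_warning"] = True
            curve.meta["length_unit"] = spec.length_unit
            curves.append(curve)
    return curves


def average_curves(curves: list[RecoveryCurve]) -> RecoveryCurve:
    """Pointwise mean of replicate curves on a shared time grid (the
    averaged-recovery read-out used for single-spot fits)."""
    t0 = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, t0):
            raise ValueError("curves must share an identical time grid")
    mean = np.mean([c.intensities for c in curves], axis=0)
    out = RecoveryCurve(times=t0.copy(), intensities=mean,
                        bleach_radius=curves[0].bleach_radius,
                        n_replicates=len(curves),
                        provenance=curves[0].provenance,
                        meta=dict(curves[0].meta))
    if curves[0].noise_sd:
        out.noise_sd = curves[0].noise_sd / np.sqrt(len(curves))
    return out
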