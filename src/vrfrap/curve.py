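"""The FRAP recovery curve container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class RecoveryCurve:
    """One fluorescence-recovery trace.

    Times are post-bleach observation times (the bleach pulse defines t = 0)
    and intensities are normalized to the prebleach level, so a fully
    recovered spot reads 1.  ``bleach_radius`` is the radius of the read-out
    disk; ``waist`` is the 1/e**2 radius of the Gaussian bleach profile when
    it differs from the read-out radius.

    Attributes
    ----------
    times : ndarray
        Strictly increasing observation times (a.u. or seconds).
    intensities : ndarray
        Normalized fluorescence, prebleach = 1.
    bleach_radius : float
        Read-out / bleach disk radius (same length unit as ``waist``).
    waist : float or None
        Gaussian profile waist; ``None`` means "equal to bleach_radius".
    n_replicates : int
        Number of averaged traces this curve represents.
    noise_sd : float or None
        Known additive noise level on normalized intensity, if any.
    provenance : str
        One of ``simulated`` (Monte Carlo), ``synthetic-model`` (analytic
        model plus noise) or ``file``.
    meta : dict
        Free-form metadata (seed, mode, generative truth, units, ...).
    """

    times: np.ndarray
    intensities: np.ndarray
    bleach_radius: float | None = None
    waist: float | None = None
    n_replicates: int = 1
    noise_sd: float | None = None
    provenance: str = "file"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("observation times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecoveryCurve):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.intensities, other.intensities)
            and self.bleach_radius == other.bleach_radius
            and self.waist == other.waist
            and self.provenance == other.provenance
        )
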