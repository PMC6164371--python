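"""Independent numerical oracle for the CTRW FRAP recovery.

Computes the exact expected recovery of a continuous time random walk on
the unbounded plane — no Gaussian approximation — by combining

* the Montroll-Weiss propagator in Fourier-Laplace space,
  g(k, s) = (1 - psi(s)) / (s (1 - psi(s) lambda(k))), with
  lambda(k) = exp(-D k^2 / 2) for Gaussian jumps of total variance 2D and
  psi the Laplace transform of the Levy waiting law alpha/(1+tau)^(1+alpha),
  analytically continued as psi(s) = alpha e^s s^alpha Gamma(-alpha, s);
* Talbot-contour numerical Laplace inversion in time;
* Fourier-Bessel (Hankel) quadrature in space against the bleach-deficit
  profile and the read-out disk.

This path shares nothing with the event-driven simulator or the analytic
recovery series, so it serves as an independent check of both: the
simulator must match it (within Monte Carlo error), while the
Gaussian-approximation series is expected to deviate from it by a small
systematic amount.
"""

import mpmath as mp
import numpy as np
from scipy.special import j1, roots_legendre


def waiting_time_laplace(alpha: float):
    """psi_hat(s) for complex s via the incomplete-gamma continuation."""

    def psi_hat(s: complex) -> complex:
        z = mp.mpc(s.real, s.imag)
        return complex(alpha * mp.e**z * z**alpha * mp.gammainc(-alpha, z))

    return psi_hat


def _talbot(t: float, M: int):
    k = np.arange(M)
    theta = -np.pi + (k + 0.5) * 2 * np.pi / M
    z = M / t * (0.5017 * theta / np.tan(0.6407 * theta) - 0.6122
                 + 0.2645j * theta)
    dz = M / t * (-0.5017 * 0.6407 * theta / np.sin(0.6407 * theta) ** 2
                  + 0.5017 / np.tan(0.6407 * theta) + 0.2645j)
    return z, dz


def ctrw_recovery_exact(times, R: float, D: float, alpha: float, K: float,
                        w: float | None = None, M: int = 32,
                        n_k: int = 600, n_series: int = 60) -> np.ndarray:
    """Exact unbounded-plane CTRW recovery I_R(t) for a Gaussian bleach
    profile of waist w (default R) read out over the disk of radius R."""
    w = R if w is None else w
    psi_hat = waiting_time_laplace(alpha)
    kmax = 30.0 / w + 10.0 / np.sqrt(D)
    xk, wk = roots_legendre(n_k)
    k = 0.5 * kmax * (xk + 1.0)
    wk = 0.5 * kmax * wk
    # Hankel transform of the bleach deficit 1 - exp(-K exp(-2 r^2/w^2))
    Fk = np.zeros_like(k)
    term = 1.0
    for n in range(1, n_series):
        term *= -K / n
        Fk += -term * (np.pi * w * w / (2 * n)) * np.exp(-k * k * w * w / (8 * n))
    lam = np.exp(-D * k * k / 2.0)
    out = []
    for t in np.asarray(times, dtype=float):
        z, dz = _talbot(t, M)
        ghat = np.zeros_like(k)
        for zj, dzj in zip(z, dz):
            p = psi_hat(zj)
            ghat += (np.exp(zj * t) * (1.0 - p) / (zj * (1.0 - p * lam)) * dzj).imag
        ghat /= M
        deficit_in_disk = R * np.sum(wk * Fk * ghat * j1(k * R))
        out.append(1.0 - deficit_in_disk / (np.pi * R * R))
    return np.array(out)
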