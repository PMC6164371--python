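"""Numba kernels for the particle ensembles.

Each kernel seeds numba's internal RNG once and runs a single-threaded
per-particle loop, so results are bit-reproducible for a fixed seed.
Waiting times follow the heavy-tailed Levy law p(tau) = alpha/(1+tau)^(1+alpha)
(sampled by inverse CDF); jumps are isotropic Gaussian with total variance
2D per jump (variance D per axis).  In Brownian mode the walk advances on a
fixed clock dt with per-step total variance 2 D dt.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def ctrw_recovery_counts(n_particles, domain_radius, D, alpha, K, R, w,
                         obs_times, epsilon, seed, brownian, dt):
    """Simulate the bleach + recovery read-out in a reflective disk.

    Returns (counts, prebleach_count, unbleached_total): counts[j] is the
    number of surviving (unbleached) particles inside the read-out disk of
    radius R at obs_times[j]; prebleach_count is the number of particles
    inside that disk before the bleach pulse; unbleached_total is the
    number of particles surviving the pulse (conserved afterwards).
    """
    np.random.seed(seed)
    n_t = obs_times.shape[0]
    counts = np.zeros(n_t, dtype=np.int64)
    prebleach = 0
    unbleached = 0
    R2 = R * R
    dom2 = domain_radius * domain_radius
    keep_r = domain_radius - epsilon
    sig_jump = np.sqrt(D)
    sig_step = np.sqrt(D * dt)
    inv_alpha = 1.0 / alpha
    two_over_w2 = 2.0 / (w * w)
    for _ in range(n_particles):
        rr = domain_radius * np.sqrt(np.random.random())
        th = 2.0 * np.pi * np.random.random()
        x = rr * np.cos(th)
        y = rr * np.sin(th)
        r2 = x * x + y * y
        if r2 <= R2:
            prebleach += 1
        # Gaussian-profile photodestruction at t = 0
        if np.random.random() >= np.exp(-K * np.exp(-two_over_w2 * r2)):
            continue
        unbleached += 1
        if brownian:
            t_next = dt
        else:
            t_next = (1.0 - np.random.random()) ** (-inv_alpha) - 1.0
        for j in range(n_t):
            tj = obs_times[j]
            while t_next <= tj:
                if brownian:
                    x += sig_step * np.random.normal()
                    y += sig_step * np.random.normal()
                    t_next += dt
                else:
                    x += sig_jump * np.random.normal()
                    y += sig_jump * np.random.normal()
                    t_next += (1.0 - np.random.random()) ** (-inv_alpha) - 1.0
                r2 = x * x + y * y
                if r2 > dom2:
                    f = keep_r / np.sqrt(r2)
                    x *= f
                    y *= f
            if x * x + y * y <= R2:
                counts[j] += 1
    return counts, prebleach, unbleached


@njit(cache=True)
def ctrw_recovery_deficit(n_particles, domain_radius, D, alpha, K, R, w,
                          obs_times, epsilon, seed, brownian, dt,
                          deficit_floor):
    """Variance-reduced read-out of the same ensemble.

    Each particle carries its analytic bleach deficit 1 - exp(-K exp(-2
    r0^2/w^2)) instead of a Bernoulli survival flag, and the occupancy of
    the read-out disk is replaced by its exact stationary expectation
    n * (R/domain_radius)^2 (the uniform density is invariant in the
    reflective disk).  The recovered intensity is then
    1 - deficit_in_disk(t) / expected_occupancy: identical in expectation
    to the binary counting estimator, with the coin-flip and bulk
    occupancy noise removed.  Particles whose deficit is below
    ``deficit_floor`` contribute nothing and are not propagated.

    Returns (deficit_sums, n_active) with deficit_sums[j] the summed
    deficit of particles inside the disk at obs_times[j].
    """
    np.random.seed(seed)
    n_t = obs_times.shape[0]
    deficit = np.zeros(n_t, dtype=np.float64)
    n_active = 0
    R2 = R * R
    dom2 = domain_radius * domain_radius
    keep_r = domain_radius - epsilon
    sig_jump = np.sqrt(D)
    sig_step = np.sqrt(D * dt)
    inv_alpha = 1.0 / alpha
    two_over_w2 = 2.0 / (w * w)
    for _ in range(n_particles):
        rr = domain_radius * np.sqrt(np.random.random())
        th = 2.0 * np.pi * np.random.random()
        x = rr * np.cos(th)
        y = rr * np.sin(th)
        d = -np.expm1(-K * np.exp(-two_over_w2 * (x * x + y * y)))
        if d < deficit_floor:
            continue
        n_active += 1
        if brownian:
            t_next = dt
        else:
            t_next = (1.0 - np.random.random()) ** (-inv_alpha) - 1.0
        for j in range(n_t):
            tj = obs_times[j]
            while t_next <= tj:
                if brownian:
                    x += sig_step * np.random.normal()
                    y += sig_step * np.random.normal()
                    t_next += dt
                else:
                    x += sig_jump * np.random.normal()
                    y += sig_jump * np.random.normal()
                    t_next += (1.0 - np.random.random()) ** (-inv_alpha) - 1.0
                r2 = x * x + y * y
                if r2 > dom2:
                    f = keep_r / np.sqrt(r2)
                    x *= f
                    y *= f
            if x * x + y * y <= R2:
                deficit[j] += d
    return deficit, n_active


@njit(cache=True)
def msd_unbounded(n_particles, D, alpha, obs_times, seed, brownian, dt):
    """Ensemble mean squared displacement from the origin, no boundary."""
    np.random.seed(seed)
    n_t = obs_times.shape[0]
    acc = np.zeros(n_t, dtype=np.float64)
    sig_jump = np.sqrt(D)
    sig_step = np.sqrt(D * dt)
    inv_alpha = 1.0 / alpha
    for _ in range(n_particles):
        x = 0.0
        y = 0.0
        if brownian:
            t_next = dt
        else:
            t_next = (1.0 - np.random.random()) ** (-inv_alpha) - 1.0
        for j in range(n_t):
            tj = obs_times[j]
            while t_next <= tj:
                if brownian:
                    x += sig_step * np.random.normal()
                    y += sig_step * np.random.normal()
                    t_next += dt
                else:
                    x += sig_jump * np.random.normal()
                    y += sig_jump * np.random.normal()
                    t_next += (1.0 - np.random.random()) ** (-inv_alpha) - 1.0
            acc[j] += x * x + y * y
    return acc / n_particles
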