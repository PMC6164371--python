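# Methods

This note documents the models, the Monte-Carlo estimators, the default
parameters and the design choices behind `vrfrap`, and states what the
synthetic validation does and does not demonstrate about real data.

## The CTRW simulator

A walker in a disk of radius 30 a.u. (reflective boundary: an escaping
particle is re-inserted radially at `domain_radius − ε`, default
ε = 10⁻³·domain radius) waits in a trap for a time drawn from the Lévy
law p(τ) = α(1+τ)^−(1+α) (inverse-CDF sampling, τ = (1−u)^−1/α − 1),
then hops instantaneously by an isotropic Gaussian displacement of total
variance 2D; travel time is neglected. All walkers draw their first
waiting time fresh at t = 0 (no aging; we verified that an aged start
systematically over-corrects fitted α upward, so the non-equilibrated
start is both the simpler and the empirically consistent convention).
The ensemble MSD then grows as 2·D_α·t^α with
D_α = D·sin(πα)/(πα), which the test suite checks through the log–log
MSD slope. A Brownian reference mode advances on a fixed clock
(Δt = 10⁻², per-step total variance 2DΔt) for control experiments.

The simulator was validated against an independent evaluation of the
exact CTRW recovery on the unbounded plane (Montroll–Weiss propagator in
Fourier–Laplace space, Talbot inversion, Hankel quadrature against the
bleach profile; `tests/ctrw_oracle.py`). At 3×10⁷ particles the two
agree to ≤2×10⁻³ at all probed times, so the simulator can be treated as
ground truth for the CTRW model.

### Photobleaching and read-out

A single Gaussian pulse at t = 0 leaves each particle unbleached with
probability exp(−K·exp(−2r²/w²)). The bleach constant defaults to
K = 1.2 (≈38% average depth over the read-out disk — a realistic
experiment; the fitted-α bias was verified to be essentially
K-independent before freezing this value). The profile waist defaults to
w = R, matching the parameterization of the analytic series; pass
`waist = R/2` for instrument-faithful runs (the measured disk radius is
twice the laser waist).

Two read-out estimators share the identical ensemble:

- **binary** — the literal experiment: Bernoulli survival, head count in
  the disk of radius R, normalized by the actual prebleach count.
- **weighted** (default) — each particle carries its analytic bleach
  deficit 1 − exp(−K·exp(−2r₀²/w²)) as a weight, and the bulk disk
  occupancy is replaced by its exact expectation n·(R/domain)² (the
  uniform density is stationary in the reflective disk). The intensity
  is 1 − deficit(t)/expected occupancy. This is a control-variate /
  Rao–Blackwell construction: identical in expectation to the binary
  count (property-tested), but free of coin-flip and bulk-occupancy
  noise, and it lets walkers with negligible deficit (< 10⁻¹²,
  i.e. far from the bleach spot) be skipped exactly. Per-point noise at
  2×10⁵ particles drops from several percent to a few 10⁻³.

### Observation grids

The engine default is 150 log-spaced points over 4 decades ending at
t = 100 a.u., mirroring the fixed-duration philosophy of the cell
protocol. The variable-radius studies instead use a per-condition window
ending at 3 half-recovery times of the largest radius,
t_½ = (R²/4D_α)^(1/α) — with D spanning {0.1…2} a decade-wide range of
timescales, a single fixed window would leave slow conditions completely
unsampled. Both grids are configurable; the chosen coverage is a
package-level study condition, stated here once and used everywhere.

## Recovery models and fitting

The three series (anomalous disk read-out; Axelrod free-Brownian;
restricted Brownian with mobile fraction M) are evaluated with a
running-term recurrence and truncated at 19 terms (≤10⁻⁶ truncation
error for K ≤ 3, tested against 200-term evaluations). Two printed-form
choices deserve note:

- the Brownian-family series includes the n = 0 term (value 1), without
  which the series would tend to a negative value at long times; with it,
  the t = 0 depth is the Axelrod identity (1−e^−K)/K and the t → ∞ limit
  is 1 (the rBm immobile part stays at the depth).
- the dispersion conversion uses the sine form D_α = D·sin(πα)/(πα)
  (the form used to drive the simulations); the Γ-function variant
  D/Γ(1−α) is available behind `dispersion_from_alpha_gamma`.

Fits are bounded trust-region least squares (0 < α ≤ 1, 0 ≤ M ≤ 1,
D, K ≥ 0) with a deterministic 3-point multi-start jittered around a
data-driven initial guess (K inverted from the first post-bleach depth,
the diffusion scale from the empirical half-recovery time via
t_½ ≈ R²/4D, α starting at 0.8, M at 0.9), because the α–D_α–K objective
is shallow. K is fitted freely by default, which also absorbs the
different normalization conventions of the anomalous (recovers to 1) and
Axelrod (starts at (1−e^−K)/K) series; `FitOptions(fix_K=…)` pins it,
and `renormalize=True` rescales every model to a unit asymptote for
χ² comparison on identical footing. Standard errors come from the
Gauss–Newton curvature at the optimum scaled by the residual variance.
χ² uses the supplied noise level when available and otherwise the
residual standard deviation of the fit itself; the estimator used is
recorded on every result.

## Variable-radius inference

Fitted parameters are regressed on 1/R by ordinary least squares
(optionally 1/variance-weighted). The intercept at 1/R = 0 is the
finite-size-corrected parameter estimate; the slope sign is the model
discriminator. `classify_motion` gates slopes on |slope| > z·SE with
z = 2 by default; the discrimination *study* uses z = 0 (pure sign
logic), since the sign is what separates the two generative processes
and the underlying experimental comparison reports signs without a test.
Extrapolation regressions are restricted to R > 1 a.u., where the
α-vs-1/R relation is approximately linear; classification regressions
use the full radii range (the restriction matters for intercepts, not
signs). The Schram inversion M(R) = M_p + 0.63·L/R (empirical constant
0.63, taken as fixed) yields L = slope/0.63 and M_p = intercept clipped
to [0,1]; the estimate is flagged invalid for negative slopes or when
L ≥ the smallest radius used (outside the relation's L < R validity).
The α-crossover radius solves intercept + slope/R = 1 and is flagged
non-physical when negative. Physical units (µm) are only attached when
the series carries a unit calibration, as with the instrument-table
radii.

## Synthetic experiments

`synthetic` emulates the confocal acquisition: 150 samples over 100 s,
0.44 s spacing early and 1.0 s late. The published constraints fix the
switch point only jointly; solving n_early + n_late = 150 and
0.44·n_early + 1.0·n_late = 100 gives 89 early + 61 late samples
(rounded), with the final sample forced onto 100 s — a reconstruction,
recorded here. Instrument radii/waists are the four measured objective
rows (0.74/0.44/0.37/0.32 µm; every radius is twice the waist). Noise is
additive iid Gaussian on normalized intensity, default σ = 0.03 (chosen
once to match experiment-scale scatter); replicates are independent
(per-cell correlation structure is not modelled). Radius-dependent
mobile-fraction truth uses the Schram law itself, so end-to-end recovery
tests are exact-arithmetic at zero noise.

## Study problem sizes

The desk-scale studies use: extrapolation grid — 3 replicate curves of
2×10⁵ particles per radius (radii 1, 1.5, 2, 2.5, 3 a.u.), 9 (α, D)
conditions; discrimination — 20 replicates per generative model, 6
curves per radius of 5×10⁵ particles (CTRW, α = 0.7, D = 0.1, a
condition where the rms jump length √(2D) is well below every bleach
radius) or of the analytic rBm truth on instrument radii; model
comparison — 8 replicates of 5×10⁵-particle curves at σ = 0.03; Schram
recovery — 6 curves per radius (≈24 curves, the scale of a real
multi-cell campaign); MSD exponent diagnostics — 2×10⁴ unbounded walkers
over six time decades (the renewal process approaches its t^α law slowly
as α → 1). A full
10⁷-particle run per curve is feasible with the weighted estimator but
unnecessary for the shipped checks.

## Known limitations

- **Extrapolation accuracy.** The 1/R→0 intercepts do *not* recover α
  and D to 5% over the shipped (α, D) grid. Two verified reasons: the
  anomalous series rests on a Gaussian approximation of the CTRW
  propagator whose true shape is a scale-free stretched exponential, so
  single-radius fits carry an R-independent α bias of up to ≈−0.1 that
  no radius extrapolation can remove (the simulator itself matches exact
  theory, see above); and at 2×10⁵ particles per curve the per-curve α
  noise (~±0.03) puts a several-percent floor on each intercept. The
  negative-slope, intercept-recovering regime is expressed only where
  jumps are small compared with the bleach spot (D ≲ 0.1 here); the
  median relative error over the grid, the quantity
  `scripts/acceptance.py` reports, is ≈15% at this scale.
- Fitted D can *exceed* its input at small D (partial-coverage
  compensation between α and D_α), so "both parameters are always
  underestimated" holds for α throughout but for D only in the
  fitted-vs-input slope sense (slope < 1), not pointwise.
- No photophysics beyond the single instantaneous pulse: no reversible
  bleaching, no monitoring bleach, no diffusion during the pulse.
- Passing synthetic tests shows the pipeline's statistical machinery is
  correct at the stated scales; it does not certify any particular cell
  dataset, where noise is structured, replicates are correlated within
  cells, and the bleach geometry is imperfect.
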