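# vrfrap

Variable-radius FRAP analysis of anomalous and restricted diffusion in
membranes: a simulation + fitting + inference pipeline for deciding whether
the hindered mobility of a membrane-bound molecule comes from continuous
time random walk (CTRW) anomalous subdiffusion or from transient trapping
in spatial domains — and, in the latter case, how large the domains are.

## Who this is for

Fluorescence recovery after photobleaching (FRAP) bleaches fluorophores in
a spot of radius R and tracks the refilling of the spot over time. A single
recovery curve is notoriously ambiguous: an anomalous-subdiffusion model
(exponent α < 1) and a Brownian model with an immobile fraction fit the
same cell data essentially equally well. Repeating the experiment at
several bleach radii and regressing the fitted parameters against 1/R
breaks the degeneracy: the two motion models push the regression slope in
opposite directions. This package provides every stage of that analysis —
an event-driven CTRW Monte-Carlo simulator with photobleaching read-out,
the three closed-form recovery models, nonlinear fitting with χ² model
comparison, the inverse-radius regressions, and a synthetic-experiment
generator mimicking a confocal acquisition protocol — for microscopists
and modellers who want to design, validate, or reanalyse vr-FRAP
experiments without committing to one diffusion model a priori.

## The models

A CTRW walker waits in a trap for a heavy-tailed random time,
p(τ) = α/(1+τ)^(1+α), then hops by a Gaussian step of total variance 2D;
for α < 1 the ensemble mean squared displacement grows as
⟨r²(t)⟩ ∝ t^α. Recovery curves (prebleach intensity = 1, Gaussian bleach
profile exp(−K·exp(−2r²/w²))) are fitted with:

- **aDm** (anomalous diffusion, uniform-disk read-out):
  I_R(t) = 1 + Σ_{n≥1} (−K)ⁿ/n! · 1/(2n) · [1 − exp(−2nR²/(R² + 4nD_α t^α))],
  with dispersion D_α = D·sin(πα)/(πα);
- **Bm** (free Brownian, Axelrod series):
  I_R(t) = Σ_{n≥0} (−K)ⁿ/n! · 1/(1 + n + 8nDt/R²);
- **rBm** (restricted Brownian):
  I_R(t) = (1−M)·(1−e^(−K))/K + M·Bm(t), mobile fraction M.

The vr-FRAP inference regresses fitted α (aDm) and M (rBm) on 1/R:
a significantly negative α slope is the CTRW finite-size signature; a
positive M slope indicates domain trapping and feeds the empirical Schram
relation M(R) = M_p + 0.63·L/R, giving the domain radius L = slope/0.63
and free fraction M_p = intercept.

## Worked example

Classify a synthetic domain-confined dataset (free fraction 0.75, domain
radius 90 nm, instrument bleach radii 0.32–0.74 µm, 3% read-out noise):

```python
import numpy as np
from vrfrap import (SyntheticDatasetSpec, generate_vrfrap_dataset,
                    fit_recovery, classify_motion,
                    regress_vs_inverse_radius, schram_domain_size)
from vrfrap.analysis import build_series

spec = SyntheticDatasetSpec(
    generative_model="rbm",
    true_params={"Mp": 0.75, "L": 0.09, "D": 0.22, "K": 1.2},
    noise_sd=0.03, replicates_per_radius=3, seed=5)
curves = generate_vrfrap_dataset(spec)
fits = [fit_recovery(c, "rbm") for c in curves]
series = build_series(fits, "rbm", length_unit="um")
m_reg = regress_vs_inverse_radius(series, "M")
est = schram_domain_size(m_reg)
print(classify_motion(M_regression=m_reg))
print(f"L = {est.L*1e3:.0f} nm, free fraction Mp = {est.Mp:.2f}, "
      f"confined fraction = {est.confined_fraction:.2f}")
```

prints

```
domain_confined
L = 85 nm, free fraction Mp = 0.76, confined fraction = 0.24
```

i.e. the positive mobile-fraction slope identifies domain confinement and
the Schram inversion recovers the 90 nm domain radius and the 75% freely
diffusing fraction from the noisy curves within a few percent.

The same stages are available from the shell:

```
vrfrap generate --model rbm --truth-file truth.json --radii table2 \
       --noise 0.03 --replicates 3 --seed 5 --out-dir data/
vrfrap fit --model all --in data/curve_R0.37_006.csv --out fits/f06.json
vrfrap vrfrap --fits-dir fits/ --out report.json
```

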