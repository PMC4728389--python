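# geldiff

Physics-based modelling of *in vivo* hydrogel degradation tracked by
autofluorescence imaging.

A subcutaneously injected, autofluorescent protein hydrogel degrades over
roughly two months, releasing fluorescent compounds that spread through
the surrounding tissue.  Whole-animal fluorescence images of the
injection site show a circularly symmetric intensity field that first
brightens, then dims and broadens.  `geldiff` turns those radial
intensity time series into a quantitative transport model and an
estimate of the apparent *in vivo* diffusivity of the released
fluorophores.  It is aimed at researchers developing degradable
biomaterials who track degradation non-invasively by fluorescence.

## Model

All intensities are dimensionless (scaled by the maximum observable
intensity); lengths are in mm, times in days.  The scaled fluorophore
concentration c(r, t) — proportional to the radiant intensity — obeys an
axisymmetric diffusion equation with a time-modulated release source:

    ∂c/∂t = D (1/r) ∂/∂r (r ∂c/∂r) + S(r, t)

    S(r, t) = A · w(t + T; k, λ) · H(R − r)
    w(t; k, λ) = (k/λ)(t/λ)^(k−1) exp(−(t/λ)^k)      (Weibull density)

    c(r, 0) = c₀ + c₁ exp(−a r^α)

with symmetry at r = 0 and c → c₀ far away.  The Weibull factor captures
the growth and attenuation of release as the gel degrades; the
complementary Heaviside step H(R − r) confines release to the gel disk of
radius R (the inner radius of the injection needle); the phase lag T
aligns the source onset with the intensity observed immediately after
injection.  The apparent diffusivity D lumps all *in vivo* transport of
the released fluorophores into a single Fickian coefficient and is the
model's only empirical parameter.

The excess field u = c − c₀ is solved analytically with the order-zero
Hankel transform, û(β) = ∫₀^∞ r J₀(βr) u(r) dr, under which each spectral
mode evolves independently:

    û(β, t) = û₀(β) e^(−Dβ²t) + A Ŝ(β) ∫₀^t w(τ+T) e^(−Dβ²(t−τ)) dτ,
    Ŝ(β) = R J₁(βR)/β,

followed by the inverse transform c(r, t) = c₀ + ∫₀^∞ β J₀(βr) û(β, t) dβ.
An independent Crank–Nicolson finite-difference solver of the same
problem serves as a numerical oracle and mass-balance auditor.

Reference parameters (bundled as the defaults): A = 500, k = 1.5,
λ = 10 day, T = 1.5 day, R = 0.42 mm, c(r, 0) = 0.1 + 0.8 exp(−0.16 r^1.5),
D = 4.32 mm²/day — about 5% of a small molecule's diffusivity in water
(~10⁻⁹ m²/s).

## Layout

| module | contents |
|---|---|
| `geldiff.forward_model` | parameter types, source term, initial profile, mass bookkeeping, TOML I/O |
| `geldiff.hankel` | analytic solver (`HankelSolver`, `solve_concentration`) |
| `geldiff.pde` | Crank–Nicolson oracle (`solve_fd`, `mass_balance_report`) |
| `geldiff.imaging` | synthetic fluorescence stacks, radial profile extraction, TIFF round-trip |
| `geldiff.inference` | diffusivity / initial-condition fitting, bootstrap intervals |
| `geldiff.cli` | `geldiff simulate | synth | extract | fit | validate` |

## Worked example

Evaluate the model at the innermost extraction radius, then recover the
diffusivity from noisy synthetic curves:

```python
>>> import numpy as np
>>> from geldiff import (reference_parameters, HankelSolver, QuadratureConfig,
...                      simulate_observations, fit_diffusivity, bootstrap_ci)
>>> src, ic, tr = reference_parameters()
>>> solver = HankelSolver(src, ic, tr)
>>> solver.concentration(2.475, np.array([0., 5., 10., 20., 40., 60.]))[0].round(4)
array([0.5291, 0.9839, 1.0126, 0.6101, 0.2726, 0.2038])
```

The curve rises from 0.53 to a peak of ~1.01 around day 10 — release
from the degrading gel outpaces diffusive spreading — and then decays
toward the 0.1 baseline as the fluorophores disperse.  Curves at larger
radii peak later: the outward-propagating diffusive wave.

```python
>>> gen = HankelSolver(src, ic, tr, QuadratureConfig.fast())
>>> obs = simulate_observations(src, ic, tr,
...                             [2.475, 4.243, 6.790, 8.770, 11.170],
...                             np.arange(0., 61.), noise_rel=0.05, seed=1,
...                             solver=gen)
>>> fit = fit_diffusivity(obs, src, ic, init_D=8.64)
>>> fit.estimates
{'D': 4.33880077142244}
>>> bootstrap_ci(obs, src, ic, fit, n_boot=200, seed=1)["D"]
(0.9, 4.325, 4.386)
```

Starting from a 2× perturbed guess, the fit recovers D = 4.34 mm²/day
(truth 4.32) from curves carrying 5% multiplicative noise, with a 90%
bootstrap interval of [4.33, 4.39].

The same pipeline is available from the shell; every command writes a
provenance record (config echo, version, seed) next to its outputs:

```sh
geldiff synth    --config params.toml --out run/ --seed 7
geldiff extract  --config params.toml --out run/ --stack run/stack.tif
geldiff fit      --config params.toml --out run/ --obs run/observations.csv
geldiff validate --config params.toml --out run/
```

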