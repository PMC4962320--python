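# udsbm — underdamped scaled Brownian motion

Tools for anomalous diffusion in a bath with a power-law time-dependent
temperature: exact and asymptotic statistics, stochastic simulation,
trajectory estimators, and an event-driven cooling granular gas.

Scaled Brownian motion (SBM) — the overdamped Langevin equation with
diffusivity D(t) = D0 (1 + t/τ0)^(α−1) — is a standard model for anomalous
diffusion with MSD ⟨x²(t)⟩ ∼ t^α (and ultraslow, logarithmic growth at
α = 0).  This package implements the full *underdamped* process (UDSBM),

    m dv/dt = −m γ(t) v + m γ(t) √(2 D(t)) ξ(t),

with T(t) = T0 (1 + t/τ0)^(−2(1−α)), γ(t) = γ0 (1 + t/τ0)^(−(1−α)) and the
time-local fluctuation–dissipation relation D = T/(mγ).  The central
(and at first sight surprising) result it reproduces: for pronounced
subdiffusion the overdamped limit *fails to describe the time-averaged MSD
even at long times* — inertial corrections persist over the lag window
1/γ0 ≪ Δ ≪ t/ν (ν = τ0 γ0), and in the ultraslow limit α = 0 essentially
forever, where the time-averaged MSD becomes precisely linear in the lag
Δ while the overdamped formula keeps a logarithmic correction.  A freely
cooling granular gas (constant restitution coefficient, Haff's law
T ∝ (1 + t/τ0)^(−2)) is the physical realisation of the α = 0 case and is
included as an event-driven hard-sphere simulation.

Intended users: researchers in single-particle tracking, stochastic
thermodynamics and granular matter who need reference curves for
ensemble/time-averaged MSDs, ergodicity-breaking and ageing diagnostics,
or a clean baseline implementation of UDSBM/SBM simulation.

## Worked example

Ultraslow UDSBM with the granular-gas-like parameter set γ0 = 1, τ0 = 30,
T0 = D0 = m = 1 (ν = 30):

```python
import numpy as np
from udsbm import ModelParams, msd, tamsd, asymptotic_regimes

p = ModelParams(T0=1.0, gamma0=1.0, m=1.0, tau0=30.0, alpha=0.0)

for t in (0.01, 10.0, 1e4, 1e8):
    print(f"MSD({t:g})  udsbm = {msd(p, t, 'udsbm'):.6g}   sbm = {msd(p, t, 'sbm'):.6g}")

for lag in (1e3, 1e5):
    ud = tamsd(p, lag, 1e9, "udsbm"); od = tamsd(p, lag, 1e9, "sbm")
    print(f"TAMSD(lag={lag:g}, t=1e9)  udsbm = {ud:.6g}   sbm = {od:.6g}   ratio = {ud/od:.3f}")

rep = asymptotic_regimes(p, (1e-3, 1e8), "msd")
print(rep.crossover_times, [round(s, 3) for s in rep.slopes], rep.labels)
```

prints

```
MSD(0.01)  udsbm = 9.96674e-05   sbm = 0.0199967
MSD(10)  udsbm = 16.2214   sbm = 17.2609
MSD(10000)  udsbm = 370.942   sbm = 348.728
MSD(1e+08)  udsbm = 962.139   sbm = 901.169
TAMSD(lag=1000, t=1e9)  udsbm = 0.000245731   sbm = 0.000880793   ratio = 0.279
TAMSD(lag=100000, t=1e9)  udsbm = 0.0254132   sbm = 0.0612515   ratio = 0.415
{'1/gamma0': 1.0, 'tau0': 30.0} [1.997, 1.157, 0.094] ['ballistic', 'intermediate', 'logarithmic']
```

Reading the numbers: at t = 0.01 ≪ 1/γ0 the underdamped MSD is ballistic,
(T0/m) t² = 10⁻⁴, two orders of magnitude below the overdamped 2 D0 t
(which has no ballistic regime); by t = 10 the two nearly agree; at long
times the MSD grows logarithmically (fitted local slope 0.094) with the
underdamped curve a factor ≈ 1 + 2/ν above the overdamped one.  The
time-averaged MSD tells the stronger story: at trace length t = 10⁹ the
overdamped prediction overshoots by a factor ≈ 3.6 at lag 10³ — the
inertial correction never becomes negligible.

The same machinery is scriptable from the shell (`udsbm analytic`,
`udsbm simulate`, `udsbm simulate-gas`, `udsbm estimate`,
`udsbm compare`); every run writes a manifest with its full configuration
and seed, and `udsbm compare` exits nonzero when an empirical curve
leaves the 3-standard-error band of an analytic one.

## Simulation and the granular gas

`simulate_udsbm` / `simulate_sbm` generate trajectory ensembles with the
explicit Euler–Maruyama scheme (bit-reproducible under a fixed seed);
`estimators` turns them (or external tracking data) into MSD, TAMSD and
velocity-correlation curves with ergodicity/ageing diagnostics.
`granular` runs an event-driven hard-sphere gas in the homogeneous
cooling state, fits Haff's law, and maps the gas onto the α = 0 model
(T0, τ0 from the cooling fit, γ0 from the velocity-autocorrelation decay);
per-axis tracer moments then overlay the analytic ultraslow curves within
Monte-Carlo error.

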