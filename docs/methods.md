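# Methods

## The model

`udsbm` implements the Langevin dynamics of a particle of mass m in a bath
whose temperature decays as a power law (kB = 1):

    T(t)     = T0 (1 + t/tau0)^(-2(1-alpha)),
    gamma(t) = gamma0 (1 + t/tau0)^(-(1-alpha)),
    D(t)     = T(t) / (m gamma(t)) = D0 (1 + t/tau0)^(alpha-1),

with D0 = T0/(gamma0 m).  The damping follows the thermal velocity
(gamma ∝ sqrt(T), the Stokes/granular-gas scaling) and the diffusivity is
fixed by the time-local fluctuation–dissipation relation.  The underdamped
equation of motion is

    dv/dt = -gamma(t) v + gamma(t) sqrt(2 D(t)) xi(t),   dx/dt = v,

with white Gaussian noise xi.  Dropping inertia gives overdamped scaled
Brownian motion (SBM), dx/dt = sqrt(2 D(t)) xi.  alpha = 1 is ordinary
Brownian motion; 0 < alpha < 1 subdiffusion; alpha > 1 superdiffusion;
alpha = 0 the ultraslow limit with logarithmic MSD, realised physically by
a granular gas cooling under Haff's law T ∝ (1 + t/tau0)^-2.  The key
dimensionless parameter is the scale separation nu = tau0 * gamma0; the
local-equilibrium closure requires nu >> 1 and the package warns below
nu = 10.

The headline physics is that for pronounced subdiffusion (small alpha) the
overdamped description of the *time-averaged* MSD fails over a persistent
intermediate lag window 1/gamma0 << Delta << t/nu, and in the ultraslow
limit the failure extends over essentially the entire observable range:
the underdamped time-averaged MSD is precisely linear in the lag while the
overdamped one carries a logarithmic correction.

## Analytic machinery

All two-time statistics derive from the exact velocity correlation.  With
Gamma(t) = ∫0^t gamma(s) ds (closed form for every alpha; the alpha = 0
logarithmic branch is special-cased, never taken as a numerical limit),

    <v(t1) v(t2)> = e^{-(Gamma(t2)-Gamma(t1))} [ <v0^2> e^{-2 Gamma(t1)}
                    + ∫0^{Gamma(t1)} e^{-2w} (2 T(s_w)/m) dw ],

where Gamma(s_w) = Gamma(t1) - w.  The substitution w = Gamma(t1) -
Gamma(s) bounds every exponential by one, so the quadrature is stable from
t = 0 to t = 1e10.  Upper limits are capped at w = 80 (weights < 1e-35).

Ensemble moments are not obtained by double quadrature of the correlation
but by integrating the exactly equivalent closed moment equations for
<v^2>, <x v> and <x^2> with `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-11).  Two reparametrisations keep the system well conditioned over
ten decades:

* relative variables e = m<v^2>/T - 1 and f = <x v>/D - 1, which decay to
  O(1/nu) instead of following the many-orders-of-magnitude decay of the
  raw moments;
* the MSD deficit R(t) = <x^2>(t) - S(t), where S is the closed-form SBM
  MSD, so the inertial part of the MSD is never recovered from a
  difference of two large numbers.

The time-averaged MSD splits as delta(Delta; t) = delta0 + Xi.  The
overdamped term delta0 is the t'-average of S(t'+Delta) - S(t'); the
closed-form antiderivative expression cancels catastrophically for
Delta << t, so the increment is evaluated with expm1/log1p and averaged by
composite Gauss–Legendre quadrature (64 near-geometric panels, 10 nodes),
accurate to ~1e-9 relative.  The inertial correction is assembled
cancellation-free from exact identities,

    Xi(Delta; t) = <[R(t'+Delta) - R(t') - 2 <x v>(t') h(t', t'+Delta)]>_{t'},
    h(t1, t2)    = ∫_{t1}^{t2} e^{-(Gamma(s)-Gamma(t1))} ds,

with h by adaptive quadrature in the Gamma variable and the outer average
on 48 near-geometric Gauss–Legendre panels (7 nodes, error estimated from
a collocated 4-node rule; the computation aborts if the estimate exceeds
1% of |delta0 + Xi|).  The lag axis refuses Delta >= 0.99 t, where the
time average is dominated by its pole at Delta = t.

Verification: at alpha = 1 the pipeline reproduces the classical closed
forms (MSD 2 D0 [t - (1-e^{-gamma0 t})/gamma0], Xi =
-(2 D0/gamma0)(1-e^{-gamma0 Delta}), exact ergodicity to 1e-6 relative);
for general alpha it agrees with brute-force Riemann double sums of the
exact velocity correlation to 1e-4 and with dense-grid averages of the
windowed increment variance to machine-level accuracy.

### Sign of the inertial correction

At leading order in 1/nu the correction Xi is non-positive: inertia can
only reduce the time-averaged MSD.  The exact result is subtler: the true
velocity variance exceeds the local-equilibrium value T/m by O(1/nu) (the
bath cools while the velocity relaxes), which for alpha < 1 makes Xi
slightly *positive* (about +2 delta0/nu) at lags beyond t/nu where the
genuine inertial memory is negligible — the same correction that puts the
ultraslow underdamped MSD a factor 1 + 2/nu above its overdamped limit.
The sign property is therefore asserted on the lag window Delta <= t/nu
(for alpha < 1) where the leading-order statement binds.

## Stochastic simulation

The integrator is the explicit Euler–Maruyama scheme with coefficients at
the left endpoint,

    v_{i+1} = v_i - gamma(t_i) v_i dt + gamma(t_i) sqrt(2 D(t_i) dt) zeta_i,
    x_{i+1} = x_i + v_i dt,

the noise amplitude being fixed by requiring the stationary velocity
variance T/m in the frozen-coefficient limit.  No higher-order or implicit
variant is used: the weak O(gamma0 dt) bias of this scheme is part of what
the package quantifies.  Steps above 0.1/gamma0 are refused;
`recommend_dt` suggests min(0.01/gamma0, 0.01 tau0).  Ensembles advance in
lockstep from one seeded PCG64 generator, so runs are bit-reproducible.
Initial velocities are thermal (variance T0/m) by default — the long-time
statistics never resolve the sub-1/gamma0 transient that this choice affects —
with cold (v0 = 0) and deterministic starts available for testing.

Two finite-resolution effects matter when simulated time averages are
compared with the analytic curves at the percent level (the time-averaged
MSD self-averages, so its across-trajectory standard error is far smaller
than the MSD's):

* the stored grid discretises the window average: spacing 1/gamma0
  overestimates a cancellation-dominated ultraslow time average by ~1% at
  unit lags (verified against the exact discrete average);
* the O(gamma0 dt) scheme bias is amplified at small lags in the
  ultraslow case by the cancellation between delta0 and Xi (ratio
  |Xi|/total ~ 13 at Delta = 1/gamma0, t = 1e4).

The simulation-versus-theory comparison therefore uses dt = 0.002/gamma0
with storage spacing 0.25/gamma0 at trace length t = 1e4 and N = 1000
trajectories — sizes at which both effects sit below the Monte-Carlo band
while a full run stays under two minutes on one core.

## Estimators

The time-averaged MSD uses all overlapping windows (the Riemann sum of the
defining integral); lags must lie on the sampling grid — snapping, never
interpolation.  Uncertainty is the across-trajectory standard error; the
autocorrelated within-trajectory error of a single time average is not
modelled.  The ergodicity-breaking ratio compares the ensemble-averaged
TAMSD with the ensemble MSD at matched (lag) times, and the ageing
exponent d log TAMSD / d log t is fitted by truncating trajectories.
Local log-log slopes come from sliding least-squares windows (default half
a decade, at least five points); non-positive values are skipped with a
warning.

## Granular gas

The event-driven simulation follows the standard scheme: lazy per-particle
states, a heap of predicted pair collisions and cell-boundary crossings,
per-particle event counters for stale-event invalidation, a cell grid with
edge >= one diameter (27-cell neighbourhoods), and periodic boundaries
with unwrapped coordinates maintained alongside so tracer MSDs need no
minimum-image correction.  Collisions are smooth-sphere, equal-mass,
constant restitution epsilon: the normal relative velocity is reversed and
scaled by epsilon, tangential components untouched; momentum is conserved
to round-off and kinetic energy is non-increasing for epsilon < 1.
A velocity-dependent (viscoelastic) restitution coefficient is out of
scope; the corresponding alpha = 1/6 phenomenology is exercised through
the Langevin model instead.

Desk-scale defaults: N = 512 spheres of unit mass and radius at packing
fraction 0.05 (box edge 35), Maxwell start recentred to zero momentum and
rescaled to T0 = 1 exactly, runs to t = 2e5 ≈ 2500 tau0 (~6e4 collisions,
seconds of wall time).  No thermostat: the gas cools freely; cluster
instabilities are not handled beyond the Haff-fit quality flag (the dilute
short runs used here stay homogeneous).

The mapping onto the ultraslow Langevin model estimates T0 and tau0 by a
log-space least-squares fit of Haff's law T0 (1 + t/tau0)^-2 (records with
R^2 < 0.99 or constant temperature are flagged), and gamma0 from the decay
of the velocity autocorrelation of the tagged particles.  Because the
damping rate itself decreases during the decay, a pure exponential fit
underestimates gamma0 by several percent; the fit instead uses the
model-consistent power law C(t)/C(0) = (1 + t/tau0)^{-nu} through the
origin, giving gamma0 = nu/tau0.  For epsilon = 0.9 this yields nu ≈ 19 —
marginal but inside the validity range, and the per-axis tracer MSD (3D
moments divided by 3) then overlays the mapped analytic curve within the
Monte-Carlo band over five decades in time.  An elastic gas maps to
ordinary Brownian motion (alpha = 1).

## What the synthetic ensembles do and do not show

The Langevin ensembles and the granular gas are generated by the package
itself under exactly the model's assumptions (Gaussian white noise,
power-law protocol; hard spheres with constant restitution).  Passing
tests therefore validate the mathematics and the numerics — regime
structure, ergodicity breaking, ageing, the gas-to-model mapping — but say
nothing about whether a given experimental single-particle-tracking system
is described by scaled Brownian motion: real data carry localisation
error, drift, finite trajectories and possibly entirely different
anomalous-diffusion mechanisms (fractional Brownian motion, trapping) that
share the MSD exponent.  External trajectory tables can be ingested via
`udsbm.io.read_spt_table` for exploratory comparison, not for model
selection, which is out of scope.

## Known limitations

* Validity degrades as O(1/nu); below nu = 10 the package only warns.
* The TAMSD machinery refuses lags within 1% of the trace length rather
  than resolving the pole region.
* The event-driven gas is desk-scale (N ~ 512, ~1e5-1e6 collisions);
  no large-N performance engineering, rough/rotating spheres, or
  inhomogeneous cooling.
* No closed-form evaluation of the hypergeometric exact MSD expression and
  no Fokker–Planck (Klein–Kramers) solver: everything runs through the
  velocity-correlation/moment-equation route.
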