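# Methods

This note records the model, the numerical schemes, the parameter
conventions and the deliberate design choices behind `mprc`, at the level a
maintainer or reviewer needs to judge what the code computes and what the
tests do and do not establish.

## Model

Neurons are time-dependent renewal processes: a cell of age `r` (time since
its last spike) under total input `h(t) = I_ext(t) + I_s(t)` fires with
hazard `S(h, r)` (1/ms). In the thermodynamic limit the all-to-all network
is described by the refractory-density equation for the age density
`q(t, r)`,

    ∂t q + ∂r q = −S(h, r) q,    q(t, 0) = A(t) = ∫ S(h, r) q(t, r) dr,

with the exponential synapse `τ_s dI_s/dt = −I_s + J_s A`. Units: time in
ms, rates in 1/ms, inputs in mV entering `exp(h)` as a dimensionless
number; `J_s` in mV·ms. The Heaviside convention is `H(0) = 1`, so the
refractory hazards switch on exactly at `r = T_ref`.

Hazard families: `exp_relax` `= e^h H(r−T_ref)(1−e^{−(r−T_ref)/τ})`
(`τ = 0` degenerates to the hard threshold `e^h H(r−T_ref)`), `ramp`
`= e^h H(r−T_ref) ε (r−T_ref)`, `tanh` `= e^h H tanh(e^h(r−T_ref))`,
`tanh_cos` (the tanh form times `1 + ε cos(ωr)`, clamped at zero where the
modulation would make the rate negative, with `dS/dh = 0` on the clamped
set), the gamma-ISI family (shape `α`, rate `e^h`), and tabulated hazards.
For every family with a pure `e^h` prefactor, `dS/dh = S`; the tanh forms
add the chain-rule term through the tanh argument; the gamma hazard has the
closed derivative `dS/dh = S(α − r e^h) + r S²`.

### Hazard ↔ ISI density

`ISI = S exp(−∫₀^r S)` and the inverse quotient `S = ISI/(1 − ∫₀^r ISI)`.
The quotient is the numerically delicate object: computing the survivor
function as `1 − cumtrapz(ISI)` loses *all* relative accuracy once it falls
below the global quadrature error (~1e−6), which happens by age
`∫S ≈ 14`. We therefore evaluate it as the backward tail integral
`surv(r) = surv(r_max) + ∫_r^{r_max} ISI`, whose relative error stays
O(dr²), with the beyond-grid mass `surv(r_max)` estimated by exponential
extrapolation of the density's terminal log-slope. Below a survivor floor
(1e−8) the hazard is held at its last finite value and the truncation age
is reported. The h-derivative quotient inherits the same treatment; for the
gamma family it remains intrinsically unstable deep in the tail (the two
numerator terms cancel), which is why the tests compare it to the analytic
form only where the survivor exceeds 1e−2.

## Spiking simulator

Per step of length `dt`, each neuron's integrated hazard is the age
trapezoid `Λ = dt·(S(r) + S(r + dt))/2`; it fires with probability
`1 − e^{−Λ}`, and the within-step spike time is drawn from the conditional
(truncated-exponential) distribution by reusing the same uniform variate
(`v = u/p`), so the age carried into the next step is the true residual
age. This makes ISI statistics accurate to O(dt²); the naive
"fire-with-`1 − e^{−S dt}`, reset to age 0, spike at the bin edge" scheme
has an O(dt) mean-ISI bias (≈0.7% at `dt = 0.1` for the hard-threshold
fixture) that would dominate any comparison with the mean-field rate at
`N = 5000`. Each spike increments the shared current by `J_s/(N τ_s)` at
the step end (so it acts from the next step on — one-step bookkeeping, not
instantaneous self-interaction) and `I_s` decays by the exact factor
`e^{−dt/τ_s}`. Initial ages are Gaussian (mean `T_ref/2`, SD `T_ref/6`,
truncated at 0), matching the mean-field initialization. One
`numpy.random.Generator` drives a run; paired perturbed/unperturbed runs
share it, so zero-amplitude pulses reproduce the control exactly.

## Mean-field integration

First-order characteristics on a uniform grid with `Δr = dt`: survivors
shift one cell with factor `1 − dt·S` (clamped at 0; an `exp(−S dt)` option
exists) and the fired mass re-enters as the newborn boundary cell,

    q₀^{n+1} = A^{n+1} = Σ_j q_j^n (1 − surv_j) + q_J^n surv_J.

Two deliberate choices differ from the obvious transcription of the
continuum equations:

* **Conservative bookkeeping.** The newborn cell is exactly the mass
  removed in the step (computed from pre-shift values), and survivors that
  reach `r_max` are recycled through the boundary (they have effectively
  all fired: `r_max = 1.25·T_ref` is chosen so the survivor there is
  negligible; the recycled flux is logged on the state). The discrete
  cell-sum mass `dt·Σ q` is then conserved to machine precision for
  arbitrarily long runs. Evaluating the boundary from post-shift values
  instead (the more literal reading) leaves the measured mass oscillating
  by `dt·(A(t) − A(0))`, several 1e−3 at `dt = 0.05` for a strongly
  pulsatile cycle — a bookkeeping artifact we prefer to eliminate
  structurally. For the same reason mass and activity use the rectangle
  (finite-volume cell) sum rather than trapezoid weights; for the
  refractory hazards `S(·, 0) = 0` and `q(r_max) ≈ 0`, so the two differ
  only by negligible endpoint terms.
* **Survival clamping.** At `dt = 0.05` the reference oscillation's input
  peaks push `S dt` slightly above 1 in the deep-tail cells, which carry
  ~e⁻⁴⁰ of the mass. Clamping the survival factor at zero (those cells
  fire entirely within the step) keeps the scheme well defined there
  instead of aborting.

The scheme is first order; halving `dt` roughly halves the period error
(verified in the tests). The asynchronous steady state solves
`A_∞ ∫₀^{r_max} exp(−∫₀^r S(h_∞)) dr = 1` with `h_∞ = I_ext + J_s A_∞` by
bracketed root finding (Brent); for the hard-threshold hazard the closed
form `A_∞ = (T_ref + e^{−h_∞})⁻¹` is used directly, leaving a residual at
machine level.

**Limit cycles.** After a transient (default 800 ms; 1500 ms for
adjoint-grade cycles), the period is the mean interval between upward
crossings of `I_s` through its running mean (sub-step crossing times by
linear interpolation, averaged over the last 10 periods); an oscillation
must lift `I_s` by at least 1e−3 of the standing current scale, below which
the regime is declared asynchronous. One period is stored as
`M = round(T/dt)` snapshots resampled by linear interpolation in time,
anchored with phase 0 at a crossing, and the start/end mismatch after one
period is reported as the periodicity error.

## Linear stability

The characteristic function of the linearized operator is evaluated two
ways: the general nested-trapezoid quadrature over the steady profile
(valid for any hazard; the double integral is accumulated in one O(J) pass
via `e^{−∫_x^r} = e^{−∫_0^r} e^{+∫_0^x}`), and the `τ = 0` closed form.
Direct integration shows the two differ by the entire factor
`(e^{h_∞} + λ)`, so they share every root; the conservation law forces the
structural root `C(0) = 0` in both, which the tests verify to 1e−8 on the
quadrature route. One numerical point matters: at the hard threshold the
hazard is discontinuous at `r = T_ref`, and trapezoid rules are only first
order across a jump *unless* the jump node carries the mean of its
one-sided limits — `rate_for_quadrature` applies exactly that correction,
restoring second order.

The Hopf line `C(iω) = 0` is traced over `I_ext` by solving the two real
equations in `(J_s, ω)` (with the steady state re-solved inside the
residual, since `h_∞` depends on `J_s`), warm-starting each point from the
previous one; seeds come from a coarse scan for a sign change of the
rightmost root's real part. Root finding in the complex plane is damped
Newton on the closed form from a multi-start grid; the reported "rightmost
root" is the best found, a deliberate heuristic (no argument-principle
accounting). Frequencies below `ω_min = 1e−3` are treated as the
structural zero. Note that for the hard-threshold hazard under strong
drive the entire root family hugs the imaginary axis (spacing `2π/T_ref`,
real parts ~1e−3), so growth/decay near the boundary is genuinely slow —
visible in the long transients the simulations need there.

## Adjoint solver and normalization

Around a stored cycle `(q̄, Ī_s)` the adjoint pair `(Z_q, Z_Is)` solves

    −∂t Z_q − ∂r Z_q = −S(h̄, r) [Z_q − Z_q(t,0) − (J_s/τ_s) Z_Is]
    −dZ_Is/dt = −Z_Is/τ_s − ∫ [Z_q − Z_q(t,0) − (J_s/τ_s) Z_Is] ∂S/∂h q̄ dr,

integrated backward along characteristics over the periodic coefficients,
with the missing top-age node filled by nearest-node copy (two-point linear
extrapolation available). Backward time contracts every Floquet component
except the neutral ones, so the iteration is a power method converging to
the periodic adjoint. Two implementation points are essential:

* **Gauge fixing.** Exact mass conservation gives a second neutral adjoint
  mode, `(Z_q ≡ const, Z_Is = 0)` — it satisfies the adjoint system
  exactly, has zero normalization bracket and zero `Z_Is`. Discretely its
  multiplier sits at `1 ± O(dt)`, so without intervention the iteration
  drifts along it indefinitely. It is projected out after every backward
  period (subtracting the age-mean of `Z_q`), which pins the gauge; the
  physical content (`Z_Is`, the bracket, `Z_q` differences) is unaffected.
* **Per-pass rescaling.** The phase mode is neutral, so its amplitude
  before normalization is meaningless; each pass is rescaled to unit sup
  norm and convergence is declared when the rescaled period changes by
  less than `adjoint_tol` (1e−6) in sup norm. The default pass budget is
  500: the reference cycle's slowest stable Floquet mode decays by only
  ~6% per period, so ~300 passes are genuinely needed; the near-marginal
  `τ = 0` case takes ~1200 (run at tolerance 1e−5 in the sweep). If the
  h-coupling vanishes (`∂S/∂h ≡ 0`) the `Z_Is` equation decouples and
  the solver returns the only periodic solution, `Z_Is ≡ 0`.

Normalization rescales both components so the bracket
`∫ Z_q ∂t q̄ dr + Z_Is dĪ_s/dt` (time derivatives by centered periodic
differences) equals `2π/T`; the time-*mean* of the bracket is used, its
maximal relative deviation is reported as the quality metric (0.5% at
`dt = 0.005` for the reference cycle), and deviations beyond 10% (or a
sign change) raise. Dividing by the mean also fixes the overall sign
automatically: the bracket is the phase speed measured by `Z`, so after
normalization positive `Z_Is` means phase advance. The conserved pairing
`⟨Z, δx⟩` along a finite-difference forward perturbation drifts by ~0.06%
per period at `dt = 0.005` — the defining adjoint property, checked
directly.

`Z_Is` is the macroscopic PRC: perturbations reach the population through
the synaptic current, and a displacement `δI_s` shifts the asymptotic phase
by `Z_Is(θ) δI_s`.

## Direct PRC measurements

A square pulse (default 0.8 mV × 0.8 ms) is injected at a chosen phase and
the asymptotic timing shift read off. Conventions:

* **Route.** By default the pulse drives the synaptic equation
  (`τ_s dI_s/dt ← … + p(t)`), the pathway `Z_Is` measures; the predicted
  shift is `(aΔ/τ_s)·Z_Is`. A pulse added to `I_ext` instead measures the
  distinct combination `Z_h = Z_Is/τ_s − dZ_Is/dt` (integration by parts of
  the adjoint pairing) and is available as `route="external"`. Reported
  responses are divided by the effective charge so they are directly
  comparable to `Z_Is`.
* **Phase.** The pulse is centered on the requested phase (a finite pulse
  samples the PRC symmetrically); the pulse must be short against `T` — an
  8 ms pulse on a 10.5 ms cycle measures a phase-average, not the PRC.
* **Shift.** Mean-field: difference of late Poincaré-crossing times
  (≥5 periods after the pulse, averaged over the last 3 crossings, mapped
  to the principal branch), times `2π/T`; positive = advance. Spiking:
  paired runs with common noise, phase anchored to a post-warmup peak of
  the activity smoothed with a Gaussian kernel (σ = T/20), shift from the
  circular mean of matched peak-time differences, averaged over trials
  with SEM.

## Coupling analysis

For two identical circuits with symmetric delayed coupling `εG_s A(t−d)`
entering each other's synaptic equation, the phase lag obeys
`dθ/dt = G(θ)` with `H(θ) = (εG_s/T) ∮ Z_I(s) Ā(s−θ) ds` and
`G(θ) = H(θ−d) − H(−θ−d)`. (`H` as printed carries no `1/τ_s`; the factor
is a constant positive scale, so zero positions and stabilities — the
quantities this module predicts — are unaffected; only the absolute drift
rate would change.) `H` is a circular cross-correlation evaluated by FFT
(on the uniform periodic grid this *is* the trapezoid sum); `G` uses
periodic linear interpolation for arbitrary `d`; zeros come from sign
changes with interpolated position and slope (negative slope = stable
lag), and zeros closer than two grid steps are merged and flagged. Only
the product `εG_s` ever enters and is carried as one number.

The coupled spiking simulation implements the delayed cross-drive as
per-spike increments `εG_s/(N τ_s)` read from a delay buffer. For the
validation runs the two circuits start with a quarter-period stagger:
in-phase and anti-phase are structurally fixed points of the symmetric
system at *every* delay, and at `εG_s = 0.2` (weak against `J_s = 15`) the
escape time from an unstable one exceeds any affordable horizon, so a
start between the fixed points is what lets the `G`-dynamics express its
prediction. The empirical lag is the circular mean of matched
smoothed-activity peak differences over the last half of the run, with
circular SD.

## Parameter fixtures and problem sizes

Named fixtures carry the standard study conditions (`fig1`–`fig5`),
including the reference oscillatory circuit (`exp_relax`, `T_ref = 10` ms,
`τ = 5` ms, `I_ext = 2` mV, `J_s = 15` mV·ms, `τ_s = 10` ms, `N = 5000`,
`dt = 0.05`; `dt = 0.005` where the cycle feeds the adjoint), the
hard-threshold bifurcation setting (`T_ref = 8` ms, `τ = 0`, `dt = 0.1`),
three alternative hazard families, and the coupled pair (`G_s = 0.2`
mV·ms, delays 0.5/2.5/4.5 ms). The `fig2` asynchronous/oscillatory marker
points (`I_ext = 0.5, J_s = 2` and `I_ext = 2, J_s = 15`) are package
choices of clearly separated representatives on the two sides of the
traced boundary. The age grid is truncated at `r_max = 1.25·T_ref`
(overridable; for hazards without a refractory period, at the age where
the survivor falls below ~1e−9).

Validation runs use reduced sizes chosen for comfortable margins: coupled
networks at `N = 1000` for 5000 ms, the finite-`N` rate comparison at
`N = 5000` for 600 ms with batch-mean standard errors (10 batches — plain
per-spike SEMs ignore the autocorrelation of recurrent activity), the
threshold-softness sweep at `dt = 0.01`. The rate comparison is made at
moderate drive (`I_ext = 0.5`): close to the Hopf boundary the finite-`N`
network develops noise-sustained quasi-cycles whose rectified contribution
raises the mean rate by ~0.5% above the `N → ∞` prediction — a real
finite-size effect, not a solver error, and the reason near-marginal
operating points are unsuitable for tight mean-rate comparisons.

## What the synthetic conditions do and do not show

All validation is against the model's own stochastic network — the correct
ground truth for a mean-field theory — under homogeneous all-to-all
coupling, exponential synapses and exact renewal neurons. Passing tests
therefore demonstrate internal consistency of theory, PDE numerics and
simulation, not that any biological circuit satisfies the renewal
assumption; heterogeneity, sparse connectivity, conductance dynamics and
spike-frequency adaptation are outside the model class (the E-I
two-population adjoint and the age-voltage construction for
conductance-based models are likewise out of scope). The hazard presets
with `e^h` prefactors make input act multiplicatively on the rate;
tabulated hazards inherit that assumption unless constructed otherwise.

## Known limitations

* First-order schemes: period and adjoint inherit O(dt) bias; the
  hard-threshold (`τ = 0`) cycle concentrates each volley in a few cells,
  its normalization bracket is flat only to ~10% even at `dt = 0.005`, and
  its mPRC amplitude should be read as approximate (its *ordering* in the
  softness sweep is robust).
* The complex root search is multi-start Newton inside a finite box;
  eigenvalues far outside it are not found.
* `delay_bifurcation` classifies zeros per delay; branch continuation
  across folds is nearest-neighbor only.
* The weak-coupling prediction concerns lag positions and stability; with
  `εG_s` finite the observed lags sit within ~0.2 ms of the predicted
  zeros, and convergence toward a stable lag is slow (the `G` timescale is
  hundreds of ms), so short runs show migration, not the settled lag.
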