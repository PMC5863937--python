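# Methods

## Kinetic model and rate laws

Gating is modelled as a continuous-time Markov chain over channel
conformations. A scheme is a set of states (conducting or not), reversible
transitions, and constraints. Each voltage-dependent step moves an
effective gating charge z (elementary charges) through the membrane field;
its rates take the single-barrier Eyring form

    k_f(V) = k_f0 * exp(-z * q_f * V / V_T)
    k_b(V) = k_b0 * exp(+z * q_b * V / V_T),    q_f + q_b = 1

with V in mV and V_T = RT/F the thermal voltage. The charge partition
(q_f, q_b) is symmetric (0.5/0.5) by default: it is the canonical
one-parameter-per-step choice when the barrier position is unknown, and it
is exposed as a configurable field (`TransitionSpec.partition`,
`KineticScheme.with_partition`) precisely because equilibrium properties
are independent of it while kinetic observables — gating-current peaks in
particular — are not. The acceptance script reports the peak quantities at
partitions 0.4/0.5/0.6 for this reason. The sign convention makes
hyperpolarization accelerate forward (activating) rates, as required for
HCN channels.

V_T defaults to 25.4 mV (~22 degC, typical for excised Xenopus-oocyte
patches). It is a configurable constant; the recording temperature is not
part of the parameter tables, and a 20-25 degC spread changes V_T by ~2%.

In the two-step models the open-row steps reuse the closed-row charges z1
and z2. With voltage-independent vertical (closed-open) steps, charge
balance around the ring only forces the row *sums* to be equal; equal
per-step charges is the minimal reading and is what the shipped catalog
uses.

## Constraints

Two constraint kinds are resolved before any simulation, so they hold by
construction and are never penalty terms:

* **Microscopic reversibility** — around every cycle the product of
  clockwise zero-voltage rates must equal the counter-clockwise product,
  and the signed step charges must cancel (validated at scheme
  construction; otherwise detailed balance could not hold at all
  voltages). One designated rate per independent cycle is derived from the
  others. In the catalog models that rate is k6 (O0 -> C0): with the
  published tables this yields 29.3 s^-1 (no cAMP) and 38.0 s^-1 (cAMP).
* **Saturating open probability** — the final closed-open isomerization
  satisfies k8 = k7 (1 - P_o,sat)/P_o,sat, with P_o,sat = 0.71 / 0.99
  (without / with cAMP) taken from single-channel measurements; this gives
  k8 = 1.27 s^-1 and 4.49e-2 s^-1 respectively.

## Propagation

Occupancy row-vectors obey dp/dt = p Q(V) with Q the generator
(off-diagonal entries are rates, rows sum to zero). Protocols are
piecewise constant in voltage, so propagation within a segment is exact:
p(t) = p(0) expm(Q t), evaluated through an eigendecomposition of Q cached
per voltage (schemes have <= 15 states and protocols few voltages). If the
eigenvector basis is ill-conditioned (condition number > 1e8) the code
falls back to scaling-and-squaring matrix exponentials per step. Modal
reconstruction loses ~eps*||Q|| per unit time on stiff segments, so each
output row is renormalized to total mass 1; accuracy against an adaptive
stiff ODE oracle is ~1e-8 per state (tested at 1e-6).

Stationary distributions use Grassmann–Taksar–Heyman state elimination,
which is subtraction-free and therefore stays accurate when rates span
many decades (naive linear solves fail beyond roughly |V| > 250 mV on
these models). Reducibility is detected structurally (strong connectivity
of numerically nonzero rates) and reported as an error.

The default initial condition is the stationary distribution at the
holding potential (0 mV in the study design), and deactivation segments
continue from the end-of-activation occupancy — the double pulse is
simulated as one continuous trajectory.

## Observables

* **Probability flux density** per reversible step,
  J(t) = k_f(V) p_from - k_b(V) p_to (s^-1), activation-direction
  positive.
* **Gating current** per channel, I_g(t) = e Σ z_step J_step(t) with
  e = 1.602e-19 C; with the activation-positive sign convention ON-gating
  currents during hyperpolarizing pulses are positive. Cumulative moved
  charge is the trapezoid integral of I_g / e on the simulation grid; an
  exact oracle (the per-state "charge potential", path-independent because
  cycle charges cancel) is used in tests to bound the quadrature error.
  Fast deactivation transits (~0.1 ms) require ~20 us sampling for
  accurate OFF-charge integrals; activation integrals are accurate at
  0.1–0.2 ms.
* **Peak detection** refines the discrete maximum with a three-point
  parabola; no smoothing is applied.
* **Activation curves** report P_o at the end of a fixed-duration pulse
  from holding, or the true stationary P_o ("infinite"). The **Boltzmann
  fit** uses amplitude / (1 + exp(z (V - V_h) / V_T)), the slope-charge
  convention on which z ~ 5 for these data; amplitude is free because
  P_o,max < 1 without cAMP.

## Synthetic data

The generator emulates the study design: per condition, 9 combinations of
activation voltage and duration crossed with 3 deactivation voltages (27
protocols), holding 0 mV. The deactivation segment lasts 2 s by default
(tails at -40 mV complete within ~0.5 s; the duration is configurable and
is not itself a fitted quantity). Sampling is uniform; the default grid is
1 kHz, and analyses in the tests use 50–200 Hz to keep run times modest —
the traces are smooth on all these grids, so the choice trades statistical
information for speed, and the methods below state the grid used.

Noise emulates averaged multi-patch recordings: each of n patches (n
drawn uniformly from 5–18) contributes additive Gaussian noise with
per-point sd a + b*sqrt(P_o(1-P_o)) (a = 0.005, b = 0.03) plus a
multiplicative patch-amplitude jitter of 5% relative sd; the emitted trace
is the patch mean with its empirical s.e.m. This reproduces the 1/sqrt(n)
shrinkage of the s.e.m. band. Two features of real recordings are *not*
emulated: correlated (colored) recording noise within a patch, and any
model mismatch — so tests passing on synthetic data demonstrate the
correctness and statistical calibration of the pipeline, not that real
recordings would determine every parameter equally well.

Two caveats follow from the averaged-patch design and are the reason the
statistical tests use a simplified configuration (independent Gaussian
noise of sd 0.01 with the sd declared, one sweep per protocol): the
empirical s.e.m. of n patches makes squared weighted residuals
F(1, n-1)-distributed (mean (n-1)/(n-3), i.e. MSE* ~ 1.2 rather than 1),
and the patch jitter introduces trace-wide correlated errors that
invalidate independent-point error bars.

An ohmic current layer (I = N g (V - V_rev) P_o) and its exact inverse are
provided to round-trip between current and P_o representations; samples at
the reversal potential are masked as indeterminate.

## Global fitting

All traces are fitted simultaneously. Rates are optimized in log-space
(positivity for free), charges linearly in [0, 12]; constraint-derived
rates are recomputed from each candidate, so constraints hold exactly
throughout. Residuals are weighted by the per-point sigma (floored at
1e-3 to avoid infinite weights on noise-free synthetic points).

Reported goodness of fit: RSS, the unweighted residual sum of squares over
all traces, and MSE*, defined here as (1/N) Σ (r_i/sigma_i)^2 — a
normalized mean square error that is ~1 for a correct model with honest
sigmas. Parameter standard errors are asymptotic: cov = (J^T J)^{-1} s^2
with J the central-difference Jacobian of the weighted residuals at the
optimum and s^2 the reduced chi-square; se is reported as percent of the
value (for log-fitted rates, 100 * se of ln k). Both formulas are isolated
behind single functions so alternative definitions can be swapped in.
A parameter with se > 60% is flagged "not determined" (n.d.). Near-singular
curvature directions get infinite variance via eigenvalue truncation and
surface as n.d. rather than as errors.

The optimizer is multistart (default 32 seeded starts; start 0 is the
user-supplied init) trust-region least squares. Single trust-region runs
stall in the long curved valleys typical of multi-exponential global fits,
so each start is *polished*: the solver is restarted from its own solution
until the cost stops improving (relative 1e-9), with 3-point difference
Jacobians. Fits are bit-reproducible for a fixed seed and tolerance set.
The bounded solver's internally scaled Jacobian is not used for errors
(its Coleman–Li scaling biases the covariance); errors always come from
the unscaled finite-difference Jacobian.

Identifiability in the two-step models deserves a note: the open-row
activation rates (k9, k11) and the direct opening rate (k5) influence the
data almost exclusively through the microscopic-reversibility product that
fixes the derived deactivation rate k6. Their product is well determined;
individually they are sloppy, and their marginal errors vary strongly
along the flat manifold. On rich synthetic data the curvature-based se at
truth-adjacent optima can come out as low as ~10–20% for k9/k11, whereas
sparser or noisier (real) recordings leave them undetermined; see the
ledger of design decisions for the resulting test outcome.

Model ranking tabulates model name, constraint flags (st/ze/f), total
gating charge sumz (the range of the per-state charge potential, which
equals z1+z2 for the catalog models and excludes the dead-end buffer
charge), free-parameter and n.d. counts, RSS and MSE*, sorted by MSE* with
ties broken by fewer free parameters, then fewer n.d. parameters. Rankings
across different trace sets are refused.

## Problem sizes used by the test suite and acceptance script

* Oracle/property tests: full catalog models, protocols of 1–20 s at
  1 kHz; stiff-ODE comparisons at rtol 1e-10.
* Saturating-charge computations: 60 s at -160 mV, 0.2 ms sampling
  (300k samples); peak currents: 5 s at -140 mV, 0.1 ms sampling.
* Recovery experiment: 10 seeds x 27 traces at 200 Hz (~35k residuals,
  12 free parameters), single polished start perturbed +-30% (rates) /
  +-5% (charges) from the generating values.

## Known limitations

* Single-barrier rate law with a fixed partition; multi-barrier or
  voltage-dependent-field effects are out of scope, and absolute
  gating-current peaks inherit the partition assumption (hence the
  reported sensitivity sweep).
* No stochastic single-channel simulation, no mode-shift states, no
  temperature dependence.
* Asymptotic (curvature) errors understate uncertainty for parameters on
  sloppy manifolds; profile or bootstrap methods would be the upgrade
  path (a parametric-bootstrap cross-check on a toy problem is part of
  the test suite).
* The model-competition tables of the original analysis are not
  reproducible without the experimental recordings; ranking is exercised
  on synthetic data only.
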