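# Methods

## Model

Each circuit couples a two-step cyclic enzymatic upstream system to zero or
more reversible downstream binding sites:

    I + E  <=>[k0+, k0-]  M  -->[c1]  E + Z,      Z -->[c2] I
    Z + Dj <=>[k3j+, k3j-] Cj                      (j = 1..N)

All reactions are mass action; bimolecular propensities in molecule counts
carry a 1/Ω volume factor, and the volume-scaled dissociation constants are
k0 = k0−·Ω/k0+ and k3j = k3j−·Ω/k3j+. Rates are time-invariant and every
question is asked at steady state, which isolates the retroactive load from
transient and intersymbol effects. Five topologies are built from these
pieces (isolated SISO; SISO broadcasting to N sites; two branches sharing
one enzyme pool, isolated or with branch 1 loaded; and two independent
SISO systems sharing the site pool, Q sites bound to branch 1). The second
branch is a replica of the first — same rate symbols — though a distinct
rate set can be supplied. Spatial transport, intersymbol interference, and
time-varying rates are out of scope by design.

Conservation laws (total enzyme, total input per branch, total per site)
are emitted with each model and checked exactly: every law annihilates
every reaction's net stoichiometry in integer arithmetic. In the
multiple-access topology a site's law spans the site and whichever complex
it can hold, which structurally enforces one-complex-at-a-time occupancy.

## Low-count regime: stationary CME and the Z-channel

The binary alphabet is concentration on-off keying: symbol i ∈ {0, 1} sets
the input total at t0 (Itot = i, with no output or complexes present
before transmission). With unit enzyme and site totals the conservation
class is tiny (3 states for the isolated circuit, 8 for the shared-enzyme
pair, N+3 for the broadcast circuit), so the state space is enumerated
exactly by depth-first assignment with residual pruning, ordered
lexicographically for determinism, with a configurable cap (default 2·10⁵
states) guarding accidental large totals.

The CTMC generator is dense; the stationary law solves πᵀQ = 0 with one
balance row replaced by normalization, restricted to the closed
communicating class reachable from the t0 state (found via graph
condensation). That restriction matters twice: the zero symbol spans a
single empty state, and non-cyclic circuits (c2 = 0) are absorbing. If
several closed classes are reachable the solver reports rather than
guesses. Residual tolerance: ‖πᵀQ‖∞ < 1e-10.

Because the zero symbol's class contains no output, P(Z1 ≥ 1 | i1 = 0) = 0
exactly, and the channel from I1(t0) to 1{Z1(ts) ≥ 1} is a Z-channel with
erasure probability A = P(Z1(ts) = 0 | i1 = 1). For two-input topologies A
is the prior mixture over the second symbol, which is exactly the affine
structure of the closed-form mixtures A0,MIMO = A0·P02 + B·P12 and
AN,MIMO = AN·P02 + G·P12; the per-branch conditionals are exposed so B and
G can be read off the CME directly. Mutual information is always computed
from the joint pmf as H(X) − H(X|Y) with 0·log 0 := 0, in nats (a bits
toggle exists on capacity utilities). The printed algebraic expansion of
the MI formula is kept only as a transcription cross-check against the
joint computation, which is the canonical definition.

## Closed-form constants and their regime

The closed forms A0 = (1+k0)c2/(c1+(1+k0)c2),
AN = 1 − c1/[(1+k0)c2 + (1+Σ1/k3j)c1], their c2 = 0 and MAC (Q-term)
variants, and the cross-branch constant B (equal catalytic rates, fast
binding) are implemented as stated. The parse of each fraction is pinned by
four exact limits that any alternative parse breaks: A0(c2=0) = 0;
A0, AN → 1 as c2 → ∞; AN(N=0) = A0; AN → 1 as N → ∞ with equal k3. Limits
are evaluated both symbolically (sympy) and at large finite surrogates
(N = 10⁶ sites; c2 = 10⁹ × the other rates), both asserted.

Numerical evidence places these forms in the fast-binding regime
k0± ≫ c1, c2: the exact CME value at unit rates is A = 3/4 against
A0 = 2/3, and the discrepancy falls as 1/scale along the ladder
k0± ∈ {10, 100, 1000}·c (below 1e-3 at the top rung, for A0, AN and B
alike). The constants are therefore treated as fast-binding asymptotics;
`b_const` warns (RegimeWarning) when evaluated below min(k0+, k0−) ≥ 100·c,
a configurable threshold. G has no closed form and is extracted from the
CME as P(Z1=0 | i1=1, i2=1) in the loaded two-branch circuit, cached per
parameter set. Whether a second branch mitigates the load reduces to the
sign of G − AN: both signs occur (the equal-dissociation ladder fixture is
a G < AN point; the sampled fast-binding draws all give G ≥ AN), and the
mitigation experiment reports the classification per draw.

## High-count regime: LNA

With a single upstream system the circuit is reduced to the one-step cyclic
reaction I + E → E + Z, Z → I. Its steady-state output mean is
μ0 = c1·E·Itot/(c2 + c1·E) and the stationary variance, from the scalar
Lyapunov equation, σ0² = c1·E·Itot·c2 / (Ω(c1·E + c2)²) — exactly 1/Ω
scaling, reproduced by the generic Lyapunov solver to machine precision.

With N identical sites, each complex sits at quasi-equilibrium
Cj = Z·Dtot/(k3 + Z), at which the binding and unbinding fluxes cancel
identically in the output equation. The default mean solver therefore
treats the input pool as unsequestered by the sites, and the fixed point is
exactly μN = μ0: in the high-count limit, where site concentrations
Dtot/Ω are vanishingly small against the input pool, the load leaves the
mean untouched and acts only on fluctuations. For finite-site studies the
`account_sequestration=True` option keeps I = Itot − Z − ΣCj in the
production term, and the free-output mean then drops below μ0 by up to
N·Dtot — the two options bracket the physical cases, and the default is
the one consistent with the LNA's own validity regime.

Two-branch steady states solve the four coupled rate equations (with
conservation substitutions and, when loaded, the quasi-equilibrium
complexes) by bounded least squares from the interior point at half the
totals, accepting only residuals below 1e-10 (relative); symmetric inputs
give symmetric outputs, and Itot2 = 0 recovers the two-step single-branch
balance.

Covariances for circuits without closed forms are computed numerically:
the Jacobian analytically from the rate equations, the diffusion matrix
from steady-state reaction fluxes scaled by 1/Ω, and the stationary
covariance from `scipy.linalg.solve_continuous_lyapunov` after a Hurwitz
check (non-stable fixed points are reported, not averaged). Channel
capacity uses the stationary variance of Z1 as signal power against unit
Gaussian noise, ½·ln(1 + σ²); the signal-variance convention is
configurable. An exploratory sweep records the sign of σ0² − σN² across
random draws (all positive in the shipped tests — the load shrinks the
output variance there); this is reported as an observation, not asserted
as a general law.

## Stochastic oracle

The Gillespie direct method (waiting time drawn first, then the reaction
index — fixed order, so seeds are portable) validates the stationary
solver: the time-averaged occupancy of one long trajectory after a 10%
burn-in is compared state by state against the stationary pmf within three
batch-means standard errors (20 batches). A single long trajectory is used
rather than many endpoint samples because the restricted chain is ergodic
on its closed class and time averaging estimates the same law at a fraction
of the cost. Trajectory lengths in the shipped tests (4·10³–1.2·10⁴ time
units at order-one propensities) were chosen so the batch-means error sits
well below the discriminating differences while the suite stays fast.

## Synthetic parameter generation

Draws are log-uniform over [1e-2, 1e2] per rate (the limiting claims span
ratios over orders of magnitude), with regimes layered on top:
fast-binding draws set binding rates at 10²–10³·⁵ times the largest
catalytic rate; non-cyclic draws set c2 = 0; large-recycling draws set
c2/c1 ∈ [1e6, 1e9]. Regime constraints are re-validated on every draw.
Ω defaults to 1 in count-regime fixtures and is swept over {1, 10, 100}
for the 1/Ω-scaling checks. The generator emulates rate-constant diversity
only — there is no measurement noise or experimental data format to
emulate — so passing tests certify the mathematical pipeline under
mass-action assumptions, not agreement with any wet-lab measurement.

## Numerical choices

- Stationary solve: dense LU with a normalization row; tolerance 1e-10.
- Root finding: Brent on the conservation interval [0, Itot], xtol 1e-12;
  vector solves by bounded least squares with tolerance at machine scale.
- Capacity: closed form ln(1 + (1−A)·A^{A/(1−A)}), cross-checked against
  Blahut–Arimoto (tolerance 1e-12, monotone bound gap) and against the
  maximum of the MI over the prior (bounded scalar optimization,
  xatol 1e-12).
- Dual upper bound: max-over-inputs KL against a swept output distribution;
  its minimum over the sweep touches capacity only to first order in the
  grid spacing (the max of two crossing KLs has a kink), which sets the
  grid-resolution tolerances used in the bound-surface checks.
- Entropy conventions: 0·log 0 := 0; pmfs validated to 1e-8 mass.

## Known limitations

- The closed-form constants are asymptotic in binding speed; no attempt is
  made to characterize their error outside the fast-binding regime beyond
  the warning threshold.
- Only the five supported topologies are validated surfaces, although the
  enumeration/generator machinery is generic.
- Time-dependent (transient) solutions, moment closures, spatial effects,
  and alphabets beyond binary on-off keying are not implemented.
- The LNA layer trusts the Hurwitz check as its only stability diagnostic;
  it does not assess the quality of the Gaussian approximation itself.
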