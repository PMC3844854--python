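# Methods

## The model

`pallidalnet` simulates a population of rodent globus pallidus (GP)
neurons — tonically active, mutually inhibitory pacemakers — driven by
rhythmic excitation from subthalamic nucleus (STN) units whose firing is
modulated by cortical slow-wave activity (SWA, ~0.8 Hz).  Under
"Parkinsonian" parameters (stronger STN bursting, doubled STN→GP and
GP→GP conductances) the population self-organizes into two anti-phase
oscillatory groups: TA neurons firing with the active SWA phase and TI
neurons firing in the inactive phase.

### GP neurons

Each GP neuron is a single compartment with a leak and ten
voltage-gated channels (NaF, NaP, Kv2, Kv3, Kv4 fast/slow, KCNQ, HVA
calcium, HCN fast/slow):

C dV/dt = g_leak (E_leak − V) + Σ_X m^μ h^ρ s^φ g_X (E_X − V) + I_syn + I_ext

with C = 141.6 pF, g_leak = 4.012 nS, E_leak = −60 mV, the tabulated
maximal conductances (NaF 5900, NaP 17.7, each Kv 590, KCNQ 1.77,
HVA 1.77, each HCN 177 nS) and ionic reversals E_K = −80, E_Na = +55,
E_Ca = +120, E_HCN = −30 mV.  Gating-molecule counts (μ, ρ, φ) follow
the standard stoichiometry table (e.g. NaF m³hs, Kv m⁴h, KCNQ m⁴, HVA
and HCN first-order).  SK channels are deliberately excluded.

Population heterogeneity applies Gaussian noise to g_NaP (50% CV) and
both HCN conductances (30% CV), truncated at zero; truncation is
required because conductances cannot be negative, and the near-zero
NaP tail is exactly the sub-population that ends up quiet.

Intracellular calcium is a dimensionless activity sensor driven by the
HVA current, d[Ca]/dt = ε(I_HVA − k_Ca [Ca]) with ε = 1e−4 and
k_Ca = 15 (≈ 670 ms relaxation time).

### Gate kinetics are calibration data, not code

The gate equations use Boltzmann steady states
x∞(V) = 1/(1 + exp((V_half − V)/k)) and sigmoidal voltage-dependent
time constants τ(V) = τ_min + (τ_max − τ_min)/(1 + exp((V − V_τ)/k_τ)).
The parameter set ships in `src/pallidalnet/data/gate_kinetics.yaml`;
any structurally compatible file can be supplied instead
(`kinetics_path` arguments / config).

The shipped values were seeded from published rodent GPe-neuron
kinetics and then calibrated against four jointly-constrained surfaces:

1. isolated pacemaking: ~95% of a heterogeneous population fires
   tonically, population mean ≈ 23 Hz (s.d. ≈ 4 Hz), rates up to
   ~200 Hz under depolarizing current, sag and rebound under
   hyperpolarization that disappear when HCN is zeroed;
2. HCN blockade: zeroing both HCN conductances slows pacemaking to
   ≈ 15 Hz;
3. graded inhibition response: under tonic GABAergic conductance the
   mean neuron slows smoothly (≈ 24 → 15 Hz over 0–5 nS) rather than
   switching off, which the network's phase-competition dynamics
   require;
4. calcium: tonic firing at ≈ 20 Hz keeps [Ca] below the
   downregulation threshold, so only the fastest-firing neurons engage
   the plasticity rule under healthy conditions.

The HCN_fast gate uses a strongly asymmetric time constant (slow
activation at hyperpolarized voltages, fast deactivation above
≈ −60 mV).  This makes the channel an activity sensor: a neuron held
hyperpolarized by sustained inhibition slowly recruits HCN and escapes,
while a regularly spiking neuron sheds the conductance on every spike.

**Known limitation.**  One monotone HCN activation curve cannot
simultaneously (a) rescue low-NaP neurons at rest (which would separate
the intact pacemaking threshold from the HCN-zeroed one and reproduce a
~12% silent fraction after HCN blockade) and (b) remain quiet over the
pacemaking trajectory, whose afterhyperpolarization reaches ≈ −79 mV,
well below rest.  The shipped calibration prioritizes surfaces 1–3;
its HCN-zeroed silent fraction is ~5% rather than ~12%, and its network
firing rates run ~1.5× the reference values, which in turn weakens the
calcium separation between healthy tonic firing and Parkinsonian
bursting (see *Downregulation* below).  A user holding the original
multicompartment-derived kinetics can drop them into the YAML file.

### HCN downregulation

When [Ca] exceeds T_HCN = 0.2, both HCN maximal conductances are
decremented between 1 ms integration control steps:

g(t+Δt) = max(0, g(t) − k_HCN·Δt / (1 + exp((θ − [Ca])/σ)))

with θ = 0.5, σ = 0.1 and k_HCN = 6e−4 µS/ms (0.6 nS/ms; on the µS
scale of the conductance table — on a nS reading the rule could remove
at most 4 nS of 354 nS in 6.5 s and would be inert).  The rule is
applied between integration steps, never inside the right-hand side,
and only ever decreases conductance.  With the shipped calibration the
rule engages weakly in network simulations (its unit behavior is fully
tested; the population-level consequence — a post-downregulation
intrinsic rate near 17 Hz — is not reproduced, because the calcium
signal cannot separate our healthy tonic firing from Parkinsonian
bursting without violating healthy-condition quiescence).

### STN spike trains

STN units are not conductance-based.  Each unit is an enhanced leaky
integrate-and-fire generator (membrane accumulation τ = 10 ms, Gaussian
noise, adaptive threshold with 20 ms decay, 2 ms absolute refractory
period).  Two stationary generators per unit — slow-irregular and
fast-irregular — run continuously and the output train samples
whichever matches the current SWA phase, so phase-windowed rates match
their targets without boundary transients; splice-point refractory
violations are removed.  Per-phase drive is calibrated by bisection to
the target rates (0.5 Hz inactive; 30 Hz active healthy, 60 Hz
Parkinsonian); the shipped drive table realizes them within ~2%.

SWA geometry: 1300 ms period = 500 ms active + 800 ms inactive; the
beta variant uses 70 ms = 30 ms active + 40 ms inactive.  Phase 0 is
anchored at active-phase onset and advances linearly, so the active
phase occupies [0, 2π·500/1300).  This convention is shared by the
generator and the analysis module; it fixes the TA/TI decision rule.

### Synapses

Conductance synapses carry an opening/closing pair with
do/dt = −o/τ_o, dc/dt = −c/τ_c, both incremented by 1 at each
presynaptic spike; I_syn = (c − o)·g_syn·(e_rev − V).  GP→GP: τ_o 5 ms,
τ_c 40 ms, e_rev −80 mV, mean unitary conductance 0.5 nS (healthy) or
1.0 nS (Parkinsonian), 3.0 nS in the high-inhibition beta variant;
STN→GP: τ_o 0.2 ms, τ_c 60 ms, 0.1/0.2 nS.  The AMPA reversal is not
specified by the source data; we use the standard glutamatergic 0 mV.
Unitary conductances are drawn per synapse (Gaussian, 30% CV, truncated
at zero).  Because the subsystem is linear, synapses sharing a
postsynaptic target and time constants are aggregated into one
conductance-weighted (o, c) pair per neuron and kind, advanced by exact
exponentials — equivalent to per-synapse states but O(n) per step.

The unitary GP→GP conductance was validated by the IPSP protocol: a
mean-parameter neuron held near −65 mV by injected current shows a
≈ 0.55 mV peak deflection for a single 0.5 nS inhibitory spike.

### Network

100 GP neurons (default), each inhibiting 20 distinct random targets
(no self-connections); 50 STN units, each exciting 2 random GP neurons.
Scaling presets (200 GP/100 STN, 300/150) keep fan-outs constant.
The Parkinsonian condition changes exactly three parameters: STN
active-phase rate 30→60 Hz, g_SG 0.1→0.2 nS, g_GG 0.5→1.0 nS.

### Numerics

All state equations are linear in their own variable given the others,
so every variable advances by its locally exact exponential update
(exponential Euler) at a fixed dt = 0.05 ms: gates relax toward
x∞(V(t)), the membrane toward its instantaneous equilibrium
(Σ gE + I)/(Σ g), calcium toward I_HVA/k_Ca, and synaptic variables
decay exactly.  The scheme is unconditionally stable, exact for the
passive membrane (the leak-only analytic-solution test passes at
1e−6 mV), and pacemaking rates change <2% under dt halving (tested).
Spikes are positive-going 0 mV crossings timed by linear interpolation
between steps; presynaptic increments land at the next step boundary
(≤ 0.05 ms delay).  STN spike events are pre-binned to integration
steps.  Membrane potentials outside [−120, +70] mV raise a diagnostic
with the neuron id and time.  Initial conditions: V = E_leak with gates
at steady state and calcium at its fixed point; the first 500 ms are
excluded from isolated-rate statistics, and network statistics use the
latter half of each run.

Randomness: every stream (population heterogeneity, wiring, unitary
conductances, STN noise) derives from the master seed through named
sub-seeds recorded in the result, so runs are bit-reproducible from
their config echo.

## Analysis

Each neuron's spikes map to unit phasors exp(iθ(s)); the resultant ω
gives the mean phase and the confidence c = |ω|/n.  Labels: QU if the
neuron fires fewer than one spike per SWA cycle in the analysis window
(latter half of the run); otherwise NM if c < 0.1; otherwise TA or TI
by whether the mean phase falls in the active or inactive phase range.
Firing rate is count/window; the ISI coefficient of variation uses the
n−1 sample standard deviation and is reported as NaN (never zero) below
three spikes.

Correlograms use the Brillinger normalization X' = T·X/(2h·N_A·N_B)
(h = half bin width), which is 1 in expectation for independent
stationary trains; the 95% band is 1 ± 1.96/√E[X] from the Poisson
approximation of bin counts.  Auto-correlograms exclude zero-lag
self-pairs.  The STN independence check runs the short-lag correlogram
on active-phase-concatenated time (within-burst firing of two units is
uncorrelated) and the long-lag correlogram on raw time, where the
shared slow-wave envelope appears as a 1300 ms oscillation.  The beta
variant is analysed through STN–GP cross-correlograms rather than phase
labels, because GP neurons fire too few spikes per 70 ms cycle for the
confidence measure to be meaningful.

## What the synthetic data do and do not show

All inputs are generated: there is no recorded data in the pipeline.
The STN generator reproduces phase-windowed rates, refractoriness and
pairwise independence, but not spike-train structure beyond that (no
intra-burst patterning, no unit-to-unit rate heterogeneity).  Passing
network tests therefore demonstrate that the *mechanism* — competition
through inhibitory collaterals under rhythmic drive — produces
anti-phase groups under the stated parameter changes; they do not
validate the model against physiological recordings beyond the summary
statistics quoted above.

## Problem sizes

Default problem sizes were chosen to characterize each quantity at
desk scale: 500 neurons × 3 s for isolated-population statistics,
4 network trials × 13 s per condition for battery statistics (the
reference protocol runs 12), and 50 units × 13 s for STN rate checks.
The trial-battery summaries report mean ± s.d. across trials.
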