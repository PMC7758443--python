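# Methods

## Scope and model structure

`mecsim` simulates strongly coupled cardiac electromechanics in one spatial
dimension. A myocyte is a chain of *N* calcium-release units (CRUs, default
50), each pairing one ionic membrane/calcium compartment set with one
sarcomere. Adjacent CRUs exchange calcium compartment-by-compartment,
membrane potential through a fast resistive coupling, and mechanical state
through an inter-sarcomere operator. Myocytes chain end-to-end through ohmic
gap junctions; fibroblasts attach electrically to terminal CRUs. Prescribed
stretch protocols and an extracellular-calcium (Ca_o) sweep probe the
threshold for spontaneous calcium release, propagating calcium waves and
delayed after-depolarizations (DADs).

All cell models are authored in this package as compact mechanistic
formulations with the current and flux structure of the standard rabbit
ventricular, myofilament and active-fibroblast model families; parameter
values are stated in the dataclasses (`IonicParams`, `MyofilamentParams`,
`StrainCouplingParams`, `FibroblastParams`) and every deviation from a
standard value is visible there.

## Ionic CRU model

Membrane currents: fast Na+ (Hodgkin–Huxley m³hj), L-type Ca2+ with a GHK
driving force (so Ca_o enters the loading pathway directly) and both
voltage- and calcium-dependent inactivation, transient outward K+, rapid and
slow delayed rectifiers, inward rectifier, Na/K pump, Na/Ca exchanger (NCX)
with allosteric calcium activation, background Na+/Ca2+ and a sarcolemmal
calcium pump. Intracellular K+ is fixed (135 mM); Na+ is dynamic. The NCX,
background and pump calcium fluxes act on the bulk cytosol; only ICaL feeds
the subsarcolemmal (SS) release space.

Calcium handling uses three compartments per CRU — SS (0.66 pL whole-cell
equivalent), junctional SR (1.16 pL) and bulk cytosol (21.45 pL) — with
rapid-equilibrium buffering (calmodulin/myosin-class sites in the cytosol,
a sarcolemmal site in SS, calsequestrin in the SR). Troponin C is *not*
buffered here: the mechanics model owns it and returns its net calcium flux
(strong coupling), which replaces the ionic model's TnC term.

### SR release and the overload instability

Release is `J_rel = k_rel · w · h(Ca_SS; Ca_SR) · (Ca_SR − Ca_SS)` with

* `h` — a steep Hill function (exponent 6) of SS calcium whose half-point
  `K_rel_ca / f_lum(Ca_SR)` falls as the SR loads (luminal sensitization,
  amplitude 12, half-point 1.2 mM, exponent 6). This makes calcium-induced
  calcium release regenerative during the ICaL trigger and makes the
  *diastolic* state lose stability once the SR is overloaded — the substrate
  for spontaneous release, waves and DADs.
* `w` — a luminal deactivation gate with a hard hysteresis band: it closes
  (τ = 5 ms) when the SR depletes below 0.40 mM, reopens (τ = 300 ms) only
  once the store has refilled past 0.45 mM *and* the SS has cooled below
  1.5 µM, and drifts closed in between. The band is essential: with any
  smooth equilibrium gate the system finds a sliding state in which a small
  standing release is recirculated indefinitely by SERCA, and release never
  terminates. The hysteresis makes every release episodic (all-or-none dump,
  refractory refill, quiescence) — the deterministic analogue of spark
  termination by local SR depletion.

SERCA uses a reversible Hill form (forward half-point 0.246 µM, reverse
1.2 mM, exponent 2.2); its equilibrium makes the SR load track diastolic
calcium, which in turn rises with Ca_o through the GHK/NCX balance. That is
the whole overload mechanism: raising Ca_o from 2.0 toward 4.5 mM raises
diastolic calcium, the SR equilibrium load crosses the luminal-sensitization
threshold, and spontaneous release appears. With the default parameters the
single-cell threshold sits near Ca_o ≈ 3.8–4.0 mM and nothing fires at
2.0 mM, consistent with the 3.7–4.3 mM window this class of experiment
reports.

## Sarcomere mechanics and mechano-electric coupling

A mean-field sarcomere: one TnC occupancy pool gates cooperative
(exponent 3) crossbridge attachment; force is attached fraction times a
hat-shaped filament-overlap function of sarcomere length (SL); length tracks
the protocol's commanded SL with a 4 ms constant (the protocols are
length-controlled; isometric means constant command). Attached crossbridges
halve the TnC off-rate (thin-filament cooperativity).

The mechano-electric coupling is an exponential strain-rate dependence of
TnC dissociation, `koff = koff0 · exp(alpha_off · dSL/dt / SL_rest)`, with
`alpha_off = 1500 ms` and the same form (constant 500 ms) on crossbridge
detachment; the on-rate is left unmodulated by default (`alpha_on = 0`).
The alphas are a calibration, not literature values: they were chosen so
that a 10% stretch applied over 100 ms (strain rate 1e-3/ms, off-rate
factor e^1.5 ≈ 4.5) sheds enough TnC calcium to raise diastolic cytosolic
calcium by more than 5%. Because exp is convex, cyclic strain raises the
*mean* off-rate, and the phase of stretch relative to the calcium transient
decides how much calcium moves from TnC into the SERCA/NCX competition —
this is what differentiates the stretch patterns.

## Stretch protocols

Four length-command waveforms (multipliers of per-sarcomere resting length),
periodic with the pacing cycle: H — isotonic-shortening sinusoid to 20%
compression; I — isometric (constant 1); S — sinusoid, 10% stretch in
systole / 10% compression in diastole; P — systolic lengthening: exponential
rise (τ = 60 ms, spanning the calcium transient) to a 15% plateau, held to
35% of the cycle, exponential decay (τ = 40 ms). P's rise constant and
offset are package choices (the waveform timing is otherwise unspecified);
the rise was set to cover the transient so that the off-rate enhancement
acts while TnC is loaded.

## Spatial couplings

* Calcium: nearest-neighbour exchange per compartment with
  τ_SS = 0.4533 ms, τ_SR = 150 ms, τ_cyto = 1.2 ms (zero-sum chain
  Laplacian, single-neighbour ends).
* Voltage: the same stencil divided by τ_Vm = 1e-5 ms — effectively
  isopotential within a myocyte — plus a 1000 mV/ms, 3 ms stimulus into
  CRU 1 (its charge spreads over all 50 CRUs, ≈ 60 mV of whole-fiber
  depolarization; scaled fibers in the test suite scale the amplitude
  accordingly).
* Gap junctions: `I = g_gap (V_up − V_down)` (400 nS) between terminal CRUs
  of adjacent myocytes, divided by per-CRU capacitance, charge-conserving
  orientation. The anti-conservative sign-flipped variant is available as an
  audit flag and demonstrably diverges.
* Mechanics: by default the "relaxed" neighbour-averaging operator
  `own + κ(neighbour mean − own)` (κ = 0.5). The "verbatim" alternative
  (2·own − neighbours inside a cell) annihilates the uniform component of
  commanded motion — under it no stretch protocol changes any sarcomere
  length — and its single-weighted inter-myocyte boundary form has a positive row
  sum and is linearly unstable; both facts drove the default. At junctions
  the interior-like zero-sum form is used.

## Heterogeneity and fibroblasts

Per-sarcomere resting lengths are i.i.d. uniform on [1.701, 2.079] µm
(mean 1.89 µm ± 10%), reproducible per seed. Fibroblasts (5-state active
membrane model: V_f, two I_Kv gates, Na+, K+; I_Kv, inward rectifier, Na/K
pump, background Na+; rest ≈ −50 mV) attach to one of the terminal five
CRUs of either end with junction conductance uniform on [0.5, 8.0] nS.
No calcium crosses the myocyte–fibroblast junction.

## Remodeled parameter set

`apply_remodeling` scales I_to ×1.30, I_Ks ×0.85, I_K1 ×0.70, Na/K pump
×1.15, once, with a provenance flag. The multi-cell and fibroblast
experiments use the remodeled set; the single-cell Ca_o × pattern sweep uses
the unremodeled set, where the scaled-down (15-beat) thresholds are stable —
with remodeling the extra excitability makes short-protocol thresholds
erratic, a scaled-run artifact documented here rather than hidden.

## Numerics

Two integration surfaces share one set of equations (asserted equivalent in
the tests):

* an adaptive stiff path — `TissueModel.rhs` for scipy's LSODA/BDF, used
  for 0D cell runs and oracle comparisons;
* the production fixed-step operator-splitting scheme (`dt = 0.02 ms`):
  Rush–Larsen exponential updates for all inf/τ gates; explicit updates for
  Na+, cytosolic calcium and mechanics; *semi-implicit exponential* updates
  for SS and SR calcium (an open release channel couples them far faster
  than any usable step, but both balances are linear in their own
  concentration once gates are frozen); and an implicit tridiagonal solve
  for the voltage coupling (τ_Vm = 1e-5 ms is explicit-unstable at any
  usable step; gap-junction entries are inside the same operator). A numba
  kernel implements the identical scheme ~70× faster than the numpy
  stepper; both are validated against each other to 1e-6 over a short
  horizon (trajectory sensitivity amplifies last-bit rounding ~1e4 per
  20 ms through an upstroke, so long-horizon pointwise comparison is not
  meaningful) and against LSODA on the assembled system.

Degenerate inputs: non-finite states abort the run with the offending
variable named and the partial result preserved; gates are clipped to
[0, 1]; concentrations floored at 1e-8 mM; sarcomere lengths outside
[1.4, 2.4] µm log a warning and clamp the overlap function.

## Scaled study conditions

The desk-scale suite and the acceptance script run 10-CRU myocytes, 15
beats at 1 Hz and a 6 s observation window on a coarse Ca_o grid
(2.0, 3.4–4.2 mM), with heterogeneity from a single seed; the full protocol
(50 CRUs, up to 200 beats to the MSE < 0.01 limit cycle, 26-step sweep, 10
replicates) is reachable through the `mecsim sweep` CLI. At 10 CRUs a
spontaneous release activates the whole fiber within a millisecond, so
events are classified "synchronous" and carry no finite wave velocity;
velocity measurement needs the 50-CRU geometry.

## What the scaled tests show — and what they do not

Green at desk scale: quiescence at Ca_o = 2.0 mM under every pattern;
finite wave thresholds for every pattern inside the overload window with
ordering P ≤ S ≤ I ≤ H (systolic stretch most, isotonic shortening least
susceptible); monotone APD90 shortening and wave-amplitude reduction by
coupled fibroblasts; DAD-magnitude reduction by gap-junction coupling.

Known limitations: (1) coupled spontaneous events remain subthreshold at
the accessible operating points — the junctional drain that damps DADs also
prevents the conducted triggered beat that would align event timing across
cells, and in a deterministic model isolated replicate cells are already
nearly synchronous, so the event-synchronization comparison does not come
out in the expected direction (the corresponding acceptance test is left
failing by design); (2) the deterministic common-pool release cannot
produce waves that activate only part of a myocyte; (3) single-seed, 15-beat
thresholds carry grid-resolution (0.2 mM) uncertainty; (4) calcium does not
cross the myocyte–fibroblast junction, and no mechano-sensitive channels
are included — both deliberate scope exclusions.
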