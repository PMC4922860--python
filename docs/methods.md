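# Methods

## The gating model

The channel is modelled as a four-state continuous-time Markov chain per
channel, states C (closed), O (open), O_block (open but pore occupied by an
outward-moving Ca²⁺), and I (long-term inactivated):

```
C <-> O -> O_block -> I,   I -> C (k_recover, default 0)
```

- **Voltage dependence.** k₁(V) = k₁⁰·1.5^(V/100 mV) and
  k₋₁(V) = k₋₁⁰·2.2^(−V/100 mV). Only the fold factors per 100 mV are
  experimentally constrained; the directions (opening favoured by
  depolarization, closure by hyperpolarization) are the package's choice —
  they are the only assignment consistent with outward steady-state
  rectification together with fast hyperpolarized tail decay.
- **Calibration.** The wild-type rate constants are fixed by two measured
  quantities at −100 mV: deactivation τ = 1/(k₁+k₋₁) = 43 ms and
  constitutive open probability k₁/(k₁+k₋₁) = 0.007, giving
  k₁⁰ = 0.244 s⁻¹ and k₋₁⁰ = 10.50 s⁻¹. The D523N set uses τ = 2.3 ms with
  k_block = 0 (no Ca²⁺ coordination site, no block, no inactivation); the
  D525N set uses τ = 37 ms and blocks like wild type. The mutants'
  constitutive P_o is not separately measured; the wild-type value 0.007 is
  reused so that only the deactivation speed and the block differ.
- **Block.** `block_condition(V, E_Ca)` is the sign of the outward Ca²⁺
  driving force, V > E_Ca, with E_Ca supplied by the Nernst relation from
  the instantaneous compartmental free Ca²⁺. The default block is
  *collective*: while the driving force is outward, the filter of every
  available (C or O) channel is occupied at rate k_block (or instantly in
  `block_speed="instantaneous"`), so the whole non-inactivated pool sits in
  O_block and inactivates with exactly p_I = 1 − exp(−t_supra/2.1 s) of
  cumulative suprathreshold time. This choice is deliberate: with the
  calibrated opening rate (k₁ ≈ 0.4 s⁻¹ near +140 mV), a scheme in which
  only the O state can be blocked funnels the pool into O_block no faster
  than k₁, and the tail-amplitude decay against cumulative suprathreshold
  time then has an apparent τ ≈ 6.5 s rather than the measured 1/k₂ ≈ 2.1 s.
  Treating filter occupancy as fast relative to gating reproduces both the
  immediate and complete loss of outward current above E_Ca and the
  single-exponential τ_inact ≈ 2.1 s. The classic open-state-only scheme
  remains available (`block_mode="open-state"`). One known artefact of the
  collective form: on repolarization the entire blocked pool transits
  through O, so the first tail after a suprathreshold step jumps above the
  pre-block tails; τ_inact analysis therefore uses only the sweeps inside
  the suprathreshold series, where amplitude decline is k₂-governed.
- **Inactivation.** k₂ = 1/2.1 s⁻¹ acts only from O_block and only while
  V > E_Ca; I is absorbing by default (recovery is negligible on the tens
  of minutes scale of the experiments being emulated).
- **Conduction.** Only O conducts. Unitary current is piecewise-ohmic,
  g_in = 121 pS below E_rev and g_out = 198 pS above it (tails are
  experimentally linear, so no GHK flux rectification is applied).
  Macroscopic current is N·p_O·g·(V−E_rev).
- **Potentiation.** An optional phenomenological multiplier on k₁,
  1 + (g_max−1)·c^h/(c^h+K^h) with defaults g_max = 3, K = 300 nM, h = 2
  of internal free Ca²⁺. It is not constrained by kinetic measurements; it
  exists to reproduce the qualitative potentiate-then-inactivate time
  course of whole-cell recordings and is off unless requested.

### Numerics

Deterministic occupancies are propagated sample-by-sample with the matrix
exponential of the 4×4 generator (cached per distinct voltage), which is
exact on piecewise-constant segments; ramps are discretised at the sample
grid with midpoint voltages. In instantaneous-block mode the propagation
uses exact closed forms (two-state relaxation below E_Ca, pure k₂ decay
above), which is what the coupled whole-cell loop uses for speed.
Occupancies are renormalised to unit sum each step; conservation holds to
10⁻⁹ throughout. The stochastic simulator draws exact exponential waiting
times per channel over the same piecewise-constant intervals
(inverse-CDF jump draws), so it is an exact sampler of the chain, not an
Euler approximation; fixed seeds give byte-identical traces.

## Permeability calculations

Monovalent test ions use the paired-bath form
P_X/P_Cs = (α_Cs,e/α_X,e)·exp(ΔE_rev·F/RT) — the exponent carries F/RT (an
inverse-dimensioned variant sometimes appears in print but is not
evaluable in these units) — where ΔE_rev is the junction-corrected shift
between the test bath and the Cs⁺ bath. Divalents use
P_X/P_Cs = α_Cs,i·u(u+1)/(4α_X,e) with u = exp(E_rev·F/RT). Internal Cs⁺
defaults to 100 mM (80 CsMES + 4×5 from Cs₄-BAPTA). Activities use the
fixed coefficient table (0.74, 0.72, 0.69, 0.29 for Na⁺, K⁺, Cs⁺, Ca²⁺)
by default; the extended Debye–Hückel evaluator
(log₁₀γ = −A z²√I/(1+B å√I)) is provided but opt-in, because no single
standard parameterisation reproduces all four tabulated values at the
recording ionic strength. Junction correction is
corrected = measured − JP; the inverse problems are solved by bracketed
Brent iteration with forward∘inverse agreement below 10⁻⁸ mV.

## Calcium accounting

Charge-to-concentration conversion uses the rounded constants
e = 1.6·10⁻¹⁹ C, N_A = 6.02·10²³ mol⁻¹ and the 2.14 pL cell volume by
default, because these are the constants used in the published worked
numbers this package is checked against; CODATA values are selectable.
The chelator solver treats buffers as independent 1:1 Ca²⁺ ligands with
*apparent* Kd supplied by the user (defaults: BAPTA 0.22 μM, EGTA 0.15 μM
at pH 7.4); pH, Mg²⁺ and ionic-strength corrections of full chelator
programs are out of scope. A single buffer is solved in closed form, and a
bracketed Brent search plus Newton polish otherwise; mass conservation
holds to 10⁻¹² relative (the Newton polish matters because the residual
slope reaches ~10⁵ in stiff, far-from-Kd regimes). The "good buffering"
band is the symmetric 1000-fold log interval around Kd, matching the
0.68–683 μM band quoted for the 21.6 μM effective BAPTA constant; the
legend value of 216 μM is selectable but is inconsistent with that band
and with the canonical sub-μM BAPTA affinity, so none of the three is
asserted as the truth. An optional fixed-ratio buffer (default ratio 40
bound : 1 free) represents intrinsic cellular buffering.

### The coupled whole-cell loop

Per sweep: simulate gating at the current E_Ca → convert occupancy to
current → integrate the inward charge of the repolarization tail window →
convert to ions with r = ([Ca]ₑ/[Na]ₑ)(P_Ca/P_Na) (0.199 in the standard
bath) → add to total Ca²⁺, re-solve the chelator equilibrium → update
E_Ca and the potentiation multiplier for the next sweep. Buffer updates
are per-sweep, not per-sample, matching the sweep-integrated estimation
procedure the loop emulates. Ca²⁺ entry is booked from the *tail windows*
(the experimentally integrated quantity), not from all inward charge;
this keeps the simulated accumulation directly comparable to published
accumulation time courses. Extrusion, dialysis by the pipette and spatial
diffusion are not modelled — accumulation is therefore an upper bound,
and the absolute potentiation/inactivation times in coupled runs are
faster than in real cells; the qualitative contrast (complete
inactivation under 5 mM BAPTA within minutes vs < 5% inactivation under
15 mM BAPTA + 5 mM EGTA over ten minutes) is the validated behaviour.

## Synthetic-data conditions

Fixture defaults are the recording conditions of the experiments they
emulate: solution recipes as printed (standard bath NaCl 150/HEPES 10/
CaCl₂ 2 mM; pipette CsMES 80/NaCl 20/HEPES 10/MgCl₂ 2/Cs₄-BAPTA 5 mM at
90 nM free Ca²⁺; divalent-free symmetric 144 mM Na⁺; NMDG 100/CaCl₂ 20;
high-buffer 15 BAPTA + 5 EGTA at 15 nM free Ca²⁺), protocols at the
published frequencies (0.5 Hz ramps, 0.2 Hz step series with
suprathreshold steps 28–42 mV above E_Ca, 300 ms/+5 mV I–V steps),
Gaussian noise SD 0.5 pA (SNR ≈ 24 against the 12.1 pA unitary level —
idealization is non-trivial but reliable), and 5 kHz sampling (20 kHz for
tail fixtures so the 2.3 ms mutant decay is resolved; 1 kHz for the
multi-minute coupled runs, ample for ≥ 40 ms kinetics). Acquisition rates
are declared choices, not measured ones.

Channel counts per fixture are set from the magnitudes of the recordings
being emulated: 700 channels for whole-cell coupled runs (sub-nA to nA
currents at typical ~20 pF cells, and a 5 mM BAPTA saturation time of a
few minutes under 0.5 Hz ramps), 150 channels for dense on-cell ensemble
patches (observing up to 11 simultaneous openings at ~4% open probability
implies a patch of order 10² channels), 8 channels for the open-probability
fixture (~10³ openings, ~4% relative standard error of the P_o estimate).
The P_o fixture's two-state rates (mean open time 10 ms, per-channel
P_o = 0.0057 at +80 mV) and the mostly-open conductance fixture
(P_o = 0.9) are constructed values recorded in the ground-truth sidecar.
The NP-EGTA uncaging emulation steps internal free Ca²⁺ instantaneously
at the flash time and feeds E_Ca accordingly.

What passing recovery tests on these fixtures shows: the analysis
operations are unbiased and correctly scaled on data generated by the
model itself. What they do not show: robustness to real-recording
pathologies (capacitive transients, series-resistance error, drifting
leak, flicker block, filtering artefacts), none of which the generator
emulates.

## Design choices on genuinely open points

- Monovalent permeabilities use the relative (ΔE_rev, paired-bath) form —
  internal Cs⁺ and impermeant NMDG⁺ make the absolute form ill-conditioned;
  the absolute divalent form is used for Ca²⁺ as printed.
- Both P_Ca/P_Cs = 7 and P_Ca/P_Na = 14.9 are kept as independent inputs;
  no conversion between them is attempted because the linking P_Na/P_Cs
  path is not uniquely determined by the available measurements.
- E_Ca values quoted for specific conditions (88 mV, 138 mV) are protocol
  metadata, not recomputed quantities.
- P_o is reported both per-channel (when N is known) and as NP_o with
  N = maximum observed level otherwise; the two are never silently mixed.
- QC thresholds are applied as strict inequalities: whole-cell records
  with seal < 1 GΩ or leak > 90 pA at −60 mV, and on-cell records with
  seal < 8 GΩ, are excluded.

## Known limitations

- The collective block idealisation overstates the first post-block tail
  (see above) and contains no Ca²⁺-concentration dependence of k_block:
  block is all-or-none in the sign of the driving force.
- No hidden-Markov rate estimation from single-channel records;
  idealization is plain half-amplitude multi-level thresholding.
- The chelator model is Ca²⁺-only with apparent constants; no kinetics
  (buffering is assumed instantaneous between sweeps).
- The compartment model is a single well-mixed volume — no diffusion,
  extrusion or store fluxes — so per-opening increments are upper bounds.
- Piecewise-ohmic conduction ignores Goldman rectification and any
  surface-charge or temperature corrections beyond the constants set.
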