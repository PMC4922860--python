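# cagate

Biophysics toolkit for cation channels that are **blocked and inactivated by
outwardly moving Ca²⁺** — the phenotype of the PKD2-L1 (polycystin-L1)
channel found in primary cilia, cerebrospinal-fluid-contacting neurons and
taste receptor cells. The package is aimed at channel biophysicists who
want to simulate this gating scheme, analyse patch-clamp records with the
standard measurement operations, and do the Ca²⁺ bookkeeping that links
channel flux to the free Ca²⁺ concentration of a cell or a femtolitre
compartment.

## What it computes

**Four-state gating model** (`cagate.gating`)

```
        k1            k_block          k2
   C  <---->  O  ------------>  O_block ----> I        (I -> C: k_recover ~ 0)
        k-1    (when V > E_Ca)   (while V > E_Ca)
```

Opening and closing rates are modestly voltage dependent — k₁ grows 1.5×
and k₋₁ 2.2× per 100 mV, in the directions that produce outward
steady-state rectification and voltage-dependent deactivation. Whenever
the membrane potential exceeds the Ca²⁺ equilibrium potential E_Ca, outward
Ca²⁺ occupies the selectivity filter (block) and blocked channels
inactivate at k₂ ≈ 1/2.1 s⁻¹, essentially irreversibly. Unitary currents
are piecewise-ohmic: 121 pS inward, 198 pS outward. Both a deterministic
occupancy solver (matrix exponential / exact closed forms) and an exact
event-driven stochastic simulator are provided, with named parameter sets
`wt` (τ_tail(−100 mV) = 43 ms, constitutive P_o(−100 mV) = 0.007),
`d523n` (τ_tail = 2.3 ms, no block) and `d525n` (τ_tail = 37 ms).

**Bi-ionic permeability** (`cagate.permeation`) — relative permeabilities
against internal Cs⁺ from reversal potentials:

- monovalent X: P_X/P_Cs = (α_Cs,e/α_X,e)·exp(ΔE_rev·F/RT)
- divalent X:  P_X/P_Cs = α_Cs,i·u(u+1)/(4α_X,e), u = exp(E_rev·F/RT)

with effective activities α = γ·[X] (fixed table γ = 0.74/0.72/0.69/0.29
for Na⁺/K⁺/Cs⁺/Ca²⁺, or an extended Debye–Hückel evaluator), Nernst
potentials, liquid-junction correction, and the Ca²⁺ current fraction
r = ([Ca]ₑ/[Na]ₑ)·(P_Ca/P_Na).

**Calcium accounting** (`cagate.calcium`) — integrated tail charge →
Ca²⁺ ion count → total-concentration increments
(Δ[Ca] = |Q|·r/(2e·N_A·V)), multi-chelator mass-action equilibria
(BAPTA/EGTA, closed-form or safeguarded root-finding with 10⁻¹² mass
conservation), "good buffering" range flags, per-opening increments for
small compartments (cell 2.14 pL, dendritic knob 113 fL, cilium 0.5 fL),
and a coupled whole-cell loop in which Ca²⁺ entry feeds back onto E_Ca,
potentiation and block — the "calcium clamp" behaviour.

**Electrophysiology analysis** (`cagate.analysis`) — recording QC filters
(seal/leak cutoffs), single-exponential fits f(t) = B + A·exp(−t/τ), Hill
fits for IC₅₀/EC₅₀, multi-level half-amplitude idealization, open
probability (P_o and NP_o conventions), ensemble averaging, I–V extraction
with interpolated reversal potentials, and τ_inact from tail amplitude vs
cumulative suprathreshold time.

**Synthetic data** (`cagate.synth`) — seeded generators for every input:
the recording-solution recipes, the four stimulus protocols (tail family,
0.5 Hz ramps, 0.2 Hz step series bracketing E_Ca, I–V steps), macroscopic
and single-channel traces with Gaussian noise, and Hill dose–response
tables, each with a ground-truth sidecar for recovery tests.

**I/O and CLI** (`cagate.traceio`, `cagate.cli`) — ATF 1.0 and CSV trace
files, YAML run configs, and a `cagate` command with `simulate`, `synth`,
`analyze`, `permeability`, `accumulate` and `compartment` subcommands.

## Worked example

Deactivation kinetics from a synthetic wild-type tail record:

```python
import numpy as np
from cagate import analysis, synth

fix = synth.make_fixture("wt-tail")            # 500 channels, +100 mV prepulse,
trace, truth = synth.generate_trace(fix)       # tail step to -100 mV
t0, t1 = fix.protocol.segment_window(2)        # the repolarization window
t = trace.times()
mask = (t > t0) & (t <= t1)
fit = analysis.fit_exponential(t[mask], trace.sweeps[0][mask])
print(f"fitted tau = {fit.tau*1e3:.1f} ms (generator: {truth['tau_tail_s']*1e3:.1f} ms)")
print(f"tail amplitude A = {fit.A:.1f} pA")
```

prints

```
fitted tau = 43.0 ms (generator: 43.0 ms)
tail amplitude A = -215.3 pA
```

i.e. the tail of 500 channels deactivating at −100 mV decays with the
wild-type 43 ms time constant. The same round trips run from the shell:

```
$ cagate permeability --ion Ca --erev 2.8
test_ion,reference_ion,ratio,erev_used_mv,method
Ca,Cs,7.0151,2.8,divalent-absolute

$ cagate compartment --name knob
compartment=knob volume_l=1.13e-13 v_mv=-55 delta_ca_um_per_opening=6.034
```

The first line inverts the divalent bi-ionic equation: a +2.8 mV reversal
in the 20 mM Ca²⁺ bath corresponds to P_Ca/P_Cs ≈ 7. The second applies
the charge-to-concentration chain to a 113 fL dendritic knob: one 100 ms
opening of a 120 pS channel at −55 mV raises knob Ca²⁺ by ≈ 6 μM.

## Layout

```
src/cagate/
  constants.py    physical constants (rounded + CODATA sets)
  permeation.py   activities, Nernst, bi-ionic permeability ratios
  gating.py       four-state model, protocols, ODE + stochastic simulators
  calcium.py      charge->Ca2+ bookkeeping, chelator equilibria, coupled loop
  analysis.py     QC, exponential/Hill fits, idealization, P_o, I-V
  synth.py        solutions/protocols/fixtures/dose-response generators
  traceio.py      ATF 1.0 + CSV traces, YAML run configs
  cli.py          the `cagate` command
docs/methods.md   model assumptions, parameter provenance, limitations
```
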