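# Methods

## Model

The lung is a rooted tree of rigid, non-storing airways feeding `N` linear
elastic compartments (default five, labelled A–E). Each edge carries a
constant resistance (cmH₂O·s/l): internal edges the named *shared*
resistances R0–R3, leaf edges the compartmental resistances. Each leaf is a
linear capacitor: alveolar pressure equals `v/C`, where `v` is the absolute
elastic volume above the zero-pressure relaxation point and `C` the
compliance (l/cmH₂O). Compartments interact only through the resistive
network — no mechanical interdependence, no viscoelastance, no tidal
opening/closure, no nonlinear R or C, no gas compressibility.

The default topology is a serial backbone from the airway opening — R0 to
node n1, R1 to n2, R2 to n3, R3 to n4 — with terminal branches n1→A, n2→B,
n3→C and n4→{D, E}. This is one consistent reading of the intended wiring;
the topology is fully configurable in the scenario file, so alternative
readings are one config edit away. Two shared-resistance presets are
shipped: the default `(R0,R1,R2,R3) = (1,1,2,1)` and an alternative
`(1,3,2,1)` (`shared="table1"`), reflecting two published variants of the
same scenario.

Baseline compartment parameters: resistances `(1, 15, 11, 15, 7)`,
compliances `(0.08, 0.06, 0.05, 0.02, 0.02)`, rest volumes all 1 l.
Ventilator: PEEP 2 cmH₂O, inspiratory time `t_i = 1` s, cycle `t_tot = 3` s.

### Drives

* **CF** — constant inspiratory flow `Q_aw` (baseline 1.7 l/s).
* **DF** — decelerating (triangular) flow `Q_max·(1 − t/t_i)`, reaching
  exactly zero at `t_i`; no terminal flow floor.
* **SF** — half-period sinusoid `Q_max·sin(πt/t_i)`, zero at both ends of
  inspiration. A quarter-sine reading ("sinusoidal" is underdetermined) was
  considered and rejected: spontaneous-breath flow is near-zero at both
  phase transitions.
* **CP** — ideal constant-pressure source `P_set` with instant rise; the
  flow profile emerges from the network. The baseline pairs `P_set = 13.75`
  cmH₂O with the CF scenario; under the default topology the set pressure
  that exactly matches CF's 1.7 l tidal volume is 13.03 cmH₂O, consistent
  with the wiring ambiguity above (the matched-volume condition, not the
  set-pressure value, is the defining constraint, and calibration enforces
  it to 1e-4 l).

Expiration is passive against an ideal PEEP source at the airway opening
(no expiratory-valve resistance), beginning exactly at `t_i` (no pause).
Amplitudes can be given directly or as a target tidal volume: flow modes
invert their closed-form volumes (`Q_aw·t_i`, `Q_max·t_i/2`,
`2·Q_max·t_i/π`); CP runs a Brent root search of the periodic-steady-state
inspired volume, which is affine and strictly increasing in `P_set`, with a
bracket capped 1000 cmH₂O above PEEP.

## Numerics

Nodal analysis of the Kirchhoff balances reduces the circuit to
`dv/dt = A·v + b·u(t)` with `u` the airway boundary value (flow or
pressure). Because the forcing within each phase is constant, affine in `t`
or sinusoidal, each phase is propagated **exactly** by the matrix
exponential of a small augmented generator (state + forcing carriers). The
output grid (default Δt = 1 ms) only samples the solution; end states are
grid-independent to machine precision. This replaces an adaptive ODE
integrator deliberately: the system is linear time-invariant per phase, so
the propagator is exact and orders of magnitude faster for sweep
experiments. Negative absolute volumes abort the run (model violated);
intercompartmental flow reversal (pendelluft) is permitted, not clipped.

The breath-to-breath map is affine, `v_end = M·v₀ + c`. `c` is the image of
the zero state and the columns of `M` come from unit basis states (all from
the same two cached phase propagators); the periodic steady state is
`v* = (I − M)⁻¹c`, guarded by a spectral-radius check (`ρ(M) < 1` always
holds for a passive RC network) and confirmed by one verification cycle to
1e-9 l. Residual end-expiratory pressures are `P_ex = v*/C`; reported
volumes `V(t) = v(t) − v*` so `V(0) = 0`.

Cumulative elastic energy `A(t)` uses a composite-Simpson cumulative
integral on the inspiration grid. The trapezoidal rule is available
(`method="trapezoid"`) but is not the default: after a constant-pressure
step the power trace decays fast enough that trapezoid's O(Δt²) bias is
visible against the exact energy–volume identity
`2CA + C²P_ex² = (V + CP_ex)²` at Δt = 1 ms (relative error ~2e-5), while
Simpson's is ~2e-8.

## Strain and strain rate

Strain is volume-linear (sphere-volume ratio), not a cube-root radius
ratio; both printed forms above are implemented and verified identical
along every trajectory. `S_max` is the maximum of strain over the whole
cycle, with the peak time reported: pendelluft genuinely shifts volume
peaks off end-inspiration (under DF, compartment A peaks at t ≈ 0.75 s and
exceeds its end-inspiratory strain by ~0.05; under CF, B and C peak ~20 ms
into expiration). Sweep tables therefore store both `V_T_comp`
(end-inspiratory volume) and `V_peak`; `S_max` is exactly
`1 + (V_peak + C·P_ex)/V_rest`.

Two strain-rate outputs are exported side by side, because the quotient
form `ICP/(V_rest·√(2CA + C²P_ex²))` evaluates along trajectories to
`Q/(C·V_rest)` whereas the time derivative of the strain expression is
`Q/V_rest` — a constant factor `C` apart, i.e. the quotient form is
dimensionally inconsistent with the strain it is paired with. The
derivative form `Q/V_rest` is the default in summaries; the quotient form
is preserved unchanged (`strain_rate_printed`), never silently corrected,
and their ratio `1/C` is asserted in the tests. The `ICP` entering the
quotient form is the same compartment's elastic ICP. Driving power
(`Q·V/C`) and resistive-inclusive total power (`Q·(V/C + P_ex + R_path·Q)`,
with `R_path` the series resistance from the airway opening) are optional
outputs; only elastic ICP feeds strain.

## Experiments

* **Mode comparison** — all modes recalibrated to the same tidal volume and
  inspiratory time before comparison.
* **PEEP sweep** (default 0–12.75 cmH₂O, step 0.25) — each mode holds its
  *set* control fixed as PEEP varies: flow modes keep amplitude (hence
  V_T), CP keeps `P_set` (its V_T shrinks with rising PEEP). This mirrors
  bedside practice; holding V_T matched for CP instead would require
  re-calibration at every PEEP and answers a different question. A
  consequence worth noting: the *level* ordering of `S_max` across
  compartments is the same for all modes on the baseline network, while the
  PEEP *sensitivity* (rise of `S_max` over the sweep) orders compartments
  differently under CP than under any flow mode — that distributional
  difference is the tested property.
* **V_T × Q_max grid** — inspiratory time follows the waveform geometry
  (CF `V_T/Q_aw`, DF `2V_T/Q_max`, SF `πV_T/(2Q_max)`); cells with
  `t_i ≥ t_tot` are marked infeasible, and cells with auto-PEEP above
  0.1 cmH₂O over set PEEP are flagged. The convexity of `S_max` in V_T
  appears where rising V_T squeezes expiration (auto-PEEP build-up); at
  generous peak flows the curvature is flat.
* **Rest-volume sweeps** (uniform 0.2–1.2 l, step 0.05; plus
  per-compartment maps) — `V_rest` enters only the strain formulas, so one
  steady-state solve per mode serves the whole grid exactly. The shipped
  heterogeneous preset `{A: 0.4, B: 0.8, C: 0.9, D: 1.2, E: 1.0}` pairs
  small rest volumes with compliant compartments and is verified to make A
  the most-strained and D the least-strained compartment under baseline CF;
  the particular values are a documented choice, not a published set.

All sweeps are pure functions of (network, settings, grid); reruns are
byte-identical.

## Limitations

Linear, time-invariant R and C; passive patient; ideal sources (no valve
dynamics, no rise time, no inspiratory pause); rigid airways without gas
storage; strain as a macro-level sphere analog without stress risers or
geometric heterogeneity. Energy is reported in cmH₂O·l (1 cmH₂O·l ≈
0.098 J); no per-minute mechanical power is computed. Results are
concept-level physiology on a five-unit caricature of the injured lung, not
patient-level predictions.
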