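# Methods

This note documents the models, numerical choices and limitations behind the
`implantheat` pipeline.  It is organized along the data flow: phantom →
sequence → power deposition (gradients, RF) → bioheat → safety metrics.

## Synthetic tissue model and implant

The phantom is a layered circular cylinder along the bore axis: skin (4 mm),
subcutaneous adipose tissue (6 mm), fat (10 mm), muscle fill, and a coaxial
cortical-bone core (radius 20 mm by default), voxelized at 2 mm isotropic
resolution with one air voxel of margin on every grid face.  Tissue
dielectric/thermal/perfusion parameters are literature-typical values for the
64–128 MHz band (see `properties.py`); they are configuration, not constants,
and any entry can be swapped through the model's property table.  The implant
materials are fixed by their data-sheet values: CoCrMo
(σ = 1.16 MS/m, λ = 14 W/m K, c_p = 450 J/kg K, ρ = 8445 kg/m³, no perfusion
or metabolism) and polyethylene (σ = 0, ρ = 940 kg/m³) for the liner.

The implant is a canonical-pose simplification of a unilateral hip
endoprosthesis: a 142 mm stem (14 mm diameter), a neck, a 30 mm hemispherical
head (230 mm total height from stem tip to head top), a hemispherical
acetabular shell (66 mm outer diameter, 8 mm thick) with a 34 mm fixation
screw through its dome, and a 10 mm polyethylene liner between head and
shell.  All parts are coaxial with the bore axis, head toward +z; no
anatomical pose information is modeled.  A voxel belongs to a primitive iff
its center lies inside (centers, not corners), which makes the voxelization
deterministic; voxel-center lattices are chosen symmetric about the implant
axis.  Note that the assembly consists of two galvanically separate metal
parts (stem+neck+head, and shell+screw); the eddy solver treats connected
components independently, so the "one implant" is electrically two
conductors, as in the real device.

Body positions 1–12 set the implant-head z coordinate to +288, +224, …,
−352, −416 mm (64 mm increments), spanning thorax imaging (implant far above
the isocenter) down to femur/knee imaging (far below).

What the generator does **not** emulate: anatomical tissue distributions
(organ-level segmentation), bilateral implants, implant/bone contact
geometry, and — important for interpreting the RF results — any field
perturbation by the implant.  Consequences are discussed under Limitations.

## Sequence synthesis

Waveforms are sampled at dt = 4 µs (≥ 250 samples across the shortest 1 ms
pulse).  RF pulses are apodized sincs,
`s(t) = sinc(TBW·t/τ)·[(1−α) + α cos(2πt/τ)]` with α = 0.5, and the
amplitude follows area-proportional flip-angle scaling — adequate for
relative B₁² power bookkeeping, deliberately not Bloch-accurate.
Gradient lobes are trapezoids; ramp times are quantized upward so the
slew-rate limit holds samplewise.  Amplitudes come from the standard moment
relations: readout plateau `G = BW/(γ̄·FOV)`, slice selection
`G = TBW/(γ̄·τ·thickness)`, phase-encode step `Δk/γ̄ = 1/(γ̄·FOV)`.  The
representative interval Δ is one TR for TSE/GRE/TrueFISP and the whole
single-shot frame for EPI (the synthesized frame slightly exceeds the nominal
43 ms TR; the frame defines Δ).  Echo timing follows the usual sequence
skeletons (TSE: 90° + echo train of 180° pulses at the 6 ms echo spacing;
GRE: 11 spoiled slice blocks per TR; TrueFISP: fully balanced lobes);
exact crusher/spoiler tables are not prescribed anywhere, so the layout is
qualitative while all moments and limits are exact.  The representative
phase-encode line defaults to the k-space edge (largest moment).

The 2 W/kg whole-body SAR rule is closed-form:
`dead = max(0, t_active (SAR/2 − 1))` per acquisition, and the acquisition
count over an exam is round-to-nearest of `total/(t_active + dead)` — the
only rounding rule consistent with both printed counts for the TSE sequence
(151 at 1.5 T, 47 at 3 T).  The exam schedule length defaults to 360 s.

## Gradient (eddy-current) exposure

Each gradient channel over Δ is partitioned into subsignals.  Automatic
detection finds the longest exactly-repeating run via autocorrelation
candidate periods (≥ 3 repeats); head/tail segments are classified aperiodic.
Manual boundaries override detection.  Each subsignal gets a truncated FFT
expansion: bins above 100 kHz are discarded, then bins are retained in
descending energy order until 99.9 % of the mean square is captured
(both thresholds configurable; Parseval bookkeeping is exposed through
`energy_captured`).

The per-harmonic electromagnetic problem is solved in the quasi-static
resistive limit.  For a harmonic source with vector potential phasor
`c·a(r)` the electric field in the metal is `E = −jωc(a + ∇ψ)`, where ψ
solves the real, frequency-independent conservation problem
`∇·(σ(∇ψ + a)) = 0` with zero normal current on the metal surface.  The
discretization is a face-flux finite-volume scheme on the metal voxels with
harmonic-mean face conductivities; one node per connected component is
grounded to fix the potential gauge, and the factorized sparse solve is
reused across axes.  Because ψ is frequency independent in this limit,
**one potential solve per coil axis serves every harmonic** — the
per-harmonic current is `J_k = −jω_k c_k σ(a + ∇ψ)`, and the superposed
time-domain current is `J(t) = −σ Σ_axes F_axis Ġ_axis(t)` with the basis
field `F = a + ∇ψ`.  Instantaneous power density is `|J(t)|²/σ`; the
Δ-averaged map uses the exact quadratic form `σ Σ_ab (F_a·F_b) M_ab` with M
the covariance of the reconstructed gradient derivatives, which keeps
cross-axis correlations.

Validity of the resistive limit is monitored through the skin depth
δ = √(2/(μσω)) (≈ 14.8 mm in CoCrMo at 1 kHz); a warning is logged whenever
a solve is requested at a frequency where δ falls below the smallest
connected part's thickness.  The neglected reaction field means power is
*overestimated* at the highest retained harmonics — a conservative direction
for a safety tool.

Coil models: the default `uniform-gradient` mode uses idealized linear maps
B_z = G·u with divergence-free gauges A = (0, Gx²/2, 0), (−Gy²/2, 0, 0) and
G z(−y/2, x/2, 0) for the x, y, z coils (the z gauge carries the
Maxwell-required concomitant terms; x/y are exact for the idealized map).
The published coil sensitivities (56.1, 56.1, 57.8 µT/(m A)) convert gradient
strength to filament current in the `filamentary` mode, which evaluates the
exact finite-segment Biot–Savart field; the shipped filament set is a generic
demonstration winding (a Maxwell pair), since real winding layouts are
proprietary.  Under the uniform model the field grows linearly without bound,
so implant power increases monotonically with distance from the isocenter;
points outside the configured linear region are flagged.

## RF exposure

The synthetic deposition map is an explicit, documented **non-physical
stand-in** for a full-wave birdcage simulation: inside the 450 mm coil
footprint, `P_RF = C·σ_tissue·r²` (the quasi-static birdcage E ∝ r scaling),
with a raised-cosine roll-off over 150 mm beyond the coil ends.  The scale C
is normalized so the *centered* body would absorb a stated whole-body SAR
(default 2 W/kg) at the reference ⟨B₁²⟩, and C is position independent, so
moving the body out of the coil reduces deposited power accordingly.  Its
purpose is pipeline exercise and relative position studies, not absolute RF
dosimetry.  Imported maps (NIfTI + JSON sidecar) are block-averaged onto the
model grid, conserving local volume integrals of power.  Implant metal voxels
carry zero RF power (PEC masking); the implant mass still counts in the SAR
denominator.  Static field strength (1.5 T vs 3 T) enters only as a
configurable scale on the RF map; the gradient chain is field independent.

Dead-time convention: RF maps are scaled by the *active-interval* ⟨B₁²⟩ and
the power combiner applies the schedule's activity fraction to RF and GC
alike, so dead-time dilution is applied exactly once.  The
`rf_mean_square_b1(include_dead=True)` path exists for SAR-compliance checks,
where the diluted average must equal the 2 W/kg limit.

## Power combination

Per thermal marching step (default 0.1 s), the deposited power is the exact
time average of the scheduled power over that step: interval-averaged P_GC
and P_RF during active acquisition intervals, zero during dead/idle times,
with straddling steps weighted by their active-time fraction.  Sub-Δ power
modulation is averaged over Δ before scheduling — at marching steps well
above Δ-internal time scales this is exact for the deposited energy.  The
three cases P1 (GC), P2 (RF), P3 = P1 + P2 share the schedule, so the P3
power map is the exact samplewise sum (the temperatures are not additive).
Halving the default step changes the 360 s maximum ΔT by well under 0.5 % on
the shipped phantom; position-ordering studies in the test suite use a 1 s
step, which leaves the orderings unchanged.

## Bioheat solver

The Pennes equation is solved in temperature-increase form ΔT = T − T₀, so
the resting field T₀ is never needed.  Thermoregulation is instantaneous and
local: perfusion multiplier `L_B = 2^(ΔT/ΔB)` with ΔB = 1.6 K, capped at 15
(32 on skin) and clamped at 1 for ΔT ≤ 0 (the behavior below the resting
temperature is not specified by the regulation model; no perfusion reduction
on cooling is the conservative reading); metabolic factor `1.1^ΔT − 1`.
Material properties are temperature independent.

Space: 7-point finite volumes with harmonic-mean face conductivities, which
handles the metal/tissue interface without special casing (implant voxels
conduct with their own λ, ρc_p and zero perfusion/metabolism).  Air voxels
carry zero capacity and zero face conductance, so they decouple exactly and
the sweeps can run unmasked.  A Robin condition λ∂ΔT/∂n = −h_amb ΔT with
h_amb = 7 W/m²K applies on tissue–air faces *inside* the grid; the grid
boundary itself is adiabatic (phantoms keep an air margin; sweating and other
h_amb dynamics are not modeled).

Time: Douglas–Gunn splitting with θ = ½ — one explicit predictor plus three
directional tridiagonal solves per step (Thomas sweeps, numba-compiled).
The nonlinear perfusion/metabolic terms are lagged one step (Picard
linearization); at the sub-second steps used here the perfusion relaxation
time ρc_p/h_b0 ~ 10³ s makes the explicit treatment uniformly stable and the
splitting second-order for the diffusion part (verified by Richardson
extrapolation in the tests; the lagged reaction term is first-order by
construction).  A useful property of the implementation: its fixed points
satisfy the *unsplit* discrete steady-state equation exactly, independent of
dt, so long-horizon steady-state oracles are step-size free.  Non-finite
updates abort with the offending voxel and step size.

Validation oracles (all in the test suite): the uniform-perfusion nonlinear
steady state against the scalar root of `2^(x/1.6)·x·h_b0 = P` (0.5 %);
a heterogeneous 20³ grid against an independent explicit-Euler stepper at
1/100 the step (1 % at 60 s); the linear 1D Robin slab against the cosh
closed form (0.5 %); and the discrete steady-state energy balance
(deposited = perfusion removal + boundary flux).

## Safety metrics

Maximum ΔT is reported whole-body and inside a region of influence — a fixed
21.7 × 18.8 × 28.2 cm box centered on the implant bounding box (a published
constant here; its derivation requires anatomical RF fields and is out of
scope).  Heated mass sums ρ·voxel volume per tissue for voxels above the 1 K
and 3 K thresholds (the ΔT equivalents of the 39 °C and 41 °C local
temperature limits under the conservative 38 °C resting assumption),
excluding the implant itself.  Time-to-threshold interpolates the running
maximum linearly between marching steps and reports "never" beyond the
simulated duration.  Distance profiles use center-to-center Euclidean
distance to the nearest implant-surface voxel (exact distance transform).

For position-sweep studies on the shipped phantom, the pointwise maximum
inside the full region of influence saturates: the layered cylinder is
translation invariant along z, so the synthetic σr² law reaches the same
surface peak whenever any part of the box is inside the coil.  The
position-dependent quantity is therefore evaluated on the near-implant
tissue shell (region of influence ∩ within 20 mm of the implant surface),
which is where implant-related heating lives.  With anatomical models or
imported RF maps this workaround is unnecessary.

## Known limitations

- Absolute ΔT values comparable to anatomical-model studies are out of
  reach by design: they require a segmented human model and full-wave RF
  fields.  The package reproduces the *mechanisms* and the printed
  sequence/SAR bookkeeping, and validates its solvers against closed forms.
- The synthetic RF law has no implant-induced field enhancement (tip lensing,
  shield currents); RF hot spots at implant extremities are therefore absent.
- The resistive-limit eddy solver ignores the reaction field; above ~1 kHz
  for centimeter-scale CoCrMo parts it overestimates deposited power
  (flagged via the skin-depth warning).
- The uniform-gradient coil grows linearly without fringe-field decay, which
  exaggerates exposure at extreme table positions relative to real coils;
  the filamentary mode exists for realistic windings but ships only with a
  demonstration geometry.
- GC-induced power in tissue (as opposed to the implant) is not modeled;
  tissue conductivities are orders of magnitude below the metal's, and the
  deposition is negligible at gradient frequencies.
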