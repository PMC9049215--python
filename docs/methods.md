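# Methods

## Model

The trunk is two identical rigid bodies (mass `m = 19 kg`, pitch
inertia `J = 0.53 kg m²`, length `2r = 0.58 m` each) pinned at a spine
joint with a linear torsional spring (`k_t = 100 N m/rad`, relaxed when
the bodies are collinear). The generalized coordinates `q = [x, y, θ,
φ]` are the whole-body COM position, the pitch of the line joining the
two body COMs, and the spine half angle; the anatomical joint angle is
`2φ`, positive in extension. The kinetic energy evaluates exactly to

    T = m(ẋ² + ẏ²) + (J + mr²cos²φ) θ̇² + (J + mr²sin²φ) φ̇²,

which yields the diagonal mass matrix and the velocity-coupling vector
`h` used by the integrator; because the legs are massless, `T` is
independent of where the legs attach.

**Leg-joint geometry.** Each leg joint sits a distance `d = 0.06 m`
beyond its body's COM *along the body axis* (orientation
`ψ_i = θ + (−1)^i φ`), giving

    hip_i = ( x + (−1)^i (r+d) cosθ cosφ − d sinθ sinφ,
              y + (−1)^i (r+d) sinθ cosφ + d cosθ sinφ ).

The odd-in-`φ` terms matter: they are what makes extension and flexion
dynamically inequivalent. Placing the hips on the COM–COM line instead
(dropping the `d sinφ` terms) makes the model exactly invariant under
`(φ, φ̇) → (−φ, −φ̇)`, which would force every extended-flight gait to
have a gathered-flight twin with identical performance — erasing the
very asymmetries (no GG gaits for `d > 0`, distinct branch
performance) the analysis is about. The exact joint placement is
therefore used throughout, including the marker model.

**Contact model.** An airborne leg keeps length `l0 = 0.69 m` and a
fixed angle `γ_td` from the vertical (positive toe-forward). Touchdown
fires when the toe height reaches zero; the toe then becomes a
frictionless pin and the leg spring (`k = 15000 N/m`) loads in
compression only. Liftoff fires when the leg returns to `l0`, and the
leg angle snaps back to `γ_td`. Both transitions happen at zero spring
deflection, so total mechanical energy is conserved across events.
Gravity is `g = 9.81 m/s²` (standard value; configurable).

## Hybrid integration

Each smooth phase is integrated with DOP853 at `rtol = atol = 1e−10`
with dense output; touchdown, liftoff, ground-crash and apex guards are
localized by the integrator's root finder. Events closer than 1e−12 s
are processed touchdown-first; a stance shorter than 1e−9 s is reported
as a degenerate (grazing) contact rather than skipped. Cycle
construction enforces exactly one stance per leg between apexes and
distinguishes four failure modes (no contact, crash, bad sequence,
apex during stance). Relative energy drift over a cycle is checked
against 1e−8 and is typically below 1e−10 at the default tolerances —
energy drift, not local error, is the accuracy surface that matters
here because the periodic-orbit search closes the state through the
energy level.

## Periodic-gait search

The Poincaré section is the COM apex (`ẏ = 0`, descending) with the
symmetry constraints `θ = 0` and `φ̇ = 0`, so the search targets cycles
that are invariant under reflection-plus-time-reversal about the apex.
Section coordinates are `z = [y*, φ*, θ̇*]`; the forward speed is the
positive root of the energy closure at fixed `E`. Newton–Raphson (tol
1e−10 on the residual norm, forward-difference Jacobian with step
1e−7, step halving up to 10 times, 50 iterations max) solves for
`(φ*, γ1_td, γ2_td)` at fixed `(E, y*, θ̇*)` with residual
`(θ, φ̇, y − y*)` at the next apex; full periodicity of the remaining
coordinates (`φ`, `θ̇` return to 1e−8) is verified afterwards, and the
left-right symmetry manifests as each leg lifting off at minus the
other leg's touchdown angle (verified to ~1e−8 in the tests).

`φ ≡ 0` with `φ̇ ≡ 0` is an invariant manifold (all moments on the
spine coordinate vanish there): a rigid-trunk bouncer family that
Newton happily converges onto. These fixed points have no defined
flight posture and are excluded (`|φ*| < 1e−9` is rejected, and
iterations entering `|φ*| < 1e−3` are aborted early).

**Seeding and continuation.** The first solutions at an anchor height
come from a coarse residual scan over `φ* ∈ [−0.3, 0.3]`,
`γ ∈ [0, 0.6]` (8×9×9 grid) followed by Newton polishing of the
best-ranked seeds. Families are then traced by natural-parameter
continuation with secant extrapolation: in `y*` for the single-valued
upper family, in `φ*` for the folded lower family (exchanging the
roles of `φ*` and `y*`), with step halving at sharp turns and enlarged
leap steps across event-sequence boundaries (e.g. the onset of double
stance) where the map is continuous but not smooth. Folded traces are
re-solved at grid heights so the two-solutions-per-`y*` structure is
explicit. A travel-reversal transform (`θ̇* → −θ̇*` with swapped
touchdown angles) is used purely as a seeding heuristic across pitch
rates — it is *not* a symmetry of the model, but it lands close enough
for Newton.

**Sweep domain.** Sweeps admit `|φ*| ≤ π/4` (spine-joint excursion at
the apex ≤ 90°). Beyond this the folded family continues into a
self-folding regime (joint angles approaching 180°) that is far
outside quadruped posture — measured cheetah spine excursion is
0.47 rad peak-to-peak — and is excluded as unphysical. Default grids:
`E = 4500 J`, `θ̇* ∈ {±0.5, ±1.5} rad/s`, `y*` from 0.60 to 0.78 m
(step 0.005 m in the pipeline default; the test-suite and acceptance
sweeps use 0.01 m, which resolves the same families at half the cost).

## Classification and branches

A cycle's type counts its flight phases (the cycle starts mid-flight
at the apex, so the first and last partial flights are one wrapped
flight) and labels each flight extended (`φ > 0`) or gathered
(`φ < 0`) at its temporal midpoint (a flight-apex variant is exposed
as an option). Two-letter types are ordered from the flight preceding
the foreleg touchdown, the foreleg being the leg whose hip leads in
the travel direction.

Branches are the two solution families in the `(y*, φ*)` plane,
labelled pointwise by the apex spine sign: Branch 1 `φ* > 0` (upper),
Branch 2 `φ* < 0` (lower, folded: two solutions per apex height in its
range). Away from Branch 1's small-`y*` tail this coincides with the
sign of the stance-averaged spine-spring torque `τ_t = −4k_tφ`
(extension-positive in Branch 1, flexion-negative in Branch 2, while
the leg ground-reaction moments `τ_i = −k(l_i − l0) ∂l_i/∂φ` are
extension-positive on stance average in every gait found). On that
tail (Types EE/E at `y* ≲ 0.645`) the spring alignment passes through
zero and reverses while the family continues smoothly — the
torque-alignment characterization of the branches is a property of
their typical members, not of every solution, which is why the label
is tied to the family (apex sign) rather than to the alignment. The
stance-averaged torque is reported separately
(`stance_spring_alignment`, and the `stance_spring_torque` column of
the metrics table).

## Performance metrics

Fluctuations are max-minus-min of `y`, `θ`, `φ` over one cycle on
dense output (2001 samples). The average velocity is `Δx/T`. Leg
impulses integrate the spring force over stance with composite Simpson
on ≥ 401 dense-output points per stance, splitting the horizontal
impulse at the instant the leg passes the vertical (root-found to
1e−12 s); an augmented-state integration oracle reproduces the
quadrature to 1e−8 in the tests. On every periodic cycle the per-leg
vertical impulse equals `m g T` (half the weight impulse of the `2m`
body) and the four signed horizontal impulses cancel pairwise — both
closures are asserted to 1e−6.

## Stability

The return map is linearized by one-sided finite differences (step
1e−6, halved on event-sequence changes) on the six apex coordinates
`(y, θ, φ, ẋ, θ̇, φ̇)` with the horizontal position quotiented out and
`ẏ = 0` defining the section. Perturbed states carry their own
perturbed energy, so the conserved energy contributes exactly one unit
eigenvalue (observed within ~2e−6 of 1 across all solutions); a gait
is orbitally stable when all other eigenvalues lie inside the unit
circle. Holding the energy fixed instead would remove the unit
eigenvalue and change none of the stability verdicts, but the
energy-inclusive construction is the one whose spectrum has the
canonical conservative-system structure.

## Synthetic marker strides

The marker module maps model states to the five sagittal markers the
measured statistics are defined on: neck root and tail root (free body
ends), T12 (spine joint), shoulder and greater trochanter (the leg
joints, at the model's exact hip placement). From the markers,
`δ_y` is the range of the shoulder–trochanter midpoint height, `δ_θ`
the range of the neck–tail line pitch, and `δ_φ` the range of the
inter-segment angle. Two scale caveats are handled explicitly: the
inter-segment angle is the joint angle `2φ` (both scales are emitted,
as `delta_phi_half` and `delta_phi_joint`), and the midpoint proxy
sits `d cosθ sinφ` above the COM, so its range is a biased estimate of
the COM-height fluctuation (the same proxy bias is present in the
measured statistics).

The generator emulates one gallop stride: single-harmonic proxy
height, pitch and inter-segment angle (amplitudes default to half the
measured fluctuations 0.057 m, 0.20 rad, 0.47 rad, so truth = 2A per
channel), stride duration 0.32 s at 15 m/s, 101 samples (≈ 315 Hz,
typical of high-speed motion capture), fixed quarter-cycle phase
offsets between channels, and optional i.i.d. Gaussian marker noise,
deterministic per seed. The COM height compensates the proxy offset so
noise-free extraction is exact by construction. What it does *not*
emulate: multi-harmonic content of real strides, soft-tissue and
digitization artifacts with temporal correlation, marker dropout, or
stride-to-stride variability — so exact noise-free recovery shows the
extraction definitions are mutually consistent, not that real data
would be recovered exactly.

Raw max-minus-min ranges are biased upward by measurement noise (the
extreme of signal-plus-noise exceeds the signal extreme); at 5 mm
noise the bias reaches ≈ 18% on `δ_y`. `extract_characteristics`
therefore takes a `lowpass_hz` option — a zero-phase 4th-order
Butterworth, the standard pre-step for motion-capture kinematics —
default off so clean data are untouched. At the documented cutoff of
six times the stride frequency the 50-replicate mean recovers the
truth within ~3% per channel at 5 mm noise.

## Numerical choices and degenerate inputs

- Integrator DOP853, `rtol = atol = 1e−10`; horizon 3 s per cycle.
- Newton: damped (factor 0.5, ≤ 10 halvings), ≤ 50 iterations,
  residual tolerance 1e−10; singular Jacobians and infeasible energy
  closures raise typed errors that continuation records as per-point
  failures, never crashes.
- Tie-break: simultaneous events within 1e−12 s process
  touchdown-before-liftoff; grazing stances (< 1e−9 s) are degenerate
  failures.
- `φ = 0` exactly at a flight midpoint makes the type undefined
  (raised as an error); `|φ*| < 1e−9` makes the branch undefined.
- The energy closure rejects section states whose potential plus
  rotational energy exceeds `E`.

## Known limitations

- Massless legs, energy conservation, and identical fore/hind halves
  are structural idealizations; the fore/hind roles in
  acceleration/deceleration are reversed relative to real cheetahs,
  a known artifact of these assumptions.
- The spine spring is symmetric in flexion/extension; real spines are
  stiffer in hyperextension.
- Only period-one symmetric gaits are sought; asymmetric or
  period-doubled gaits, and the full two-parameter solution manifold,
  are out of scope.
- Branch-2 traces stop at the `|φ*| ≤ π/4` posture bound, not at a
  dynamical boundary; solutions beyond it exist mathematically but
  describe a self-folding trunk.
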