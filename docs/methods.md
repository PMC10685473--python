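# Methods

This note documents the model implemented by `footkin`, the choices made
where the design was genuinely open, and what the synthetic validation
does and does not establish.

## Coordinate conventions

The internal lab frame is right-handed with X along the walking
direction, Y vertical up, and Z to the subject's left. File axes are
remapped through a signed axis permutation in the trial configuration,
because motion-capture exporters disagree on the vertical axis. Markers
are kept in millimetres (the native unit of C3D-family data); conversion
to SI happens only inside the kinetics module.

## Segment frames

Each segment frame is built from an Origin point, a Long-Axis point and
a Plane point: `z = unit(long_axis − origin)`, `x = unit((plane −
origin) × z)`, `y = z × x`. The packaged definition table
(`footkin/data/segment_definitions.yaml`, user-overridable) lists, per
segment, those three points and fixed RX/RY/RZ attitude offsets.

Two conventions had to be fixed where the catalogue alone is ambiguous:

* **Offset rotation sense.** Offsets are applied as intrinsic rotations
  about the segment's own axes, in order X, Y, Z, rotating the attitude
  by −θ (equivalently: rotating the segment's coordinate data by +θ).
  This is the unique sense under which the catalogued offsets fulfil
  their purpose of bringing all foot segments into a common neutral
  orientation (x medio-lateral, y up, z anterior). With the opposite
  sense the forefoot and hallux frames come out flipped relative to the
  hindfoot. For this model only single RZ offsets are nonzero, so the
  X→Y→Z order is observationally irrelevant and documented for safety.
* **Medio-lateral direction.** For a right foot the construction yields
  x pointing to the subject's *right*; a frame with x left, y up and
  z anterior would be left-handed and cannot be produced by any proper
  rotation. Clinical signs are therefore applied at output (below)
  rather than baked into the axes.

The left-side table flips the sign of each RZ offset; left frames are
then exact mirror images of right frames (`F_left = S F_right D` with
`S = diag(1,1,−1)`, `D = diag(−1,1,1)`), which the test suite verifies.

The hindfoot long axis runs from the bottom-calcaneus marker to the
ankle joint centre and is therefore anterosuperior (~55° from the
horizontal), not anterior; the midfoot, forefoot and hallux long axes
are within ~15° of the walking direction in neutral stance.

**Shank reference.** The shank frame uses the knee-marker midpoint as
knee centre, the inter-malleolar midpoint as ankle centre, and the
lateral knee marker as plane point. A full lower-body marker model is
out of scope; using a foot-fixed ankle marker as the shank plane point
would slave the shank frame to the foot.

**A structural property worth knowing.** The forefoot frame takes its
Plane marker from the *midfoot* (NV) and the hallux frame takes its
Plane marker from the *forefoot* (23T). Consequently the long-axis
twist of these two segments is not independently measured: it is
determined by the parent segment through the plane construction. The
forefoot and hallux effectively contribute two rotational degrees of
freedom each (the direction of their long axis), which is consistent
with reporting only sagittal and transverse motion for the hallux. The
synthetic generator realises prescribed Lisfranc/first-MTP rotations
through the same plane projection and records the realised rotation as
ground truth; for the ankle and Chopart joints realised equals
prescribed exactly.

## Angles and sign conventions

Intersegmental rotation is distal relative to proximal,
`R_rel = R_parentᵀ R_child`, decomposed with the x–z–y Cardan sequence
(`R = Rx(α)·Rz(β)·Ry(γ)`; α sagittal, β frontal, γ transverse). The
extraction is closed-form (`β = asin(−R01)`, `α = atan2(R21, R11)`,
`γ = atan2(R02, R00)`) and is cross-checked against an independent
library implementation in the tests. Within 0.1° of the |β| = 90°
gimbal singularity a warning is emitted and angles are still returned;
the foot's frontal-plane excursions stay far from it.

Raw Cardan angles are mapped to clinical conventions by an explicit
sign table: the dorsiflexion-positive convention used for angle curves
(`dorsiflexion_positive`: dorsiflexion, inversion, internal rotation/abduction
positive) and the plantarflexion-positive convention used for moment
curves (`plantarflexion_positive`). The two differ only in the sagittal plane. The
sagittal factor is side-independent (mirroring a motion leaves the raw
x-rotation unchanged — conjugating `Rx` by the mirror is the identity),
while the frontal and transverse factors flip with side; mirrored
left-side trials therefore report identical clinical curves, which is
tested for both angles and moments.

Neutral-posture offsets are *not* subtracted by default — reported
angles are raw relative orientations, including each joint's anatomical
neutral decomposition. An optional static-calibration subtraction
(`static_offsets`) is available for labs that zero against a standing
trial.

## Filtering, events, normalization

* Markers: zero-phase Butterworth low-pass, 6 Hz cutoff, 2nd order run
  forward and backward (4th-order effective). Zero phase avoids event
  timing shifts. The cutoff is configurable; `None` disables.
* Ground reaction: an optional low-pass exists but is off by default.
  Plate records are decimated to the marker rate with a polyphase
  anti-alias FIR; the CoP, undefined off-contact, is instead linearly
  re-sampled within contact intervals only.
* Gaps: marker gaps of at most 5 frames are linearly interpolated
  before filtering; longer gaps in required markers are an error.
* Events: heel strike is the first sample with |vertical force| above
  20 N; toe off the first subsequent fall below 15 N (5 N hysteresis
  suppresses threshold chatter). The cycle ends at the next ipsilateral
  heel strike when the record contains one, otherwise it is extrapolated
  from a default stance fraction of 0.60.
* Normalization: curves are linearly interpolated onto exactly 101
  samples at 0–100% of the cycle. Orientation matrices, which cannot be
  linearly interpolated, are sampled nearest-frame onto the same grid
  when resolving moment components (axes change slowly at 60 Hz).

The MLA height/length ratio uses the 1MTH–BC distance as length and the
perpendicular distance of NV from that line as height; it is
dimensionless and invariant to rigid motion and uniform scaling.

## Anthropometrics and inverse dynamics

Defaults (all overridable, packaged as named constants):

| parameter | default | meaning |
|---|---|---|
| `foot_mass_fraction` | 0.0137 | foot mass / body mass |
| `toe_volume_fraction` (τ) | 0.08 | hallux share of foot volume |
| `radii_of_gyration` | (0.257, 0.245, 0.124) | per local axis (ml, vertical, longitudinal), fraction of segment length |

Masses: hindfoot `0.5(1−τ)`, midfoot and forefoot `0.25(1−τ)` each,
hallux `τ` of the foot mass, from the volumetric apportioning rule at
homogeneous density; Σ masses equals the foot mass by construction.
Centres of mass sit halfway along each segment long axis; inertia is
diagonal in the segment frame, `I = m·diag((r_k·L)²)`.

Joint centres are the distal chain origins of the frame table: ankle and
Chopart share the ankle joint centre (the midfoot's catalogued Origin),
Lisfranc uses MidNC, the first MTP uses 1MTH. The model equips these
joints with no other centres; note the ankle/Chopart coincidence means
their CPcross crossing indices coincide as well.

Per joint, the Newton–Euler free body comprises all segments distal to
it. COM accelerations and angular rates come from central finite
differences at the marker rate (angular velocity from the skew part of
`Ṙ Rᵀ`). The full single-plate ground reaction (force at the CoP plus
the free vertical moment, when channels permit computing it) loads every
joint's distal free body — no force partitioning is attempted with one
plate — and segment inertial and gravitational terms are retained.
Moments are resolved into the proximal segment's anatomical axes
(declared per segment in the definition table, since the shank's local
axes are permuted relative to the foot segments'), mass-normalized, and
signed per the moment convention. Power is `M · (ω_child − ω_parent) /
body mass` with everything in the lab frame.

**CPcross.** The crossing index of a joint is the first percent-cycle
sample at which the CoP is valid and lies anterior to the joint centre
along the progression axis (estimated from the horizontal heel-marker
displacement over stance). Samples before the crossing are flagged, not
altered; a joint the CoP never crosses is fully flagged with a warning.
For a monotone heel-to-toe CoP the crossing indices are non-decreasing
along the chain.

## CMC

The within-day coefficient of multiple correlation (Kadaba
formulation):

    R = sqrt( 1 − [Σ_{jt}(Y_jt − Ȳ_t)² / (T(M−1))] / [Σ_{jt}(Y_jt − Ȳ)² / (MT−1)] )

A flat ensemble (denominator ≈ 0, detected with a relative tolerance
against rounding) or a negative radicand yields `defined = False` rather
than a clamped value, so degenerate ensembles stay visible. Labels:
strong R ≥ 0.7 (the boundary is classified strong), moderate ≥ 0.3,
poor below. Test–retest ensembles across sessions use the same formula;
sessions are distinguished by the ensemble key, not by a different
estimator.

## The synthetic gait generator

The generator is the package's ground-truth instrument: a rigid shank
(constant forward speed, small vertical bob, ±8° sagittal tilt) carries
the four foot segments, each rotated relative to its parent by
prescribed per-plane waveforms. Waveforms are periodic cubic splines
through a handful of keypoints, rescaled so their range over the cycle
equals the requested range of motion exactly. Markers are rigidly
attached; each joint pivots about its distal frame Origin, which makes
the marker-derived frames reproduce the prescribed chain exactly
(modulo the forefoot/hallux plane-slaving noted above). Defaults
describe a healthy adult: 64 kg, 1.22 m/s, 1.31 m stride (cycle ≈
1.07 s), 60% stance, hallux sagittal ROM 37.3°, hindfoot 26.3°, midfoot
6.5° with the reversed sagittal trend, forefoot 14.2°, and an arch
whose height/length ratio stays within ~0.10–0.20 and reaches its
minimum shortly before toe-off. Neutral marker coordinates are
anatomically plausible placements for a ~250 mm adult foot.

The vertical force is `BW·(1.40 sin(πu) + 0.45 sin(3πu))` over stance
(u the stance fraction): a double-hump profile with ~1.3 BW peaks, a
~0.95 BW valley at midstance, and a stance-average within a few percent
of body weight. A half-sine series was preferred over raised-cosine
humps because its sharp onset keeps threshold-based event detection
within 1% of the prescribed stance timing. Anteroposterior and
mediolateral shears are small sine lobes (braking then propulsion); a
small free vertical moment is included; the mediolateral shear and free
moment mirror with side. The CoP is anchored to the moving foot and
eases from the heel marker to the hallux with `u^0.7` progression.
Marker noise, when requested, is seeded isotropic white Gaussian noise
added after exact generation.

The generator prescribes kinematics and ground reaction *independently*:
there is no forward-dynamics consistency between the motion and the
plate record. This is deliberate — the inverse-dynamics code is
validated against an independently coded per-frame free-body oracle on
the same inputs, which tests the implementation rather than the physical
plausibility of the scenario. Ground-truth moments therefore test
numerical agreement, not gait physiology.

What the generator does *not* emulate: soft-tissue artefact (marker
noise is white, real artefact is correlated and low-frequency), double
support on separate plates, marker occlusion/gaps, inter-subject
anatomy variation, or physically consistent GRFs. Passing the
round-trip tests shows the pipeline correctly inverts the model's
geometry and mechanics; it does not certify accuracy on real feet.

## Numerical choices

* Orthonormality of constructed frames: enforced to 1e-12 in tests;
  degenerate (collinear) marker triples yield NaN frames per frame and
  an error if every frame is degenerate.
* Cardan round trip: compose∘extract agrees to 1e-9° for |β| < 75°.
* Finite differences: `numpy.gradient` stencils (2nd-order central,
  one-sided at edges) for both the vectorised kinetics and the
  loop-based oracle, so the comparison isolates the free-body algebra.
* Inertia uses the time-mean segment length (constant for rigid data).
* CoP solving from raw plate channels treats the recorded force and
  moment as describing the same load about the plate origin; validity
  requires |vertical force| ≥ the 20 N contact threshold.
* Determinism: all stochastic paths (noise, repeatability simulations)
  take explicit seeds; reruns are bit-identical.

## Known limitations

* **Noise sensitivity of the small frames.** With 2 mm white marker
  noise (≈0.8 mm effective after the 6 Hz filter), frame-axis noise
  scales as noise/lever with inter-marker levers of only 25–45 mm on
  this marker set; midfoot-chain curves then carry up to ~3° RMS error,
  and the frontal/transverse hindfoot and midfoot curves are the most
  affected — the same axes that show the lowest repeatability in
  practice. Sub-degree recovery under such noise is not achievable with
  human-scale marker placements; at realistic optical noise levels
  (≤0.5 mm) all curves recover well under 1°.
* The ankle and Chopart joints share a centre by construction, so
  single-plate CPcross cannot separate their onset times.
* Swing-phase kinetics are the inertial-only solution (no external
  load), and the single-plate assumption overloads distal joints before
  their CPcross crossing — which is exactly the motivation for
  reporting the masked variant alongside the unmasked one.
* The CLI manifest records wall-clock timestamps; determinism claims
  apply to the data outputs (CSV/JSON results), not the manifest file.
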