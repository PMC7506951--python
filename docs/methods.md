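# Methods

This note documents the models, conventions and design choices behind
`poserehab`, and what its synthetic experiments do and do not show.

## Pose representation and distance

A limb pose is four joint angles in radians: shoulder rotation (azimuth of
the upper arm about the torso's downward axis, measured from the frontal
plane), shoulder opening (elevation of the upper arm away from the torso
axis), elbow rotation (forearm rotation about the upper-arm axis) and elbow
opening (interior shoulder–elbow–wrist angle; π = straight arm). Angles are
validated against an anatomical envelope (default [−π, π]; openings are
non-negative in the simulator's tighter per-joint envelopes).

The pose distance is `d = 1 − 1/(1 + D)` with `D = Σ (Δaᵢ)²` over the four
angles. `d` lies in [0, 1), is zero iff the poses coincide, is symmetric, and
is strictly increasing in any single |Δa|. Two variants are shipped behind
`formula`:

* `as_printed` (default): `D` is the raw sum of squared differences;
* `euclidean`: `D = √Σ(Δa)²`, the literal Euclidean norm.

The two readings coexist because the flattened formula and its textual
description ("normalised Euclidean distance") disagree; both agree at
`D = 1` (a single 1-rad error gives `d = 0.5` either way), so the worked
values used in tests discriminate the variants only through multi-angle
cases. Neither is asserted to be the "true" intent; the as-printed form is
the default. Radians are used throughout: with degrees the 0.28–0.4
threshold band would demand sub-degree imitation accuracy, which is not
plausible for children.

Skeleton-to-angle conversion (`angles_from_skeleton`) uses a torso frame
derived from the shoulder-centre and spine reference points (downward axis)
and the global +y direction (frontal axis). The convention is fixed by the
forward construction `skeleton_from_angles` and is exactly invertible away
from the gimbal configurations (arm colinear with the torso axis, fully
straight elbow), where the azimuthal angles are defined as 0. Output is
invariant under global translation and uniform scaling; global rotation is
not a claimed invariance because the frontal reference is a fixed world
axis. Degenerate (zero-length) segments raise a dedicated error.

## Session engine

Time is simulated in discrete ticks at 10 Hz; "hold for 2 s" means 20
consecutive in-tolerance ticks inside a 40-tick (4 s) attempt window. This
makes runs exactly reproducible and makes the hold requirement a simple run
length.

An attempt is *accepted* when **both** limbs stay within the shared θ
simultaneously for a full hold: the threshold governs the whole body pose,
while monitoring and QUEST extraction treat limbs individually (the per-limb
`held` mask in the angle record marks runs where that limb alone sustained
tolerance — a patient with one impaired arm still earns range-of-motion
credit for the healthy arm on a failed pose).

Threshold dynamics: θ starts at 0.28 and lives in [0.28, 0.4]. Updates are
applied once per pose, after its outcome: ×1.02 on a skip, ×0.98 on a
first-attempt success, unchanged on a later success, clamped to the band.
The multiplicative reading of "2 %" is the default; an additive ±0.02
variant exists behind `update_mode="additive"` but traverses the whole band
in six steps, which is inconsistent with gradual session trajectories.
A success on attempt 2 or 3 deliberately leaves θ unchanged — only the two
extreme outcomes are specified behaviour.

Responder failures abort the session with the partial log flagged
incomplete; an empty attempt trajectory is simply an incorrect attempt
(vacuous hold). Distraction events reported by the simulator are logged;
no replanning is attempted (therapy-level planning is out of scope).

## Synthetic patient

The simulator stands in for the child and the motion-capture stack. Per
attempt it emits a two-limb trajectory: `reaction_ticks` (default 3) at a
rest pose (arms down), a 6-tick linear ramp to the target clamped into the
limb's range of motion (ROM), then holding with independent zero-mean
Gaussian jitter per joint per tick, clamped back into the ROM. The jitter
s.d. on attempt *k* is `noise_scale · (1 − learning_rate)^(k−1)`, a simple
model of within-pose learning. With probability `distraction_probability`
an attempt is non-compliant: the patient ramps instead to a far posture
(every joint shifted 1 rad toward the roomier envelope side, guaranteeing a
per-limb distance ≈ 0.8, well above the tolerance ceiling). The probability
is applied independently per attempt, since the simulator is invoked once
per attempt.

Presets (`unimpaired`, `right_arm_deficit`, `dystonia_like`,
`global_impairment`) qualitatively mimic common impairment patterns:
one-sided ROM restriction, high slowly-improving tremor, and bilateral
restriction. Their parameters are plausibility choices for exercising the
session dynamics — more skips and a rising θ under impairment, clean
first-attempt runs without — **not** estimates of any real patient, and no
claim of biomechanical or clinical validity attaches to them. Real data
differ in ways the simulator does not model: correlated multi-joint errors,
fatigue, intermittent tracking dropouts, and therapist interaction.

The pose library is a set of 13 named, reachable arm postures (forward
reach, T-pose, overhead, elbow bends, …) used both for session plans and as
classifier targets; it includes deep elbow flexion and near-full extension
so every QUEST item criterion is attainable by some posture.

## QUEST scoring

Only the four dissociated-movement items observable from shoulder/elbow
angles are scored, per limb. Item definitions over held samples:

| item | defining angle | default criterion |
| --- | --- | --- |
| shoulder flexion | opening · cos(rotation), floored at 0 | ≥ π/2 |
| shoulder abduction | opening · \|sin(rotation)\| | ≥ π/2 |
| elbow flexion | π − elbow opening | ≥ 3π/4 |
| elbow extension | elbow opening | ≥ 17π/18 |

The azimuthal decomposition attributes shoulder elevation to its forward
(sagittal) and lateral (frontal) components. "Held" is taken from the
session engine's per-limb tick record, not re-derived. Criterion angles are
configuration with the defaults above (full-range readings of the QUEST
items); the cut-offs used by any deployed clinical system are not claimed
to match. Scoring: 2 if the criterion was reached during a held sample,
1 otherwise (covering both "could not complete" and "not tested"). Raw
points over 8 items span [8, 16]; the normalized score is the affine map
`100·(raw − 8)/8`, reported alongside the raw points since the original
point-counting convention is not fixed here. Overrides replace an item
score, are recorded with a note, and totals are recomputed from items, so
the normalization identity always holds.

## Pose-correctness classifier

Features are the 4 expected + 4 achieved angles of one limb; labels come
from the explicit oracle `d(achieved, expected) ≤ θ` at fixed θ = 0.28
(inclusive boundary, matching the session rule). Trees are
`DecisionTreeClassifier(criterion="entropy")` with `min_samples_leaf` as the
single complexity control — the information-gain family with leaf-size
pruning only. Every leaf yields one rule (conjunction of axis-aligned angle
inequalities); rule-list classification is exactly equivalent to the tree
and is the serialized model format, keeping the artifact inspectable by a
therapist.

The synthetic corpus draws expected angles from the pose library and
achieved angles as expected + Gaussian noise, with a per-example noise s.d.
drawn uniformly from {0.05, 0.15, 0.35, 0.7} rad — spanning near-perfect
imitation, typical attempts, impaired reaches and non-compliance. If a
custom mixture yields a class balance outside [20 %, 80 %], the corpus is
regenerated once with a widened mixture and a warning. The experiment
protocol is a 6600-example corpus, random 50/50 train/test split, and means
over 20 runs, swept over the minimum-objects-per-leaf parameter.

On this corpus the default protocol (min 30 objects per leaf) measures a
mean held-out accuracy of ≈ 88–89 %; unconstrained trees reach ≈ 92 %. The
gap is a property of the chosen noise mixture: the 0.35-rad component sits
almost exactly on the θ = 0.28 decision boundary, concentrating mass where
a leaf-limited axis-aligned partition is weakest. The corresponding test
asserting the >90 % figure is therefore expected to fail under these study
conditions; the mixture was fixed on realism grounds and deliberately not
retuned to the outcome. Accuracy on a synthetic corpus is in any case a
surrogate — it measures how well a shallow tree mimics a known analytic
rule under this noise model, not performance on real patient data.

## Numerical choices and degenerate inputs

* Threshold clamping happens after the update; boundary comparisons
  (`d ≤ θ`, criterion `achieved ≥ cut-off`) are inclusive as specified.
* Angle CSVs are written with 17 significant digits and parsed with
  pandas' round-trip float precision so logs round-trip bit-exactly.
* Session logs are JSON-lines (header, one line per pose, events) with a
  companion CSV of per-tick angles; both have readers and writers and
  byte-identical reruns under a fixed seed are tested.
* Every stochastic draw flows from one named seed; the pipeline fans a
  master seed into per-stage seeds (< 2³¹) via named `SeedSequence`
  substreams recorded in the run manifest.
* Problem sizes in the default test and acceptance runs (sessions of
  10–40 poses, 6600-example corpora, 20-run averages) match the experiment
  protocol while keeping a full run in minutes on one CPU.

## Known limitations

* No real sensing: skeletons are synthetic, and the skeleton-angle
  convention, while self-consistent and invertible, is one of several
  defensible conventions.
* The simulator's Gaussian, per-joint-independent noise is a deliberate
  simplification; passing tests demonstrate the engine's logic, not
  clinical behaviour.
* Only the dissociated-movements section of QUEST is scored; grasp, weight
  bearing and protective extension need hand tracking and physical
  interaction outside this scope.
* Left/right accuracy differences reported for real cohorts are data
  properties and are not reproduced by the symmetric synthetic corpus.
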