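# poserehab

A hardware-free toolkit for **adaptive pose-imitation therapy** in paediatric
upper-limb rehabilitation. In robot- or coach-guided sessions a child is asked
to imitate a sequence of arm postures; `poserehab` implements the
computational core of such a system — pose evaluation, difficulty adaptation,
automatic clinical scoring and an explainable pose classifier — driven by a
synthetic patient simulator instead of a robot and depth camera, so every
component runs and is testable offline.

## What it computes

**Pose distance.** Each upper limb is described by four joint angles
*a₁…a₄* ∈ {shoulder rotation, shoulder opening, elbow rotation, elbow
opening} (radians). The mismatch between the imitated (*human*) and requested
(*robot*) posture is

    d(a_human, a_robot) = 1 − 1 / (1 + Σᵢ (aᵢ_human − aᵢ_robot)²)

normalized into [0, 1); a Euclidean variant that takes √ of the sum is
available behind `formula="euclidean"`. A pose is *correct* when `d ≤ θ`.

**Adaptive threshold.** The tolerance θ ∈ [0.28, 0.4] starts at the strict
end, 0.28. The patient gets three attempts per posture and must hold it for
at least two seconds (simulated at 10 Hz). After each posture θ adapts:
+2 % when the pose was abandoned (skipped) after three failed attempts,
−2 % when it succeeded on the first attempt, unchanged otherwise, always
clamped to the band. The session log records every attempt, distance, raw
angle sample and the θ trajectory.

**QUEST scoring.** From the raw angle record the package scores the four
dissociated-movement items of the Quality of Upper Extremity Skills Test
per limb (shoulder flexion, shoulder abduction, elbow flexion, elbow
extension): 2 points when the criterion angle was reached during a held
posture, 1 point when the movement could not be completed or tested. Raw
points span [8, 16]; a normalized score maps that to [0, 100]. Therapist
overrides are recorded and totals recomputed.

**Explainable pose classifier.** A decision tree (entropy splits,
scikit-learn compatible estimator `PoseCorrectnessTree`) learns the
distance-threshold judgement from the eight raw angles (4 expected +
4 achieved). Complexity is controlled only by the minimum number of objects
per leaf; any fitted tree flattens into human-readable rules
(`IF achieved_shoulder_opening <= 1.23 AND … -> incorrect`) that reproduce
its predictions exactly.

## Worked example

```bash
poserehab make-fixtures --out-dir demo --n-poses 12 --preset right_arm_deficit --seed 7
poserehab run-session --plan demo/plan.yaml --profile demo/profile.yaml \
    --seed 7 --out demo/log.jsonl --angles-out demo/angles.csv --verbose
```

```
pose   0 pose-000-touch_shoulders     attempts=1 accepted theta=0.2800
pose   1 pose-001-right_forward       attempts=3 skipped  theta=0.2856
pose   2 pose-002-right_forward       attempts=3 skipped  theta=0.2913
pose   3 pose-003-t_pose              attempts=3 skipped  theta=0.2971
pose   4 pose-004-left_side_raise     attempts=1 accepted theta=0.2912
...
12 poses, 9 skipped, final theta 0.3214 -> demo/log.jsonl
```

The simulated patient has a right-arm range-of-motion deficit (shoulder
elevation capped at 0.9 rad): postures within reach are accepted on the first
attempt and tighten θ by 2 %; postures demanding the impaired shoulder are
skipped after 3 attempts and relax θ by 2 %, so the tolerance drifts up from
0.28 toward its 0.4 ceiling.

```bash
poserehab quest-report --log demo/log.jsonl --angles demo/angles.csv --out demo/report.json
# raw points 13/16, normalized 62.5 -> demo/report.json
```

The left limb earns 2 points on most items; the right shoulder items score 1
because the capped shoulder never reached the π/2 criterion — exactly the
asymmetry the profile encodes.

```bash
poserehab train-pose-tree --n-examples 6600 --min-leaf 30 --runs 20 --seed 7 --out demo/model.json
# mean held-out accuracy over 20 runs: 88.66% (47 rules) -> demo/model.json
```

Trains the pose-correctness tree on a 6600-example oracle-labelled corpus
(random 50/50 split, 20 runs) and exports the rule-list model. `poserehab
sweep` tabulates the accuracy/tree-size trade-off over a range of leaf sizes,
and `poserehab run-pipeline --config demo/pipeline.yaml` chains
plan → session → report → classifier with a reproducibility manifest
(input digests, per-stage seeds).

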