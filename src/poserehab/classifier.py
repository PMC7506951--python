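"""Explainable pose-correctness classification.

A decision tree learns to reproduce the distance-threshold judgement of
pose correctness from the raw angles alone.  Each example carries eight
features — the four expected (requested) joint angles and the four achieved
(imitated) ones — and a binary label assigned by the explicit oracle rule
``pose_distance(achieved, expected) <= theta``.  Trees are grown with
entropy (information-gain) splits; complexity is controlled solely through
the minimum number of training objects a leaf may hold, and every trained
tree can be flattened into an ordered list of human-readable rules that
reproduce its predictions exactly.

The experiment protocol mirrors the original study: a 6600-example corpus,
a random 50/50 train/test split, accuracy averaged over 20 runs, and a
sweep over the minimum-objects-per-leaf parameter trading accuracy against
tree size.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .kinematics import ANGLE_NAMES, FormulaFlag, JointAngles, pose_distance
from .simulate import JOINT_ENVELOPES, POSE_LIBRARY

__all__ = [
    "FEATURE_NAMES",
    "PoseExample",
    "ClassifierDataset",
    "PoseCorrectnessTree",
    "Rule",
    "label_with_oracle",
    "generate_training_corpus",
    "train_tree",
    "sweep_min_leaf",
    "extract_rules",
    "apply_rules",
    "rules_to_json",
    "rules_from_json",
]

#: Feature order: the four expected angles then the four achieved angles.
FEATURE_NAMES = tuple(f"expected_{n}" for n in ANGLE_NAMES) + tuple(f"achieved_{n}" for n in ANGLE_NAMES)

LABELS = ("correct", "incorrect")


def label_with_oracle(
    expected: JointAngles,
    achieved: JointAngles,
    theta: float,
    formula: FormulaFlag = "as_printed",
) -> str:
    """Ground-truth label from the explicit distance rule (inclusive boundary)."""
    return "correct" if pose_distance(achieved, expected, formula) <= theta else "incorrect"


@dataclass(frozen=True)
class PoseExample:
    """One labelled example: expected vs achieved angles of a single limb."""

    expected: JointAngles
    achieved: JointAngles
    label: str
    side: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def features(self) -> np.ndarray:
        return np.concatenate([self.expected.as_array(), self.achieved.as_array()])


@dataclass
class ClassifierDataset:
    """A single-limb corpus plus its labelling provenance (theta, seed)."""

    examples: list[PoseExample]
    side: str
    theta: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(e.side != self.side for e in self.examples):
            raise ValueError("all examples in a dataset must share one side")

    def __len__(self) -> int:
        return len(self.examples)

    def features(self) -> np.ndarray:
        return np.array([e.features() for e in self.examples])

    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.examples])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features(), columns=list(FEATURE_NAMES))
        df["side"] = self.side
        df["label"] = self.labels()
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, theta: float) -> "ClassifierDataset":
        df = pd.read_csv(path)
        side = str(df["side"].iloc[0])
        examples = [
            PoseExample(
                expected=JointAngles.from_array(row[:4]),
                achieved=JointAngles.from_array(row[4:8]),
                label=lbl,
                side=side,
            )
            for row, lbl in zip(df[list(FEATURE_NAMES)].to_numpy(), df["label"])
        ]
        return cls(examples=examples, side=side, theta=theta)


def _sample_achieved(expected: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    noisy = expected + rng.normal(0.0, scale, size=4)
    lo = np.array([JOINT_ENVELOPES[n][0] for n in ANGLE_NAMES])
    hi = np.array([JOINT_ENVELOPES[n][1] for n in ANGLE_NAMES])
    return np.clip(noisy, lo, hi)


#: Per-example noise scales (rad) spanning near-perfect imitation (0.05),
#: typical attempts (0.15), impaired reaches (0.35) and non-compliance (0.7).
DEFAULT_NOISE_SCALES = (0.05, 0.15, 0.35, 0.7)


def generate_training_corpus(
    n: int,
    theta: float = 0.28,
    noise_scales: tuple[float, ...] = DEFAULT_NOISE_SCALES,
    seed: int = 0,
    side: str = "right",
    formula: FormulaFlag = "as_printed",
) -> ClassifierDataset:
    """Synthesize an oracle-labelled pose corpus.

    Expected angles are drawn from the pose library; achieved angles add
    per-joint Gaussian noise whose per-example scale is drawn uniformly from
    ``noise_scales`` so that both classes occur.  If the class balance falls
    outside [20%, 80%] the corpus is regenerated once with an extra extreme
    scale appended and a warning is emitted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    def _generate(scales: tuple[float, ...], gen_seed: int) -> ClassifierDataset:
        rng = np.random.default_rng(gen_seed)
        names = sorted(POSE_LIBRARY)
        examples = []
        for _ in range(n):
            name = names[int(rng.integers(len(names)))]
            expected = POSE_LIBRARY[name][0 if side == "left" else 1].as_array()
            scale = float(scales[int(rng.integers(len(scales)))])
            achieved = _sample_achieved(expected, scale, rng)
            e = JointAngles.from_array(expected)
            a = JointAngles.from_array(achieved)
            examples.append(PoseExample(expected=e, achieved=a, label=label_with_oracle(e, a, theta, formula), side=side))
        return ClassifierDataset(examples=examples, side=side, theta=theta, seed=gen_seed)

    ds = _generate(noise_scales, seed)
    frac = float(np.mean(ds.labels() == "correct"))
    if not 0.2 <= frac <= 0.8:
        warnings.warn(
            f"class balance {frac:.2f} outside [0.2, 0.8]; regenerating with widened noise mixture",
            stacklevel=2,
        )
        widened = tuple(noise_scales) + ((1.2,) if frac > 0.8 else (0.02,))
        ds = _generate(widened, seed + 1)
    return ds


class PoseCorrectnessTree(ClassifierMixin, BaseEstimator):
    """Decision-tree pose-correctness classifier (entropy splits).

    A scikit-learn-compatible estimator over the 8 angle features.  The only
    complexity control is ``min_objects_per_leaf`` — the smallest number of
    training examples any leaf may hold — matching the protocol under which
    the model family was evaluated.  No other pruning is applied.

    Attributes (after :meth:`fit`)
    ------------------------------
    tree_ : DecisionTreeClassifier
        The fitted sklearn tree.
    classes_ : ndarray
        Class labels.
    node_count_ : int
        Total number of nodes (internal + leaves); odd for a binary tree.
    n_leaves_ : int
        Number of leaves, equal to the number of extractable rules.
    """

    def __init__(self, min_objects_per_leaf: int = 30, random_state: int | None = None):
        self.min_objects_per_leaf = min_objects_per_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"X must have {len(FEATURE_NAMES)} feature columns")
        if self.min_objects_per_leaf < 1:
            raise ValueError("min_objects_per_leaf must be >= 1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.tree_ = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=self.min_objects_per_leaf,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.tree_.classes_
        self.node_count_ = int(self.tree_.tree_.node_count)
        self.n_leaves_ = int(self.tree_.get_n_leaves())
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        return self.tree_.predict(np.asarray(X, dtype=float))


def train_tree(
    dataset: ClassifierDataset,
    min_objects_per_leaf: int = 30,
    split_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[PoseCorrectnessTree, float]:
    """Train on a random split and return (model, held-out accuracy)."""
    X, y = dataset.features(), dataset.labels()
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, train_size=split_fraction, random_state=seed, shuffle=True)
    model = PoseCorrectnessTree(min_objects_per_leaf=min_objects_per_leaf, random_state=seed).fit(X_tr, y_tr)
    accuracy = float(np.mean(model.predict(X_te) == y_te))
    return model, accuracy


def sweep_min_leaf(
    dataset: ClassifierDataset,
    leaf_values: list[int],
    runs: int = 20,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Accuracy/size trade-off over the minimum-objects-per-leaf parameter.

    For each leaf value, ``runs`` independent splits are trained and the
    mean held-out accuracy and mean tree size (node count) reported — the
    table behind the two monitoring curves of the original experiment.
    """
    if not leaf_values:
        raise ValueError("leaf_values must be non-empty")
    if list(leaf_values) != sorted(leaf_values):
        raise ValueError("leaf_values must be ascending")
    rows = []
    for leaf in leaf_values:
        accs, sizes = [], []
        for r in range(runs):
            model, acc = train_tree(dataset, min_objects_per_leaf=leaf, seed=base_seed + r)
            accs.append(acc)
            sizes.append(model.node_count_)
        rows.append(
            {
                "min_objects_per_leaf": leaf,
                "mean_accuracy": float(np.mean(accs)),
                "mean_tree_size": float(np.mean(sizes)),
                "runs": runs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rule extraction


@dataclass(frozen=True)
class Rule:
    """One leaf as a conjunction of angle inequalities implying a label."""

    conditions: tuple[tuple[str, str, float], ...]  # (feature, "<=" or ">", threshold)
    label: str
    n_samples: int = 0

    def matches(self, x: np.ndarray) -> bool:
        idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
        for feat, op, thr in self.conditions:
            v = x[idx[feat]]
            if op == "<=" and not v <= thr:
                return False
            if op == ">" and not v > thr:
                return False
        return True

    def __str__(self) -> str:
        if not self.conditions:
            return f"ALWAYS -> {self.label}"
        conds = " AND ".join(f"{f} {op} {thr:.4f}" for f, op, thr in self.conditions)
        return f"IF {conds} -> {self.label}"


def extract_rules(model: PoseCorrectnessTree) -> list[Rule]:
    """Flatten a fitted tree into one rule per leaf (left-to-right order).

    Applying the rules reproduces the tree's predictions exactly on any
    input; the rule list is the explainability artifact handed to a
    therapist.
    """
    check_is_fitted(model, "tree_")
    t = model.tree_.tree_
    classes = model.classes_
    rules: list[Rule] = []

    def walk(node: int, conds: tuple[tuple[str, str, float], ...]) -> None:
        if t.children_left[node] == -1:  # leaf
            label = str(classes[int(np.argmax(t.value[node]))])
            rules.append(Rule(conditions=conds, label=label, n_samples=int(t.n_node_samples[node])))
            return
        feat = FEATURE_NAMES[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + ((feat, "<=", thr),))
        walk(t.children_right[node], conds + ((feat, ">", thr),))

    walk(0, ())
    return rules


def apply_rules(rules: list[Rule], X) -> np.ndarray:
    """Classify rows of X with an extracted rule list (first match wins)."""
    X = np.asarray(X, dtype=float)
    out = []
    for x in X:
        for rule in rules:
            if rule.matches(x):
                out.append(rule.label)
                break
        else:
            raise ValueError("no rule matched; rule list is not exhaustive")
    return np.array(out)


def rules_to_json(rules: list[Rule], min_objects_per_leaf: int | None = None) -> str:
    """Serialize a rule list as versioned JSON — the shipped model format."""
    doc = {
        "schema_version": 1,
        "feature_names": list(FEATURE_NAMES),
        "min_objects_per_leaf": min_objects_per_leaf,
        "rules": [dataclasses.asdict(r) for r in rules],
    }
    return json.dumps(doc, indent=2)


def rules_from_json(text: str) -> list[Rule]:
    doc = json.loads(text)
    return [
        Rule(
            conditions=tuple((f, op, float(thr)) for f, op, thr in r["conditions"]),
            label=r["label"],
            n_samples=int(r.get("n_samples", 0)),
        )
        for r in doc["rules"]
    ]
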