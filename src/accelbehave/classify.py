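"""Random-forest behaviour classification, metrics, and a rule-tree baseline.

The forest follows the study design throughout: 500 classification trees,
three candidate predictors per split, terminal nodes of at least five
training records and internal splits of at least ten.  Accuracy is reported
per behaviour as precision, recall and F-measure, with unweighted macro
means and their standard error over classes, plus the out-of-bag (OOB) error
and the mean-decrease-in-Gini variable ranking.

The rule tree is a hand-editable ordered list of threshold rules — the
manual classification method the forest is compared against.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion

from .features import FeatureFrame

_NON_PREDICTORS = ("time_s", "individual_id", "bout_id", "behaviour")


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 500
    predictors_per_split: int = 3
    min_node_train: int = 5    # minimum terminal-node size while growing trees
    min_node_predict: int = 10  # minimum node size eligible for a further split
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.predictors_per_split < 1:
            raise ValueError("predictors_per_split must be >= 1")


@dataclass
class GiniRanking:
    """Variables ordered by mean decrease in Gini impurity (descending)."""

    ranking: list[tuple[str, float]]

    def __post_init__(self) -> None:
        values = [g for _, g in self.ranking]
        if any(b > a + 1e-12 for a, b in zip(values, values[1:])):
            raise ValueError("ranking must be non-increasing")

    @property
    def variables(self) -> list[str]:
        return [v for v, _ in self.ranking]


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    variables: list[str]
    classes: list[str]
    config: RFConfig
    oob_error_pct: float
    gini: GiniRanking


def _predictor_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c not in _NON_PREDICTORS]


def train_rf(train_records: pd.DataFrame, cfg: RFConfig = RFConfig(),
             variables: list[str] | None = None) -> TrainedModel:
    """Fit a bagged classification forest on labelled feature records.

    Ties in the across-tree vote break to the lowest class index
    (alphabetical behaviour order), independent of the seed.
    """
    variables = variables or _predictor_columns(train_records)
    y = train_records["behaviour"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if not 1 <= cfg.predictors_per_split <= len(variables):
        raise ValueError("predictors_per_split must be within the variable count")
    X = train_records[variables].to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.predictors_per_split,
        min_samples_leaf=cfg.min_node_train,
        min_samples_split=cfg.min_node_predict,
        bootstrap=True, oob_score=True, n_jobs=1,
        random_state=cfg.seed % (2 ** 31))
    forest.fit(X, y)
    oob_error_pct = float((1.0 - forest.oob_score_) * 100.0)
    order = np.argsort(-forest.feature_importances_, kind="stable")
    gini = GiniRanking([(variables[i], float(forest.feature_importances_[i]))
                        for i in order])
    return TrainedModel(forest, list(variables), list(forest.classes_), cfg,
                        oob_error_pct, gini)


def predict_rf(model: TrainedModel, records: pd.DataFrame) -> np.ndarray:
    """Plurality vote of the ensemble for each record."""
    missing = [v for v in model.variables if v not in records.columns]
    if missing:
        raise ValueError(f"records are missing model variable(s): {missing}")
    X = records[model.variables].to_numpy(dtype=float)
    return model.forest.predict(X)


# ---------------------------------------------------------------------------
# evaluation


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassMetrics:
    """Per-behaviour precision/recall/F with macro means and SEMs.

    Undefined entries (a behaviour never predicted, or absent from the test
    set) are NaN — reported as N/A — and excluded from the macro rows.
    The SEM is the k-1 sample standard deviation over classes divided by
    the square root of the class count.
    """

    confusion: pd.DataFrame
    precision: dict[str, float]
    recall: dict[str, float]
    f: dict[str, float]
    oob_error_pct: float | None = None

    def _macro(self, values: dict[str, float]) -> tuple[float, float]:
        arr = np.array([v for v in values.values() if not math.isnan(v)])
        if arr.size == 0:
            return float("nan"), float("nan")
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        return float(arr.mean()), sem

    @property
    def macro_precision(self) -> float:
        return self._macro(self.precision)[0]

    @property
    def macro_recall(self) -> float:
        return self._macro(self.recall)[0]

    @property
    def macro_f(self) -> float:
        return self._macro(self.f)[0]

    @property
    def sem_precision(self) -> float:
        return self._macro(self.precision)[1]

    @property
    def sem_recall(self) -> float:
        return self._macro(self.recall)[1]

    @property
    def sem_f(self) -> float:
        return self._macro(self.f)[1]

    def macro_f_over(self, behaviours, missing_as: float = 0.0) -> float:
        """Mean F over the given behaviours, scoring N/A entries as ``missing_as``.

        Unlike the table-style macro rows (which drop N/A, as printed
        reports do), this treats a behaviour the model never identifies as a
        failure — the right accounting when ranking model quality.
        """
        vals = [missing_as if (b not in self.f or math.isnan(self.f[b]))
                else self.f[b] for b in behaviours]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def macro_f_complete(self) -> float:
        """Macro F over every class in the confusion matrix, N/A scored as 0."""
        return self.macro_f_over(list(self.confusion.index))

    def to_frame(self) -> pd.DataFrame:
        rows = [(b, self.precision[b], self.recall[b], self.f[b])
                for b in self.precision]
        df = pd.DataFrame(rows, columns=["behaviour", "precision", "recall",
                                         "f_measure"])
        df.loc[len(df)] = ("MEAN", self.macro_precision, self.macro_recall,
                           self.macro_f)
        df.loc[len(df)] = ("SEM", self.sem_precision, self.sem_recall, self.sem_f)
        return df


def evaluate(pred: np.ndarray, true: np.ndarray,
             labels: list[str] | None = None,
             oob_error_pct: float | None = None) -> ClassMetrics:
    """Confusion matrix and per-class precision/recall/F-measure."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ")
    if labels is None:
        labels = sorted(set(true) | set(pred))
    cm = _sk_confusion(true, pred, labels=labels)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f: dict[str, float] = {}
    for i, b in enumerate(labels):
        tp = float(cm[i, i])
        fp = float(cm[:, i].sum() - tp)
        fn = float(cm[i, :].sum() - tp)
        p = tp / (tp + fp) if tp + fp > 0 else float("nan")
        r = tp / (tp + fn) if tp + fn > 0 else float("nan")
        precision[b] = p
        recall[b] = r
        f[b] = f_measure(p, r) if not (math.isnan(p) or math.isnan(r)) else float("nan")
    return ClassMetrics(confusion, precision, recall, f, oob_error_pct)


# ---------------------------------------------------------------------------
# rule tree


_RULE_RE = re.compile(
    r"^\s*(?P<var>\w+)\s*(?P<op>[<>]=?)\s*(?P<thr>[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)"
    r"\s*->\s*(?P<label>\w+)\s*$")
_ELSE_RE = re.compile(r"^\s*else\s*->\s*(?P<label>\w+)\s*$")

_OPS = {"<": np.less, "<=": np.less_equal, ">": np.greater, ">=": np.greater_equal}


@dataclass
class RuleTree:
    """Ordered threshold rules; the first matching rule labels a record.

    The text form is one rule per line, ``<variable> <op> <threshold> ->
    <behaviour>``, closed by a mandatory ``else -> <behaviour>`` line that
    makes the tree total.  Blank lines and ``#`` comments are ignored.
    """

    rules: list[tuple[str, str, float, str]]
    default: str

    @classmethod
    def parse(cls, text: str) -> "RuleTree":
        rules: list[tuple[str, str, float, str]] = []
        default: str | None = None
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if default is not None:
                raise ValueError(f"line {lineno}: rules after the else line")
            m = _ELSE_RE.match(line)
            if m:
                default = m["label"]
                continue
            m = _RULE_RE.match(line)
            if not m:
                raise ValueError(f"line {lineno}: cannot parse rule {line!r}")
            rules.append((m["var"], m["op"], float(m["thr"]), m["label"]))
        if default is None:
            raise ValueError("rule tree needs a final 'else -> <behaviour>' line")
        return cls(rules, default)

    def to_text(self) -> str:
        lines = [f"{v} {op} {thr:g} -> {lab}" for v, op, thr, lab in self.rules]
        lines.append(f"else -> {self.default}")
        return "\n".join(lines) + "\n"

    def validate(self, variables) -> None:
        unknown = [v for v, _, _, _ in self.rules if v not in variables]
        if unknown:
            raise ValueError(f"rules reference unknown variable(s): {unknown}")


#: thresholds tuned on the default synthetic calibration set; edit freely.
#: the narrow trot band reflects how heavily walk/trot/run amplitudes overlap
DEFAULT_RULE_TREE_TEXT = """\
# manual behaviour classification: first matching rule wins
Pitch < -27 -> feed
Roll > 1.5 -> groom
Roll < -1.5 -> groom
VeDBAs < 0.08 -> rest
VeDBAs >= 1.05 -> shake
VeDBAs >= 0.40 -> run
VeDBAs >= 0.36 -> trot
else -> walk
"""


def default_rule_tree() -> RuleTree:
    return RuleTree.parse(DEFAULT_RULE_TREE_TEXT)


def classify_rule_tree(frame: FeatureFrame | pd.DataFrame,
                       tree: RuleTree) -> np.ndarray:
    """Deterministic per-record labels by first matching rule."""
    df = frame.data if isinstance(frame, FeatureFrame) else frame
    tree.validate(df.columns)
    n = len(df)
    out = np.full(n, None, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for var, op, thr, label in tree.rules:
        hit = unassigned & _OPS[op](df[var].to_numpy(dtype=float), thr)
        out[hit] = label
        unassigned &= ~hit
    out[unassigned] = tree.default
    return out
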