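"""Random-forest classification of the seven major B-NHL subtypes.

The predictor discriminates ABC DLBCL, GCB DLBCL, PMBL, FL, MCL, SLL and a
merged MZL category (nodal/splenic MZL, MALT and LPL) from gene-level
normalised expression of the marker panel.  The forest uses the Gini
split criterion with ``max_depth=20`` and ``min_samples_split=4`` and, by
default, 5000 trees; remaining hyperparameters are the scikit-learn
defaults (sqrt(n_features) candidate features per split, bootstrap
resampling).  Class probabilities are reported as the fraction of trees
voting for each class, and the call is the argmax with ties broken by the
canonical label order below.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

#: canonical label order; also the argmax tie-break order
SUBTYPES = ("ABC", "GCB", "PMBL", "FL", "MCL", "SLL", "MZL")

#: diagnoses merged into the MZL category on load
LABEL_ALIASES = {"MALT": "MZL", "LPL": "MZL"}

TRAIN, VALIDATION = "TRAIN", "VALIDATION"


class CohortError(ValueError):
    pass


def canonicalize_label(label: str) -> str:
    label = LABEL_ALIASES.get(label, label)
    if label not in SUBTYPES:
        raise CohortError(f"unknown subtype label {label!r}")
    return label


@dataclass
class LabeledCohort:
    """Expression matrix joined to subtype labels and cohort assignment."""

    expr: pd.DataFrame              # samples x genes
    labels: pd.Series               # subtype per sample
    cohort: pd.Series | None = None  # TRAIN / VALIDATION per sample

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.labels.index):
            raise CohortError("expression and label sample ids differ")
        self.labels = self.labels.map(canonicalize_label)
        if self.cohort is not None and not self.expr.index.equals(
                self.cohort.index):
            raise CohortError("expression and cohort sample ids differ")

    def subset(self, which: str) -> "LabeledCohort":
        if self.cohort is None:
            raise CohortError("cohort not assigned; call split_cohort first")
        keep = self.cohort == which
        return LabeledCohort(self.expr.loc[keep], self.labels.loc[keep],
                             self.cohort.loc[keep])


def load_labels(path, sample_ids=None) -> pd.Series:
    """Read a labels CSV (sample_id, subtype); MALT/LPL remap to MZL."""
    df = pd.read_csv(path)
    labels = df.set_index("sample_id")["subtype"].map(canonicalize_label)
    if sample_ids is not None:
        labels = labels.reindex(sample_ids)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise CohortError(f"samples without a label: {missing[:5]}")
    return labels


def split_cohort(cohort: LabeledCohort, fraction: float = 2 / 3,
                 seed: int = 0) -> LabeledCohort:
    """Stratified-by-label random train/validation assignment.

    Reproducible under ``seed``; every label needs >= 2 samples to
    stratify.  ``fraction`` is the training share.
    """
    if cohort.cohort is not None and cohort.cohort.notna().any():
        raise CohortError("cohort tags already assigned")
    counts = cohort.labels.value_counts()
    if fraction < 1.0 and (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise CohortError(f"cannot stratify: labels with <2 samples: {bad}")
    assignment = pd.Series(TRAIN, index=cohort.expr.index)
    if fraction < 1.0:
        train_idx, val_idx = train_test_split(
            cohort.expr.index, train_size=fraction,
            stratify=cohort.labels, random_state=seed)
        assignment.loc[val_idx] = VALIDATION
    return LabeledCohort(cohort.expr, cohort.labels, assignment)


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the subtype forest."""

    n_trees: int = 5000
    criterion: str = "gini"
    max_depth: int = 20
    min_samples_split: int = 4
    seed: int = 0


@dataclass
class SubtypeModel:
    """A fitted subtype forest with its feature contract."""

    forest: RandomForestClassifier
    features: list[str]
    config: ForestConfig
    panel_checksum: str = ""

    def save(self, path) -> None:
        joblib.dump({"format": "rtmis-subtype-model", "version": 1,
                     "forest": self.forest, "features": self.features,
                     "config": self.config, "labels": list(SUBTYPES),
                     "panel_checksum": self.panel_checksum}, path)

    @classmethod
    def load(cls, path) -> "SubtypeModel":
        blob = joblib.load(path)
        if blob.get("format") != "rtmis-subtype-model":
            raise ValueError(f"{path}: not a subtype model file")
        return cls(forest=blob["forest"], features=blob["features"],
                   config=blob["config"],
                   panel_checksum=blob.get("panel_checksum", ""))


def panel_checksum(panel) -> str:
    h = hashlib.sha256()
    for p in panel.probes:
        h.update(f"{p.marker_id}:{p.product}".encode())
    return h.hexdigest()[:16]


def train(cohort: LabeledCohort, config: ForestConfig | None = None,
          checksum: str = "") -> SubtypeModel:
    """Fit the subtype forest on the cohort's TRAIN rows.

    Requires at least two distinct labels and a complete expression matrix;
    deterministic for a given seed and input.
    """
    config = config or ForestConfig()
    if cohort.cohort is not None:
        cohort = cohort.subset(TRAIN)
    X, y = cohort.expr, cohort.labels
    if X.isna().any().any():
        where = X.isna().stack()
        sample, marker = where[where].index[0]
        raise CohortError(f"missing expression value: sample {sample!r}, "
                          f"marker {marker!r}")
    if y.nunique() < 2:
        raise CohortError("training requires at least two subtype labels")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, criterion=config.criterion,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        random_state=config.seed)
    forest.fit(X.to_numpy(), y.to_numpy())
    return SubtypeModel(forest=forest, features=list(X.columns),
                        config=config, panel_checksum=checksum)


def predict(model: SubtypeModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample class probabilities (tree-vote fractions) and call.

    ``expr`` columns must cover the model's features; extra columns and
    column order are ignored.  Returns a DataFrame with one probability
    column per subtype in canonical order plus a ``call`` column.
    """
    missing = [f for f in model.features if f not in expr.columns]
    if missing:
        raise CohortError(f"expression matrix lacks model features: "
                          f"{missing[:5]}")
    X = expr[model.features].to_numpy()
    # vote fractions: each tree casts one vote for its predicted class
    votes = np.zeros((X.shape[0], len(SUBTYPES)))
    class_index = {c: SUBTYPES.index(c) for c in model.forest.classes_}
    for tree in model.forest.estimators_:
        pred = model.forest.classes_[
            np.argmax(tree.predict_proba(X), axis=1)]
        for j, c in enumerate(pred):
            votes[j, class_index[c]] += 1
    probs = votes / len(model.forest.estimators_)
    out = pd.DataFrame(probs, index=expr.index, columns=list(SUBTYPES))
    out["call"] = [SUBTYPES[i] for i in np.argmax(probs, axis=1)]
    return out


@dataclass
class ConcordanceReport:
    """Accuracy summary of predicted vs expected subtype."""

    confusion: pd.DataFrame         # rows = expected, cols = predicted
    probabilities: pd.DataFrame | None = None  # per-sample vectors + call

    @classmethod
    def from_confusion(cls, confusion: pd.DataFrame) -> "ConcordanceReport":
        order = [s for s in SUBTYPES if s in confusion.index]
        confusion = confusion.reindex(index=order, columns=order,
                                      fill_value=0)
        return cls(confusion=confusion.astype(int))

    @property
    def n(self) -> int:
        return int(self.confusion.to_numpy().sum())

    @property
    def n_correct(self) -> int:
        return int(np.diag(self.confusion.to_numpy()).sum())

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n

    @property
    def per_class_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.confusion.to_numpy()),
                         index=self.confusion.index, dtype=float)
        return (diag / self.confusion.sum(axis=1)).rename("accuracy")

    def class_accuracy(self, *labels: str) -> float:
        """Pooled accuracy over a subset of expected classes."""
        sub = self.confusion.loc[list(labels)]
        correct = sum(int(sub.loc[l, l]) for l in labels)
        return correct / int(sub.to_numpy().sum())

    def summary(self) -> str:
        lines = [f"samples: {self.n}",
                 f"accuracy: {self.n_correct}/{self.n} "
                 f"({100 * self.accuracy:.1f}%)",
                 "per-class accuracy:"]
        totals = self.confusion.sum(axis=1)
        diag = np.diag(self.confusion.to_numpy())
        for label, correct, total in zip(self.confusion.index, diag, totals):
            pct = 100 * correct / total if total else float("nan")
            lines.append(f"  {label:<5} {correct}/{total} ({pct:.1f}%)")
        lines.append("confusion matrix (rows = expected):")
        lines.append(self.confusion.to_string())
        return "\n".join(lines)


def evaluate(predictions: pd.DataFrame,
             labels: pd.Series) -> ConcordanceReport:
    """Confusion matrix and accuracies of predictions against labels."""
    labels = labels.map(canonicalize_label)
    if not predictions.index.equals(labels.index):
        labels = labels.reindex(predictions.index)
        if labels.isna().any():
            raise CohortError("predictions and labels sample ids differ")
    order = list(SUBTYPES)
    confusion = pd.crosstab(labels, predictions["call"]).reindex(
        index=order, columns=order, fill_value=0)
    confusion.index.name = "expected"
    confusion.columns.name = "predicted"
    report = ConcordanceReport.from_confusion(confusion)
    report.probabilities = predictions
    return report
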