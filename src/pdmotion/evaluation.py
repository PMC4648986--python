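"""Evaluation protocols and metrics for frame-level classification.

Two protocols mirror the study design: leave-one-subject-out (train on
n-1 subjects, test on the held-out one; measures cross-person
generalization) and stratified frame-level k-fold cross-validation.  In
both, the <-1,1> normalizer and the classifier are fit on the training
portion only.

Metrics per class:

* effectiveness — the percentage of a class's true frames that were
  recognized (per-class recall);
* second-order error — the percentage of frames *assigned* to a class that
  truly belong elsewhere (false-discovery share of the predicted class).

Reports carry per-fold breakdowns plus means and N-1 standard deviations
across folds/subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import fit_normalizer

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion",
    "effectiveness",
    "second_order_error",
    "leave_one_subject_out",
    "cross_validation",
]


@dataclass
class ConfusionMatrix:
    """Integer counts[true][pred] over a fixed class vocabulary."""

    classes: list
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, cls) -> int:
        return self.classes.index(cls)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("confusion matrices over different vocabularies")
        return ConfusionMatrix(self.classes, self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(true_labels, predicted_labels, classes: list | None = None) -> ConfusionMatrix:
    """Exact counts of (true, predicted) label pairs."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label sequences must have equal length")
    if classes is None:
        classes = sorted(set(t) | set(p))
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        counts[idx[ti], idx[pi]] += 1
    return ConfusionMatrix(classes=list(classes), counts=counts)


def effectiveness(cm: ConfusionMatrix, cls) -> float:
    """Per-class recall in percent; NaN when the class has no true frames."""
    i = cm.index(cls)
    denom = cm.counts[i, :].sum()
    if denom == 0:
        return float("nan")
    return 100.0 * cm.counts[i, i] / denom


def second_order_error(cm: ConfusionMatrix, cls) -> float:
    """Share of frames assigned to ``cls`` that belong elsewhere (percent)."""
    i = cm.index(cls)
    denom = cm.counts[:, i].sum()
    if denom == 0:
        return float("nan")
    return 100.0 * (denom - cm.counts[i, i]) / denom


@dataclass
class EvaluationReport:
    """Per-class summary plus per-fold breakdown for one protocol run."""

    protocol: str
    classes: list
    effectiveness_mean: dict
    effectiveness_sd: dict
    second_order_error_mean: dict
    per_fold: pd.DataFrame  # one row per (fold, class)
    pooled: ConfusionMatrix
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.classes:
            rows.append(
                {
                    "class": c,
                    "effectiveness": self.effectiveness_mean[c],
                    "sd": self.effectiveness_sd[c],
                    "second_order_error": self.second_order_error_mean[c],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "classes": list(self.classes),
            "effectiveness": {str(c): self.effectiveness_mean[c] for c in self.classes},
            "sd": {str(c): self.effectiveness_sd[c] for c in self.classes},
            "second_order_error": {
                str(c): self.second_order_error_mean[c] for c in self.classes
            },
            "metadata": dict(self.metadata),
        }


_FEATURE_META = ("frame_start_s", "label", "subject_id")


def _split_xy(df: pd.DataFrame):
    feats = [c for c in df.columns if c not in _FEATURE_META]
    return df[feats].to_numpy(float), df["label"].to_numpy(object), feats


def _fold_reports(fold_results, classes, protocol, metadata) -> EvaluationReport:
    rows = []
    pooled = None
    for fold_id, cm in fold_results:
        pooled = cm if pooled is None else pooled + cm
        for c in classes:
            rows.append(
                {
                    "fold": fold_id,
                    "class": c,
                    "effectiveness": effectiveness(cm, c),
                    "second_order_error": second_order_error(cm, c),
                    "n_true": int(cm.counts[cm.index(c), :].sum()),
                }
            )
    per_fold = pd.DataFrame(rows)
    eff_mean, eff_sd, soe_mean = {}, {}, {}
    for c in classes:
        vals = per_fold.loc[per_fold["class"] == c, "effectiveness"].dropna()
        eff_mean[c] = float(vals.mean()) if len(vals) else float("nan")
        eff_sd[c] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        errs = per_fold.loc[per_fold["class"] == c, "second_order_error"].dropna()
        soe_mean[c] = float(errs.mean()) if len(errs) else float("nan")
    return EvaluationReport(
        protocol=protocol,
        classes=list(classes),
        effectiveness_mean=eff_mean,
        effectiveness_sd=eff_sd,
        second_order_error_mean=soe_mean,
        per_fold=per_fold,
        pooled=pooled,
        metadata=metadata,
    )


def _run_fold(train_df, test_df, trainer, classes):
    X_tr, y_tr, feats = _split_xy(train_df)
    X_te, y_te, _ = _split_xy(test_df)
    norm = fit_normalizer(X_tr, feats)
    model = trainer(norm.transform(X_tr), y_tr)
    pred = model.predict(norm.transform(X_te))
    return confusion(y_te, pred, classes)


def leave_one_subject_out(
    cohort: pd.DataFrame, trainer, classes: list | None = None
) -> EvaluationReport:
    """One fold per subject: fit on the other subjects, test on the held-out one.

    ``cohort`` is a pooled feature table with ``subject_id`` and ``label``
    columns (as produced by ``features.featurize_cohort``); ``trainer`` is a
    callable ``(X_normalized, y) -> ClassifierModel``.  The report is
    invariant to subject ordering (subjects are processed in sorted order).
    """
    subjects = sorted(cohort["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    if classes is None:
        classes = sorted(cohort["label"].unique())
    folds = []
    for subj in subjects:
        test_df = cohort[cohort["subject_id"] == subj]
        if test_df.empty:
            raise ValueError(f"subject {subj} has no frames")
        train_df = cohort[cohort["subject_id"] != subj]
        folds.append((subj, _run_fold(train_df, test_df, trainer, classes)))
    return _fold_reports(
        folds, classes, "leave_one_subject_out", {"n_subjects": len(subjects)}
    )


def cross_validation(
    frames: pd.DataFrame, trainer, k: int = 10, seed: int = 0, classes: list | None = None
) -> EvaluationReport:
    """Stratified frame-level k-fold cross-validation (default k = 10)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if classes is None:
        classes = sorted(frames["label"].unique())
    y = frames["label"].to_numpy(object)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        scarce = counts[counts < k].index.tolist()
        raise ValueError(f"classes with fewer than k={k} frames: {scarce}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_id, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds.append(
            (fold_id, _run_fold(frames.iloc[tr], frames.iloc[te], trainer, classes))
        )
    return _fold_reports(folds, classes, "cross_validation", {"k": k, "seed": seed})
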