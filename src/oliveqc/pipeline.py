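"""Screening pipeline: grade cascades, defect models and their evaluation.

Quality grading is a two-stage cascade of binary PLS-DA models.  Scheme A
first isolates extra-virgin oils (EVOO vs no-EVOO) and then separates the
rest (VOO vs LOO); scheme B first isolates the non-edible lampante grade
(LOO vs no-LOO) — the screening-relevant decision — and then EVOO vs VOO.
Defects (musty, rancid, fusty/muddy sediment) get three independent binary
models trained on the defective-capable grades (VOO+LOO) only.

Every model carries its own Kennard-Stone 75/25 calibration/external split;
latent variables are chosen by 10-split venetian-blinds cross-validation on
the calibration set (ordered by Kennard-Stone rank, so the interleaved folds
spread across the design space); class assignment uses the Bayes-rule
threshold.  External-validation rows never enter any fit, threshold or
component-selection step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemometrics import (
    PlsDaClassifier,
    RocResult,
    bayes_threshold,
    fit_pls,
    fit_plsda,
    kennard_stone_split,
    roc_curve,
    vip_scores,
)
from .simulate import DEFECTS, GRADES, SensoryLabel

__all__ = [
    "BinaryScreeningModel",
    "CascadeModel",
    "DefectModelSet",
    "EvaluationReport",
    "train_binary_model",
    "train_grade_cascade",
    "train_grade_models",
    "train_defect_models",
    "classify",
    "evaluate",
    "cascade_external_accuracy",
]

#: Default screening probability threshold: samples whose class probability
#: reaches it are flagged "confident" (panel assessment less urgent).
DEFAULT_SCREENING_THRESHOLD = 0.70
MIN_CLASS_SIZE = 8


def _grades_of(labels: Sequence[SensoryLabel]) -> np.ndarray:
    return np.array([l.grade for l in labels])


@dataclass
class BinaryScreeningModel:
    """One binary PLS-DA model with its own calibration/external split."""

    name: str
    classifier: PlsDaClassifier
    cal_ids: list[str]   # Kennard-Stone selection order
    val_ids: list[str]
    y_cal: np.ndarray
    y_val: np.ndarray
    n_splits: int = 10

    @property
    def positive_label(self) -> str:
        return self.classifier.positive_label

    @property
    def negative_label(self) -> str:
        return self.classifier.negative_label


def train_binary_model(features: pd.DataFrame, y: np.ndarray, name: str,
                       positive_label: str, negative_label: str,
                       calibration_fraction: float = 0.75,
                       n_splits: int = 10,
                       max_components: int = 10) -> BinaryScreeningModel:
    """Kennard-Stone split, CV component selection, Bayes-thresholded fit."""
    y = np.asarray(y).astype(int).ravel()
    for cls, lbl in ((1, positive_label), (0, negative_label)):
        if int(np.sum(y == cls)) < MIN_CLASS_SIZE:
            raise ValueError(f"{name}: class {lbl!r} has fewer than "
                             f"{MIN_CLASS_SIZE} samples")
    plan = kennard_stone_split(features.to_numpy(float), calibration_fraction)
    cal, val = plan.calibration, plan.validation
    clf = fit_plsda(features.iloc[cal].to_numpy(float), y[cal],
                    max_components=max_components, n_splits=n_splits,
                    positive_label=positive_label,
                    negative_label=negative_label,
                    x_names=list(features.columns))
    return BinaryScreeningModel(
        name=name, classifier=clf,
        cal_ids=list(features.index[cal]), val_ids=list(features.index[val]),
        y_cal=y[cal], y_val=y[val], n_splits=n_splits)


@dataclass
class CascadeModel:
    """Two-stage quality-grade cascade."""

    scheme: str  # "A" | "B"
    stage1: BinaryScreeningModel
    stage2: BinaryScreeningModel
    feature_names: list[str]

    @property
    def isolated_grade(self) -> str:
        return "EVOO" if self.scheme == "A" else "LOO"


def train_grade_cascade(features: pd.DataFrame,
                        labels: Sequence[SensoryLabel],
                        scheme: str = "B",
                        calibration_fraction: float = 0.75,
                        n_splits: int = 10,
                        max_components: int = 10) -> CascadeModel:
    """Train the two-stage cascade for one scheme.

    Stage 1 is fitted on the full calibration set; stage 2 only on the
    calibration samples of the two grades stage 1 does not isolate.
    """
    if scheme not in ("A", "B"):
        raise ValueError(f"scheme must be 'A' or 'B', got {scheme!r}")
    grades = _grades_of(labels)
    for g in GRADES:
        if int(np.sum(grades == g)) < MIN_CLASS_SIZE:
            raise ValueError(f"grade {g} has fewer than {MIN_CLASS_SIZE} samples")
    isolated = "EVOO" if scheme == "A" else "LOO"
    rest = [g for g in GRADES if g != isolated]

    stage1 = train_binary_model(
        features, (grades == isolated).astype(int),
        name=f"{isolated} vs no-{isolated}",
        positive_label=isolated, negative_label=f"no-{isolated}",
        calibration_fraction=calibration_fraction,
        n_splits=n_splits, max_components=max_components)

    # Stage 2 sees only the stage-1 calibration rows of the remaining grades,
    # in Kennard-Stone order, so the external set stays untouched.
    grade_by_id = {l.sample_id: l.grade for l in labels}
    sub_ids = [sid for sid in stage1.cal_ids if grade_by_id[sid] in rest]
    sub_X = features.loc[sub_ids]
    sub_y = np.array([grade_by_id[sid] == rest[0] for sid in sub_ids], dtype=int)
    for cls, lbl in ((1, rest[0]), (0, rest[1])):
        if int(np.sum(sub_y == cls)) < 4:
            raise ValueError(f"stage-2 class {lbl} has fewer than 4 "
                             "calibration samples")
    clf2 = fit_plsda(sub_X.to_numpy(float), sub_y,
                     max_components=max_components, n_splits=n_splits,
                     positive_label=rest[0], negative_label=rest[1],
                     x_names=list(features.columns))
    val2 = [sid for sid in stage1.val_ids if grade_by_id[sid] in rest]
    stage2 = BinaryScreeningModel(
        name=f"{rest[0]} vs {rest[1]}", classifier=clf2,
        cal_ids=sub_ids, val_ids=val2,
        y_cal=sub_y,
        y_val=np.array([grade_by_id[sid] == rest[0] for sid in val2], int),
        n_splits=n_splits)
    return CascadeModel(scheme=scheme, stage1=stage1, stage2=stage2,
                        feature_names=list(features.columns))


def train_grade_models(features: pd.DataFrame,
                       labels: Sequence[SensoryLabel],
                       **kwargs) -> dict[str, BinaryScreeningModel]:
    """The four independently split quality-grade models.

    EVOO vs no-EVOO and LOO vs no-LOO on all samples; VOO vs LOO and
    EVOO vs VOO on the respective two-grade subsets.
    """
    grades = _grades_of(labels)
    models: dict[str, BinaryScreeningModel] = {}
    models["EVOO vs no-EVOO"] = train_binary_model(
        features, (grades == "EVOO").astype(int), "EVOO vs no-EVOO",
        "EVOO", "no-EVOO", **kwargs)
    models["LOO vs no-LOO"] = train_binary_model(
        features, (grades == "LOO").astype(int), "LOO vs no-LOO",
        "LOO", "no-LOO", **kwargs)
    for pos, neg in (("VOO", "LOO"), ("EVOO", "VOO")):
        mask = np.isin(grades, (pos, neg))
        sub = features.loc[mask]
        models[f"{pos} vs {neg}"] = train_binary_model(
            sub, (grades[mask] == pos).astype(int), f"{pos} vs {neg}",
            pos, neg, **kwargs)
    return models


@dataclass
class DefectModelSet:
    """Independent binary models for the three modeled defects."""

    models: dict[str, BinaryScreeningModel] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.models.items())


def train_defect_models(features: pd.DataFrame,
                        labels: Sequence[SensoryLabel],
                        **kwargs) -> DefectModelSet:
    """Three defect-presence models, trained on VOO+LOO samples only.

    A defect whose classes cannot support a model is recorded in
    ``errors``; the remaining models are still trained.
    """
    grades = _grades_of(labels)
    mask = np.isin(grades, ("VOO", "LOO"))
    if not mask.any():
        raise ValueError("no VOO or LOO samples to train defect models on")
    sub = features.loc[mask]
    sub_labels = [l for l, m in zip(labels, mask) if m]
    out = DefectModelSet()
    for defect in DEFECTS:
        y = np.array([l.has_defect(defect) for l in sub_labels], dtype=int)
        try:
            out.models[defect] = train_binary_model(
                sub, y, f"{defect} vs no-{defect}", defect, f"no-{defect}",
                **kwargs)
        except ValueError as exc:
            out.errors[defect] = str(exc)
    return out


# -------------------------------------------------------------- screening
def classify(cascade: CascadeModel, features: pd.DataFrame,
             defect_models: DefectModelSet | None = None,
             screening_threshold: float = DEFAULT_SCREENING_THRESHOLD,
             ) -> pd.DataFrame:
    """Screen samples through the cascade (and optional defect models).

    Stage 1 decides membership of the isolated grade; remaining samples go
    to stage 2.  The reported probability comes from the deciding stage only
    — no probability chaining — and the screening flag is ``confident`` iff
    that probability reaches the user threshold.
    """
    if list(features.columns) != cascade.feature_names:
        raise ValueError("feature columns do not match the trained cascade")
    X = features.to_numpy(float)
    p1 = cascade.stage1.classifier.predict_proba(X)
    p2 = cascade.stage2.classifier.predict_proba(X)
    rows = []
    for i, sid in enumerate(features.index):
        if p1[i] >= 0.5:
            grade, prob, stage = cascade.isolated_grade, float(p1[i]), 1
        else:
            pos = p2[i] >= 0.5
            grade = (cascade.stage2.positive_label if pos
                     else cascade.stage2.negative_label)
            prob, stage = float(p2[i] if pos else 1.0 - p2[i]), 2
        rows.append({
            "sample_id": sid, "predicted_grade": grade,
            "probability": prob, "stage": stage,
            "flag": "confident" if prob >= screening_threshold else "uncertain",
        })
    out = pd.DataFrame(rows).set_index("sample_id")
    if defect_models is not None:
        for defect, model in defect_models:
            out[f"p_{defect}"] = model.classifier.predict_proba(X)
    return out


def cascade_external_accuracy(cascade: CascadeModel,
                              features: pd.DataFrame,
                              labels: Sequence[SensoryLabel],
                              ) -> dict[str, float]:
    """Stage-1 and overall three-grade accuracy on the external set."""
    grade_by_id = {l.sample_id: l.grade for l in labels}
    ext = cascade.stage1.val_ids
    pred = classify(cascade, features.loc[ext])
    truth = np.array([grade_by_id[sid] for sid in ext])
    stage1_truth = truth == cascade.isolated_grade
    stage1_pred = pred["predicted_grade"].to_numpy() == cascade.isolated_grade
    return {
        "stage1_accuracy": float(np.mean(stage1_pred == stage1_truth)),
        "overall_accuracy": float(np.mean(pred["predicted_grade"].to_numpy()
                                          == truth)),
        "n_external": len(ext),
    }


# -------------------------------------------------------------- evaluation
def _cv_predictions(features: pd.DataFrame, model: BinaryScreeningModel,
                    ) -> np.ndarray:
    """Held-out class predictions for the calibration rows (venetian blinds).

    Re-runs the interleaved folds at the selected component count, refitting
    the Bayes threshold inside every fold.
    """
    X = features.loc[model.cal_ids].to_numpy(float)
    y = model.y_cal
    n = len(y)
    a_sel = model.classifier.n_components
    pred = np.empty(n, dtype=int)
    for f in range(model.n_splits):
        test = np.arange(f, n, model.n_splits)
        if test.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), test)
        a = min(a_sel, len(train) - 1)
        sub = fit_pls(X[train], y[train], a)
        thr, posterior = bayes_threshold(sub.predict(X[train]), y[train])
        pred[test] = (np.asarray(posterior(sub.predict(X[test]))) >= 0.5)
    return pred


@dataclass
class EvaluationReport:
    """Per-model classification table, ROC, VIP and probability summaries."""

    table: pd.DataFrame          # category x {calibration, cv, external} %
    rocs: dict[str, RocResult]
    vip: pd.DataFrame            # variables x models
    probability_summary: pd.DataFrame
    probability_data: dict[str, pd.DataFrame]


def evaluate(models: Mapping[str, BinaryScreeningModel],
             features: pd.DataFrame,
             probability_level: float = 0.70) -> EvaluationReport:
    """Percent-correct tables, external ROC/AUC, VIP and probability plots.

    The table reports, per model, the percentage of correctly classified
    samples of the positive and negative category in calibration, venetian
    cross-validation and external validation.  ROC curves use the external
    decision values with the Bayes threshold as operating point.  The
    probability summary gives the fraction of samples of each category whose
    class probability (cross + external validation pooled) exceeds
    ``probability_level``.
    """
    rows, rocs, vip_cols = [], {}, {}
    prob_rows, prob_data = [], {}
    for name, m in models.items():
        clf = m.classifier
        Xc = features.loc[m.cal_ids].to_numpy(float)
        Xv = features.loc[m.val_ids].to_numpy(float)
        pred_cal = clf.predict(Xc)
        pred_cv = _cv_predictions(features, m)
        pred_val = clf.predict(Xv) if len(m.val_ids) else np.empty(0, int)

        for cls, label in ((1, clf.positive_label), (0, clf.negative_label)):
            def pct(pred, truth):
                sel = truth == cls
                if not sel.any():
                    return np.nan
                return 100.0 * float(np.mean(pred[sel] == cls))
            rows.append({
                "model": name, "category": label,
                "calibration_pct": pct(pred_cal, m.y_cal),
                "cv_pct": pct(pred_cv, m.y_cal),
                "external_pct": pct(pred_val, m.y_val),
            })

        if len(m.val_ids) and len(np.unique(m.y_val)) == 2:
            rocs[name] = roc_curve(m.y_val, clf.decision_values(Xv),
                                   operating_threshold=clf.threshold)
        vip_cols[name] = vip_scores(clf.pls)

        # Probability-vs-sample data (cross + external validation pooled).
        p_cv = np.asarray(clf.posterior(_cv_decision_values(features, m)))
        p_val = clf.predict_proba(Xv) if len(m.val_ids) else np.empty(0)
        pooled = pd.DataFrame({
            "sample_id": list(m.cal_ids) + list(m.val_ids),
            "set": ["cv"] * len(m.cal_ids) + ["external"] * len(m.val_ids),
            "y_true": np.r_[m.y_cal, m.y_val],
            "p_positive": np.r_[p_cv, p_val],
        })
        prob_data[name] = pooled
        in_cls = pooled[pooled.y_true == 1]
        out_cls = pooled[pooled.y_true == 0]
        prob_rows.append({
            "model": name,
            f"{clf.positive_label}_above_{probability_level:.0%}":
                100.0 * float((in_cls.p_positive > probability_level).mean()),
            f"{clf.negative_label}_above_{probability_level:.0%}":
                100.0 * float(((1 - out_cls.p_positive) > probability_level).mean()),
        })

    table = pd.DataFrame(rows)
    vip = pd.DataFrame(vip_cols, index=list(features.columns))
    prob = pd.DataFrame(
        [{"model": r["model"],
          "in_class_pct_above_level": list(r.values())[1],
          "out_class_pct_above_level": list(r.values())[2]}
         for r in prob_rows])
    return EvaluationReport(table=table, rocs=rocs, vip=vip,
                            probability_summary=prob,
                            probability_data=prob_data)


def _cv_decision_values(features: pd.DataFrame,
                        model: BinaryScreeningModel) -> np.ndarray:
    """Held-out decision values for calibration rows (interleaved folds)."""
    X = features.loc[model.cal_ids].to_numpy(float)
    y = model.y_cal
    n = len(y)
    a_sel = model.classifier.n_components
    out = np.empty(n)
    for f in range(model.n_splits):
        test = np.arange(f, n, model.n_splits)
        if test.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), test)
        sub = fit_pls(X[train], y[train], min(a_sel, len(train) - 1))
        out[test] = sub.predict(X[test])
    return out
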