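"""Cohort statistics and the cross-validated random-forest panel classifier.

Univariate analytics (group means/medians/ratios, Welch t-tests,
cross-correlation screen) plus a repeated stratified 10-fold random
forest with pooled ROC, percentile and bootstrap confidence intervals,
and a Youden-rule operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import presets

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "univariate_summary",
    "crossval_rf",
    "operating_point",
    "roc_compare",
    "bootstrap_auc_ci",
]


def univariate_summary(
    cohort: pd.DataFrame,
    metabolites: Sequence[str] | None = None,
    positive_label: str = "PCa",
) -> dict:
    """Per-metabolite cohort statistics and the cross-correlation screen.

    Returns ``{"per_metabolite": DataFrame, "cross_correlation": DataFrame}``.
    The per-metabolite table carries grand and per-group mean/SD/median/
    range, the positive/negative ratios of means and medians and the
    Welch two-sided t-test p-value.
    """
    if metabolites is None:
        metabolites = [
            c for c in cohort.columns if c not in ("sample_id", "group")
        ]
    groups = cohort["group"].unique()
    if len(groups) != 2:
        raise ValueError("univariate summary needs exactly two groups")
    neg_label = next(g for g in groups if g != positive_label)
    pos = cohort[cohort["group"] == positive_label]
    neg = cohort[cohort["group"] == neg_label]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 samples per group")

    rows = []
    for m in metabolites:
        all_v, pos_v, neg_v = cohort[m], pos[m], neg[m]
        if pos_v.std(ddof=1) == 0 and neg_v.std(ddof=1) == 0:
            # degenerate zero-variance groups: the test is ill-defined
            pvalue = 1.0 if pos_v.mean() == neg_v.mean() else 0.0
        else:
            pvalue = stats.ttest_ind(pos_v, neg_v, equal_var=False).pvalue
        rows.append(
            {
                "metabolite": m,
                "grand_mean": all_v.mean(),
                "grand_sd": all_v.std(ddof=1),
                "grand_median": all_v.median(),
                "range_low": all_v.min(),
                "range_high": all_v.max(),
                f"{neg_label}_mean": neg_v.mean(),
                f"{neg_label}_sd": neg_v.std(ddof=1),
                f"{neg_label}_median": neg_v.median(),
                f"{positive_label}_mean": pos_v.mean(),
                f"{positive_label}_sd": pos_v.std(ddof=1),
                f"{positive_label}_median": pos_v.median(),
                "mean_ratio": pos_v.mean() / neg_v.mean(),
                "median_ratio": pos_v.median() / neg_v.median(),
                "t_pvalue": pvalue,
            }
        )
    per_met = pd.DataFrame(rows).set_index("metabolite")
    corr = cohort[list(metabolites)].corr()
    return {"per_metabolite": per_met, "cross_correlation": corr}


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest cross-validation settings."""

    n_trees: int = 500
    max_features_per_split: int = 3
    folds: int = 10
    repeats: int = 100
    seed: int = 0
    features: tuple = presets.CLASSIFIER_FEATURES
    positive_label: str = "PCa"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ClassifierReport:
    """Repeated-CV results: per-repeat AUCs, pooled ROC and predictions."""

    aucs: np.ndarray
    auc_mean: float
    auc_ci: tuple[float, float]
    pooled_fpr: np.ndarray
    pooled_tpr: np.ndarray
    pooled_thresholds: np.ndarray
    pooled_auc: float
    y_true: np.ndarray  # (repeats, n) out-of-fold labels (constant rows)
    y_prob: np.ndarray  # (repeats, n) out-of-fold positive-class probabilities
    config: ClassifierConfig = field(default_factory=ClassifierConfig)


def crossval_rf(cohort: pd.DataFrame, cfg: ClassifierConfig = ClassifierConfig()) -> ClassifierReport:
    """Repeated stratified k-fold random-forest cross-validation.

    Per repeat, out-of-fold positive-class probabilities are pooled into
    one ROC/AUC; the report carries the per-repeat AUC distribution (mean
    and 2.5–97.5 percentile CI) and a single pooled ROC over all repeats'
    predictions. All randomness derives from ``cfg.seed``.
    """
    X = cohort[list(cfg.features)].to_numpy(dtype=float)
    y = (cohort["group"] == cfg.positive_label).to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    max_features = min(cfg.max_features_per_split, X.shape[1])
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = ss.generate_state(2 * cfg.repeats)

    n = y.size
    probs = np.empty((cfg.repeats, n))
    aucs = np.empty(cfg.repeats)
    for rep in range(cfg.repeats):
        skf = StratifiedKFold(
            n_splits=cfg.folds, shuffle=True, random_state=int(child_seeds[2 * rep] % 2**31)
        )
        oof = np.empty(n)
        for train, test in skf.split(X, y):
            rf = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                max_features=max_features,
                random_state=int(child_seeds[2 * rep + 1] % 2**31),
                n_jobs=1,
            )
            rf.fit(X[train], y[train])
            oof[test] = rf.predict_proba(X[test])[:, 1]
        probs[rep] = oof
        aucs[rep] = roc_auc_score(y, oof)

    pooled_y = np.tile(y, cfg.repeats)
    pooled_p = probs.ravel()
    fpr, tpr, thr = roc_curve(pooled_y, pooled_p)
    ci = (
        float(np.percentile(aucs, 2.5)),
        float(np.percentile(aucs, 97.5)),
    )
    return ClassifierReport(
        aucs=aucs,
        auc_mean=float(np.mean(aucs)),
        auc_ci=ci,
        pooled_fpr=fpr,
        pooled_tpr=tpr,
        pooled_thresholds=thr,
        pooled_auc=float(roc_auc_score(pooled_y, pooled_p)),
        y_true=np.tile(y, (cfg.repeats, 1)),
        y_prob=probs,
        config=cfg,
    )


def bootstrap_auc_ci(
    report: ClassifierReport, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the pooled-prediction AUC (by sample)."""
    rng = np.random.default_rng(seed)
    y = report.y_true[0]
    n = y.size
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = report.y_true[:, idx].ravel()
        pb = report.y_prob[:, idx].ravel()
        if yb.min() == yb.max():
            continue
        vals.append(roc_auc_score(yb, pb))
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def _youden_point(fpr, tpr) -> tuple[float, float]:
    j = tpr - fpr
    i = int(np.argmax(j))
    return float(tpr[i]), float(1.0 - fpr[i])


def operating_point(report: ClassifierReport, method: str = "youden") -> dict:
    """Operating point on the pooled ROC with percentile CIs over repeats.

    Returns sensitivity/specificity at the threshold maximizing Youden's
    J on the pooled curve, plus 2.5–97.5 percentile intervals of the
    per-repeat Youden points.
    """
    if method != "youden":
        raise ValueError(f"unknown operating-point method {method!r}")
    if report.pooled_thresholds.size < 2:
        raise ValueError("degenerate single-threshold ROC")
    sens, spec = _youden_point(report.pooled_fpr, report.pooled_tpr)
    per_sens, per_spec = [], []
    for rep in range(report.y_prob.shape[0]):
        fpr, tpr, _ = roc_curve(report.y_true[rep], report.y_prob[rep])
        s, p = _youden_point(fpr, tpr)
        per_sens.append(s)
        per_spec.append(p)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_ci": (
            float(np.percentile(per_sens, 2.5)),
            float(np.percentile(per_sens, 97.5)),
        ),
        "specificity_ci": (
            float(np.percentile(per_spec, 2.5)),
            float(np.percentile(per_spec, 97.5)),
        ),
    }


def roc_compare(report: ClassifierReport, reference: Mapping | None = None) -> dict:
    """Overlay summary of the classifier ROC against a reference test.

    ``reference`` may be None (classifier only), a
    ``{"sensitivity", "specificity", "auc"}`` triple, or a tabulated
    curve ``{"fpr": ..., "tpr": ..., "auc": ...}``.
    """
    op = operating_point(report)
    out = {
        "classifier": {
            "fpr": report.pooled_fpr.tolist(),
            "tpr": report.pooled_tpr.tolist(),
            "auc": report.auc_mean,
            "operating_point": {
                "sensitivity": op["sensitivity"],
                "specificity": op["specificity"],
            },
        },
        "reference": None,
        "auc_difference": None,
    }
    if reference:
        ref = dict(reference)
        out["reference"] = ref
        if "auc" in ref:
            out["auc_difference"] = report.auc_mean - float(ref["auc"])
    return out
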