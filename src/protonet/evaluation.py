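"""Leave-one-subject-out evaluation of tremor detectors.

One cross-validation fold per subject: the held-out subject contributes no
windows — prototype or otherwise — to normalization statistics, basis
fitting, weight training or threshold selection. Decision thresholds are set
on training scores to hit a specificity of ~0.95 (band 0.945-0.955);
sensitivity and AUROC are aggregated across folds of subjects that have
tremor windows, specificity across all folds, mirroring how free-living
tremor detectors are reported. Stratified metrics break sensitivity down by
tremor movement sub-class and specificity by daily-life activity sub-class,
exposing confuser activities (periodic "suspicious" arm movements) that
inflate false positives in plain classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .features import FeatureTable, FEATURE_NAMES, zscore_fit_apply
from .dpm import build_basis_set
from .rbf import SingleLayerRBFNet, TwoLayerRBFNet, TwoLayerConfig
from .io import TREMOR_SUBCLASSES, NONTREMOR_SUBCLASSES

SPECIFICITY_BAND = (0.945, 0.955)
WINDOW_S = 2.0


# ---------------------------------------------------------------------------
# folds


def loso_folds(table: FeatureTable) -> Iterator[tuple[str, FeatureTable, FeatureTable]]:
    """Yield (held_out_subject, train_table, test_table) per subject.

    Training rows include the other subjects' prototype windows; the held-out
    subject's rows (prototypes included) appear only in the test table.
    """
    subjects = list(pd.unique(table.frame["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    for subject in subjects:
        mask = table.frame["subject_id"] == subject
        yield subject, table.select(~mask.to_numpy()), table.select(mask.to_numpy())


# ---------------------------------------------------------------------------
# thresholds and metrics


def select_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    band: tuple[float, float] = SPECIFICITY_BAND,
    return_info: bool = False,
):
    """Pick the decision threshold targeting ~95% training specificity.

    Candidate thresholds are the midpoints between consecutive distinct
    scores (plus sentinels). The candidate whose training specificity is
    closest to the band centre (0.95) wins; ties break toward higher
    sensitivity. When no candidate's specificity falls inside the open band
    (e.g. perfectly separated or degenerate scores), the closest-to-0.95
    candidate is still returned, flagged as a fallback.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold selection needs both classes")
    neg = np.sort(scores[labels == 0])
    uniq = np.unique(scores)
    cand = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + np.spacing(uniq[-1]) ]]
    )
    # specificity at threshold thr: fraction of negatives strictly below thr
    spec = np.searchsorted(neg, cand, side="left") / len(neg)
    pos = np.sort(scores[labels == 1])
    sens = 1.0 - np.searchsorted(pos, cand, side="left") / len(pos)
    target = 0.5 * (band[0] + band[1])
    order = np.lexsort((-sens, np.abs(spec - target)))
    best = order[0]
    in_band = band[0] < spec[best] < band[1]
    thr = float(cand[best])
    if return_info:
        return thr, {
            "specificity": float(spec[best]),
            "sensitivity": float(sens[best]),
            "fallback": not in_band,
        }
    return thr


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """(sensitivity, specificity, AUROC) at the given threshold; AUROC via
    the rank statistic (ties handled by mid-ranks). Undefined entries (a
    class absent) are NaN."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos = labels == 1
    sens = float(np.mean(pred[pos])) if pos.any() else np.nan
    spec = float(np.mean(~pred[~pos])) if (~pos).any() else np.nan
    auroc = (
        float(roc_auc_score(labels, scores))
        if pos.any() and (~pos).any()
        else np.nan
    )
    return sens, spec, auroc


# ---------------------------------------------------------------------------
# models


def train_baselines(X: np.ndarray, y: np.ndarray, seed: int = 0) -> dict:
    """The two reference classifiers: an l2 logistic regression with
    inverse-class-frequency weights and a random forest with per-tree
    class-balanced bootstrap weighting. Both deterministic given the seed."""
    logistic = LogisticRegression(
        class_weight="balanced", max_iter=2000, random_state=seed
    ).fit(X, y)
    forest = RandomForestClassifier(
        n_estimators=200,
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    return {"logistic": logistic, "random_forest": forest}


def _fit_model(name: str, train: FeatureTable, seed: int, two_layer_config=None):
    """Fit one of the four evaluated models on a (z-scored) training table;
    returns a scoring callable."""
    X, y = train.X, train.y
    if name == "single_layer":
        basis = build_basis_set(train, shuffle_seed=seed)
        res = SingleLayerRBFNet(y, X, basis).fit()
        return res.predict_proba
    if name == "two_layer":
        cfg = two_layer_config or TwoLayerConfig(seed=seed)
        res = TwoLayerRBFNet.from_feature_table(train, config=cfg).fit()
        return res.predict_proba
    if name in ("logistic", "random_forest"):
        clf = train_baselines(X, y, seed=seed)[name]
        return lambda Z: clf.predict_proba(Z)[:, 1]
    raise ValueError(f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# fold results


@dataclass
class FoldResult:
    subject_id: str
    threshold: float
    sensitivity: float
    specificity: float
    auroc: float
    sensitivity_by_subclass: dict[str, float]
    specificity_by_subclass: dict[str, float]
    predicted_tremor_s: float
    true_tremor_s: float
    n_test_windows: int

    def to_record(self) -> dict:
        rec = {
            "subject_id": self.subject_id,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auroc": self.auroc,
            "predicted_tremor_s": self.predicted_tremor_s,
            "true_tremor_s": self.true_tremor_s,
            "n_test_windows": self.n_test_windows,
        }
        for sub, v in self.sensitivity_by_subclass.items():
            rec[f"sens_{sub}"] = v
        for sub, v in self.specificity_by_subclass.items():
            rec[f"spec_{sub}"] = v
        return rec


def _fold_stratified(test: FeatureTable, pred: np.ndarray) -> tuple[dict, dict]:
    """Per-sub-class cells for one fold; a sub-class absent from the fold is
    absent from the dict (not reported as 0)."""
    frame = test.frame
    sens = {}
    for sub in TREMOR_SUBCLASSES:
        m = (
            (frame["label"] == "tremor")
            & (frame["sub_class"] == sub)
            & frame["prototype"]
        ).to_numpy()
        if m.any():
            sens[sub] = float(np.mean(pred[m]))
    spec = {}
    for sub in NONTREMOR_SUBCLASSES:
        m = ((frame["label"] == "non_tremor") & (frame["sub_class"] == sub)).to_numpy()
        if m.any():
            spec[sub] = float(np.mean(~pred[m]))
    return sens, spec


def evaluate_fold(
    subject: str,
    train: FeatureTable,
    test: FeatureTable,
    model: str = "two_layer",
    seed: int = 0,
    two_layer_config=None,
    global_normalization: bool = False,
    full_table: FeatureTable | None = None,
) -> FoldResult:
    """Fit + threshold on the training subjects, score the held-out subject.

    Default normalization is fold-safe (z-score stats from training subjects
    only); ``global_normalization=True`` reproduces the global variant where
    the statistics come from the whole cohort (requires ``full_table``).
    """
    if global_normalization:
        if full_table is None:
            raise ValueError("global_normalization requires the full table")
        stats_src = zscore_fit_apply(full_table)
        stats = stats_src.stats
    else:
        stats = None
    train_z = zscore_fit_apply(train, stats=stats)
    test_z = zscore_fit_apply(test, stats=train_z.stats)
    score_fn = _fit_model(model, train_z, seed, two_layer_config)
    thr = select_threshold(score_fn(train_z.X), train_z.y)
    scores = score_fn(test_z.X)
    sens, spec, auroc = compute_metrics(scores, test_z.y, thr)
    pred = scores >= thr
    strat_sens, strat_spec = _fold_stratified(test_z, pred)
    return FoldResult(
        subject_id=subject,
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        auroc=auroc,
        sensitivity_by_subclass=strat_sens,
        specificity_by_subclass=strat_spec,
        predicted_tremor_s=float(pred.sum() * WINDOW_S),
        true_tremor_s=float(test_z.y.sum() * WINDOW_S),
        n_test_windows=len(test_z.frame),
    )


@dataclass
class EvaluationReport:
    model: str
    folds: list[FoldResult]
    aggregates: dict = field(default_factory=dict)
    stratified: dict = field(default_factory=dict)
    agreement: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "folds": [f.to_record() for f in self.folds],
            "aggregates": self.aggregates,
            "stratified": self.stratified,
            "agreement": self.agreement,
        }


def run_loso(
    table: FeatureTable,
    model: str = "two_layer",
    seed: int = 0,
    two_layer_config=None,
    global_normalization: bool = False,
    compute_agreement: bool = True,
) -> EvaluationReport:
    """Full leave-one-subject-out evaluation of one model."""
    folds = [
        evaluate_fold(
            subject,
            train,
            test,
            model=model,
            seed=seed,
            two_layer_config=two_layer_config,
            global_normalization=global_normalization,
            full_table=table if global_normalization else None,
        )
        for subject, train, test in loso_folds(table)
    ]
    report = EvaluationReport(model=model, folds=folds)
    sens = np.array([f.sensitivity for f in folds])
    spec = np.array([f.specificity for f in folds])
    auroc = np.array([f.auroc for f in folds])
    has_pos = ~np.isnan(sens)

    def _ms(v):
        v = v[~np.isnan(v)]
        return (float(np.mean(v)), float(np.std(v))) if len(v) else (np.nan, np.nan)

    report.aggregates = {
        "sensitivity": _ms(sens),
        "specificity": _ms(spec),
        "auroc": _ms(auroc),
        "n_folds": len(folds),
        "n_folds_with_tremor": int(has_pos.sum()),
    }
    report.stratified = stratified_metrics(folds)
    if compute_agreement and has_pos.sum() >= 3:
        pred_s = np.array([f.predicted_tremor_s for f in folds])[has_pos]
        true_s = np.array([f.true_tremor_s for f in folds])[has_pos]
        report.agreement = duration_agreement(pred_s, true_s)
    return report


def stratified_metrics(folds: Sequence[FoldResult]) -> dict:
    """Across-fold mean/SD per sub-class cell, with the number of folds
    possessing the sub-class; folds lacking a sub-class contribute nothing
    (the cell is absent, not zero)."""
    out: dict[str, dict] = {"sensitivity": {}, "specificity": {}}
    for sub in TREMOR_SUBCLASSES:
        vals = [
            f.sensitivity_by_subclass[sub]
            for f in folds
            if sub in f.sensitivity_by_subclass
        ]
        if vals:
            out["sensitivity"][sub] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals)),
                "n_folds": len(vals),
            }
    for sub in NONTREMOR_SUBCLASSES:
        vals = [
            f.specificity_by_subclass[sub]
            for f in folds
            if sub in f.specificity_by_subclass
        ]
        if vals:
            out["specificity"][sub] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals)),
                "n_folds": len(vals),
            }
    return out


# ---------------------------------------------------------------------------
# learning curves


def learning_curve(
    table: FeatureTable,
    durations_min: Sequence[float] = (0.5, 1, 2, 5, 10, 20, 32),
    model: str = "logistic",
    seeds: Sequence[int] = (0,),
    two_layer_config=None,
) -> pd.DataFrame:
    """AUROC vs amount of training data, with cumulative sampling.

    Per fold and seed, training windows are shuffled once; each duration uses
    the first ``duration * 60 / 2`` windows, so smaller samples are strict
    subsets of larger ones (new data is added to the existing sample rather
    than resampled). Folds/durations whose sample lacks a class are skipped.
    """
    durations = sorted(durations_min)
    records = []
    for subject, train, test in loso_folds(table):
        if test.y.sum() == 0:
            continue
        for seed in seeds:
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(train.frame))
            for dur in durations:
                k = min(int(dur * 60 / WINDOW_S), len(order))
                sub = train.select(np.isin(np.arange(len(train.frame)), order[:k]))
                if len(np.unique(sub.y)) < 2:
                    continue
                try:
                    train_z = zscore_fit_apply(sub)
                    test_z = zscore_fit_apply(test, stats=train_z.stats)
                    score_fn = _fit_model(model, train_z, seed, two_layer_config)
                    auroc = roc_auc_score(test_z.y, score_fn(test_z.X))
                except ValueError:
                    continue
                records.append(
                    {
                        "subject_id": subject,
                        "seed": seed,
                        "duration_min": dur,
                        "n_windows": k,
                        "auroc": float(auroc),
                    }
                )
    df = pd.DataFrame(records)
    if len(df):
        summary = df.groupby("duration_min")["auroc"].agg(["mean", "std", "count"])
        df.attrs["summary"] = summary
    return df


# ---------------------------------------------------------------------------
# agreement statistics


def pearson_ci(x: np.ndarray, y: np.ndarray, confidence: float = 0.8):
    """Pearson R with a Fisher-z confidence interval; NaN for constant
    input (undefined correlation)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, (np.nan, np.nan)
    res = spstats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), (float(ci.low), float(ci.high))


def icc_2_1(x: np.ndarray, y: np.ndarray, confidence: float = 0.8):
    """ICC(2,1): two-way random effects, absolute agreement, single measure,
    between two parallel measurements (e.g. predicted vs annotated tremor
    seconds per subject), with an F-based confidence interval.

    An exact-agreement pair (zero residual and zero rater effect) returns
    ICC 1 with a degenerate (1, 1) interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D arrays, n >= 3")
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return np.nan, (np.nan, np.nan)
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return 1.0, (1.0, 1.0)
    alpha = 1.0 - confidence
    # Satterthwaite df for the F bounds (McGraw & Wong)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(icc), (np.nan, np.nan)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num_v / den_v if den_v > 0 else np.inf
    f_low = spstats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_up = spstats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    return float(icc), (float(lower), float(upper))


def duration_agreement(
    predicted_s: np.ndarray, true_s: np.ndarray, confidence: float = 0.8
) -> dict:
    """Agreement between per-subject predicted and annotated tremor duration:
    Pearson R (Fisher-z CI) and ICC(2,1) absolute agreement (F-based CI),
    both at the given confidence level (default 80%)."""
    r, r_ci = pearson_ci(predicted_s, true_s, confidence)
    icc, icc_ci = icc_2_1(predicted_s, true_s, confidence)
    return {
        "pearson_r": r,
        "pearson_ci": r_ci,
        "icc": icc,
        "icc_ci": icc_ci,
        "confidence": confidence,
    }
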