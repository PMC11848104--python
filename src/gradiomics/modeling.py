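"""Response labeling, SVM modeling, and frequency-based feature selection.

The classification target is volumetric treatment response: a lesion whose
follow-up volume falls below 80% of its initial volume (>= 20% reduction)
is a *responder*; follow-up at or above 80% makes it a *non-responder*.
The non-responder class — the clinically critical minority — is the
positive class throughout: SVM coefficients with positive sign push toward
non-response, and sensitivity/precision/F1 are reported against it.

Fifteen model configurations arise from crossing three timepoint modes
(first MRI, second MRI, delta) with five region series:

* A — 9 features from the tumor core,
* B — 9 features from the whole peritumoral margin,
* C — the 9 elementwise core/margin ratios,
* D — 9 features selected from the 72 octant-margin features,
* E — 9 features selected from all 90.

Selection for D/E is frequency-based recursive feature elimination: within
each of ``iters`` reshuffled 5-fold stratified splits, a linear-SVM RFE
(eliminating one feature per round) is fit on each standardized training
fold; the features most frequently reaching the top ``n_select`` across
all iterations are retained. The ensemble feature-selection (EFS) model
pools the top-9 sets of the three E-series models (tagged by mode) and
re-runs the same frequency selection on that union.

All estimators are linear-kernel SVMs (C = 1 by default) with balanced
class weights; imputation and standardization are fit inside training
folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import RFE
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gradients import FEATURE_NAMES, PARAMS, STATS
from .regions import OCTANT_LABELS

__all__ = [
    "CohortTable",
    "SeriesSpec",
    "SelectionResult",
    "CVMetrics",
    "ModelReport",
    "StratificationError",
    "POSITIVE_LABEL",
    "MODES",
    "SERIES",
    "MODEL_NAMES",
    "assign_response_label",
    "build_series_matrix",
    "rfe_frequency_select",
    "cross_validate",
    "compute_metrics",
    "run_all_individual_models",
    "efs_model",
    "report_feature_stats",
]

POSITIVE_LABEL = "non_responder"
RESPONSE_THRESHOLD = 0.8  # follow-up / initial volume ratio

MODES = ("mri1", "mri2", "delta")
SERIES = ("A", "B", "C", "D", "E")
_MODE_NUM = {"mri1": "1", "mri2": "2", "delta": "3"}
#: Canonical names of the 15 individual model configurations (1A..3E).
MODEL_NAMES = tuple(f"{_MODE_NUM[m]}{s}" for m in MODES for s in SERIES)

_METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "precision", "f1", "auc")
_RATIO_EPS = 1e-12


class StratificationError(ValueError):
    """Class structure incompatible with the requested stratified folds."""


@dataclass
class CohortTable:
    """Lesion-level feature frames plus volumes and response labels.

    ``features`` maps each available timepoint mode to a DataFrame indexed
    by lesion_id with the 90 canonical feature columns. Labels derive from
    the volume pair via :func:`assign_response_label` unless given.
    """

    features: dict[str, pd.DataFrame]
    initial_volume_mm3: pd.Series
    followup_volume_mm3: pd.Series
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if "mri1" not in self.features:
            raise ValueError("cohort must at least contain mri1 features")
        index = self.features["mri1"].index
        if index.duplicated().any():
            raise ValueError("duplicate lesion_id in cohort")
        for mode, df in self.features.items():
            if list(df.columns) != list(FEATURE_NAMES):
                raise ValueError(f"{mode} features do not follow the canonical 90-name schema")
            if not df.index.equals(index):
                raise ValueError(f"{mode} features indexed differently from mri1")
        if self.labels is None:
            self.labels = pd.Series(
                [
                    assign_response_label(vi, vf)
                    for vi, vf in zip(self.initial_volume_mm3[index], self.followup_volume_mm3[index])
                ],
                index=index,
            )

    @property
    def modes(self) -> tuple[str, ...]:
        return tuple(m for m in MODES if m in self.features)

    def y(self) -> np.ndarray:
        """Binary target: 1 = non-responder (positive class)."""
        return (self.labels.values == POSITIVE_LABEL).astype(int)


@dataclass
class SeriesSpec:
    """One model configuration: timepoint mode × region series."""

    mode: str = "mri1"
    series: str = "E"
    n_select: int = 9

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.series not in SERIES:
            raise ValueError(f"series must be one of {SERIES}, got {self.series!r}")

    @property
    def name(self) -> str:
        return f"{_MODE_NUM[self.mode]}{self.series}"


@dataclass
class SelectionResult:
    """Outcome of frequency-based RFE selection."""

    selected: list[str]
    frequency: dict[str, int]
    mean_rank: dict[str, float]
    n_iterations: int
    tie_breaker_log: list[str] = field(default_factory=list)


@dataclass
class CVMetrics:
    """Aggregate metrics over folds × iterations, with per-fold raw values."""

    summary: pd.DataFrame  # index = metric, columns = mean/sd/ci_low/ci_high
    fold_scores: pd.DataFrame  # one row per (iteration, fold)

    def mean(self, metric: str) -> float:
        return float(self.summary.loc[metric, "mean"])


@dataclass
class ModelReport:
    name: str
    spec: SeriesSpec
    selection: SelectionResult | None
    features: list[str]
    metrics: CVMetrics


def assign_response_label(initial_volume: float, followup_volume: float) -> str:
    """Label a lesion from its volume change at follow-up.

    Responder means at least a 20% reduction (follow-up strictly below 80%
    of the initial volume); a follow-up at or above that threshold — the
    exact 80% boundary included — is a non-responder.
    """
    if initial_volume <= 0 or followup_volume <= 0:
        raise ValueError("volumes must be positive")
    return "responder" if followup_volume < RESPONSE_THRESHOLD * initial_volume else POSITIVE_LABEL


def _series_columns(series: str) -> list[str]:
    core = [f"core_{p}_{s}" for p in PARAMS for s in STATS]
    margin = [f"margin_{p}_{s}" for p in PARAMS for s in STATS]
    octant = [f"oct_{o}_{p}_{s}" for o in OCTANT_LABELS for p in PARAMS for s in STATS]
    if series == "A":
        return core
    if series == "B":
        return margin
    if series == "D":
        return octant
    if series == "E":
        return core + margin + octant
    raise ValueError(series)


def build_series_matrix(cohort: CohortTable, spec: SeriesSpec):
    """Design matrix + binary labels for one mode × series configuration.

    Series C forms the elementwise core/margin ratio for each of the nine
    (parameter, statistic) pairs; a near-zero denominator yields NaN (the
    modeling pipeline imputes within training folds). Returns
    ``(X: DataFrame, y: ndarray)`` with y = 1 for non-responders.
    """
    if spec.mode not in cohort.features:
        raise ValueError(f"cohort has no {spec.mode!r} features (modes: {cohort.modes})")
    df = cohort.features[spec.mode]
    if spec.series == "C":
        X = pd.DataFrame(index=df.index)
        for p in PARAMS:
            for s in STATS:
                num = df[f"core_{p}_{s}"].to_numpy(dtype=float)
                den = df[f"margin_{p}_{s}"].to_numpy(dtype=float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = np.where(np.abs(den) < _RATIO_EPS, np.nan, num / den)
                X[f"ratio_{p}_{s}"] = ratio
    else:
        X = df[_series_columns(spec.series)].copy()
    return X, cohort.y()


def _make_svm(C: float = 1.0) -> SVC:
    return SVC(kernel="linear", C=C, class_weight="balanced")


def _make_pipeline(C: float = 1.0) -> Pipeline:
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("svm", _make_svm(C)),
    ])


def _check_stratifiable(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both response classes must be present")
    if counts.min() < folds:
        raise StratificationError(
            f"minority class has {counts.min()} samples, fewer than {folds} folds"
        )


def _rank_features(X_train: np.ndarray, y_train: np.ndarray, names, n_select: int, C: float):
    """One RFE fit on an imputed+standardized training fold.

    Returns (selected name set, ranking array aligned with names); RFE
    eliminates a single feature per round so ranking is a full ordering.
    """
    imp = SimpleImputer(strategy="median").fit(X_train)
    Xs = StandardScaler().fit_transform(imp.transform(X_train))
    rfe = RFE(_make_svm(C), n_features_to_select=n_select, step=1)
    rfe.fit(Xs, y_train)
    sel = {n for n, keep in zip(names, rfe.support_) if keep}
    return sel, rfe.ranking_


def _top_by_frequency(counts, ranks, n_select, names):
    """Order candidates by frequency desc, mean RFE rank asc, name asc."""
    mean_rank = {n: (float(np.mean(ranks[n])) if ranks[n] else float("inf")) for n in names}
    order = sorted(names, key=lambda n: (-counts.get(n, 0), mean_rank[n], n))
    top = order[:n_select]
    log = []
    if len(order) > n_select and counts.get(order[n_select - 1], 0) == counts.get(order[n_select], 0):
        log.append(
            f"frequency tie at cutoff ({counts.get(order[n_select - 1], 0)}): "
            f"kept {order[n_select - 1]!r} over {order[n_select]!r} by mean rank/name"
        )
    return top, mean_rank, log


def rfe_frequency_select(
    X: pd.DataFrame,
    y: np.ndarray,
    n_select: int = 9,
    folds: int = 5,
    iters: int = 50,
    seed: int = 0,
    C: float = 1.0,
) -> SelectionResult:
    """Frequency-based RFE over repeated stratified cross-validation.

    Each iteration reshuffles the stratified folds; linear-SVM RFE on every
    standardized training fold yields a top-``n_select`` set, and the
    iteration's own top set is the most frequent over its folds. The final
    selection is the ``n_select`` features appearing in the most iteration
    top-sets, ties broken by better (lower) mean RFE rank, then name.
    Deterministic given the seed.
    """
    names = list(X.columns)
    if len(names) < n_select:
        raise ValueError(f"pool of {len(names)} features cannot yield {n_select}")
    _check_stratifiable(y, folds)
    Xv = X.to_numpy(dtype=float)
    iter_counts: dict[str, int] = {}
    all_ranks: dict[str, list[int]] = {n: [] for n in names}
    log: list[str] = []
    for it in range(iters):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + it)
        fold_counts: dict[str, int] = {}
        for train_idx, _ in skf.split(Xv, y):
            sel, ranking = _rank_features(Xv[train_idx], y[train_idx], names, n_select, C)
            for n in sel:
                fold_counts[n] = fold_counts.get(n, 0) + 1
            for n, r in zip(names, ranking):
                all_ranks[n].append(int(r))
        top, _, tie_log = _top_by_frequency(fold_counts, all_ranks, n_select, names)
        log.extend(f"iter {it}: {m}" for m in tie_log)
        for n in top:
            iter_counts[n] = iter_counts.get(n, 0) + 1
    selected, mean_rank, tie_log = _top_by_frequency(iter_counts, all_ranks, n_select, names)
    log.extend(f"final: {m}" for m in tie_log)
    return SelectionResult(
        selected=selected,
        frequency={n: iter_counts.get(n, 0) for n in names},
        mean_rank=mean_rank,
        n_iterations=iters,
        tie_breaker_log=log,
    )


def compute_metrics(tp: int, fn: int, tn: int, fp: int,
                    y_true=None, scores=None) -> dict[str, float]:
    """Standard binary metrics against the non-responder-positive polarity.

    Precision with no predicted positives is reported as 0 (flagged via the
    ``precision_undefined`` key); AUC is computed from decision scores when
    provided, else NaN.
    """
    if min(tp, fn, tn, fp) < 0 or tp + fn + tn + fp == 0:
        raise ValueError("confusion counts must be non-negative with a positive total")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / (tp + fn + tn + fp)
    undefined_prec = (tp + fp) == 0
    prec = 0.0 if undefined_prec else tp / (tp + fp)
    f1 = 0.0 if (prec + sens) == 0 or np.isnan(sens) else 2 * prec * sens / (prec + sens)
    auc = float("nan")
    if y_true is not None and scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return {
        "sensitivity": sens, "specificity": spec, "accuracy": acc,
        "precision": prec, "f1": f1, "auc": auc,
        "precision_undefined": float(undefined_prec),
    }


def _aggregate_folds(rows: list[dict]) -> CVMetrics:
    fold_df = pd.DataFrame(rows)
    summary = {}
    for m in _METRIC_NAMES:
        vals = fold_df[m].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        summary[m] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "ci_low": float(np.percentile(vals, 2.5)),
            "ci_high": float(np.percentile(vals, 97.5)),
        }
    return CVMetrics(summary=pd.DataFrame(summary).T, fold_scores=fold_df)


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    selected: list[str] | None = None,
    folds: int = 5,
    iters: int = 50,
    seed: int = 0,
    C: float = 1.0,
) -> CVMetrics:
    """Repeated stratified k-fold evaluation of a linear SVM.

    Per fold: imputation and standardization are fit on the training split,
    a balanced linear SVM is fit, and the held-out fold is scored (confusion
    metrics from predictions, ROC AUC from decision values). The summary
    reports mean, SD, and 95% percentile interval over all folds ×
    iterations.
    """
    if selected is not None:
        missing = [f for f in selected if f not in X.columns]
        if missing:
            raise ValueError(f"selected features absent from matrix: {missing}")
        X = X[selected]
    _check_stratifiable(y, folds)
    Xv = X.to_numpy(dtype=float)
    rows = []
    for it in range(iters):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + it)
        for fold, (tr, te) in enumerate(skf.split(Xv, y)):
            pipe = _make_pipeline(C)
            pipe.fit(Xv[tr], y[tr])
            pred = pipe.predict(Xv[te])
            score = pipe.decision_function(Xv[te])
            tp = int(np.sum((pred == 1) & (y[te] == 1)))
            fn = int(np.sum((pred == 0) & (y[te] == 1)))
            tn = int(np.sum((pred == 0) & (y[te] == 0)))
            fp = int(np.sum((pred == 1) & (y[te] == 0)))
            m = compute_metrics(tp, fn, tn, fp, y_true=y[te], scores=score)
            m.update({"iteration": it, "fold": fold})
            rows.append(m)
    return _aggregate_folds(rows)


def _evaluate_spec(cohort: CohortTable, spec: SeriesSpec, folds, iters, seed, C) -> ModelReport:
    X, y = build_series_matrix(cohort, spec)
    selection = None
    if spec.series in ("D", "E"):
        selection = rfe_frequency_select(X, y, n_select=spec.n_select,
                                         folds=folds, iters=iters, seed=seed, C=C)
        features = selection.selected
    else:
        features = list(X.columns)
    metrics = cross_validate(X, y, selected=features, folds=folds,
                             iters=iters, seed=seed, C=C)
    return ModelReport(name=spec.name, spec=spec, selection=selection,
                       features=list(features), metrics=metrics)


def run_all_individual_models(
    cohort: CohortTable,
    n_select: int = 9,
    folds: int = 5,
    iters: int = 50,
    seed: int = 0,
    C: float = 1.0,
) -> dict[str, ModelReport]:
    """Evaluate every mode × series configuration available in the cohort.

    A two-timepoint cohort yields the full 15 models (1A..3E); a cohort with
    only the first scan (the fSRT-style path) yields the 5 first-MRI models
    with a warning. Fold shuffling and selection share the seed policy, so
    repeated runs are identical.
    """
    import warnings

    reports: dict[str, ModelReport] = {}
    available = cohort.modes
    if available != MODES:
        warnings.warn(
            f"cohort provides modes {available}; running {5 * len(available)} "
            "of the 15 configurations", stacklevel=2,
        )
    for mode in available:
        for series in SERIES:
            spec = SeriesSpec(mode=mode, series=series, n_select=n_select)
            reports[spec.name] = _evaluate_spec(cohort, spec, folds, iters, seed, C)
    return reports


def efs_model(
    cohort: CohortTable,
    seed: int = 0,
    n_select: int = 9,
    folds: int = 5,
    iters: int = 50,
    C: float = 1.0,
    e_reports: dict[str, ModelReport] | None = None,
):
    """Ensemble feature selection over the three E-series models.

    The candidate pool is the union of the top-9 sets of 1E, 2E and 3E,
    each name tagged by its mode (``mri1:...``); the same frequency-based
    RFE then reduces the pool to ``n_select`` features, which are
    cross-validated and refit on the full cohort for the signed coefficient
    report (positive coefficients push toward the non-responder class).

    Returns ``(SelectionResult, CVMetrics, coefficients: Series)``.
    """
    if "mri2" not in cohort.features or "delta" not in cohort.features:
        raise ValueError("EFS requires both timepoints (mri2 and delta modes)")
    pool_frames = []
    for mode in MODES:
        name = f"{_MODE_NUM[mode]}E"
        if e_reports is not None and name in e_reports and e_reports[name].selection is not None:
            top = e_reports[name].selection.selected
        else:
            X, y = build_series_matrix(cohort, SeriesSpec(mode=mode, series="E", n_select=n_select))
            top = rfe_frequency_select(X, y, n_select=n_select, folds=folds,
                                       iters=iters, seed=seed, C=C).selected
        df = cohort.features[mode][top].copy()
        df.columns = [f"{mode}:{c}" for c in df.columns]
        pool_frames.append(df)
    pool = pd.concat(pool_frames, axis=1)
    y = cohort.y()
    selection = rfe_frequency_select(pool, y, n_select=n_select, folds=folds,
                                     iters=iters, seed=seed, C=C)
    metrics = cross_validate(pool, y, selected=selection.selected, folds=folds,
                             iters=iters, seed=seed, C=C)
    # full-cohort refit for the coefficient report
    imp = SimpleImputer(strategy="median")
    Xs = StandardScaler().fit_transform(imp.fit_transform(pool[selection.selected]))
    svm = _make_svm(C).fit(Xs, y)
    coefficients = pd.Series(svm.coef_.ravel(), index=selection.selected)
    return selection, metrics, coefficients


def report_feature_stats(X: pd.DataFrame, y: np.ndarray, selected: list[str],
                         alpha: float = 0.05):
    """Pairwise Spearman correlations and per-feature two-group tests.

    For each selected feature, Shapiro-Wilk normality (alpha = 0.05) on both
    groups decides between a two-sample t-test (both normal) and the
    Mann-Whitney U test; two-sided p-values are reported unadjusted, with a
    Benjamini-Hochberg column added for reference.
    """
    if not selected:
        raise ValueError("selected feature list is empty")
    groups = [X.loc[y == 0, selected], X.loc[y == 1, selected]]
    if min(len(g) for g in groups) < 3:
        raise ValueError("each group needs at least 3 samples for the reports")
    spearman = X[selected].astype(float).corr(method="spearman")
    rows = []
    for feat in selected:
        a = groups[0][feat].dropna().to_numpy(dtype=float)
        b = groups[1][feat].dropna().to_numpy(dtype=float)
        normal = all(
            len(np.unique(g)) > 2 and stats.shapiro(g).pvalue > alpha for g in (a, b)
        )
        if normal:
            test, p = "t-test", stats.ttest_ind(a, b).pvalue
        else:
            test, p = "mannwhitneyu", stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({"feature": feat, "test": test, "p_value": float(p)})
    tests = pd.DataFrame(rows).set_index("feature")
    tests["p_bh"] = stats.false_discovery_control(tests["p_value"].to_numpy(), method="bh")
    return {"spearman": spearman, "group_tests": tests}
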