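"""Outcome prediction: FIBE feature selection, leave-one-out evaluation,
cross-site stability ranking, clinical-variable fusion and comparison
against ordinal expert severity scores.

FIBE (forward inclusion / backward elimination) is a wrapper selector:
it starts from the single feature with the smallest cross-validated
prediction error, greedily adds the feature whose inclusion most
reduces the error while any inclusion strictly reduces it, then removes
the feature whose exclusion most reduces the error while any exclusion
strictly reduces it, and alternates until a full forward+backward pass
changes nothing or a feature cap (the one-in-ten rule) is reached.
Because the subset stays small at all times, the selector itself limits
overfitting risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone, is_classifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from hiemap.core_io import CohortTable, ValidationError

__all__ = [
    "FIBEResult",
    "PredictionReport",
    "default_learner",
    "fibe_select",
    "loocv_predict",
    "rank_feature_stability",
    "fuse_clinical",
    "compare_to_expert_score",
]

FIBE_PASS_LIMIT = 50
NICHD_ORDER = ("0", "1A", "1B", "2A", "2B", "3")


@dataclass(frozen=True)
class FIBEResult:
    selected: tuple[str, ...]
    trajectory: tuple[tuple[str, str, float], ...]  # (step type, feature, cv error)
    cap: int
    final_cv_error: float
    pass_limit_hit: bool = False


@dataclass(frozen=True)
class PredictionReport:
    task: str                      # "binary" | "continuous"
    predictions: np.ndarray        # per-fold (= per-patient) predictions
    truth: np.ndarray
    sensitivity: float | None = None
    specificity: float | None = None
    rmse: float | None = None
    model_id: str = ""
    seed: int = 0
    selected_per_fold: tuple[tuple[str, ...], ...] = ()


def default_learner(task: str):
    """Linear-kernel SVM for binary outcomes, linear SVR for continuous."""
    if task == "binary":
        return SVC(kernel="linear")
    return SVR(kernel="linear")


def _is_binary(y: np.ndarray) -> bool:
    """A target drawn from {0, 1} is a binary outcome.

    A single-valued {0, 1} target is still *typed* binary — callers must
    reject it as degenerate rather than silently regress on it.
    """
    vals = np.unique(y[~np.isnan(y)])
    return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


def _prepare(X: pd.DataFrame) -> pd.DataFrame:
    """Median-impute missing cells and append missingness indicators."""
    X = X.copy()
    for col in list(X.columns):
        if X[col].isna().any():
            med = X[col].median()
            X[f"{col}__missing"] = X[col].isna().astype(float)
            X[col] = X[col].fillna(0.0 if np.isnan(med) else med)
    return X


def _cv_error(X: np.ndarray, y: np.ndarray, learner, binary: bool,
              n_splits: int, seed: int, n_repeats: int = 1) -> float:
    """Inner cross-validated prediction error (misclassification rate for
    binary outcomes, RMSE for continuous), with standardization refit on
    each training split.  ``n_repeats`` averages over re-partitioned
    folds, reducing the variance of the estimate — important when the
    error drives greedy selection, where a noisy estimate makes useless
    features look spuriously helpful."""
    mean, _ = _cv_error_with_sem(X, y, learner, binary, n_splits, seed, n_repeats)
    return mean


def _cv_error_with_sem(X: np.ndarray, y: np.ndarray, learner, binary: bool,
                       n_splits: int, seed: int,
                       n_repeats: int = 1) -> tuple[float, float]:
    """Mean fold error and its standard error over repeated partitions."""
    folds: list[float] = []
    for r in range(n_repeats):
        folds.extend(_cv_fold_errors(X, y, learner, binary, n_splits,
                                     seed + 1000 * r))
    arr = np.asarray(folds)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem


def _cv_fold_errors(X: np.ndarray, y: np.ndarray, learner, binary: bool,
                    n_splits: int, seed: int) -> list[float]:
    n = len(y)
    n_splits = min(n_splits, n)
    if binary:
        min_class = int(np.bincount(y.astype(int), minlength=2).min())
        if min_class < 2:
            # too few members of one class to stratify: resubstitution fallback
            pipe = Pipeline([("scale", StandardScaler()), ("model", clone(learner))])
            pipe.fit(X, y)
            return [float(np.mean(pipe.predict(X) != y))]
        n_splits = max(min(n_splits, min_class), 2)
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=max(n_splits, 2), shuffle=True, random_state=seed)
        split_iter = splitter.split(X)
    errs = []
    for tr, te in split_iter:
        pipe = Pipeline([("scale", StandardScaler()), ("model", clone(learner))])
        pipe.fit(X[tr], y[tr])
        pred = pipe.predict(X[te])
        if binary:
            errs.append(float(np.mean(pred != y[te])))
        else:
            errs.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
    return errs


def fibe_select(table: pd.DataFrame, target: np.ndarray, learner=None,
                cap: int = 30, inner_splits: int = 5, seed: int = 0,
                inner_repeats: int = 3,
                pass_limit: int = FIBE_PASS_LIMIT) -> FIBEResult:
    """Forward-inclusion / backward-elimination wrapper feature selection.

    ``table`` holds candidate features (columns, unique names); the
    selection criterion is the inner cross-validated prediction error of
    ``learner`` on the candidate subset (``inner_repeats`` repeated
    partitions).  A step is accepted only when the error drops by more
    than one standard error of the fold-error mean — with many noise
    candidates, the minimum of a noisy error estimate almost surely
    shows *some* spurious decrease, so a plain strict-decrease rule
    would chain useless features indefinitely.  Ties break
    lexicographically by feature name so the outcome is independent of
    column order.
    """
    if cap < 1:
        raise ValidationError("cap must be >= 1")
    y = np.asarray(target, dtype=np.float64)
    if np.unique(y).size < 2:
        raise ValidationError("target has no variation")
    X = _prepare(table)
    names = sorted(X.columns)
    if len(names) < 1:
        raise ValidationError("need at least one candidate feature")
    binary = _is_binary(y)
    if learner is None:
        learner = default_learner("binary" if binary else "continuous")

    def err(subset: Sequence[str]) -> tuple[float, float]:
        return _cv_error_with_sem(X[list(subset)].to_numpy(), y, learner, binary,
                                  inner_splits, seed, n_repeats=inner_repeats)

    # seed subset: single most informative feature
    best_feat = min(names, key=lambda f: (err([f])[0], f))
    selected = [best_feat]
    current, current_sem = err(selected)
    trajectory = [("include", best_feat, current)]

    def accepted(new_err: float, new_sem: float) -> bool:
        return new_err < current - max(new_sem, current_sem)

    pass_limit_hit = False
    for _pass in range(pass_limit):
        changed = False
        # forward inclusion
        while len(selected) < cap:
            candidates = [f for f in names if f not in selected]
            if not candidates:
                break
            scored = sorted((*err(selected + [f]), f) for f in candidates)
            best_err, best_sem, f = scored[0]
            if accepted(best_err, best_sem):
                selected.append(f)
                current, current_sem = best_err, best_sem
                trajectory.append(("include", f, current))
                changed = True
            else:
                break
        # backward elimination
        while len(selected) > 1:
            scored = sorted((*err([g for g in selected if g != f]), f)
                            for f in selected)
            best_err, best_sem, f = scored[0]
            if accepted(best_err, best_sem):
                selected.remove(f)
                current, current_sem = best_err, best_sem
                trajectory.append(("exclude", f, current))
                changed = True
            else:
                break
        if not changed:
            break
    else:
        pass_limit_hit = True

    return FIBEResult(selected=tuple(selected), trajectory=tuple(trajectory),
                      cap=cap, final_cv_error=current,
                      pass_limit_hit=pass_limit_hit)


def loocv_predict(table: pd.DataFrame, target: np.ndarray, learner=None,
                  selection: str | Mapping = "all", seed: int = 0,
                  fibe_cap: int = 30, inner_splits: int = 3) -> PredictionReport:
    """Leave-one-out outcome prediction without information leakage.

    N folds, each patient tested exactly once; imputation,
    standardization and (when ``selection='fibe'``) feature selection
    are refit inside every training fold.  Binary outcomes report
    sensitivity (adverse outcomes correctly predicted) and specificity
    (normal outcomes correctly predicted); continuous outcomes report
    the RMSE between predicted and actual scores.
    """
    y = np.asarray(target, dtype=np.float64)
    n = len(y)
    if n < 3:
        raise ValidationError("need at least 3 patients")
    if len(table) != n:
        raise ValidationError("feature table and target disagree in length")
    binary = _is_binary(y)
    if np.unique(y).size < 2:
        raise ValidationError("target has a single value" if not binary
                              else "binary target has a single class")
    task = "binary" if binary else "continuous"
    if learner is None:
        learner = default_learner(task)

    preds = np.empty(n)
    selected_per_fold = []
    for i in range(n):
        tr = np.arange(n) != i
        X_tr = _prepare(table.iloc[tr])
        X_te = table.iloc[[i]].copy()
        # apply the training fold's imputation to the test row
        for col in X_tr.columns:
            if col.endswith("__missing"):
                base = col[: -len("__missing")]
                X_te[col] = X_te[base].isna().astype(float)
        for col in table.columns:
            if X_te[col].isna().any():
                X_te[col] = X_tr[col].median()
        X_te = X_te[X_tr.columns]
        cols = list(X_tr.columns)
        if selection == "fibe":
            res = fibe_select(table.iloc[tr], y[tr], learner=learner,
                              cap=fibe_cap, inner_splits=inner_splits, seed=seed)
            cols = list(res.selected)
            selected_per_fold.append(res.selected)
        pipe = Pipeline([("scale", StandardScaler()), ("model", clone(learner))])
        pipe.fit(X_tr[cols].to_numpy(), y[tr])
        preds[i] = pipe.predict(X_te[cols].to_numpy())[0]

    if binary:
        pos = y == 1
        sens = float(np.mean(preds[pos] == 1)) if pos.any() else None
        spec = float(np.mean(preds[~pos] == 0)) if (~pos).any() else None
        return PredictionReport(task="binary", predictions=preds, truth=y,
                                sensitivity=sens, specificity=spec,
                                model_id=type(learner).__name__, seed=seed,
                                selected_per_fold=tuple(selected_per_fold))
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    return PredictionReport(task="continuous", predictions=preds, truth=y,
                            rmse=rmse, model_id=type(learner).__name__,
                            seed=seed, selected_per_fold=tuple(selected_per_fold))


def rank_feature_stability(tables_by_site: Mapping[str, pd.DataFrame],
                           targets_by_site: Mapping[str, np.ndarray],
                           learner=None, lam: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Rank features by cross-site predictive stability.

    Each feature gets, per site, a univariate transfer score: a model on
    that feature is trained on the *other* sites and evaluated on the
    held-out site (leave-one-site-out), scoring 1 - error for binary
    targets and -RMSE for continuous.  The stability score is
    ``mean_across_sites - lam * std_across_sites``, so a feature that
    predicts equally well everywhere outranks one that excels at a
    single site, and a site-invariant feature (e.g. Z-based) outranks a
    raw-intensity feature whose scale shifts between scanners.
    Features missing at any site are flagged and ranked last.
    """
    sites = list(tables_by_site)
    if len(sites) < 2:
        raise ValidationError("need at least 2 sites")
    all_features = sorted(set().union(*(t.columns for t in tables_by_site.values())))
    rows = []
    for feat in all_features:
        missing = any(feat not in tables_by_site[s].columns
                      or tables_by_site[s][feat].isna().all() for s in sites)
        if missing:
            rows.append((feat, float("nan"), float("nan"), -np.inf, True))
            continue
        y_all = {s: np.asarray(targets_by_site[s], dtype=np.float64) for s in sites}
        binary = all(_is_binary(y_all[s]) for s in sites)
        per_site = []
        for held_out in sites:
            train_sites = [s for s in sites if s != held_out]
            X_tr = np.concatenate([
                _prepare(tables_by_site[s][[feat]]).to_numpy()[:, :1]
                for s in train_sites])
            y_tr = np.concatenate([y_all[s] for s in train_sites])
            X_te = _prepare(tables_by_site[held_out][[feat]]).to_numpy()[:, :1]
            y_te = y_all[held_out]
            if np.unique(y_tr).size < 2 or np.std(X_tr[:, 0]) == 0:
                per_site.append(0.0)
                continue
            lrn = learner or default_learner("binary" if binary else "continuous")
            pipe = Pipeline([("scale", StandardScaler()), ("model", clone(lrn))])
            pipe.fit(X_tr, y_tr)
            pred = pipe.predict(X_te)
            if binary:
                per_site.append(1.0 - float(np.mean(pred != y_te)))
            else:
                per_site.append(-float(np.sqrt(np.mean((pred - y_te) ** 2))))
        mean = float(np.mean(per_site))
        sd = float(np.std(per_site))
        rows.append((feat, mean, sd, mean - lam * sd, False))
    out = pd.DataFrame(rows, columns=["feature", "mean_score", "std_score",
                                      "stability", "missing_at_site"])
    return out.sort_values(["stability", "feature"],
                           ascending=[False, True]).reset_index(drop=True)


def fuse_clinical(table: pd.DataFrame, cohort: CohortTable,
                  variables: Sequence[str]) -> pd.DataFrame:
    """Append clinical variables under the ``clinical.*`` namespace.

    Categorical variables are one-hot encoded.  The fused table keeps
    the same row order/index as the MRI feature table, so downstream
    selection and prediction run unchanged.
    """
    missing = [v for v in variables if v not in cohort.frame.columns]
    if missing:
        raise ValidationError(f"clinical variables not in cohort: {missing}")
    ids = list(table.index.astype(str))
    unknown = [i for i in ids if i not in cohort.frame.index]
    if unknown:
        raise ValidationError(f"patients absent from cohort table: {unknown}")
    clin = cohort.frame.loc[ids, list(variables)].copy()
    out = table.copy()
    for var in variables:
        col = clin[var]
        if pd.api.types.is_numeric_dtype(col):
            out[f"clinical.{var}"] = col.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(col, prefix=f"clinical.{var}", dtype=float)
            for c in dummies.columns:
                out[c] = dummies[c].to_numpy()
    return out


def compare_to_expert_score(report_ml: PredictionReport,
                            scores: Sequence[str],
                            outcomes: np.ndarray) -> pd.DataFrame:
    """Side-by-side accuracy of the ML model vs ordinal expert-score cuts.

    Every cut of the six-level NICHD-NRN scale (score >= level predicts
    an adverse outcome) is evaluated for sensitivity/specificity next to
    the ML report's values.
    """
    y = np.asarray(outcomes, dtype=np.float64)
    ranks = np.array([NICHD_ORDER.index(s) for s in scores])
    rows = [{"predictor": f"ml:{report_ml.model_id}", "cut": "",
             "sensitivity": report_ml.sensitivity,
             "specificity": report_ml.specificity}]
    pos = y == 1
    for cut in range(1, len(NICHD_ORDER)):
        pred = (ranks >= cut).astype(float)
        sens = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
        spec = float(np.mean(pred[~pos] == 0)) if (~pos).any() else float("nan")
        rows.append({"predictor": "expert", "cut": f">={NICHD_ORDER[cut]}",
                     "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)
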