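"""Random-forest diagnostic models and the cross-cohort evaluation design.

The learner is a standard random forest (scikit-learn); what this module
contributes is the evaluation machinery around it:

* repeated stratified cross-validation (20 x 5-fold by default) with an
  inner tuning grid that never sees test-fold rows;
* permutation significance of the mean CV AUROC with the plus-one rule;
* cohort-to-cohort transfer and leave-one-cohort-out (LOCO) validation;
* rank-aggregated Gini importance and the incremental minimal-panel
  procedure (add features by rank until the mean CV AUROC plateaus);
* external validation on held-out cohorts, non-target-disease specificity
  and early-stage evaluation with per-fold class rebalancing.

All randomness flows from one seed through named substreams.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .profiles import StudyMetadata
from .utils import substream_seed

log = logging.getLogger(__name__)


@dataclass
class RandomForestSpec:
    """Forest hyperparameters and the (small, fixed) inner tuning grid.

    ``tune=True`` selects ``max_features`` x ``min_samples_leaf`` by inner
    3-fold AUROC on the training rows only.
    """

    n_estimators: int = 500
    tune: bool = False
    max_features_grid: tuple = ("sqrt", 0.333)
    min_samples_leaf_grid: tuple = (1, 5)
    max_features: object = "sqrt"
    min_samples_leaf: int = 1

    def make(self, seed: int, max_features=None, min_samples_leaf=None) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features if max_features is None else max_features,
            min_samples_leaf=(
                self.min_samples_leaf if min_samples_leaf is None else min_samples_leaf
            ),
            random_state=seed % (2**31 - 1),
            n_jobs=1,
        )


def auroc(scores, labels) -> float:
    """AUROC via the Mann-Whitney formulation (half credit for ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _case_indicator(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "SOU":
        return (y == "case").astype(int)
    return y.astype(int)


def _fit_with_tuning(
    x: np.ndarray, y: np.ndarray, spec: RandomForestSpec, seed: int
) -> RandomForestClassifier:
    """Fit a forest, optionally grid-tuned by inner 3-fold AUROC on (x, y) only."""
    if not spec.tune:
        rf = spec.make(seed)
        rf.fit(x, y)
        return rf
    best, best_auc = None, -1.0
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed % (2**31 - 1))
    for mf in spec.max_features_grid:
        for leaf in spec.min_samples_leaf_grid:
            aucs = []
            for tr, te in inner.split(x, y):
                rf = spec.make(seed, max_features=mf, min_samples_leaf=leaf)
                rf.fit(x[tr], y[tr])
                prob = rf.predict_proba(x[te])[:, 1]
                if len(np.unique(y[te])) < 2:
                    continue
                aucs.append(auroc(prob, y[te]))
            mean_auc = float(np.mean(aucs)) if aucs else 0.5
            if mean_auc > best_auc:
                best_auc, best = mean_auc, (mf, leaf)
    rf = spec.make(seed, max_features=best[0], min_samples_leaf=best[1])
    rf.fit(x, y)
    return rf


@dataclass
class CVResult:
    mean_auroc: float
    fold_aurocs: list[float]
    importances: pd.Series  # mean Gini importance across fold models


def repeated_cv(
    X: pd.DataFrame,
    y,
    folds: int = 5,
    repeats: int = 20,
    spec: RandomForestSpec | None = None,
    seed: int = 0,
    balance: bool = False,
) -> CVResult:
    """Repeated stratified k-fold CV returning the mean AUROC over all folds.

    The tuner (when enabled) runs inside each training split, so no test
    row ever influences hyperparameter choice or fitting.  With
    ``balance=True`` the majority class is down-sampled to the minority
    size within every training split (used for early-stage evaluation).
    """
    spec = spec or RandomForestSpec()
    yb = _case_indicator(y)
    xv = X.to_numpy(dtype=float)
    if np.bincount(yb).min() < folds:
        raise ValueError("smallest class has fewer samples than folds")
    fold_aurocs: list[float] = []
    imps = np.zeros(X.shape[1])
    n_models = 0
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=substream_seed(seed, f"cvfold{rep}")
        )
        for fi, (tr, te) in enumerate(skf.split(xv, yb)):
            if balance:
                tr = _downsample(tr, yb, substream_seed(seed, f"bal{rep}_{fi}"))
            rf = _fit_with_tuning(xv[tr], yb[tr], spec, substream_seed(seed, f"rf{rep}_{fi}"))
            prob = rf.predict_proba(xv[te])[:, 1]
            fold_aurocs.append(auroc(prob, yb[te]))
            imps += rf.feature_importances_
            n_models += 1
    return CVResult(
        float(np.mean(fold_aurocs)),
        fold_aurocs,
        pd.Series(imps / n_models, index=X.columns),
    )


def _downsample(train_idx: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    groups = [train_idx[y[train_idx] == c] for c in np.unique(y[train_idx])]
    m = min(len(g) for g in groups)
    picked = [rng.choice(g, size=m, replace=False) for g in groups]
    out = np.concatenate(picked)
    rng.shuffle(out)
    return out


def permutation_significance(
    X: pd.DataFrame,
    y,
    spec: RandomForestSpec | None = None,
    n_perm: int = 1000,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    model_factory=None,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value of the mean CV AUROC under label shuffling.

    p = (1 + #{null >= observed}) / (n_perm + 1); with a strong signal and
    1000 permutations the p-value floors at 1/1001 ~ 0.001.
    ``model_factory(seed)`` may supply a custom scikit-learn classifier;
    by default the random-forest spec is used.
    """
    yb = _case_indicator(y)
    rng = np.random.default_rng(substream_seed(seed, "permsig"))

    def cv_stat(labels: np.ndarray, s: int) -> float:
        if model_factory is None:
            return repeated_cv(
                X, labels, folds=folds, repeats=repeats, spec=spec, seed=s
            ).mean_auroc
        xv = X.to_numpy(dtype=float)
        aucs = []
        for rep in range(repeats):
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=substream_seed(s, f"pf{rep}")
            )
            for tr, te in skf.split(xv, labels):
                clf = model_factory(substream_seed(s, "clf"))
                clf.fit(xv[tr], labels[tr])
                aucs.append(auroc(clf.predict_proba(xv[te])[:, 1], labels[te]))
        return float(np.mean(aucs))

    observed = cv_stat(yb, substream_seed(seed, "obs"))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = cv_stat(rng.permutation(yb), substream_seed(seed, f"null{b}"))
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return observed, float(p), null


# ---------------------------------------------------------------------------
# Cross-cohort evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalMatrix:
    cohorts: list[str]
    auroc: pd.DataFrame            # train-cohort rows x test-cohort columns
    loco: pd.Series | None = None  # per held-out cohort
    perm_p: pd.DataFrame | None = None


def _cohort_xy(X: pd.DataFrame, meta: StudyMetadata, cohort: str, features):
    samples = meta.samples_of(cohort)
    return (
        X.loc[samples, features],
        _case_indicator(meta.data.loc[samples, "group"]),
    )


def transfer_matrix(
    X: pd.DataFrame,
    meta: StudyMetadata,
    features: list[str],
    spec: RandomForestSpec | None = None,
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> EvalMatrix:
    """Cohort-to-cohort AUROC matrix; diagonal = within-cohort repeated CV."""
    spec = spec or RandomForestSpec()
    cohorts = meta.cohorts
    if len(cohorts) < 2:
        raise ValueError("need >= 2 cohorts")
    meta.require_both_groups()
    mat = pd.DataFrame(np.nan, index=cohorts, columns=cohorts)
    for ci in cohorts:
        xi, yi = _cohort_xy(X, meta, ci, features)
        mat.loc[ci, ci] = repeated_cv(
            xi, yi, folds=folds, repeats=repeats, spec=spec,
            seed=substream_seed(seed, f"diag_{ci}"),
        ).mean_auroc
        rf = _fit_with_tuning(
            xi.to_numpy(float), yi, spec, substream_seed(seed, f"transfer_{ci}")
        )
        for cj in cohorts:
            if cj == ci:
                continue
            xj, yj = _cohort_xy(X, meta, cj, features)
            mat.loc[ci, cj] = auroc(rf.predict_proba(xj.to_numpy(float))[:, 1], yj)
    return EvalMatrix(cohorts, mat)


def loco(
    X: pd.DataFrame,
    meta: StudyMetadata,
    features: list[str],
    spec: RandomForestSpec | None = None,
    seed: int = 0,
) -> pd.Series:
    """Leave-one-cohort-out: train on the pooled rest, test on the held-out cohort."""
    spec = spec or RandomForestSpec()
    cohorts = meta.cohorts
    if len(cohorts) < 3:
        raise ValueError("LOCO needs >= 3 cohorts")
    meta.require_both_groups()
    out = {}
    for held in cohorts:
        train_samples = [
            s for c in cohorts if c != held for s in meta.samples_of(c)
        ]
        xt = X.loc[train_samples, features].to_numpy(float)
        yt = _case_indicator(meta.data.loc[train_samples, "group"])
        rf = _fit_with_tuning(xt, yt, spec, substream_seed(seed, f"loco_{held}"))
        xh, yh = _cohort_xy(X, meta, held, features)
        out[held] = auroc(rf.predict_proba(xh.to_numpy(float))[:, 1], yh)
    return pd.Series(out)


def aggregate_importance(per_cohort_importance: dict[str, pd.Series]) -> list[str]:
    """Rank aggregation of per-cohort Gini importances.

    Features are ordered by the mean of their within-cohort ranks (1 = most
    important); ties break by mean raw importance (descending), then id.
    """
    cohorts = list(per_cohort_importance)
    if not cohorts:
        raise ValueError("no importances supplied")
    feats = list(per_cohort_importance[cohorts[0]].index)
    for c, s in per_cohort_importance.items():
        if set(s.index) != set(feats):
            raise ValueError(f"cohort {c!r} importance missing features")
    ranks = pd.DataFrame(
        {c: s.rank(ascending=False, method="average") for c, s in per_cohort_importance.items()}
    )
    mean_rank = ranks.mean(axis=1)
    mean_imp = pd.DataFrame(per_cohort_importance).mean(axis=1)
    order = pd.DataFrame({"rank": mean_rank, "neg_imp": -mean_imp})
    order["id"] = order.index
    return list(order.sort_values(["rank", "neg_imp", "id"]).index)


@dataclass
class PanelTrace:
    ranked_features: list[str]
    auroc_at_size: dict[int, float]
    chosen_size: int
    chosen_panel: list[str] = field(default_factory=list)


def incremental_panel(
    X: pd.DataFrame,
    y,
    ranked_features: list[str],
    max_size: int,
    spec: RandomForestSpec | None = None,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    plateau_tol: float = 0.001,
) -> PanelTrace:
    """Add features by rank; stop at the smallest size within tol of the max AUROC."""
    if not ranked_features:
        raise ValueError("empty ranking")
    if max_size > len(ranked_features):
        raise ValueError("max_size exceeds available features")
    auroc_at_size: dict[int, float] = {}
    for s in range(1, max_size + 1):
        cols = ranked_features[:s]
        auroc_at_size[s] = repeated_cv(
            X[cols], y, folds=folds, repeats=repeats, spec=spec,
            seed=substream_seed(seed, f"panel{s}"),
        ).mean_auroc
    best = max(auroc_at_size.values())
    chosen = min(s for s, a in auroc_at_size.items() if a >= best - plateau_tol)
    return PanelTrace(
        list(ranked_features), auroc_at_size, chosen, list(ranked_features[:chosen])
    )


def _restrict(X: pd.DataFrame, panel: list[str]) -> pd.DataFrame:
    missing = [f for f in panel if f not in X.columns]
    if len(missing) == len(panel):
        raise ValueError("no panel feature present in the table")
    out = X.reindex(columns=panel, fill_value=0.0)
    if missing:
        warnings.warn(f"panel features absent from table, zero-filled: {missing}")
    return out


def evaluate_external(
    panel: list[str],
    X_train: pd.DataFrame,
    meta_train: StudyMetadata,
    X_valid: pd.DataFrame,
    meta_valid: StudyMetadata,
    spec: RandomForestSpec | None = None,
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> dict:
    """Independent validation of a fixed marker panel on held-out cohorts.

    Three views: within-validation-cohort repeated CV; transfer (train on
    each discovery cohort, test on each validation cohort); pooled-discovery
    training tested on each validation cohort.  Missing panel features in
    the validation table are zero-filled with a warning.
    """
    spec = spec or RandomForestSpec()
    xv = _restrict(X_valid, panel)
    xt = _restrict(X_train, panel)
    cv = {}
    for c in meta_valid.cohorts:
        xc, yc = _cohort_xy(xv, meta_valid, c, panel)
        cv[c] = repeated_cv(
            xc, yc, folds=folds, repeats=repeats, spec=spec,
            seed=substream_seed(seed, f"extcv_{c}"),
        ).mean_auroc
    transfer = pd.DataFrame(np.nan, index=meta_train.cohorts, columns=meta_valid.cohorts)
    for ci in meta_train.cohorts:
        xi, yi = _cohort_xy(xt, meta_train, ci, panel)
        rf = _fit_with_tuning(xi.to_numpy(float), yi, spec, substream_seed(seed, f"ext_{ci}"))
        for cj in meta_valid.cohorts:
            xj, yj = _cohort_xy(xv, meta_valid, cj, panel)
            transfer.loc[ci, cj] = auroc(rf.predict_proba(xj.to_numpy(float))[:, 1], yj)
    rf_all = _fit_with_tuning(
        xt.to_numpy(float),
        _case_indicator(meta_train.data["group"]),
        spec,
        substream_seed(seed, "ext_pooled"),
    )
    pooled = {}
    for cj in meta_valid.cohorts:
        xj, yj = _cohort_xy(xv, meta_valid, cj, panel)
        pooled[cj] = auroc(rf_all.predict_proba(xj.to_numpy(float))[:, 1], yj)
    return {"cv": pd.Series(cv), "transfer": transfer, "pooled": pd.Series(pooled)}


def specificity_eval(
    panel: list[str],
    X_train: pd.DataFrame,
    meta_train: StudyMetadata,
    disease_sets: dict[str, tuple[pd.DataFrame, StudyMetadata]],
    spec: RandomForestSpec | None = None,
    seed: int = 0,
) -> pd.Series:
    """AUROC of the panel model on non-target case/control sets.

    The model is trained once on the pooled discovery data restricted to
    the panel; a disease whose signal is unrelated to the panel should
    score near 0.5.
    """
    spec = spec or RandomForestSpec()
    xt = _restrict(X_train, panel)
    rf = _fit_with_tuning(
        xt.to_numpy(float),
        _case_indicator(meta_train.data["group"]),
        spec,
        substream_seed(seed, "spec_train"),
    )
    out = {}
    for name, (xd, md) in disease_sets.items():
        xr = _restrict(xd, panel).loc[md.sample_ids]
        yd = _case_indicator(md.data["group"])
        out[name] = auroc(rf.predict_proba(xr.to_numpy(float))[:, 1], yd)
    return pd.Series(out)


def early_stage_eval(
    X: pd.DataFrame,
    meta: StudyMetadata,
    panel: list[str],
    spec: RandomForestSpec | None = None,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    run_loco: bool = True,
) -> dict:
    """Controls-vs-early-stage evaluation with per-fold class rebalancing.

    Keeps controls plus cases whose ``stage`` is ``early``, then runs
    repeated CV (majority class down-sampled inside every training fold)
    and, when each cohort retains early cases, a LOCO pass on the same
    down-sampling rule.
    """
    if "stage" not in meta.data.columns:
        raise ValueError("metadata has no stage column")
    m = meta.data
    keep = (m["group"] == "control") | ((m["group"] == "case") & (m["stage"] == "early"))
    sub = StudyMetadata(m[keep].copy())
    n_early = int(((sub.data["group"] == "case")).sum())
    if n_early == 0:
        raise ValueError("no early-stage cases")
    for c in sub.cohorts:
        if (sub.data.loc[sub.data["cohort"] == c, "group"] == "case").sum() == 0:
            raise ValueError(f"no early cases in cohort {c!r}")
    xs = _restrict(X.loc[sub.sample_ids], panel)
    ys = sub.data["group"]
    cv = repeated_cv(
        xs, ys, folds=folds, repeats=repeats, spec=spec,
        seed=substream_seed(seed, "early_cv"), balance=True,
    )
    out = {"cv_mean_auroc": cv.mean_auroc, "n_early_cases": n_early}
    if run_loco and len(sub.cohorts) >= 3:
        out["loco"] = loco(xs, sub, panel, spec=spec, seed=substream_seed(seed, "early_loco"))
    return out
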