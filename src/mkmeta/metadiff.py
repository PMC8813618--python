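"""Cross-cohort differential abundance: batch correction + fixed-effects meta-analysis.

The pipeline mirrors the covariate-adjusted meta-analytic approach used for
multi-study microbiome testing: relative abundances are arcsine-square-root
transformed, cohort (batch) effects are removed with a zero-preserving
empirical-Bayes location/scale adjustment (ComBat-style), a linear model
``abundance ~ group + age quartile + sex + BMI class`` is fitted within
each cohort, and per-cohort group coefficients are pooled with
inverse-variance fixed-effects weights.  Heterogeneity is summarized by
Cochran's Q and I^2; multiplicity by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import (
    AbundanceTable,
    StudyMetadata,
    arcsine_sqrt,
    discretize_covariates,
    to_relative,
)

log = logging.getLogger(__name__)

FOLD_CHANGE_PSEUDO = 1e-6
VARIANCE_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# ComBat-style batch adjustment (zero-preserving)
# ---------------------------------------------------------------------------

def _covariate_design(meta_disc: pd.DataFrame) -> np.ndarray:
    """Dummy-coded covariates (age quartile, sex, BMI class), no intercept."""
    parts = []
    for col in ("age_quartile", "sex", "bmi_category"):
        d = pd.get_dummies(meta_disc[col], prefix=col, drop_first=True, dtype=float)
        parts.append(d.to_numpy())
    return np.hstack(parts) if parts else np.empty((len(meta_disc), 0))


def combat_adjust(
    transformed: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    eb_iterations: int = 100,
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch adjustment of a transformed matrix.

    Per feature: standardize against a covariate-adjusted grand model,
    shrink per-batch means (normal prior) and variances (inverse-gamma
    prior, method-of-moments hyperparameters, iterated to convergence),
    then restore the grand location/scale.  Entries that were exactly zero
    before adjustment stay exactly zero (structural absences are not
    invented into presences) and adjusted values are clipped at zero.

    Parameters
    ----------
    transformed:
        samples x features matrix on the arcsine-sqrt scale.
    batch:
        per-sample batch (cohort) labels, aligned with ``transformed``.
    covariates:
        optional samples x covariates dummy design (no intercept, no batch
        columns) preserved during standardization.
    """
    y = transformed.to_numpy(dtype=float).copy()
    batch = pd.Series(batch).reindex(transformed.index)
    batches = list(pd.unique(batch))
    if len(batches) < 2:
        return transformed.copy()
    n, p = y.shape
    zero_mask = y == 0

    b_design = pd.get_dummies(batch, dtype=float)[batches].to_numpy()
    n_b = b_design.sum(axis=0)
    for bi, b in enumerate(batches):
        if np.allclose(y[b_design[:, bi] == 1].var(axis=0), 0):
            raise ValueError(f"batch {b!r} has zero variance for all features")
    x_cov = (
        covariates.reindex(transformed.index).to_numpy(dtype=float)
        if covariates is not None
        else np.empty((n, 0))
    )
    design = np.hstack([b_design, x_cov])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    grand_mean = (n_b / n) @ beta[: len(batches)]
    fitted = design @ beta
    var_pooled = ((y - fitted) ** 2).mean(axis=0)
    var_pooled = np.maximum(var_pooled, VARIANCE_FLOOR)

    stand_mean = grand_mean[None, :] + x_cov @ beta[len(batches):]
    z = (y - stand_mean) / np.sqrt(var_pooled)[None, :]

    adjusted = z.copy()
    for bi, b in enumerate(batches):
        idx = b_design[:, bi] == 1
        zb = z[idx]
        gamma_hat = zb.mean(axis=0)
        delta_hat = zb.var(axis=0, ddof=1)
        # hyperpriors by method of moments across features
        gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        d_bar, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        lam = (d_bar**2 + 2 * s2) / s2 if s2 > 0 else 2.0 + 1e3
        theta = (d_bar**3 + d_bar * s2) / s2 if s2 > 0 else d_bar
        m = idx.sum()
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        for _ in range(eb_iterations):
            g_new = (m * tau2 * gamma_hat + delta_star * gamma_bar) / (m * tau2 + delta_star)
            ssq = ((zb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * ssq) / (m / 2 + lam - 1)
            if np.max(np.abs(g_new - gamma_star)) < 1e-8 and np.max(
                np.abs(d_new - delta_star)
            ) < 1e-8:
                gamma_star, delta_star = g_new, d_new
                break
            gamma_star, delta_star = g_new, d_new
        delta_star = np.maximum(delta_star, VARIANCE_FLOOR)
        adjusted[idx] = (zb - gamma_star[None, :]) / np.sqrt(delta_star)[None, :]

    out = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    out = np.clip(out, 0.0, None)
    out[zero_mask] = 0.0
    return pd.DataFrame(out, index=transformed.index, columns=transformed.columns)


# ---------------------------------------------------------------------------
# Per-cohort effects and fixed-effects pooling
# ---------------------------------------------------------------------------

@dataclass
class CohortEffect:
    feature_id: str
    cohort: str
    beta: float
    se: float
    n: int


def _group_design(meta_disc: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + case indicator + discrete covariates; case column is 1."""
    cols = ["intercept", "group[case]"]
    x = [np.ones(len(meta_disc)), (meta_disc["group"] == "case").to_numpy(float)]
    for col in ("age_quartile", "sex", "bmi_category"):
        d = pd.get_dummies(meta_disc[col], prefix=col, drop_first=True, dtype=float)
        for c in d.columns:
            cols.append(c)
            x.append(d[c].to_numpy())
    return np.column_stack(x), cols


def cohort_effects(
    adjusted: pd.DataFrame, meta: StudyMetadata, cohort: str
) -> pd.DataFrame:
    """Covariate-adjusted group coefficients for all features in one cohort.

    Least-squares fit of transformed abundance on case/control status plus
    discretized age, sex and BMI.  Returns a DataFrame indexed by feature
    with columns beta, se, n; degenerate (zero-residual-variance) features
    get NaN and a log note.
    """
    samples = meta.samples_of(cohort)
    md = discretize_covariates(
        StudyMetadata(meta.data.loc[samples])
    ).data
    if set(md["group"]) != {"case", "control"}:
        raise ValueError(f"cohort {cohort!r} lacks both groups")
    x, colnames = _group_design(md)
    y = adjusted.loc[samples].to_numpy(dtype=float)
    n, k = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        # name the first column whose removal restores full rank
        for j in range(k - 1, 0, -1):
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank:
                raise ValueError(f"rank-deficient design: collinear column {colnames[j]!r}")
        raise ValueError("rank-deficient design")
    if n < k + 1:
        raise ValueError(f"cohort {cohort!r}: n={n} too small for {k} design columns")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta_all = xtx_inv @ x.T @ y          # k x p
    resid = y - x @ beta_all
    sigma2 = (resid**2).sum(axis=0) / (n - k)
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])
    degenerate = sigma2 <= VARIANCE_FLOOR
    if degenerate.any():
        log.info("cohort %s: %d degenerate feature(s) skipped", cohort, degenerate.sum())
    out = pd.DataFrame(
        {"beta": beta_all[1], "se": se, "n": n}, index=adjusted.columns
    )
    out.loc[degenerate, ["beta", "se"]] = np.nan
    return out


def cohort_effect(
    adjusted: pd.DataFrame, meta: StudyMetadata, feature: str, cohort: str
) -> CohortEffect:
    """Single-feature variant of :func:`cohort_effects`."""
    row = cohort_effects(adjusted[[feature]], meta, cohort).loc[feature]
    if not np.isfinite(row["se"]) or row["se"] <= 0:
        raise ValueError(f"degenerate feature {feature!r} in cohort {cohort!r}")
    return CohortEffect(feature, cohort, float(row["beta"]), float(row["se"]), int(row["n"]))


@dataclass
class MetaDiffResult:
    feature_id: str
    beta_pooled: float
    se_pooled: float
    z: float
    p: float
    Q: float
    I2: float
    fold_change: float = np.nan
    fdr: float = np.nan

    @property
    def direction(self) -> str:
        return "up" if self.beta_pooled >= 0 else "down"


def fixed_effects_pool(effects: list[CohortEffect]) -> MetaDiffResult:
    """Inverse-variance fixed-effects pooling with Cochran's Q and I^2.

    w_k = 1/se_k^2; beta = sum(w b)/sum(w); se = sum(w)^{-1/2};
    Q = sum w (b - beta)^2; I^2 = max(0, (Q - df)/Q) * 100.
    """
    if not effects:
        raise ValueError("no cohort effects to pool")
    cohorts = [e.cohort for e in effects]
    if len(set(cohorts)) != len(cohorts):
        raise ValueError("duplicate cohorts in pooling input")
    betas = np.array([e.beta for e in effects])
    ses = np.array([e.se for e in effects])
    if np.any(ses <= 0) or not np.all(np.isfinite(ses)):
        raise ValueError("non-positive or non-finite standard error")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    q = float((w * (betas - beta) ** 2).sum())
    df = len(effects) - 1
    i2 = 0.0 if q <= df or q == 0 else 100.0 * (q - df) / q
    return MetaDiffResult(effects[0].feature_id, beta, se, z, p, q, i2)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# The per-kingdom differential pipeline
# ---------------------------------------------------------------------------

def meta_differential_abundance(
    table: AbundanceTable,
    meta: StudyMetadata,
    batch_correct: bool = True,
) -> pd.DataFrame:
    """Full differential-abundance meta-analysis of one abundance table.

    Steps: relative abundance -> arcsine-sqrt -> ComBat-style cohort
    adjustment -> per-cohort covariate-adjusted effects -> fixed-effects
    pooling -> BH FDR and log2 fold change (case vs control mean relative
    abundance, pseudo-count 1e-6).

    Returns a DataFrame indexed by feature with columns beta_pooled,
    se_pooled, z, p, Q, I2, fold_change, fdr, direction, n_cohorts.
    Features degenerate in every cohort are dropped.
    """
    meta.require_both_groups()
    rel = table if table.is_relative else to_relative(table)
    rel = rel.subset_samples(meta.sample_ids)
    transformed = arcsine_sqrt(rel)
    if batch_correct and len(meta.cohorts) > 1:
        cov = _covariate_design(discretize_covariates(meta).data)
        cov_df = pd.DataFrame(cov, index=meta.data.index)
        transformed = combat_adjust(transformed, meta.data["cohort"], cov_df)
    per_cohort = {c: cohort_effects(transformed, meta, c) for c in meta.cohorts}

    is_case = (meta.data["group"] == "case").to_numpy()
    case_mean = rel.data.to_numpy()[is_case].mean(axis=0)
    ctrl_mean = rel.data.to_numpy()[~is_case].mean(axis=0)
    fc = np.log2((case_mean + FOLD_CHANGE_PSEUDO) / (ctrl_mean + FOLD_CHANGE_PSEUDO))
    fc = pd.Series(fc, index=rel.data.columns)

    rows = []
    for f in rel.data.columns:
        effs = [
            CohortEffect(f, c, float(t.loc[f, "beta"]), float(t.loc[f, "se"]), int(t.loc[f, "n"]))
            for c, t in per_cohort.items()
            if np.isfinite(t.loc[f, "se"]) and t.loc[f, "se"] > 0
        ]
        if not effs:
            log.info("feature %s degenerate in all cohorts; dropped", f)
            continue
        r = fixed_effects_pool(effs)
        rows.append(
            {
                "feature_id": f,
                "beta_pooled": r.beta_pooled,
                "se_pooled": r.se_pooled,
                "z": r.z,
                "p": r.p,
                "Q": r.Q,
                "I2": r.I2,
                "fold_change": fc[f],
                "direction": r.direction,
                "n_cohorts": len(effs),
            }
        )
    res = pd.DataFrame(rows).set_index("feature_id")
    res["fdr"] = bh_fdr(res["p"].to_numpy())
    res["kingdom"] = [table.kingdom(f) for f in res.index]
    return res


def differential_features(
    results: pd.DataFrame, alpha: float = 0.05, on: str = "p"
) -> pd.DataFrame:
    """Features whose chosen statistic (raw p or BH FDR) falls below alpha."""
    if on not in ("p", "fdr"):
        raise ValueError("on must be 'p' or 'fdr'")
    return results[results[on] < alpha].copy()
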