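"""Alpha/beta diversity, classical ordination and PERMANOVA.

Alpha diversity is summarized by the Shannon index H = -sum p ln p and the
Gini-Simpson index 1 - sum p^2.  Community differences are assessed on
Bray-Curtis distances with principal coordinate analysis and a one-factor
PERMANOVA using the plus-one permutation p-value convention
(min p = 1/(B+1)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
import statsmodels.formula.api as smf

from .profiles import AbundanceTable, StudyMetadata, discretize_covariates

log = logging.getLogger(__name__)


def shannon(p: np.ndarray) -> float:
    """Shannon index H = -sum_{p_i>0} p_i ln p_i of a composition."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative entries")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("input must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson(p: np.ndarray) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative entries")
    return float(1.0 - (p**2).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon and Simpson indices of a relative table."""
    if not table.is_relative:
        raise ValueError("alpha_diversity expects a relative table")
    rows = {
        s: (shannon(table.data.loc[s].to_numpy()), simpson(table.data.loc[s].to_numpy()))
        for s in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["shannon", "simpson"])


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v), in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("negative entries")
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(u - v).sum() / denom)


def distance_matrix(table: AbundanceTable) -> pd.DataFrame:
    """All-pairs Bray-Curtis distances as a symmetric DataFrame."""
    d = squareform(pdist(table.data.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    a = -0.5 * dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dist: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinates) of a distance matrix.

    Returns coordinates on the first ``k`` positive axes (ordered by
    descending eigenvalue) and the full eigenvalue spectrum, negative
    eigenvalues included for inspection.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    g = _gower_center(d)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10).sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive axes available; truncating k={k}")
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    idx = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(d.shape[0])
    cols = [f"PCo{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=idx, columns=cols), evals


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


def permanova(
    dist: pd.DataFrame, labels, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    pseudo-F partitions the total sum of squared distances into between-
    and within-group parts; significance comes from free label permutation
    with p = (1 + #{F_perm >= F_obs}) / (B + 1).
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match the distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError(f"singleton group: {uniq[np.argmin(counts)]!r}")
    d2 = d**2
    ss_total = d2.sum() / (2 * n)

    def ss_within(assign: np.ndarray) -> float:
        ss = 0.0
        for g in range(len(uniq)):
            idx = np.flatnonzero(assign == g)
            ss += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return ss

    a = len(uniq)
    ssw = ss_within(inv)
    ssb = ss_total - ssw
    f_obs = (ssb / (a - 1)) / (ssw / (n - a))
    r2 = ssb / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(inv)
        ssw_p = ss_within(perm)
        f_p = ((ss_total - ssw_p) / (a - 1)) / (ssw_p / (n - a))
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations)


def shannon_group_test(table: AbundanceTable, meta: StudyMetadata) -> pd.Series:
    """Covariate-adjusted linear model for the case/control Shannon contrast.

    OLS of Shannon ~ group + cohort + age quartile + sex + BMI class; the
    returned Series carries the group coefficient, its standard error and
    two-sided p-value.  This is the package's documented substitute for a
    mixed-model test of alpha diversity.
    """
    alpha = alpha_diversity(table)
    dm = discretize_covariates(meta).data.copy()
    dm["shannon"] = alpha["shannon"]
    model = smf.ols(
        "shannon ~ C(group, Treatment('control')) + C(cohort) + C(age_quartile)"
        " + C(sex) + C(bmi_category)",
        data=dm,
    ).fit()
    term = [t for t in model.params.index if t.startswith("C(group")][0]
    return pd.Series(
        {
            "beta": model.params[term],
            "se": model.bse[term],
            "p": model.pvalues[term],
            "n": int(model.nobs),
        }
    )
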