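"""Compositionality-corrected co-abundance networks and their cross-cohort meta-analysis.

Correlations between taxa cannot be read off relative abundances directly:
the closure to a constant sum induces spurious negative dependence.  The
estimator here follows the SparCC/FastSpar idea — under a sparsity
assumption the "basis" (absolute-scale) variances solve a linear system in
the log-ratio variances t_ij = var ln(x_i/x_j), and basis correlations
follow as rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j).  Strongly
correlated pairs violate the sparsity assumption, so the strongest pairs
are iteratively excluded from the system and the estimate refined (20
iterations by default).  Per-cohort significance comes from permutations
that recompute the full refined estimator; cohorts are then combined per
edge by Fisher's method on p-values and the median correlation magnitude,
gated at FDR < 1e-5 and |median r| > 0.3 (fair) / 0.6 (moderate).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .metadiff import bh_fdr
from .profiles import AbundanceTable, StudyMetadata

log = logging.getLogger(__name__)

OMEGA_FLOOR = 1e-8


def estimate_fractions(counts: np.ndarray) -> np.ndarray:
    """Posterior-mean fractions (count + 1) / (rowsum + D) under a flat Dirichlet prior.

    Deterministic single-point estimate (no Dirichlet resampling), so the
    whole network pipeline is reproducible without averaging.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    d = counts.shape[1]
    rowsum = counts.sum(axis=1, keepdims=True)
    return (counts + 1.0) / (rowsum + d)


def _logratio_variances(fracs: np.ndarray) -> np.ndarray:
    """t_ij = var over samples of ln(x_i / x_j), sample variance (ddof=1)."""
    logx = np.log(fracs)
    v = logx.var(axis=0, ddof=1)
    cov = np.cov(logx, rowvar=False)
    t = v[:, None] + v[None, :] - 2 * cov
    np.fill_diagonal(t, 0.0)
    return t


def _solve_basis(t: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    With no exclusions the system t_i = (D-2) w_i^2 + sum_j w_j^2 has the
    closed-form solution w_i^2 = (t_i - W)/(D-2), W = sum t_i / (2D-2);
    excluded pairs drop out of both the t_i sums and the coefficient
    matrix (per-feature degrees replace D-1).
    """
    d = t.shape[0]
    mask = np.ones((d, d), dtype=bool)
    np.fill_diagonal(mask, False)
    for i, j in excluded:
        mask[i, j] = mask[j, i] = False
    t_i = np.where(mask, t, 0.0).sum(axis=1)
    m_i = mask.sum(axis=1)  # remaining partners per feature
    a = mask.astype(float)
    np.fill_diagonal(a, m_i)
    omega2, *_ = np.linalg.lstsq(a, t_i, rcond=None)
    low = omega2 < OMEGA_FLOOR
    if low.any():
        warnings.warn(f"{int(low.sum())} basis variance(s) floored at {OMEGA_FLOOR}")
        omega2 = np.maximum(omega2, OMEGA_FLOOR)
    return omega2


def _rho_from(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    w = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t) / (2 * np.outer(w, w))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def basis_correlations(fracs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass basis correlation matrix and basis variances.

    Requires D >= 4 features (the approximation is underdetermined below
    that) and n >= 10 samples.
    """
    fracs = np.asarray(fracs, dtype=float)
    n, d = fracs.shape
    if d < 4:
        raise ValueError("need at least 4 features (system underdetermined)")
    if n < 10:
        raise ValueError("need at least 10 samples")
    t = _logratio_variances(fracs)
    omega2 = _solve_basis(t, set())
    return _rho_from(t, omega2), omega2


def refine_exclusions(
    fracs: np.ndarray,
    n_exclusions: int = 20,
    exclusion_threshold: float = 0.1,
) -> np.ndarray:
    """Iteratively exclude the strongest pair and re-solve (SparCC refinement).

    Each of up to ``n_exclusions`` iterations removes the not-yet-excluded
    pair with the largest |rho| above ``exclusion_threshold`` from the
    estimating equations, then recomputes basis variances and correlations.
    Features left with fewer than 3 partners are frozen at their last
    estimate.  Stops early when no pair exceeds the threshold.
    """
    fracs = np.asarray(fracs, dtype=float)
    t = _logratio_variances(fracs)
    d = t.shape[0]
    if d < 4:
        raise ValueError("need at least 4 features (system underdetermined)")
    excluded: set[tuple[int, int]] = set()
    frozen = np.zeros(d, dtype=bool)
    omega2 = _solve_basis(t, excluded)
    rho = _rho_from(t, omega2)
    for _ in range(n_exclusions):
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        cand[frozen, :] = 0.0
        cand[:, frozen] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        partners = np.ones((d, d), dtype=bool)
        np.fill_diagonal(partners, False)
        for a, b in excluded:
            partners[a, b] = partners[b, a] = False
        newly_frozen = (partners.sum(axis=1) < 3) & ~frozen
        if newly_frozen.any():
            warnings.warn(
                f"{int(newly_frozen.sum())} feature(s) frozen with <3 remaining partners"
            )
            frozen |= newly_frozen
        omega2_new = _solve_basis(t, excluded)
        omega2 = np.where(frozen, omega2, omega2_new)
        rho_new = _rho_from(t, omega2)
        keep_old = frozen[:, None] | frozen[None, :]
        rho = np.where(keep_old, rho, rho_new)
    return rho


def sparcc_correlations(
    counts: np.ndarray, n_exclusions: int = 20, exclusion_threshold: float = 0.1
) -> np.ndarray:
    """Counts -> posterior fractions -> refined basis correlation matrix."""
    return refine_exclusions(
        estimate_fractions(counts), n_exclusions, exclusion_threshold
    )


def permutation_pvalues(
    counts: np.ndarray,
    rho_observed: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    n_exclusions: int = 20,
    exclusion_threshold: float = 0.1,
) -> np.ndarray:
    """Two-sided permutation p-values for every correlation.

    Each permutation shuffles every feature's counts across samples
    independently (destroying all dependence, preserving margins) and
    recomputes the *full refined* estimator, so the null distribution
    matches the actual statistic.  p_ij = (1 + #{|rho_perm| >= |rho_obs|})
    / (B + 1); the diagonal is set to 1.
    """
    counts = np.asarray(counts)
    rng = np.random.default_rng(seed)
    d = counts.shape[1]
    exceed = np.zeros((d, d), dtype=int)
    abs_obs = np.abs(rho_observed)
    perm = counts.copy()
    for _ in range(n_permutations):
        for j in range(d):
            perm[:, j] = rng.permutation(perm[:, j])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho_p = sparcc_correlations(perm, n_exclusions, exclusion_threshold)
        exceed += np.abs(rho_p) >= abs_obs
    p = (1 + exceed) / (n_permutations + 1)
    np.fill_diagonal(p, 1.0)
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# Cross-cohort combination
# ---------------------------------------------------------------------------

@dataclass
class EdgeEstimate:
    feature_i: str
    feature_j: str
    r: float
    p: float
    cohort: str


def cohort_edge_estimates(
    table: AbundanceTable,
    meta: StudyMetadata,
    group: str,
    features: list[str] | None = None,
    n_permutations: int = 1000,
    n_exclusions: int = 20,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cohort refined correlations and permutation p for one phenotype group.

    Returns a long DataFrame (feature_i, feature_j, r, p, cohort) over all
    unordered pairs, one block per cohort.
    """
    feats = features or table.feature_ids
    rows = []
    for ci, cohort in enumerate(meta.cohorts):
        samples = [
            s
            for s in meta.samples_of(cohort)
            if meta.data.loc[s, "group"] == group
        ]
        counts = table.data.loc[samples, feats].to_numpy()
        rho = sparcc_correlations(counts, n_exclusions, exclusion_threshold)
        p = permutation_pvalues(
            counts, rho, n_permutations, seed=seed + ci,
            n_exclusions=n_exclusions, exclusion_threshold=exclusion_threshold,
        )
        for a, b in itertools.combinations(range(len(feats)), 2):
            rows.append(
                {
                    "feature_i": feats[a],
                    "feature_j": feats[b],
                    "r": float(rho[a, b]),
                    "p": float(p[a, b]),
                    "cohort": cohort,
                }
            )
    return pd.DataFrame(rows)


def fisher_combine(pvals) -> tuple[float, float]:
    """Fisher's method: chi2 = -2 sum ln p, upper tail at 2k df.

    Exact zeros are floored to the smallest positive float with a warning
    (permutation p-values cannot legitimately be 0 under the plus-one rule).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-value floored before Fisher combination")
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = float(-2 * np.log(p).sum())
    return chi2, float(stats.chi2.sf(chi2, 2 * p.size))


@dataclass
class MetaNetwork:
    """Combined cross-cohort network: one row per retained edge."""

    edges: pd.DataFrame  # feature_i, feature_j, kingdom_i, kingdom_j,
    #                      median_r, fisher_chi2, combined_p, fdr, n_cohorts,
    #                      kingdom_pair, tier
    group: str = ""
    all_candidates: pd.DataFrame | None = None


def tier_of(median_r: float, fair: float = 0.3, moderate: float = 0.6) -> str:
    a = abs(median_r)
    if a > moderate:
        return "moderate"
    if a > fair:
        return "fair"
    return "none"


def build_meta_network(
    edge_estimates: pd.DataFrame,
    kingdom_of: dict[str, str],
    fdr_cut: float = 1e-5,
    r_cut: float = 0.3,
    group: str = "",
) -> MetaNetwork:
    """Combine per-cohort edges: median r, Fisher p, BH FDR, |r| gate, tiers.

    Edges observed in only a subset of cohorts are combined over the
    available cohorts with ``n_cohorts`` recorded.  FDR is computed across
    all candidate pairs of this network (one phenotype group).
    """
    if edge_estimates.empty:
        raise ValueError("no edge estimates supplied")
    rows = []
    for (fi, fj), grp in edge_estimates.groupby(["feature_i", "feature_j"], sort=True):
        chi2, cp = fisher_combine(grp["p"].to_numpy())
        med = float(np.median(grp["r"]))
        ki = kingdom_of.get(fi, "bacteria")
        kj = kingdom_of.get(fj, "bacteria")
        rows.append(
            {
                "feature_i": fi,
                "feature_j": fj,
                "kingdom_i": ki,
                "kingdom_j": kj,
                "kingdom_pair": "intra" if ki == kj else "inter",
                "median_r": med,
                "fisher_chi2": chi2,
                "combined_p": cp,
                "n_cohorts": len(grp),
            }
        )
    cand = pd.DataFrame(rows)
    cand["fdr"] = bh_fdr(cand["combined_p"].to_numpy())
    cand["tier"] = [tier_of(r, fair=r_cut) for r in cand["median_r"]]
    kept = cand[(cand["fdr"] < fdr_cut) & (cand["median_r"].abs() > r_cut)].copy()
    return MetaNetwork(kept.reset_index(drop=True), group=group, all_candidates=cand)


def group_meta_networks(
    table: AbundanceTable,
    meta: StudyMetadata,
    features: list[str] | None = None,
    n_permutations: int = 1000,
    fdr_cut: float = 1e-5,
    r_cut: float = 0.3,
    seed: int = 0,
    **sparcc_kw,
) -> dict[str, MetaNetwork]:
    """Case and control meta-networks from per-cohort refined estimates."""
    out = {}
    for group in ("case", "control"):
        est = cohort_edge_estimates(
            table, meta, group, features, n_permutations, seed=seed, **sparcc_kw
        )
        out[group] = build_meta_network(
            est, dict(table.kingdom_of), fdr_cut, r_cut, group=group
        )
    return out


def network_summary(network: MetaNetwork) -> dict:
    """Node/edge counts, intra/inter-kingdom split, signed-edge counts."""
    e = network.edges
    nodes = set(e["feature_i"]) | set(e["feature_j"]) if len(e) else set()
    return {
        "n_nodes": len(nodes),
        "n_edges": int(len(e)),
        "n_intra": int((e["kingdom_pair"] == "intra").sum()) if len(e) else 0,
        "n_inter": int((e["kingdom_pair"] == "inter").sum()) if len(e) else 0,
        "n_positive": int((e["median_r"] > 0).sum()) if len(e) else 0,
        "n_negative": int((e["median_r"] < 0).sum()) if len(e) else 0,
    }


def to_graphml(network: MetaNetwork, path) -> None:
    g = nx.Graph()
    for _, row in network.edges.iterrows():
        g.add_node(row["feature_i"], kingdom=row["kingdom_i"])
        g.add_node(row["feature_j"], kingdom=row["kingdom_j"])
        g.add_edge(
            row["feature_i"],
            row["feature_j"],
            median_r=float(row["median_r"]),
            fdr=float(row["fdr"]),
            tier=row["tier"],
        )
    nx.write_graphml(g, path)
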