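"""Shadow-feature (Boruta-style) relevance selection and collinearity filtering.

Each iteration appends one shuffled "shadow" copy of every surviving real
feature, fits a random forest on the augmented matrix, and scores a hit
for real features whose Gini importance exceeds the maximum shadow
importance.  A two-sided binomial test on the hit count (success
probability 0.5 under irrelevance), Bonferroni-corrected across features
still undecided, confirms or rejects features; the loop ends when nothing
is tentative or at ``max_runs``.  Confirmed candidates then pass a greedy
collinearity filter keeping only features whose absolute Pearson
correlation with every already-kept, higher-ranked feature stays below a
threshold (0.7 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .utils import KINGDOMS

log = logging.getLogger(__name__)


@dataclass
class BorutaDecision:
    feature_id: str
    status: str  # confirmed | tentative | rejected
    hits: int
    runs: int
    p_adjusted: float


def boruta_select(
    X: pd.DataFrame,
    y,
    max_runs: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 300,
) -> list[BorutaDecision]:
    """Shadow-feature relevance selection over a samples x features matrix.

    Parameters
    ----------
    X, y:
        feature matrix and binary labels; at least two classes with >= 5
        samples each.
    max_runs:
        iteration cap (matching the R package's ``maxRuns`` default 1000).
    alpha:
        per-test significance level before Bonferroni correction
        (``pValue`` = 0.05, ``mcAdj`` = True analogue).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("constant y: need at least 2 classes")
    if counts.min() < 5:
        raise ValueError("need at least 5 samples per class")
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    status = {f: "tentative" for f in features}
    hits = {f: 0 for f in features}
    runs = {f: 0 for f in features}
    p_adj = {f: 1.0 for f in features}

    xvals = X.to_numpy(dtype=float)
    col_of = {f: i for i, f in enumerate(features)}
    run = 0
    while run < max_runs and any(s == "tentative" for s in status.values()):
        run += 1
        surviving = [f for f in features if status[f] != "rejected"]
        idx = [col_of[f] for f in surviving]
        real = xvals[:, idx]
        shadow = real.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(np.hstack([real, shadow]), y)
        imp = rf.feature_importances_
        real_imp, shadow_imp = imp[: len(surviving)], imp[len(surviving):]
        shadow_max = shadow_imp.max()
        for f, v in zip(surviving, real_imp):
            runs[f] += 1
            if v > shadow_max:
                hits[f] += 1
        # binomial decision, Bonferroni over features still undecided
        undecided = [f for f in surviving if status[f] == "tentative"]
        n_tests = max(1, len(undecided))
        for f in undecided:
            p_hi = float(stats.binom.sf(hits[f] - 1, runs[f], 0.5))
            p_lo = float(stats.binom.cdf(hits[f], runs[f], 0.5))
            if p_hi * n_tests < alpha:
                status[f] = "confirmed"
                p_adj[f] = min(1.0, p_hi * n_tests)
            elif p_lo * n_tests < alpha:
                status[f] = "rejected"
                p_adj[f] = min(1.0, p_lo * n_tests)
    for f in features:
        if status[f] == "tentative":
            p_hi = stats.binom.sf(hits[f] - 1, runs[f], 0.5) if runs[f] else 1.0
            p_adj[f] = min(1.0, p_hi * len(features))
    log.info(
        "boruta: %d confirmed, %d rejected, %d tentative after %d runs",
        sum(s == "confirmed" for s in status.values()),
        sum(s == "rejected" for s in status.values()),
        sum(s == "tentative" for s in status.values()),
        run,
    )
    return [
        BorutaDecision(f, status[f], hits[f], runs[f], float(p_adj[f])) for f in features
    ]


def confirmed_features(decisions: list[BorutaDecision]) -> list[str]:
    """Confirmed feature ids in input order (tentative are excluded)."""
    return [d.feature_id for d in decisions if d.status == "confirmed"]


def collinearity_filter(
    candidates: list[str],
    X: pd.DataFrame,
    r_threshold: float = 0.7,
    ranking: list[str] | None = None,
) -> list[str]:
    """Greedy de-correlation pass in descending importance order.

    A candidate is kept iff its absolute Pearson correlation with every
    already-kept feature is strictly below ``r_threshold``.  ``ranking``
    (most important first) must cover all candidates; by default the
    candidate order itself is the ranking.
    """
    missing = [c for c in candidates if c not in X.columns]
    if missing:
        raise ValueError(f"candidates not in X: {missing}")
    if ranking is None:
        ranking = list(candidates)
    not_ranked = set(candidates) - set(ranking)
    if not_ranked:
        raise ValueError(f"ranking missing candidates: {sorted(not_ranked)}")
    order = [f for f in ranking if f in set(candidates)]
    kept: list[str] = []
    for f in order:
        x = X[f].to_numpy(dtype=float)
        ok = True
        for g in kept:
            r = _pearson(x, X[g].to_numpy(dtype=float))
            if abs(r) >= r_threshold:
                ok = False
                break
        if ok:
            kept.append(f)
    return kept


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def combine_kingdom_features(per_kingdom: dict[str, list[str]]) -> list[str]:
    """Union of per-kingdom kept lists in stable kingdom-then-rank order."""
    seen: set[str] = set()
    out: list[str] = []
    order = [k for k in KINGDOMS if k in per_kingdom] + [
        k for k in per_kingdom if k not in KINGDOMS
    ]
    for k in order:
        for f in per_kingdom[k]:
            if f in seen:
                raise ValueError(f"feature id collision across kingdoms: {f!r}")
            seen.add(f)
            out.append(f)
    return out
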