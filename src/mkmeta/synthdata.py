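"""Multi-cohort, multi-kingdom compositional count simulator with known truth.

The generator produces the study layout the downstream stages expect:
several balanced case/control cohorts profiled over bacterial, fungal,
archaeal and viral features, with per-cohort batch shifts, planted
disease markers of known sign, mild covariate confounding, correlated
feature blocks (within and across kingdoms) and structural zeros.

Generation model, in order:

1. per-feature baseline log-abundances from a normal with an added
   exponential right tail (a few dominant taxa, many rare ones);
2. correlated blocks induced by a Gaussian copula on the log scale,
   matching a requested basis correlation matrix exactly;
3. per-cohort, per-feature batch shifts ~ N(0, batch_sd^2);
4. signed marker effects added to case samples on the log scale;
5. covariate contributions (age, sex, BMI) for a random 10% of features;
6. exponentiation and closure to a composition, then independent
   Bernoulli dropout (structural zeros, applied before counts are drawn);
7. multinomial counts with a Poisson-distributed library size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import AbundanceTable, StudyMetadata
from .utils import KINGDOMS

LOG_SD = 1.0           # log-scale SD of per-sample biological variation
TAIL_SCALE = 1.5       # exponential tail added to baseline log-abundances
COVARIATE_FRACTION = 0.1
CASE_AGE_SHIFT = 2.0   # years; mild confounding of age with disease status


@dataclass
class SimulationConfig:
    """Study-design knobs for :func:`generate_study`.

    ``correlated_blocks`` is a list of ``(feature_ids, target_r)`` pairs;
    each block receives pairwise correlation ``target_r`` on the log scale
    through the copula.  Feature ids are ``<kingdom>__f<k>`` (zero-based).
    """

    n_cohorts: int = 5
    samples_per_cohort_per_class: int = 30
    n_features_per_kingdom: dict = field(
        default_factory=lambda: {"bacteria": 100, "fungi": 100, "archaea": 100, "viruses": 100}
    )
    n_markers_per_kingdom: dict = field(
        default_factory=lambda: {"bacteria": 10, "fungi": 10, "archaea": 10, "viruses": 10}
    )
    marker_log_fold_effect: float = 1.0
    batch_sd: float = 0.3
    correlated_blocks: list = field(default_factory=list)
    zero_inflation: float = 0.1
    library_size_mean: int = 20000
    covariate_effect_sd: float = 0.1
    seed: int = 0
    # fraction of cases flagged early-stage, and the scaling of the marker
    # effect in those samples (1.0 = same signal as advanced disease)
    early_stage_fraction: float = 0.5
    early_effect_scale: float = 1.0
    # optional explicit marker ids per kingdom (overrides random choice)
    marker_features: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if self.samples_per_cohort_per_class < 1:
            raise ValueError("zero samples requested")
        if not self.n_features_per_kingdom or all(
            v == 0 for v in self.n_features_per_kingdom.values()
        ):
            raise ValueError("zero features requested")
        for k, n in self.n_features_per_kingdom.items():
            if k not in KINGDOMS:
                raise ValueError(f"unknown kingdom {k!r}")
            if self.n_markers_per_kingdom.get(k, 0) > n:
                raise ValueError(f"more markers than features for kingdom {k!r}")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.batch_sd < 0 or self.covariate_effect_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation, for recovery scoring."""

    marker_effects: dict            # feature id -> signed log-scale effect
    batch_shifts: pd.DataFrame      # cohort x feature
    basis_correlation: pd.DataFrame  # feature x feature, used by the copula

    @property
    def marker_ids(self) -> set:
        return set(self.marker_effects)

    def to_json(self, path) -> None:
        obj = {
            "marker_effects": self.marker_effects,
            "batch_shifts": self.batch_shifts.to_dict(orient="index"),
            "basis_correlation_features": list(self.basis_correlation.index),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def feature_ids_for(config: SimulationConfig) -> tuple[list[str], dict]:
    ids: list[str] = []
    kingdom_of: dict[str, str] = {}
    for k in KINGDOMS:
        n = config.n_features_per_kingdom.get(k, 0)
        for i in range(n):
            fid = f"{k}__f{i:04d}"
            ids.append(fid)
            kingdom_of[fid] = k
    return ids, kingdom_of


def _build_basis_correlation(config: SimulationConfig, ids: list[str]) -> np.ndarray:
    D = len(ids)
    C = np.eye(D)
    pos = {f: i for i, f in enumerate(ids)}
    for bi, (members, r) in enumerate(config.correlated_blocks):
        if not -1 < r < 1:
            raise ValueError(f"block {bi}: target correlation must lie in (-1, 1)")
        idx = []
        for f in members:
            if f not in pos:
                raise ValueError(f"block {bi}: unknown feature {f!r}")
            idx.append(pos[f])
        for a in idx:
            for b in idx:
                if a != b:
                    C[a, b] = r
        sub = C[np.ix_(idx, idx)]
        if np.linalg.eigvalsh(sub).min() < -1e-10:
            raise ValueError(f"block {bi}: requested correlation is not positive semi-definite")
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("combined correlation matrix is not positive semi-definite")
    return C


def generate_study(
    config: SimulationConfig,
) -> tuple[dict[str, AbundanceTable], StudyMetadata, SyntheticTruth]:
    """Simulate the full study; returns per-kingdom count tables, metadata, truth.

    Counts for one sample are drawn from a single multinomial across all
    kingdoms jointly, so the per-kingdom tables are slices of one
    composition and their row sums add up to the sample's library size.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, kingdom_of = feature_ids_for(config)
    D = len(ids)
    cohorts = [f"cohort{c + 1}" for c in range(config.n_cohorts)]
    n_per_class = config.samples_per_cohort_per_class
    n_per_cohort = 2 * n_per_class
    N = config.n_cohorts * n_per_cohort

    # (1) baselines with heavy right tail
    baseline = rng.normal(0.0, 1.0, size=D) + rng.exponential(TAIL_SCALE, size=D)

    # (2) copula correlation structure
    C = _build_basis_correlation(config, ids)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(D))
    z = rng.standard_normal((N, D)) @ L.T
    logab = baseline[None, :] + LOG_SD * z

    # metadata: balanced case/control per cohort, mild age confounding
    sample_ids = []
    cohort_col, group_col = [], []
    for c in cohorts:
        for g in ("control", "case"):
            for i in range(n_per_class):
                sample_ids.append(f"{c}_{g}_{i:03d}")
                cohort_col.append(c)
                group_col.append(g)
    meta = pd.DataFrame(
        {"cohort": cohort_col, "group": group_col}, index=pd.Index(sample_ids, name="sample_id")
    )
    is_case = (meta["group"] == "case").to_numpy()
    age = rng.uniform(30, 80, size=N) + CASE_AGE_SHIFT * is_case
    sex = np.where(rng.random(N) < 0.5, "female", "male")
    bmi = rng.normal(24.0, 3.0, size=N)
    meta["age"] = age
    meta["sex"] = sex
    meta["bmi"] = bmi
    stage = np.full(N, "", dtype=object)
    early = rng.random(N) < config.early_stage_fraction
    stage[is_case] = np.where(early[is_case], "early", "advanced")
    meta["stage"] = stage

    # (3) batch shifts
    batch = rng.normal(0.0, config.batch_sd, size=(config.n_cohorts, D))
    cohort_index = {c: i for i, c in enumerate(cohorts)}
    logab += batch[[cohort_index[c] for c in cohort_col], :]

    # (4) signed marker effects in cases
    marker_effects: dict[str, float] = {}
    for k in KINGDOMS:
        nk = config.n_markers_per_kingdom.get(k, 0)
        pool = [f for f in ids if kingdom_of[f] == k]
        if k in config.marker_features:
            chosen = list(config.marker_features[k])
            if not set(chosen) <= set(pool):
                raise ValueError(f"marker_features for {k!r} not a subset of its features")
        else:
            chosen = list(rng.choice(pool, size=nk, replace=False)) if nk else []
        for f in chosen:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            marker_effects[f] = sign * config.marker_log_fold_effect
    effect_vec = np.array([marker_effects.get(f, 0.0) for f in ids])
    scale = np.where(stage == "early", config.early_effect_scale, 1.0)
    logab += (is_case * scale)[:, None] * effect_vec[None, :]

    # (5) covariate contributions for a random 10% of features
    n_cov = max(1, int(round(COVARIATE_FRACTION * D)))
    cov_feats = rng.choice(D, size=n_cov, replace=False)
    cov_design = np.column_stack(
        [
            (age - np.mean(age)) / np.std(age),
            (sex == "male").astype(float) - 0.5,
            (bmi - np.mean(bmi)) / np.std(bmi),
        ]
    )
    coef = rng.normal(0.0, config.covariate_effect_sd, size=(3, n_cov))
    logab[:, cov_feats] += cov_design @ coef

    # (6) composition + structural zeros
    comp = np.exp(logab)
    comp /= comp.sum(axis=1, keepdims=True)
    if config.zero_inflation > 0:
        keep = rng.random((N, D)) >= config.zero_inflation
        # never zero out an entire sample: retain its largest component
        top = np.argmax(comp, axis=1)
        keep[np.arange(N), top] = True
        comp = comp * keep
        comp /= comp.sum(axis=1, keepdims=True)

    # (7) multinomial counts at Poisson library sizes
    libsize = rng.poisson(config.library_size_mean, size=N)
    libsize = np.maximum(libsize, 1)
    counts = np.empty((N, D), dtype=np.int64)
    for s in range(N):
        counts[s] = rng.multinomial(libsize[s], comp[s])

    counts_df = pd.DataFrame(counts, index=meta.index, columns=ids)
    tables = {}
    for k in KINGDOMS:
        cols = [f for f in ids if kingdom_of[f] == k]
        if cols:
            tables[k] = AbundanceTable(
                counts_df[cols].copy(), {f: k for f in cols}, is_relative=False
            )
    truth = SyntheticTruth(
        marker_effects=marker_effects,
        batch_shifts=pd.DataFrame(batch, index=cohorts, columns=ids),
        basis_correlation=pd.DataFrame(C, index=ids, columns=ids),
    )
    return tables, StudyMetadata(meta), truth


def combined_table(tables: dict[str, AbundanceTable]) -> AbundanceTable:
    """Concatenate per-kingdom tables into one samples x features table."""
    parts = [tables[k] for k in KINGDOMS if k in tables]
    data = pd.concat([t.data for t in parts], axis=1)
    kingdom_of: dict[str, str] = {}
    for t in parts:
        kingdom_of.update(t.kingdom_of)
    return AbundanceTable(data, kingdom_of, is_relative=False)


def truth_marker_set(truth: SyntheticTruth, kingdom: str) -> set:
    """Planted marker ids belonging to one kingdom."""
    if kingdom not in KINGDOMS:
        raise KeyError(f"unknown kingdom: {kingdom!r}")
    return {f for f in truth.marker_ids if f.split("__")[0] == kingdom}


def random_function_map(
    gene_ids: list[str],
    n_groups: int,
    rng: np.random.Generator,
    genes_per_group: tuple[int, int] = (20, 200),
) -> dict[str, set]:
    """Random many-to-many gene -> pathway map for functional-profile simulation."""
    lo, hi = genes_per_group
    mapping: dict[str, set] = {g: set() for g in gene_ids}
    for gi in range(n_groups):
        size = int(rng.integers(lo, min(hi, len(gene_ids)) + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        for g in members:
            mapping[g].add(f"pathway{gi:03d}")
    return {g: s for g, s in mapping.items() if s}
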