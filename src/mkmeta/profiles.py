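"""Abundance tables and study metadata: containers, TSV I/O, transforms.

The canonical on-disk dialect is a features-as-rows TSV (merged
Kraken/Bracken style): first column the feature id, optional second column
``kingdom``, remaining columns one per sample.  In memory the orientation is
samples x features (a pandas DataFrame), which is what every model in the
package consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .utils import KINGDOMS

log = logging.getLogger(__name__)

GROUPS = ("control", "case")


@dataclass
class AbundanceTable:
    """Samples x features abundance matrix with per-feature kingdom labels.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with one column per feature;
        non-negative reals (counts or relative abundances).
    kingdom_of:
        Mapping feature id -> kingdom.  Features without an entry default
        to ``bacteria``.
    is_relative:
        True when each row is a composition summing to 1.
    """

    data: pd.DataFrame
    kingdom_of: dict[str, str] = field(default_factory=dict)
    is_relative: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("negative abundance")
        if self.is_relative:
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative table rows must sum to 1 +/- 1e-9")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def kingdom(self, feature: str) -> str:
        return self.kingdom_of.get(feature, "bacteria")

    def kingdoms(self) -> list[str]:
        seen = {self.kingdom(f) for f in self.feature_ids}
        return [k for k in KINGDOMS if k in seen] + sorted(seen - set(KINGDOMS))

    def subset_kingdom(self, kingdom: str) -> "AbundanceTable":
        cols = [f for f in self.feature_ids if self.kingdom(f) == kingdom]
        if not cols:
            raise KeyError(f"unknown kingdom: {kingdom!r}")
        return AbundanceTable(
            self.data[cols].copy(),
            {f: kingdom for f in cols},
            is_relative=False,
        )

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(
            self.data.loc[list(sample_ids)].copy(), dict(self.kingdom_of), self.is_relative
        )


@dataclass
class StudyMetadata:
    """Per-sample cohort, phenotype and covariates (age, sex, BMI)."""

    data: pd.DataFrame  # index: sample_id; columns cohort, group, age, sex, bmi [, stage]

    REQUIRED = ("cohort", "group", "age", "sex", "bmi")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        bad = set(self.data["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cohorts(self) -> list[str]:
        return list(pd.unique(self.data["cohort"]))

    def samples_of(self, cohort: str) -> list[str]:
        return list(self.data.index[self.data["cohort"] == cohort])

    def require_both_groups(self) -> None:
        """Modeling precondition: every cohort holds both classes."""
        for c in self.cohorts:
            groups = set(self.data.loc[self.data["cohort"] == c, "group"])
            if groups != set(GROUPS):
                raise ValueError(f"cohort {c!r} lacks one of the groups {GROUPS}")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_abundance(table: AbundanceTable, path) -> None:
    """Write the features-as-rows TSV (feature_id, kingdom, samples...)."""
    out = table.data.T
    out.insert(0, "kingdom", [table.kingdom(f) for f in out.index])
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_abundance(path, is_relative: bool = False) -> AbundanceTable:
    """Read a features-as-rows abundance TSV.

    Raises distinct errors for duplicate ids, negative values and ragged
    rows.  A ``kingdom`` column, when present, populates ``kingdom_of``.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValueError(f"ragged rows in abundance table: {exc}") from exc
    if raw.index.has_duplicates:
        raise ValueError("duplicate feature ids in abundance table")
    kingdom_of: dict[str, str] = {}
    if "kingdom" in raw.columns:
        kingdom_of = raw["kingdom"].to_dict()
        raw = raw.drop(columns="kingdom")
    if raw.columns.has_duplicates:
        raise ValueError("duplicate sample ids in abundance table")
    try:
        mat = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance value: {exc}") from exc
    if mat.isna().to_numpy().any():
        raise ValueError("ragged rows in abundance table (missing cells)")
    if (mat.to_numpy() < 0).any():
        raise ValueError("negative abundance")
    return AbundanceTable(mat.T, kingdom_of, is_relative=is_relative)


def write_metadata(meta: StudyMetadata, path) -> None:
    out = meta.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> StudyMetadata:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return StudyMetadata(df)


# ---------------------------------------------------------------------------
# Transformations and filters
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    vals = table.data.to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = list(table.data.index[zero])
        raise ValueError(f"all-zero sample(s): {bad}")
    rel = pd.DataFrame(
        vals / sums[:, None], index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(rel, dict(table.kingdom_of), is_relative=True)


def arcsine_sqrt(table: AbundanceTable) -> pd.DataFrame:
    """Variance-stabilizing arcsin(sqrt(p)) transform of a relative table.

    Maps [0, 1] onto [0, pi/2]; zeros stay exactly zero, so no pseudo-count
    is needed at this stage.
    """
    if not table.is_relative:
        raise ValueError("arcsine_sqrt requires a relative-abundance table")
    vals = table.data.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("entries outside [0, 1]")
    return pd.DataFrame(
        np.arcsin(np.sqrt(vals)), index=table.data.index, columns=table.data.columns
    )


def filter_features(
    table: AbundanceTable,
    min_prevalence: float = 0.1,
    min_mean_abundance: float = 0.0,
) -> AbundanceTable:
    """Keep features by prevalence (nonzero fraction) and mean relative abundance.

    Column order is preserved; thresholds are inclusive (``>=``).
    """
    for name, t in (("min_prevalence", min_prevalence), ("min_mean_abundance", min_mean_abundance)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rel = table if table.is_relative else to_relative(table)
    prev = (table.data.to_numpy() > 0).mean(axis=0)
    mean_ab = rel.data.to_numpy().mean(axis=0)
    keep = (prev >= min_prevalence) & (mean_ab >= min_mean_abundance)
    if not keep.any():
        raise ValueError("no features survive the filter")
    cols = [f for f, k in zip(table.feature_ids, keep) if k]
    return AbundanceTable(
        table.data[cols].copy(),
        {f: table.kingdom(f) for f in cols},
        is_relative=table.is_relative,
    )


BMI_LABELS = ("lean", "overweight", "obese")


def discretize_covariates(meta: StudyMetadata) -> StudyMetadata:
    """Discretize age into within-dataset quartiles and BMI into WHO-style classes.

    BMI classes: lean (<25), overweight (25-30], obese (>30).  A "lean
    (>25)" label sometimes seen in clinical metadata contradicts the
    overweight interval, so the conventional <25 cut-off is applied and a
    warning is emitted.
    """
    warnings.warn(
        "BMI classes use lean <25, overweight (25,30], obese >30; "
        "a printed 'lean (>25)' label is treated as a typo for '<25'",
        stacklevel=2,
    )
    df = meta.data.copy()
    for col in ("age", "bmi"):
        if df[col].isna().any():
            bad = list(df.index[df[col].isna()])
            raise ValueError(f"missing {col} for samples: {bad}")
    age = df["age"].astype(float)
    # Rank-based quartiles are robust to heavy ties (qcut would drop bins).
    frac = age.rank(method="average", pct=True)
    q = np.minimum(np.ceil(frac * 4).astype(int), 4)
    df["age_quartile"] = [f"Q{i}" for i in q]
    bmi = df["bmi"].astype(float)
    df["bmi_category"] = np.select(
        [bmi < 25, bmi <= 30], ["lean", "overweight"], default="obese"
    )
    return StudyMetadata(df)
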