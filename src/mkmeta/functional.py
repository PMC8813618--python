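"""Gene-to-pathway aggregation, functional differential analysis, species-function screens.

Functional group (orthology group / pathway) abundance is the plain sum of
member-gene relative abundances per sample — a gene annotated to several
groups contributes fully to each, and the sums are deliberately not
renormalized.  Differential testing of functional groups reuses the same
batch-adjusted fixed-effects meta-analysis as taxa.  Species-function
association is a flat all-against-all Spearman screen gated at
FDR < 0.01.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .metadiff import bh_fdr, meta_differential_abundance
from .profiles import AbundanceTable, StudyMetadata

log = logging.getLogger(__name__)

FunctionMap = dict[str, set]  # gene id -> set of group ids


def read_function_map(path) -> FunctionMap:
    """Two-column TSV (gene_id, group_id) -> many-to-many mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "group_id"], dtype=str)
    out: FunctionMap = {}
    for g, grp in zip(df["gene_id"], df["group_id"]):
        out.setdefault(g, set()).add(grp)
    return out


def write_function_map(fmap: FunctionMap, path) -> None:
    rows = [(g, grp) for g in sorted(fmap) for grp in sorted(fmap[g])]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def aggregate(gene_table: AbundanceTable, fmap: FunctionMap) -> AbundanceTable:
    """Sum member-gene relative abundances into group-level abundances."""
    if not gene_table.is_relative:
        raise ValueError("aggregate expects a relative gene table")
    covered = [g for g in gene_table.feature_ids if g in fmap and fmap[g]]
    if not covered:
        raise ValueError("function map covers zero genes of the table")
    groups = sorted({grp for g in covered for grp in fmap[g]})
    gidx = {grp: i for i, grp in enumerate(groups)}
    indicator = np.zeros((len(gene_table.feature_ids), len(groups)))
    for ci, g in enumerate(gene_table.feature_ids):
        for grp in fmap.get(g, ()):  # many-to-many: full contribution to each
            indicator[ci, gidx[grp]] = 1.0
    agg = gene_table.data.to_numpy() @ indicator
    return AbundanceTable(
        pd.DataFrame(agg, index=gene_table.data.index, columns=groups),
        {grp: "function" for grp in groups},
        is_relative=False,  # sums are not renormalized
    )


def functional_diff(
    group_table: AbundanceTable, meta: StudyMetadata, **kwargs
) -> pd.DataFrame:
    """Differential functional groups via the same meta-analytic pipeline as taxa.

    Group-level sums are renormalized per sample inside the pipeline (the
    arcsine-sqrt step needs proportions); everything else — batch
    adjustment, covariate-adjusted cohort effects, fixed-effects pooling,
    BH FDR — is identical to the taxon analysis.
    """
    res = meta_differential_abundance(group_table, meta, **kwargs)
    res["kingdom"] = "function"
    return res


def species_function_association(
    species_table: AbundanceTable,
    function_table: AbundanceTable,
    fdr_cut: float = 0.01,
) -> pd.DataFrame:
    """All-against-all Spearman screen between species and functional groups.

    Returns pairs passing BH FDR < ``fdr_cut`` with columns species,
    function, rho, p, fdr.  Constant vectors are skipped with a log note.
    """
    if list(species_table.sample_ids) != list(function_table.sample_ids):
        raise ValueError("species and function tables must share samples in order")
    sp = species_table.data
    fn = function_table.data
    sp_ok = [c for c in sp.columns if sp[c].nunique() > 1]
    fn_ok = [c for c in fn.columns if fn[c].nunique() > 1]
    skipped = (len(sp.columns) - len(sp_ok)) + (len(fn.columns) - len(fn_ok))
    if skipped:
        log.info("species_function_association: %d constant vector(s) skipped", skipped)
    if not sp_ok or not fn_ok:
        return pd.DataFrame(columns=["species", "function", "rho", "p", "fdr"])
    rho, p = stats.spearmanr(sp[sp_ok].to_numpy(), fn[fn_ok].to_numpy())
    ns = len(sp_ok)
    rho_block = np.atleast_2d(rho)[:ns, ns:]
    p_block = np.atleast_2d(p)[:ns, ns:]
    rows = [
        {
            "species": s,
            "function": f,
            "rho": float(rho_block[i, j]),
            "p": float(p_block[i, j]),
        }
        for i, s in enumerate(sp_ok)
        for j, f in enumerate(fn_ok)
    ]
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out[out["fdr"] < fdr_cut].reset_index(drop=True)
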