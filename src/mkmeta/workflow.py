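"""End-to-end orchestration: simulate -> profile -> test -> select -> model -> network.

``run_pipeline`` executes the whole study on one configuration and writes
every stage's tables plus a run manifest (config snapshot, seeds, file
digests) under the output directory.  Every constant of the analysis
(permutation counts, CV design, correlation cut-offs, FDR gates, Boruta
runs) is a named configuration key; the package defaults are the
full-scale analysis values, while the demo configuration scales the
stochastic budgets down so the study runs on one CPU in minutes.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, featselect, functional, metadiff, modeling, networks, synthdata
from .profiles import (
    AbundanceTable,
    StudyMetadata,
    arcsine_sqrt,
    discretize_covariates,
    filter_features,
    to_relative,
    write_abundance,
    write_metadata,
)
from .synthdata import SimulationConfig, combined_table
from .utils import KINGDOMS, rng_for, substream_seed

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage knobs in one place; YAML-serializable."""

    seed: int = 0
    out_dir: str = "mkmeta_run"
    # simulation (None -> caller supplies tables/metadata paths)
    simulate: dict | None = None
    n_validation_cohorts: int = 0
    tables_dir: str | None = None
    metadata_path: str | None = None
    # profiles
    min_prevalence: float = 0.1
    min_mean_abundance: float = 0.0
    # diversity
    permanova_permutations: int = 999
    # metadiff
    diff_alpha: float = 0.05
    diff_on: str = "p"
    # featselect
    boruta_max_runs: int = 1000
    boruta_alpha: float = 0.05
    boruta_trees: int = 300
    collinearity_threshold: float = 0.7
    # modeling
    cv_folds: int = 5
    cv_repeats: int = 20
    rf_trees: int = 500
    rf_tune: bool = False
    model_permutations: int = 1000
    panel_max_size: int = 16
    panel_plateau_tol: float = 0.001
    panel_cv_repeats: int = 5
    # networks
    network_permutations: int = 1000
    network_exclusions: int = 20
    network_exclusion_threshold: float = 0.1
    network_fdr_cut: float = 1e-5
    network_r_cut: float = 0.3
    network_max_features: int = 40
    # functional
    functional_pathways: int = 10
    functional_fdr_cut: float = 0.01
    run_functional: bool = True
    run_networks: bool = True
    run_models: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def demo_config(seed: int = 0, out_dir: str = "mkmeta_demo") -> PipelineConfig:
    """The bundled small-study configuration: 5 cohorts x 60 samples,
    4 kingdoms x 100 features, reduced permutation/CV budgets."""
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        simulate=dict(
            n_cohorts=5,
            samples_per_cohort_per_class=30,
            n_features_per_kingdom={k: 100 for k in KINGDOMS},
            n_markers_per_kingdom={k: 8 for k in KINGDOMS},
            marker_log_fold_effect=1.2,
            batch_sd=0.3,
            zero_inflation=0.1,
            library_size_mean=20000,
            correlated_blocks=[
                ([f"bacteria__f{i:04d}" for i in range(4)], 0.7),
                (["bacteria__f0004", "bacteria__f0005", "fungi__f0000", "fungi__f0001"], 0.7),
            ],
            # make the correlated features disease markers too, so the
            # co-abundance stage (whose candidates are the differential
            # features) can recover the planted edges
            marker_features={
                "bacteria": [f"bacteria__f{i:04d}" for i in range(8)],
                "fungi": [f"fungi__f{i:04d}" for i in range(8)],
            },
        ),
        permanova_permutations=199,
        boruta_max_runs=50,
        boruta_trees=100,
        cv_repeats=3,
        rf_trees=100,
        model_permutations=49,
        panel_cv_repeats=2,
        panel_max_size=12,
        network_permutations=199,
        network_max_features=30,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full study; returns a dict of in-memory stage results.

    Stage order: simulate (optional) -> profiles -> diversity -> metadiff
    -> featselect per kingdom -> modeling (single-kingdom, multi-kingdom
    combinations, panel, transfer/LOCO, external validation when
    validation cohorts exist) -> networks -> functional.  Any stage
    failure aborts with the stage name; outputs written so far remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "setup"
    manifest: dict = {
        "config": asdict(config),
        "package_version": _version(),
        "seed": config.seed,
        "substreams": {},
        "digests": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    results: dict = {}
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        if config.simulate is not None:
            sim_seed = substream_seed(config.seed, "simulate")
            manifest["substreams"]["simulate"] = sim_seed
            sim = dict(config.simulate)
            n_val = config.n_validation_cohorts
            if n_val:
                sim["n_cohorts"] = sim.get("n_cohorts", 5) + n_val
            sc = SimulationConfig(**sim, seed=sim_seed)
            tables, meta, truth = synthdata.generate_study(sc)
            all_cohorts = meta.cohorts
            discovery = all_cohorts[: len(all_cohorts) - n_val]
            validation = all_cohorts[len(all_cohorts) - n_val:]
            for k, t in tables.items():
                write_abundance(t, out / f"abundance_{k}.tsv")
            write_metadata(meta, out / "metadata.tsv")
            truth.to_json(out / "truth.json")
            results["truth"] = truth
        elif config.tables_dir and config.metadata_path:
            from .profiles import read_abundance, read_metadata

            tables = {}
            for k in KINGDOMS:
                p = Path(config.tables_dir) / f"abundance_{k}.tsv"
                if p.exists():
                    tables[k] = read_abundance(p)
            if not tables:
                raise ValueError("no abundance tables found in tables_dir")
            meta = read_metadata(config.metadata_path)
            discovery, validation = meta.cohorts, []
            results["truth"] = None
        else:
            raise ValueError("config missing: provide either a 'simulate' block or "
                             "both 'tables_dir' and 'metadata_path'")
        combined = combined_table(tables)
        disc_samples = [s for c in discovery for s in meta.samples_of(c)]
        meta_disc = StudyMetadata(meta.data.loc[disc_samples].copy())
        results["tables"], results["meta"] = tables, meta
        results["discovery_cohorts"], results["validation_cohorts"] = discovery, validation

        # ------------------------------------------------------------------
        stage = "profiles"
        combined_disc = combined.subset_samples(disc_samples)
        filtered = filter_features(
            combined_disc, config.min_prevalence, config.min_mean_abundance
        )
        rel = to_relative(filtered)
        results["filtered"] = filtered

        # ------------------------------------------------------------------
        stage = "diversity"
        div_seed = substream_seed(config.seed, "diversity")
        manifest["substreams"]["diversity"] = div_seed
        alpha = diversity.alpha_diversity(rel)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        dist = diversity.distance_matrix(rel)
        coords, evals = diversity.pcoa(dist, k=2)
        coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        perma = {
            "group": asdict(
                diversity.permanova(
                    dist, meta_disc.data["group"].to_numpy(),
                    config.permanova_permutations, seed=div_seed,
                )
            ),
            "cohort": asdict(
                diversity.permanova(
                    dist, meta_disc.data["cohort"].to_numpy(),
                    config.permanova_permutations, seed=div_seed + 1,
                )
            ),
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shannon_test = diversity.shannon_group_test(rel, meta_disc)
        perma["shannon_group_model"] = {k: float(v) for k, v in shannon_test.items()}
        (out / "permanova.json").write_text(json.dumps(perma, indent=1))
        results["diversity"] = {"alpha": alpha, "permanova": perma, "pcoa_eigenvalues": evals}

        # ------------------------------------------------------------------
        stage = "metadiff"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diff_all = []
            for k in KINGDOMS:
                try:
                    kt = filtered.subset_kingdom(k)
                except KeyError:
                    continue
                res = metadiff.meta_differential_abundance(kt, meta_disc)
                diff_all.append(res)
            diff = pd.concat(diff_all)
        diff.to_csv(out / "differential_abundance.tsv", sep="\t")
        called = metadiff.differential_features(diff, config.diff_alpha, config.diff_on)
        results["metadiff"], results["differential"] = diff, called

        # ------------------------------------------------------------------
        stage = "featselect"
        sel_seed = substream_seed(config.seed, "featselect")
        manifest["substreams"]["featselect"] = sel_seed
        rel_disc = to_relative(filtered)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            transformed = arcsine_sqrt(rel_disc)
            cov = metadiff._covariate_design(discretize_covariates(meta_disc).data)
            adjusted = metadiff.combat_adjust(
                transformed, meta_disc.data["cohort"],
                pd.DataFrame(cov, index=meta_disc.data.index),
            )
        y = meta_disc.data["group"].to_numpy()
        kept_per_kingdom: dict[str, list[str]] = {}
        decisions_frames = []
        for k in KINGDOMS:
            cand = [f for f in called.index if called.loc[f, "kingdom"] == k]
            if not cand:
                kept_per_kingdom[k] = []
                continue
            dec = featselect.boruta_select(
                adjusted[cand], y,
                max_runs=config.boruta_max_runs, alpha=config.boruta_alpha,
                seed=substream_seed(sel_seed, k), n_estimators=config.boruta_trees,
            )
            confirmed = featselect.confirmed_features(dec)
            # rank confirmed features by |pooled effect| for the greedy pass
            ranking = sorted(confirmed, key=lambda f: -abs(diff.loc[f, "beta_pooled"]))
            kept = featselect.collinearity_filter(
                confirmed, adjusted, config.collinearity_threshold, ranking
            )
            kept_per_kingdom[k] = kept
            decisions_frames.append(
                pd.DataFrame(
                    [
                        {**asdict(d), "kingdom": k, "kept_after_filter": d.feature_id in kept}
                        for d in dec
                    ]
                )
            )
        sel = pd.concat(decisions_frames) if decisions_frames else pd.DataFrame()
        sel.to_csv(out / "selected_features.tsv", sep="\t", index=False)
        multi = featselect.combine_kingdom_features(kept_per_kingdom)
        results["selected"] = kept_per_kingdom
        results["multi_kingdom_features"] = multi

        # ------------------------------------------------------------------
        stage = "modeling"
        if config.run_models and multi:
            mod_seed = substream_seed(config.seed, "modeling")
            manifest["substreams"]["modeling"] = mod_seed
            spec = modeling.RandomForestSpec(
                n_estimators=config.rf_trees, tune=config.rf_tune
            )
            X = adjusted
            y_disc = meta_disc.data["group"]
            combo_rows = []
            present = [k for k in KINGDOMS if kept_per_kingdom.get(k)]
            for r in range(1, len(present) + 1):
                for combo in itertools.combinations(present, r):
                    feats = featselect.combine_kingdom_features(
                        {k: kept_per_kingdom[k] for k in combo}
                    )
                    cvres = modeling.repeated_cv(
                        X[feats], y_disc, folds=config.cv_folds,
                        repeats=config.cv_repeats, spec=spec,
                        seed=substream_seed(mod_seed, "combo_" + "_".join(combo)),
                    )
                    combo_rows.append(
                        {
                            "combination": "+".join(combo),
                            "n_features": len(feats),
                            "mean_cv_auroc": cvres.mean_auroc,
                        }
                    )
            combos = pd.DataFrame(combo_rows)
            combos.to_csv(out / "kingdom_combinations.tsv", sep="\t", index=False)

            # per-cohort importances for rank aggregation
            per_cohort_imp = {}
            for c in discovery:
                samples = meta_disc.samples_of(c)
                cvres = modeling.repeated_cv(
                    X.loc[samples, multi], meta_disc.data.loc[samples, "group"],
                    folds=config.cv_folds, repeats=max(2, config.cv_repeats // 2),
                    spec=spec, seed=substream_seed(mod_seed, f"imp_{c}"),
                )
                per_cohort_imp[c] = cvres.importances
            ranked = modeling.aggregate_importance(per_cohort_imp)
            trace = modeling.incremental_panel(
                X, y_disc, ranked,
                max_size=min(config.panel_max_size, len(ranked)),
                spec=spec, folds=config.cv_folds, repeats=config.panel_cv_repeats,
                seed=substream_seed(mod_seed, "panel"),
                plateau_tol=config.panel_plateau_tol,
            )
            panel = trace.chosen_panel
            pd.DataFrame(
                {
                    "size": list(trace.auroc_at_size),
                    "mean_cv_auroc": list(trace.auroc_at_size.values()),
                }
            ).to_csv(out / "panel_trace.tsv", sep="\t", index=False)

            ev = modeling.transfer_matrix(
                X, meta_disc, panel, spec=spec, folds=config.cv_folds,
                repeats=max(2, config.cv_repeats // 2),
                seed=substream_seed(mod_seed, "transfer"),
            )
            ev.loco = modeling.loco(
                X, meta_disc, panel, spec=spec, seed=substream_seed(mod_seed, "loco")
            )
            ev.auroc.to_csv(out / "transfer_matrix.tsv", sep="\t")
            ev.loco.to_csv(out / "loco.tsv", sep="\t", header=["auroc"])

            obs_auc, perm_p, _ = modeling.permutation_significance(
                X[panel], y_disc, spec=spec, n_perm=config.model_permutations,
                folds=config.cv_folds, repeats=1,
                seed=substream_seed(mod_seed, "permsig"),
            )
            results["modeling"] = {
                "combinations": combos,
                "ranked_features": ranked,
                "panel_trace": trace,
                "panel": panel,
                "eval": ev,
                "panel_cv_auroc": obs_auc,
                "panel_permutation_p": perm_p,
            }

            if validation:
                val_samples = [s for c in validation for s in meta.samples_of(c)]
                meta_val = StudyMetadata(meta.data.loc[val_samples].copy())
                comb_val = combined.subset_samples(val_samples)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    x_val = arcsine_sqrt(to_relative(comb_val))
                ext = modeling.evaluate_external(
                    panel, X, meta_disc, x_val, meta_val, spec=spec,
                    folds=config.cv_folds, repeats=max(2, config.cv_repeats // 2),
                    seed=substream_seed(mod_seed, "external"),
                )
                ext["transfer"].to_csv(out / "external_transfer.tsv", sep="\t")
                results["external"] = ext
            if "stage" in meta_disc.data.columns and (
                meta_disc.data["stage"] == "early"
            ).any():
                results["early_stage"] = modeling.early_stage_eval(
                    X, meta_disc, panel, spec=spec, folds=config.cv_folds,
                    repeats=max(2, config.panel_cv_repeats),
                    seed=substream_seed(mod_seed, "early"),
                )

        # ------------------------------------------------------------------
        stage = "networks"
        if config.run_networks:
            net_seed = substream_seed(config.seed, "networks")
            manifest["substreams"]["networks"] = net_seed
            net_feats = list(called.sort_values("p").index[: config.network_max_features])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nets = networks.group_meta_networks(
                    filtered, meta_disc, net_feats,
                    n_permutations=config.network_permutations,
                    fdr_cut=config.network_fdr_cut,
                    r_cut=config.network_r_cut,
                    seed=net_seed,
                    n_exclusions=config.network_exclusions,
                    exclusion_threshold=config.network_exclusion_threshold,
                )
            for g, net in nets.items():
                net.edges.to_csv(out / f"network_{g}.tsv", sep="\t", index=False)
                networks.to_graphml(net, out / f"network_{g}.graphml")
            results["networks"] = nets

        # ------------------------------------------------------------------
        stage = "functional"
        if config.run_functional:
            fun_seed = substream_seed(config.seed, "functional")
            manifest["substreams"]["functional"] = fun_seed
            gene_table = to_relative(filtered.subset_kingdom("bacteria"))
            fmap = synthdata.random_function_map(
                gene_table.feature_ids, config.functional_pathways,
                rng_for(fun_seed, "map"),
                genes_per_group=(10, max(20, len(gene_table.feature_ids) // 2)),
            )
            functional.write_function_map(fmap, out / "function_map.tsv")
            agg = functional.aggregate(gene_table, fmap)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fdiff = functional.functional_diff(agg, meta_disc)
            fdiff.to_csv(out / "functional_differential.tsv", sep="\t")
            sp_feats = list(called.index[:20]) or list(filtered.feature_ids[:20])
            assoc = functional.species_function_association(
                AbundanceTable(
                    rel.data[sp_feats].copy(), {f: filtered.kingdom(f) for f in sp_feats}
                ),
                agg,
                fdr_cut=config.functional_fdr_cut,
            )
            assoc.to_csv(out / "species_function_associations.tsv", sep="\t", index=False)
            results["functional"] = {"diff": fdiff, "associations": assoc}

    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["digests"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    results["manifest"] = manifest
    report_text = report(results)
    (out / "report.md").write_text(report_text)
    results["report"] = report_text
    return results


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("mkmeta")
    except Exception:
        return "unknown"


def report(results: dict) -> str:
    """Human-readable study summary; includes truth recovery when available."""
    lines = ["# mkmeta study report", ""]
    if "diversity" in results:
        pg = results["diversity"]["permanova"]["group"]
        pc = results["diversity"]["permanova"]["cohort"]
        lines += [
            "## Community structure",
            f"- PERMANOVA group:  R2={pg['R2']:.4f}  p={pg['p']:.4g}",
            f"- PERMANOVA cohort: R2={pc['R2']:.4f}  p={pc['p']:.4g}",
            "",
        ]
    if "metadiff" in results:
        diff = results["metadiff"]
        called = results["differential"]
        per_k = called.groupby("kingdom").size().to_dict()
        lines += [
            "## Differential abundance",
            f"- features tested: {len(diff)}; called: {len(called)} ({per_k})",
            "",
        ]
    truth = results.get("truth")
    if truth is not None and "differential" in results:
        called_set = set(results["differential"].index)
        tested = set(results["metadiff"].index)
        markers = truth.marker_ids & tested
        tp = len(called_set & markers)
        recall = tp / len(markers) if markers else float("nan")
        precision = tp / len(called_set) if called_set else float("nan")
        lines += [
            "## Truth recovery (differential calls)",
            f"- planted markers tested: {len(markers)}; recall={recall:.3f}, "
            f"precision={precision:.3f}",
            "",
        ]
    if "modeling" in results:
        m = results["modeling"]
        lines += ["## Diagnostic models", "", "| combination | features | mean CV AUROC |",
                  "|---|---|---|"]
        for _, row in m["combinations"].iterrows():
            lines.append(
                f"| {row['combination']} | {row['n_features']} | {row['mean_cv_auroc']:.3f} |"
            )
        trace = m["panel_trace"]
        lines += [
            "",
            f"- panel: {len(m['panel'])} features, CV AUROC {m['panel_cv_auroc']:.3f}, "
            f"permutation p {m['panel_permutation_p']:.4g}",
            f"- panel size trace: "
            + ", ".join(f"{s}:{a:.3f}" for s, a in trace.auroc_at_size.items()),
            f"- mean cohort-to-cohort AUROC: "
            f"{_offdiag_mean(m['eval'].auroc):.3f}; mean LOCO: {m['eval'].loco.mean():.3f}",
            "",
        ]
    if "early_stage" in results:
        es = results["early_stage"]
        lines += [
            f"- early-stage CV AUROC: {es['cv_mean_auroc']:.3f} "
            f"({es['n_early_cases']} early cases)",
            "",
        ]
    if "networks" in results:
        lines += ["## Co-abundance meta-networks", ""]
        for g, net in results["networks"].items():
            s = networks.network_summary(net)
            lines.append(
                f"- {g}: {s['n_nodes']} nodes, {s['n_edges']} edges "
                f"({s['n_intra']} intra-, {s['n_inter']} inter-kingdom; "
                f"{s['n_positive']}+ / {s['n_negative']}-)"
            )
        lines.append("")
    if "functional" in results:
        f = results["functional"]
        n_sig = int((f["diff"]["p"] < 0.05).sum())
        lines += [
            "## Functional analysis",
            f"- pathways tested: {len(f['diff'])}; p<0.05: {n_sig}; "
            f"species-function associations kept: {len(f['associations'])}",
            "",
        ]
    return "\n".join(lines)


def _offdiag_mean(mat: pd.DataFrame) -> float:
    vals = mat.to_numpy().copy()
    np.fill_diagonal(vals, np.nan)
    return float(np.nanmean(vals))
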