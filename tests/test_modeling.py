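"""Evaluation machinery: AUROC, CV leakage guards, transfer/LOCO, panel procedure."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from mkmeta.modeling import (
    RandomForestSpec,
    aggregate_importance,
    auroc,
    early_stage_eval,
    evaluate_external,
    incremental_panel,
    loco,
    permutation_significance,
    repeated_cv,
    specificity_eval,
    transfer_matrix,
)
from mkmeta.profiles import StudyMetadata, arcsine_sqrt, to_relative
from mkmeta.synthdata import SimulationConfig, combined_table, generate_study

FAST = RandomForestSpec(n_estimators=60)


def _study(seed=0, effect=1.5, cohorts=3, n=20, markers=6, **kw):
    cfg = SimulationConfig(
        n_cohorts=cohorts,
        samples_per_cohort_per_class=n,
        n_features_per_kingdom={"bacteria": 30},
        n_markers_per_kingdom={"bacteria": markers},
        marker_log_fold_effect=effect,
        batch_sd=0.2,
        zero_inflation=0.0,
        seed=seed,
        **kw,
    )
    tables, meta, truth = generate_study(cfg)
    x = arcsine_sqrt(to_relative(tables["bacteria"]))
    return x, meta, truth


class TestAuroc:
    def test_perfect_and_tied(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_hand_counted_pairs(self):
        # concordant pairs: 1 of 4 -> 0.25
        assert auroc([0.9, 0.2, 0.8, 0.1], [0, 0, 1, 1]) == pytest.approx(0.25)

    def test_matches_brute_force_pair_counting(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auroc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestRepeatedCV:
    def test_oracle_feature_near_perfect(self, rng):
        n = 60
        y = np.array(["case", "control"] * (n // 2))
        x = pd.DataFrame(
            {"oracle": (y == "case").astype(float), "noise": rng.normal(size=n)}
        )
        res = repeated_cv(x, y, folds=5, repeats=2, spec=FAST, seed=0)
        assert res.mean_auroc >= 0.99

    def test_permuted_labels_near_chance(self, rng):
        """Null CV AUROC averages to chance (large enough n avoids the
        small-sample pessimistic bias of cross-validated null scores)."""
        aucs = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            x = pd.DataFrame(r.normal(size=(200, 5)))
            x.columns = [f"f{i}" for i in range(5)]
            y = r.permutation(["case", "control"] * 100)
            aucs.append(repeated_cv(x, y, folds=5, repeats=2, spec=FAST, seed=seed).mean_auroc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_deterministic_given_seed(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        y = ["case", "control"] * 20
        r1 = repeated_cv(x, y, folds=4, repeats=2, spec=FAST, seed=9)
        r2 = repeated_cv(x, y, folds=4, repeats=2, spec=FAST, seed=9)
        assert r1.fold_aurocs == r2.fold_aurocs

    def test_leak_canary_shuffled_training_labels_destroy_signal(self, rng):
        """If CV were leaking test rows into training, shuffling training labels
        would still score above chance on a signal dataset; it must not."""
        n = 100
        y = np.array(["case", "control"] * (n // 2))
        x = pd.DataFrame(
            {"s1": (y == "case") + rng.normal(0, 0.4, n), "n1": rng.normal(size=n)}
        )
        honest = repeated_cv(x, y, folds=5, repeats=2, spec=FAST, seed=0).mean_auroc
        shuffled = repeated_cv(
            x, np.random.default_rng(1).permutation(y), folds=5, repeats=2, spec=FAST, seed=0
        ).mean_auroc
        assert honest > 0.85
        assert abs(shuffled - 0.5) < 0.12


class TestPermutationSignificance:
    def test_strong_signal_hits_floor(self, rng):
        n = 60
        y = np.array(["case", "control"] * (n // 2))
        x = pd.DataFrame({"oracle": (y == "case").astype(float)})
        _, p, _ = permutation_significance(
            x, y, n_perm=99, folds=3, seed=0,
            model_factory=lambda s: LogisticRegression(max_iter=200),
        )
        assert p == pytest.approx(1 / 100)

    def test_p_has_plus_one_floor(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 3)))
        y = ["case", "control"] * 15
        _, p, null = permutation_significance(
            x, y, n_perm=19, folds=3, seed=1,
            model_factory=lambda s: LogisticRegression(max_iter=200),
        )
        assert p >= 1 / 20
        assert len(null) == 19


class TestTransferLoco:
    def test_matrix_shape_and_shared_signal(self):
        x, meta, _ = _study(seed=4, effect=2.0, cohorts=3, n=20)
        ev = transfer_matrix(x, meta, list(x.columns), spec=FAST, repeats=2, seed=0)
        assert ev.auroc.shape == (3, 3)
        assert not ev.auroc.isna().any().any()
        assert float(np.diag(ev.auroc).min()) > 0.8
        off = ev.auroc.to_numpy()[~np.eye(3, dtype=bool)]
        assert off.min() >= 0.8

    def test_cohort_specific_signal_does_not_transfer(self, rng):
        """Signal planted in one cohort only: its row transfers near chance."""
        x, meta, _ = _study(seed=6, effect=0.0, cohorts=3, n=25)
        c1 = meta.samples_of("cohort1")
        cases1 = [s for s in c1 if meta.data.loc[s, "group"] == "case"]
        x = x.copy()
        x.loc[cases1, x.columns[:5]] += 0.4  # cohort1-only effect
        ev = transfer_matrix(x, meta, list(x.columns), spec=FAST, repeats=2, seed=0)
        assert ev.auroc.loc["cohort1", "cohort1"] > 0.8
        others = [ev.auroc.loc["cohort1", c] for c in ("cohort2", "cohort3")]
        assert np.mean(others) == pytest.approx(0.5, abs=0.15)

    def test_loco_output_and_held_out_permutation(self):
        x, meta, _ = _study(seed=8, effect=2.0, cohorts=3, n=20)
        lo = loco(x, meta, list(x.columns), spec=FAST, seed=0)
        assert len(lo) == 3
        assert lo.min() > 0.8
        # permute labels of one held-out cohort only -> its LOCO near chance
        md = meta.data.copy()
        rng = np.random.default_rng(0)
        c3 = meta.samples_of("cohort3")
        md.loc[c3, "group"] = rng.permutation(md.loc[c3, "group"].to_numpy())
        lo2 = loco(x, StudyMetadata(md), list(x.columns), spec=FAST, seed=0)
        assert abs(lo2["cohort3"] - 0.5) < 0.2

    def test_loco_tends_to_beat_transfer(self):
        """Pooled training generalizes at least as well as single-cohort training."""
        diffs = []
        for seed in range(5):
            x, meta, _ = _study(seed=40 + seed, effect=1.0, cohorts=3, n=15)
            ev = transfer_matrix(x, meta, list(x.columns), spec=FAST, repeats=1, seed=seed)
            lo = loco(x, meta, list(x.columns), spec=FAST, seed=seed)
            off = ev.auroc.to_numpy()[~np.eye(3, dtype=bool)]
            diffs.append(lo.mean() - off.mean())
        assert np.mean(diffs) >= 0


class TestImportanceAndPanel:
    def test_identical_rankings_preserved(self):
        imp = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
        got = aggregate_importance({"c1": imp, "c2": imp.copy()})
        assert got == ["a", "b", "c"]

    def test_consensus_first_place(self):
        imps = {
            f"c{i}": pd.Series({"top": 0.6, "x": 0.2 + 0.01 * i, "y": 0.2 - 0.01 * i})
            for i in range(5)
        }
        assert aggregate_importance(imps)[0] == "top"

    def test_tie_broken_by_mean_importance(self):
        got = aggregate_importance(
            {
                "c1": pd.Series({"a": 0.9, "b": 0.5}),
                "c2": pd.Series({"a": 0.1, "b": 0.6}),
            }
        )
        # mean ranks tie at 1.5; mean importance: a=0.5, b=0.55 -> b first
        assert got == ["b", "a"]

    def test_incremental_panel_plateau(self, rng):
        n = 120
        y = np.array(["case", "control"] * (n // 2))
        yn = (y == "case").astype(float)
        cols = {}
        for i in range(3):
            cols[f"info{i}"] = yn + rng.normal(0, 0.35, n)
        for i in range(7):
            cols[f"noise{i}"] = rng.normal(size=n)
        x = pd.DataFrame(cols)
        ranked = [f"info{i}" for i in range(3)] + [f"noise{i}" for i in range(7)]
        trace = incremental_panel(x, y, ranked, max_size=8, spec=FAST, repeats=3, seed=0)
        assert len(trace.auroc_at_size) == 8
        assert trace.chosen_size <= 5
        assert trace.auroc_at_size[3] > 0.9

    def test_single_informative_feature_panel_of_one(self, rng):
        n = 100
        y = np.array(["case", "control"] * (n // 2))
        x = pd.DataFrame(
            {"oracle": (y == "case").astype(float),
             "n1": rng.normal(size=n), "n2": rng.normal(size=n)}
        )
        trace = incremental_panel(x, y, ["oracle", "n1", "n2"], 3, spec=FAST, repeats=2, seed=0)
        assert trace.chosen_size == 1
        assert trace.chosen_panel == ["oracle"]

    def test_max_size_validated(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            incremental_panel(x, ["case", "control"] * 20, ["a", "b"], 5, spec=FAST)


class TestExternalAndSpecificity:
    def test_external_validation_same_truth_generalizes(self):
        cfg = SimulationConfig(
            n_cohorts=5,
            samples_per_cohort_per_class=18,
            n_features_per_kingdom={"bacteria": 30},
            n_markers_per_kingdom={"bacteria": 6},
            marker_log_fold_effect=2.0,
            batch_sd=0.2,
            zero_inflation=0.0,
            seed=15,
        )
        tables, meta, truth = generate_study(cfg)
        x = arcsine_sqrt(to_relative(tables["bacteria"]))
        disc = [f"cohort{i}" for i in (1, 2, 3)]
        val = [f"cohort{i}" for i in (4, 5)]
        ms = meta.data
        meta_d = StudyMetadata(ms[ms["cohort"].isin(disc)].copy())
        meta_v = StudyMetadata(ms[ms["cohort"].isin(val)].copy())
        panel = sorted(truth.marker_ids)
        out = evaluate_external(
            panel, x.loc[meta_d.sample_ids], meta_d, x.loc[meta_v.sample_ids], meta_v,
            spec=FAST, repeats=2, seed=0,
        )
        assert out["pooled"].min() >= 0.8
        assert out["transfer"].shape == (3, 2)

    def test_missing_panel_feature_zero_filled_with_warning(self):
        x, meta, truth = _study(seed=16, effect=2.0)
        panel = sorted(truth.marker_ids) + ["bacteria__ghost"]
        with pytest.warns(UserWarning, match="zero-filled"):
            out = evaluate_external(
                panel, x, meta, x.drop(columns=x.columns[:0]), meta,
                spec=FAST, repeats=1, seed=0,
            )
        assert out["pooled"].min() > 0.7

    def test_specificity_disjoint_signal_near_chance(self):
        """A non-target disease with disjoint markers scores ~0.5; the
        target's own data scores highest."""
        x, meta, truth = _study(
            seed=17, effect=2.0, cohorts=3, n=25,
            marker_features={"bacteria": [f"bacteria__f{i:04d}" for i in range(6)]},
        )
        panel = sorted(truth.marker_ids)
        # non-target disease: same generator, different planted markers
        cfg2 = SimulationConfig(
            n_cohorts=1,
            samples_per_cohort_per_class=40,
            n_features_per_kingdom={"bacteria": 30},
            n_markers_per_kingdom={"bacteria": 6},
            marker_log_fold_effect=2.0,
            batch_sd=0.0,
            zero_inflation=0.0,
            seed=18,
            marker_features={"bacteria": [f"bacteria__f{i:04d}" for i in range(20, 26)]},
        )
        t2, m2, _ = generate_study(cfg2)
        x2 = arcsine_sqrt(to_relative(t2["bacteria"]))
        disjoint = set(cfg2.marker_features["bacteria"]) & truth.marker_ids
        assert not disjoint  # construction check: signals do not overlap
        res = specificity_eval(
            panel, x, meta, {"other": (x2, m2), "target": (x, meta)}, spec=FAST, seed=0
        )
        assert res["other"] == pytest.approx(0.5, abs=0.15)
        assert res["target"] == res.max()


class TestEarlyStage:
    def test_same_effect_early_cases_comparable_auroc(self):
        x, meta, truth = _study(seed=19, effect=2.0, cohorts=3, n=25, early_effect_scale=1.0)
        panel = sorted(truth.marker_ids)
        res = early_stage_eval(x, meta, panel, spec=FAST, repeats=2, seed=0, run_loco=False)
        full = repeated_cv(x[panel], meta.data["group"], folds=5, repeats=2, spec=FAST, seed=0)
        assert abs(res["cv_mean_auroc"] - full.mean_auroc) < 0.07

    def test_half_effect_early_cases_intermediate_auroc(self):
        x, meta, truth = _study(seed=20, effect=2.0, cohorts=3, n=30, early_effect_scale=0.35)
        panel = sorted(truth.marker_ids)
        res = early_stage_eval(x, meta, panel, spec=FAST, repeats=2, seed=0, run_loco=False)
        full = repeated_cv(x[panel], meta.data["group"], folds=5, repeats=2, spec=FAST, seed=0)
        assert 0.5 < res["cv_mean_auroc"] < full.mean_auroc

    def test_requires_early_cases(self):
        x, meta, truth = _study(seed=21, early_stage_fraction=0.0)
        with pytest.raises(ValueError, match="early"):
            early_stage_eval(x, meta, sorted(truth.marker_ids), spec=FAST)
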