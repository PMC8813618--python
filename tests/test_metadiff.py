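"""Batch adjustment, per-cohort effects, pooling arithmetic and calibration."""

import numpy as np
import pandas as pd
import pytest

from mkmeta.metadiff import (
    CohortEffect,
    bh_fdr,
    cohort_effect,
    cohort_effects,
    combat_adjust,
    differential_features,
    fixed_effects_pool,
    meta_differential_abundance,
)
from mkmeta.profiles import StudyMetadata, to_relative
from mkmeta.synthdata import SimulationConfig, combined_table, generate_study


class TestFixedEffectsPool:
    def test_hand_worked_two_cohorts(self):
        effects = [
            CohortEffect("f", "c1", 0.2, 0.1, 30),
            CohortEffect("f", "c2", 0.4, 0.1, 30),
        ]
        r = fixed_effects_pool(effects)
        assert r.beta_pooled == pytest.approx(0.3)
        assert r.se_pooled == pytest.approx(0.1 / np.sqrt(2), abs=1e-4)
        assert r.Q == pytest.approx(2.0)
        assert r.I2 == pytest.approx(50.0)
        assert r.direction == "up"

    def test_single_cohort_passthrough(self):
        r = fixed_effects_pool([CohortEffect("f", "c1", -0.5, 0.2, 20)])
        assert r.beta_pooled == pytest.approx(-0.5)
        assert r.se_pooled == pytest.approx(0.2)
        assert r.Q == 0.0 and r.I2 == 0.0
        assert r.direction == "down"

    def test_homogeneous_betas_no_heterogeneity(self):
        effects = [CohortEffect("f", f"c{i}", 0.3, 0.1 * (i + 1), 30) for i in range(4)]
        r = fixed_effects_pool(effects)
        assert r.Q == pytest.approx(0.0, abs=1e-12)
        assert r.I2 == 0.0

    def test_i2_invariant_to_cohort_order(self):
        effects = [
            CohortEffect("f", "c1", 0.1, 0.05, 30),
            CohortEffect("f", "c2", 0.5, 0.12, 30),
            CohortEffect("f", "c3", -0.2, 0.2, 30),
        ]
        r1 = fixed_effects_pool(effects)
        r2 = fixed_effects_pool(effects[::-1])
        assert r1.I2 == pytest.approx(r2.I2)
        assert r1.beta_pooled == pytest.approx(r2.beta_pooled)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_pool([CohortEffect("f", "c1", 0.1, 0.0, 10)])

    def test_consistency_on_homogeneous_cohorts(self, rng):
        """|beta_pooled - delta| < 3 se_pooled in >= 99% of replicates."""
        delta, ok, reps = 0.4, 0, 300
        for _ in range(reps):
            betas = delta + rng.normal(0, 0.1, size=5)
            effects = [
                CohortEffect("f", f"c{i}", float(b), 0.1, 30)
                for i, b in enumerate(betas)
            ]
            r = fixed_effects_pool(effects)
            ok += abs(r.beta_pooled - delta) < 3 * r.se_pooled
        assert ok / reps >= 0.99


class TestBhFdr:
    def test_step_up_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.04])
        assert q == pytest.approx([0.03, 0.03, 0.04])

    def test_degenerate_inputs(self):
        assert bh_fdr([1.0, 1.0]).tolist() == [1.0, 1.0]
        assert bh_fdr([0.2]).tolist() == [0.2]
        with pytest.raises(ValueError):
            bh_fdr([])

    def test_fdr_at_least_p(self, rng):
        p = rng.uniform(size=50)
        assert np.all(bh_fdr(p) >= p - 1e-12)


def _meta_frame(n_per_group, cohort="c1", seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "cohort": [cohort] * n,
            "group": ["control"] * n_per_group + ["case"] * n_per_group,
            "age": rng.uniform(30, 80, n),
            "sex": rng.choice(["male", "female"], n),
            "bmi": rng.normal(24, 3, n),
        },
        index=[f"{cohort}_s{i}" for i in range(n)],
    )


class TestCohortEffect:
    def test_group_mean_difference_without_covariate_signal(self):
        md = _meta_frame(30)
        meta = StudyMetadata(md)
        rng = np.random.default_rng(1)
        y = rng.normal(1.0, 0.05, size=(60, 1))
        y[30:] += 0.5  # cases shifted by delta
        x = pd.DataFrame(y, index=md.index, columns=["f1"])
        eff = cohort_effect(x, meta, "f1", "c1")
        assert eff.beta == pytest.approx(0.5, abs=0.05)
        assert eff.se > 0

    def test_constant_feature_raises_degenerate(self):
        md = _meta_frame(10)
        x = pd.DataFrame(np.ones((20, 1)), index=md.index, columns=["f1"])
        with pytest.raises(ValueError, match="degenerate"):
            cohort_effect(x, StudyMetadata(md), "f1", "c1")

    def test_planted_marker_recovered_positive(self):
        """Positive planted effect gives beta > 0 in nearly all replicates."""
        hits = 0
        for r in range(20):
            md = _meta_frame(100, seed=r)
            rng = np.random.default_rng(1000 + r)
            y = rng.normal(0.5, 0.2, size=(200, 1))
            y[100:] += 0.15
            x = pd.DataFrame(y, index=md.index, columns=["f1"])
            eff = cohort_effect(x, StudyMetadata(md), "f1", "c1")
            hits += eff.beta > 0
        assert hits >= 19

    def test_collinear_covariate_named(self):
        md = _meta_frame(20)
        md["bmi"] = 24.0
        md["age"] = np.where(md["group"] == "case", 70.0, 40.0)
        # age quartiles now duplicate the group indicator -> rank deficient
        x = pd.DataFrame(
            np.random.default_rng(0).normal(size=(40, 1)), index=md.index, columns=["f1"]
        )
        with pytest.raises(ValueError, match="collinear column"):
            cohort_effects(x, StudyMetadata(md), "c1")


class TestCombatAdjust:
    def test_single_batch_identity(self):
        md = _meta_frame(10)
        x = pd.DataFrame(
            np.random.default_rng(0).normal(size=(20, 5)),
            index=md.index,
            columns=[f"f{i}" for i in range(5)],
        )
        out = combat_adjust(x, pd.Series("b1", index=x.index))
        pd.testing.assert_frame_equal(out, x)

    def test_mean_shift_removed(self, rng):
        n, p = 150, 30
        base = rng.normal(0.8, 0.15, size=(2 * n, p))
        base[n:] += 0.4  # pure batch mean shift
        idx = [f"s{i}" for i in range(2 * n)]
        x = pd.DataFrame(base, index=idx, columns=[f"f{i}" for i in range(p)])
        batch = pd.Series(["b1"] * n + ["b2"] * n, index=idx)
        gap_before = np.abs(base[:n].mean(0) - base[n:].mean(0))
        out = combat_adjust(x, batch).to_numpy()
        gap_after = np.abs(out[:n].mean(0) - out[n:].mean(0))
        assert np.all(gap_after < 0.1 * gap_before)

    def test_zeros_stay_zero_and_no_negatives(self, rng):
        n, p = 30, 20
        base = np.abs(rng.normal(0.5, 0.3, size=(2 * n, p)))
        base[rng.random((2 * n, p)) < 0.3] = 0.0
        base[n:] += 0.2
        idx = [f"s{i}" for i in range(2 * n)]
        x = pd.DataFrame(base, index=idx, columns=[f"f{i}" for i in range(p)])
        out = combat_adjust(x, pd.Series(["b1"] * n + ["b2"] * n, index=idx)).to_numpy()
        assert np.all(out[base == 0] == 0)
        assert np.all(out >= 0)


class TestPipeline:
    def test_null_type_one_error_calibrated(self):
        """No planted markers: ~5% of features called at p<0.05."""
        cfg = SimulationConfig(
            n_cohorts=5,
            samples_per_cohort_per_class=30,
            n_features_per_kingdom={"bacteria": 200},
            n_markers_per_kingdom={"bacteria": 0},
            marker_log_fold_effect=0.0,
            batch_sd=0.3,
            zero_inflation=0.05,
            seed=21,
        )
        tables, meta, _ = generate_study(cfg)
        res = meta_differential_abundance(tables["bacteria"], meta)
        rate = (res["p"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_planted_markers_recovered(self, small_combined):
        table, meta, truth = small_combined
        res = meta_differential_abundance(table, meta)
        called = set(differential_features(res, 0.05, "p").index)
        markers = truth.marker_ids & set(res.index)
        recall = len(called & markers) / len(markers)
        assert recall >= 0.9

    def test_direction_matches_planted_sign(self, small_combined):
        table, meta, truth = small_combined
        res = meta_differential_abundance(table, meta)
        ok = total = 0
        for f, eff in truth.marker_effects.items():
            if f in res.index and res.loc[f, "p"] < 0.05:
                total += 1
                ok += (res.loc[f, "direction"] == "up") == (eff > 0)
        assert total >= 5
        assert ok / total >= 0.9

    def test_alpha_zero_empty(self, small_combined):
        table, meta, _ = small_combined
        res = meta_differential_abundance(table, meta)
        assert len(differential_features(res, 0.0, "p")) == 0

    def test_batch_correction_reduces_cohort_signal(self):
        """ComBat shrinks cohort-attributable PERMANOVA R2, group p stays low."""
        from mkmeta.diversity import permanova
        from mkmeta.profiles import arcsine_sqrt
        from scipy.spatial.distance import pdist, squareform

        cfg = SimulationConfig(
            n_cohorts=3,
            samples_per_cohort_per_class=25,
            n_features_per_kingdom={"bacteria": 60},
            n_markers_per_kingdom={"bacteria": 12},
            marker_log_fold_effect=1.5,
            batch_sd=0.5,
            zero_inflation=0.0,
            seed=33,
        )
        tables, meta, _ = generate_study(cfg)
        x = arcsine_sqrt(to_relative(tables["bacteria"]))
        adj = combat_adjust(x, meta.data["cohort"])

        def r2(mat, labels):
            d = pd.DataFrame(squareform(pdist(mat)))
            return permanova(d, labels, n_permutations=99, seed=0).R2

        cohort_r2_before = r2(x.to_numpy(), meta.data["cohort"].to_numpy())
        cohort_r2_after = r2(adj.to_numpy(), meta.data["cohort"].to_numpy())
        assert cohort_r2_after < 0.5 * cohort_r2_before

        d = pd.DataFrame(squareform(pdist(adj.to_numpy())))
        pg = permanova(d, meta.data["group"].to_numpy(), n_permutations=99, seed=1).p
        assert pg < 0.05
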