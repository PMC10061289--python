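import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy import stats

from gliomune.scoring import ANTITUMOR_ROLES, PROTUMOR_ROLES
from gliomune.synthetic import (
    CohortConfig,
    load_cohort,
    make_cohort,
    make_panel,
    make_pathways,
    simulate_expression,
    simulate_survival,
)


class TestPanel:
    def test_default_panel_has_803_disjoint_markers_in_29_sets(self):
        panel, universe = make_panel(CohortConfig())
        assert len(panel) == 29
        sizes = [len(panel[name]) for name in panel.names]
        assert sum(sizes) == 803
        assert set(sizes) <= {27, 28}
        assert len(panel.universe()) == 803  # disjoint by construction
        assert len(universe) == 803 + 1200

    def test_all_nine_composite_roles_present(self):
        panel, _ = make_panel(CohortConfig())
        for role in (*PROTUMOR_ROLES, *ANTITUMOR_ROLES):
            assert role in panel.names
            assert panel.roles[role] == role

    def test_single_small_set(self):
        cfg = CohortConfig(n_cell_types=1, markers_per_type=5, n_background_genes=200)
        panel, universe = make_panel(cfg)
        assert len(panel) == 1
        assert len(universe) == 5 + 200

    def test_same_seed_same_panel(self):
        a, _ = make_panel(CohortConfig(seed=5))
        b, _ = make_panel(CohortConfig(seed=5))
        assert a == b


class TestExpression:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_samples=20, with_images=False, seed=3)
        a = make_cohort(cfg).expression
        b = make_cohort(cfg).expression
        assert a.equals(b)

    def test_different_seeds_differ(self):
        a = make_cohort(CohortConfig(n_samples=20, with_images=False, seed=1))
        b = make_cohort(CohortConfig(n_samples=20, with_images=False, seed=2))
        assert not a.expression.equals(b.expression)

    def test_inflamed_markers_exceed_cold_markers_for_every_cell_type(self):
        cohort = make_cohort(CohortConfig(n_samples=150, with_images=False, seed=0))
        c3 = cohort.true_subtype == "C3"
        c2 = cohort.true_subtype == "C2"
        for name in cohort.panel.names:
            genes = sorted(cohort.panel[name])
            mean_c3 = cohort.expression.loc[genes, c3.to_numpy()].mean().mean()
            mean_c2 = cohort.expression.loc[genes, c2.to_numpy()].mean().mean()
            assert mean_c3 > mean_c2, name

    def test_pathway_direction_pattern(self):
        cohort = make_cohort(CohortConfig(n_samples=150, with_images=False, seed=0))
        c3 = (cohort.true_subtype == "C3").to_numpy()
        c2 = (cohort.true_subtype == "C2").to_numpy()
        hyp = sorted(cohort.pathways["hypoxia"])
        cal = sorted(cohort.pathways["calcium_signaling"])
        expr = cohort.expression
        assert expr.loc[hyp, c3].mean().mean() > expr.loc[hyp, c2].mean().mean()
        assert expr.loc[cal, c2].mean().mean() > expr.loc[cal, c3].mean().mean()

    def test_unknown_label_rejected(self):
        cfg = CohortConfig(n_samples=4, with_images=False)
        panel, universe = make_panel(cfg)
        pathways = make_pathways(cfg)
        with pytest.raises(ValueError, match="C9"):
            simulate_expression(panel, pathways, ["C1", "C9", "C2", "C3"], cfg,
                                universe=universe)

    def test_no_signal_configuration_gives_chance_clustering(self):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        from gliomune.scoring import minmax_normalize, ssgsea_scores

        cohort = make_cohort(
            CohortConfig(
                n_samples=90,
                with_images=False,
                infiltration_effect=0.0,
                pathway_effect=0.0,
                seed=4,
            )
        )
        norm = minmax_normalize(ssgsea_scores(cohort.expression, cohort.panel))
        labels = KMeans(3, n_init=10, random_state=0).fit(norm.T.to_numpy()).labels_
        ari = adjusted_rand_score(cohort.true_subtype, labels)
        assert abs(ari) < 0.05


class TestSurvival:
    def test_no_censoring_all_events(self):
        cfg = CohortConfig(n_samples=50, censor_rate=0.0, with_images=False)
        surv = simulate_survival(["C1"] * 50, cfg, np.random.default_rng(0))
        assert (surv["os_event"] == 1).all()
        assert (surv["os_months"] > 0).all()

    def test_invalid_censor_rate_rejected(self):
        with pytest.raises(ValueError, match="censor_rate"):
            CohortConfig(censor_rate=1.0)

    def test_equal_hazards_give_uniform_logrank_p(self):
        from gliomune.characterize import km_logrank

        ps = []
        for seed in range(40):
            cfg = CohortConfig(
                n_samples=90, hazard_per_subtype=(0.05, 0.05, 0.05),
                with_images=False, seed=seed,
            )
            labels = np.repeat(["C1", "C2", "C3"], 30)
            surv = simulate_survival(labels, cfg, np.random.default_rng(seed))
            labels = pd.Series(labels, index=surv.index)
            ps.append(km_logrank(surv, labels).p_value)
        # p-values roughly uniform: no excess small values
        assert np.mean(np.array(ps) < 0.05) <= 0.15
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_hazard_ratio_orders_km_medians(self):
        wins = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = CohortConfig(
                n_samples=300,
                hazard_per_subtype=(0.05, 0.02, 0.06),  # C2 hazard 1/3 of C3
                with_images=False,
                seed=seed,
            )
            labels = np.repeat(["C2", "C3"], 150)
            surv = simulate_survival(labels, cfg, np.random.default_rng(seed))
            medians = {}
            for g in ("C2", "C3"):
                sel = np.array(labels) == g
                kmf = KaplanMeierFitter().fit(
                    surv["os_months"][sel], surv["os_event"][sel]
                )
                medians[g] = kmf.median_survival_time_
            wins += int(medians["C2"] > medians["C3"])
        assert wins >= int(0.95 * n_rep)


class TestImages:
    def test_zero_perturbation_gives_identical_rater_masks(self):
        cohort = make_cohort(CohortConfig(n_samples=3, rater_perturb_radius=0, seed=0))
        for sid in cohort.sample_ids:
            assert (cohort.masks[sid] == cohort.masks_rater2[sid]).all()
            assert (cohort.masks[sid] == cohort.masks_intra2[sid]).all()

    def test_masks_nonempty_and_inside_volume(self, imaging_cohort):
        for sid in imaging_cohort.sample_ids:
            for mask in (
                imaging_cohort.masks[sid],
                imaging_cohort.masks_rater2[sid],
                imaging_cohort.masks_intra2[sid],
            ):
                assert mask.any()
                assert not mask[0].any() and not mask[-1].any()

    def test_no_batch_effect_when_gain_and_offset_zero(self):
        cohort = make_cohort(
            CohortConfig(n_samples=20, batch_gain_sd=0.0, batch_offset_sd=0.0, seed=2)
        )
        background = {
            b: [
                cohort.volumes[sid]["T1"][~cohort.masks[sid]].mean()
                for sid in cohort.sample_ids
                if cohort.batch[sid] == b
            ]
            for b in cohort.batch.unique()
        }
        means = [np.mean(v) for v in background.values() if v]
        assert np.ptp(means) < 0.5  # sampling noise only

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError, match="32"):
            make_cohort(CohortConfig(n_samples=2, image_shape=(16, 16, 16)))

    def test_subtype_changes_image_intensity(self, imaging_cohort):
        means = {
            st: [
                imaging_cohort.volumes[sid]["T2"][imaging_cohort.masks[sid]].mean()
                for sid in imaging_cohort.sample_ids
                if imaging_cohort.true_subtype[sid] == st
            ]
            for st in set(imaging_cohort.true_subtype)
        }
        # inflamed tumors are the brightest on average when present
        collapsed = {st: np.mean(v) for st, v in means.items() if v}
        if "C3" in collapsed and "C2" in collapsed:
            assert collapsed["C3"] > collapsed["C2"]


class TestCohort:
    def test_round_trip_through_directory(self, tmp_path):
        cfg = CohortConfig(n_samples=4, seed=6)
        cohort = make_cohort(cfg, out_dir=tmp_path / "cohort")
        back = load_cohort(tmp_path / "cohort", cfg)
        assert np.allclose(
            back.expression.to_numpy(), cohort.expression.to_numpy(), rtol=1e-6
        )
        assert back.panel == cohort.panel
        assert (back.true_subtype == cohort.true_subtype).all()
        sid = cohort.sample_ids[0]
        assert np.allclose(back.volumes[sid]["T1"], cohort.volumes[sid]["T1"],
                           rtol=1e-6)
        assert (back.masks[sid] == cohort.masks[sid]).all()

    def test_subtype_counts_follow_multinomial_draw(self):
        counts = []
        for seed in range(40):
            cohort = make_cohort(
                CohortConfig(
                    n_samples=60,
                    subtype_proportions=(0.45, 0.26, 0.29),
                    with_images=False,
                    seed=seed,
                )
            )
            counts.append(cohort.true_subtype.value_counts().reindex(
                ["C1", "C2", "C3"]).to_numpy())
        mean = np.mean(counts, axis=0)
        assert np.allclose(mean, [27, 15.6, 17.4], atol=2.5)

    def test_all_subtypes_present_at_or_above_30_samples(self):
        for seed in range(5):
            cohort = make_cohort(
                CohortConfig(n_samples=30, with_images=False, seed=seed)
            )
            assert set(cohort.true_subtype) == {"C1", "C2", "C3"}

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortConfig(subtype_proportions=(0.5, 0.5, 0.5))

    def test_clinical_table_is_aligned(self, imaging_cohort):
        assert list(imaging_cohort.clinical.index) == imaging_cohort.sample_ids
        assert set(imaging_cohort.clinical.columns) >= {
            "subtype", "os_months", "os_event", "batch", "grade",
        }
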