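"""Generator behavior: sigmoid programs, counts, feedback coupling, cohorts."""

import numpy as np
import pytest
from scipy import stats

from tet2traj.evaluation import child_seeds
from tet2traj.simulate import (
    ModuleActivationParams,
    SimulationConfig,
    expected_module_curve,
    generate_bulk_cohort,
    generate_cells,
    generate_ihc_cohort,
    module_definitions,
    module_mean,
    type_label,
)
from tet2traj.survival import CATEGORIES, logrank_test


class TestModuleMean:
    def test_midpoint_gives_half_amplitude(self):
        p = ModuleActivationParams("M", baseline=1.0, amplitude=2.0, steepness=0.3, midpoint=40.0)
        assert module_mean(40.0, p) == pytest.approx(1.0 + 1.0)

    def test_saturation_below_midpoint_at_large_steepness(self):
        p = ModuleActivationParams("M", baseline=1.0, amplitude=2.0, steepness=50.0, midpoint=50.0)
        assert module_mean(10.0, p) == pytest.approx(1.0, abs=1e-6)

    def test_direct_evaluation(self):
        # 1.0 + 2.0 / (1 + exp(-0.2 * (60 - 50))) = 1 + 2 / (1 + e^-2)
        p = ModuleActivationParams("M", baseline=1.0, amplitude=2.0, steepness=0.2, midpoint=50.0)
        assert module_mean(60.0, p) == pytest.approx(1.0 + 2.0 / (1.0 + np.exp(-2.0)), abs=1e-4)
        assert module_mean(60.0, p) == pytest.approx(2.7616, abs=1e-4)

    def test_domain_checked(self):
        p = ModuleActivationParams("M", 1.0, 2.0, 0.2, 50.0)
        with pytest.raises(ValueError):
            module_mean(101.0, p)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(steepness=-0.1), "steepness"),
            (dict(midpoint=120.0), "midpoint"),
            (dict(amplitude=0.0), "amplitude"),
        ],
    )
    def test_invalid_params_name_the_field(self, kwargs, msg):
        base = dict(module_name="M", baseline=1.0, amplitude=1.0, steepness=0.2, midpoint=50.0)
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            ModuleActivationParams(**base)


class TestGenerateCells:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_cells=50, seed=3)
        m1, a1, t1 = generate_cells(cfg)
        m2, a2, t2 = generate_cells(cfg)
        assert np.array_equal(m1.values, m2.values)
        assert a1.equals(a2)
        assert np.array_equal(t1.t_true, t2.t_true)

    def test_counts_are_nonnegative_integers(self, small_run):
        v = small_run["matrix"].values
        assert (v >= 0).all()
        assert np.array_equal(v, np.round(v))

    def test_no_all_zero_module_gene(self, small_run):
        m = small_run["matrix"]
        module_cols = [i for i, g in enumerate(m.gene_ids) if not g.startswith("BG_")]
        assert (m.values[:, module_cols].sum(axis=0) > 0).all()

    def test_mean_library_size_near_target(self):
        cfg = SimulationConfig(n_cells=2000, conditions=("FLAG",), seed=5)
        m, _, _ = generate_cells(cfg)
        realized = m.values.sum(axis=1).mean()
        assert abs(realized - cfg.library_size_mean) / cfg.library_size_mean < 0.10

    def test_type_labels_follow_thresholds(self, small_run):
        truth = small_run["truth"]
        early = truth.t_true < 20
        assert (truth.type_label[early] == "I").all()
        assert set(truth.type_label) <= {"I", "II", "III", "IV", "V"}

    def test_type_fractions_match_threshold_widths(self):
        # pooled timepoint mixture is uniform, so each 20-unit type band
        # should hold ~20% of cells up to binomial error
        cfg = SimulationConfig(n_cells=2000, conditions=("FLAG",), seed=11)
        _, _, truth = generate_cells(cfg)
        for lab in ("I", "II", "III", "IV", "V"):
            frac = (truth.type_label == lab).mean()
            assert abs(frac - 0.2) < 0.04

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(dispersion=-1.0)
        with pytest.raises(ValueError, match="feedback_gamma"):
            SimulationConfig(feedback_gamma=1.0)
        with pytest.raises(ValueError, match="n_cells"):
            SimulationConfig(n_cells=0)

    def test_conditions_exchangeable_without_feedback(self):
        # with gamma = 0 the FLAG and TET2CD per-module means are i.i.d.;
        # two-sample t-tests at alpha = 0.01 should rarely reject
        tests, rejections = 0, 0
        for seed in child_seeds(42, 20):
            cfg = SimulationConfig(n_cells=250, feedback_gamma=0.0, seed=seed)
            m, ann, _ = generate_cells(cfg)
            cond = ann["condition"].to_numpy()
            for mod in module_definitions(cfg):
                cols = [i for i, g in enumerate(m.gene_ids) if g in set(mod.genes)]
                per_cell = m.values[:, cols].mean(axis=1)
                p = stats.ttest_ind(per_cell[cond == "FLAG"], per_cell[cond == "TET2CD"]).pvalue
                tests += 1
                rejections += p < 0.01
        assert rejections / tests <= 0.05

    def test_feedback_damps_emt_in_upper_trajectory(self):
        # noiseless curves: TET2CD strictly below FLAG for EMT at matched late t
        cfg = SimulationConfig(feedback_gamma=0.5)
        t = np.linspace(50.0, 100.0, 51)
        flag = expected_module_curve(cfg, "EMT_MARKERS", "FLAG", t)
        tcd = expected_module_curve(cfg, "EMT_MARKERS", "TET2CD", t)
        assert (tcd < flag).all()
        # and TET2 targets are boosted under TET2CD
        flag_t = expected_module_curve(cfg, "TET2_TARGETS", "FLAG", t)
        tcd_t = expected_module_curve(cfg, "TET2_TARGETS", "TET2CD", t)
        assert (tcd_t > flag_t).all()


class TestBulkCohort:
    def test_singleton_sample_is_one_cells_normalized_profile(self):
        # with one cell per sample the size factor is exactly 1, so
        # expm1 of the bulk profile recovers integer counts
        cfg = SimulationConfig(n_cells=10, seed=2)
        bulk, ann, truth = generate_bulk_cohort(cfg, n_samples=5, cells_per_sample=1, seed=8)
        recovered = np.expm1(bulk.values)
        assert np.allclose(recovered, np.round(recovered), atol=1e-8)

    def test_stage_labels_monotone_in_latent_t(self):
        cfg = SimulationConfig(n_cells=10, seed=2)
        _, ann, _ = generate_bulk_cohort(cfg, n_samples=40, cells_per_sample=3, seed=8)
        order = ann.sort_values("t_sample")["stage"].tolist()
        rank = {"I": 0, "II": 1, "III": 2, "IV": 3}
        assert all(rank[a] <= rank[b] for a, b in zip(order, order[1:]))

    def test_extreme_samples_separate_by_amplitude_sign(self):
        cfg = SimulationConfig(n_cells=10, seed=2)
        bulk, ann, _ = generate_bulk_cohort(cfg, n_samples=30, cells_per_sample=5, seed=4)
        lo = np.argmin(ann["t_sample"].to_numpy())
        hi = np.argmax(ann["t_sample"].to_numpy())
        for p in cfg.module_params:
            cols = [i for i, g in enumerate(bulk.gene_ids) if g.startswith(p.module_name)]
            diff = bulk.values[hi, cols].mean() - bulk.values[lo, cols].mean()
            assert np.sign(diff) == np.sign(p.amplitude)

    def test_degenerate_stage_rule_rejected(self):
        cfg = SimulationConfig(n_cells=10, seed=2)
        with pytest.raises(ValueError, match="stage_rule"):
            generate_bulk_cohort(cfg, 5, 2, stage_rule=(50.0, 25.0, 75.0))
        with pytest.raises(ValueError, match="n_samples"):
            generate_bulk_cohort(cfg, 1, 2)


class TestIHCCohort:
    def test_no_censoring_means_all_events(self):
        records = generate_ihc_cohort(50, hazard_beta=1.0, censor_rate=0.0, seed=1)
        assert all(r.event == 1 for r in records)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_ihc_cohort(5, 1.0)
        with pytest.raises(ValueError):
            generate_ihc_cohort(50, -0.5)

    def test_null_hazard_gives_nonsignificant_logrank(self):
        # hazard_beta = 0: survival independent of nuclear fraction
        nonsig = 0
        for seed in child_seeds(7, 20):
            records = generate_ihc_cohort(200, hazard_beta=0.0, censor_rate=0.2, seed=seed)
            groups = [
                (
                    [r.time for r in records if r.category == c],
                    [r.event for r in records if r.category == c],
                )
                for c in CATEGORIES
            ]
            _, _, p = logrank_test(groups)
            nonsig += p >= 0.05
        assert nonsig >= 18  # >= 90% of 20 seeds

    def test_protective_hazard_favors_nuclear_categories(self):
        from tet2traj.survival import km_median

        best = 0
        for seed in child_seeds(21, 5):
            records = generate_ihc_cohort(500, hazard_beta=1.5, censor_rate=0.2, seed=seed)
            medians = {}
            for c in CATEGORIES:
                t = [r.time for r in records if r.category == c]
                e = [r.event for r in records if r.category == c]
                medians[c] = km_median(t, e)
            best += max(medians, key=medians.get) == "nucleus_only"
        assert best >= 4


def test_type_label_edges_right_open():
    assert list(type_label([0.0, 19.999, 20.0, 40.0, 79.999, 80.0, 100.0])) == [
        "I", "I", "II", "III", "IV", "V", "V",
    ]
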