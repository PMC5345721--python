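"""Generator correctness: determinism, noiseless limits, planted structure."""

import numpy as np
import pytest
from pandas.testing import assert_frame_equal

from dosagegi import SimConfig
from dosagegi.growth import compute_doubling_time
from dosagegi.synthetic import (
    GroundTruth,
    logistic_od,
    simulate_feature_table,
    simulate_ground_truth,
    simulate_growth_curves,
    simulate_screen_plate,
    simulate_spot_assay,
)


class TestDeterminism:
    def test_identical_seed_gives_identical_outputs(self, small_config):
        t1 = simulate_ground_truth(small_config)
        t2 = simulate_ground_truth(small_config)
        assert_frame_equal(t1.strains, t2.strains)
        assert_frame_equal(t1.pairs, t2.pairs)
        c1 = simulate_growth_curves(small_config, t1)
        c2 = simulate_growth_curves(small_config, t2)
        assert_frame_equal(c1, c2)
        p1 = simulate_screen_plate(small_config, t1, "Q-SDL0")
        p2 = simulate_screen_plate(small_config, t2, "Q-SDL0")
        assert_frame_equal(p1, p2)
        f1 = simulate_feature_table(small_config, t1)
        f2 = simulate_feature_table(small_config, t2)
        assert_frame_equal(f1, f2)

    def test_different_seeds_differ(self, small_config):
        other = SimConfig(**{**small_config.__dict__, "seed": 999})
        t1 = simulate_ground_truth(small_config)
        t2 = simulate_ground_truth(other)
        assert not t1.strains["fitness"].equals(t2.strains["fitness"])


class TestGrowthModel:
    def test_large_capacity_limit_is_exponential(self):
        """With K far above the OD range the curve is exponential and the
        downstream doubling time equals the analytic one."""
        cfg = SimConfig(wt_doubling=90.0, carrying_capacity=1e12,
                        od_noise_sd=0.0)
        t = np.arange(0, 1441, 15.0)
        od = logistic_od(t, 1.0, cfg)
        assert np.allclose(od, 0.1 * 2 ** (t / 90.0), rtol=1e-6)
        est = compute_doubling_time(t, od)
        assert abs(est.minutes - 90.0) / 90.0 < 1e-6

    def test_half_fitness_doubles_early_doubling_time(self):
        cfg = SimConfig(wt_doubling=90.0, carrying_capacity=1e12,
                        od_noise_sd=0.0)
        t = np.arange(0, 1441, 15.0)
        est = compute_doubling_time(t, logistic_od(t, 0.5, cfg))
        assert abs(est.minutes - 180.0) / 180.0 < 1e-6

    def test_curve_shape_and_counts(self, small_config, small_truth):
        curves = simulate_growth_curves(small_config, small_truth)
        n_times = int(small_config.horizon // small_config.sampling_interval) + 1
        n_strains = (small_truth.strains["klass"] != "query").sum()
        expected = (n_strains * small_config.strain_replicates
                    + small_config.wt_replicates) * n_times
        assert len(curves) == expected
        assert (curves["od600"] >= 0).all()

    def test_toxic_fraction_converges(self):
        """Generated toxic fraction matches the configured rate within the
        binomial 95% CI at large n."""
        from scipy.stats import binom
        cfg = SimConfig(seed=21, n_kinases=2000, n_tfs=2000)
        truth = simulate_ground_truth(cfg)
        for klass, frac in (("kinase", 0.20), ("TF", 0.26)):
            grp = truth.strains[truth.strains["klass"] == klass]
            lo, hi = binom.interval(0.95, len(grp), frac)
            assert lo <= grp["toxic"].sum() <= hi


class TestSpotSimulator:
    def test_methods_worked_example_counts(self):
        """fa=1, fb=0.8, gi=-0.6 -> double shows 1 of 5 spots."""
        cfg = SimConfig(spot_noise_prob=0.0)
        ind, ctrl = simulate_spot_assay(1.0, 0.8, -0.6, cfg)
        assert (ind.wt_spots, ind.a_spots, ind.b_spots, ind.double_spots) \
            == (5, 5, 4, 1)
        assert (ctrl.a_spots, ctrl.b_spots, ctrl.double_spots) == (5, 5, 5)

    def test_no_interaction_full_viability(self):
        cfg = SimConfig(spot_noise_prob=0.0)
        ind, _ = simulate_spot_assay(1.0, 1.0, 0.0, cfg)
        assert (ind.a_spots, ind.b_spots, ind.double_spots) == (5, 5, 5)

    def test_lethality_floor(self):
        cfg = SimConfig(spot_noise_prob=0.0)
        ind, _ = simulate_spot_assay(0.8, 0.9, -(0.8 * 0.9), cfg)
        assert ind.double_spots == 0

    def test_invalid_inputs_rejected(self):
        cfg = SimConfig()
        with pytest.raises(ValueError):
            simulate_spot_assay(1.2, 0.5, 0.0, cfg)
        with pytest.raises(ValueError):
            SimConfig(spot_count_max=0).validate()


class TestScreenPlate:
    def test_uniform_fitness_no_noise_gives_uniform_sizes(self):
        cfg = SimConfig(seed=1, n_kinases=2, n_tfs=20, toxic_fraction_tf=0.0,
                        toxic_fraction_kinase=0.0, gi_rate=0.0,
                        colony_noise_sd=0.0, plate_effect_sd=0.0)
        truth = simulate_ground_truth(cfg)
        truth.strains["fitness"] = 1.0
        plate = simulate_screen_plate(cfg, truth, "Q-SDL0",
                                      background="control")
        sizes = plate.loc[plate["size"] > 0, "size"]
        assert np.allclose(sizes, sizes.iloc[0])

    def test_planted_effect_shrinks_block_by_expected_ratio(self):
        """gi=-0.6 on a fb=0.8 pair: block mean is 0.2/0.8 of its
        no-interaction expectation (closed form of the observation model)."""
        cfg = SimConfig(seed=1, n_kinases=1, n_tfs=10, colony_noise_sd=0.0,
                        plate_effect_sd=0.0, n_sdl_queries=1, n_ddl_queries=0)
        truth = simulate_ground_truth(cfg)
        truth.strains.loc[truth.strains.strain_id == "TF003", "fitness"] = 0.8
        truth.pairs["gi_effect"] = 0.0
        truth.pairs.loc[truth.pairs.tf_id == "TF003", "gi_effect"] = -0.6
        mut = simulate_screen_plate(cfg, truth, "Q-SDL0", background="mutant")
        ctl = simulate_screen_plate(cfg, truth, "Q-SDL0", background="control")
        m = mut[mut.strain_id == "TF003"]["size"].mean()
        c = ctl[ctl.strain_id == "TF003"]["size"].mean()
        assert m / c == pytest.approx(0.2 / 0.8, rel=1e-12)

    def test_too_many_strains_rejected(self):
        cfg = SimConfig(n_tfs=400)
        truth = simulate_ground_truth(cfg)
        with pytest.raises(ValueError, match="exceed"):
            simulate_screen_plate(cfg, truth, "Q-SDL0")

    def test_geometry_and_border_flags(self, small_config, small_truth):
        plate = simulate_screen_plate(small_config, small_truth, "Q-SDL0")
        assert len(plate) == 32 * 48
        border = plate[plate.border_flag]
        assert set(border["row"]).issubset(set(range(2)) | set(range(30, 32))
                                           | set(range(32)))
        # every TF occupies exactly one 2x2 block
        tf = plate[plate.strain_id.str.startswith("TF")]
        counts = tf.groupby("strain_id").size()
        assert (counts == 4).all()


class TestFeatureTable:
    def test_group_means_near_targets(self):
        """Defaults at study group sizes: sample means within 15%."""
        cfg = SimConfig(seed=13)
        truth = simulate_ground_truth(cfg)
        feats = simulate_feature_table(cfg, truth)
        kin = feats[feats.klass == "kinase"]
        for toxic, target in ((True, 309.0), (False, 218.0)):
            got = kin.loc[kin.toxic == toxic, "disorder_len"].mean()
            assert abs(got - target) / target < 0.15

    def test_labels_trace_to_truth(self, small_config, small_truth):
        feats = simulate_feature_table(small_config, small_truth)
        merged = feats.merge(small_truth.strains, left_on="gene",
                             right_on="strain_id")
        assert (merged["toxic_x"] == merged["toxic_y"]).all()

    def test_empty_group_warns_and_emits_none(self):
        cfg = SimConfig(seed=2, n_kinases=5, n_tfs=5, toxic_fraction_kinase=0.0,
                        toxic_fraction_tf=0.0)
        truth = simulate_ground_truth(cfg)
        with pytest.warns(UserWarning, match="empty"):
            feats = simulate_feature_table(cfg, truth)
        assert not feats["toxic"].any()

    def test_no_strains_gives_empty_table(self):
        cfg = SimConfig(seed=2, n_kinases=0, n_tfs=0)
        truth = simulate_ground_truth(cfg)
        with pytest.warns(UserWarning):
            feats = simulate_feature_table(cfg, truth)
        assert feats.empty


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"toxic_fraction_tf": 1.3},
        {"od_start": 0.0},
        {"horizon": -1.0},
        {"gi_magnitudes": (0.0,)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()

    def test_ground_truth_invariants(self, small_truth):
        assert isinstance(small_truth, GroundTruth)
        s = small_truth.strains
        assert ((s.fitness > 0) & (s.fitness <= 1.5)).all()
        assert small_truth.pairs["gi_effect"].between(-1, 1).all()
        # every pair references known strains
        ids = set(s.strain_id)
        assert set(small_truth.pairs.query_id) <= ids
        assert set(small_truth.pairs.tf_id) <= ids
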