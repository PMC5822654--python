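"""Synthetic study generator: roster, nominations, outcomes, missingness."""

import numpy as np
import pandas as pd
import pytest

import friendnet as fn
from friendnet.synthetic import ITEM_COLS, design_matrix


class TestRoster:
    def test_count_bookkeeping(self):
        cfg = fn.SimulationConfig(n_schools=2, children_per_school=10, seed=1)
        roster = fn.generate_roster(cfg)
        assert len(roster) == 20
        assert roster["school_id"].nunique() == 2
        assert roster["child_id"].is_unique

    def test_activity_score_is_item_sum_in_range(self, small_study):
        roster = small_study.roster
        assert (roster["activity_score"] == roster[ITEM_COLS].sum(axis=1)).all()
        assert roster["activity_score"].between(0, 12).all()

    def test_seeded_determinism(self):
        cfg = fn.SimulationConfig(n_schools=3, children_per_school=15, seed=42)
        r1 = fn.generate_roster(cfg)
        r2 = fn.generate_roster(cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            fn.generate_roster(fn.SimulationConfig(n_schools=0))
        with pytest.raises(ValueError):
            fn.SimulationConfig(rho=1.2).validate()
        with pytest.raises(ValueError):
            fn.SimulationConfig(sigma=-1.0).validate()

    def test_marginals_near_targets(self):
        cfg = fn.SimulationConfig(n_schools=40, children_per_school=30, p_female=0.55, seed=5)
        roster = fn.generate_roster(cfg)
        assert abs((roster["sex"] == "F").mean() - 0.55) < 0.04
        assert abs(roster["imd"].mean() - 15.0) < 1.0
        assert abs(roster["bmi_z"].mean() - 0.3) < 0.1
        assert (roster["imd"] > 0).all()


class TestNominations:
    def test_degenerate_homophily(self):
        cfg = fn.SimulationConfig(n_schools=3, children_per_school=20, p_same_sex_tie=1.0, seed=2)
        roster = fn.generate_roster(cfg)
        noms = fn.generate_nominations(roster, cfg)
        sex = roster.set_index("child_id")["sex"]
        same = sex.loc[noms["nominator_id"]].to_numpy() == sex.loc[noms["nominee_id"]].to_numpy()
        assert same.all()

    def test_same_sex_fraction_near_target(self):
        cfg = fn.SimulationConfig(n_schools=40, children_per_school=30, seed=3)
        roster = fn.generate_roster(cfg)
        noms = fn.generate_nominations(roster, cfg)
        assert len(noms) > 10_000 * 0.3  # enough ties for a frequency check
        sex = roster.set_index("child_id")["sex"]
        same = sex.loc[noms["nominator_id"]].to_numpy() == sex.loc[noms["nominee_id"]].to_numpy()
        # with small schools a same-sex pool occasionally runs dry, so the
        # realised fraction sits at or slightly below the target
        assert 0.85 < same.mean() <= 0.92

    def test_cap_and_structure(self, small_study):
        noms = small_study.nominations
        per_child = noms.groupby("nominator_id").size()
        assert per_child.max() <= 4
        assert (noms["nominator_id"] != noms["nominee_id"]).all()
        # within school, ranks unique per nominator
        assert not noms.duplicated(["nominator_id", "rank"]).any()
        roster = small_study.roster.set_index("child_id")
        assert (
            roster.loc[noms["nominator_id"], "school_id"].to_numpy()
            == roster.loc[noms["nominee_id"], "school_id"].to_numpy()
        ).all()

    def test_singleton_school_emits_none(self):
        roster = pd.DataFrame(
            {"child_id": ["a"], "school_id": ["s1"], "sex": ["F"]}
        )
        noms = fn.generate_nominations(roster, fn.SimulationConfig(n_schools=1, seed=0))
        assert len(noms) == 0


class TestOutcomes:
    def test_rho_zero_is_linear_model(self, small_study):
        cfg = fn.SimulationConfig(n_schools=2, children_per_school=10, rho=0.0, seed=7)
        roster = fn.generate_roster(cfg)
        noms = fn.generate_nominations(roster, cfg)
        W = fn.study_weight_matrix(roster, noms)
        roster = roster.set_index("child_id").loc[W.ids].reset_index()
        X = design_matrix(roster)
        rng_a = np.random.default_rng(9)
        rng_b = np.random.default_rng(9)
        y = fn.generate_outcomes(W, X, cfg, rng_a)
        # reconstruct Xb + u + eps with the same rng stream
        schools = pd.Series(W.schools)
        u_school = {s: rng_b.normal(0.0, cfg.school_sd) for s in schools.unique()}
        u = schools.map(u_school).to_numpy()
        eps = rng_b.normal(0.0, cfg.sigma, size=W.n)
        expected = X @ np.asarray(cfg.beta) + u + eps
        np.testing.assert_allclose(y, expected, rtol=1e-12)

    def test_defining_identity_residual(self):
        cfg = fn.SimulationConfig(n_schools=3, children_per_school=12, rho=0.3, seed=8)
        roster = fn.generate_roster(cfg)
        noms = fn.generate_nominations(roster, cfg)
        W = fn.study_weight_matrix(roster, noms)
        roster = roster.set_index("child_id").loc[W.ids].reset_index()
        X = design_matrix(roster)
        rng_a = np.random.default_rng(10)
        rng_b = np.random.default_rng(10)
        y = fn.generate_outcomes(W, X, cfg, rng_a)
        schools = pd.Series(W.schools)
        u_school = {s: rng_b.normal(0.0, cfg.school_sd) for s in schools.unique()}
        u = schools.map(u_school).to_numpy()
        eps = rng_b.normal(0.0, cfg.sigma, size=W.n)
        resid = (np.eye(W.n) - cfg.rho * W.w) @ y - X @ np.asarray(cfg.beta) - u - eps
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_infeasible_rho_names_interval(self, small_study):
        cfg = fn.SimulationConfig(n_schools=2, children_per_school=10, seed=7)
        roster = fn.generate_roster(cfg)
        noms = fn.generate_nominations(roster, cfg)
        W = fn.study_weight_matrix(roster, noms)
        X = np.ones((W.n, 1))
        with pytest.raises(ValueError, match="feasible interval"):
            fn.generate_outcomes(W, X, cfg, rho=1.5, beta=(0.0,))


class TestMissingness:
    def test_zero_rates_leave_data_unchanged(self, small_study):
        cfg = fn.SimulationConfig(missing_rates={}, seed=1)
        out, mask = fn.apply_missingness(small_study.roster, cfg)
        pd.testing.assert_frame_equal(out, small_study.roster)
        assert not mask.to_numpy().any()

    def test_binomial_rate(self):
        cfg = fn.SimulationConfig(
            n_schools=40, children_per_school=25, seed=21,
            missing_rates={"mean_sedentary": 0.18},
        )
        roster = fn.generate_roster(cfg)
        roster["mean_sedentary"] = np.random.default_rng(0).normal(430, 30, len(roster))
        roster["mean_mvpa"] = np.random.default_rng(1).normal(60, 15, len(roster))
        out, mask = fn.apply_missingness(roster, cfg)
        n = len(roster)
        n_missing = int(mask["mean_sedentary"].sum())
        tol = 4 * np.sqrt(n * 0.18 * 0.82)
        assert abs(n_missing - 0.18 * n) < tol

    def test_seeded_pattern_reproducible(self, small_study, small_config):
        out1, mask1 = fn.apply_missingness(small_study.roster, small_config)
        out2, mask2 = fn.apply_missingness(small_study.roster, small_config)
        pd.testing.assert_frame_equal(out1, out2)
        pd.testing.assert_frame_equal(mask1, mask2)

    def test_rate_one_rejected(self, small_study):
        with pytest.raises(ValueError):
            fn.SimulationConfig(missing_rates={"bmi_z": 1.0}).validate()


class TestEpochGenerator:
    def test_planted_zero_block_verbatim(self):
        profile = fn.ActivityProfile(n_days=1, nonwear_blocks=((100, 70),))
        (day,) = fn.generate_epoch_series(profile, seed=4)
        assert (day.counts[600:1020] == 0).all()

    def test_five_day_profile(self):
        days = fn.generate_epoch_series(fn.ActivityProfile(n_days=5), seed=4)
        assert len(days) == 5
        assert sum(d.weekend for d in days) == 2
        assert all(d.counts.min() >= 0 for d in days)

    def test_seeded_determinism(self):
        a = fn.generate_epoch_series(fn.ActivityProfile(n_days=2), seed=9)
        b = fn.generate_epoch_series(fn.ActivityProfile(n_days=2), seed=9)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.counts, db.counts)


class TestStudyAssembly:
    def test_nomination_members_and_cap(self, small_study):
        roster_ids = set(small_study.roster["child_id"])
        assert set(small_study.nominations["nominator_id"]) <= roster_ids
        assert set(small_study.nominations["nominee_id"]) <= roster_ids
        assert small_study.nominations.groupby("nominator_id").size().max() <= 4

    def test_study_determinism(self, small_config, small_study):
        again = fn.generate_study(small_config)
        pd.testing.assert_frame_equal(again.roster, small_study.roster)
        pd.testing.assert_frame_equal(again.observed, small_study.observed)
        pd.testing.assert_frame_equal(again.nominations, small_study.nominations)

    def test_write_study_round_trip(self, small_study, tmp_path):
        fn.write_study(small_study, tmp_path)
        roster = pd.read_csv(tmp_path / "roster.csv")
        assert len(roster) == len(small_study.roster)
        assert (tmp_path / "truth.json").exists()
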