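"""Stage-2 abundance forest: fold rule, features, CV, importance, maps."""

import numpy as np
import pandas as pd
import pytest

from occ2abund import abundance as ab


def fold_rule_oracle(n, per_fold=5, max_k=10, min_nonzero=30):
    """Closed-form restatement of the five-nonzero-per-fold rule."""
    if n >= per_fold * max_k:
        return max_k
    if n >= min_nonzero:
        return n // per_fold
    return None


class TestFoldRule:
    @pytest.mark.parametrize("n,expected", [
        (42, 8),     # eightfold CV at 42 nonzero points
        (50, 10),    # the 10-fold cutoff
        (500, 10),
        (30, 6),
        (9, None),   # refused outright
        (29, None),
        (0, None),
    ])
    def test_examples(self, n, expected):
        got = ab.choose_fold_count(n)
        if expected is None:
            assert isinstance(got, ab.FoldRefusal)
            assert got.n_nonzero == n
        else:
            assert got == expected

    def test_exhaustive_agreement_up_to_500(self):
        for n in range(501):
            got = ab.choose_fold_count(n)
            want = fold_rule_oracle(n)
            if want is None:
                assert isinstance(got, ab.FoldRefusal)
            else:
                assert got == want

    def test_smallest_n_reaching_ten_folds_is_fifty(self):
        first = next(n for n in range(501)
                     if ab.choose_fold_count(n) == 10)
        assert first == 50


def make_maps(n_species=3, n=8, seed=0):
    rng = np.random.default_rng(seed)
    occupancy = {f"sp{i + 1:02d}": rng.random((n, n)) for i in range(n_species)}
    cover = {c: rng.random((n, n)) for c in ab.COVER_NAMES}
    return occupancy, cover


class TestAssembleFeatures:
    def test_column_count_and_order_25_species(self):
        occupancy, cover = make_maps(25)
        out = ab.assemble_features(occupancy, cover, "sp07")
        covs = [c for c in out.columns if c != "cell_id"]
        assert len(covs) == 25 + 4          # every species' P plus 4 covers
        assert covs[0] == "P_sp07"          # focal first
        assert covs[-4:] == list(ab.COVER_NAMES)
        assert covs[1:-4] == sorted(covs[1:-4])

    def test_two_species_gives_six_columns(self):
        occupancy, cover = make_maps(2)
        out = ab.assemble_features(occupancy, cover, "sp01")
        assert len(out.columns) - 1 == 6

    def test_nodata_rows_excluded_and_counted(self):
        occupancy, cover = make_maps(2)
        occupancy["sp01"][0, 0] = np.nan
        out = ab.assemble_features(occupancy, cover, "sp01")
        assert out.attrs["n_excluded_nodata"] == 1
        assert len(out) == 63

    def test_missing_focal_map_rejected(self):
        occupancy, cover = make_maps(2)
        with pytest.raises(ValueError, match="sp09"):
            ab.assemble_features(occupancy, cover, "sp09")


def linear_dataset(n_rows=2000, seed=0, noise=0.0):
    """Abundance exactly 10 * focal occupancy (plus optional noise)."""
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame({
        "P_focal": rng.random(n_rows),
        "P_other": rng.random(n_rows),
        "C_A": rng.random(n_rows), "C_W": rng.random(n_rows),
        "C_O": rng.random(n_rows), "C_E": rng.random(n_rows)})
    y = 10.0 * feats["P_focal"].to_numpy()
    if noise:
        y = np.clip(y + rng.normal(0, noise, n_rows), 0, 100)
    return feats, y


class TestFit:
    def test_recovers_deterministic_relationship(self):
        feats, y = linear_dataset()
        model = ab.fit_abundance_rf(feats.iloc[:1500], y[:1500], "focal",
                                    {"n_estimators": 200}, seed=1)
        pred = model.predict(feats.iloc[1500:])
        held_mae = np.mean(np.abs(pred - y[1500:]))
        assert held_mae < 1.0

    def test_all_zero_abundance_predicts_zero(self):
        feats, _ = linear_dataset(200)
        with pytest.warns(UserWarning, match="constant"):
            model = ab.fit_abundance_rf(feats, np.zeros(200), "focal",
                                        {"n_estimators": 20}, seed=1)
        assert (model.predict(feats) == 0).all()

    def test_permuted_labels_destroy_fit(self):
        feats, y = linear_dataset(1200, seed=2)
        rng = np.random.default_rng(3)
        y_perm = rng.permutation(y)
        model = ab.fit_abundance_rf(feats.iloc[:800], y_perm[:800], "focal",
                                    {"n_estimators": 100}, seed=2)
        pred = model.predict(feats.iloc[800:])
        obs = y_perm[800:]
        r2 = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert abs(r2) < 0.15

    def test_predictions_never_exceed_observed_max(self):
        """Tree averaging is interpolative: max(pred) <= max(obs)."""
        feats, y = linear_dataset(500, seed=4, noise=3.0)
        model = ab.fit_abundance_rf(feats, y, "focal", {"n_estimators": 100},
                                    seed=4)
        probe, _ = linear_dataset(500, seed=5)
        assert model.predict(probe).max() <= y.max() + 1e-9

    def test_out_of_range_abundance_rejected(self):
        feats, _ = linear_dataset(50)
        with pytest.raises(ValueError):
            ab.fit_abundance_rf(feats, np.full(50, 101.0), "focal")

    def test_deterministic_under_seed(self):
        feats, y = linear_dataset(300, seed=6, noise=2.0)
        a = ab.fit_abundance_rf(feats, y, "f", {"n_estimators": 50}, seed=9)
        b = ab.fit_abundance_rf(feats, y, "f", {"n_estimators": 50}, seed=9)
        np.testing.assert_array_equal(a.predict(feats), b.predict(feats))


class TestCrossValidate:
    def test_k_below_two_rejected(self):
        feats, y = linear_dataset(100)
        with pytest.raises(ValueError):
            ab.cross_validate(feats, y, k=1)

    def test_leaked_target_gives_near_zero_error(self):
        feats, y = linear_dataset(400, seed=7, noise=2.0)
        feats = feats.copy()
        feats["leak"] = y  # target duplicated as a feature
        report = ab.cross_validate(feats, y, k=5, hyperparameters={
            "n_estimators": 100, "max_features": None}, seed=7)
        assert report.pooled_rmse < 1.0

    def test_rmse_dominates_mae_every_fold(self):
        feats, y = linear_dataset(400, seed=8, noise=4.0)
        report = ab.cross_validate(feats, y, k=5,
                                   hyperparameters={"n_estimators": 50}, seed=8)
        for r, m in zip(report.fold_rmse, report.fold_mae):
            assert r >= m - 1e-12
        assert report.r_squared_caveat

    def test_fold_error_formulas(self):
        """obs [0, 4] against preds [2, 2]: RMSE = MAE = 2."""
        from occ2abund.metrics import mae, rmse
        assert rmse([0.0, 4.0], [2.0, 2.0]) == 2.0
        assert mae([0.0, 4.0], [2.0, 2.0]) == 2.0


class TestImportance:
    def test_sole_driver_ranked_first(self):
        feats, y = linear_dataset(600, seed=9)
        model = ab.fit_abundance_rf(feats, y, "focal", {"n_estimators": 100},
                                    seed=9)
        imp = ab.variable_importance(model, feats, y, seed=9)
        assert imp["covariate"].iloc[0] == "P_focal"

    def test_noise_covariates_near_zero_importance(self):
        feats, y = linear_dataset(600, seed=10)
        model = ab.fit_abundance_rf(feats, y, "focal", {"n_estimators": 100},
                                    seed=10)
        imp = ab.variable_importance(model, feats, y, seed=10).set_index("covariate")
        signal = imp.loc["P_focal", "importance"]
        for noise_cov in ("P_other", "C_A", "C_E"):
            assert imp.loc[noise_cov, "importance"] < 0.05 * signal

    def test_competitor_with_strong_interaction_ranks_high(self):
        """Abundance suppressed by a competitor's occupancy: the competitor's
        map carries real importance."""
        rng = np.random.default_rng(12)
        n = 1500
        feats = pd.DataFrame({
            "P_focal": rng.random(n), "P_comp": rng.random(n),
            "C_A": rng.random(n), "C_W": rng.random(n),
            "C_O": rng.random(n), "C_E": rng.random(n)})
        y = np.clip(20 * feats["P_focal"] * (1 - 0.9 * feats["P_comp"]), 0, 100)
        model = ab.fit_abundance_rf(feats, y.to_numpy(), "focal",
                                    {"n_estimators": 150}, seed=12)
        imp = ab.variable_importance(model, feats, y.to_numpy(), seed=12)
        assert "P_comp" in set(imp["covariate"].iloc[:3])


class TestPredictMap:
    def fit(self):
        occupancy, cover = make_maps(3, n=10, seed=13)
        feats = ab.assemble_features(occupancy, cover, "sp01")
        y = 10 * feats["P_sp01"].to_numpy()
        model = ab.fit_abundance_rf(feats, y, "sp01", {"n_estimators": 50},
                                    seed=13)
        return model, occupancy, cover

    def test_map_nonnegative_and_gridded(self):
        model, occupancy, cover = self.fit()
        out = ab.predict_abundance_map(model, occupancy, cover)
        assert out.shape == (10, 10)
        assert np.nanmin(out) >= 0

    def test_zero_cutoff_coerces_small_predictions(self):
        model, occupancy, cover = self.fit()
        raw = ab.predict_abundance_map(model, occupancy, cover)
        cut = ab.predict_abundance_map(model, occupancy, cover, zero_cutoff=3.0)
        small = raw < 3.0
        assert (cut[small] == 0).all()
        np.testing.assert_array_equal(cut[~small], raw[~small])

    def test_grid_mismatch_rejected(self):
        model, occupancy, cover = self.fit()
        occupancy["sp02"] = occupancy["sp02"][:5, :5]
        with pytest.raises(ValueError, match="mismatch"):
            ab.predict_abundance_map(model, occupancy, cover)

    def test_nodata_propagates(self):
        model, occupancy, cover = self.fit()
        cover["C_A"] = cover["C_A"].copy()
        cover["C_A"][2, 2] = np.nan
        out = ab.predict_abundance_map(model, occupancy, cover)
        assert np.isnan(out[2, 2])
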