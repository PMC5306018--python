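"""Stage-1 SDM machinery: splits, algorithm fits, selection, ensembles."""

import numpy as np
import pandas as pd
import pytest

from occ2abund import sdm
from occ2abund.grids import CovariateStack, GridSpec
from occ2abund.sdm import FittedSDM, ModelScore


def fake_model(roc, tss, name="rf", repeat=0):
    m = FittedSDM(algorithm=name, repeat=repeat, seed=0, pipeline=None,
                  feature_names=[])
    m.score = ModelScore(roc_auc=roc, tss=tss, tss_threshold=0.5)
    return m


class TestSplit:
    def test_sizes_disjoint_exhaustive(self):
        train, test = sdm.split_data(10, 0.7, seed=1)
        assert len(train) == 7 and len(test) == 3
        assert set(train) | set(test) == set(range(10))
        assert set(train) & set(test) == set()

    def test_same_seed_same_partition(self):
        assert (sdm.split_data(50, 0.7, 5)[0] == sdm.split_data(50, 0.7, 5)[0]).all()

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            sdm.split_data(9, 0.7, 0)


def toy_features(n, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 2))
    if separable:
        y = (x[:, 0] > 0).astype(int)
    else:
        y = rng.integers(0, 2, n)
    return pd.DataFrame(x, columns=["env01", "env02"]), y


@pytest.mark.parametrize("name", sdm.ALGORITHM_NAMES)
def test_every_algorithm_separates_separable_data(name):
    feats, y = toy_features(200, seed=1)
    hp = {"rf": {"n_estimators": 50}, "gbm": {"n_estimators": 50}}.get(name)
    model = sdm.fit_algorithm(name, feats, y, hyperparameters=hp, seed=1)
    test_feats, test_y = toy_features(100, seed=2)
    preds = model.predict(test_feats)
    assert preds.min() >= 0 and preds.max() <= 1
    from occ2abund.metrics import roc_auc
    assert roc_auc(preds, test_y) > 0.95


def test_label_noise_gives_chance_auc():
    """Labels independent of covariates: held-out AUC near one half."""
    feats, y = toy_features(1000, seed=3, separable=False)
    model = sdm.fit_algorithm("glm", feats.iloc[:700], y[:700], seed=3)
    from occ2abund.metrics import roc_auc
    auc = roc_auc(model.predict(feats.iloc[700:]), y[700:])
    assert abs(auc - 0.5) < 0.1


def test_single_class_training_rejected():
    feats, _ = toy_features(50)
    with pytest.raises(ValueError, match="single class"):
        sdm.fit_algorithm("glm", feats, np.ones(50, int))


def test_unknown_algorithm_lists_registry():
    feats, y = toy_features(50)
    with pytest.raises(ValueError, match="maxent_like"):
        sdm.fit_algorithm("boosted_llama", feats, y)


class TestSelectModels:
    def test_leading_group_chosen(self):
        """15 clearly stronger models (the RF repeats pattern) beat 75 others."""
        models = [fake_model(0.9 + i * 1e-4, 0.6, "rf") for i in range(15)]
        models += [fake_model(0.8 - (i % 10) * 0.001, 0.5 - (i % 7) * 0.01)
                   for i in range(75)]
        chosen = sdm.select_models(models, gap=0.05, fallback_k=20)
        assert len(chosen) == 15
        assert all(m.score.roc_auc >= 0.9 for m in chosen)

    def test_no_gap_falls_back_to_top_20(self):
        models = [fake_model(0.5 + 0.004 * i, 0.3 + 0.004 * i)
                  for i in range(90)]
        assert len(sdm.select_models(models)) == 20

    def test_fewer_than_fallback_all_selected(self):
        models = [fake_model(0.5 + 0.01 * i, 0.3 + 0.01 * i) for i in range(12)]
        assert len(sdm.select_models(models)) == 12

    def test_gap_must_hold_in_both_metrics(self):
        """A ROC gap alone is not a leading group when TSS overlaps."""
        models = [fake_model(0.95, 0.50) for _ in range(5)]
        models += [fake_model(0.70 - 0.001 * i, 0.49 + 0.001 * i)
                   for i in range(30)]
        chosen = sdm.select_models(models, gap=0.05, fallback_k=20)
        assert len(chosen) == 20

    def test_matches_brute_force_on_random_score_sets(self):
        def brute_force(models, gap, k):
            srt = sorted(models, key=lambda m: -m.score.roc_auc)
            for i in range(1, len(srt)):
                grp, rest = srt[:i], srt[i:]
                if (min(m.score.roc_auc for m in grp)
                        - max(m.score.roc_auc for m in rest) >= gap
                        and min(m.score.tss for m in grp)
                        - max(m.score.tss for m in rest) >= gap):
                    return set(id(m) for m in grp)
            if len(srt) <= k:
                return set(id(m) for m in srt)
            cut = srt[k - 1].score.roc_auc
            return set(id(m) for m in srt if m.score.roc_auc >= cut)

        rng = np.random.default_rng(11)
        for trial in range(50):
            n = int(rng.integers(1, 40))
            models = [fake_model(round(float(rng.uniform(0.5, 1.0)), 2),
                                 round(float(rng.uniform(0.0, 0.9)), 2))
                      for _ in range(n)]
            got = set(id(m) for m in sdm.select_models(models, 0.05, 20))
            assert got == brute_force(models, 0.05, 20)


class _ConstantModel(FittedSDM):
    """Stand-in member predicting a fixed map (committee tests)."""

    def __init__(self, values, roc=0.8):
        super().__init__(algorithm="rf", repeat=0, seed=0, pipeline=None,
                         feature_names=["env01"])
        self.values = np.asarray(values, float)
        self.score = ModelScore(roc, 0.5, 0.5)

    def predict(self, features):
        return self.values


class TestRejectInconsistent:
    features = pd.DataFrame({"env01": np.linspace(0, 1, 64)})

    def test_identical_members_none_rejected(self):
        v = np.linspace(0.1, 0.9, 64)
        members = [_ConstantModel(v) for _ in range(5)]
        kept = sdm.reject_inconsistent(members, self.features, 0.25)
        assert len(kept) == 5

    def test_complement_predictor_rejected(self):
        v = np.tile([0.05, 0.95], 32)
        members = [_ConstantModel(v) for _ in range(4)]
        members.append(_ConstantModel(1 - v))
        kept = sdm.reject_inconsistent(members, self.features, 0.25)
        assert members[-1] not in kept
        assert members[-1].rejected
        assert len(kept) == 4

    def test_survivor_floor_holds_under_adversarial_committee(self):
        """Members scattered far from any consensus: at least 2 survive."""
        rng = np.random.default_rng(13)
        members = [_ConstantModel(rng.integers(0, 2, 64).astype(float))
                   for _ in range(7)]
        kept = sdm.reject_inconsistent(members, self.features,
                                       deviation_threshold=0.01)
        assert len(kept) >= 2


class TestEnsemble:
    def test_equal_roc_is_plain_mean(self):
        members = [_ConstantModel([0.2], roc=0.8), _ConstantModel([0.4], roc=0.8)]
        ens = sdm.build_ensemble(members)
        assert ens.predict(pd.DataFrame({"env01": [0.0]}))[0] == pytest.approx(0.3)

    def test_single_member_identity(self):
        ens = sdm.build_ensemble([_ConstantModel([0.77])])
        assert ens.predict(pd.DataFrame({"env01": [0.0]}))[0] == pytest.approx(0.77)

    def test_roc_weighted_mean_closed_form(self):
        members = [_ConstantModel([1.0], roc=0.8), _ConstantModel([0.0], roc=0.6)]
        ens = sdm.build_ensemble(members)
        assert ens.predict(pd.DataFrame({"env01": [0.0]}))[0] == \
            pytest.approx(0.8 / 1.4)

    def test_weights_normalized(self):
        ens = sdm.build_ensemble([_ConstantModel([0.5], roc=r)
                                  for r in (0.7, 0.8, 0.9)])
        assert ens.weights.sum() == pytest.approx(1.0)
        assert (ens.weights >= 0).all()

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            sdm.build_ensemble([])

    def test_prediction_is_convex_combination(self):
        rng = np.random.default_rng(17)
        maps = [rng.random(64) for _ in range(4)]
        members = [_ConstantModel(m, roc=r)
                   for m, r in zip(maps, (0.6, 0.7, 0.8, 0.9))]
        ens = sdm.build_ensemble(members)
        pred = ens.predict(pd.DataFrame({"env01": np.zeros(64)}))
        stacked = np.stack(maps)
        assert (pred >= stacked.min(axis=0) - 1e-12).all()
        assert (pred <= stacked.max(axis=0) + 1e-12).all()


class TestPredictOccupancy:
    def make_stack(self, with_nan=False):
        grid = GridSpec(nx=6, ny=6)
        stack = CovariateStack(grid)
        rng = np.random.default_rng(19)
        a = rng.standard_normal((6, 6))
        if with_nan:
            a[0, 0] = np.nan
        stack.add_layer("env01", a)
        stack.add_layer("env02", rng.standard_normal((6, 6)))
        return stack

    def fit_ensemble(self):
        feats, y = toy_features(100, seed=5)
        models = []
        for r in range(2):
            m = sdm.fit_algorithm("glm", feats, y, seed=r)
            m.score = ModelScore(0.9, 0.6, 0.5)
            models.append(m)
        return sdm.build_ensemble(models)

    def test_map_in_unit_interval(self):
        ens = self.fit_ensemble()
        out = sdm.predict_occupancy(ens, self.make_stack())
        assert np.nanmin(out) >= 0 and np.nanmax(out) <= 1
        assert out.shape == (6, 6)

    def test_nodata_cells_propagate(self):
        ens = self.fit_ensemble()
        out = sdm.predict_occupancy(ens, self.make_stack(with_nan=True))
        assert np.isnan(out[0, 0])
        assert np.isfinite(out).sum() == 35

    def test_missing_covariate_named_in_error(self):
        ens = self.fit_ensemble()
        grid = GridSpec(nx=6, ny=6)
        stack = CovariateStack(grid)
        stack.add_layer("env01", np.zeros((6, 6)))
        with pytest.raises(ValueError, match="env02"):
            sdm.predict_occupancy(ens, stack)
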