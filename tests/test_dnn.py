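"""Pyramid candidate enumeration, CV selection and tournament."""

import numpy as np
import pandas as pd
import pytest

from ldlkit.dnn import (
    DEFAULT_FEATURES,
    DnnCandidate,
    DnnConfig,
    DnnLdlModel,
    TrainedEstimator,
    crossval_select,
    enumerate_candidates,
    fit_predict,
    tournament_final,
)
from ldlkit.panels import PanelValidationError
from ldlkit.simulate import CohortParams, generate_cohort, split_cohort

FAST = DnnConfig(depth_classes=(2,), node_grid=(10,), k_folds=3, max_epochs=40, final_max_epochs=80)


def _linear_cohort(n=800, seed=0, noise=0.0):
    """Noiseless (or noisy) linear target: ldl = tc - hdl - tg/5."""
    r = np.random.default_rng(seed)
    tc = r.uniform(120, 280, n)
    hdl = r.uniform(30, 80, n)
    tg = r.uniform(30, 350, n)
    y = tc - hdl - tg / 5 + r.normal(0, noise, n)
    return pd.DataFrame({"tc": tc, "hdl": hdl, "tg": tg, "ldl_measured": y})


class TestEnumeration:
    def test_depth2_exhaustive(self):
        cands = enumerate_candidates([2], [10, 20, 30])
        assert [c.widths for c in cands] == [
            (10, 10), (20, 10), (20, 20), (30, 10), (30, 20), (30, 30)
        ]

    @pytest.mark.parametrize("depth,expected", [(2, 6), (4, 15), (6, 28)])
    def test_stars_and_bars_counts(self, depth, expected):
        # multisets of size d over a 3-width grid: C(d+2, d)
        assert len(enumerate_candidates([depth], [10, 20, 30])) == expected

    def test_singleton(self):
        assert [c.widths for c in enumerate_candidates([1], [30])] == [(30,)]

    def test_per_depth_caps(self):
        cands = enumerate_candidates([2, 4, 6], [10, 20, 30], {6: 10, 4: 20, 2: 30})
        by_depth = {}
        for c in cands:
            by_depth.setdefault(c.depth, []).append(c)
        assert len(by_depth[6]) == 1 and by_depth[6][0].widths == (10,) * 6
        assert len(by_depth[4]) == 5  # multisets of {10,20} of size 4
        assert len(by_depth[2]) == 6
        assert all(max(c.widths) <= 20 for c in by_depth[4])

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            enumerate_candidates([2], [])

    def test_pyramid_constraint_enforced(self):
        with pytest.raises(ValueError):
            DnnCandidate((10, 20))
        for c in enumerate_candidates([4], [10, 20, 30]):
            assert all(a >= b for a, b in zip(c.widths, c.widths[1:]))


class TestCrossvalSelect:
    def test_partition_identity(self):
        from sklearn.model_selection import KFold

        n = 1_000
        folds = list(KFold(n_splits=10, shuffle=True, random_state=0).split(np.empty((n, 1))))
        held_out = [te for _, te in folds]
        assert all(len(te) == 100 for te in held_out)
        all_idx = np.sort(np.concatenate(held_out))
        np.testing.assert_array_equal(all_idx, np.arange(n))

    def test_single_candidate_returned_unconditionally(self):
        df = _linear_cohort(300, seed=1, noise=1.0)
        winners, table = crossval_select([DnnCandidate((10, 10))], df, k=3, seed=0, config=FAST)
        assert winners[2][0].widths == (10, 10)
        assert np.isfinite(winners[2][1])

    def test_true_architecture_wins_on_planted_data(self):
        # target generated by a tiny relu network vs a much-too-small rival
        r = np.random.default_rng(5)
        n = 5_000
        df = _linear_cohort(n, seed=5, noise=0.0)
        X = df[["tc", "hdl", "tg"]].to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        W = r.normal(0, 1, (3, 8))
        y = np.maximum(Xs @ W, 0).sum(axis=1) * 10 + 100 + r.normal(0, 1, n)
        df["ldl_measured"] = y
        cfg = DnnConfig(depth_classes=(1, 2), node_grid=(1, 20), k_folds=3, max_epochs=60)
        winners, _ = crossval_select(
            [DnnCandidate((1,)), DnnCandidate((20, 20))], df, k=3, seed=2, config=cfg
        )
        assert winners[2][1] < winners[1][1]  # capacity match has lower cv error

    def test_winner_not_worse_than_same_depth_candidates(self):
        df = _linear_cohort(400, seed=3, noise=2.0)
        cands = enumerate_candidates([2], [5, 10])
        cfg = DnnConfig(depth_classes=(2,), node_grid=(5, 10), k_folds=3, max_epochs=30)
        winners, table = crossval_select(cands, df, k=3, seed=1, config=cfg)
        assert winners[2][1] <= table["cv_mse"].min() + 1e-12


class TestTournament:
    def test_argmin_and_tiebreak(self):
        df = _linear_cohort(400, seed=4, noise=1.0)
        deriv, internal = split_cohort(df, (0.7, 0.3), seed=9)
        finalists = [(DnnCandidate((10, 10)), 2.0), (DnnCandidate((10,)), 2.5)]
        final, table = tournament_final(finalists, deriv, internal, seed=0, config=FAST)
        assert final.candidate.widths == tuple(
            table.loc[table["val_mse"].idxmin(), "widths"]
        )

    def test_identical_finalists_pick_first_by_tiebreak(self):
        df = _linear_cohort(300, seed=6, noise=1.0)
        deriv, internal = split_cohort(df, (0.7, 0.3), seed=9)
        finalists = [(DnnCandidate((10, 10)), 1.0), (DnnCandidate((10, 10)), 1.0)]
        final, table = tournament_final(finalists, deriv, internal, seed=0, config=FAST)
        assert final.candidate.widths == (10, 10)
        assert table["val_mse"].nunique() == 1  # identical refits -> tie broken by order

    def test_empty_validation_is_error(self):
        df = _linear_cohort(100, seed=7)
        with pytest.raises(ValueError):
            tournament_final([(DnnCandidate((10,)), 1.0)], df, df.iloc[:0], config=FAST)


class TestTrainedEstimator:
    def test_capacity_on_noiseless_linear_data(self):
        df = _linear_cohort(2_000, seed=8, noise=0.0)
        cfg = DnnConfig(depth_classes=(2,), node_grid=(30,), k_folds=3,
                        max_epochs=400, final_max_epochs=400, early_stop_patience=40)
        res = DnnLdlModel(df, df, cfg).fit(seed=0)
        pred = res.predict(df)
        assert np.sqrt(np.mean((pred - df["ldl_measured"]) ** 2)) < 1.0

    def test_predict_deterministic_and_rowwise(self):
        df = _linear_cohort(500, seed=9, noise=2.0)
        res = DnnLdlModel(df.iloc[:400], df.iloc[400:], FAST).fit(seed=1)
        p1 = res.predict(df)
        p2 = res.predict(df)
        np.testing.assert_array_equal(p1, p2)
        perm = np.random.default_rng(0).permutation(len(df))
        np.testing.assert_array_equal(res.predict(df.iloc[perm]), p1[perm])

    def test_missing_feature_names_the_field(self):
        df = _linear_cohort(200, seed=10)
        res = DnnLdlModel(df.iloc[:150], df.iloc[150:], FAST).fit(seed=1)
        with pytest.raises(PanelValidationError) as exc:
            fit_predict(res.final, df.drop(columns=["tg"]))
        assert exc.value.field == "tg"

    def test_save_load_predicts_bit_identically(self, tmp_path):
        df = _linear_cohort(300, seed=11, noise=2.0)
        res = DnnLdlModel(df.iloc[:200], df.iloc[200:], FAST).fit(seed=3)
        path = tmp_path / "model.json"
        res.final.save(path)
        back = TrainedEstimator.load(path)
        np.testing.assert_array_equal(back.predict(df), res.predict(df))
        assert back.candidate == res.final.candidate
        assert back.input_features == DEFAULT_FEATURES

    def test_full_search_reproducible_end_to_end(self):
        df = generate_cohort(CohortParams(n=1_500, seed=13))
        deriv, internal = split_cohort(df, (0.7, 0.3), seed=1)
        cfg = DnnConfig(depth_classes=(2,), node_grid=(5, 10), k_folds=3, max_epochs=30)
        r1 = DnnLdlModel(deriv, internal, cfg).fit(seed=21)
        r2 = DnnLdlModel(deriv, internal, cfg).fit(seed=21)
        assert r1.final.candidate == r2.final.candidate
        np.testing.assert_array_equal(r1.predict(internal), r2.predict(internal))
        pd.testing.assert_frame_equal(r1.cv_table, r2.cv_table)
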