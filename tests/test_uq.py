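"""Latent-distance UQ: kNN oracle, cutoff calibration, gated screening."""

import numpy as np
import pandas as pd
import pytest

from irphos.regression import PhosphorPropertyModel
from irphos.uq import (
    CutoffPolicy,
    assess,
    calibrate_cutoff,
    error_vs_cutoff,
    screen,
    uq_distance,
)


def brute_knn_mean(query, train, k):
    d = np.sort(np.linalg.norm(train - query, axis=1))
    return d[:k].mean()


class TestDistance:
    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(11)
        train = rng.normal(size=(100, 6))
        queries = rng.normal(size=(25, 6))
        got = uq_distance(queries, train, k=10)
        expected = [brute_knn_mean(q, train, 10) for q in queries]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_coincident_query_distance_zero(self):
        train = np.zeros((12, 3))
        assert uq_distance(np.zeros((1, 3)), train, k=10)[0] == 0.0

    def test_k_equal_training_size_means_all(self):
        rng = np.random.default_rng(2)
        train = rng.normal(size=(15, 4))
        q = rng.normal(size=(1, 4))
        got = uq_distance(q, train, k=15)[0]
        assert got == pytest.approx(np.linalg.norm(train - q, axis=1).mean())

    def test_too_few_training_points_rejected(self):
        with pytest.raises(ValueError, match="k=10"):
            uq_distance(np.zeros((1, 3)), np.zeros((5, 3)), k=10)


class TestCalibration:
    def test_hand_computed_reference(self):
        cal = calibrate_cutoff([1, 2, 3, 4, 10])
        scaled = np.array([0.1, 0.2, 0.3, 0.4, 1.0])
        assert cal.normalization == 10
        assert cal.cutoff == pytest.approx(
            min(scaled.mean() + 2 * scaled.std(), 1.0)
        )

    def test_equal_distances_give_unit_cutoff(self):
        cal = calibrate_cutoff([3.0, 3.0, 3.0])
        assert cal.cutoff == 1.0

    def test_largest_normalized_reference_is_one(self):
        ref = [0.5, 1.5, 2.5]
        cal = calibrate_cutoff(ref)
        assert max(np.array(ref) / cal.normalization) == 1.0

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_cutoff([0.0, 0.0])

    def test_gate_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 5, size=200)
        cal = calibrate_cutoff(raw)
        accepted_small = {i for i, a in enumerate(assess(raw, cal)) if a.accepted}
        cal.cutoff = cal.cutoff * 1.5
        accepted_large = {i for i, a in enumerate(assess(raw, cal)) if a.accepted}
        assert accepted_small <= accepted_large


def _fitted_ann(n=300, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(-1, 1, size=(n, 5)),
                     columns=[f"f{i}" for i in range(5)])
    y = 2 + X["f0"] - 0.5 * X["f3"] + 0.05 * rng.standard_normal(n)
    return PhosphorPropertyModel(X, y, kind="ann").fit(seed=seed), X, y


class TestErrorVsCutoff:
    def test_full_cutoff_recovers_overall_mae(self):
        res, X, y = _fitted_ann()
        table = error_vs_cutoff(res, X, y)
        last = table.iloc[-1]
        assert last["retained_fraction"] == 1.0
        assert last["mae"] == pytest.approx(res.evaluate(X, y)["mae"])

    def test_retained_fraction_nondecreasing_and_empty_bins_nan(self):
        res, X, y = _fitted_ann()
        table = error_vs_cutoff(res, X, y)
        assert (np.diff(table["retained_fraction"]) >= 0).all()
        assert np.isnan(table.loc[table["retained_fraction"] == 0, "mae"]).all()


class TestScreening:
    def setup_models(self):
        res, X, y = _fitted_ann(seed=4)
        return {"em5050": res}, X

    def test_zero_cutoff_rejects_everything(self):
        models, X = self.setup_models()
        from irphos.uq import UQCalibration

        report = screen(
            X.iloc[:20],
            pd.DataFrame({"cn_id": ["CN1"] * 20, "nn_id": ["NN1"] * 20},
                         index=X.index[:20]),
            models,
            calibrations={"em5050": UQCalibration(normalization=1.0, cutoff=0.0)},
        )
        assert report.accepted_ids == []

    def test_training_rows_accepted(self):
        models, X = self.setup_models()
        report = screen(
            X.iloc[:30],
            pd.DataFrame({"cn_id": ["CN1"] * 30, "nn_id": ["NN1"] * 30},
                         index=X.index[:30]),
            models,
            reference_features=X.iloc[100:200],
        )
        # training points sit deep inside the latent cloud
        assert len(report.accepted_ids) >= 25

    def test_acceptance_independent_of_ordering(self):
        models, X = self.setup_models()
        lig = pd.DataFrame({"cn_id": ["CN1"] * 50, "nn_id": ["NN1"] * 50},
                           index=X.index[:50])
        ref = X.iloc[200:300]
        fwd = screen(X.iloc[:50], lig, models, reference_features=ref)
        rev = screen(X.iloc[:50][::-1], lig[::-1], models, reference_features=ref)
        assert set(fwd.accepted_ids) == set(rev.accepted_ids)

    def test_far_cohort_rejected_more_often(self):
        models, X = self.setup_models()
        rng = np.random.default_rng(9)
        far = pd.DataFrame(rng.uniform(4, 6, size=(40, 5)), columns=X.columns,
                           index=[f"far{i}" for i in range(40)])
        near = X.iloc[:40].set_axis([f"near{i}" for i in range(40)])
        both = pd.concat([near, far])
        lig = pd.DataFrame({"cn_id": ["CN1"] * 80, "nn_id": ["NN1"] * 80},
                           index=both.index)
        report = screen(both, lig, models, reference_features=X.iloc[100:250])
        acc = report.table["accepted"]
        assert acc[:40].mean() > acc[40:].mean()

    def test_extremes_and_ligand_frequencies(self):
        models, X = self.setup_models()
        lig = pd.DataFrame(
            {"cn_id": [f"CN{i % 3}" for i in range(100)],
             "nn_id": [f"NN{i % 2}" for i in range(100)]},
            index=X.index[:100],
        )
        report = screen(
            X.iloc[:100], lig, models, reference_features=X.iloc[150:280],
            extreme_quantile=0.05,
        )
        ext = report.extremes["em5050"]
        assert len(ext["top"]) == len(ext["bottom"]) >= 1
        freq = report.ligand_frequencies["em5050"]
        assert freq.sum() == 2 * (len(ext["top"]) + len(ext["bottom"]))
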