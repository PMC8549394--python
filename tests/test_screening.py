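import numpy as np
import pytest

from mixqspr import screening
from mixqspr.ann_model import FoldEnsemble
from mixqspr.screening import (
    CombinationMatrix,
    enumerate_library,
    read_matrix,
    screen,
    write_matrix,
)


class TestEnumerateLibrary:
    def test_counts(self):
        assert len(enumerate_library(["a", "b", "c"], ["x", "y"])) == 6
        assert len(enumerate_library(["a"], ["x"])) == 1

    def test_row_major_order(self):
        ils = enumerate_library(["a", "b"], ["x", "y"])
        assert [il.il_code for il in ils] == ["a_x", "a_y", "b_x", "b_y"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            enumerate_library([], ["x"])


class TestCombinationMatrix:
    def test_explored_count(self):
        m = CombinationMatrix(["a", "b"], ["x", "y"], np.array([[True, False], [False, False]]))
        assert m.n_explored == 1
        assert len(m.candidates()) == 3

    def test_round_trip(self, tmp_path):
        m = CombinationMatrix(
            ["a", "b", "c"], ["x", "y"], np.array([[1, 0], [0, 1], [0, 0]], dtype=bool)
        )
        p = tmp_path / "combos.txt"
        write_matrix(m, p)
        again = read_matrix(p)
        assert again.cations == m.cations and again.anions == m.anions
        np.testing.assert_array_equal(again.explored, m.explored)

    def test_bad_cell_rejected(self, tmp_path):
        p = tmp_path / "combos.txt"
        p.write_text("\tx\ty\na\tX\tY\n")
        with pytest.raises(ValueError, match="X or O"):
            read_matrix(p)

    def test_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "combos.txt"
        p.write_text("\tx\ty\na\tX\n")
        with pytest.raises(ValueError, match="ragged"):
            read_matrix(p)

    def test_candidate_count_complements_explored(self):
        rng = np.random.default_rng(3)
        grid = rng.random((7, 5)) < 0.3
        m = CombinationMatrix([f"c{i}" for i in range(7)], [f"a{j}" for j in range(5)], grid)
        assert len(m.candidates()) == 35 - m.n_explored


class _StubModel:
    """Predicts a fixed value per feature row, keyed by the cation block sum."""

    def __init__(self, mapping):
        self.mapping = mapping

    def predict(self, x):
        return np.array([self.mapping(row) for row in np.atleast_2d(x)])


def stub_ensemble(mapping, task="regression"):
    return FoldEnsemble(models=[_StubModel(mapping)] * 5, task=task)


class TestScreen:
    @pytest.fixture(scope="class")
    def trained_small(self, small_components, small_dataset, tmp_path_factory):
        """A quickly trained real model over the small synthetic study."""
        from mixqspr.ann_model import HyperParams, TrainingConfig, train_ensemble
        from mixqspr.descriptors import featurize_dataset
        from mixqspr.preprocess import BoundingBoxAD, RangeScaler

        points, truth = small_dataset
        features, kept, _ = featurize_dataset(points, small_components)
        x = features.to_numpy(dtype=float)
        scaler = RangeScaler.fit(x, features.columns)
        ad = BoundingBoxAD.fit(x, features.columns)
        y = np.array([p.log_selectivity for p in kept])
        folds = [(np.arange(len(x)), np.arange(len(x)))] * 5
        ens = train_ensemble(
            scaler.transform(x), y, folds,
            HyperParams("glorot-uniform", 100, 10, "adamax"),
            TrainingConfig(task="regression", epochs=60, seed=2),
        )
        return ens, scaler, ad, truth

    def test_sorted_descending_with_code_tiebreak(self, small_components):
        from mixqspr.preprocess import BoundingBoxAD, RangeScaler
        from mixqspr.descriptors import featurize_dataset
        from mixqspr.chem_io import DataPoint, IonicLiquid

        cations = [c.code for c in small_components if c.role == "cation"]
        anions = [c.code for c in small_components if c.role == "anion"]
        candidates = enumerate_library(cations, anions)
        pts = [
            DataPoint(il, "SOL1", "RAF1", 298.15, 0.0) for il in candidates
        ]
        features, _, _ = featurize_dataset(pts, small_components)
        x = features.to_numpy(dtype=float)
        scaler = RangeScaler.fit(x, features.columns)
        ad = BoundingBoxAD.fit(x, features.columns)
        ens = stub_ensemble(lambda row: 0.5)  # all tied -> order by il_code
        records = screen(
            candidates, "SOL1", "RAF1", 298.15, ens, None, scaler, ad, small_components
        )
        assert [r.il_code for r in records] == sorted(r.il_code for r in records)
        assert all(r.in_ad for r in records)

    def test_ranking_is_permutation_of_candidates(self, small_components):
        from mixqspr.preprocess import BoundingBoxAD, RangeScaler

        cations = [c.code for c in small_components if c.role == "cation"]
        anions = [c.code for c in small_components if c.role == "anion"]
        candidates = enumerate_library(cations, anions)
        scaler = RangeScaler.fit(np.zeros((2, 69)))
        ad = BoundingBoxAD.fit(np.zeros((2, 69)))
        ens = stub_ensemble(lambda row: float(row.sum()))
        fwd = screen(candidates, "SOL1", "RAF1", 298.15, ens, None, scaler, ad, small_components)
        rev = screen(candidates[::-1], "SOL1", "RAF1", 298.15, ens, None, scaler, ad, small_components)
        assert {r.il_code for r in fwd} == {il.il_code for il in candidates}
        assert [r.il_code for r in fwd] == [r.il_code for r in rev]

    def test_out_of_domain_candidate_reported_not_dropped(self, small_components):
        from mixqspr.preprocess import BoundingBoxAD, RangeScaler

        cations = [c.code for c in small_components if c.role == "cation"]
        anions = [c.code for c in small_components if c.role == "anion"]
        candidates = enumerate_library(cations[:2], anions[:2])
        # a narrow non-degenerate box far from any real descriptor values
        train = np.vstack([np.zeros(69), np.full(69, 1e-3)])
        scaler = RangeScaler.fit(train)
        ad = BoundingBoxAD.fit(train)
        ens = stub_ensemble(lambda row: 1.0)
        records = screen(candidates, "SOL1", "RAF1", 298.15, ens, None, scaler, ad, small_components)
        assert len(records) == len(candidates)
        assert all(not r.in_ad for r in records)

    def test_planted_argmax_ranked_first(self, trained_small, small_components):
        ens, scaler, ad, truth = trained_small
        cations = [c.code for c in small_components if c.role == "cation"]
        anions = [c.code for c in small_components if c.role == "anion"]
        candidates = enumerate_library(cations, anions)
        records = screen(
            candidates, "SOL1", "RAF1", 308.15, ens, None, scaler, ad, small_components
        )
        q = truth[
            (truth.solute == "SOL1") & (truth.raffinate == "RAF1") & (truth.temperature_K == 308.15)
        ].copy()
        q["il"] = q.cation + "_" + q.anion
        planted = dict(zip(q.il, q.log10_S_true))
        best_planted = max(planted.values())
        assert planted[records[0].il_code] >= best_planted - 0.3
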