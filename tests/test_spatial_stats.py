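import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialniche import (CellTable, bcc_preset, BCC_CANVAS,
                          community_type_proportions, generate_tissue,
                          kruskal_wallis, nearest_type_distance,
                          summarize_distances)

from conftest import make_random_table


def table_from(rows, vocab):
    frame = pd.DataFrame(rows, columns=["sample_id", "cell_id", "x_px",
                                        "y_px", "cell_type"])
    return CellTable(frame, vocab)


class TestNearestTypeDistance:
    def test_pythagorean_with_calibration(self, abc_vocab):
        cells = table_from([("s", "q", 0.0, 0.0, "A"),
                            ("s", "t", 3.0, 4.0, "B")], abc_vocab)
        out = nearest_type_distance(cells, ["A"], ["B"], px_per_um=2.65)
        assert out["distance_px"].iat[0] == 5.0
        assert out["distance_um"].iat[0] == pytest.approx(5.0 / 2.65)
        assert out["distance_um"].iat[0] == pytest.approx(1.8868, abs=1e-4)

    def test_coincident_distinct_cells(self, abc_vocab):
        cells = table_from([("s", "q", 1.0, 1.0, "A"),
                            ("s", "t", 1.0, 1.0, "B")], abc_vocab)
        out = nearest_type_distance(cells, ["A"], ["B"])
        assert out["distance_px"].iat[0] == 0.0
        assert out["distance_um"].iat[0] == 0.0

    def test_self_excluded_when_query_is_target(self, abc_vocab):
        cells = table_from([("s", "a", 0.0, 0.0, "A"),
                            ("s", "b", 7.0, 0.0, "A")], abc_vocab)
        out = nearest_type_distance(cells, ["A"], ["A"])
        np.testing.assert_array_equal(out["distance_px"], [7.0, 7.0])

    def test_matches_brute_force_oracle(self):
        cells, vocab = make_random_table(300, n_types=3, seed=10)
        out = nearest_type_distance(cells, list(vocab.names),
                                    list(vocab.names), px_per_um=2.65)
        coords = cells.coordinates()
        types = cells.frame["cell_type"].to_numpy()
        for _, row in out.iterrows():
            q = cells.frame.index[cells.frame["cell_id"] == row["cell_id"]][0]
            t_rows = np.flatnonzero((types == row["target_type"])
                                    & (np.arange(len(cells)) != q))
            d = np.sqrt(((coords[t_rows] - coords[q]) ** 2).sum(axis=1))
            assert row["distance_px"] == d.min()

    def test_missing_target_warns_and_emits_nan(self, abc_vocab):
        cells = table_from([("s", "a", 0.0, 0.0, "A")], abc_vocab)
        with pytest.warns(UserWarning, match="no 'B' cells"):
            out = nearest_type_distance(cells, ["A"], ["B"])
        assert out["distance_px"].isna().all()

    def test_per_cell_group_labels(self, abc_vocab):
        cells = table_from([("s", "a", 0.0, 0.0, "A"),
                            ("s", "b", 1.0, 0.0, "A"),
                            ("s", "t", 3.0, 0.0, "B")], abc_vocab)
        groups = np.array(["g1", None, None], dtype=object)
        out = nearest_type_distance(cells, groups, ["B"])
        assert len(out) == 1
        assert out["query_group"].iat[0] == "g1"
        assert out["distance_px"].iat[0] == 3.0

    def test_gamma_validation(self, abc_vocab):
        cells = table_from([("s", "a", 0.0, 0.0, "A")], abc_vocab)
        with pytest.raises(ValueError, match="px_per_um"):
            nearest_type_distance(cells, ["A"], ["A"], px_per_um=0.0)

    def test_px_um_single_division(self):
        cells, vocab = make_random_table(100, n_types=2, seed=3)
        out = nearest_type_distance(cells, [vocab.names[0]],
                                    [vocab.names[1]], px_per_um=2.65)
        np.testing.assert_allclose(out["distance_um"] * 2.65,
                                   out["distance_px"], rtol=1e-12)

    def test_rigid_transform_invariance(self):
        cells, vocab = make_random_table(150, n_types=2, seed=6)
        base = nearest_type_distance(cells, [vocab.names[0]], [vocab.names[1]])
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xy = cells.coordinates() @ rot.T + [1500.0, 1500.0]
        frame = cells.frame.copy()
        frame["x_px"], frame["y_px"] = xy[:, 0], xy[:, 1]
        moved = nearest_type_distance(CellTable(frame, vocab),
                                      [vocab.names[0]], [vocab.names[1]])
        np.testing.assert_allclose(base["distance_px"], moved["distance_px"],
                                   rtol=1e-9)


class TestSummarizeDistances:
    def _table(self, values, group="g", target="B"):
        return pd.DataFrame({
            "sample_id": "s", "cell_id": [f"c{i}" for i in range(len(values))],
            "query_group": group, "target_type": target,
            "distance_px": np.array(values) * 2.65,
            "distance_um": values,
        })

    def test_single_value(self):
        summary, _ = summarize_distances(self._table([4.2]))
        assert summary["mean_um"].iat[0] == 4.2
        assert summary["median_um"].iat[0] == 4.2

    def test_mean_of_three(self):
        summary, density = summarize_distances(self._table([1.0, 2.0, 3.0]),
                                               n_bins=3, max_um=3.0)
        assert summary["mean_um"].iat[0] == 2.0
        assert density["count"].sum() == 3

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_distances(pd.DataFrame(columns=["query_group",
                                                      "target_type",
                                                      "distance_um"]))


class TestCommunityTypeProportions:
    def test_direct_arithmetic(self, abc_vocab):
        cells = table_from([("s", f"c{i}", float(i), 0.0, t)
                            for i, t in enumerate("AABC")], abc_vocab)
        labels = np.array(["x"] * 4)
        out = community_type_proportions(labels, cells, abc_vocab,
                                         focus_types=["A", "B"])
        assert out.loc[("s", "x"), "A"] == 50.0
        assert out.loc[("s", "x"), "B"] == 25.0

    def test_absent_focus_type_is_zero(self, abc_vocab):
        cells = table_from([("s", "c0", 0.0, 0.0, "A")], abc_vocab)
        out = community_type_proportions(np.array(["x"]), cells, abc_vocab)
        assert out.loc[("s", "x"), "B"] == 0.0

    def test_full_vocabulary_sums_to_100(self):
        cells, vocab = make_random_table(120, n_types=4, seed=5, n_samples=2)
        labels = np.random.default_rng(0).choice(["u", "v", "w"], 120)
        out = community_type_proportions(labels, cells, vocab)
        np.testing.assert_allclose(out.sum(axis=1), 100.0, atol=1e-6)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        # no location difference; identical ranks in both groups
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_values_identical(self):
        h, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_hand_computed_three_groups(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(scipy.stats.chi2.sf(7.2, df=2), rel=1e-12)
        assert p == pytest.approx(0.0273, abs=1e-4)

    def test_tie_correction(self):
        # with ties, H must be divided by 1 - sum(t^3 - t)/(N^3 - N)
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0, 4.0]]
        h, _ = kruskal_wallis(groups)
        ref_h, _ = scipy.stats.kruskal(*groups)
        assert h == pytest.approx(ref_h)

    def test_validation(self):
        with pytest.raises(ValueError, match="two groups"):
            kruskal_wallis([[1, 2]])
        with pytest.raises(ValueError, match="non-empty"):
            kruskal_wallis([[1], []])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=rng.integers(3, 10)) for _ in range(3)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestPlantedGeometryDistances:
    def test_bit_nearer_macrophages_than_bst(self):
        cells, truth = generate_tissue(bcc_preset(), BCC_CANVAS, seed=4)
        out = nearest_type_distance(cells, ["BIT", "BST"], ["Macrophage"])
        summary, _ = summarize_distances(out)
        means = summary.set_index("query_group")["mean_um"]
        assert means["BIT"] < means["BST"]
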