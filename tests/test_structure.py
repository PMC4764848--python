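"""Metabolic distance, clustering, PCA grouping, distance-trait correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from hybridmet import (
    DistanceMatrix,
    Panel,
    ParentLine,
    average_linkage_cluster,
    cut_two_groups,
    distance_trait_correlation,
    enumerate_diallel,
    pca_grouping,
    squared_euclidean_distance,
)


class TestDistance:
    def test_pythagorean_toy(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        d = squared_euclidean_distance(m)
        assert d.between("a", "b") == 25.0
        assert d.between("a", "a") == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.uniform(-2, 2, size=(3, 2)), index=list("abc"))
        d = squared_euclidean_distance(m)
        for i in m.index:
            for j in m.index:
                manual = float(((m.loc[i] - m.loc[j]) ** 2).sum())
                assert d.between(i, j) == pytest.approx(manual, abs=1e-12)

    def test_invariants(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(6, 4)))
        arr = squared_euclidean_distance(m).values.to_numpy()
        assert (arr >= 0).all()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 0.0)


def _dist(frame):
    return DistanceMatrix(values=frame)


class TestClustering:
    def test_hand_worked_merge_sequence(self):
        d = pd.DataFrame([[0, 1, 10], [1, 0, 10], [10, 10, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        merges = average_linkage_cluster(_dist(d))
        assert merges.iloc[0][["left", "right", "height"]].tolist() == ["a", "b", 1.0]
        assert merges.iloc[1]["height"] == 10.0  # average of d(a,c)=d(b,c)=10

    def test_two_points(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        merges = average_linkage_cluster(_dist(d))
        assert len(merges) == 1 and merges.iloc[0]["height"] == 3.0

    def test_equidistant_tie_breaks_lexicographically(self):
        d = pd.DataFrame(5.0 * (1 - np.eye(3)), index=list("cab"), columns=list("cab"))
        merges = average_linkage_cluster(_dist(d))
        assert sorted(merges.iloc[0][["left", "right"]]) == ["a", "b"]

    def test_matches_scipy_on_random_fixture(self):
        """Merge heights agree with scipy's average linkage (tie-free input)."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 3))
        frame = pd.DataFrame(
            ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1),
            index=list("abcdefgh"), columns=list("abcdefgh"))
        merges = average_linkage_cluster(_dist(frame))
        from scipy.spatial.distance import squareform
        Z = linkage(squareform(frame.to_numpy(), checks=False), method="average")
        np.testing.assert_allclose(np.sort(merges["height"].to_numpy()),
                                   np.sort(Z[:, 2]), rtol=1e-10)

    def test_heights_non_decreasing(self, small_study):
        d = squared_euclidean_distance(small_study.log2)
        merges = average_linkage_cluster(d)
        h = merges["height"].to_numpy()
        assert (np.diff(h) >= -1e-9).all()

    def test_recovers_subspecies_groups(self, full_study):
        """At full analyte count the dendrogram splits indica from japonica."""
        d = squared_euclidean_distance(full_study.log2)
        memb = cut_two_groups(average_linkage_cluster(d), list(d.values.index))
        groups = {p.id: p.group for p in full_study.panel}
        split = {}
        for pid, side in memb.items():
            split.setdefault(side, set()).add(groups[pid])
        assert all(len(s) == 1 for s in split.values())


class TestPCA:
    def test_trace_conservation(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        _, eigval, _ = pca_grouping(m)
        assert eigval.sum() == pytest.approx(4.0)

    def test_rank_one_two_columns(self):
        x = np.arange(6, dtype=float)
        m = pd.DataFrame({"a": x, "b": 2 * x + 1})
        scores, eigval, kept = pca_grouping(m)
        np.testing.assert_allclose(eigval, [2.0, 0.0], atol=1e-12)
        assert kept == 1

    def test_eigsolver_oracle(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(6, 4)))
        _, eigval, _ = pca_grouping(m)
        z = (m - m.mean()) / m.std(ddof=1)
        ref = np.sort(np.linalg.eigvalsh(np.corrcoef(z.to_numpy().T)))[::-1]
        np.testing.assert_allclose(eigval, ref, atol=1e-10)

    def test_scores_centered(self, small_study):
        scores, _, _ = pca_grouping(small_study.log2)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame({"a": rng.normal(size=5), "b": rng.normal(size=5),
                          "c": np.ones(5)})
        with pytest.warns(UserWarning, match="zero-variance"):
            _, eigval, _ = pca_grouping(m)
        assert len(eigval) == 2


class TestDistanceTraitCorrelation:
    def _setup(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        panel = Panel([ParentLine(f"P{i}", "indica") for i in range(n)])
        cross = enumerate_diallel(panel)
        m = pd.DataFrame(rng.normal(size=(n, 4)), index=panel.ids)
        return panel, cross, squared_euclidean_distance(m)

    def test_response_equal_to_distance(self):
        _, cross, d = self._setup()
        resp = pd.DataFrame(
            {"y": [d.between(f, m) for f, m in cross.hybrids]}, index=cross.hybrid_ids)
        table = distance_trait_correlation(d, resp, cross)
        assert table.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_response_uncorrelated(self):
        panel, cross, d = self._setup(n=18, seed=1)
        rng = np.random.default_rng(2)
        resp = pd.DataFrame({"y": rng.normal(size=len(cross))}, index=cross.hybrid_ids)
        table = distance_trait_correlation(d, resp, cross)
        assert abs(table.iloc[0]["r"]) < 0.15
        assert table.iloc[0]["p_value"] > 0.05

    def test_constant_response_flagged(self):
        _, cross, d = self._setup()
        resp = pd.DataFrame({"y": np.ones(len(cross))}, index=cross.hybrid_ids)
        table = distance_trait_correlation(d, resp, cross)
        assert np.isnan(table.iloc[0]["r"])
        assert "undefined" in table.iloc[0]["note"]
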