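"""PCA, MANOVA, CVA and UPGMA against direct oracles."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from pitmorph.morphospace import (
    cva,
    manova,
    model_comparison_report,
    pca,
    truncate_scores,
    upgma,
)
from pitmorph.superimposition import full_gpa
from pitmorph.synthetic import ObserverStudyConfig, generate_observer_study
from pitmorph.types import DistanceMatrix

from conftest import make_config


class TestPCA:
    def test_identical_individuals_degenerate(self, rng):
        x = np.tile(rng.normal(size=12), (5, 1))
        res = pca(x)
        assert res.degenerate and res.dimensionality == 0
        assert res.proportion_variance.sum() == 0.0

    def test_planar_data_has_two_components(self, rng):
        basis = rng.normal(size=(2, 9))
        x = rng.normal(size=(20, 2)) @ basis
        res = pca(x)
        assert res.proportion_variance[:2].sum() == pytest.approx(1.0, abs=1e-9)
        assert res.dimensionality == 2

    def test_matches_covariance_eigendecomposition(self, rng):
        x = rng.normal(size=(10, 6))
        res = pca(x)
        eig = np.sort(np.linalg.eigvalsh(np.cov(x, rowvar=False)))[::-1]
        np.testing.assert_allclose(res.eigenvalues[: len(eig)], eig, atol=1e-10)
        np.testing.assert_allclose(
            res.proportion_variance[: len(eig)], eig / eig.sum(), atol=1e-10
        )

    def test_scores_covariance_is_diagonal(self, small_study):
        res = pca(full_gpa(small_study.configurations))
        k = res.dimensionality
        cov = np.cov(res.scores[:, :k], rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-9 * np.max(np.diag(cov))

    def test_proportions_sorted_and_sum_to_one(self, small_study):
        res = pca(full_gpa(small_study.configurations))
        p = res.proportion_variance
        assert np.all(np.diff(p) <= 1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_individuals(self, rng):
        with pytest.raises(ValueError):
            pca(rng.normal(size=(2, 6)))


class TestManova:
    def test_separated_groups_significant(self, rng):
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3)) + 10.0
        res = manova(np.vstack([a, b]), ["a"] * 20 + ["b"] * 20)
        assert res.p < 0.01

    def test_null_calibration(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(40, 3))
            res = manova(x, ["a"] * 20 + ["b"] * 20)
            rejections += res.p < 0.05
        assert rejections <= 10  # ~alpha of 100 null runs

    def test_statistic_selection_rule(self, rng):
        gaussian = rng.normal(size=(60, 4))
        res = manova(gaussian, ["a", "b"] * 30)
        assert res.statistic_name == "Hotelling-Lawley" and res.scores_normal
        skewed = rng.lognormal(0, 1.5, size=(60, 4))
        res = manova(skewed, ["a", "b"] * 30)
        assert res.statistic_name == "Wilks" and not res.scores_normal

    def test_too_many_columns_rejected(self, rng):
        with pytest.raises(ValueError, match="truncate"):
            manova(rng.normal(size=(10, 9)), ["a"] * 5 + ["b"] * 5)


class TestCVA:
    def test_identical_groups(self, rng):
        x = np.tile(rng.normal(size=(1, 4)), (20, 1))
        res = cva(x, ["a", "b"] * 10, n_permutations=99, rng=0)
        assert res.mahalanobis_D == pytest.approx(0.0, abs=1e-9)
        assert res.p_mahalanobis == pytest.approx(1.0)

    def test_add_one_lower_bound(self, rng):
        x = np.vstack([rng.normal(size=(15, 3)), rng.normal(size=(15, 3)) + 50.0])
        res = cva(x, ["a"] * 15 + ["b"] * 15, n_permutations=999, rng=1)
        assert res.p_mahalanobis == pytest.approx(1.0 / 1000.0)
        assert res.p_procrustes == pytest.approx(1.0 / 1000.0)

    def test_permutation_count_validation(self, rng):
        with pytest.raises(ValueError):
            cva(rng.normal(size=(10, 2)), ["a", "b"] * 5, n_permutations=0)

    def test_two_groups_required(self, rng):
        with pytest.raises(ValueError):
            cva(rng.normal(size=(9, 2)), ["a", "b", "c"] * 3)


def upgma_oracle(d):
    """Naive average linkage recomputing means from the original matrix."""
    n = d.shape[0]
    clusters = [(i,) for i in range(n)]
    heights = {}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                lo, hi = sorted((min(clusters[i]), min(clusters[j])))
                key = (avg, lo, hi)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (avg, _, _), i, j = best
        merged = clusters[i] + clusters[j]
        heights[frozenset(f"L{k}" for k in merged)] = avg / 2.0
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


class TestUPGMA:
    def test_pair_merges_at_half_distance(self):
        tree = upgma(DistanceMatrix(("A", "B"), np.array([[0.0, 3.0], [3.0, 0.0]])))
        assert tree.root.height == pytest.approx(1.5)

    def test_four_item_worked_example(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 2.0
        d[2, 3] = d[3, 2] = 4.0
        tree = upgma(DistanceMatrix(("A", "B", "C", "D"), d))
        depth = tree.cophenetic_depth()
        assert depth[frozenset(("A", "B"))] == pytest.approx(1.0)
        assert depth[frozenset(("C", "D"))] == pytest.approx(2.0)
        assert depth[frozenset(("A", "C"))] == pytest.approx(5.0)

    def test_matches_average_linkage_oracle_up_to_six_leaves(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            n = int(rng.integers(3, 7))
            m = rng.uniform(0.5, 3.0, size=(n, n))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 0.0)
            labels = tuple(f"L{i}" for i in range(n))
            tree = upgma(DistanceMatrix(labels, m))
            got = tree.cophenetic_depth()
            expected = upgma_oracle(m)
            # compare merge heights of every cluster the oracle formed
            got_heights = sorted(round(v, 9) for v in got.values())
            exp_pairwise = sorted(
                round(min(h for s, h in expected.items() if {a, b} <= set(s)), 9)
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            )
            assert got_heights == exp_pairwise

    def test_matches_scipy_cophenetic_depths(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0.5, 3.0, size=(8, 8))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        labels = tuple(f"L{i}" for i in range(8))
        tree = upgma(DistanceMatrix(labels, m))
        depth = tree.cophenetic_depth()
        coph = squareform(cophenet(scipy_average(squareform(m))))
        for i in range(8):
            for j in range(i + 1, 8):
                assert depth[frozenset((f"L{i}", f"L{j}"))] == pytest.approx(
                    coph[i, j] / 2.0, rel=1e-9
                )

    def test_constant_shift_preserves_topology(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = rng.uniform(0.5, 3.0, size=(6, 6))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 0.0)
            labels = tuple("ABCDEF")
            t1 = upgma(DistanceMatrix(labels, m))
            shifted = m + 1.7
            np.fill_diagonal(shifted, 0.0)
            t2 = upgma(DistanceMatrix(labels, shifted))

            def topology(node):
                if node.is_leaf:
                    return node.label
                return frozenset(topology(c) for c in node.children)

            assert topology(t1.root) == topology(t2.root)

    def test_nan_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(("A", "B"), m))


class TestModelComparison:
    @pytest.fixture(scope="class")
    def report(self):
        datasets = {
            scheme: generate_observer_study(
                ObserverStudyConfig(n_pits_per_carnivore=10, landmark_scheme=scheme, seed=17)
            )
            for scheme in ("LM17", "hybrid30")
        }
        return model_comparison_report(datasets, n_permutations=99, seed=17)

    def test_cumulative_percentages_monotone(self, report):
        assert (report["pc1_2_pct"] <= report["pc1_10_pct"] + 1e-9).all()
        assert (report["pc1_10_pct"] <= 100.0 + 1e-9).all()

    def test_hybrid_concentrates_more_variance(self, report):
        by = report.set_index(["scheme", "space"])
        assert (
            by.loc[("hybrid30", "shape"), "pc1_10_pct"]
            > by.loc[("LM17", "shape"), "pc1_10_pct"]
        )

    def test_missing_scheme_skipped(self):
        ds = generate_observer_study(
            ObserverStudyConfig(n_pits_per_carnivore=5, seed=3)
        )
        report = model_comparison_report(
            {"LM17": ds, "LM5": None}, spaces=("shape",), n_permutations=19
        )
        assert set(report["scheme"]) == {"LM17"}


def test_truncate_scores_caps_columns(rng):
    x = rng.normal(size=(12, 40))
    res = pca(x)
    labels = ["a"] * 6 + ["b"] * 6
    scores = truncate_scores(res, labels)
    assert scores.shape[1] <= 12 - 2 - 1
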