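"""Raw, centroid-deviation and Procrustes-based observer error measures."""

import numpy as np
import pytest

from pitmorph.error_analysis import (
    centroid_deviation_errors,
    centroid_deviation_vectors,
    error_summary,
    kruskal_wallis_matrix,
    per_landmark_summary,
    procrustes_distances_to_reference,
    raw_pairwise_errors,
    repeatability_measures,
)
from pitmorph.superimposition import full_gpa
from pitmorph.synthetic import (
    AnalystProfile,
    ObserverStudyConfig,
    default_analysts,
    generate_observer_study,
)
from pitmorph.types import SCHEME_LM17, ObserverDataset

from conftest import make_config


def two_analyst_dataset(rng, offset=(0.3, 0.0, 0.0)):
    coords = rng.normal(size=(17, 3))
    a = make_config(coords, pit_id="P1", analyst_id="A1", carnivore_label="wolf")
    b = a.replace(analyst_id="A2", coords=coords + np.asarray(offset))
    return ObserverDataset(configurations=[a, b])


class TestRawErrors:
    def test_identical_analysts_zero(self, rng):
        ds = two_analyst_dataset(rng, offset=(0, 0, 0))
        errors = raw_pairwise_errors(ds)
        assert (errors["error_mm"] == 0).all()

    def test_translation_construction(self, rng):
        errors = raw_pairwise_errors(two_analyst_dataset(rng))
        assert errors["error_mm"].to_numpy() == pytest.approx(np.full(17, 0.3))

    def test_rigid_motion_of_whole_pit_is_invisible(self, rng):
        """Moving every analyst's copy of a pit jointly leaves errors unchanged."""
        ds = two_analyst_dataset(rng)
        before = raw_pairwise_errors(ds)["error_mm"].to_numpy()
        shift = np.array([5.0, -2.0, 1.0])
        moved = ObserverDataset(
            configurations=[c.replace(coords=c.coords + shift) for c in ds.configurations]
        )
        after = raw_pairwise_errors(moved)["error_mm"].to_numpy()
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_noise_scale_recovery_against_truth(self):
        """Median displacement from the generator truth recovers the
        configured per-landmark scales (analyst factors divided out)."""
        ds = generate_observer_study(ObserverStudyConfig(seed=33))
        profiles = {p.analyst_id: p for p in default_analysts()}
        for lab in ("LM1", "LM5", "LM14"):
            ratios = []
            for cfg in ds.configurations:
                truth = ds.true_configurations[cfg.pit_id]
                d = np.linalg.norm(cfg.position(lab) - truth.position(lab))
                ratios.append(d / profiles[cfg.analyst_id].per_landmark_noise_scale[lab])
            assert np.median(ratios) == pytest.approx(1.0, abs=0.15)


class TestCentroidDeviation:
    def test_coincident_points_zero(self, rng):
        ds = two_analyst_dataset(rng, offset=(0, 0, 0))
        errors = centroid_deviation_errors(ds)
        assert (errors["error_mm"] == 0).all()

    def test_two_analysts_split_the_midpoint(self, rng):
        errors = centroid_deviation_errors(two_analyst_dataset(rng, offset=(1.0, 0, 0)))
        assert errors["error_mm"].to_numpy() == pytest.approx(np.full(34, 0.5))

    def test_per_landmark_summary_columns(self, small_study):
        table = per_landmark_summary(centroid_deviation_errors(small_study))
        assert list(table.columns) == ["median", "nmad", "sqrt_bwmv", "n"]
        assert set(table.index) == set(SCHEME_LM17)


class TestErrorSummary:
    def test_single_value_cell(self, rng):
        ds = two_analyst_dataset(rng)
        errors = raw_pairwise_errors(ds)
        one = errors[errors["landmark"] == "LM1"]
        table = error_summary(one, subsets={"LM1": ("LM1",)}, strata=("Absolute",))
        row = table.loc[("LM1", "Absolute")]
        assert row["min"] == row["median"] == row["max"]
        assert row["nmad"] == 0.0

    def test_subset_filtering(self, small_study):
        errors = raw_pairwise_errors(small_study)
        table = error_summary(errors)
        n5 = table.loc[("LM1-5", "Absolute"), "n"]
        n17 = table.loc[("LM1-17", "Absolute"), "n"]
        assert n5 == n17 * 5 / 17

    def test_removing_noisy_landmarks_reduces_error(self):
        """With LM14-17 scales dominant, the LM1-13 median sits below LM1-17."""
        scales = {lab: (0.6 if lab in ("LM14", "LM15", "LM16", "LM17") else 0.1)
                  for lab in SCHEME_LM17}
        analysts = tuple(
            AnalystProfile(f"A{r}", r, scales) for r in (1, 2, 3)
        )
        ds = generate_observer_study(
            ObserverStudyConfig(n_pits_per_carnivore=10, analysts=analysts, seed=5)
        )
        table = error_summary(raw_pairwise_errors(ds))
        assert (
            table.loc[("LM1-13", "Absolute"), "median"]
            < table.loc[("LM1-17", "Absolute"), "median"]
        )

    def test_empty_collection_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            error_summary(pd.DataFrame(columns=["landmark", "error_mm"]))


class TestRepeatability:
    def test_identical_distances_give_equal_shares(self):
        import pandas as pd

        rows = [
            {"pit_id": f"P{i}", "analyst_id": a, "carnivore_label": "wolf", "distance": d}
            for a in ("A1", "A2", "A3")
            for i, d in enumerate([0.1, 0.2, 0.3])
        ]
        rm = repeatability_measures(pd.DataFrame(rows))
        for v in rm.values():
            assert v == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_shares_sum_to_one(self, small_study):
        ens = full_gpa(small_study.configurations)
        rm = repeatability_measures(procrustes_distances_to_reference(ens))
        assert sum(rm.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= v <= 1.0 for v in rm.values())

    def test_unbalanced_design_refused(self):
        import pandas as pd

        rows = [
            {"pit_id": "P1", "analyst_id": "A1", "carnivore_label": None, "distance": 0.1},
            {"pit_id": "P2", "analyst_id": "A1", "carnivore_label": None, "distance": 0.2},
            {"pit_id": "P1", "analyst_id": "A2", "carnivore_label": None, "distance": 0.1},
        ]
        with pytest.raises(ValueError, match="balanced"):
            repeatability_measures(pd.DataFrame(rows))

    def test_all_zero_distances_refused(self):
        import pandas as pd

        rows = [
            {"pit_id": "P1", "analyst_id": a, "carnivore_label": None, "distance": 0.0}
            for a in ("A1", "A2")
        ]
        with pytest.raises(ValueError, match="zero"):
            repeatability_measures(pd.DataFrame(rows))

    def test_noisiest_analyst_has_largest_share(self):
        base = default_analysts()
        analysts = tuple(
            p.scaled({1: 2.0, 2: 1.5, 3: 1.0}[p.experience_rank] /
                     {1: 1.3, 2: 1.15, 3: 1.0}[p.experience_rank])
            for p in base
        )
        ds = generate_observer_study(
            ObserverStudyConfig(n_pits_per_carnivore=15, analysts=analysts, seed=8)
        )
        ens = full_gpa(ds.configurations)
        rm = repeatability_measures(procrustes_distances_to_reference(ens))
        assert max(rm, key=rm.get) == "A1"


class TestCentroidDeviationVectors:
    def test_single_analyst_vectors_vanish(self, rng):
        configs = [
            make_config(rng.normal(size=(5, 3)), pit_id=f"P{i}", analyst_id="A1")
            for i in range(4)
        ]
        ens = full_gpa(configs)
        vectors = centroid_deviation_vectors(ens)
        np.testing.assert_allclose(vectors["A1"], 0.0, atol=1e-12)

    def test_weighted_sum_is_zero(self, small_study):
        ens = full_gpa(small_study.configurations)
        vectors = centroid_deviation_vectors(ens)
        counts = {
            a: sum(c.analyst_id == a for c in ens.configurations) for a in vectors
        }
        total = sum(counts[a] * vectors[a] for a in vectors)
        np.testing.assert_allclose(total, 0.0, atol=1e-10)

    def test_systematic_bias_shows_at_the_biased_landmark(self):
        analysts = tuple(
            AnalystProfile(f"A{r}", r, {lab: 0.02 for lab in SCHEME_LM17})
            for r in (1, 2, 3)
        )
        ds = generate_observer_study(
            ObserverStudyConfig(n_pits_per_carnivore=10, analysts=analysts, seed=3)
        )
        idx = SCHEME_LM17.index("LM14")
        biased = []
        for c in ds.configurations:
            if c.analyst_id == "A1":
                coords = c.coords.copy()
                coords[idx] += [0.4, 0.0, 0.0]
                c = c.replace(coords=coords)
            biased.append(c)
        ens = full_gpa(biased)
        vectors = centroid_deviation_vectors(ens)
        magnitudes = np.linalg.norm(vectors["A1"], axis=1)
        assert np.argmax(magnitudes) == idx


def test_kruskal_wallis_matrix_shape(small_study):
    ens = full_gpa(small_study.configurations)
    distances = procrustes_distances_to_reference(ens)
    table = kruskal_wallis_matrix(distances)
    assert len(table) == 3  # A1-A2, A1-A3, A2-A3
    assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
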