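"""Proportional similarity index, Levins' breadth, generalist/specialist
classification and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rarebio.containers import CoverageMatrix, SampleInfo
from rarebio.niche import (
    NicheClassifier,
    classify_niche,
    levins_breadth,
    ps_index,
    ps_null_test,
)

CAT3 = {"s1": "winter", "s2": "spring", "s3": "summer"}
EQUAL_Q = pd.Series({"s1": 0.1, "s2": 0.1, "s3": 0.1})


class TestPsIndex:
    def test_matching_distributions_score_one(self):
        mag = pd.Series({"s1": 0.004, "s2": 0.004, "s3": 0.004})
        assert ps_index(mag, CAT3, "cells", EQUAL_Q) == pytest.approx(1.0)

    def test_confinement_to_one_of_three_equal_categories(self):
        mag = pd.Series({"s1": 0.004, "s2": 0.0, "s3": 0.0})
        assert ps_index(mag, CAT3, "cells", EQUAL_Q) == pytest.approx(1 / 3)

    def test_printed_formula_hand_case(self):
        # p = (0.5, 0.5, 0), q = (0.25, 0.25, 0.5): sum|p-q| = 1, PS = 0.5
        mag = pd.Series({"s1": 0.02, "s2": 0.02, "s3": 0.0})
        community = pd.Series({"s1": 0.1, "s2": 0.1, "s3": 0.2})
        assert ps_index(mag, CAT3, "cells", community) == pytest.approx(0.5)

    def test_samples_basis_uses_sampling_effort(self):
        cats = {"s1": "winter", "s2": "winter", "s3": "spring", "s4": "spring"}
        mag = pd.Series({"s1": 0.01, "s2": 0.01, "s3": 0.0, "s4": 0.0})
        # p = (1, 0), q = (0.5, 0.5) -> PS = 0.5
        assert ps_index(mag, cats, "samples") == pytest.approx(0.5)

    def test_absent_population_rejected(self):
        mag = pd.Series({"s1": 0.0, "s2": 0.0, "s3": 0.0})
        with pytest.raises(ValueError, match="PS undefined"):
            ps_index(mag, CAT3, "cells", EQUAL_Q)

    def test_zero_availability_category_rejected(self):
        mag = pd.Series({"s1": 0.01, "s2": 0.0, "s3": 0.0})
        community = pd.Series({"s1": 0.1, "s2": 0.1, "s3": 0.0})
        with pytest.raises(ValueError, match="zero community abundance"):
            ps_index(mag, CAT3, "cells", community)

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3).filter(
            lambda v: sum(v) > 1e-6
        ),
        st.lists(st.floats(1e-3, 1.0), min_size=3, max_size=3),
    )
    def test_bounds_and_rescaling_invariance(self, mag_vals, community_vals):
        mag = pd.Series(dict(zip(["s1", "s2", "s3"], mag_vals)))
        community = pd.Series(dict(zip(["s1", "s2", "s3"], community_vals)))
        value = ps_index(mag, CAT3, "cells", community)
        assert 0.0 <= value <= 1.0 + 1e-12
        scaled = ps_index(mag * 7.3, CAT3, "cells", community)
        assert scaled == pytest.approx(value)


class TestLevins:
    def test_uniform_is_maximal(self):
        b, b_std = levins_breadth([0.25, 0.25, 0.25, 0.25])
        assert b == pytest.approx(4.0)
        assert b_std == pytest.approx(1.0)

    def test_hand_case(self):
        b, b_std = levins_breadth([0.8, 0.2])
        assert b == pytest.approx(1 / 0.68)
        assert b_std == pytest.approx((1 / 0.68 - 1) / 1)

    def test_confined_is_minimal(self):
        b, b_std = levins_breadth([0.0, 0.0, 1.0])
        assert b == pytest.approx(1.0)
        assert b_std == pytest.approx(0.0)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            levins_breadth([1.0])

    def test_bounds_on_generated_profiles(self, default_dataset):
        profiles = classify_niche(default_dataset["matrix"], default_dataset["samples"])
        usable = profiles.dropna(subset=["levins_b"])
        assert ((usable["levins_b"] >= 1 - 1e-9) & (usable["levins_b"] <= 3 + 1e-9)).all()
        assert ((usable["levins_b_std"] >= -1e-9) & (usable["levins_b_std"] <= 1 + 1e-9)).all()


def _matrix_from_rel(rel: pd.DataFrame) -> CoverageMatrix:
    breadth = rel.where(rel <= 0, 0.95).where(rel > 0, 0.0)
    return CoverageMatrix(rel * 1000, breadth, rel)


def _samples_for(columns, season_of, year=2011):
    import datetime

    return [
        SampleInfo(c, datetime.date(year, 6, 1), season_of[c],
                   f"{season_of[c]}_{year}", 2302.6)
        for c in columns
    ]


class TestClassifyNiche:
    def test_three_mag_terciles(self):
        # planted PS ordering: m_gen tracks availability, m_spec confined,
        # m_mid in between
        rel = pd.DataFrame(
            {
                "s1": [0.01, 0.004, 0.012],
                "s2": [0.01, 0.002, 0.0001],
                "s3": [0.01, 0.02, 0.0001],
            },
            index=["m_gen", "m_mid", "m_spec"],
        )
        samples = _samples_for(rel.columns, CAT3)
        profiles = classify_niche(_matrix_from_rel(rel), samples).set_index("mag_id")
        assert profiles.loc["m_gen", "label"] == "generalist"
        assert profiles.loc["m_mid", "label"] == "intermediate"
        assert profiles.loc["m_spec", "label"].endswith("specialist")

    def test_single_sample_mag_excluded(self):
        rel = pd.DataFrame(
            {
                "s1": [0.01, 0.004, 0.012, 0.03],
                "s2": [0.01, 0.002, 0.0001, 0.0],
                "s3": [0.01, 0.02, 0.0001, 0.0],
            },
            index=["m1", "m2", "m3", "m_once"],
        )
        samples = _samples_for(rel.columns, CAT3)
        profiles = classify_niche(_matrix_from_rel(rel), samples).set_index("mag_id")
        assert profiles.loc["m_once", "label"] == "excluded"
        assert profiles.loc["m_once", "n_samples_detected"] == 1

    def test_too_few_classifiable_rejected(self):
        rel = pd.DataFrame(
            {"s1": [0.01, 0.02], "s2": [0.01, 0.02], "s3": [0.01, 0.02]},
            index=["m1", "m2"],
        )
        samples = _samples_for(rel.columns, CAT3)
        with pytest.raises(ValueError, match="classifiable"):
            classify_niche(_matrix_from_rel(rel), samples)

    def test_tercile_sizes_bound_label_counts(self, default_dataset):
        profiles = classify_niche(default_dataset["matrix"], default_dataset["samples"])
        n = (profiles["label"] != "excluded").sum()
        n_gen = (profiles["label"] == "generalist").sum()
        n_spec = profiles["label"].str.endswith("specialist").sum()
        assert n_gen <= n // 3
        assert n_spec <= n // 3

    def test_specialist_subdivision_by_rank_comparison(self, default_dataset):
        profiles = classify_niche(default_dataset["matrix"], default_dataset["samples"])
        regular = profiles[profiles["label"] == "regular_specialist"]
        strict = profiles[profiles["label"] == "strict_specialist"]
        assert (regular["rank_sub"] >= regular["rank_main"]).all()
        assert (strict["rank_sub"] < strict["rank_main"]).all()

    def test_excluded_iff_single_sample_detection(self, default_dataset):
        profiles = classify_niche(default_dataset["matrix"], default_dataset["samples"])
        excluded = profiles["label"] == "excluded"
        assert (profiles.loc[excluded, "n_samples_detected"] <= 1).all()
        assert (profiles.loc[~excluded, "n_samples_detected"] > 1).all()


class TestPsNullTest:
    def test_availability_tracking_population_not_significant(self):
        cats = {f"s{i}": ("winter", "spring", "summer")[i % 3] for i in range(9)}
        mag = pd.Series({s: 0.01 for s in cats})
        community = pd.Series({s: 0.1 for s in cats})
        p = ps_null_test(mag, cats, "cells", community, n_perm=99, seed=0)
        assert p > 0.5

    def test_planted_specialist_detected_across_seeds(self):
        cats = {f"s{i}": ("winter", "spring", "summer")[i % 3] for i in range(12)}
        mag = pd.Series(
            {s: (0.02 if c == "winter" else 1e-5) for s, c in cats.items()}
        )
        community = pd.Series({s: 0.1 for s in cats})
        hits = sum(
            ps_null_test(mag, cats, "cells", community, n_perm=199, seed=seed) < 0.05
            for seed in range(10)
        )
        assert hits >= 9

    def test_seed_reproducibility(self):
        cats = {f"s{i}": ("winter", "spring")[i % 2] for i in range(8)}
        mag = pd.Series({s: (0.02 if i % 2 else 0.001) for i, s in enumerate(cats)})
        community = pd.Series({s: 0.1 for s in cats})
        a = ps_null_test(mag, cats, "cells", community, n_perm=199, seed=42)
        b = ps_null_test(mag, cats, "cells", community, n_perm=199, seed=42)
        assert a == b

    def test_requires_enough_permutations_and_categories(self):
        cats = {"s1": "winter", "s2": "winter"}
        mag = pd.Series({"s1": 0.01, "s2": 0.01})
        with pytest.raises(ValueError):
            ps_null_test(mag, cats, "samples", n_perm=10, seed=0)
        with pytest.raises(ValueError, match="two categories"):
            ps_null_test(mag, cats, "samples", n_perm=99, seed=0)
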