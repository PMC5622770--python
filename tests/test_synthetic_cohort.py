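"""Generator structure, determinism and closed-form ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from dietswap import recall_io
from dietswap.schema import DENSITY_FIELDS
from dietswap.synthetic_cohort import (
    GeneratorConfig,
    analytic_expected_deltas,
    generate_cohort,
    generate_food_library,
    milk_type_weights,
    stratum_popularity,
)


class TestFoodLibrary:
    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(seed=5)
        lib1 = generate_food_library(cfg)
        lib2 = generate_food_library(cfg)
        pd.testing.assert_frame_equal(lib1, lib2)

    def test_rtec_codes_have_cereal_prefixes(self):
        lib = generate_food_library(GeneratorConfig(seed=1))
        rtec = lib[lib["food_class"] == "rtec"]
        assert len(rtec) == 8
        assert rtec["food_code"].str.startswith(
            ("571", "572", "573", "574")
        ).all()

    def test_zero_range_propagates(self):
        cfg = GeneratorConfig(seed=2)
        spec = dict(cfg.food_library_spec)
        rtec = spec["rtec"]
        dens = dict(rtec.densities)
        dens["whole_grain_ozeq"] = (0.0, 0.0)
        spec["rtec"] = dataclasses.replace(rtec, densities=dens)
        cfg = dataclasses.replace(cfg, food_library_spec=spec)
        lib = generate_food_library(cfg)
        assert (lib.loc[lib["food_class"] == "rtec", "whole_grain_ozeq"] == 0).all()

    def test_empty_class_fatal(self):
        cfg = GeneratorConfig(seed=2)
        spec = dict(cfg.food_library_spec)
        spec["beverage"] = dataclasses.replace(spec["beverage"], count=0)
        cfg = dataclasses.replace(cfg, food_library_spec=spec)
        with pytest.raises(ValueError, match="beverage"):
            generate_food_library(cfg)


class TestConfigValidation:
    def test_distributions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="age_dist"):
            GeneratorConfig(age_dist={"1-3": 0.5, "4-8": 0.4})

    def test_behavior_probabilities_bounded(self):
        with pytest.raises(ValueError):
            GeneratorConfig(p_skip_breakfast=0.6, p_beverage_only=0.5)


class TestCohortStructure:
    def test_determinism(self):
        cfg = GeneratorConfig(seed=9, n_participants=150)
        p1, r1, _ = generate_cohort(cfg)
        p2, r2, _ = generate_cohort(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_different_seeds_differ(self):
        p1, r1, _ = generate_cohort(GeneratorConfig(seed=1, n_participants=100))
        p2, r2, _ = generate_cohort(GeneratorConfig(seed=2, n_participants=100))
        assert not r1["energy_kcal"].equals(r2["energy_kcal"])

    def test_validates_clean(self, small_cohort):
        _, participants, records, _ = small_cohort
        report = recall_io.validate_dataset(participants, records)
        assert report.error_count == 0

    def test_p_skip_one_gives_no_breakfast(self):
        cfg = GeneratorConfig(
            seed=3, n_participants=100, p_skip_breakfast=1.0,
            p_beverage_only=0.0, p_rtec_breakfast=0.0,
        )
        _, records, _ = generate_cohort(cfg)
        from dietswap.schema import BREAKFAST_CLASS
        assert not records["occasion"].isin(BREAKFAST_CLASS).any()

    def test_all_rtec_breakfast_nothing_eligible(self):
        from dietswap.substitution import assess_eligibility_all
        cfg = GeneratorConfig(
            seed=3, n_participants=100, p_skip_breakfast=0.0,
            p_beverage_only=0.0, p_rtec_breakfast=1.0,
        )
        _, records, _ = generate_cohort(cfg)
        elig = assess_eligibility_all(records)
        assert (elig["status"] != "eligible").all()

    def test_two_recall_share_near_85pct(self):
        cfg = GeneratorConfig(seed=13, n_participants=2000)
        participants, _, _ = generate_cohort(cfg)
        share = (participants["n_recalls"] == 2).mean()
        assert share == pytest.approx(0.85, abs=0.02)

    def test_weights_positive_and_consistent(self, small_cohort):
        _, participants, _, _ = small_cohort
        assert (participants["weight_day1"] > 0).all()
        two = participants["n_recalls"] == 2
        assert (participants.loc[two, "weight_2day"] > 0).all()
        assert (participants.loc[~two, "weight_2day"] == 0).all()

    def test_milk_type_weights_ordering(self):
        young = milk_type_weights("1-3")
        old = milk_type_weights("71+")
        assert young[0] > old[0]   # whole milk fades
        assert young[2] < old[2]   # skim grows


class TestGroundTruth:
    def test_equal_densities_zero_delta(self):
        cfg = GeneratorConfig(seed=4)
        lib = generate_food_library(cfg)
        # force composite == replaced mean for one field
        lib.loc[lib["food_class"].isin(["rtec", "breakfast_solid"]),
                "sodium_mg"] = 500.0
        truth = analytic_expected_deltas(cfg, lib)
        assert truth.expected_delta_model1["sodium_mg"] == pytest.approx(0.0)

    def test_linearity_in_replaced_kcal(self):
        cfg1 = GeneratorConfig(seed=4)
        spec = dict(cfg1.food_library_spec)
        bs = spec["breakfast_solid"]
        spec2 = dict(spec)
        spec2["breakfast_solid"] = dataclasses.replace(
            bs, portion_kcal=(2 * bs.portion_kcal[0], 2 * bs.portion_kcal[1]),
        )
        cfg2 = dataclasses.replace(cfg1, food_library_spec=spec2)
        lib = generate_food_library(cfg1)
        t1 = analytic_expected_deltas(cfg1, lib)
        t2 = analytic_expected_deltas(cfg2, lib)
        for f in ("whole_grain_ozeq", "fiber_g", "solid_fat_g"):
            assert t2.expected_delta_model1[f] == pytest.approx(
                2.0 * t1.expected_delta_model1[f]
            )

    def test_model2_whole_grain_below_model1(self):
        # milk carries no whole grain, so blending it in dilutes the gain
        truth = analytic_expected_deltas(GeneratorConfig(seed=4))
        assert (
            truth.expected_delta_model2["whole_grain_ozeq"]
            <= truth.expected_delta_model1["whole_grain_ozeq"]
        )

    def test_popularity_vectors_normalized(self):
        cfg = GeneratorConfig(seed=4)
        lib = generate_food_library(cfg)
        codes = list(lib.loc[lib["food_class"] == "rtec", "food_code"])
        pops = stratum_popularity(cfg, codes)
        for v in pops.values():
            assert v.sum() == pytest.approx(1.0)


class TestCompositeRecovery:
    def test_popularity_recovered_at_n5000(self):
        # consistency of the energy-share estimator for component weights;
        # the cohort is concentrated on two strata so each has thousands of
        # cereal occasions and the estimator's own noise sits inside the
        # 0.03-per-weight tolerance
        from dietswap.composite_profiles import build_rtec_composite
        age_dist = {g: 0.0 for g in _default_ages()}
        age_dist.update({"20-30": 0.5, "31-50": 0.5})
        race_dist = {"NHWhite": 1.0, "NHBlack": 0.0, "MexAmerican": 0.0,
                     "OtherHispanic": 0.0, "OtherMixed": 0.0}
        cfg = GeneratorConfig(
            seed=21, n_participants=5000, rtec_popularity_alpha=2.0,
            p_rtec_breakfast=0.7, p_beverage_only=0.1, p_skip_breakfast=0.1,
            age_dist=age_dist, race_dist=race_dist,
        )
        participants, records, truth = generate_cohort(cfg)
        comps = build_rtec_composite(records, participants)
        for stratum in (("20-30", "NHWhite"), ("31-50", "NHWhite")):
            prof = comps[stratum]
            assert prof.fallback_level == "stratum"
            for code, w_true in truth.rtec_popularity[stratum].items():
                assert prof.component_weights.get(code, 0.0) == pytest.approx(
                    w_true, abs=0.03,
                )


def _default_ages():
    from dietswap.schema import AGE_GROUPS
    return AGE_GROUPS
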