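"""Eligibility logic and isocaloric replacement for both models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietswap import substitution as sub
from dietswap.composite_profiles import CompositeProfile, MilkProfile
from dietswap.schema import DENSITY_FIELDS
from tests.conftest import make_record


def comp(whole_grain=4.0, fiber=8.0, solid_fat=1.0, ed=3.75, price=1.3, **extra):
    dens = {f: 0.0 for f in DENSITY_FIELDS}
    dens.update({"whole_grain_ozeq": whole_grain, "fiber_g": fiber,
                 "solid_fat_g": solid_fat})
    dens.update(extra)
    return CompositeProfile(
        stratum=("20-30", "NHWhite"), component_weights={"57100001": 1.0},
        density_per_1000kcal=dens, energy_density_kcal_per_g=ed,
        price_per_1000kcal=price,
    )


def milk_prof(p_milk=1.0, share=0.3, dairy=8.0, sfa=24.0, **extra):
    dens = {f: 0.0 for f in DENSITY_FIELDS}
    dens.update({"dairy_cupeq": dairy, "sfa_g": sfa})
    dens.update(extra)
    return MilkProfile(
        stratum=("20-30", "NHWhite"), p_milk=p_milk, milk_energy_share=share,
        density_per_1000kcal=dens, energy_density_kcal_per_g=0.5,
        price_per_1000kcal=0.9,
    )


def day(*recs):
    return pd.DataFrame(list(recs))


class TestEligibility:
    def test_cappuccino_and_doughnut(self):
        # beverage untouched, doughnut calories replaced
        d = day(
            make_record(line="l1", code="92100000", occasion="breakfast",
                        kcal=150, beverage=True),
            make_record(line="l2", code="53100000", occasion="breakfast",
                        kcal=200),
        )
        e = sub.assess_eligibility(d)
        assert e.status == "eligible"
        assert e.replaced_kcal == pytest.approx(200.0)
        assert e.replaced_record_ids == frozenset({"l2"})

    def test_beverage_only_breakfast(self):
        d = day(make_record(code="92100000", kcal=120, beverage=True))
        e = sub.assess_eligibility(d)
        assert e.status == "beverage_only"
        assert e.replaced_kcal == 0.0

    def test_rtec_at_breakfast_blocks_substitution(self):
        d = day(
            make_record(line="l1", code="57100001", kcal=150),
            make_record(line="l2", code="53100000", kcal=100),
        )
        e = sub.assess_eligibility(d)
        assert e.status == "rtec_at_breakfast"
        assert e.replaced_kcal == 0.0

    def test_skipped_breakfast(self):
        d = day(make_record(occasion="dinner", kcal=700))
        assert sub.assess_eligibility(d).status == "skipped_breakfast"

    def test_desayuno_and_brunch_count_as_breakfast(self):
        for occ in ("desayuno", "brunch"):
            d = day(make_record(occasion=occ, kcal=250))
            e = sub.assess_eligibility(d)
            assert e.status == "eligible"
            assert e.replaced_kcal == pytest.approx(250.0)

    def test_beverage_addition_not_replaced(self):
        d = day(
            make_record(line="l1", code="92100000", kcal=5, beverage=True),
            make_record(line="l2", code="91100000", kcal=30, addition=True),
            make_record(line="l3", code="53100000", kcal=200),
        )
        e = sub.assess_eligibility(d)
        assert e.replaced_kcal == pytest.approx(200.0)

    def test_rtec_outside_breakfast_does_not_block(self):
        d = day(
            make_record(line="l1", code="53100000", kcal=200),
            make_record(line="l2", code="57100001", occasion="snack", kcal=150),
        )
        assert sub.assess_eligibility(d).status == "eligible"


class TestModel1:
    def test_ineligible_day_identity(self):
        d = day(make_record(occasion="dinner", kcal=700))
        out = sub.apply_model1(d, comp())
        pd.testing.assert_frame_equal(
            out.records.drop(columns="synthetic"), d,
        )

    def test_linear_scaling_of_densities(self):
        d = day(make_record(kcal=200))
        out = sub.apply_model1(d, comp(whole_grain=4.0))
        syn = out.records[out.records["synthetic"]]
        assert len(syn) == 1
        assert syn["whole_grain_ozeq"].iloc[0] == pytest.approx(0.8)
        assert syn["energy_kcal"].iloc[0] == pytest.approx(200.0)
        assert syn["grams"].iloc[0] == pytest.approx(200.0 / 3.75)
        assert syn["is_rtec"].iloc[0]

    def test_energy_conservation(self):
        d = day(
            make_record(line="l1", kcal=321.5),
            make_record(line="l2", code="92100000", kcal=87.3, beverage=True),
            make_record(line="l3", occasion="lunch", kcal=654.2),
        )
        out = sub.apply_model1(d, comp())
        assert out.records["energy_kcal"].sum() == pytest.approx(
            d["energy_kcal"].sum(), abs=1e-6,
        )

    def test_non_breakfast_records_untouched(self):
        d = day(
            make_record(line="l1", kcal=200),
            make_record(line="l2", occasion="dinner", kcal=600),
        )
        out = sub.apply_model1(d, comp())
        dinner = out.records[out.records["occasion"] == "dinner"]
        pd.testing.assert_frame_equal(
            dinner.drop(columns="synthetic").reset_index(drop=True),
            d[d["occasion"] == "dinner"].reset_index(drop=True),
        )


class TestModel2:
    def test_p_milk_zero_degenerates_to_model1(self):
        d = day(make_record(kcal=250))
        m1 = sub.apply_model1(d, comp())
        m2 = sub.apply_model2(d, comp(), milk_prof(p_milk=0.0))
        pd.testing.assert_frame_equal(
            m1.records, m2.records.assign(),
        )

    def test_milk_energy_split(self):
        d = day(make_record(kcal=300))
        out = sub.apply_model2(d, comp(), milk_prof(p_milk=1.0, share=0.3))
        syn = out.records[out.records["synthetic"]]
        milk = syn[syn["is_milk"]]
        cereal = syn[~syn["is_milk"]]
        assert milk["energy_kcal"].iloc[0] == pytest.approx(90.0)
        assert cereal["energy_kcal"].iloc[0] == pytest.approx(210.0)

    def test_energy_conservation(self):
        d = day(make_record(kcal=413.7))
        out = sub.apply_model2(d, comp(), milk_prof(p_milk=0.6, share=0.28))
        assert out.records["energy_kcal"].sum() == pytest.approx(413.7, abs=1e-6)

    def test_whole_grain_dominated_by_model1_when_milk_has_none(self):
        # milk whole-grain density 0 -> model 2 whole grain <= model 1
        for kcal in (150.0, 275.0, 402.5):
            d = day(make_record(kcal=kcal))
            m1 = sub.apply_model1(d, comp()).records["whole_grain_ozeq"].sum()
            m2 = sub.apply_model2(
                d, comp(), milk_prof(p_milk=0.7, share=0.25)
            ).records["whole_grain_ozeq"].sum()
            assert m2 <= m1


class TestMonotonicity:
    @given(st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=25, deadline=None)
    def test_richer_composite_weakly_raises_total(self, extra_fiber):
        d = day(make_record(kcal=200, fiber_g=2.0))
        base = sub.apply_model1(d, comp(fiber=5.0)).records["fiber_g"].sum()
        richer = sub.apply_model1(
            d, comp(fiber=5.0 + extra_fiber)
        ).records["fiber_g"].sum()
        assert richer >= base - 1e-12


class TestVectorizedEquivalence:
    def test_matches_per_day_application(self, small_cohort):
        _, participants, records, _ = small_cohort
        from dietswap import composite_profiles as cp
        comps = cp.build_rtec_composite(records, participants)
        milks = cp.build_milk_profile(records, participants)
        bulk = sub.apply_model_all(records, participants, comps, milks)

        pmap = participants.set_index("participant_id")
        rng = np.random.default_rng(5)
        day_keys = records[["participant_id", "recall_day"]].drop_duplicates()
        sample = day_keys.sample(n=25, random_state=2)
        for _, (pid, rd) in sample.iterrows():
            d = records[(records["participant_id"] == pid)
                        & (records["recall_day"] == rd)]
            stratum = (pmap.at[pid, "age_group"], pmap.at[pid, "race_eth"])
            per_day = sub.apply_model2(
                d.reset_index(drop=True), comps[stratum], milks[stratum]
            )
            b = bulk[(bulk["participant_id"] == pid)
                     & (bulk["recall_day"] == rd)]
            assert b["energy_kcal"].sum() == pytest.approx(
                per_day.records["energy_kcal"].sum()
            )
            assert b["whole_grain_ozeq"].sum() == pytest.approx(
                per_day.records["whole_grain_ozeq"].sum()
            )

    def test_cohort_energy_conservation(self, small_cohort):
        _, participants, records, _ = small_cohort
        from dietswap import composite_profiles as cp
        comps = cp.build_rtec_composite(records, participants)
        m1 = sub.apply_model_all(records, participants, comps)
        keys = ["participant_id", "recall_day"]
        pre = records.groupby(keys)["energy_kcal"].sum()
        post = m1.groupby(keys)["energy_kcal"].sum()
        assert np.allclose(pre.sort_index(), post.sort_index(), atol=1e-6)
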