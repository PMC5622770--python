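"""Composite cereal and milk profile construction."""

import numpy as np
import pandas as pd
import pytest

from dietswap import composite_profiles as cp
from dietswap.schema import DENSITY_FIELDS
from tests.conftest import make_participant, make_record


def _two_cereal_setup(kcal1=100.0, kcal2=100.0, w1=1.0, w2=1.0):
    participants = pd.DataFrame([
        make_participant("P1", age=30, stratum="S0", psu=1, w1=w1, w2=w1),
        make_participant("P2", age=30, stratum="S0", psu=2, w1=w2, w2=w2),
    ])
    records = pd.DataFrame([
        make_record("P1", 1, "l1", "57100001", kcal=kcal1, fiber_g=2.0,
                    energy_density=4.0),
        make_record("P2", 1, "l1", "57200002", kcal=kcal2, fiber_g=4.0,
                    energy_density=3.5),
    ])
    return participants, records


class TestRtecComposite:
    def test_single_component_equals_that_cereal(self):
        participants = pd.DataFrame([
            make_participant("P1", stratum="S0", psu=1),
            make_participant("P2", stratum="S0", psu=2),
        ])
        records = pd.DataFrame([
            make_record("P1", 1, "l1", "57100001", kcal=120,
                        fiber_g=8.0, whole_grain_ozeq=5.0, energy_density=3.8),
        ])
        comps = cp.build_rtec_composite(records, participants)
        prof = comps[("20-30", "NHWhite")]
        assert prof.component_weights == {"57100001": 1.0}
        assert prof.density_per_1000kcal["fiber_g"] == pytest.approx(8.0)
        assert prof.density_per_1000kcal["whole_grain_ozeq"] == pytest.approx(5.0)
        assert prof.energy_density_kcal_per_g == pytest.approx(3.8)

    def test_equal_energy_two_cereals_average_density(self):
        participants, records = _two_cereal_setup()
        comps = cp.build_rtec_composite(records, participants)
        prof = comps[("20-30", "NHWhite")]
        # equal survey-weighted energy, fiber densities 2 and 4 -> 3
        assert prof.density_per_1000kcal["fiber_g"] == pytest.approx(3.0)
        assert prof.component_weights["57100001"] == pytest.approx(0.5)

    def test_survey_weights_shift_component_weights(self):
        participants, records = _two_cereal_setup(w1=3.0, w2=1.0)
        comps = cp.build_rtec_composite(records, participants)
        prof = comps[("20-30", "NHWhite")]
        assert prof.component_weights["57100001"] == pytest.approx(0.75)
        assert prof.density_per_1000kcal["fiber_g"] == pytest.approx(2.5)

    def test_convexity_every_field(self, small_cohort):
        _, participants, records, _ = small_cohort
        comps = cp.build_rtec_composite(records, participants)
        rtec = records[records["is_rtec"]]
        dens = {
            f: (rtec[f] * 1000.0 / rtec["energy_kcal"]) for f in DENSITY_FIELDS
        }
        for prof in comps.values():
            for f in DENSITY_FIELDS:
                lo, hi = dens[f].min(), dens[f].max()
                assert lo - 1e-9 <= prof.density_per_1000kcal[f] <= hi + 1e-9

    def test_permutation_invariance(self, toy_participants, toy_records):
        comps1 = cp.build_rtec_composite(toy_records, toy_participants)
        shuffled = toy_records.sample(frac=1.0, random_state=3).reset_index(drop=True)
        comps2 = cp.build_rtec_composite(shuffled, toy_participants)
        for s in comps1:
            assert comps1[s].component_weights == comps2[s].component_weights
            for f in DENSITY_FIELDS:
                assert comps1[s].density_per_1000kcal[f] == pytest.approx(
                    comps2[s].density_per_1000kcal[f]
                )

    def test_fallback_chain_fills_all_strata(self, toy_participants, toy_records):
        comps = cp.build_rtec_composite(toy_records, toy_participants)
        assert len(comps) == 40  # 8 age groups x 5 races
        levels = {p.fallback_level for p in comps.values()}
        assert "stratum" in levels and "national" in levels

    def test_no_rtec_anywhere_fatal(self, toy_participants):
        records = pd.DataFrame([make_record(code="53100000")])
        with pytest.raises(ValueError, match="RTEC"):
            cp.build_rtec_composite(records, toy_participants)


class TestMilkProfile:
    def test_no_milk_ever(self):
        participants = pd.DataFrame([
            make_participant("P1", stratum="S0", psu=1),
            make_participant("P2", stratum="S0", psu=2),
        ])
        records = pd.DataFrame([
            make_record("P1", 1, "l1", "57100001", kcal=100),
        ])
        milks = cp.build_milk_profile(records, participants)
        assert all(m.p_milk == 0.0 for m in milks.values())

    def test_every_occasion_one_third_milk(self):
        participants = pd.DataFrame([
            make_participant("P1", stratum="S0", psu=1),
            make_participant("P2", stratum="S0", psu=2),
        ])
        records = pd.DataFrame([
            make_record("P1", 1, "l1", "57100001", kcal=200),
            make_record("P1", 1, "l2", "11100000", kcal=100, milk=True,
                        beverage=True, energy_density=0.5, dairy_cupeq=8.0),
            make_record("P2", 1, "l1", "57200002", kcal=300),
            make_record("P2", 1, "l2", "11100000", kcal=150, milk=True,
                        beverage=True, energy_density=0.5, dairy_cupeq=8.0),
        ])
        milks = cp.build_milk_profile(records, participants)
        prof = milks[("20-30", "NHWhite")]
        assert prof.p_milk == pytest.approx(1.0)
        assert prof.milk_energy_share == pytest.approx(1.0 / 3.0)
        assert prof.density_per_1000kcal["dairy_cupeq"] == pytest.approx(8.0)

    def test_milk_other_occasion_not_counted(self):
        participants = pd.DataFrame([
            make_participant("P1", stratum="S0", psu=1),
            make_participant("P2", stratum="S0", psu=2),
        ])
        records = pd.DataFrame([
            make_record("P1", 1, "l1", "57100001", kcal=200),
            make_record("P1", 1, "l2", "11100000", kcal=100, milk=True,
                        beverage=True, occasion="dinner"),
        ])
        milks = cp.build_milk_profile(records, participants)
        assert milks[("20-30", "NHWhite")].p_milk == 0.0

    def test_children_milk_composite_fattier_than_elders(self, small_cohort):
        # generator defaults give young children more whole milk, so their
        # milk composite SFA density must exceed the oldest adults'
        _, participants, records, _ = small_cohort
        milks = cp.build_milk_profile(records, participants)
        young = milks[("1-3", "NHWhite")]
        old = milks[("71+", "NHWhite")]
        assert young.fallback_level == "stratum" and old.fallback_level == "stratum"
        assert (
            young.density_per_1000kcal["sfa_g"] > old.density_per_1000kcal["sfa_g"]
        )


class TestGramsForEnergy:
    def test_division_oracle(self):
        assert round(cp.grams_for_energy(312.0, 3.67)) == 85
        assert cp.grams_for_energy(100.0, 4.0) == pytest.approx(25.0)

    def test_zero_energy(self):
        assert cp.grams_for_energy(0.0, 3.5) == 0.0

    def test_nonpositive_density_fatal(self):
        with pytest.raises(ValueError):
            cp.grams_for_energy(100.0, 0.0)


class TestSerialization:
    def test_profiles_roundtrip(self, toy_participants, toy_records):
        comps = cp.build_rtec_composite(toy_records, toy_participants)
        milks = cp.build_milk_profile(toy_records, toy_participants)
        d = cp.profiles_to_dict(comps, milks)
        comps2, milks2 = cp.profiles_from_dict(d)
        assert set(comps2) == set(comps)
        s = ("20-30", "NHWhite")
        assert comps2[s].density_per_1000kcal == comps[s].density_per_1000kcal
        assert milks2[s].p_milk == milks[s].p_milk
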