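"""Per-fish bioenergetics: thermal scaling, ingestion, allocation, growth."""

import numpy as np
import pytest

from sticklesim.fish import (
    ADULT, EGG, JUVENILE, LARVA,
    Fish,
    allocate_energy,
    assimilate,
    develop_offspring,
    grow,
    maintenance_cost,
    max_ingestion,
    metabolic_scaling,
    temperature_scaling,
)
from sticklesim.params import BioenergeticsParams

WIDE = (-2.0, 40.0, 45.0)  # window wide enough that T_ref+10 is untapered


def make_adult(p, mass=1.0, reserves=None, sex="F"):
    return Fish(
        id=0, sex=sex, age=400, stage=ADULT, structural_mass=mass,
        reserves=p.reserve_capacity(mass) * 0.5 if reserves is None else reserves,
        length=p.length_from_mass(mass),
    )


class TestThermalScaling:
    def test_unity_at_reference(self, bio):
        assert temperature_scaling(15.0, 2.0, 15.0, bio.thermal_window) == 1.0

    def test_q10_definition_below_optimum(self):
        assert temperature_scaling(25.0, 2.0, 15.0, WIDE) == pytest.approx(2.0)
        assert temperature_scaling(5.0, 2.0, 15.0, WIDE) == pytest.approx(0.5)

    @pytest.mark.parametrize("temp", [32.0, 35.0, -2.0, -10.0])
    def test_zero_outside_window(self, bio, temp):
        assert temperature_scaling(temp, 2.0, 15.0, bio.thermal_window) == 0.0

    def test_taper_reaches_zero_continuously(self, bio):
        ct_min, ct_opt, ct_max = bio.thermal_window
        just_below = temperature_scaling(ct_max - 1e-6, 2.0, 15.0, bio.thermal_window)
        assert 0 < just_below < 1e-4 * 2 ** ((ct_max - 15) / 10)
        near_min = temperature_scaling(ct_min + 1e-6, 2.0, 15.0, bio.thermal_window)
        assert 0 < near_min < 1e-5

    def test_metabolic_scaling_is_pure_q10(self):
        assert metabolic_scaling(25.0, 2.0, 15.0) == pytest.approx(2.0)
        assert metabolic_scaling(35.0, 2.0, 15.0) == pytest.approx(4.0)


class TestIngestionAndMaintenance:
    def test_ingestion_power_law_in_mass(self, bio):
        small = max_ingestion(make_adult(bio, 0.5), 15.0, bio)
        big = max_ingestion(make_adult(bio, 1.0), 15.0, bio)
        assert big / small == pytest.approx(2.0 ** bio.ingestion_mass_exponent)

    def test_ingestion_zero_at_thermal_maximum(self, bio):
        assert max_ingestion(make_adult(bio), bio.thermal_window[2], bio) == 0.0

    def test_ingestion_vanishes_with_mass(self, bio):
        tiny = max_ingestion(make_adult(bio, 1e-9), 15.0, bio)
        assert tiny < 1e-7

    def test_egg_and_dead_fish_cannot_feed(self, bio):
        egg = Fish(id=1, sex="F", stage=EGG, structural_mass=bio.egg_mass)
        with pytest.raises(ValueError):
            max_ingestion(egg, 15.0, bio)
        dead = make_adult(bio)
        dead.alive = False
        with pytest.raises(ValueError):
            max_ingestion(dead, 15.0, bio)

    def test_maintenance_reference_point(self, bio):
        assert maintenance_cost(make_adult(bio, 1.0), 15.0, bio) == pytest.approx(
            bio.maintenance_coeff
        )

    def test_maintenance_q10(self, bio):
        cost15 = maintenance_cost(make_adult(bio), 15.0, bio)
        cost25 = maintenance_cost(make_adult(bio), 25.0, bio)
        assert cost25 / cost15 == pytest.approx(bio.q10_metabolism)

    def test_maintenance_power_law(self, bio):
        one = maintenance_cost(make_adult(bio, 1.0), 15.0, bio)
        two = maintenance_cost(make_adult(bio, 2.0), 15.0, bio)
        assert two / one == pytest.approx(2.0 ** bio.metabolic_mass_exponent)


class TestAssimilation:
    def test_zero_in_zero_out(self, bio):
        assert assimilate(0.0, bio) == 0.0

    def test_arithmetic(self):
        p = BioenergeticsParams(food_energy_density=3000.0,
                                assimilation_efficiency=0.7)
        assert assimilate(0.01, p) == pytest.approx(21.0)

    def test_perfect_efficiency_preserves_energy(self):
        p = BioenergeticsParams(assimilation_efficiency=1.0)
        assert assimilate(0.01, p) == pytest.approx(0.01 * p.food_energy_density)


class TestAllocation:
    def test_exact_maintenance_leaves_nothing(self, bio):
        fish = make_adult(bio)
        maint = maintenance_cost(fish, 15.0, bio)
        led = allocate_energy(fish, maint, 15.0, False, bio)
        assert led.maintenance == pytest.approx(maint)
        assert led.reproduction == led.growth == led.storage_delta == 0.0
        assert abs(led.residual()) < 1e-9

    def test_fasting_draws_reserves(self, bio):
        fish = make_adult(bio)
        maint = maintenance_cost(fish, 15.0, bio)
        led = allocate_energy(fish, 0.0, 15.0, False, bio)
        assert led.storage_delta == pytest.approx(-maint)
        assert not fish.starved
        assert abs(led.residual()) < 1e-9

    def test_exhausted_reserves_flag_starvation(self, bio):
        fish = make_adult(bio, reserves=0.0)
        led = allocate_energy(fish, 0.0, 15.0, False, bio)
        assert fish.starved
        assert led.deficit == pytest.approx(maintenance_cost(fish, 15.0, bio))
        assert abs(led.residual()) < 1e-9

    def test_huge_surplus_overflows_but_balances(self, bio):
        fish = make_adult(bio)
        fish.reserves = bio.reserve_capacity(fish.structural_mass)  # full
        led = allocate_energy(fish, 1e6, 15.0, False, bio)
        assert led.overflow > 0
        assert abs(led.residual()) < 1e-9

    def test_breeding_female_fills_gonad_up_to_quota(self, bio):
        fish = make_adult(bio, sex="F")
        maint = maintenance_cost(fish, 15.0, bio)
        quota = bio.repro_quota_coeff * fish.structural_mass ** bio.metabolic_mass_exponent
        led = allocate_energy(fish, maint + 2 * quota, 15.0, True, bio)
        assert led.reproduction == pytest.approx(quota)
        assert fish.gonad == pytest.approx(quota)
        assert abs(led.residual()) < 1e-9

    def test_males_and_off_season_fish_do_not_invest(self, bio):
        male = make_adult(bio, sex="M")
        maint = maintenance_cost(male, 15.0, bio)
        led = allocate_energy(male, maint + 50.0, 15.0, True, bio)
        assert led.reproduction == 0.0
        female = make_adult(bio, sex="F")
        led2 = allocate_energy(female, maint + 50.0, 15.0, False, bio)
        assert led2.reproduction == 0.0


class TestGrowth:
    def test_zero_energy_changes_nothing(self, bio):
        fish = make_adult(bio)
        mass, length = fish.structural_mass, fish.length
        grow(fish, 0.0, bio)
        assert fish.structural_mass == mass and fish.length == length

    def test_length_weight_roundtrip(self, bio):
        fish = make_adult(bio, 0.42)
        grow(fish, 37.0, bio)
        back = bio.mass_from_length(fish.length)
        assert back == pytest.approx(fish.structural_mass, rel=1e-9)

    def test_additivity_in_energy(self, bio):
        a = make_adult(bio, 0.3)
        b = make_adult(bio, 0.3)
        grow(a, 80.0, bio)
        grow(b, 40.0, bio)
        grow(b, 40.0, bio)
        assert a.structural_mass == pytest.approx(b.structural_mass, rel=1e-12)

    def test_mass_never_decreases(self, bio):
        fish = make_adult(bio)
        with pytest.raises(ValueError):
            grow(fish, -1.0, bio)


class TestDevelopment:
    def test_completes_in_base_duration_at_reference(self, rng):
        p = BioenergeticsParams(egg_duration_days=6.0, thermal_window=WIDE)
        egg = Fish(id=0, sex="F", stage=EGG, structural_mass=p.egg_mass)
        days = 0
        while egg.stage == EGG:
            develop_offspring(egg, 15.0, p, rng)
            days += 1
        assert days == 6

    def test_q10_halves_duration(self, rng):
        p = BioenergeticsParams(egg_duration_days=6.0, q10_ingestion=2.0,
                                thermal_window=WIDE)
        egg = Fish(id=0, sex="F", stage=EGG, structural_mass=p.egg_mass)
        days = 0
        while egg.stage == EGG:
            develop_offspring(egg, 25.0, p, rng)
            days += 1
        assert days == int(np.ceil(6 / 2))

    def test_no_development_below_thermal_minimum(self, bio, rng):
        egg = Fish(id=0, sex="F", stage=EGG, structural_mass=bio.egg_mass)
        for _ in range(50):
            develop_offspring(egg, bio.thermal_window[0], bio, rng)
        assert egg.stage == EGG and egg.develop_progress == 0.0

    def test_larva_matures_into_feeding_juvenile(self, bio, rng):
        larva = Fish(id=0, sex="F", stage=LARVA, structural_mass=bio.egg_mass)
        while larva.stage == LARVA:
            develop_offspring(larva, 15.0, bio, rng)
        assert larva.stage == JUVENILE
        lo, hi = bio.offspring_mass_range
        assert lo <= larva.structural_mass <= hi
        assert larva.length == pytest.approx(
            bio.length_from_mass(larva.structural_mass)
        )

    def test_post_larval_stages_rejected(self, bio, rng):
        with pytest.raises(ValueError):
            develop_offspring(make_adult(bio), 15.0, bio, rng)
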