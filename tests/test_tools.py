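"""Syringe volume math, media-fill batching, tip pickup, transfer retry loop."""

import math

import pytest

from frondlab.design import ExperimentSpec, randomize_layout
from frondlab.errors import CapacityError, SeekError, ToolConfigError, VolumeError
from frondlab.gcode import virtual_execute, home
from frondlab.tools import (
    PipetteConfig,
    StochasticEmptinessOracle,
    SyringeConfig,
    aspirate,
    dispense,
    fill_wells,
    manual_transfer_instructions,
    pickup_tip,
    transfer_duckweed,
    volume_to_travel,
)


class TestSyringe:
    def test_zero_volume_zero_travel(self):
        assert volume_to_travel(SyringeConfig(), 0.0) == 0.0

    def test_hand_multiplied_travel(self):
        cfg = SyringeConfig(travel_per_uL=0.002)
        assert volume_to_travel(cfg, 5000) == pytest.approx(10.0)

    def test_linearity(self):
        cfg = SyringeConfig()
        v = 1234.5
        assert volume_to_travel(cfg, 2 * v) == pytest.approx(2 * volume_to_travel(cfg, v))

    def test_negative_volume_rejected(self):
        with pytest.raises(VolumeError):
            volume_to_travel(SyringeConfig(), -1.0)

    def test_aspirate_beyond_capacity_rejected(self):
        cfg = SyringeConfig(capacity_uL=10000)
        with pytest.raises(VolumeError):
            aspirate(cfg, 10001)

    def test_dispense_below_zero_rejected(self):
        cfg = SyringeConfig(current_volume=100)
        with pytest.raises(VolumeError):
            dispense(cfg, 101)

    def test_aspirate_dispense_round_trip(self):
        cfg, _ = aspirate(SyringeConfig(), 8000)
        cfg, _ = dispense(cfg, 8000)
        assert cfg.current_volume == pytest.approx(0.0)


def _layout(toy_labware, genotypes=("g1",), media=("m1",), replicates=16, seed=3):
    spec = ExperimentSpec(
        name="fill", genotypes=genotypes, media=media, replicates=replicates,
        labware=toy_labware, seed=seed,
    )
    return randomize_layout(spec)


class TestFillWells:
    def test_single_batch_16_wells(self, loaded_deck, toy_labware):
        layout = _layout(toy_labware, replicates=16)
        plan = fill_wells(loaded_deck, layout, "m1", 1000.0, SyringeConfig())
        assert plan.n_batches == 1
        assert plan.total_dispensed == pytest.approx(16000.0)
        # 16 dispenses: one plunger-retract per well after the single aspirate
        dispenses = [v for v in plan.volume_trace][1:]
        assert len(dispenses) == 16

    def test_two_batches_60_wells(self, toy_deck, toy_labware):
        toy_deck.add_labware(0, toy_labware, role="reservoir")
        for slot in (1, 2, 3):
            toy_deck.add_labware(slot, toy_labware)
        layout = _layout(toy_labware, replicates=60)
        plan = fill_wells(toy_deck, layout, "m1", 1000.0, SyringeConfig(capacity_uL=50000))
        assert plan.n_batches == math.ceil(60000 / 50000) == 2
        assert plan.total_dispensed == pytest.approx(60000.0)

    def test_unknown_media_rejected(self, loaded_deck, toy_labware):
        layout = _layout(toy_labware)
        from frondlab.errors import LayoutLookupError

        with pytest.raises(LayoutLookupError):
            fill_wells(loaded_deck, layout, "brine", 1000.0, SyringeConfig())

    def test_overfilled_well_rejected(self, loaded_deck, toy_labware):
        layout = _layout(toy_labware)
        with pytest.raises(CapacityError):
            fill_wells(loaded_deck, layout, "m1", toy_labware.well_capacity_uL + 1, SyringeConfig())

    def test_media_swap_prompt_only_when_needed(self, loaded_deck, toy_labware):
        layout = _layout(toy_labware)
        plan = fill_wells(loaded_deck, layout, "m1", 500.0, SyringeConfig(), loaded_media="m0")
        assert len(plan.prompts) == 1 and "m1" in plan.prompts[0]
        plan2 = fill_wells(loaded_deck, layout, "m1", 500.0, SyringeConfig(), loaded_media="m1")
        assert plan2.prompts == []

    def test_volume_conservation_and_bounds(self, loaded_deck, toy_labware):
        layout = _layout(toy_labware, replicates=60)
        syringe = SyringeConfig(capacity_uL=50000)
        plan = fill_wells(loaded_deck, layout, "m1", 1000.0, syringe)
        assert all(-1e-9 <= v <= syringe.capacity_uL + 1e-9 for v in plan.volume_trace)
        assert plan.syringe.current_volume == pytest.approx(0.0)

    def test_stream_is_legal_on_virtual_machine(self, loaded_deck, toy_labware):
        layout = _layout(toy_labware)
        plan = fill_wells(loaded_deck, layout, "m1", 1000.0, SyringeConfig())
        _, violations = virtual_execute([home()] + plan.commands)
        assert violations == []


class TestPickupTip:
    def test_seek_step_count_from_hand_arithmetic(self):
        pip = PipetteConfig(tip_seek_step=0.5, contact_z=4.0)
        result = pickup_tip(pip, (100.0, 50.0), start_z=10.0)
        assert result.n_steps == 12  # (10 - 4) / 0.5
        assert result.pipette.has_tip

    def test_already_in_contact_zero_steps(self):
        pip = PipetteConfig(contact_z=4.0)
        result = pickup_tip(pip, (100.0, 50.0), start_z=4.0)
        assert result.n_steps == 0
        assert result.pipette.has_tip

    def test_unreachable_contact_is_seek_failure(self):
        pip = PipetteConfig(contact_z=4.0, max_seek_travel=5.0)
        with pytest.raises(SeekError):
            pickup_tip(pip, (100.0, 50.0), start_z=20.0)

    def test_double_pickup_rejected(self):
        pip = PipetteConfig(has_tip=True)
        with pytest.raises(ToolConfigError):
            pickup_tip(pip, (100.0, 50.0), start_z=10.0)

    def test_seek_never_descends_past_contact(self):
        pip = PipetteConfig(tip_seek_step=0.7, contact_z=4.0)
        result = pickup_tip(pip, (100.0, 50.0), start_z=10.0)
        seek_z = [c.z for c in result.commands[3:]]
        assert min(seek_z) >= pip.contact_z - 1e-9


class TestTransferDuckweed:
    def test_certain_success_single_round(self):
        wells = [f"W{i}" for i in range(24)]
        report = transfer_duckweed("src", wells, "loop", 3, StochasticEmptinessOracle(1.0, seed=1))
        assert report.rounds == 1
        assert report.n_occupied == 24
        assert all(o.attempts == 1 for o in report.wells.values())

    def test_certain_failure_exhausts_rounds(self):
        wells = list("abcd")
        report = transfer_duckweed("src", wells, "syringe", 3, StochasticEmptinessOracle(0.0, seed=1))
        assert report.rounds == 3
        assert report.n_empty == 4
        assert all(o.attempts == 3 for o in report.wells.values())

    def test_half_success_two_rounds_within_binomial_bounds(self):
        # P(occupied after 2 rounds at p=0.5) = 1 - 0.5^2 = 0.75
        wells = list(range(100))
        report = transfer_duckweed(
            "src", wells, "angled_loop", 2, StochasticEmptinessOracle(0.5, seed=7)
        )
        frac = report.n_occupied / 100
        half_width = 2.576 * math.sqrt(0.75 * 0.25 / 100)  # 99% normal bounds
        assert abs(frac - 0.75) <= half_width

    def test_occupied_wells_never_reattempted(self):
        wells = list(range(50))
        attempts_log = []
        oracle = StochasticEmptinessOracle(0.5, seed=3)
        report = transfer_duckweed(
            "src", wells, "loop", 5, oracle, attempt_hook=lambda w, r: attempts_log.append((w, r))
        )
        for well, outcome in report.wells.items():
            rounds_attempted = [r for w, r in attempts_log if w == well]
            assert rounds_attempted == list(range(1, outcome.attempts + 1))

    def test_retry_set_shrinks_monotonically(self):
        per_round: dict[int, int] = {}
        oracle = StochasticEmptinessOracle(0.4, seed=9)
        transfer_duckweed(
            "src", list(range(60)), "loop", 6, oracle,
            attempt_hook=lambda w, r: per_round.__setitem__(r, per_round.get(r, 0) + 1),
        )
        sizes = [per_round[r] for r in sorted(per_round)]
        assert sizes == sorted(sizes, reverse=True)

    def test_unknown_tool_rejected(self):
        with pytest.raises(ToolConfigError):
            transfer_duckweed("src", ["a"], "tweezers", 1, StochasticEmptinessOracle(1.0))


class TestManualInstructions:
    def test_one_instruction_per_assigned_well(self, toy_labware):
        layout = _layout(toy_labware, genotypes=("g1", "g2"), media=("m1",), replicates=3)
        lines = manual_transfer_instructions(layout)
        assert len(lines) == 6
        assert all("tweezers" in line for line in lines)
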