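"""Plan a media fill and replay it on the virtual machine.

Fills every well assigned to one media with 1000 µL from the 50cc syringe,
then executes the generated G-code against the rule-checking virtual
machine.  The printed batch count shows the refill logic (the syringe holds
50 mL, so 16 x 1000 µL needs a single aspiration) and a legal stream ends
with zero violations.
"""

from frondlab import (
    DeckLayout, ExperimentSpec, LabwareDefinition, SyringeConfig,
    fill_wells, randomize_layout, virtual_execute,
)
from frondlab.gcode import home

plate24 = LabwareDefinition(
    name="plate24", rows=4, columns=6, well_spacing_x=19.0, well_spacing_y=19.0,
    a1_offset_x=15.0, a1_offset_y=14.0, footprint_x=127.8, footprint_y=85.5,
    well_capacity_uL=3000.0,
)
spec = ExperimentSpec(
    name="fill", genotypes=("Lm5500",), media=("NaCl0",), replicates=16,
    labware=plate24, seed=3,
)
layout = randomize_layout(spec)

deck = DeckLayout(slot_origins=tuple((140.0 * c, 100.0 * r) for r in range(3) for c in range(2)))
deck.add_labware(0, plate24, role="reservoir")
deck.add_labware(1, plate24, role="plate")

plan = fill_wells(deck, layout, "NaCl0", 1000.0, SyringeConfig(), loaded_media=None)
for prompt in plan.prompts:
    print("PROMPT:", prompt)
print(f"{len(plan.commands)} commands, {plan.n_batches} aspiration batch(es), "
      f"{plan.total_dispensed:.0f} µL dispensed")

state, violations = virtual_execute([home()] + plan.commands)
print(f"virtual replay: final position {state.xyz}, {len(violations)} violations")
# 1 batch / 16000 µL: one syringe fill covers all 16 wells; 0 violations = stream is legal.
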