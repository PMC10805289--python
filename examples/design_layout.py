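"""Randomize a plate layout for a genotype x media x replicate design.

Builds the 4 x 4 x 4 salt-response design on 24-well plates, prints how many
plates it needs and the map of plate 1.  Each printed cell is the
genotype/media condition assigned to that well; '-' marks unused wells.
"""

from frondlab import ExperimentSpec, LabwareDefinition, randomize_layout, render_plate_map

plate24 = LabwareDefinition(
    name="plate24", rows=4, columns=6, well_spacing_x=19.0, well_spacing_y=19.0,
    a1_offset_x=15.0, a1_offset_y=14.0, footprint_x=127.8, footprint_y=85.5,
    well_capacity_uL=3000.0,
)
spec = ExperimentSpec(
    name="saltassay",
    genotypes=("Sp7498", "Lm5500", "Lm8627", "Wa7733"),
    media=("NaCl0", "NaCl25", "NaCl50", "NaCl100"),
    replicates=4,
    labware=plate24,
    seed=11,
)
layout = randomize_layout(spec)
print(f"{layout.total_wells} wells across {len(layout.plates)} plates")
print(render_plate_map(layout, 1))
# 64 wells / 3 plates: the minimum number of 24-well plates for 16 conditions x 4 replicates.
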