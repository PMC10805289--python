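# Methods

This note records the models, conventions and numerical choices behind
frondlab, and what the synthetic validation does and does not demonstrate.

## Coordinate and labware conventions

Machine coordinates are millimetres with the origin at the deck front-left
corner, +x right, +y rear. Labware offsets run from the labware front-left
corner to the center of well A1; row letters increase with +y, columns are
1-based, deck slots 0-based. The well center of column j, row i (0-based)
in slot s is

    x = origin_x(s) + a1_offset_x + (j − 1)·spacing_x
    y = origin_y(s) + a1_offset_y + i·spacing_y

Labware documents use a minimal flat JSON schema (grid, spacing, A1 offset,
footprint, capacity); OpenTrons-style nested documents (`wells`/`ordering`)
are accepted by extracting the same parameters from the per-well
coordinates rather than re-implementing the full vendor schema. Validation
rejects empty grids, non-positive capacities, and any grid whose last
row/column falls outside the footprint. Slot origins are configuration, not
constants, because deck attachments differ between builds; the test deck
uses six 140 × 100 mm bays in a 3 × 2 grid.

The deck has exactly six slots. By convention slot 0 holds source material
(media or duckweed reservoir) and slots 1–5 hold destination labware; the
convention is a default role, not a hard restriction.

## Machine model

G-code follows Duet/RepRapFirmware conventions: `G28` home, `G0` travel,
`T<n>`/`T-1` tool select/deselect. Coordinates render with fixed 3-decimal
precision so command streams are byte-stable and parse∘emit is the
identity; feedrates render with `%g`. Tool pickup/park macros are
firmware-side and abstracted into the tool-select verbs.

The virtual machine replays streams under four legality rules — no motion
before homing, stay inside the axis envelope, no tool select while another
tool is active, no deselect without an active tool — collecting violations
rather than raising (a `strict` mode raises on the first). Homing is
modeled as moving to the axis minima. The default envelope is a
300 × 300 × 300 mm cube and the default travel clearance 30 mm; both are
configuration, since machine builds vary. Safe travel between two points is
always three moves (retract to max(clearance, current z), traverse, descend),
so the traverse never drops below the clearance.

Hardware access is a transport contract, `send(line) -> reply`; the virtual
machine implements it, and a lazy-import pyserial transport is provided for
physical controllers but never exercised in tests.

## Tools

Syringes are linear actuators: plunger travel = volume × `travel_per_uL`.
The 50cc default calibration (0.0012 mm/µL) is a fixture value — real
calibrations come from the rig. Media fills iterate over the wells assigned
to one media, refilling at the reservoir whenever the remaining syringe
volume cannot cover the next dispense; the batch count is therefore
⌈total/capacity⌉ for uniform dispenses. A reservoir-swap prompt is emitted
whenever the requested media differs from what is loaded. Dispense depth,
reservoir needle depth and feedrates are configuration with documented
fixture defaults; well volume bookkeeping treats frond transfer as
volume-neutral.

Pipette tip pickup emulates the limit-switch flexure: the platform advances
in `tip_seek_step` increments until z reaches `contact_z`, giving
⌈(start_z − contact_z)/step⌉ increments, with a `max_seek_travel` bound
that turns a missing tip into a seek failure instead of a crash.

Duckweed transfer is a verify-and-retry loop: round 1 attempts every
destination well; after each round an emptiness oracle (frond segmentation
on a fresh image in production; a seeded stochastic stub in tests) marks
wells still empty, and only those are retried. `max_rounds` defaults to 3:
unbounded retries would be admissible but trade assay duration for
occupancy, and a finite default keeps termination provable. Tool choice
(standard loop, right-angle loop for heavy multi-frond ramets, syringe) is
configuration. A manual mode emits per-well tweezer instructions instead of
motion.

## Experiment design

The randomizer builds the multiset of G·M·R condition tokens, shuffles it
with a seeded `random.Random`, and deals tokens row-major into
⌈G·M·R / wells-per-plate⌉ plates (slots 1–5, so capacity is five plates).
Contiguous dealing means only the last plate is partial; users who care
about edge effects can hand-edit the saved JSON, and `validate_layout`
re-tallies replicate counts after any edit. Blocking/stratification is
deliberately out of scope. The seed is stored in the JSON
(`format_version: 1`) so layouts are reproducible and auditable, and the
experiment directory (`layout/`, `images/`, `results/`) is created
atomically with no silent overwrite.

## Imaging

Filenames are `<YYYY-MM-DD>_<experiment>_plate<k>_<well>.png` — ISO dates
and underscore separators, with underscores forbidden in experiment names
so parsing is unambiguous. Per-well sessions order captures by plate index
then row-major wells. Whole-deck mode plans a single capture plus a tile
map; the pixel/machine mapping (px/mm scale, pixel origin, tile size) is a
calibration config. Cropping is exact sub-rectangle extraction — tiles are
copies, and an off-image tile is an error rather than a clamp. Capture is
behind a two-method camera protocol so the synthetic generator can stand in
for camera hardware.

## Frond quantification

Segmentation: RGB → HSV, threshold the saturation channel (default 80/255),
intersect with a circular well mask inset by `well_mask_margin` (default
6 px) to exclude wall glare, label 8-connected regions, and filter by area
(≥ 50 px²) and circularity 4πA/P² (≥ 0.60). Region area is the pixel count
and perimeter the scikit-image contour estimate; a zero-perimeter
(single-pixel) region is assigned circularity 1 and in practice removed by
the area filter. The shape criterion is stated in the field as a
perimeter-to-area ratio; that raw ratio is scale-dependent, so the
normalized circularity is the default and the raw variant is kept behind
`use_perimeter_area_ratio`. The threshold is rig-specific by nature
(lighting), so defaults here are fixture values tuned once for the
synthetic appearance model, overridable per experiment. Rejected-region
statistics are returned for QC rather than discarded.

Growth curves aggregate per-well areas into per-(genotype, media) daily
replicate means (mean, not sum — a documented choice) with standard
deviations; missing wells are absent, never zero-filled. Rates come from
`polyfit` of log mean area against day, dropping non-positive means; fewer
than two usable days yields NaN.

## Synthetic data

The generator is the study-conditions oracle. Fronds are saturated green
disks (hue 120°, saturation 200/255, value 0.78) on a low-saturation gray
well (gray 110 inside the well circle, 60 outside), optionally with a
low-order Fourier boundary jitter; ground truth is the exact painted-pixel
count of the union mask. Noise has two components: mean-preserving
multiplicative log-normal noise on the daily target area (coefficient of
variation `noise_cv`) and additive Gaussian pixel noise. Fixture noise is
σ = 6 gray levels and boundary jitter 0.12 — strong enough that threshold
flips occur but isolated, so the area filter removes them.

Time series follow A(t) = A₀·e^{rt} at t = 0 … days−1 (`days` counts
imaging sessions). Default study conditions for simulated assays:
A₀ = 300 px², r = 0.30/day, cv = 0.05, 7 days, 160 px well images —
sizes chosen so a full 64-well, 448-image simulation generates and analyzes
in seconds while leaving frond areas far from the well-capacity clip
(30% of the well circle, at which point areas are clipped and flagged).
A target area is realized as the fewest equal disks with radius ≤ 16 px,
placed by rejection sampling without overlap, falling back to a
deterministic ring arrangement in crowded wells.

What passing synthetic tests shows: the geometry, bookkeeping, filtering
and fitting logic are correct, and the pipeline recovers known growth rates
through the full image path. What it does not show: robustness to real
photography — uneven illumination, specular water reflections, overlapping
or stacked fronds, roots, species-dependent color — none of which the
appearance model contains. The saturation threshold in particular must be
re-tuned on any real rig.

## Known limitations

- No fluid dynamics: fills are volume bookkeeping plus motion, not droplet
  physics; transfer success is an oracle, not a frond-pickup model.
- No kinematics or acceleration modeling in the virtual machine; it checks
  legality, not timing.
- No frond counting, species classification or root measurement; the
  readout is total area only.
- No significance testing on growth curves; the analysis stops at
  per-condition rate estimates.
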