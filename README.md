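# frondlab

A hardware-optional Python toolkit for automated duckweed growth assays on
an open, tool-changing motion platform.

Duckweeds (Lemnaceae — *Lemna*, *Spirodela*, *Wolffia*) are tiny floating
aquatic plants whose top-down frond area is a convenient growth readout.
A growth assay on an automated platform runs in four stages: randomize a
genotype × media × replicate design onto microplates, set the plates up
(fill media with a syringe tool, transfer fronds with an inoculation loop
under camera verification), image every well daily, and quantify frond area
into growth curves. frondlab implements all four stages as a library that
never needs the physical machine: every motion is G-code replayed against a
rule-checking virtual machine, and every image can come from a synthetic
generator with exact ground truth.

It is written for plant biologists and lab-automation developers who want
to develop and test assay workflows in code (notebooks, scripts, CI) before
— or instead of — running them on hardware.

## What's in the box

| Module | Purpose |
| --- | --- |
| `frondlab.labware` | OpenTrons-style labware definitions, the six-slot deck, machine coordinates of any well |
| `frondlab.gcode` | G-code emit/parse (Duet dialect), safe-z travel planning, a legality-checking virtual machine |
| `frondlab.tools` | 10cc/50cc syringes, OT-2 pipette tip pickup via a virtual limit switch, camera-verified transfer with retries |
| `frondlab.design` | Seeded randomization of plate layouts, editable JSON persistence, text plate maps |
| `frondlab.imaging` | Round-trippable `date_experiment_plateK_WELL.png` naming, session planning, whole-deck tile cropping |
| `frondlab.quantify` | HSV-saturation segmentation, contour area/roundness filtering, growth curves and rate fits |
| `frondlab.synthetic` | Seed-deterministic well images and full simulated experiments with painted-pixel ground truth |

## The core quantification model

A well image is converted to HSV and binarized on the saturation channel,
S(x, y) ≥ τ (default τ = 80 of 255), inside a circular well mask. Connected
regions are filtered by area A ≥ A_min (default 50 px²) and circularity

    c = 4πA / P² ≥ c_min        (c = 1 for a disk; default c_min = 0.60)

to reject lighting speckle and glare streaks. Total frond area per well is
ΣA over kept regions; a well with no kept region is "empty" (also used to
verify transfers). Per condition (genotype g, media m), daily replicate
means Ā_gm(t) are fit by log-linear least squares,

    log Ā_gm(t) = log A₀ + r·t,

and the slope r is the relative growth rate per day.

## Worked example

```
$ python examples/full_growth_assay.py
simulated 40 images (8 wells x 5 days)
genotype   media  rate_per_day
  Lm5500   NaCl0      0.286981
  Lm5500 NaCl100      0.304995
  Wa7733   NaCl0      0.296550
  Wa7733 NaCl100      0.300996
```

This simulates a 2 × 2 × 2 assay growing exponentially at 0.30/day with 5%
well-to-well area noise, writes the experiment tree (layout JSON + image
files), then runs the analysis pipeline over those images. The fitted
`rate_per_day` values recover the simulated 0.30/day to within a few
percent; the residual spread is the injected noise plus pixel
rasterization. The other scripts in `examples/` walk through layout
randomization, virtual media fills, verified transfer, and single-well
segmentation the same way.

A thin CLI mirrors the common operations
(`frondlab design new`, `frondlab deck locate`, `frondlab machine replay`,
`frondlab analyze`, `frondlab synth`); run `frondlab --help`.

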