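# pavotrain

Generative simulation of the peacock's train: how a condensed zigzag
lattice of feather follicles on the uropygial anchor plate expands into the
bilaterally symmetric, hexagonally packed eyespot fan of the display — and
why eyespot number is an age-determined trait rather than a freely varying
one.

## The science

The train coverts of *Pavo cristatus* insert on the ventral face of the
uropygium in tightly packed rows of 10 and 11 follicles that alternate and
stagger by half the within-row pitch (a zigzag — the 2-D analogue of densest
sphere packing). Each follicle carries one feather whose tip bears one
eyespot, so the condensed plate layout *is* the blueprint of the display:

* **Symmetry.** An 11-row has one follicle on the midline and five on each
  side; the 10-rows occupy the midpoints. Expanded bilaterally, the fan is
  exactly mirror-symmetric. A uniformly spaced, half-pitch-staggered row
  arrangement can only be mirror-symmetric when consecutive row sizes
  alternate parity — 10/11 is the smallest dense solution near this row
  width, which the package makes precise.
* **Complexity.** The staggered lattice, spread over concentric arcs
  (`angle = midline + x · span / (2·x_max)`, radius `base + row · pitch`),
  yields hexagonal eyespot packing; parallel (unstaggered) rows yield a
  palm-leaf pattern of radial lines instead. The package quantifies this
  contrast with a Delaunay-neighbor *hexagonality* score, the CV of
  nearest-neighbor distances, a mirror-symmetry error, and a radial-line
  count.
* **Constraint.** Rows accrete annually (10, 11, 10, ...), so the eyespot
  count is set by age: 16 eyespot-bearing rows carry
  `8·10 + 8·11 = 168` eyespots (the familiar 165–170 band of mature males),
  a 20-year accumulation passes 200, and within an age cohort the variance
  is exactly zero — all variation sits between cohorts or comes from damage.
* **Rings.** An 11-feather row reads as an inverted tandem duplication
  (`T5..T1 C T1..T5`); walking outward from its center gives the 6
  concentric zones of a single ocellus.

A seeded synthetic-specimen generator emulates museum summary data (rows
17–19, fishtail counts near the 3-row/4-row modes, feather lengths as
truncated Normals), making every downstream summary testable without
specimens.

## Worked example

```python
import pavotrain as pt

lattice = pt.build_lattice("zigzag_10_11", n_rows=18)
print(len(lattice))                       # 189  (9 rows of 10 + 9 rows of 11)

pattern = pt.classify_feathers(pt.expand(lattice), n_fishtail_rows=4, n_minor_rows=2)
print(pattern.class_counts())             # {'eyespot': 126, 'fishtail': 42, 'minor': 21}

m = pt.compute_metrics(pattern)           # eyespot-class points only
print(round(m.hexagonality, 3))           # 0.648
print(round(m.nn_distance_cv, 3))         # 0.154
print(m.n_radial_lines)                   # 21   (11 grid lines + 10 midpoint lines)
print(m.symmetry_error)                   # 0.0

mp = pt.compute_metrics(
    pt.classify_feathers(pt.expand(pt.build_lattice("parallel_10_11", 18)), 4, 2)
)
print(round(mp.hexagonality, 3))          # 0.613  (less hexagonal than zigzag)
print(round(mp.nn_distance_cv, 3))        # 0.250  (less uniform than zigzag)

print(pt.total_follicles("alt_10_11", 16))  # 168  -> the 165-170 mature band
print(pt.total_follicles("alt_10_11", 20))  # 210  -> ">200" lifetime ceiling
```

The same pipeline is scriptable from the shell:

```sh
pavotrain simulate --scheme zigzag_10_11 --out out/       # CSVs, SVG/PNG, metrics.json
pavotrain compare --out out/                              # metrics across 4 schemes
pavotrain grow --max-age 20 --out out/                    # accretion trajectory
pavotrain specimens -n 21 --seed 13 --out out/            # synthetic museum table
pavotrain render-eyespot --out out/                       # palindromic ring model
```

Every command writes a `run_meta.json` sidecar with the config hash, seed
and version.

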