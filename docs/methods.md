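# Methods

## The lattice model

The anchor-plate lattice lives in a plane with the midline at `x = 0`, the
anterior (newest) row at `y = 0`, and posterior rows at increasing
`y = row_index · row_pitch`. All geometry is in abstract plate units: no
absolute follicle spacing is known, only the relative arrangement, so one
within-row pitch is the natural unit.

Row placement is exact-arithmetic by design, because downstream invariants
(mirror symmetry, half-pitch staggering) are asserted to machine precision:

* A **centered row** of `n` follicles sits at offsets
  `(i − (n−1)/2) · pitch`. Odd `n` lands on the integer grid (one follicle
  exactly on the midline, five per side for `n = 11`); even `n` lands on the
  half-integer grid. Offsets are constructed as exact floating-point mirror
  pairs.
* **Zigzag, alternating 10/11**: nothing more is needed — the two parity
  grids interleave at exactly half a pitch on their own. This is the crux of
  the model: *a uniformly spaced, mirror-symmetric row staggered at half a
  pitch from a mirror-symmetric neighbor exists only when the two row sizes
  differ in parity.* (A symmetric uniformly spaced row of size `n` is forced
  onto the integer grid for odd `n` and the half-integer grid for even `n`;
  two rows of equal parity therefore cannot stagger.) The alternating-parity
  scheme is the only one that combines dense staggering with exact bilateral
  symmetry.
* **Zigzag, constant row size** (the 10/10 and 11/11 contrast schemes):
  offset rows displace every off-midline follicle half a pitch *away from
  the midline* (a midline follicle stays put). For even sizes this gives the
  skip-center grid (±1…±5 for size 10): the gap midpoints of the reference
  row plus one slot beyond each end, every follicle exactly half a pitch
  from its nearest reference-row neighbor. For odd sizes the mid-feather
  remains on the midline — the one documented exception to the exact
  half-pitch offset, accepted because bilateral symmetry is the
  non-negotiable property of the expansion.
* **Parallel**: every row is stretched over the same horizontal span
  `(max_row_size − 1) · pitch`, so unequal row sizes get unequal pitches and
  no stagger arises. This is the minimal "no offset" reading of a parallel
  arrangement with mixed row sizes.

Follicle diameters default to a linear gradient from 0.5 (anterior, newest)
to 1.0 (posterior, oldest) units; the biology only says the gradient is
monotone, so the simplest monotone profile is the default and any
non-decreasing map may be supplied.

## The fan expansion

A single affine map sends plate `x` to display angle for all rows:
`angle = midline + x · span / (2·x_max)`, with row `r` on the arc of radius
`base_radius + r · radial_pitch`. Using one map (rather than stretching each
row across the fan independently) is what preserves the half-pitch stagger
as exactly half the angular pitch — the property that turns dense plate
packing into hexagonal display packing. For a full 360° span the angular
scale uses `span / (2·x_max + within_row_pitch)` so the two fan edges do not
coincide and a single row of `n` spaces uniformly at `360/n` degrees.

Defaults: `fan_span = 180°` and `midline_angle = 90°` (the erected train is
roughly a half disc, mirror axis vertical); `base_radius = 3` units, chosen
so that the innermost arc's point spacing (`3 · 18° ≈ 0.94` units) is
commensurate with the default `radial_pitch = 1` — the displayed fan has
comparable spacing along and between rows. Dot sizes grow linearly from 0.5
to 1.0 outward, mirroring the follicle gradient. Row index grows with
follicle age, so the oldest rows land outermost, where
`classify_feathers` labels them fishtail (default 4 rows; 3–5 is the
age-dependent range) and the innermost rows minor (default 2; 2–3 observed).

## Pattern statistics

All statistics operate on eyespot-class points by default (the packing
claims concern the eyespot field, not the fishtail fringe); pass
`classes=None` to use all points.

* **hexagonality** — fraction of interior points whose Delaunay neighbor
  degree is exactly 6. "Interior" means not on the convex-hull *outline*:
  hull vertices plus any point within `1e-9 ×` extent of a hull edge line.
  (Collinear boundary points must count as boundary, otherwise the tie-break
  jitter below randomly reclassifies them and boundary artifacts leak into
  the score.) Degenerate inputs — co-circular quadruples such as square
  grids, or same-arc quadruples in any fan — are broken by deterministic
  Gaussian jitter of `1e-9 ×` extent drawn from the fixed seed 0, applied
  before triangulation only; scores are therefore reproducible bit-for-bit.
  A perfect triangular lattice scores 1.0; the jittered 5×5 square grid
  scores 7/9.
* **nn_distance_cv** — SD/mean (population SD) of nearest-neighbor
  distances; 0 for perfectly uniform spacing.
* **symmetry_error** — each point is reflected across the mirror line; the
  score is the mean distance from reflected points to their nearest
  original, normalized by the mean nearest-neighbor distance. Residues
  below `1e-12 ×` the coordinate scale are treated as exact zeros
  (reflection roundoff).
* **radial_line_count** — angles sorted and split where a gap reaches the
  tolerance (default: half the minimum within-row angular pitch, which
  separates grid lines from midpoint lines exactly; a `1e-9` relative guard
  keeps boundary-equal gaps from collapsing). Full-circle fans merge the
  wrap-around gap.

Both hexagonality and nn_distance_cv are cross-checked in the test suite
against independent brute-force implementations (monotone-chain hull,
empty-circumcircle triangle enumeration, pairwise-distance scans).

**Where the zigzag advantage holds.** Under the default geometry the
zigzag 10/11 fan is more hexagonal and more uniformly spaced than the
parallel 10/11 fan, with 21 interleaved radial lines versus ≤ 11. The
ordering is robust for fan spans around the natural display (150–210°) with
radial pitch up to about the inner-arc point spacing. When the radial pitch
substantially exceeds the angular spacing the rows decouple radially, both
arrangements degrade toward row-chain packings, and the contrast can vanish
— the property test sweeps the regime where the fan actually resembles a
displaying train.

## The accretion (growth) model

`rows_at_age(a) = min(rows_per_year · a, max_rows)` with `rows_per_year = 1`
and `max_rows = 19` (the top of the observed 17–19 range) by default.
Feather classes partition the alternating row sums at every age; the
eyespot count of a cohort is therefore a deterministic function of age —
within-cohort variance is zero by construction, and year-over-year
increments can only be 0, 10, 11 or 21.

Train length uses the saturating exponential
`L(a) = L∞ · (1 − exp(−k·a))` with `L∞ = 160 cm` (near the longest museum
feather lengths) and `k = 0.5 /yr` (≈95% of asymptote by age 6, when
displays mature). Only "asymptotic in age" is biologically given; the
specific bounded monotone form and its parameters are package choices,
exposed as `GrowthParams`.

## The palindromic ring model

`build_palindrome(k)` returns `T_k…T_1 C T_1…T_k`; `palindrome_to_rings`
reads outward from the center, giving `k + 1` concentric zones. The default
`k = 5` matches an 11-feather row (five structurally distinct follicle
types per side of the central feather) and yields the 6 zones of an
ocellus. Zone labels are abstract; colors are presentation-only. The model
is structural: no cellular induction, invagination dynamics, or optics are
simulated.

## The synthetic-specimen generator

Each specimen samples a row count (uniform on {17, 18, 19} for
*P. cristatus*; fixed 19 for *P. muticus*), fishtail rows on {3, 4}, minor
rows on {2, 3}; takes the deterministic lattice prediction per class;
removes eyespot feathers by independent per-feather Bernoulli damage
(default rate 0.05 — small, since most count spread comes from age classes);
and draws ESL/FTL lengths from zero-truncated Normals at the published
summary means/SDs (cristatus 112.68 ± 25.58 / 134.15 ± 32.17 cm; muticus
101.66 ± 25.53 / 120.16 ± 29.49 cm). Records carry both the damaged
(observed) and intact (damage-corrected) eyespot counts, since museum
counting conventions for broken feathers are ambiguous. Summaries report
N/Mean/SD/Min/Max per species with the sample SD (`n − 1`; defined as 0 for
a single record).

What the generator emulates: the marginal summary statistics and the
age/damage structure of count variation. What it does not: correlations the
real data may contain (age–length coupling beyond the row count,
seasonality of molt, non-independent feather damage, measurement error).
Passing tests therefore validate the model's internal logic and its
consistency with the published summaries, not the museum data themselves.

## Determinism and problem sizes

All stochastic paths take an explicit integer seed (`numpy.random.
default_rng`); identical seeds give bitwise-identical CSV output. SVG output
is generated with fixed number formatting and is byte-stable. The test suite
and the acceptance script use an 18-row default plate (189 follicles, 126
eyespot-class points), 10,000 specimens for the row-count emulation, 1,000
individuals per age cohort for the variance check, and brute-force oracle
comparisons on random instances of up to 50 points.

## Known limitations

* 2-D only: the flat frontal projection of the fan, not the convex
  3-D train surface (positions, not depths, are the modelled quantities).
* No feather-shaft/barb geometry, iridescence, or spectral color.
* The 11/11 zigzag cannot be simultaneously mirror-symmetric and fully
  half-pitch staggered (parity argument above); the implementation keeps
  symmetry and documents the midline exception.
* No fitness or mate-choice modelling: eyespot counts and lengths are
  produced, their behavioral consequences are out of scope.
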