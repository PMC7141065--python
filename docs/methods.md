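# Methods

This note documents the models and procedures scanpathkit implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Scanpath strings

A *scanpath* is the ordered sequence of AOI labels visited by one
participant's fixations on one stimulus. AOIs are axis-aligned rectangles,
treated as **half-open** (`[x0, x1) × [y0, y1)`) so that AOIs tiling a
stimulus never double-claim a point; ties on shared edges go to the
rectangle whose interior lies to the right/below. Assignment returns the
first containing AOI in definition order, or an off-AOI sentinel.

Fixations landing outside every AOI are **dropped** by default when building
the string (the `keep` policy retains the sentinel token for sensitivity
analyses). A consequence, chosen deliberately: two fixations separated by a
dropped off-AOI fixation count as adjacent, so transition totals stay
consistent with string length.

*Truncation* collapses each maximal run of equal consecutive tokens to one
token. It is idempotent, never lengthens a sequence, and removes exactly the
information that self-transitions carry — which is why transition analysis
operates on un-truncated strings and distance analysis defaults to raw
strings as well (truncation is an explicit preprocessing flag). Note that
truncation is not distance-contracting in general; no such relation is
assumed anywhere.

## Levenshtein comparison

Scanpath dissimilarity is unit-cost edit distance (insertion, deletion,
substitution), computed by the standard two-row dynamic programme. It is a
true metric on token sequences. All-pairs matrices over the participants of
one stimulus are symmetric with zero diagonal; for display they are divided
by their maximum ("max-normalized"), mapping into `[0, 1]` while preserving
entry ordering. A degenerate all-zero matrix is left unchanged and only
flagged, avoiding 0/0.

Because raw Levenshtein distance is bounded below by the length difference
of its arguments, heavy-tailed scanpath-length distributions dominate
pairwise distances; this matters for power, see *Limitations*.

## Dwell grids from DBSCAN core points

To segment a stimulus without researcher-imposed regions, pooled fixation
positions (per stimulus, both groups together — one shared grid is what
makes per-cell group comparison meaningful) are scanned over a descending
ladder of candidate radii (default 64, 48, 32, 24, 16, 12, 8 px) with
DBSCAN's core-point rule: a point is *core* if at least `min_pts` points
(default 5, itself included) lie within `eps`. Core-point existence is
monotone in `eps`, so the candidates are probed smallest-first and the first
success is returned; if none succeeds the largest candidate is used with a
warning. The grid's base cell dimension is the **core-point diameter**
`2·eps*`; cell counts are `floor(extent / base)` (at least 1) per axis, and
cells are stretched to tile the stimulus exactly, so cells may be
rectangular but each side is at least the base dimension.

Each fixation's full duration is added to the single cell containing its
position (cells half-open, the stimulus's right/bottom edge belonging to the
last cell); durations are not splatted or weighted. Out-of-bounds fixations
are counted and tallied separately so total duration is conserved exactly.
DBSCAN clustering itself is delegated to scikit-learn; tests verify it
against an independent O(n²) neighborhood-expansion reference.

## Transitions

`counts[a][b]` tallies adjacent token pairs, self-pairs included, so one
scanpath of n tokens contributes exactly n − 1 transitions and aggregate
totals equal Σ(nᵢ − 1). Edge lists for chord diagrams keep a chosen label
subset (e.g. the four anterior leads), include self-loops, omit zero counts,
and are deterministically ordered (source then target, alphabet order).

## Group statistics

All group comparisons are two-sided Mann–Whitney U tests. The reported
statistic **W is the U of the first sample** — the number of (xᵢ, yⱼ) pairs
with xᵢ > yⱼ, ties counting ½ — matching R's `wilcox.test`, so
`W(x,y) + W(y,x) = n_x·n_y`. Exact enumeration is used when both samples
have ≤ 8 observations and no ties; otherwise the normal approximation with
continuity and tie correction (scipy's implementation behind the module
surface). When every pooled value is identical the test is degenerate and
p = 1 by convention. The continuity-corrected approximation is slightly
conservative at very small n; calibration checks therefore run at sample
sizes in the asymptotic regime (n = 40 per group).

Per-AOI duration tests pool **individual fixation durations** by group
within each AOI — the observation unit that makes rank statistics in the
thousands attainable — and are judged at the Bonferroni-adjusted level
α/m over the m AOIs of the stimulus (0.05/13 ≈ 0.004). AOIs that one group
never fixated are flagged untestable rather than failing the family.

The scanpath-distance comparison supports two observation units:

- `per-participant-mean` (default): each participant contributes the mean
  Levenshtein distance to their *same-group* peers (requires ≥ 2 per
  group);
- `pooled-pairs`: all within-group pairwise distances are the observations
  (n(n−1)/2 per group; these are not independent, so its p-values are
  approximate and it is mainly useful descriptively).

Both are provided because summary statistics reported for analyses of this
kind cannot always be reproduced from group sizes under either unit; the
choice is exposed rather than guessed.

## The synthetic-data generator

Every analysis is exercised on generated data with known truth. One
participant's viewing of one stimulus is simulated as:

1. scanpath length ~ rounded lognormal, moment-matched to mean 23 visits,
   SD 18.25 (mode ≈ 11, heavy right tail), minimum 1;
2. AOI sequence from a first-order Markov chain over the 13-AOI layout
   (12 leads in a 4×3 block, full-width rhythm strip at the bottom,
   labels A–M in reading order, default 1280×960 px);
3. fixation duration ~ lognormal, moment-matched to mean 312.97 ms,
   SD 384.86 ms (the only per-fixation duration moments available to anchor
   on; the lognormal family is a modeling choice, exposed as config);
4. position: with probability `p_uniform` (default 0.2) uniform in the
   current AOI, otherwise Gaussian around the AOI-centre hotspot
   (sd = min(side)/6), clipped strictly inside the half-open rectangle;
5. onsets cumulative with a fixed 30 ms saccade gap, hence strictly
   increasing.

Seeding is hierarchical: master seed plus a CRC-derived per-participant
offset, so datasets are byte-reproducible and adding participants never
perturbs existing ones.

The default transition structure is a *systematic reader*: dwell 0.45,
advance to the next AOI in reading order 0.35, backtrack 0.08, re-check the
rhythm strip 0.12, with structural zeros elsewhere — targeted saccades, not
uniform teleporting. Structural sparsity is also what makes the
transition-frequency recovery check meaningful: with ~770 visits per row in
a 10,000-fixation run, a 13-state row with mass spread over all cells has an
expected empirical-vs-true discrepancy of ≈ 0.07 in L1 regardless of
implementation correctness (binomial noise, `E[L1] ≈ 0.8·Σ√(pᵢ(1−pᵢ))/√N`).
Recovery is therefore measured in **total-variation distance** (half the
L1), the standard distance between discrete distributions, with tolerance
0.05 on rows visited ≥ 500 times; the sparse default rows sit at
E[TV] ≈ 0.02.

The "incorrect interpreter" analogue is produced by **blending the
transition matrix and initial distribution toward uniform**:
`T' = (1−λ)·T + λ·U`. The blend λ is the separation dial: λ = 0 duplicates
the reference model, λ = 1 is a uniform random walker; within-group
Levenshtein distances grow with λ. Group-specific attention hotspots (for
dwell-grid experiments) are produced by re-weighting transitions into one
AOI.

### The power-study configuration

Group-separation experiments (detection of the built-in direction at
λ = 0.6 with 15 participants per group) use a dedicated, documented model
pair, `power_study_models()`: start fixed at the top-left AOI, advance 0.90,
dwell 0.05, backtrack 0.05, **no rhythm-strip rechecks**. The last exclusion
is a first-order-chain artifact, not a claim about behaviour: after a strip
visit a memoryless chain cannot resume the interrupted position, so strip
rechecks phase-shift the remainder of the sequence and misrepresent a
systematic reader as noise.

## What the generator does and does not emulate

It reproduces the structural features the analyses depend on: group sizes,
the 13-AOI layout, heavy-skewed scanpath lengths, lognormal durations,
Markov transition behaviour with a controllable group difference, and
clustered fixation positions. It does **not** emulate saccade trajectories,
pupil data, drift/calibration error beyond uniform position noise,
participant-level expertise heterogeneity within a group, or the clinical
content of different ECG conditions. Passing tests therefore demonstrate
correctness of the computations and detectability of generator-built
effects — not that real correct/incorrect interpreter groups will separate
at these sample sizes.

## Numerical choices and degenerate inputs

- Matrix CSVs are written at full `repr` precision and re-read with
  round-trip float parsing, so write/read is lossless.
- Length-summary mode breaks ties toward the smallest attained length; SD
  uses the n−1 denominator and is 0 for n = 1; range is the single number
  max − min.
- `normalize` on an all-zero matrix returns it unchanged (flag set).
- Empty fixation lists yield empty scanpaths; empty point sets yield empty
  cluster labelings; a core-point search with no qualifying candidate falls
  back to the largest radius with a warning, and an oversized base dimension
  falls back to a single-cell grid with a warning.
- Invalid fixation rows (non-numeric fields, duration ≤ 0, onset < 0, or
  onsets that do not strictly increase within a participant × stimulus) are
  reported with line numbers and skipped, never fatal.

## Known limitations

- **Distance-based group detection is length-noise limited.** Because
  `d(a,b) ≥ |len(a) − len(b)|` and lengths are heavy-tailed (SD 18.25 at
  mean 23), a single long-scanpath draw shifts a whole group's within-group
  distance observations. At λ = 0.6 and n = 15 per group the direction
  (blended group more dissimilar) is detected in roughly 85% of seeded
  replicates under the power configuration — and even replacing the
  reference group by an idealized deterministic reader (distance exactly the
  length difference) caps the rate near 92–98% depending on the observation
  unit. Reliable detection at these sample sizes needs either tighter length
  distributions or length-normalized dissimilarities, both outside the
  present method's definition.
- Pooled-pairs observations are dependent; treat that unit's p-values as
  descriptive.
- The DBSCAN-derived cell size reflects the tightest local density anywhere
  on the stimulus; with tight synthetic hotspots the ladder typically
  bottoms out at its smallest radius, producing fine grids.
- First-order Markov scanpaths cannot represent "return after interruption"
  behaviour; see the power-study note above.
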