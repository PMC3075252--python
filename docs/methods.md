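# Methods

## Model and assumptions

`pantracks` treats a species' distribution as a graph-theoretic object: the
minimum spanning tree (MST) over its occurrence points under **planar
Euclidean distance in decimal-degree space**. This is a deliberate fidelity
choice, not an oversight: the congruence thresholds users supply (cut
value, `lmin`, `lmax`, `lmax.line`) are themselves degrees in the flat
lon/lat plane, and reference configurations (e.g. cut = 2°, lmin = 2.5°)
are only meaningful there. Consequences: distances are distorted away from
the equator, and data straddling the antimeridian are not handled. A
geodesic mode is explicitly out of scope.

Generalized tracks rest on the assumption that co-distributed species
leave spatially congruent MSTs. Congruence is decided segment-by-segment,
entirely from the four endpoint projections between a segment pair — the
method never measures interior-to-interior distances except in one case
(below). Detection of *nodes* (intersections of generalized tracks) is out
of scope.

## Parameters

| parameter | units | meaning |
|---|---|---|
| `cut_value` | degrees | points closer than this collapse to one before MST construction |
| `lmin` | degrees | rule-1 bound on the minimum inter-segment distance |
| `lmax` | degrees | rule-1 bound on the maximum inter-segment distance |
| `lmax_line` | degrees | rule-2 bound on the full-overlap perpendicular distance |
| `min_si` | fraction | similarity threshold at which two tracks merge |

The constraint `0 ≤ cut ≤ lmin ≤ lmax ≤ lmax.line` is enforced before any
data is read; each violation is reported naming the specific inequality.
There are **no default distance parameters**: they are data-scale
dependent, and silent defaults on degree-scale thresholds produce nonsense
on continental data. All five must be supplied to `pantracks run`.

## Geometric and numerical choices

- **Foot detection.** The projection parameter t of a point onto a segment
  counts as a foot in the closed interval [0, 1] with tolerance 1e-9
  degrees, so segments sharing a vertex touch rather than knife-edge-miss.
  The same 1e-9 is added to every threshold comparison; it exists for
  cross-platform reproducibility, not as a scientific tuning knob.
- **dmin is the true inter-segment minimum.** The four endpoint
  projections overestimate the minimum when segments properly cross (the
  true minimum, zero, is interior), so crossing pairs — detected by an
  orientation test — get `dmin = 0`. This preserves the identity
  "`dmin` = 0 iff the segments intersect or touch". `dmax` needs no such
  repair: the pair maximum is always attained at an endpoint.
- **`dmax.line` side selection.** Full overlap can hold in both directions
  at once; the smaller of the two side-maxima is used — the most
  permissive reading consistent with the rule being an OR over directions.
- **Degenerate segments** (zero length) are treated as points: they can
  satisfy rule 1 but never produce full overlap. They cannot occur inside
  tracks (exact duplicates are merged before MST construction) but are
  handled for API robustness.
- **Rule order.** Rule 2 is tested before rule 1 purely for reporting;
  the congruent/not-congruent outcome is order-independent.
- **Deduplication** is a greedy single pass in input order keeping the
  first point of each cluster (original coordinates, no centroids): this
  makes the operation order-deterministic and idempotent, applied within
  each species only.
- **MST determinism.** Kruskal over edges sorted by (weight, i, j): among
  equal-weight edges the lexicographically smallest index pair wins. This
  is load-bearing — the end-to-end contract is byte-identical KML for
  identical inputs.

## Pipeline scheduling

The source method does not pin down a merge order, so the pipeline uses a
reproducible two-phase schedule: (1) every unordered species pair is
compared in input order and each congruent pair emits a candidate
generalized track (MST over the congruent segments' endpoints only —
collecting full vertex sets would make the SI reduction vacuous);
(2) candidates are reduced at a fixed point: while any pair satisfies
`si_max ≥ min_si`, the highest-`si_max` pair (ties by lexicographic taxa)
is replaced by one MST over the union of their vertices. Each merge
strictly decreases the candidate count, so termination is guaranteed; at
the fixed point no two surviving tracks are redundant at the threshold.

Two deliberate refinements:

- A reduction merge additionally requires `si_max > 0`: with
  `min_si = 0` the bare threshold would join fully disjoint candidates,
  whereas the intended behaviour is collapsing the connected components of
  the congruence graph.
- SI numerators count an edge's whole length once it is congruent with any
  edge of the other track (no partial-length proration), matching an index
  defined as a sum of congruent segment lengths.
- A final sweep discards any track whose taxa are a proper subset of
  another's with SI toward it ≥ `min_si`. After the fixed point this is
  provably vacuous (no pair retains `si_max ≥ min_si`); it is kept as a
  cheap guard should the scheduling ever change.

A merged track's later comparisons use the *new* MST's edges, not the
original species' edges; on real data this can yield different final track
counts than schedules that re-compare against untouched individual tracks.

## Input and output conventions

Input rows are `taxon, latitude, longitude` (delimiter auto-detected per
file: comma, tab, or whitespace); KML emits `lon,lat,0`. The axis swap
between the two conventions is explicit in the code and pinned by tests.
Malformed or out-of-range rows are collected with line numbers into a
validation report and never abort a parse unless every row fails. Taxon
names match as exact strings; names differing only in case or underscores
are warned about, never merged. Tracks are written as MultiGeometries of
two-point LineStrings because an MST branches and a single LineString
cannot represent it. KML output is checked structurally (well-formed XML,
KML 2.2 namespace, folder/placemark/coordinate structure) and by a
six-decimal round-trip; no offline XSD validator is available in the
supported environment.

## Synthetic benchmark

The generator states a world of linear corridors: each corridor is a
polyline, each of its species is sampled uniformly by arc length and
perturbed by isotropic Gaussian jitter (per-component sd, in degrees;
Gaussian chosen as the conventional noise model). A `span` variant
restricts a species to part of its corridor, producing the sub-tracks that
make the SI genuinely asymmetric. The built-in benchmark uses three gently
bent corridors of length ≈ 10.1° (a continental-scale corridor), 50°
apart, 10 species × 30 points at jitter 0.1°, with analysis parameters
cut 0.2, lmin 0.5, lmax 0.8, lmax.line 1.0, min-SI 0.8 — chosen once at
the scale of that world. What a green recovery establishes: the geometry,
merging and reduction logic recover planted structure when corridors are
unambiguously separated. What it does not: robustness to spatially biased
sampling, range edges, or niche structure, none of which the generator
emulates.

One caveat is quantified rather than hidden: a recovered track's vertex
set contains essentially all ~300 jittered points of its corridor, so the
maximum vertex-to-corridor deviation behaves like the maximum of hundreds
of half-normal draws, E[max] ≈ σ·√(2 ln 2N) ≈ 3.6 σ. A per-point 3 σ
acceptance band on the directed Hausdorff distance is therefore expected
to be exceeded at most seeds; the corresponding check is kept at its
stated bound and fails honestly (≈ 0.36° vs 0.30° at the fixed seed)
while track count and taxa purity are exact.

## Known limitations

- Planar degrees only; no geodesics, projections, or antimeridian logic.
- All-pairs segment comparison is O(E₁·E₂) per track pair (vectorised);
  very large datasets rely on the cut value to control MST sizes.
- The reduction schedule is one defensible determinisation of an
  underspecified procedure; other schedules can produce different (equally
  defensible) generalized-track counts on real data.
- Node detection and statistical support for generalized tracks are not
  implemented.
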