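# Methods

This note records the models and algorithms pedivis implements, the
assumptions behind them, the defaults that matter, and what the test suite
does and does not establish.

## Pedigree model and validation

A pedigree is a directed acyclic structure over individuals with optional
mother/father links; founders have both parents missing. Ingestion
normalises sex codes ({1, M, male} / {2, F, female}, anything else
unknown) and missing-parent codes ("", "0", "NA") to a single internal
sentinel, so CSV and PLINK `.fam` inputs behave identically downstream.

Validation reports rather than throws: self-parenting, a named parent of
the wrong recorded sex, parent ids absent from the table, ancestry cycles,
and twin groups that are singletons or mix parents or zygosity codes. A
parent of *unknown* sex occupying a mother/father slot is a warning, not
an error — unknown-sex individuals are legal everywhere, and the slot
itself carries the needed information. Cycle detection is a hard error
because generation leveling diverges on cyclic input.

Founder padding (`both_or_none`) gives each single-parent individual a
synthetic opposite-sex co-parent, one per half-sibship, flagged
`placeholder` so renderers draw them semi-transparent. The connection
geometry assumes two-parent matings; padding makes that uniform.

Family labels are connected components of the graph whose edges are
parent-child links and co-parent links. The component containing the
smallest personID (string order) gets label "1", the next "2", and so on:
labels are reproducible across runs and row orders.

## Kinship and relatedness matrices

Kinship uses the classical recursion, evaluated in topological
(parents-first) order with the full matrix memoised:

    phi(i,i) = (1 + phi(m_i, f_i)) / 2
    phi(i,j) = (phi(m_i, j) + phi(f_i, j)) / 2,   j not a descendant of i

with phi against a missing parent equal to 0. Founders are assumed
non-inbred and mutually unrelated; there is no provision for founder
kinship input. The additive (numerator) matrix is 2·phi elementwise; its
diagonal is 1 + F with F the inbreeding coefficient. Complexity is O(n²)
time and memory, adequate for tens of thousands of individuals.

The mitochondrial matrix is the indicator of a shared matrilineal founder
(follow mother links to the top). Its unit entries form an equivalence
relation, so the matrix is block-diagonal under a permutation grouping
matrilines — the property the heatmap and highlighting features exploit.

As an independent cross-check (not a production path) the package ships a
gene-dropping Monte-Carlo estimator: two uniquely labelled alleles per
founder, uniform transmission, identity-by-descent sharing averaged over
replicates, with per-entry standard errors. The test suite compares the
recursion against it on random small pedigrees. Note that a "within k
standard errors everywhere" comparison is a per-entry confidence
statement: over thousands of entries a few chance exceedances of 3 s.e.
are expected even when the recursion is exact (it is), which is why the
unit suite uses a 4 s.e. screen.

## Layout

A layered (Sugiyama-style) pipeline replaces per-family recursive
placement, trading exact-optimal crossing minimisation (NP-hard) for
determinism and speed:

1. **Leveling.** Founders at generation 0; each child one row below its
   deepest parent (longest-path leveling); mating partners lifted to a
   common row; both rules iterated to a fixpoint and normalised to start
   at 0 per family. Partner equalization is skipped when one partner is an
   ancestor of the other (a parent-child mating cannot share a row with
   itself one row down); such spouse links are drawn as cross-row arcs.
2. **Ordering.** Sibships are kept contiguous, married-in spouses pulled
   next to their partner, blocks seeded by the parents' mean position.
   Barycenter sweeps (one down pass + one up pass per sweep, at most 4
   sweeps) reorder rows by mean neighbor position; a sweep that does not
   reduce the crossing count is rolled back, so the count is
   non-increasing. All ties break by ascending personID: the layout is a
   pure function of the table.
3. **Loop breaking.** A person with several matings keeps their primary
   symbol beside the mating whose children are drawn first; each further
   mating whose partner is not already adjacent gets a dashed duplicate
   symbol inserted beside that partner. Duplicates share the personID,
   carry `duplicateIndex >= 1`, and are marked in the rendering.
4. **Coordinates.** x is the ordinal slot (unit spacing) within the row;
   a single bottom-up pass slides each adjacent mating pair so its
   midpoint sits over its children's centre, clamped to preserve >= 1.0
   spacing to neighbours (pairs are processed left to right, so a
   rightmost pair yields; a spouse shared with an already-centred pair is
   not moved again). Children are never moved under their parents — the
   deepest generation keeps its slot order, which can leave a bottom-row
   only child left of its parents' midpoint; the sibship bar bridges the
   offset. Families are laid out independently and tiled horizontally
   with a 2.0-unit gutter.

## Connections

Per mating: a horizontal spouse segment between the two serving symbols, a
vertical drop from their midpoint to the sibship bar at
`childRow - barOffset` (default 0.35 units), a bar spanning the children's
stubs (extended to the drop point if the drop lands outside; emitted only
when there are >= 2 children or the single child is offset from the
midpoint), and one vertical stub per child. Co-twins' stubs become
diagonals converging to one apex on the bar; monozygotic pairs add a tie
joining the diagonals at mid-height, dizygotic pairs do not. Because
matings are derived from co-parenthood, a childless couple produces no
segments — marriage records without offspring are not representable in
the tabular input.

Overlap resolution replaces any spouse or drop segment passing within
`nodeClearance` (default 0.25 units) of a non-member symbol — and any
drop sharing a vertical corridor with an earlier drop (ordered by mating
id) — with a one-control-point quadratic Bezier whose control point sits
`curveOffset` (default 0.3) to the freer side (ties bow left; spouse
segments bow above the row). A quadratic with a single control point is
the minimal curve every backend supports. The defaults are package
choices, exposed in the configuration.

## Rendering

Standard human-pedigree nomenclature: squares male, circles female,
diamonds unknown; filled symbols affected; placeholders semi-transparent;
duplicates dashed with a repetition mark. Both backends consume one shared
draw list, so static and interactive geometry are identical by
construction; the static backend returns a live matplotlib `Figure`, the
interactive one a self-contained SVG + JavaScript HTML document with
tooltips, wheel zoom and drag panning, written by this package and
requiring no network or runtime dependency.

The configuration schema has 176 documented leaf parameters in nine groups
(symbols, lines, labels, highlight, layoutParams, interactive, canvas,
heatmap, pbd). Every leaf is typed with a default; unknown keys fail with
a nearest-name suggestion; a config round-trips losslessly through YAML;
dotted-path overrides are accepted on the command line.

## Heatmaps and phenotype by degree

Clustered heatmaps use average-linkage agglomerative clustering on the
distance `max(0, 1 - r)` (clamped because inbred diagonals exceed 1) and
reorder rows and columns by dendrogram leaf order — exactly a permutation
`P M Pᵀ` of the input.

`phenotype_by_degree` enumerates unordered within-family pairs with both
phenotype values present, bins them by relatedness (exact grouping, or
snapping to the nearest power of two within 1e-6), and per bin reports the
double-entered Pearson correlation — each pair entered both ways, so the
estimate is symmetric in pair order — with a 95% interval from the Fisher
z transform using the number of *unique* pairs: `atanh(r) ±
1.96/sqrt(n-3)`. Double entry removes role asymmetry; doubling n would
understate uncertainty. Bins with fewer than `minPairs` (default 4) pairs
carry no interval; zero-variance bins report an undefined correlation
without failing; if no bin is estimable the call errors.

Under a purely additive model the expected bin correlation is
relatedness × h², e.g. 0.30 in the first-degree bin at h² = 0.6.

**Known limitation.** The Fisher-z interval assumes independent pairs.
Relative pairs drawn from one connected pedigree share members, and that
pseudo-replication makes the interval anti-conservative: empirically,
coverage on a single 60-couple population is ~80% rather than 95%. The
calibration test therefore uses the classical one-pair-per-family design
(phenotype observed on one parent and one child per nuclear family),
where the assumption holds and measured coverage is ~95%. Interpret
intervals from densely sampled pedigrees as lower bounds on uncertainty.

## Synthetic data generator

The generator grows a population forward in time: `foundingCouples`
couples at generation 0; each couple's offspring count Poisson
(`meanOffspring`, default 2.5); fair-coin sex; each new adult mates with
probability `pMate` (default 0.8), choosing a same-generation
within-pedigree partner with probability `pCousinMarriage` (default 0.05,
full sibs excluded) and otherwise a new immigrant founder; a sibship
contains a twin pair with probability `twinRate` (default 0.02),
monozygotic with probability `pMZ` (default 0.4, same sex enforced). The
generator is a pure function of its parameters, and every output passes
validation with zero errors.

Phenotypes follow the additive polygenic model: founder breeding values
N(0, h²); a child's breeding value is the parental midpoint plus
Mendelian-segregation noise with variance `h²/2 · (1 - (F_m + F_d)/2)` —
inbred parents transmit less segregation variance, which keeps h²
recovery unbiased under consanguinity — plus environment N(0, 1 - h²),
so the population phenotypic variance is ~1.

What the generator does *not* emulate: mortality and age structure,
assortative mating, shared-environment effects, dominance or epistasis,
X-linkage, genotyped markers. Passing tests therefore demonstrate
correctness of the algorithms under the additive random-mating model, not
robustness to those real-data features.

## Problem sizes used in the test suite

Chosen to exercise the algorithms at meaningful scale while keeping the
suite quick: the throughput check renders a ~1,200-person pedigree
end-to-end; layout/connection invariants run over 200 random pedigrees;
oracle agreement uses 50 pedigrees of <= 15 people at 10^5 gene-dropping
replicates (fixed seed 20240101); heritability recovery uses a 500+
person pedigree and CI coverage 200 replicates of 100 families each.
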