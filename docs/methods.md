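# Methods

This note documents the models, parameters and numerical choices behind
`cascadehor`, and what the synthetic fixtures do and do not establish about
real centromeric data.

## Divergence and monomer families

Divergence between two sequences is defined as
`100 · editdistance(a, b) / max(|a|, |b|)` under a global (end-to-end)
alignment with unit costs (edlib). Normalising by the longer sequence length
rather than by an alignment length makes the metric independent of which
co-optimal alignment a library happens to return, and makes it checkable
against a plain dynamic-programming oracle (the test suite does this to
1e-9 on hundreds of random pairs).

Families are cut from an average-linkage dendrogram at the 5% threshold.
The 5% rule ("monomers under 5% divergence are the same type") reads as a
clique condition, but strict complete linkage is brittle when variant
monomers sit near the threshold; average linkage approximates the clique
reading while tolerating single outliers. Linkage is configurable
(`single | average | complete`). The all-vs-all matrix saturates entries
above a 15% search cap to 100 by default — far above any clustering
threshold in use, so no family decision changes, but the edit-distance
search can abandon early.

Each family consensus is a star alignment: members are globally aligned
onto a member of median length, bases are tallied per reference column
(with one slot for single-base insertions after each column), and the
majority symbol wins; base ties break alphabetically and gap-majority
columns are dropped. For members under 5% mutual divergence this is
essentially exact; multi-base insertions are truncated to their first base,
a simplification that matters only above the divergence regime families
can contain.

## Tiling phase

Tiling a tandem region at its base period requires choosing the offset of
the first monomer boundary (the *phase*). The phase matters structurally: a
frame cut mid-monomer turns a cascading 15mer of 9 types into a consistent
but wrong annotation with 11 junction types. Three facts drive the design:

* periodicity evidence begins at the array's first monomer, so the region
  start anchors the frame to within a few bp;
* among nearby offsets, the boundary-aligned one minimises the number of
  monomer classes (junction frames manufacture extra types);
* within the remaining plateau of class-count ties, the total within-class
  column disagreement is exactly zero at the true boundary of a noise-free
  cascading array, and near-minimal at low noise.

The selector therefore searches only offsets within ±8 bp of the region
start and ranks them by (class count, column disagreement, distance to the
region start). For Willard's arrays every offset ties and the frame is
genuinely conventional — any rotation of the type labels is an equally
valid annotation, and reported quantities (n, τ, copy count) are invariant
to it. Residual phase error is zero at zero divergence and a few bp at 1-2%
divergence; indel-driven drift further down an array produces rotated
duplicate families, which are detected by cyclic consensus comparison
(infix alignment against the doubled consensus) and dropped before the
scan re-anchors every boundary.

## Scanning

Every kept family consensus is searched over both strands of the whole
assembly by iterative best-hit extraction: edlib's infix mode reports all
loci tied at the current best edit distance; they are masked and the search
repeats until the best distance exceeds the acceptance bound. A hit is
accepted when `100·d / max(|consensus|, span) ≤ 25%` — within-type
divergence is below 5% and between-type divergence above 20%, so 25%
accepts true monomers of a known family while rejecting flank noise.
Overlaps resolve greedily by ascending divergence, then leftmost position,
then lowest family id; a candidate overlapping an accepted instance is
trimmed to the free interval and kept only if ≥80% of the consensus length
survives, which preserves the tandem tiling when neighbouring alignments
disagree by a few bp. Families with fewer than 3 members are reported but
excluded from scanning: a 1–2 member "family" is typically an outlier
monomer whose consensus would always win back its own locus and corrupt
the type sequence there.

Tandem enumeration numbers instances 1..N in genomic order when the gap to
the nearest neighbour is at most half a monomer length; isolated instances
stay in the track unnumbered. Enumeration runs across inter-array gaps, but
gaps wider than 10 monomer lengths are recorded as array breaks.

## MD series and period support

Each enumerated monomer's MD period is the index distance to the next
monomer of its family (absent for final occurrences). Arrays are detected
per break-delimited span: the primary period n is the *largest* period
holding at least 20% of the span's MD points. The largest-eligible rule
matters for cascading HORs — in a canonical 15mer only 5 of 15 monomers
carry the full period 15 (~33% of points) while the subfragment period 4
holds ~40%, so "most supported" would misreport the unit.

Subfragment periods (p < n) must recur copy for copy: the threshold is a
count of at least 0.5 × (span monomers / n), i.e. half the estimated copy
number. A fraction-of-points rule cannot work here: in a canonical 20mer
exactly one monomer per copy carries period 15, so its support converges to
1/20 of points *from below* and any ≥5%-of-points cut excludes a genuine
subfragment. Secondary periods (p > n) need at least 6 points and 1% of
the span's MD points, with less support than the primary — enough to keep
the 34-monomer doublet tertiary repeat (~4% of points in the 25mer array)
while discarding stray distances.

## Canonical units, copies, schemes

The canonical unit is the most frequent cyclic equivalence class of
n-grams of the span's type sequence. Rotation is fixed in two steps: the
anchor is the earliest occurrence of the class that starts a tandem
repetition, and for single-unit arrays the rotation is then refined to the
one whose segmentation yields the fewest copies — the frame in which
variant copies are contiguous sub-blocks of the unit rather than split
fragments. If a second non-equivalent class of length n±1 has at least 10%
of the primary class's support the array is interspersed and both units
are reported; windows that are merely a unit-plus-duplicated-edge slide
over an existing unit's tandem run are not counted as units.

Copies are segmented greedily: exact unit occurrences (longest unit first)
are canonical; leftover stretches split into variants at occurrences of
the unit's start type. Anchoring *only* on the start type would be wrong
for cascading HORs — the canonical 15mer itself contains two monomers of
its start type, so canonical matches must take precedence.

The cascading scheme places each copy's monomers in the column of their
type (types t1..tτ by order of first appearance) and starts a new row
whenever the next type index does not exceed the current one (m ≤ k). The
break-on-equality reading is required: the narrative rule "a monomer of a
type already placed in the current row moves to the next row" alone would
not break rows on strictly decreasing transitions, and m < k alone would
not break on immediate type repeats; m ≤ k satisfies both descriptions and
reproduces the four-row 15mer and two-row 20mer layouts.

## The synthetic generator

Monomer type libraries descend from one random ancestor at a substitution
rate calibrated so pairwise inter-type divergence lands around 27%
(within the observed 20–40% band); rejection sampling enforces the
configurable ≥20% floor. Array emission mutates each monomer independently
at the requested within-type rate, with 1% of mutation events as
single-base indels so scanning must tolerate length jitter. Flanks are
i.i.d. uniform A/C/G/T, guaranteeing no spurious periodicity; truth
coordinates are 0-based half-open on the emitted forward strand. All
randomness flows through per-function seeded generators, so identical
seeds give byte-identical fixtures; the generator functions use distinct
stream tags so that a library and an assembly built with the same seed do
not share a random stream.

What the fixtures do not emulate: real alphoid base composition (flanks
and types are uniform-composition — the AT-richness and CENP-B boxes of
real alpha satellite are absent), shared conserved blocks between monomer
types (inter-type divergence here is i.i.d., so the raw ~171 bp spectrum
peak is weaker than in real arrays), higher-order homogenisation gradients
along arrays, and assembly artefacts. Passing tests therefore establish
correctness of the inference machinery under the stated divergence regime,
not performance on real centromeres.

## Problem sizes and defaults

The shipped analyses use 50-copy zero-divergence arrays for the 15mer and
20mer reconstructions (750 and 1000 monomers), the 48-copy doublet 25mer
array (1152 monomers), a 60-copy 65/35 canonical/variant mix at 2%
divergence for noisy recovery, and a four-array chromosome-15-like
assembly of ~1 800 monomers (~360 kb); each runs in seconds to tens of
seconds. Key defaults: word length 12 and search window 6 000 bp for the
raw spectrum (the window must cover the largest HOR, 34 × 171 ≈ 5.8 kb);
target period 171 ± 10 bp; family threshold 5%; scan acceptance 25%;
primary support 20%; subfragment copy-fraction 0.5; secondary support 1%
with ≥6 points; regions need 50 enumerated monomers. Raw-spectrum peaks
are called above `max(10, median + 5·1.4826·MAD)` — a robust floor chosen
because a handful of genuine tall peaks would otherwise inflate a
mean/SD-based cutoff, and an all-zero null would collapse it.

## Known limitations

* Absolute monomer phase is conventional for Willard's arrays and accurate
  to a few bp elsewhere; reported boundaries inherit that uncertainty.
* Interspersed arrays report copy counts per unit, but rotation refinement
  is disabled there, so copy boundaries at 25/26mer junctions follow the
  tandem anchor rather than a parsimony criterion.
* The track TSV does not persist array-break annotations; the `hor`
  subcommand reconstructs them from genomic gaps.
* Arrays that abut without an intervening gap are not split by
  change-point detection; the primary period of the merged span wins.
* IUPAC ambiguity codes are treated as mismatches throughout.
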