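# cascadehor

Discovery and structural annotation of alpha-satellite higher-order repeats
(HORs) in genomic assemblies — including *cascading* HORs, whose canonical
copies contain more than one monomer of the same type.

## The problem

Primate centromeres are built from ~171 bp alpha satellite monomers arranged
in tandem. Monomers within one HOR copy are highly diverged from each other
(roughly 20–40%), yet whole HOR copies repeat almost perfectly (<5%
divergence between copies). Monomers under 5% mutual divergence define a
*monomer type*; a HOR unit of *n* monomers drawn from *τ* distinct types is
an *n*mer. In classical Willard's HORs every monomer of a copy has a
distinct type (τ = n). In cascading HORs some types recur within the copy
(τ < n): for example a 15mer built from only 9 types, or a 20mer from 19
types. Interspersed arrays mix two closely related units (e.g. 25mers and
26mers sharing 22 of 29 types), and structured variant copies can create
repeat periods *longer* than the unit (a 34-monomer tertiary repeat from
deletion doublets).

`cascadehor` finds these structures de novo:

1. **Period spectrum** — for every position, the distance to the next exact
   occurrence of its k-word; tandem alpha satellite shows peaks at ~171 bp
   and multiples.
2. **Monomer candidates** — regions periodic at ~171 bp are tiled into
   candidate monomers, with the tiling phase chosen so that monomer classes
   are fewest and most internally consistent.
3. **Families** — an all-vs-all divergence matrix (global alignment edit
   distance, percent of the longer length) is clustered at the 5% threshold
   (average linkage); each family gets a star-alignment majority consensus.
4. **Scan** — the assembly is searched base by base with every family
   consensus on both strands; overlapping hits are resolved to the
   non-overlapping best-hit tiling and tandem monomers are enumerated 1..N.
5. **HOR structure** — the monomer-distance (MD) series assigns each
   enumerated monomer the index distance to the next monomer of the same
   type. Dense MD lines reveal arrays and their primary period n; supported
   periods below n are subfragments, periods above n are secondary/tertiary
   repeats. The canonical unit is the most frequent cyclic type subsequence
   of length n; copies are segmented and labelled canonical/variant; and the
   *cascading scheme* lays each copy out in rows aligned by type columns
   (a new row starts whenever the next type index does not increase).

A synthetic-assembly generator (`cascadehor.simulate`) plants monomer
libraries, canonical/variant copies, deletion doublets, strand flips and
random flanks with exact ground truth, and drives the test suite.

## Worked example

Simulate a 10-copy cascading 15mer array at 1% within-type divergence and
run the full pipeline:

```sh
cascadehor simulate --preset 15mer --seed 5 --copies 10 --intra-divergence 1.0 --out fix
cascadehor run fix.fa --out report
```

Output:

```
hor1: n=15 tau=9 copies=10 type=cascading subfragments=[4, 7, 11]
```

Read: one HOR array was found; its unit is 15 monomers long (n=15) but uses
only 9 distinct monomer types (τ=9), so it is a cascading HOR; all 10
planted copies were recovered; and the MD diagram shows subfragment periods
4, 7 and 11 — the distances at which repeated types recur inside and between
copies. `report/` contains the BED/TSV/JSON bundle: the monomer track,
MD series, monomer-level GRM spectrum, per-copy table and the cascading
scheme rendered as rows × type columns:

```
 t1 t2 t3 t4 t5 t6 t7 t8 t9
 m1 m2 m3 m4
```

The same pipeline stages are available individually (`spectrum`, `monomers`,
`families`, `scan`, `hor`), and `simulate --preset chr15-like` emits a
four-array assembly (Willard's 18mer, interspersed 25/26mer with deletion
doublets, cascading 20mer, cascading 15mer) for end-to-end exercise.

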