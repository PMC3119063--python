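# Methods

This note documents the models, algorithms, parameters and design choices
behind `strainpair`: what each stage assumes, why its defaults are what
they are, and what the simulation-based tests do and do not demonstrate
about real data.

## The comparison model

The package assumes two genomes that are *co-linear*: descended from a
recent common ancestor with no inversions or translocations, so that a
single monotone correspondence maps one chromosome onto the other. Under
that assumption the pair can be represented exactly as an alternating
series of **runs** — maximal segments that are character-identical at
corresponding positions — and **connectors** — the divergent sequence
pairs in between. A point substitution is a connector of length one on
each side; an indel has length zero on one side; a replacement has two
unrelated non-zero sides. Concatenating the sides of all elements in order
reproduces each input byte-exactly (the *tiling property*); this is
asserted in tests for every map the code ever builds.

### Unique-word anchoring

Runs are seeded only from words (k-mers) that occur **exactly once in each
genome**. This is the key to robustness against dispersed repeats: a
repeated word can never anchor, so a duplicated segment is matched only
through the unique words of its co-linear context, and extension ("as long
as the sequences remain identical") then absorbs the locally corresponding
copy. `N` never matches anything, so assembly gaps always surface inside
connectors.

Two phases:

1. **Scaffold** (`build_scaffold`): anchors from unique 15-mers are
   extended to maximal runs (vectorized per diagonal), the
   maximum-total-length strictly co-ordered subset is selected (weighted
   longest-increasing-subsequence on the partner coordinate, Fenwick
   prefix-maxima), and runs are accepted in decreasing length until their
   cumulative length first reaches 30% of the shorter genome (the crossing
   run included). The 30% is interpreted against min(|A|,|B|); at 98.6%
   identity the choice is immaterial because the accepted runs are the
   handful of longest ones either way.
2. **Refinement** (`refine`): each gap between accepted runs is processed
   recursively — find the longest acceptable unique-word run inside the
   gap pair, intercalate it, recurse on both flanks; a gap with no
   acceptable run becomes a single connector. Implemented with an explicit
   stack (gaps can contain thousands of events).

**Word-length schedule.** The classical formulation uses 3-mers in
refinement, but a unique 3-mer only exists in segments of roughly ≤ 200 bp
(64 word types); in a 10 kb gap every 3-mer recurs. Refinement therefore
starts at a word length scaled to the gap (⌊log₄ of the shorter side⌋,
clamped to 3–15) and escalates (doubling, finally the whole side as one
word) whenever no unique shared word exists — the homopolymer corner case
resolves at the final step. The defining connector property is preserved:
a connector is emitted only after no acceptable run was found at any
attempted word length, and the recursion bottoms out at the 3-mer scale,
so the comparison remains base-by-base.

**Chance-match guard.** Two unrelated sequences of lengths *m* and *n*
share identical substrings up to about log₄(mn) long by chance alone (two
random 100-mers already share several unique 3-words). Refinement
therefore intercalates a run only if it is longer than
⌈log₄(lenA·lenB)⌉ + 3; the margin 3 puts the chance of a spurious split at
~4⁻³ per gap. Without this guard, deletion-coupled insertions — unrelated
sequences at the same position — are shredded into fragments by
coincidental matches. Shorter genuine runs in *similar* gaps are not lost:
the recursion shrinks the gaps around every accepted run, and the floor
shrinks with them.

### Junction normalization

When an indel junction carries a direct repeat, its placement is ambiguous
by cyclic shift. Maximal runs force one particular placement (whichever
neighbouring run was intercalated first claims the shared copy), so the
map stores that placement and **all boundary comparisons are made modulo
the shift class** (`ComparisonMap.connector_shift_range`, and the
`shift_slack` of simulator ground truth). A detected junction repeat is
invariant under the shift: it appears either as a prefix of the retained
segment matching the right flank or as a suffix matching the left flank,
and `flanking_direct_repeat` checks both phases.

### Difference counts and identity

A connector's `n_diffs` is the unit-cost optimal global alignment distance
of its two sides, and identity is matching columns over total columns
(gaps count in the denominator) — computed with edlib, with a 10 kb
per-side cap (larger connectors are always classified by the
length-difference criterion first). Shared identity is matches over
columns across all runs plus trivial connectors, excluding the
strain-specific set; shared fraction is the genome fraction outside
strain-specific regions.

The comparison is deterministic (no randomness anywhere in the map
construction) and symmetric up to tie-breaking (equal-longest runs choose
the smallest A-start, then B-start).

## Triage and the divergence filter

Criteria, tested in order (a)–(c): length difference ≥ 20 bp; more than 10
single-base differences; identity < 50% for connectors with both sides
≥ 7 bp. These thresholds are the standard, deliberately relaxed screen for
non-trivial differences in near-identical genome pairs.

The published analyses followed the automatic screen with a manual BLASTN
inspection that discarded regions of "enhanced sequence variability". The
divergence filter emulates that judgment reproducibly: the connector plus
150 bp of context on each side is globally aligned and **dropped** only
when *all* of the following hold — no gap run ≥ 20 bp, length difference
< 20 bp, flanked identity ≥ 0.60, and region-only identity ≥ 0.70.
The last guard is needed because unrelated sequence pairs under unit-cost
alignment show a spurious identity of ~0.47–0.53 (p99 ≤ 0.63, measured on
random pairs): a genuine short replacement flanked by 300 identical bases
would otherwise look "contiguous and well above 60% identical" and be
wrongly discarded, whereas a true substitution cluster dense enough to
trigger criterion (b) has region identity well above 0.70. All four
thresholds are configuration fields; exact reproduction of a human
curation step is explicitly not promised.

## Region classification

Precedence, most specific first:

1. **Element core deletion** — a complete catalog element spans the long
   side while a fused-terminal (`terminal_only`) remnant of the *same*
   family sits at the junction in the other strain, with a junction direct
   repeat. This is tested before the generic element rule because the
   region is ≥ 80% covered by the complete hit too, and the generic rule
   would shadow it.
2. **Mobile element insertion** — one side ≥ 80% covered by catalog
   hit(s), the other side no longer than the family's maximum target
   duplication + 5 bp. `MGE_transposon` for TP-A/TP-B, `MGE_repeat` for
   MITE/PATE/SMR.
3. **Switch repeat** — both sides are catalog elements (different
   families, or the same family in opposite orientation).
4. **Polyrepeat** — a tandem unit (period 1–50) explains ≥ 90% of each
   side with ≥ 80% per-copy identity and at least two copies; when one
   side is empty the array must continue into a flank (otherwise there is
   no repeat context and the region is a plain indel). No exact
   insertion point exists in a tandem array; only unit and copy numbers
   are reported.
5. **Deletion-coupled insertion (DCI)** — both sides at least 20 bp, the
   same cut-off that defines an independent indel.
6. **Indel** otherwise; size classes short < 150 bp ≤ medium ≤ 1.5 kb
   < long, always recomputed from max(lenA, lenB).

Polarity (insertion vs deletion) follows the rule order: junction direct
repeat → deletion in the strain with the single copy; catalog element →
insertion in the carrier; strongly deviant composition → insertion of
foreign DNA; otherwise unknown.

## Repeat-mediated deletions

The signature: the retained strain reads `…R core R…`, the other strain
`…R…` — the core plus exactly one repeat copy is deleted, so
`deleted_total = core + repeat` (the length law; `apply_repeat_mediated_deletion`
is the constructive inverse and is round-tripped in tests). Repeats
shorter than 4 bp are not reported (chance floor); variant repeats with
≤ 1 mismatch per 10 bp are reported flagged inexact but never counted in
the census. The chance model `E = n·p^k` with `p = Σ f_b²` (uniform: 1/4)
reproduces the standard expectation of 0.39 ≈ 0.4 chance 4-mer junction
repeats among 99 indels; an "exactly-k" or "at-least-k" model gives 0.29
or 0.52 and is evidently not what that figure used. Census bins: 4, 5, 6,
7–9, 10–19, ≥ 20.

## Mobile-element analysis

Family discovery (iterative BLASTN saturation and manual boundary
curation) is expert work and out of scope; the module matches supplied
family consensi. Hits are seeded by 12-mers, clustered by position, and
two candidate boundary sets are verified with unit-cost alignment: the
infix location of the consensus in the window (best for complete copies)
and the raw seed span (best for fused-terminal remnants, where an infix
aligner stretches the absent core over unrelated sequence). Completeness:

* **complete** — ≥ 90% of the consensus matched, with ≥ 80% identity after
  excluding candidate-side insertions (a complete element may itself carry
  a nested element);
* **terminal_only** — shorter than the family minimum, and the consensus
  prefix plus suffix explain ≥ 80% of the hit with ≥ 8 bp matched at each
  end (fused termini after core deletion);
* **partial** — a contiguous infix match of ≥ 30% of the consensus at
  ≥ 80% identity.

The terminal/partial guards prevent cross-matching between families that
share inverted terminal repeats (a MITE and its parent transposon).

SSEI calling: a hit is an SSEI when it coincides with a strain-specific
region (≥ 90% reciprocal overlap, boundaries modulo junction shift) whose
other side is at most the family's maximum TD + 5 bp; *common* when a
same-family hit occupies the aligned position in the other genome;
*within_indel* when strictly nested inside a larger strain-specific
region. Target duplications delegate to the junction-repeat detector; the
constraint that TP-A/PATE/SMR never cause TDs is enforced at the catalog
level and checked against detections. The targeting matrix counts every
hit strictly nested (≥ 1 bp of host on both sides) inside another hit,
per genome, inner category × host category, crediting the smallest host.

## Genome statistics

* GC windows: non-overlapping 1 kb, N excluded from numerator and
  denominator, all-N windows excluded from the statistics; flagged at
  |z| > 2.5 against the replicon's window mean/SD.
* Cumulative skew: per-window (X−Y)/(X+Y), zero when the denominator is
  zero, cumulative sum; reverse-complementing the genome negates the GC
  series window-for-window.
* Tetramer avoidance: counts on both strands; expectation from the
  maximal-order Markov model E(w₁w₂w₃w₄) = N(w₁w₂w₃)·N(w₂w₃w₄)/N(w₂w₃),
  the standard construction for word-avoidance statistics; zero-count
  middle dinucleotides yield an undefined (NaN) ratio, reported as such.
* Tetramer deviation profile: overlapping 5 kb windows at 1 kb step; per
  window the RMS over all 256 tetramers of the binomial z-score against
  whole-replicon frequencies. This is a documented approximation of
  windowed tetranucleotide-composition browsing, not any specific external
  tool's statistic; it is used as a qualitative foreign-DNA signal and is
  validated as such (planted foreign segments peak; homogeneous genomes
  stay flat).

## The simulator

`derive_strain_pair` plants, at configurable counts: scattered single-base
differences (default 1.4% of eligible positions, each assigned to one
strain — the divergence level at which shared identity measures 0.986);
insertions and deletions in three size classes (20–149, 150–1500,
1501–8000 bp — the long class is capped so the default 50 events fit a
300 kb ancestor, a 10× scale-down of a ~3 Mb chromosome, with 100 bp
spacing); DCIs (independent i.i.d. inserts, both ≥ 20 bp, at the same
ancestral position); repeat-mediated deletions (repeat 4–22 bp, core
30–500 bp, written into both strains and collapsed in one); polyrepeat
copy-number changes (unit 3–8 bp, copy difference ≥ ⌈24/period⌉, at least
two common copies so the array context survives in both strains);
element insertions with category-appropriate TDs; common and nested
(element-in-element) copies in both strains for targeting statistics; and
element core deletions of a PATE-style family whose 22 bp terminal direct
repeat collapses a 390 bp element to a 52 bp fused-terminal remnant.

**Junction conventions.** Payload boundary bases are constrained to differ
from their neighbours, and repeat cores from their flanking bases;
substitutions keep a 30 bp margin from event junctions. Without these
constraints the planted ground truth itself would be ill-defined — a
payload whose first base equals the next genome base genuinely describes a
different (shifted) event, and a core that extends the repeat genuinely
contains a longer repeat. Events are placed with a minimum spacing
(default 100 bp) by stretching uniform draws around the event footprints;
infeasible demands fail with the offending category named.

The truth log records every event (including substitutions) with exact
final coordinates in both strains, the expected region, its junction
ambiguity (`shift_slack`), payloads and consumed ancestor bases — so
replaying the log on the ancestor reproduces both genomes byte-exactly
(asserted in tests: the simulator is its own oracle).

**What the simulator does not model**: phylogenetic structure, selection,
codon structure, local composition heterogeneity, sequencing error, and
element-family divergence (catalog copies are planted exact). Passing the
recovery tests therefore demonstrates the pipeline's correctness on
well-separated events in a neutral background; on real genomes, boundary
ambiguity from diverged repeats and event clustering (hypervariable
regions hold dozens of events within a few kb) will reduce boundary
exactness even when detection is correct.

## History versus parsimony (the alignment-oracle corpus)

An event-resolved decomposition reports the *history* of a pair; a global
aligner reports the *parsimony optimum*. These coincide only when the
differences are well separated: when a substitution sits within
cost-neutral drift range of a gap, or two opposite-sign indels sit within
roughly twice the smaller indel's length, the optimal alignment merges
adjacent events into a cheaper joint interpretation that no event
decomposition can reproduce (measured: ~7% of 2 kb pairs at 100 bp
spacing; none at 400 bp spacing with a 200 bp substitution margin). The
alignment-equivalence test corpus therefore separates its differences, and
on it the map-induced alignment (runs as matches, connectors aligned
optimally inside) achieves exactly the optimal unit-cost distance — i.e.
the map *is* an optimal global alignment whose difference columns are the
connectors. The independent oracle is a hand-written Needleman–Wunsch DP
with an affine tie-break (fewest gap openings among unit-cost-optimal
alignments), which keeps gaps contiguous instead of scattered over chance
single-base matches.

## Numerical and degenerate-input choices

* Internal coordinates 0-based half-open; reports 1-based inclusive (BED
  0-based half-open). Round-trips are exact.
* An empty genome compares as a single pure-indel connector; identical
  genomes give one run and no connector; identity over an empty shared
  sequence raises rather than returning a value.
* Ties everywhere break deterministically (smallest start, then partner
  start); identical inputs give identical maps.
* Problem sizes used by the test suite and acceptance script — 300 kb
  recovery pairs with 50 events, 500 tiling pairs of 1–100 kb
  (log-uniform), 100 alignment-oracle pairs ≤ 2 kb, 150–300 kb statistics
  genomes — are the package's standard desk-scale validation sizes; all
  scale linearly if increased.

## Known limitations

* No reverse-strand matching and no rearrangement detection: the method is
  for co-linear pairs by design, and inputs violating that assumption will
  produce huge connectors rather than an error.
* The divergence filter is a reproducible emulation of a manual curation
  step, not a reproduction of it; on real data its keep/drop boundary
  should be reviewed around its thresholds.
* Element totals depend entirely on the supplied catalog; without the
  curated family set of a real organism, counts are not comparable to
  published totals.
* Connector difference counts above the 10 kb per-side cap are not
  computed (such connectors are always non-trivial by length anyway).
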