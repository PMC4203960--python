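# Methods

`promoscan` analyzes the sequence-motif architecture of promoter regions,
conventionally the 2 kb immediately upstream of a transcription start
site (TSS).  This note records the models and procedures implemented, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic data generator does and does not
emulate.

## Coordinate convention

Sequences are stored 5'→3' on the gene's strand with the TSS-adjacent
base last.  Intervals are 0-based half-open on the string; TSS-relative
positions are `index − length`, so the last base of a 2,000-bp promoter
sits at −1 and the first at −2000.  The promoter is partitioned into
distal [−2000, −500), proximal [−500, −100) and core [−100, 0) regions;
the boundaries are half-open with −500 in the proximal and −100 in the
core region (published range notations leave the boundary assignment
open; we fix one and document it).  Motif anchors for binning and region
assignment default to the interval midpoint, which avoids edge bias for
long elements such as islands; a `start` anchor is available.

N bases are universal mismatches: no repeat, island, quadruplex tract or
consensus match may span one.

## Perfect short tandem repeats

An STR call is a perfect (mismatch-free) tandem repetition of a
primitive 2–6 bp unit with at least six complete units.  Mononucleotide
runs are never called (their unit is non-primitive at every period ≥ 2).
Fixed, deterministic scanning semantics:

- a repeat is reported once, anchored at the leftmost full unit, at its
  primitive period only — (AG)₁₂ is one period-2 call, never additionally
  a period-4 (AGAG)₆ call;
- trailing partial units are excluded; the reported interval is exactly
  `units × period` bases;
- adjacent repeats of different motifs are separate calls and share no
  bases: the left run is extended greedily first, the right run starts
  where the left reported interval ends and is re-checked against the
  six-unit minimum.

Units are grouped into motif families by canonicalization: the
lexicographically smallest string over all cyclic rotations of the unit
and of its reverse complement (AC = AC/CA/GT/TG).  Trinucleotide units
additionally carry a 0/33/67/100%GC class (count of G/C in the unit;
rotation- and strand-invariant).

The scanner is validated by exhaustive oracle equivalence: an
independently written brute-force search over every (start, period)
produces identical call sets on hundreds of seeded random 2-kb sequences
and on repeat-dense stitched sequences.

## CpG islands

The classical criteria: GC fraction > 0.5, CpG observed/expected ratio
O/E = N(CpG)·L / (N(C)·N(G)) > 0.6, length ≥ 200 bp, all evaluated with
a 100-bp window.  All thresholds are strict; boundary values fail.

Algorithm: every 100-bp window (step 1) is scored for GC and O/E; each
*position* is assigned the mean score of all windows covering it, and
candidate islands are maximal runs of positions whose averaged GC and
O/E both pass.  Per-position averaging keeps island edges within a few
bases of the underlying CG-rich block — merging raw window extents
instead would bleed half a window of flank into every edge and turn a
199-bp block into a >200-bp call.  Candidates are then trimmed 1 bp at a
time from whichever end lies in the locally weaker 10-bp context (fewer
C/G; ties trim left) until the whole reported span itself passes GC and
O/E, and sub-200-bp candidates are discarded, so every emitted island
satisfies all three criteria on its own reported span.  An island
reaching the promoter end is flagged `truncated_at_tss` and its right
edge is never trimmed: that boundary is the TSS, not a compositional
edge.  N counts toward length but toward no composition count.

Promoters are classed NCGI (no island) or LCGI when summed island length
strictly exceeds 800 bp — historically a top-decile cut on chicken
promoters; the classifier also reports the empirical quantile of the
threshold so a top-X% cut can be re-derived on any dataset.

## Potential G-quadruplex sequences (PQS)

A PQS is four ordered non-overlapping guanine tracts, each ≥ 4
consecutive G (the tetrad count = shortest used tract), separated by
loops ≥ 0 nt, spanning ≤ 30 nt in total.  A longer physical G-run may
contribute a shorter used tract at any offset.  Placements whose whole
span is undisrupted poly-G (which includes every all-loops-zero
placement) are excluded: a bare G₃₀ folds no loop structure and is
reported by the polypurine scanner instead.  "Minimum number of tetrads
four" is read as minimum G-tract length 4 (stacked quartets); the
alternative reading (≥ 4 tracts of ≥ 3 G) is inconsistent with the
poly-G arithmetic and rejected.

One call is kept per region by a deterministic rank — larger tetrad,
then smaller loop-length variance, then smaller span, then leftmost —
with greedy disjoint selection.  This replaces proprietary G-scores;
downstream analysis uses only presence and position.  Only the G-rich
given strand is scanned by default (`both_strands` is available).  A
locus may legitimately be both an STR and a PQS (e.g. (GGGGT)₆); the
scanners never suppress each other.

Candidate enumeration is validated against an exhaustive four-nested
loop search on short sequences.

## Consensus motifs

IUPAC patterns are compiled to regular expressions and matched on both
strands (minus-strand hits reported on forward coordinates); overlapping
hits are all reported.  Defaults: TATA box `TATAWAW` (the canonical
consensus; the positional preference near −31/−30 is a result, not an
input) and the distal element `CWGCWSWG` = C[A/T]GC[A/T][C/G][A/T]G.
Poly-A and poly-G blocks are maximal single-base runs with a default
minimum of 10 bp — a stated proxy for discovered polypurine blocks whose
exact extents depend on the discovery tool.  All patterns and the run
minimum are config-overridable.

## Statistics

- **Frequency-table comparison**: motifs ranked by reference count
  (ties alphabetical, deterministic), the bottom ⌊10%⌋ pruned, remaining
  motifs aligned across tables with absent motifs as zero.  Pearson r is
  the default "correlation r" (Spearman available); Kendall tau-b with
  tie correction provides the trend test, exact for n ≤ 8 without ties,
  tie-corrected normal approximation otherwise.  Correlations are
  computed on counts.
- **Mann–Whitney U** (unit-count contrasts, e.g. di- vs tetra+
  repeats): U with tie-corrected variance, 0.5 continuity correction and
  signed z (positive when the first sample is larger); exact p by full
  labeling enumeration when both samples are ≤ 8 (ties included).
- **Fisher's exact test**: 2×2 through the hypergeometric distribution
  (two-sided by summing tables no more probable than observed); r×c
  tables by exact enumeration of the margin-preserving null (vectorized
  for 2×c) when the state space fits a budget, otherwise a seeded
  Monte-Carlo permutation p (≥ 10⁵ draws) with its standard error.
  Degenerate tables are skipped with a message, never silently tested.
- **GO over-representation**: for each gene group (PQS, STR, LCGI,
  NCGI) and term, a one-sided FET on [[k, n−k], [K−k, (N−n)−(K−k)]];
  raw p with a 0.01 cutoff, matching common practice in functional
  annotation tools; Benjamini–Hochberg q-values are emitted as a clearly
  optional extra column, and an EASE-style variant (one success removed)
  is available behind a flag.  Group membership is non-exclusive except
  the STR-over-PQS rule: a locus called by both scanners counts as STR
  evidence, so a gene joins the PQS group only if it has a PQS locus not
  overlapped by any of its STR calls.

All exact tests are checked against independent enumeration oracles;
the r×c test's null p-distribution is checked for uniformity under
simulated independence.

## Synthetic promoter generator

The generator emulates the statistical structure the analysis assumes,
with ground truth, so every stage is testable without genome downloads.

**Background**: per-position base composition follows a linear GC
gradient (defaults 0.48 → 0.57 toward the TSS) through a first-order
chain that depletes CpG dinucleotides to a target background O/E
(default 0.25, the vertebrate methylation–deamination regime) while
preserving the marginal composition exactly in expectation.  The
depletion is essential: an independent-base background above 50% GC
satisfies the island criteria by definition, and island calling would
be undiscriminating near the TSS.

**Planted elements** (replacing background bases at uniform-random
non-overlapping positions): STRs at 0.114 per promoter drawn from the
packaged chicken motif-family frequencies with unit counts di U{6..9},
tri U{6..7}, tetra+ U{6..12} (the avian pattern: tetra+ units exceed di
units); CG-rich islands in 58.3% of promoters, lengths U{200..900}
(≈10% of promoters exceed the 800-bp LCGI cut), GC 0.65, O/E target
1.2; G4 blocks (four G₄ tracts, loops 1–3 nt avoiding G) in 7.8% of
promoters; a TATA realization at −31 in 10%.  Planted STR/G4 elements
carry 1-bp guard bases chosen so background cannot extend the motif,
chance G-runs within 30 bp of a planted G4 block are disrupted, and
island segments are redrawn until they are cleanly callable in
isolation — design guarantees that make planted truth exactly
recoverable, so recovery tests measure the scanners, not planting luck.
Annotations: each of 50 GO terms has base prevalence 0.10; planted odds
ratios (default 5) multiply the assignment odds inside designated motif
groups.

**What it does not emulate**: isochore/dinucleotide structure beyond
CpG depletion, repeat length polymorphism, TSS-truncated island
geometry, positional clustering of real islands near the TSS, or any
correlation between motif presence and GC background.  Passing recovery
tests therefore demonstrates correctness of the measurement pipeline
under the stated statistical conditions, not fidelity to any particular
genome.

**Near-threshold plantings**: islands of 200–250 bp sit at the calling
limit by construction; in context their recovery is not guaranteed
(edge mixing with the depleted background can push the flagged run
below 200 bp).  Sensitivity guarantees are stated for realized islands
with GC ≥ 0.6, O/E ≥ 1.0 and length ≥ 250, where recovery is ≥ 99%.

A single seeded generator stream drives every draw, so a fixed seed
reproduces promoters, truth and annotations byte for byte.  Background
false-positive rates per scanner (random sequence spawns spurious
calls) are measured on a planting-free run and subtracted in rate
recovery.

## Pipeline and determinism

`run_all` executes scan → arrange → compare → enrich from a single YAML
config (unknown keys rejected; defaults are the standard scanner
parameters above), writes all call tables, BED6 files, frequency and
contingency tables, profiles, enrichment records and a heat-map-ready
matrix, plus a JSON manifest (version, parameters, seed, input/output
checksums).  Outputs carry no timestamps and all orderings and float
formats are fixed, so identical config and inputs give byte-identical
directories.  Figures are not rendered; every matrix needed for one is
exported as TSV.

Problem sizes in the shipped tests: oracle equivalence on 500 random
2-kb sequences; rate recovery on 5,000 simulated promoters with a
5,000-promoter background control; GO power/size over 50 seeded
annotation replicates (group 200 of 2,000 genes, prevalence 10%, odds
ratio 5).  The acceptance script simulates 3,858 promoters, the size of
a typical annotated promoter extract.

## Known limitations

- The island trimming rule is a documented in-house procedure; it
  enforces the three criteria on the reported span but is not a
  re-implementation of any specific legacy tool, whose internal edge
  handling differs.
- The r×c Monte-Carlo fallback gives a stochastic p (with reported
  standard error); exact enumeration covers all table shapes used by
  the pipeline's own outputs at default settings.
- Kendall-tau p-values with ties rely on the normal approximation; at
  the table sizes used here (≥ 18 aligned motifs) this is standard
  practice.
- Reverse-strand (C-rich) quadruplexes and imperfect/interrupted
  repeats are out of scope by design.
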