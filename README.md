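# promoscan

Sequence-motif architecture of gene promoter regions.

Eukaryotic promoters — here the 2 kb immediately upstream of a
transcription start site (TSS) — concentrate short tandem repeats
(STRs), CpG islands (CGIs), potential G-quadruplex sequences (PQSs) and
fixed consensus elements such as the TATA box, and the abundance,
position and mutual arrangement of these motifs differ between
lineages and correlate with gene function.  `promoscan` is a toolkit
for quantifying that architecture: it scans promoter FASTA for each
motif class, profiles their positions relative to the TSS, classifies
their arrangement relative to CpG islands, compares motif-frequency
tables across species, and tests gene sets defined by motif presence
for GO-term over-representation.  A seeded synthetic-promoter generator
with ground truth stands in for genome extracts, so the whole pipeline
is testable offline.

It is written for comparative and regulatory genomicists who want the
classical motif definitions implemented exactly and deterministically:

- **STRs**: perfect tandem repeats of primitive 2–6 bp units, ≥ 6
  complete units, mononucleotides excluded; units canonicalized to
  motif families by the lexicographic minimum over cyclic rotations and
  the reverse complement (AC = AC/CA/GT/TG).
- **CGIs**: 100-bp sliding window, GC > 50%, CpG O/E =
  N(CpG)·L/(N(C)·N(G)) > 0.6, length ≥ 200 bp (strict inequalities);
  islands reaching the promoter end are flagged as TSS-truncated;
  promoters classed NCGI (no island) / LCGI (> 800 bp total island).
- **PQSs**: four G-tracts of ≥ 4 G, loops ≥ 0, span ≤ 30 nt,
  undisrupted poly-G excluded; one call per locus by deterministic rank.
- **Statistics**: frequency-table comparison with bottom-10% minor-motif
  pruning (Pearson/Spearman r, Kendall τ-b), tie-corrected Mann–Whitney
  U with exact small-sample p, Fisher's exact test for 2×2 and r×c
  tables (exact enumeration or seeded Monte-Carlo), and one-sided
  Fisher-exact GO enrichment at the conventional p < 0.01 cutoff.

## Worked example

Scan the classic shared locus — a 30-nt (GGGGT)₆ block is simultaneously
a perfect pentanucleotide STR of six units and a G-quadruplex motif:

```python
>>> from promoscan import Promoter
>>> from promoscan import str_scanner, pqs_scanner
>>> p = Promoter(gene_id="DLX3", seq="GGGGT" * 6)
>>> c = str_scanner.scan_strs(p)[0]
>>> c.period, c.units, c.canonical_motif
(5, 6, 'ACCCC')
>>> q = pqs_scanner.scan_pqs(p)[0]
>>> (q.interval.start, q.interval.end), q.loops
((0, 19), (1, 1, 1))
```

Run the full pipeline on a simulated promoter set:

```
$ cat run.yaml
simulate: {n_promoters: 3858}
seed: 42
$ promoscan run-all --config run.yaml --out-dir out/
promoscan run summary
=====================
promoters analyzed:        3858
mean GC fraction:          0.5448
STR calls:                 446
STR per sequence:          0.1156
% genes with >=1 STR:      11.53
CGI calls:                 2234
% genes with CGI:          57.88
LCGI promoters:            487
NCGI promoters:            1625
PQS calls:                 345
% genes with PQS:          8.89
tetra+ vs di unit counts:  z = 5.011, p = 5.41e-07
most common CGI relation:  downstream
significant GO terms:      5
   LCGI T002  p = 1.77e-19
   NCGI T003  p = 3.67e-74
    PQS T000  p = 1.63e-31
    PQS T011  p = 0.00933
    STR T001  p = 1.25e-41
```

Reading the output: the generator plants STRs at 0.114 per promoter,
islands in 58.3% of promoters, G4 blocks in 7.8%, and one enriched GO
term per motif group (T000–T003); the scanners measure back 0.1156
STR/sequence (planting plus a small background of chance repeats),
57.9% CGI genes, and a Mann–Whitney z of +5.0 for the planted excess of
tetra-/penta-/hexanucleotide unit counts over dinucleotides.  All four
planted terms are recovered at p < 0.01; `T011` is one false flag among
200 group×term tests, consistent with the raw-p cutoff.  `out/`
contains the per-call TSV/BED tables, GC and positional bin profiles,
arrangement and co-occurrence contingency tables with their Fisher
tests, the enrichment matrix, and a `manifest.json` with parameters and
checksums; rerunning with the same config reproduces every file byte
for byte.

Other subcommands: `simulate`, `scan-str`, `scan-cgi`, `scan-pqs`,
`scan-consensus`, `arrange`, `compare`, `enrich`, `report` (see
`promoscan --help`).

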