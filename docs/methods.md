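# Methods

## Coordinate model

All genomic coordinates are 0-based, half-open (BED convention); GTF
input/output converts from/to 1-based closed exactly at the I/O
boundary. Adjacent half-open intervals never overlap, which removes the
±1 ambiguity from every interval test. "Downstream" always means
further along the direction of transcription: larger coordinates on the
plus strand, smaller on the minus strand, with equality never counting
as downstream.

A polyadenylation *site* is a single cleavage position; when a polyA
track supplies an interval, its strand-wise 3′-most base is used. PolyA
sites are assigned to genes by the BED name column when it matches a
gene id, otherwise to the nearest same-strand gene within a window
(default 10 kb, configurable) — polyA track formats vary in how they
encode the gene link, so both routes are supported and logged.

The polyA-to-exon distance runs from the last genuine cleavage position
to the gene-proximal boundary of the *Alu* exon (its start on the plus
strand, its end on the minus strand). The alternative reference point —
the *Alu* element boundary rather than the exon boundary — is
deliberately not the default: the exon boundary is the position that
splicing actually selects, and the gap-length semantics keep the
smallest observable distance at 1 bp.

## Detection

Junctions are the exact intron gaps of split reads, aggregated per
(chromosome, gap start, gap end) with read counts. A predicted exon
becomes an *Alu*-exon candidate iff

1. its acceptor or donor position lies inside an *Alu* element annotated
   antisense to the exon's strand, and that splice site coincides with a
   junction carrying ≥ `min_junction_reads` reads (default 1 — a single
   junction-spanning read is the minimal evidence for a used splice
   site), and
2. no other predicted exon overlaps it on the same strand by ≥ 1 nt
   (identical duplicate predictions are collapsed first).

Splice-site-to-junction matching is exact coordinate equality. Both the
simulator and splice-aware aligners emit base-precise junctions; a fuzz
window would only mask upstream processing errors.

## Classification

**Gene linkage.** Breadth-first search over the junction graph from the
candidate's splice sites, hopping junction → exon → junction, up to
`max_hops` (default 3, enough for an *Alu* exon plus a downstream
cryptic-exon chain). The candidate links to the gene whose annotated
span (same strand) contains a reached position; ties at equal hop count
go to the gene nearest upstream in transcription direction.

**Locus class.** The last genuine polyA site is the strand-wise most
downstream annotated site across all of the gene's transcripts (genes
without any annotated site fall back to the gene 3′ end, with a
warning). An *Alu* exon whose gene-proximal boundary is strictly
downstream of that site is *intergenic* (this implies the entire exon is
downstream); otherwise it is *intronic*.

**Mechanism.** Junctions into the *Alu* exon acceptor are split by their
donor: donors that are annotated donors upstream of the terminal exon
support *terminal-exon skipping*; donors strictly inside the terminal
exon body support *cryptic 5′ splice-site activation*; both classes at
≥ `min_reads` (default 1) give *both*. Exon boundaries themselves never
count as "inside" the terminal exon: a donor at the terminal exon's own
donor site is ordinary terminal splicing, not a cryptic site.

**Splicing contribution.** At the *Alu* exon 3′ splice site, a read is
junction-spanning when it contains the exact intron gap ending at the
acceptor, and continuously aligning when one block covers ≥ 10 nt on
*each* side of the acceptor boundary. The one-sided alternative cannot
distinguish spliced from unspliced molecules, so the two-sided reading
is the default (the flank width is a parameter). The statistic is
junction / (junction + continuous), absent on 0/0.

**Inclusion estimate.** Discriminating reads are junction reads into the
*Alu* acceptor (only *Alu*-derived isoforms produce them) versus, per
scenario, canonical terminal-exon acceptor junction reads (skipping) or
reads aligning continuously across the cryptic donor boundary (cryptic
5′ SS and both — only the canonical isoform retains terminal-exon
sequence past that boundary). Raw counts are biased by isoform length:
a read population of fixed size spread over a longer isoform yields
fewer reads per position. Each count is therefore scaled by the emitting
isoform's effective length (isoform length − read length + 1, the
standard effective-length normalisation) divided by the width of the
start-position window that produces the diagnostic alignment (read
length − 1 for a junction, read length − 2·flank + 1 for a covering
block). The corrected ratio is an unbiased estimate of the fraction of
transcripts carrying the *Alu* exon, regardless of length differences
between isoforms; isoform lengths are reconstructed from the annotated
primary transcript, the *Alu* exon, the observed cryptic donor, and the
junction-reachable downstream exon chain.

**Downstream cryptic exons.** Predicted exons strictly downstream of the
*Alu* exon reachable by a junction chain starting at its donor, counted
by graph reachability (chain depth capped at 10).

## Synthetic data

The generator emulates the genomic configuration the analysis assumes.
Each gene occupies a private 30-kb slot (precluding interval
collisions by construction): two constitutive exons (200 nt), a 600-nt
terminal exon whose 3′ end is the genuine polyA cleavage site, and — for
event genes — an antisense *Alu* element 40 nt wider than its 150-nt
*Alu* exon, placed so the planted polyA-to-exon distance is exact.
About 30 % of genes carry a second (tandem, upstream) genuine polyA
site, and a quarter carry a second annotated transcript, exercising the
"last site"/"primary transcript" selections. Event-free genes receive a
silent antisense decoy *Alu* with 30 % probability, exercising
specificity. Minus-strand genes are coordinate reflections of the plus
layout, so every strand-aware code path runs on half of the data.

Defaults encode the study conditions: 50 % of genes with events;
scenario mix 0.45 / 0.37 / 0.18 (skipping / cryptic 5′ SS / both);
distances log-uniform on [41 bp, 21.4 kb] so the planted histogram spans
the empirically observed envelope; control inclusion ~ Uniform(0, 0.15)
and knockdown inclusion ~ Uniform(0.10, 0.80), echoing the observed rise
of inclusion upon loss of repression without asserting specific values;
26.2 % of events gain one (else two, with probability 0.25) downstream
cryptic exons; read depth 500 per gene and condition; read length 75.
The novel polyA site used upon exonisation is placed after the last
planted exon and recorded in the truth table, but deliberately excluded
from the genuine polyA track: "intergenic" is defined against annotated
sites, which would not contain the cryptic cleavage product.

Reads are exact sub-windows of the chosen isoform — no sequencing-error
or coverage-bias model, because every downstream statistic consumes
junction geometry and counts, not base calls. Each read picks the
*Alu*-derived isoform with probability equal to the planted inclusion
(Bernoulli; the "both" scenario splits *Alu* reads 50/50 between its two
structures, configurable). Start positions are drawn on a randomly
offset uniform lattice over the isoform: marginally uniform, while
guaranteeing that every junction of an expressed isoform is spanned once
the isoform draws a handful of reads — so planted events are recoverable
by construction rather than by seed luck. FPKM matrices give event genes
one *Alu*-containing isoform and 1–3 others across a 16-tissue panel;
per-tissue relative abundance is Beta-perturbed around the gene's base
inclusion (concentration 10), totals are log-normal, and 5 % of
gene/tissue cells are zeroed to exercise the undefined (0/0) path.

What passing on these data does **not** show: robustness to alignment
error, fuzzy junction boundaries, overlapping genes, expression-
dependent exon prediction, or paired-end/stranded library artefacts.
The simulator validates the logic of the pipeline, not aligner quality.

## Ortholog filter

The exon correspondence between human and mouse is input data (conserved
exon pairs from an orthology resource), never computed here; criterion
(iii)'s "conservation" is therefore annotation-level membership in that
correspondence. "Extends beyond" is evaluated at transcript 3′ ends
(the comparison concerns annotated isoforms, not gene spans). Criterion
(iii) is evaluated relative to the 5′-most qualifying *Alu* exon and is
vacuously true when no *Alu* exon qualifies (the pair already fails
criterion ii). The toy-pair generator realises all eight combinations
of extension × *Alu* flag × post-*Alu* conserved exon; when no extension
exists the *Alu* flag lands on an internal exon (a genuine intragenic
exonisation), which correctly fails the downstream criterion.

## Numerical and reporting choices

- Tie-breaks are deterministic everywhere: candidate processing and
  output rows are sorted by coordinates; linkage ties go to the nearest
  upstream gene, then lexicographic gene id; the modal cryptic donor
  breaks count ties by position.
- Histograms are presentation choices: splicing contribution in ten
  equal bins on [0, 1]; distances in 1-kb bins.
- Degenerate inputs: 0/0 ratios are reported as absent, never 0;
  unlinked candidates survive with `locus_class=unlinked`; genes without
  polyA sites fall back to the gene 3′ end with a warning; zero-FPKM
  tissues are excluded from the tissue-specificity spread (flag
  threshold 0.10 on max−min relative abundance).
- Determinism: one `numpy` Generator seeded from the run seed drives the
  generator; per-condition read sets use child seed sequences. Outputs
  carry the tool version, a hash over the effective parameters, and the
  seed; identical config + seed reproduce byte-identical files.
- The tests and the acceptance script use 200 genes at depth 500 for
  recovery, 100 genes at depth 2000 for the inclusion calibration, and
  60 genes at depth 200 for the contribution-oracle check — sizes at
  which every binomial check is well-powered while the suite stays
  quick.

## Known limitations

- Single-end SAM subset only (M/N/S); BAM/paired-end reconstruction and
  FASTQ are out of scope, as is de-novo exon prediction from coverage.
- Read strand is not required to match gene strand (unstranded libraries
  are the common case); junction assignment is purely coordinate-based.
- The intronic class is reported but not further quantified (no
  upstream-exon competition statistics).
- No statistical testing of differential inclusion between conditions;
  the inclusion estimates are descriptive.
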