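# Methods

This note documents the models implemented in `gmocap`, the parameters that
matter, the design choices made where the design was genuinely open, and what
the synthetic test conditions do and do not demonstrate.

## Screening panel and probe design

The default panel (`gmocap.panel.PANEL`) lists 40 structural elements —
11 promoters, 6 terminators, 22 genes, 1 miscellaneous — with their lengths
(total 52,534 bp) and public provenance (NCBI accessions and patents).
Selection markers (nptII and kin) are deliberately excluded: trace bacterial
or plasmid DNA from the enzymes used in library preparation would light them
up spuriously.

The real sequences are not bundled. `synthetic_panel_database(seed)`
generates random A/C/G/T sequences with the exact panel lengths, so the
entire pipeline runs offline and the length checksum is preserved. Two
correlations that the method's behaviour depends on are emulated:
`cry1Ab_c`/`cry1Ac` are generated ~92 % identical (cry variants are nearly
homologous and best-hit assignment must still resolve them) and `pat`/`bar`
share a ~60 %-identical stretch (the mixed-sample separation case). A
synthetic panel cannot reproduce real cross-hybridisation or real host
homologies; conclusions from it concern the pipeline's algorithms, not any
particular organism.

Probes are verbatim 120 bp substrings tiled every 110 bp (~8 % overlap, no
degeneracy), with the final probe of each element end-anchored and elements
shorter than a probe covered by a single full-element probe. Full coverage
of every element base is an invariant, checked by an interval-union oracle.
Thermodynamic scoring (GC/Tm, cross-hybridisation) is out of scope.

## Capture and sequencing model

Shearing draws fragment lengths uniformly in 150–200 bp and start positions
uniformly per genome; the source genome of each fragment is drawn with
probability proportional to (copy fraction × genome length), i.e. the
component fraction is a genome-copy fraction and DNA mass scales with copies
times length. Capture retains a fragment when it overlaps probe-covered
genome sequence by at least `min_overlap = 20` bp; any other fragment
survives with `off_target_rate = 1e-4`. This is the simplest model that
reproduces the observed behaviour of enrichment — a huge on-target excess
with a small uniform background — and it deliberately omits capture
chemistry (probe affinity, GC bias, fragment-length bias). Junction capture
falls out naturally: a fragment straddling the insert border is retained
through the probe bases inside the insert, which is what lets contigs cross
into plant DNA.

Sequencing emits mate 1 as the first 75 bp of the fragment and mate 2 as the
first 75 bp of its reverse complement, with i.i.d. substitution errors at
`error_rate = 0.002` (an Illumina-like figure) and constant quality
characters (the pipeline does not use qualities). Indel errors, quality
decay along the read, PCR duplicates and adapter read-through are not
modelled. Every random draw derives from `SampleSpec.seed` through separate
`SeedSequence` streams, so identical specs give byte-identical FASTQ.

## Read classification

Alignment is seed-and-extend: a dual-entry k-mer index (k = 15, both
strands) proposes (element, strand, diagonal) candidates; candidates are
extended by banded local Smith–Waterman (band ±16; match +1, mismatch −1,
gap open −2, gap extend −1). The single best-scoring element wins; ties
within `tie_tol = 0` set an ambiguity flag and resolve to the
lexicographically smallest element id, so counts are deterministic and are
not split fractionally. A read is positive when identity ≥ 0.90 over ≥ 40
aligned columns; both thresholds are explicit parameters rather than
inherited from an external aligner's defaults, so the filter is
reproducible. On instances small enough to check exhaustively, the
seed-and-extend result equals full Smith–Waterman whenever a seed exists
(tested against Biopython's `PairwiseAligner` as an independent oracle);
reads whose best alignment has no exact 15-mer seed are reported unassigned,
which at ≥ 90 % identity over 75 bp is rare.

## Detection

RPKM uses **total sequenced reads** in the denominator. The alternative —
per million *mapped* reads — is degenerate under enrichment: the mapped
total is tiny, grows with GM content, and is near zero in negative controls,
which would destroy comparability across samples. With the total-read
denominator the expected element share is a·f/(a·f + b) in the GM fraction f
(a = on-target capture rate, b = off-target background): strictly increasing
but saturating once nearly all captured reads are insert-derived. The
dose–response tests therefore assert a strict rise while the statistic is
unsaturated and a noise-tolerant non-decrease (three relative standard
errors) between 1 % and 10 %.

The threshold is `max(mean + 5·sd, 25)` per element, estimated across
negative-control runs; with a single control the SD falls back to the spread
pooled across elements. Detection is strict (`rpkm > threshold`): the
boundary belongs to the background. A Monte-Carlo test draws Gaussian
background, fits the model on 30 simulated controls and verifies ≥ 99 %
of fresh background draws classify as negative (Chebyshev guarantees ≥ 96 %
with no distributional assumption). Endogenous flags annotate rather than
clear detections, because an expected positive is still information.

## Assembly

Positive reads — those assigned to detected elements, plus their mates even
when unassigned — feed a canonical-k-mer de Bruijn assembler (odd k = 31 for
75 bp reads). Edges below `min_edge_cov = 2` are dropped (suppressing
singleton error k-mers at ≥ 20× coverage), dead-end tips shorter than 2k are
clipped, and two-branch bubbles whose sides are ≥ 95 % identical collapse to
the higher-coverage side. Maximal unbranched paths ≥ 100 bp are emitted in
canonical orientation, ordered by descending length then sequence, so an
identical read multiset yields byte-identical FASTA. Paired-end information
is used only for read rescue, not scaffolding: contig order across gaps is
reported as unordered with a gap flag. A single bespoke assembler replaces
multi-assembler merging; at 75 bp/desk scale it reconstructs clean templates
exactly (coverage ≥ 2 everywhere, repeat-free) and reaches ≥ 99 % contig
identity at 1 % substitution error and 30×.

## Annotation, junctions and layouts

Elements (both strands) and, when available, the host reference are locally
aligned to each contig with the same banded DP but stiffer scoring (match
+1, mismatch −3, gaps −5/−2). The stiff scheme matters at junctions: with
+1/−1 scoring a local alignment random-walks tens of bases past the true
boundary into unrelated sequence, while at −3 per mismatch the drift is a
base or two. Overlapping hits are resolved greedily by score, with
lower-scoring hits trimmed back to the accepted boundary (tolerated overlap
10 bp) rather than discarded — a host flank and an element hit should abut,
not compete. Uncovered stretches ≥ 30 bp are reported as `unknown`.

A junction is any host/non-host adjacency within 20 bp. The border is
`left` when, read on the host forward strand, plant DNA precedes the
construct; the reported host coordinate is the reference base flanking the
insert, which for both borders equals the insertion site. On simulations
with ≤ 1 % substitution error the called coordinate lands within ±5 bp of
truth (typically 0–1 bp).

Layout grouping works from construct-specific evidence: contigs sharing a
gene-category element merge into one inferred construct (union-find).
Contigs carrying only shared element classes (promoters/terminators/misc)
attach to the gene group when exactly one exists; when there is no gene
group at all, all element-bearing contigs form a single layout (so a
construct split by an unprobed interior still reports as one layout with a
gap); when several gene groups exist, promoter/terminator-only contigs are
listed as `shared`, since flanking evidence cannot place them. This keeps
constructs with < 90 %-identical genes separate while not fragmenting
single-construct samples.

## Study conditions and problem sizes

Synthetic hosts are 50–60 kb random genomes; the GTS-like event inserts
p35S–linker–EPSPS1–linker–tNOS plus an unknown 150 bp rearranged tail at a
fixed site. The rearrangement is modelled as unknown sequence only: a > k
duplication of EPSPS sequence would introduce a repeat that breaks the
single-contig reconstruction, and characterising repeat-induced
fragmentation is not what the fixture is for. Simulations use 1 M sheared
fragments for the 0.1/1/10 % dose ladder, 2 M for 1 %-characterisation,
60 k for the 50/50 mixed sample and 200 k for each negative control — sizes
chosen so that the 0.1 % sample still yields a handful of fragments per
element (the regime the method claims) while a full run of the suite stays
in the minutes range. Because the hosts are ~5 orders of magnitude smaller
than real plant genomes at equal insert size, absolute values of "% reads
aligned" are far higher than a real run would show; the qualitative
dose–response, sensitivity, specificity and junction-accuracy behaviour are
the transferable results.

## Known limitations

* Capture efficiency is binary-plus-noise; no affinity, GC or length bias.
* Substitution-only error model; no indels or quality structure.
* The assembler has no scaffolding or repeat resolution beyond simple
  bubbles; constructs with long internal repeats will fragment.
* Layout inference cannot order contigs within a gapped construct and will
  group two different constructs that share the *same* gene element.
* Synthetic panels carry no real homology to real host genomes, so
  endogenous-element behaviour is exercised through declared donor maps and
  embedded copies, not discovered homology.
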