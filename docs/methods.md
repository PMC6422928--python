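# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limits of `csikit`. Everything quantitative stated
here is computed by the test suite or the acceptance script; nothing is
quoted from elsewhere.

## Coordinates and interval model

All internal and emitted coordinates are 0-based half-open (BED
convention); GTF input (1-based inclusive) is converted on read. A CSI
chain for a gene is a set of adjacent half-open intervals sharing
boundaries: `CSI_k.end == CSI_{k+1}.begin` in genomic + orientation, with
index 1 always abutting the distal stop codon on either strand. The
identifier `gene:stop_begin-end` is lossless (parseable back to its four
fields) and the emitted BED is the 8-column dialect
`chrom begin end identifier 1 strand gene_id symbol`, tab-separated, no
header. The score column is the constant 1.

## Annotation stage

* **Distal stop codon** — strand-aware extreme over all `stop_codon`
  features of a gene (max `end` on +, min `begin` on −); duplicate or
  overlapping stop records are merged first, so the operation is
  idempotent. Genes with exons but no stop codon are non-coding for our
  purposes and excluded with a warning: the method needs a CDS anchor.
* **Terminal region** — from the distal stop to the nearest coding-exon
  boundary of any *other* gene in the 3′ direction, regardless of that
  gene's strand, truncated at `max_extent` (default 40,000 bp; genome-wide
  site surveys put <5 % of clustered polyA sites beyond 40 kb of the stop
  codon, so longer extensions are rarely evidence-backed). `capped` is
  only set when the 40 kb truncation was the binding constraint. A gene
  whose stop codon is already inside another gene's coding exon gets no
  region.
* **Union annotations** — gene records under different ids (e.g. Ensembl +
  RefSeq) merge when their symbols match and spans overlap on one
  chrom/strand; the first-seen id wins. Two genes that share a distal stop
  coordinate are deliberately *both* allowed to claim a cluster
  (flagged ambiguous) rather than guessing a winner.

## PolyA site calling

* **Tally key** — a read's 5′ end in transcript orientation:
  `reference_start` for forward alignments, `reference_end − 1` for
  reverse. Default `strand_mode="same"` (the aligned strand is the
  transcript strand); `"opposite"` flips the attributed strand and keys on
  the alignment's other end, for libraries sequenced antisense to the
  transcript.
* **Internal-priming screen** — a deterministic stand-in for trained
  cleavage-site classifiers, keeping only the sign contract (positive =
  true polyA event). Over the 30 nt downstream of the candidate site:
  reject if A-fraction ≥ 0.65 (strict `<` to pass; a site exactly at the
  threshold is rejected) or any A-run ≥ 6 nt; reject sites with < 10 nt of
  downstream sequence. The 40 nt-up / 30 nt-down window matches the
  convention such classifiers are trained on. Externally computed per-site
  scores can be injected from a TSV and take precedence per site, so a
  published classifier's output can replace the heuristic without code
  changes. Score magnitude is informational only.
* **Clustering** — single-linkage chaining of accepted sites ≤ 30 bp
  apart. Chaining can extend a cluster's total span beyond 30 bp; we chose
  chaining (over fixed-span windows) because it is order-invariant,
  idempotent, and guarantees inter-cluster gaps > 30 bp. The cluster
  *representative* (assignment distance) is the max-read-count member,
  ties to the most 3′; the *boundary coordinate* used for interval
  construction is the most 3′ member, so the reported UTR extent is
  maximal. `min_reads` defaults to 1 (every screened site counts).

## Quantification

* **Unique mapping** — records with multiplicity tag `NH == 1`, falling
  back to MAPQ ≥ 30 when the tag is absent.
* **Overlap semantics** — a read increments every CSI that any aligned
  block overlaps by ≥ 1 bp; a boundary-spanning read counts in both
  flanking CSIs (per-interval coverage semantics — deliberate double
  counting, matching coverage-utility behavior). Spliced reads are judged
  on blocks, not the full reference span. A `primary_interval_only` flag
  counts each read once, in its largest-overlap CSI.
* **CPM** — `raw × 1e6 / library_size`. The default library size is the
  per-sample total over the counted CSIs (self-contained; CPM columns sum
  to exactly 1e6); whole-library totals can be passed instead and are the
  right choice when CSI-mapped reads are a small fraction of a real
  library.
* **Rounding** — `⌊CPM + 0.5⌋` elementwise; exact .5 rounds up, a
  convention forced by the formula (2.5 → 3, 2.49 → 2).
* **Contiguity filter** — per gene, only the maximal prefix of CSIs with
  pooled count > 0 (across all samples of the comparison) is testable;
  everything at/after the first zero-count CSI is excluded with a reason
  code. Expression evidence must be contiguous from the CDS end because a
  distal interval without proximal coverage cannot belong to the same
  transcript population.

## Differential usage

* **WITHIN** — two-sided Fisher exact test (one-sided available) on
  `[[A_i, ΣA−A_i], [B_i, ΣB−B_i]]`, where `A_i` sums rounded CPM over
  condition replicates. Single-CSI genes (ψ ≡ 1) and genes with a zero
  total in either condition are excluded with machine-readable reason
  codes. ψ sums to 1 per gene/condition exactly; Δψ sums to 0.
* **PAIRWISE** — equal-variance Student's t on the per-replicate rounded
  CPM vectors (Welch and raw-CPM variants via flags); both vectors
  constant and equal ⇒ p = 1, constant and different ⇒ p = 0. Requires
  ≥ 2 replicates per side, else a reason code.
* **FDR** — Benjamini–Hochberg step-up applied globally across all tested
  CSIs per method per comparison (delegated to
  `statsmodels.multipletests(method="fdr_bh")`; tests verify it against a
  direct step-up computation).
* **Export** — flattened GFF (aggregate-gene + exonic-part lines) and
  two-column per-sample count files keyed `gene:index`, for
  negative-binomial exon-usage GLM tools; running that GLM is out of
  scope.

## Motif enrichment

Windows are `width` (default 100) nt centered on the 3′ boundary of each
significant CSI ("surrounding the CSI site" is read as ±width/2 around the
boundary; 5′-boundary and both-boundary anchors are flags), strand
oriented, transcribed T→U. The background is a per-sequence dinucleotide
shuffle (Altschul–Erickson Eulerian-walk construction, exact dinucleotide
multiset conservation; `k=1` letter shuffle available), fixed seed.
Enrichment counts sequences-with-≥1-hit, not total hits, so hit clumping
inside one sequence cannot masquerade as enrichment; one-sided Fisher p,
BH across motifs. Centrality: a 21-offset subwindow (matching the width of
the known −30..−10 concentration zone of the polyA signal) slides over the
scannable offsets; each placement is binomial-tested against the uniform
expectation and the best placement is reported with a Bonferroni
correction over placements. Consensus scanning is IUPAC-exact;
position-weight matrices are out of scope.

## Synthetic universe

The generator emulates the minimal world the pipeline needs: one contig,
genes alternating strands, each with one coding exon, a stop codon, three
planted cleavage sites 250 bp apart (well beyond the 30 bp cluster gap),
a polyA-signal hexamer 10–30 nt upstream of every site (where the cleavage
machinery binds it), and one decoy A-run (15 nt) planted between the stop
codon and the first site. Background sequence caps homopolymers at 4 nt so
every screen rejection traces to a planted decoy. PolyA-Seq reads start
within ±jitter (default 2, max 5) nt of planted sites; RNA-Seq reads pick
an isoform from the condition's true usage vector and land uniformly
within that isoform's UTR span, so interval coverage follows the survival
function Σ_{j≥k} ψ_j (verified against a closed-form expectation in the
tests). Defaults: 6 genes, depth 50 polyA reads/site, 500 RNA reads per
gene per sample, 2 replicates per condition.

What the generator does **not** model: sequencing errors and base
qualities, paired-end fragments, spliced UTRs (spliced-read counting is
exercised by separate hand-built fixtures), multimapping, and realistic
whole-transcriptome library composition. A green end-to-end test therefore
establishes the pipeline's interval arithmetic, screening, assignment and
statistics — not robustness to alignment artifacts.

Where distributional claims are tested (null error rate, shift recovery),
counts are generated directly on the CPM scale (library size fixed at 1e6
so rounded CPM equals the simulated counts). This pins the statistic to
the stated per-CSI depths; with the self-contained CPM denominator and a
tiny simulated transcriptome, the 1e6 rescaling would otherwise inflate
every count by a large constant and the stated depths would no longer
mean what they say. Null rejection of the WITHIN test is checked against
0.05 + 3·MC-SE over 800 interval tests; a planted Δψ = 0.3 at ≥ 500 reads
per gene per condition must be recovered with correct sign in ≥ 90 % of
genes.

## Numerical conventions and degenerate inputs

Exact-tie handling: cluster-representative ties go 3′; equidistant cluster
assignments go to all tied genes, flagged; the priming A-fraction
threshold is strict. Fisher and t p-values come from scipy; the test suite
holds them to exact-rational enumeration (Fisher, margins to 40) and the
closed-form pooled-variance statistic respectively. The within-test
enumeration check is exhaustive for condition totals ≤ 16 and sampled up
to 40 to stay inside the suite's runtime budget. Empty inputs return empty
outputs (tally, BED reader, BH on length-0); genes with zero clusters
produce no CSIs and are logged as unresolved rather than falling back to
annotated UTR ends, keeping the annotation strictly evidence-based.

## Known limitations

Only the distal-most stop codon is used, so APA downstream of alternative
stop codons is invisible, as are non-coding genes. Interval construction
is only as complete as the polyA-Seq evidence. The WITHIN test collapses
replicates (variance is not modelled; the DEXSeq-style export exists for
that). The internal-priming heuristic is cruder than a trained classifier
— it enforces only the sign contract, and the score-injection path exists
precisely so trained scores can replace it.
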