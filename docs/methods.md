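# Methods

## Coordinate conventions

All interval arithmetic inside the package uses 0-based half-open
coordinates. GTF (1-based closed) is converted at the I/O boundary in
both directions; BED12 is native. An intron spans `[donor_site,
acceptor_site)` where `donor_site` is the first intronic base. Keeping a
single convention internally is what lets junction identity be tested by
exact tuple equality with no per-module offsets.

Strand is `+`, `-` or unknown (`.`). Unstranded alignments (typical for
unstranded cDNA protocols) can acquire a strand from splice-motif
orientation during validation: each junction's motif check reports which
orientation read canonically, and the alignment takes the consensus when
all its canonical junctions agree. With the default GT–AG motif set a
single intron can never read canonically in both orientations (its first
two bases would have to be both `GT` and `CT`), so per-junction inference
is unambiguous; the ambiguity branch exists for configurations that widen
the motif set.

## Validation model

A junction is *motif-valid* when the genomic text reads `GT…AG` across
the intron in transcript orientation (`CT…AC` in genomic text for
minus-strand transcripts). Only this canonical class is accepted by
default; the minor spliceosomal classes (GC–AG, AT–AC) fail, which is
deliberately conservative for curation — the point of the filter is high
precision, and short-read evidence cannot rescue an intron the motif
check rejects.

A junction is *evidence-valid* when its exact `(chrom, start, end)`
coordinates occur in the short-read junction database with aggregated
read count ≥ `min_support` (default 1: any orthogonal observation
validates; the threshold is exposed because deeper short-read data can
justify a higher floor, and retention is provably monotone in it).
Lookup ignores strand by default — short-read aligners infer junction
strand from the same motifs anyway, so coordinates alone identify an
intron; a strand-aware mode exists. Matching tolerance is 0 bp: a
shifted intron is a different intron, which is exactly what makes the
evidence check remove the donor-shift artifact.

A read is retained iff it has ≥ 2 exons and every junction is both
motif- and evidence-valid. Single-exon reads carry no checkable junction
and are never retained; they are excluded from isoform calling rather
than rescued, because nothing distinguishes a genuine mono-exonic
transcript from genomic-DNA contamination or a severely truncated read.

## Collapse

Isoform identity is the junction code — chromosome, strand, and the
ordered intron chain. Collapse groups retained reads by code; the model
extent is the furthest observed start and end across members (truncation
makes per-read ends unreliable, so the extremes are the best available
estimate of the true TSS/TES), and support is the member count. Output
order is (chrom, start, code text), making the operation invariant to
input permutation. Codes differing by a single base are distinct models:
no fuzzy merging.

Fragment absorption (`subset_collapse`) is off by default: merging a
model whose chain is a contiguous sub-chain of a longer model's chain is
plausible — truncated reads produce exactly such fragments — but
destroys real short isoforms that share their introns with a longer
form, so exact-code merging is the conservative default and absorption
is a flag. When enabled, a fragment is absorbed only if its terminal
exons do not reach into the flanking introns of the host chain, and its
extent extends the host only when the matched sub-chain sits at the
host's boundary.

## Classification

The annotation contributes one code per multi-exon transcript
(single-exon transcripts have no code, consistent with the validation
rule). Categories partition the models:

* `annotated` — code present in the annotation's code set;
* `novel_isoform_known_gene` — unannotated code whose model span shares
  ≥ 1 bp with some gene's genic region;
* `novel_gene` — unannotated code overlapping no genic region.

A genic region is the union of a gene's transcript spans, introns
included — an isoform living entirely inside a known gene's intron still
belongs to that gene for bookkeeping purposes. Overlap is
strand-agnostic by default (the comparison is a locus-level intersect,
and antisense transcripts overlapping a known gene are not "new genes");
a strand-specific flag exists. Novel-gene model spans are clustered by
single-linkage any-overlap per chromosome into candidate new gene
regions.

Exon-level novelty uses the same any-overlap convention: a model exon is
novel only if it shares zero bases with every annotated exon on its
chromosome. Distinct exons are counted by exact coordinates, so
alternative ends of one internal exon count separately; this is the only
reproducible rule absent a merging criterion, and it is applied
consistently in the new-gene exon counts.

In the summary, "genes with new annotations" counts distinct annotated
genes that received at least one novel isoform plus the new gene
regions, so that every new annotation maps into exactly one counted
region.

## Analytics

* **Overlap matrix** — per pair of named feature sets, the percentage of
  row elements whose span intersects (≥ 1 bp) any column element's span.
  Span-level, strand-agnostic, asymmetric; the diagonal of a non-empty
  set is 100 %. Empty sets render `NA`.
* **Coverage profile** — per annotated transcript, exonic bases covered
  by the union of read exons. Transcript length is exonic length (read
  coverage is exonic, so the ratio must be too). The ">90 %" histogram
  uses a strict inequality: a transcript covered exactly 0.90 of its
  length is not counted. Length-bin edges default to 0–6000 in 250-bp
  steps with an open overflow bin.
* **Splice-distance profile** — for each observed junction, the donor is
  the intron start on `+` and the intron end on `-`; the acceptor is the
  converse. The signed offset to the nearest annotated site of the same
  kind on the same chromosome is flipped on the minus strand so that
  positive always means downstream in transcript direction — the
  donor-shift artifact therefore appears as a positive peak in (0,
  max_shift]. Window defaults to ±50 bp at 1-bp resolution; farther
  sites land in an overflow bucket; equidistant ties resolve to the
  lower-coordinate site. Junctions with unknown strand are skipped
  (their offsets cannot be oriented).

## Simulator

The generator emulates the study design the pipeline targets: a genome,
an annotation with alternative isoforms, spliced long reads with the two
characteristic error modes, and junction-level short-read evidence.

Geometry: `n_genes` (default 20) laid out round-robin across `n_chroms`
(2) chromosomes of `chrom_length` (100 kb) with 200–1000 bp intergenic
gaps. Each gene has a master chain of 3–6 exons of 80–300 bp separated
by introns of 60–400 bp; 2–4 isoforms per gene are the master chain plus
exon-skipping variants (internal exons dropped), so isoforms of one gene
share exon boundaries but differ in intron chain — matching how
alternative isoforms share splice sites in real annotations. Every
planted intron receives canonical dinucleotides in gene orientation.
Each intron also carries a decoy donor dinucleotide at a random offset
of 4–`max_shift` (10) bases downstream of the true donor, reflecting the
observation that donor misplacement happens at sites with multiple
candidate donors, and guaranteeing the shift artifact has a target.

Reads: 5–20 per isoform. Truncation (defaults: 0.4 probability at 5′,
0.2 at 3′, reflecting libraries in which roughly half the reads fail to
span their transcript) removes a uniform number of whole terminal exons —
possibly down to a single exon — and trims the new terminal exon's outer
edge; internal junction coordinates are never altered, so truncated
reads are exact contiguous sub-chains of their source isoform. The
donor shift moves, with probability `p_donor_shift` per junction, the
donor-side intron boundary to the nearest downstream canonical
dinucleotide within `max_shift` bases (transcript orientation); the
shifted junction is motif-valid by construction but absent from the
short-read evidence, which is precisely the error class the evidence
check exists to remove.

Evidence: every true junction of every isoform — including hidden genes,
since short reads observe the transcriptome rather than the annotation —
is emitted with a count drawn from 5–50, omitted with probability
`p_junction_unsupported` (default 0). Artifact junctions are never
emitted.

Hiding: `n_hidden_genes` genes and `n_hidden_isoforms` non-first
isoforms of visible genes are excluded from the emitted annotation,
giving ground truth for the `novel_gene` and
`novel_isoform_known_gene` categories respectively.

Determinism: four independent RNG streams (genome, reads, hiding,
evidence) are derived from the single seed, so identical configurations
give byte-identical output files.

What the simulator does **not** model: base-level sequencing errors and
indels (reads are coordinate-perfect apart from the two structural error
modes), realistic expression-level distributions (read counts are
uniform per isoform), overlapping or nested genes, alternative 5′/3′
terminal exons (isoform variation is exon-skipping only), non-canonical
splice classes, and read-level short-read simulation (evidence is
junction-level because the pipeline consumes junctions). Passing tests
therefore demonstrate the correctness of the curation logic under its
own assumptions — exact junction coordinates, canonical splicing — not
robustness to base-calling noise, which in real data is the aligner's
problem, upstream of this pipeline's contract.

## Problem sizes and numerical choices

Tests and the acceptance script run on the default geometry (20 genes,
~50–60 isoforms, ~600–800 long reads, ~100 junctions, two 100 kb
chromosomes), which exercises every code path in seconds while keeping
brute-force per-base oracles (explicit base-set intersection) feasible
as independent checks. Donor-shift rate recovery uses 15–25 reads per
isoform (≥ 2000 junction observations) so the observed artifact fraction
is compared to its expectation within a 99 % binomial confidence
interval. There is no floating-point tolerance anywhere in the core:
every comparison is integer interval arithmetic or exact string
equality, which is why determinism can be asserted at the byte level.

## Known limitations

* The pipeline starts from spliced alignments in BED12; it does not
  parse SAM/BAM or re-align reads.
* Novel single-exon transcripts are invisible by design: validation
  requires at least one junction.
* One extent per code: multiple TSS/TES clusters within one intron chain
  are not separated.
* The evidence check is exact-coordinate; a true junction absent from
  the short-read data (shallow coverage, tissue mismatch) removes every
  read that contains it. This is the intended precision/recall
  trade-off, tunable only in the direction of more stringency
  (`min_support`).
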