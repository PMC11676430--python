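# Methods

## Pair-finding model

A gene is reduced to its gene-level span and strand; its TSS is the 5′-most
annotated position of the gene feature (`start` on +, `end` on −). Working at
gene level is an assumption: alternative promoters and per-transcript TSSs
are ignored, so a pair's "inter-TSS" region is only as accurate as the gene
boundaries in the annotation.

Candidate pairs are one minus- and one plus-strand gene on the same
chromosome with |TSS₊ − TSS₋| strictly below the threshold (default 1000 bp;
999 passes, 1000 fails). Two further rules make the catalog well defined:

* **Adjacency.** No third gene's TSS may lie strictly between the pair's
  TSSs. Nested or overlapping third genes whose TSS falls outside the
  inter-TSS window do not block a pair. The synthetic suite includes a
  stress case where an intervening TSS breaks an otherwise valid pair and
  the interloper pairs instead.
* **One pair per gene.** When a gene has several candidate partners, the
  smallest TSS distance wins; exact ties are broken by the lexicographically
  smaller partner id, making output deterministic. A consequence worth
  knowing: raising the threshold only appends candidates with larger
  distances, so previously reported pairs are preserved verbatim (this is
  tested).

A pair has overlapping 5′ ends iff TSS₊ ≤ TSS₋. Equality is classed as
overlapping: a zero-length inter-TSS region cannot act as a spacer.
Mitochondrial and unplaced sequences are treated like any chromosome.

Gene density is genes/Mb per chromosome; the divergent ratio is the fraction
of a chromosome's genes that sit in pairs. The density–pair correlation is a
standard Pearson product-moment r (scipy), with both response choices
(pair count and divergent ratio) exposed because either is a defensible
reading of "distribution vs density"; the genome-total row is excluded, and
zero variance raises an undefined-correlation error rather than returning a
value.

## Promoter fragments

Fragment spans are inclusive of both boundary coordinates:
[min(TSS), max(TSS)] for the between-TSS mode, so a non-overlapping pair at
distance d yields d + 1 bp and an overlapping pair still yields a
non-degenerate fragment. The ±1 convention is arbitrary and declared here
and in output metadata. The between-ATG mode spans the two start-codon A
positions (5′-most CDS base per gene, strand-aware) and exists for
validation-style cloning of pairs whose TSSs are too close to cover the
promoter.

Controls are `upstream_bp` (default 1000) windows upstream of `n`
(default 3000) genes outside every pair, sampled without replacement under a
seed; a minus-strand gene's window extends rightward on the reference and is
reverse-complemented. Genes whose window would run off the contig are
ineligible rather than padded, which slightly biases controls away from
contig edges.

GC content is (G+C)/(A+C+G+T) with N and other ambiguity codes excluded from
the denominator; an all-ambiguous sequence has undefined GC and is dropped
from GC summaries (but kept in length histograms). GC is reported on the
reference plus strand; it is strand-invariant, and that invariance is a
tested property. Histograms use left-closed/right-open bins — 100-bp length
bins, 20-point GC bands with the last band closed at 100 — with the edges
recorded in the summary JSON.

## Expression classification

The per-tissue rule is ordered: both FPKM < 1 → co-silent; otherwise the
ratio a/b decides, co-expressed inside the closed band [0.25, 4]. Reading
the band as closed, and letting the ratio decide the mixed case (one gene
above 1, the other below), are the two places the rule needed a decision;
both are pinned by boundary tests. A single zero FPKM gives an infinite (or
zero) ratio → unidirectional; both-zero is co-silent via the first clause.
The rule is symmetric in its arguments because the band is
reciprocal-symmetric — a tested property.

Replicates are combined by mean FPKM per gene *before* classification.
Classify-then-vote across replicates is a plausible alternative; mean-first
was chosen because it is deterministic for even replicate counts and uses
all reads. With fewer than ~3 replicates and FPKMs near 1, the two schemes
can disagree.

Cross-tissue overlap is a three-set Venn: seven disjoint region counts that
partition the union (conservation tested). The 2^−ΔΔCt helper implements the
standard relative-expression estimate from target/reference Ct values in
treated vs control samples.

## Motif scanning

Core elements are fixed-length character-class patterns (TATA, INR, BRE,
DPE, CCAAT as listed in the README), matched window by window — equivalent
to regex matching here, but stated because it fixes overlap semantics: every
matching window is reported, with no greedy masking. Windows containing N
never match. Minus-strand hits are found by scanning the reverse complement
and reflecting coordinates, so both scanners satisfy an exact strand-mirror
property. The DPE pattern is short and degenerate and therefore matches
densely; no TSS-distance filter is applied, so DPE counts should be read as
pattern density, not as validated elements.

PWMs are built from JASPAR count matrices as
`w[b,i] = log2(((c[b,i] + p·q[b]) / (Σ_b c[b,i] + p)) / q[b])` with
pseudocount p = 0.8 split by the background q (uniform 0.25 by default) —
the construction used by the common JASPAR toolchains, with every constant
exposed as a parameter. The relative score of a window rescales its score
between the matrix's attainable extremes (per-column minima/maxima sums);
the default report threshold is 0.70. Relative scores are invariant to
scaling all counts (with the pseudocount scaled alike) to 1e−9, and the
scanner is checked window-for-window against a naive per-window matcher and
against the Biopython PSSM log-odds as an independent reference for the
weights themselves.

## Synthetic data: what it does and does not emulate

The generator plants loci (pairs and single background genes) left to right
on each chromosome with ≥ 2 kb separation — comfortably above the 1 kb
pairing threshold — so the planted pairs are provably the only divergent
pairs and closed-loop recovery must be exact, not approximate. Inter-TSS
distances are drawn from Beta(1, 1.357) rescaled to [1, 999], which places
about half the mass below 400 bp, matching the compactness of fish BDPs; the
sampler is injectable. A fixed fraction of pairs (default 0.20) is planted
with overlapping 5′ ends. Base composition is achieved by per-base sampling
probabilities (default 42% GC inside BDP fragments, 38% elsewhere), not by
post-hoc editing, so local composition is realistic at the dinucleotide
level only in expectation. Genes get a minimal gene/mRNA/CDS structure with
a 20–60 bp 5′ UTR so the between-ATG mode is exercised; there are no
introns, no isoforms, no repeats, and no CpG-island structure.

Expression tables realize planted states with margins away from the decision
boundaries (co-expressed ratios within [0.4, 2.5], unidirectional ratios
≥ 6, silent FPKMs ≤ 0.7) and multiplicative lognormal replicate noise at a
given CV (default 0.2, mean-preserving). Planted per-tissue proportions
default to the values observed across medaka gonads, brain, and liver.
Consequently, passing recovery tests shows the classifier implements the
rule correctly and robustly at realistic noise — it does *not* show that
real tissues satisfy the margins, and real FPKM values near the thresholds
will classify less stably than the synthetic ones.

Everything is a deterministic function of (spec, seed) via a single
`numpy.random.Generator`; byte-identical FASTA/GFF/TSV across reruns is a
tested contract.

## Problem sizes and numerical choices

The packaged per-chromosome survey table is desk-scale arithmetic and runs
in milliseconds. Closed-loop acceptance computations use 200 planted pairs
(recovery), 500 fragments (GC/length summaries), 1000 pairs (expression
proportions), and 100 random sequences of 50–500 bp (scanner-oracle
agreement) — sizes at which binomial sampling error is well inside the
stated tolerances (±1.5 GC points at n = 500; ±3 proportion points at
n = 1000) while the whole script stays in the seconds range. No tolerances
are applied where exactness is achievable: pair recovery, state recovery at
zero noise, scanner-oracle agreement, and determinism are all checked for
equality.

The density–pair Pearson correlation over the packaged survey table is
dominated by the mitochondrial row (density 1850/Mb vs ~30–50 for nuclear
chromosomes): r ≈ −0.72 with MT, ≈ +0.57 (counts) or ≈ +0.06 (ratio)
without. The package therefore reports r for whichever rows and response
the caller supplies and takes no position on a single headline value.

## Known limitations

* Gene-level TSSs only; no per-transcript promoter resolution.
* The one-pair-per-gene rule is a modeling choice; genomes with genuinely
  shared hub genes would need a multi-pair variant.
* FPKM tables are taken as given; no quantification or normalization is
  performed, and comparisons across tissues inherit whatever biases the
  upstream quantification carried.
* The PWM scanner reports pattern matches, not binding: no conservation,
  chromatin, or positional prior is used.
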