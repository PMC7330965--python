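# Methods

This note records the models, rules and numerical choices behind
`lncscan`, what the synthetic-data generator does and does not emulate,
and the known limitations of the statistical components.

## Transcript model and coordinates

All interval arithmetic uses 0-based half-open coordinates on the forward
genomic strand; GTF I/O converts to and from that format's 1-based
inclusive convention at the boundary, so the conversion appears exactly
once in the code base. Exon chains are sorted and checked disjoint at
construction. Transcripts with unresolved strand (`.` in GTF) are
rejected outright: the AS-event vocabulary and the antisense class are
both strand-dependent, and a strandless transcript cannot be placed in
either. Gene grouping trusts the file's `gene_id` — upstream assembly
comparison tools have already clustered transcripts into loci, and
re-clustering here would silently change their identities.

## Identification cascade

The screen applies, in order: a candidate filter (spliced length strictly
greater than 200 nt AND at least 2 exons; the exon rule is a deliberate
strictness against single-exon assembly noise and can be relaxed to 1), an
ORF-length coding screen, and positional classification. Every input
transcript lands in exactly one bucket — `filter_failed`, `coding`,
`sense_overlap`, `genic_other`, `lincRNA`, `incRNA`, `antisense` — so the
partition can be audited.

**Coding screen.** External coding-potential tools (CPC/CNCI/CPAT-style
classifiers, domain scans) are replaced by a transparent ORF-length rule:
a transcript is coding when its longest coding stretch reaches
`orf_max_aa = 100` aa. Both complete ORFs (ATG through an in-frame stop)
and stop-free ATG-led open stretches count as coding capacity — an
assembled fragment of a real mRNA often lacks the stop codon, and treating
a 900-nt open frame as noncoding would be indefensible. Only the three
frames of the annotated strand are scanned, matching how coding tools
treat strand-resolved assemblies. The 100-aa default sits far above the
ORF lengths of identified plant lncRNA populations (mean ≈ 96 nt ≈ 32 aa)
and far below genuine mRNA ORFs, so the rule is insensitive to modest
threshold changes; it is configurable.

**Positional classes.** Precedence is same-strand exonic overlap
(dropped, unresolvable from the sense mRNA population) > antisense
(exon-exon opposite-strand overlap — exonic evidence outranks
containment) > incRNA (whole transcript inside a single intron of a
coding gene, either strand; introns are the gaps of the gene's merged
exon union) > lincRNA (no overlap with any coding-gene span). A
transcript overlapping a gene span while matching none of these (an exon
hanging off a gene end without touching its exons) is dropped as
`genic_other`; the five named outcomes alone cannot be total.

**Per-chromosome distribution.** The result carries lncRNA counts per
chromosome, lncRNAs per hundred reference genes, transcribed-gene counts
(gene FPKM ≥ 0.1 in ≥ 1 library) and the Pearson correlation (two-sided
t-test) between per-chromosome lncRNA and transcribed-gene counts. With
few chromosomes this correlation is only indicative.

**Truncated isoforms.** Within a coding gene, the isoform with the longest
complete ORF is the reference; an isoform is `truncated-noncoding` when it
lacks a complete ORF or encodes less than `trunc_frac = 0.7` of the
reference aa length. The 0.7 default separates frameshift/early-stop
products from isoforms with small in-frame indels; genes with no complete
ORF anywhere are skipped with a warning rather than classified blind.

## Alternative-splicing classification

Two isoforms of one locus (same chromosome and strand, overlapping spans)
are compared as piecewise-constant membership functions over the union of
their exon boundaries (per base: exonic, intronic, or outside the span).
Maximal connected regions where the memberships differ are labelled
independently:

* a region reaching outside one isoform's span is terminal: 5'-side
  differences are TSS, 3'-side TTS (strand-aware);
* an internal region with uniform pattern and exonic context on both
  flanks is IR (one isoform's exon retains the other's intron);
* intronic context on both flanks is ES (a complete exon of one isoform
  inside an intron of the other);
* mixed flanks are AE (an internal exon edge moved — alternative
  donor/acceptor).

Regions matching none of these (e.g. a difference region spanning the
whole locus, or internally heterogeneous patterns) are labelled `other`
and excluded from the five-type summary. Decomposing a comparison into
independently labelled maximal difference regions means a compound variant
emits several events (e.g. skipping two non-adjacent exons gives two ES);
this is the event-decomposition convention of standard AS classifiers.

Locus-level counting deduplicates by (event type, genomic region): an
exon missing from one of three isoforms appears in two pairwise
comparisons but is one physical event. Pairwise counting is available via
`count_mode="pairwise"`. Loci are formed by genomic-span overlap on one
strand. Two single-exon isoforms have no splice structure to compare and
yield no events.

Two mirror properties follow from strand-awareness and are tested:
mirroring coordinates while keeping strand labels swaps TSS↔TTS and
preserves ES/IR/AE (the 5' end lands on the other genomic side), while a
genuine reverse complement (mirror plus strand flip) preserves all five
types.

The summary table reports per-type counts and percentages rounded to two
decimals; five independent roundings can drift the sum from 100.00 by up
to 0.025. A zero-event summary is flagged rather than divided by zero.

## Expression

FPKM is `count · 10⁹ / (library_total · spliced_length)`; library totals
default to column sums but can exceed them (sidecar line in the counts
TSV) when the totals include reads on transcripts outside the table.
Presence for Venn partitions is FPKM strictly above 0.1 (configurable; the
threshold at which a gene counts as transcribed uses the same value).
Seed-specific counts (present in ≥ 1 seed library and absent from the
rest) are reported when the seed libraries are named.

**Differential abundance.** With no replicates per library, the
two-library contrast uses the Audic–Claverie exact conditional test:
under equal Poisson rates, `P(y | x) = (n₂/n₁)^y (x+y)! / (x! y!
(1+n₂/n₁)^(x+y+1))`, the NegBinom(x+1, n₁/(n₁+n₂)) pmf at y; the
two-sided p doubles the smaller tail. q-values are Benjamini–Hochberg.
Retention requires q < 0.01 and |log₂FC| > 1, with fold change on
depth-normalised rates plus a 10⁻⁶ pseudocount for zero-count stability.

Two caveats are inherent and documented rather than hidden. First, the
conditional construction fixes one library as reference, so swapping the
pair is not an exact identity on p (log₂FC negates exactly; retention
sets agree; p agrees on the log scale). Second — and more importantly —
the test models *counting* noise only. Under biological overdispersion
(negative-binomial counts with dispersion α, variance μ + αμ²) its
p-values are anti-conservative by orders of magnitude for counts with
μ ≫ 1/α: the between-library biological variance masquerades as signal.
On a no-difference negative-binomial simulation at the generator's
default dispersion 0.1 about two thirds of 1000 transcripts reach
q < 0.01, while the same code under a Poisson null flags none. This is
precisely why replicate-aware NB models exist; any single-replicate DAL
list, here or in the surveys this pipeline emulates, should be read as a
ranking, not a calibrated discovery set. The acceptance suite measures
both numbers instead of asserting away the problem.

## Target prediction

Gene-level expression is the sum of isoform FPKM. Cis candidates are
coding genes whose span lies within 100 kb of the lncRNA span (closest
edges, same chromosome, either strand); retention requires Pearson and
Spearman both at |r| ≥ 0.6 with agreeing sign and both p < 0.05 (the
conjunctive reading; a disjunctive mode is exposed). Trans candidates are
the remaining coding genes; retention requires Pearson r > 0.9 with
p < 0.05 and, optionally, the complementarity screen. Cis-retained genes
are not duplicated as trans for the same lncRNA.

**Correlation scale.** Correlations are computed on log₂(FPKM + 0.01) by
default. Expression across organs is log-normal-like; raw-scale Pearson
is dominated by the largest values, and under multiplicative counting
noise of CV² ≈ α it is bounded near 1/(1+α) ≈ 0.91 at α = 0.1 no matter
how tightly two transcripts are co-regulated — which would make the 0.9
trans threshold unreachable in principle. On the log scale the counting
noise is additive (≈ α + 1/μ) and strong co-regulation is measurable.
Spearman is unaffected by the transform. `log_transform=False` restores
raw-scale behaviour.

With four libraries the correlation p-values are nearly powerless
(|r| ≥ 0.95 is needed for p < 0.05 at n = 4); the module warns below six
libraries and proceeds, matching the realities of small organ panels.
Incidentally retained pairs under n = 4 should be expected.

**Complementarity.** The LncTar-style energy model is replaced by a
transparent base-pair-weight score: the lncRNA is reversed (antiparallel
hybridisation) and slid along the mRNA over all offsets at which the
shorter sequence is fully contained; each aligned pair scores GC = −3,
AU = −2, GU = −1, mismatch 0, and the sum is normalised by the
paired-region length (≤ 0; more negative is stronger). Full containment
is required because partial overlaps would make the per-nt minimum
degenerate (a single GC pair scores −3.0). Note that random uniform
sequences average ≈ −0.75/nt under these weights, so the default cutoff
of −0.1/nt is permissive — the filter mainly removes pairing-free
(e.g. composition-skewed) pairs, and the correlation rule does the heavy
lifting. The cutoff is configurable and the filter switchable.

## Synthetic data

The generator emulates the *inputs* of a four-library organ panel
(root, leaf, two developing-seed stages) over a small multi-chromosome
genome with an A/B subgenome naming scheme; defaults are four chromosomes
of 400 kb, 100 coding genes of 2–10 exons, ten planted lncRNAs per
positional class, one AS locus per event type, negative-binomial
dispersion 0.1 and 10⁶ mapped reads per library — desk-scale stand-ins
for a crop transcriptome, not a read-level simulation.

Placements are constructive, not sampled-and-checked: coding genes carry
a written-in CDS of ≥ 147 aa; lncRNA loci are filled with ATG-free
sequence interleaved every 24 nt with a G-free block containing stop
codons in all three frames, so no planted lncRNA (including splice
variants over the locus and antisense transcripts that borrow ≤ 84 nt of
a host coding exon) can harbour an ORF of 50 aa or more — a 2× margin
below the 100-aa screen. Both margins are re-verified after generation
and violation is an error. Chromosome loading is deterministically
unequal (bounded weights) so per-chromosome distribution statistics are
non-degenerate. Everything derives from one integer seed via numpy's
PCG64; identical designs give byte-identical output files.

Counts: per-transcript log-normal baselines (σ = 1.2), per-library
log-normal organ effects (σ = 1.5), negative-binomial sampling
(variance μ + αμ²), per-library depth normalisation. Venn designs are
enforced by zeroing planted lncRNAs in absent libraries (presence in the
remaining libraries is then essentially certain: dropout probability
< 10⁻⁷ at the planted abundances). Planted lncRNA–gene correlations
share the lncRNA's library profile plus Gaussian noise whose variance is
calibrated so the *observed* log-scale correlation — after the
counting-noise variance α + 1/μ on both sides — is centred on the target
r; without that correction NB sampling attenuates a planted 0.95 to
≈ 0.85–0.90. Correlation-plan lncRNAs are kept all-present (zeroed
libraries would destroy the planted correlation), and trans partner
genes are placed on a different chromosome than their lncRNA.

Because the paper-style four-library panel leaves correlation thresholds
no statistical room (at n = 4 a true r = 0 pair exceeds the 0.6 rule far
too often for a zero-false-positive requirement to be testable), the
correlation-recovery fixtures expand to 48 pseudo-libraries — chosen by a
power analysis so that a null pair passes |r| ≥ 0.6 with probability
≈ 3·10⁻⁶, making "zero decoys retained over 500 decoy pairs" a fair
requirement; the calibration fixture uses 12. This deliberately departs
from the four-library study design and is a validation device, not a
claim about real panels.

What the generator does **not** emulate — and what closed-loop passes
therefore do not establish about real data: read-level errors and
mapping ambiguity, assembly artefacts (fragmented or chimeric models),
homeologous duplication between subgenomes, isoform-abundance mixtures
within a gene, GC/length biases in counting, and correlated biology
between neighbouring genes. The closed loop shows the *rules* are
implemented exactly; on real assemblies the error budget is dominated by
the upstream steps these emulations idealise.

## Numerical and policy details

* ORF ties (equal length) break to the smallest start; open stretches are
  truncated to whole codons; codons containing N never match ATG or stop.
* Complete-ORF aa counts exclude the stop codon and include the Met.
* An empty event summary reports zero percentages with a flag.
* Constant expression vectors make correlation undefined; such pairs are
  skipped rather than given r = 0.
* BH q-values are computed within each two-library contrast.
* `run_all` reruns are byte-identical for a fixed config; all randomness
  lives in the generator, seeded from the design.
* Acceptance-style measurements in `scripts/acceptance.py` derive all
  RNG streams from `--seed` (kept below 2³¹) and touch nothing outside
  the repository.
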