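# Methods

This note documents the statistical model, the simulator, numerical choices
and the limits of what the test suite shows. Everything quantitative stated
here is computed by the package's tests or scripts; nothing is asserted from
memory.

## Association scan

Each SNP with calls in four states (hom-A, het, hom-B, missing) is reduced
to two 2×2 case/control tables: {hom-A} vs {het + hom-B} and {hom-B} vs
{het + hom-A}. Both are tested with a two-tailed Fisher exact test; the
per-SNP summary is −log₁₀ of the smaller p-value. This pooling targets a
recessive model directly: under recessive inheritance the affected dogs
concentrate in one homozygote class, and pooling heterozygotes with the
opposite homozygote is the most powerful 2×2 collapse of the 2×3 genotype
table for that alternative.

The exact test sums hypergeometric point probabilities over all tables with
the observed margins whose probability does not exceed that of the observed
table. Implementation details:

- All point probabilities are computed as log-gamma sums and accumulated
  with `logsumexp`, so −log₁₀(p) stays finite for arbitrarily extreme
  tables (p values far below the 10⁻³⁰⁸ floating-point floor).
- The two-tailed inclusion rule uses a relative tie tolerance of 1 + 10⁻⁷
  on the point probability, the common convention for handling
  floating-point ties; the tests verify equality with an exact
  rational-arithmetic enumeration at 10⁻⁹ relative error, so the tolerance
  only ever matters for genuine ties.
- Missing calls are dropped per SNP; samples with unknown phenotype are
  ignored. A monomorphic SNP is reported with p = 1 rather than dropped, so
  the locus count (and hence the Bonferroni bar) is stable.
- The family-wise bar is log₁₀(n_snps × tests_per_snp / α), counting both
  pooled tests per SNP in the denominator. The function returns the exact
  value; when displayed at two decimals the bar is rounded *upward*, so a
  printed threshold never understates the required evidence.

## Homozygosity blocks and the minimal LD interval

A SNP conforms at stringency k (of n affected samples) when at least k
non-missing calls are homozygous for one shared allele. Three per-SNP roles
follow:

- **conforming** — extends a run and counts toward its SNP tally;
- **neutral** — conformity fails only because of missing calls
  (homozygotes + missing ≥ k): the run passes over the SNP. Without this
  role, realistic no-call rates would shatter every full-stringency block,
  because any single missing call at any SNP would end the run;
- **breaking** — discordant called genotypes exceed n − k: the run ends.

A block is a maximal run on one chromosome, its span measured from first to
last *conforming* SNP with size (end − start)/10⁶ Mb — no +1; the convention
is invisible at reported precision but fixed. At k = n − 1 the
non-conforming dog may differ from SNP to SNP, which makes every n/n block
provably contained in an (n−1)/n block; the census reports both stringency
levels above a size threshold (1.0 Mb by default). The shared allele is
required per SNP, not across the block, since phase is unknown.

The minimal LD interval implements its definition in full: the all-case
block that is *absent from controls* as a shared homozygous haplotype.
Candidate blocks are ranked lexicographically by (at most one conforming
control, overlap with the association-peak region, size). A conforming
control is annotated, never used to shrink the interval — the one dog that
did conform in the mapped study turned out to be affected. The pipeline
builds the interval on the chromosome carrying the peak signal and passes
the span of genome-wide-significant SNPs as the anchor region.

## Dosage correlation and multiplex classification

Genotypes are coded as dosages (0/1/2 copies of a designated allele) and
compared by Pearson correlation over pairwise-complete samples. Pearson r on
dosage is invariant to which allele is designated (jointly flipping both
vectors negates nothing), and symmetric. A constant vector or fewer than two
complete pairs returns an explicit `None` ("undefined"), never a NaN that
could propagate. The multiplex classifier maps observed amplicon sizes to
NORMAL / CARRIER / AFFECTED and returns UNCALLED with a reason for an empty
or unexpected size set; it is total over all subsets of the two expected
sizes.

## Deletion model and consequence prediction

For two equal-length, non-overlapping repeat copies on one chromosome,
unbalanced recombination removes |Δstart| bases — the segment between
homologous repeat positions — and leaves a single chimeric copy. The
canonical removed interval is [low.start, high.start − 1]; any crossover
offset shifts the interval without changing its length or whole-exon
content. With ≥ 2 repeat mismatches the crossover window is the open
interval between the first and second mismatch offsets; given the observed
chimeric sequence the window narrows to (last offset carrying the low-copy
variant, first offset carrying the high-copy variant), with interleaved
variants rejected as inconsistent with a single crossover. With < 2
mismatches the whole repeat is returned, flagged.

Consequence prediction accepts only whole-exon deletions (a partial-exon
overlap raises: cryptic splicing is out of scope). The mutant mRNA is the
splice of the remaining exons in transcript order; translation starts at the
original start codon; codons are scanned for the first stop. The reported
stop position is the 1-based offset of the stop codon's *last* base within
its (original-numbering) exon, so "base 6 of exon 17" denotes a stop
occupying bases 4–6. Retained residues exclude the stop;
retained + lost = normal protein length = CDS/3 − 1. Edge cases: a deletion
removing the start-codon exon is flagged `NO_PROTEIN`; no stop before the
transcript end is flagged `NONSTOP`; deleting zero exons reproduces the
normal protein exactly, with no premature-stop fields. Domain status is
purely positional: intact if the domain ends within the retained length,
lost if it starts beyond it, partial otherwise. Reverse-strand genes store
exons in transcript order (descending genomic coordinates); all consequence
outputs are invariant under reverse-complementing the genome and flipping
the strand label (tested).

In-silico PCR is exact-match: the forward primer on the given strand, the
reverse primer as its reverse complement downstream; product length is the
inclusive span. Multiple sites return every admissible product with an
ambiguity flag; `max_size` emulates the extension limit of a protocol
(used to express that a >24 kb product does not amplify while the 1.5 kb
collapsed-allele product does).

## The breed simulator

The simulator emulates a small-founder, closed, inbred population
segregating a recessive disease, ascertained the way the mapped study
ascertained its dogs.

- **Founders.** `n_founder_haplotypes` (default 20) haplotypes with allele
  frequencies drawn per locus from a symmetric Beta(0.8, 0.8) prior. SNP
  columns are redrawn until polymorphic among the founders, emulating a
  genotyping chip's ascertained marker panel — a real panel contains no
  a-priori monomorphic markers, and without this step fixed stretches would
  masquerade as homozygosity blocks.
- **Panel.** 5 chromosomes × 1,000 SNPs over 40 Mb each (25 SNPs/Mb, the
  genome-wide density of the mapped study's 60k panel), positions uniform.
  The disease mutation is a hidden pseudo-locus at a configurable position,
  carried by founder haplotype 0, and excluded from the released panel.
- **Pedigree.** Discrete generations (default 8, a few decades of dog
  breeding at a 4–5 year generation interval) of `n_individuals_per_generation`
  (default 30), random mating with a carrier-mating bias (0.3, rising to
  0.7 in the last three generations) so the recessive allele survives drift.
  Meiosis draws a Poisson number of crossovers per chromosome (default mean
  0.5, ≈1.25 cM/Mb) with uniform positions and no interference. Founder
  origin is tracked per locus alongside alleles, which yields exact realized
  IBD tracts for the truth record.
- **Ascertainment.** Cases and controls are sampled as small litters
  (1–3 pups) from matings within a restricted pool of ~6 breeding carriers —
  the popular-sire structure of closed breeds. This collapse of ancestral
  paths is what gives the cases a shared homozygosity block of a few Mb
  around the mutation (measured median ≈ 3 Mb at defaults), while the small
  litters keep the cases as weakly related as such a design allows,
  mirroring a least-related case selection. Controls are unaffected
  litter-mates and half-sibs — a family-matched design; unmatched random
  controls would introduce case/control stratification and genome-wide
  false association peaks. If the mutation is lost or the requested counts
  cannot be realized, a `SimulationError` explains which knob to change.
- **Noise.** Genotyping noise concentrates in a small fraction of poorly
  performing assays (default 3% of loci with 30% no-calls and 5% wrong
  calls) on top of low per-call rates at well-behaved loci (1.5% missing,
  10⁻⁴ error) — the clustered-error structure of array genotyping, in which
  most duplicate discordance is no-call-vs-call and bad assays are exactly
  what call-rate QC removes. Errors replace a call with a different called
  state; missingness is applied last.
- **Null mode.** `disease_chromosome=None` simulates the same population
  without ascertainment and with phenotype labels unrelated to genotype,
  for family-wise-error studies.

Everything is deterministic given `seed` (single `numpy` Generator;
byte-identical output files).

**What the simulator does not emulate:** coalescent-accurate LD decay,
real CanFam sequence or marker spacing, genotype-intensity-level artifacts,
interference in recombination, overlapping generations or realistic
pedigree records. Passing recovery tests therefore show that the pipeline
correctly exploits the *structure* the study relied on (founder IBD,
recessive ascertainment, matched controls), not that it would perform
identically on any particular real panel.

## The gene/genome fixture

The fixture is a synthetic minus-strand, 22-exon gene on a ~33 kb synthetic
chromosome whose structural numbers equal the published canine *ADAM9*
values: 2,781 nt mRNA = 29 nt 5′UTR + 2,460 nt CDS (819 aa) + 292 nt 3′UTR;
exons 15–16 total 290 nt (not divisible by 3, forcing the frameshift);
exons 1–14 carry 1,593 coding nt (divisible by 3, so the junction falls on
a codon boundary); two 1,278 bp intronic repeats with 6 mismatches and
genomic starts 23,221 bp apart flank exons 15–16. The CDS is generated from
stop-free sense codons and then the first seven bases of exon 17 are
patched to `CAATGAC`: in the post-deletion frame this reads CAA·TGA (stop
ends at base 6 of exon 17); in the normal frame the affected codons stay
sense because every stop codon ends in A or G, so a codon ending in the
patched C cannot be a stop. Generation order is not the contract — a
validation pass re-derives every structural invariant from the emitted
sequences (normal translation, mutant transcript length, stop position,
deletion size) and refuses to return an inconsistent fixture. Two primer
assays are placed to reproduce the multiplex genotyping logic: one pair
inside the deleted intron 15 (602 bp product, normal allele only) and one
deletion-flanking pair (24,736 bp on the normal allele — beyond any
extension limit — collapsing to 1,515 bp on the mutant).

## Problem sizes and numerical choices

The test suite and acceptance checks run at the sizes the analyses were
designed around: 42-dog panels of 5,000 SNPs; 50 simulated breeds for the
truth-locus recovery rate; 200 single-chromosome null replicates of 1,000
SNPs for the family-wise error bound; exhaustive Fisher-oracle comparison
for all tables of total ≤ 16 plus 600 sampled tables up to N = 60; block-
finder oracle comparison on 10 × 300 matrices. Homozygote-class ties in
`snp_conforms` (possible only at k ≤ n/2) resolve to the A allele;
chromosome labels sort numerically when integer-like, then lexically;
coordinates are 1-based inclusive internally with BED exports converted to
0-based half-open.

## Known limitations

- The truth-locus recovery rate at default conditions is limited by marker
  resolution: a crossover landing in the single SNP gap flanking the
  mutation truncates the detected block one SNP short of the locus. At
  25 SNPs/Mb this bounds recovery at roughly 95% regardless of pipeline
  choices.
- Genotypes are unphased throughout; the block statistic is
  homozygosity-by-state per SNP, not a haplotype model, and no
  HMM/probabilistic ROH caller is provided.
- The Fisher scan assumes exchangeable labels within the matched design; it
  applies no stratification or mixed-model correction (none was used in the
  workflow it implements).
- The consequence model does not predict cryptic splicing, NMD, or protein
  structure; repeat coordinates are inputs, not discovered by alignment.
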