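"""Synthetic study data: a closed-breed gene-drop simulator and an
ADAM9-like gene/genome fixture.

The simulator emulates the statistical structure of a small-founder,
heavily inbred breed segregating a recessive retinal disease: founder
haplotypes drawn from a symmetric Beta allele-frequency prior, discrete
generations of random mating with Poisson-distributed crossovers (no
interference), carrier-biased matings in the final generations, and a
case/control sample ascertained on mutation homozygosity.  Sporadic
missing calls and genotype errors are injected last.  The ground truth
(mutation locus, carrier founder haplotype, per-sample mutation genotype,
realized IBD block per case) is emitted alongside the genotypes for
parameter-recovery tests.

The gene fixture is a synthetic minus-strand 22-exon gene whose structural
numbers match the published canine ADAM9 transcript: a 2,781 nt mRNA
(29 nt 5'UTR + 2,460 nt CDS + 292 nt 3'UTR, 819 aa), exons 15–16 totalling
290 nt, two intronic 1,278 bp LTR-like repeats with 6 mismatches whose
start coordinates differ by 23,221 bp, and an engineered premature stop
ending at base 6 of exon 17 in the post-deletion reading frame.  Sequences
are generated and then patched to satisfy the stop-codon constraints; a
validation pass over the emitted model, not generation order, is the
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .deletion_model import (
    DeletionEvent,
    GeneModel,
    GenomicInterval,
    RepeatPair,
    apply_deletion,
    nahr_deletion,
    transcript_consequence,
    write_domain_table,
    write_gene_gff3,
)
from .genotype_io import CASE, CONTROL, MISSING, GenotypeMatrix, SnpLocus

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulationError",
    "simulate_breed",
    "write_truth",
    "read_truth",
    "FixtureSpec",
    "GeneFixture",
    "generate_gene_fixture",
]


class SimulationError(RuntimeError):
    """Raised when the requested case/control sample cannot be realized."""


@dataclass
class SimConfig:
    """Parameters of the closed-breed simulation.

    Defaults are sized to the mapped study: 20 cases and 22 controls from a
    breed founded by a handful of dogs, genotyped on a scaled panel of
    ~5,000 SNPs over 5 chromosomes.
    """

    n_founder_haplotypes: int = 20
    n_generations: int = 8
    n_chromosomes: int = 5
    chromosome_length_bp: int = 40_000_000
    n_snps_per_chromosome: int = 1000
    recombination_rate: float = 0.5  # expected crossovers per chromosome per meiosis
    allele_frequency_prior: tuple[float, float] = (0.8, 0.8)  # Beta shape parameters
    missing_rate: float = 0.015  # per call, well-behaved loci
    genotype_error_rate: float = 1e-4  # per call, well-behaved loci
    bad_locus_rate: float = 0.03  # fraction of poorly performing assays
    bad_locus_missing_rate: float = 0.30
    bad_locus_error_rate: float = 0.05
    n_cases: int = 20
    n_controls: int = 22
    disease_chromosome: Optional[str] = "3"
    disease_position: int = 24_000_000
    n_individuals_per_generation: int = 30
    litter_size_range: tuple[int, int] = (1, 3)  # sampled per mating (inclusive)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.genotype_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.n_founder_haplotypes < 4 or self.n_founder_haplotypes % 2:
            raise ValueError("n_founder_haplotypes must be an even number >= 4")


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated panel."""

    chromosome: str
    position: int
    founder_haplotype: int
    genotypes: dict[str, int]  # sample id -> mutation dosage, pre-error
    ibd_blocks: dict[str, tuple[int, int]]  # case id -> (start, end) bp

    def case_ids(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g == 2]


def _sample_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.3) + 8))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _meiosis(
    rng: np.random.Generator,
    h1: np.ndarray,
    h2: np.ndarray,
    o1: np.ndarray,
    o2: np.ndarray,
    chrom_slices: list[slice],
    chrom_positions: list[np.ndarray],
    length_bp: int,
    rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: allele and founder-origin arrays after recombination."""
    gam = np.empty_like(h1)
    org = np.empty_like(o1)
    for sl, pos in zip(chrom_slices, chrom_positions):
        k = rng.poisson(rate)
        start = rng.integers(2)
        if k == 0:
            use2 = np.full(pos.size, bool(start))
        else:
            xs = np.sort(rng.uniform(1, length_bp, size=k))
            use2 = ((start + np.searchsorted(xs, pos)) % 2).astype(bool)
        gam[sl] = np.where(use2, h2[sl], h1[sl])
        org[sl] = np.where(use2, o2[sl], o1[sl])
    return gam, org


def simulate_breed(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Gene-drop a recessive mutation through a closed breed and sample a
    case/control panel.

    Deterministic given ``config.seed``.  Raises :class:`SimulationError`
    when the requested number of mutation homozygotes cannot be realized
    (e.g. the mutation drifts out of the population) — rerun with another
    seed, more founder carriers, or fewer generations.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]

    # loci per chromosome, plus one hidden mutation pseudo-locus
    ascertained = config.disease_chromosome is not None
    loci: list[SnpLocus] = []
    mut_idx = -1
    for c in chroms:
        pos = _sample_positions(rng, config.n_snps_per_chromosome, config.chromosome_length_bp)
        if ascertained and c == config.disease_chromosome:
            pos = pos[pos != config.disease_position]
            pos = np.sort(np.append(pos, config.disease_position))
        for p in pos:
            if ascertained and c == config.disease_chromosome and p == config.disease_position:
                mut_idx = len(loci)
                loci.append(SnpLocus(id="__mutation__", chromosome=c, position=int(p)))
            else:
                loci.append(
                    SnpLocus(id=f"snp_{c}_{int(p)}", chromosome=c, position=int(p))
                )
    n_cols = len(loci)
    if ascertained and mut_idx < 0:
        raise ValueError("disease_chromosome not among simulated chromosomes")

    positions = np.array([loc.position for loc in loci])
    chrom_labels = np.array([loc.chromosome for loc in loci])
    chrom_slices, chrom_positions = [], []
    for c in chroms:
        idx = np.flatnonzero(chrom_labels == c)
        chrom_slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
        chrom_positions.append(positions[idx])

    # founder haplotypes; SNP columns are redrawn until polymorphic among
    # the founders, emulating a genotyping chip's ascertained marker panel
    a, b = config.allele_frequency_prior
    n_f = config.n_founder_haplotypes
    freqs = rng.beta(a, b, size=n_cols)
    haps = (rng.random((n_f, n_cols)) < freqs).astype(np.int8)
    for _ in range(100):
        mono = np.flatnonzero((haps.sum(axis=0) == 0) | (haps.sum(axis=0) == n_f))
        if mono.size == 0:
            break
        freqs[mono] = rng.beta(a, b, size=mono.size)
        haps[:, mono] = (rng.random((n_f, mono.size)) < freqs[mono]).astype(np.int8)
    founder_id = 0
    if ascertained:
        haps[:, mut_idx] = 0
        haps[founder_id, mut_idx] = 1
    origins = np.repeat(np.arange(n_f, dtype=np.int16)[:, None], n_cols, axis=1)

    def carrier(ind) -> bool:
        h1, h2, _, _ = ind
        return ascertained and bool(h1[mut_idx] or h2[mut_idx])

    population = [
        (haps[2 * i], haps[2 * i + 1], origins[2 * i], origins[2 * i + 1])
        for i in range(n_f // 2)
    ]

    n_per_gen = config.n_individuals_per_generation
    for g in range(config.n_generations):
        bias = 0.7 if g >= config.n_generations - 3 else 0.3
        carriers = [i for i, ind in enumerate(population) if carrier(ind)]
        new_pop = []
        for _ in range(n_per_gen):
            if carriers and rng.random() < bias:
                p1 = int(rng.choice(carriers))
            else:
                p1 = int(rng.integers(len(population)))
            p2 = p1
            while p2 == p1:
                if len(carriers) > 1 and rng.random() < bias:
                    p2 = int(rng.choice(carriers))
                else:
                    p2 = int(rng.integers(len(population)))
            args = (chrom_slices, chrom_positions, config.chromosome_length_bp,
                    config.recombination_rate)
            g1, og1 = _meiosis(rng, *population[p1], *args)
            g2, og2 = _meiosis(rng, *population[p2], *args)
            new_pop.append((g1, g2, og1, og2))
        population = new_pop

    # ascertainment: cases are mutation homozygotes from carrier x carrier
    # matings; controls are their non-homozygous relatives
    case_inds, ctrl_inds = [], []
    if ascertained:
        carriers = [ind for ind in population if carrier(ind)]
        if len(carriers) < 2:
            raise SimulationError(
                "mutation lost from the population; increase the carrier-mating "
                "bias, reduce n_generations, or change the seed"
            )
        # cases arrive in litters from carrier x carrier matings, the way a
        # colony or kennel produces them; litter-mates also supply the
        # matched non-homozygous controls.  The breeding pool is a handful
        # of carriers (popular-sire structure), which keeps the disease
        # haplotype's ancestral paths few and its shared block a few Mb wide
        n_breeders = min(len(carriers), 6)
        breeder_idx = rng.choice(len(carriers), size=n_breeders, replace=False)
        breeders = [carriers[int(i)] for i in breeder_idx]
        max_tries = 100 * (config.n_cases + config.n_controls)
        tries = 0
        while (len(case_inds) < config.n_cases or len(ctrl_inds) < config.n_controls):
            tries += 1
            if tries > max_tries:
                raise SimulationError(
                    "could not realize the requested case/control counts; "
                    "change the seed or enlarge the final generation"
                )
            args = (chrom_slices, chrom_positions, config.chromosome_length_bp,
                    config.recombination_rate)
            if len(case_inds) < config.n_cases:
                i1, i2 = rng.choice(len(breeders), size=2, replace=False)
                sire, dam = breeders[int(i1)], breeders[int(i2)]
            else:
                # cases filled: remaining controls come from breeder x
                # population matings, keeping controls family-matched to the
                # cases (half-sib litters) as in a matched study design
                sire = breeders[int(rng.integers(len(breeders)))]
                dam = population[int(rng.integers(len(population)))]
            lo_l, hi_l = config.litter_size_range
            for _ in range(int(rng.integers(lo_l, hi_l + 1))):
                g1, og1 = _meiosis(rng, *sire, *args)
                g2, og2 = _meiosis(rng, *dam, *args)
                child = (g1, g2, og1, og2)
                dosage = int(g1[mut_idx] + g2[mut_idx])
                if dosage == 2 and len(case_inds) < config.n_cases:
                    case_inds.append(child)
                elif dosage < 2 and len(ctrl_inds) < config.n_controls:
                    ctrl_inds.append(child)
    else:
        # null panel: random individuals, phenotype labels unrelated to genotype
        need = config.n_cases + config.n_controls
        picks = rng.choice(len(population), size=need, replace=len(population) < need)
        sampled = [population[int(i)] for i in picks]
        case_inds = sampled[: config.n_cases]
        ctrl_inds = sampled[config.n_cases :]

    samples = case_inds + ctrl_inds
    sample_ids = [f"case{i + 1:02d}" for i in range(len(case_inds))] + [
        f"ctrl{i + 1:02d}" for i in range(len(ctrl_inds))
    ]
    phenotypes = np.array(
        [CASE] * len(case_inds) + [CONTROL] * len(ctrl_inds), dtype=np.int8
    )

    calls_all = np.stack([h1 + h2 for h1, h2, _, _ in samples]).astype(np.int8)

    # truth before error injection
    truth_geno: dict[str, int] = {}
    ibd: dict[str, tuple[int, int]] = {}
    if ascertained:
        d_slice = chrom_slices[chroms.index(config.disease_chromosome)]
        d_pos = positions[d_slice]
        local_mut = mut_idx - d_slice.start
        for sid, (h1, h2, o1, o2) in zip(sample_ids, samples):
            truth_geno[sid] = int(h1[mut_idx] + h2[mut_idx])
            if truth_geno[sid] == 2:
                both = (o1[d_slice] == founder_id) & (o2[d_slice] == founder_id)
                lo = local_mut
                while lo > 0 and both[lo - 1]:
                    lo -= 1
                hi = local_mut
                while hi < both.size - 1 and both[hi + 1]:
                    hi += 1
                ibd[sid] = (int(d_pos[lo]), int(d_pos[hi]))
    else:
        for sid in sample_ids:
            truth_geno[sid] = 0

    # drop the hidden mutation column from the released panel
    keep = np.ones(n_cols, dtype=bool)
    if ascertained:
        keep[mut_idx] = False
    calls = calls_all[:, keep]
    out_loci = [loc for j, loc in enumerate(loci) if keep[j]]

    # genotyping noise: errors and no-calls concentrate in a small fraction
    # of poorly performing assays (which call-rate QC is meant to remove);
    # well-behaved loci get low per-call rates.  Errors replace the call
    # with a different called state; missingness is applied afterwards.
    bad = rng.random(calls.shape[1]) < config.bad_locus_rate
    err_rate = np.where(bad, config.bad_locus_error_rate, config.genotype_error_rate)
    mis_rate = np.where(bad, config.bad_locus_missing_rate, config.missing_rate)
    if np.any(err_rate > 0):
        err = rng.random(calls.shape) < err_rate[None, :]
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if np.any(mis_rate > 0):
        mis = rng.random(calls.shape) < mis_rate[None, :]
        calls = np.where(mis, np.int8(MISSING), calls)

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        phenotypes=phenotypes,
        loci=out_loci,
        calls=calls,
        alleles=[("A", "G")] * len(out_loci),
    )
    truth = SimTruth(
        chromosome=config.disease_chromosome or "",
        position=config.disease_position if ascertained else 0,
        founder_haplotype=founder_id,
        genotypes=truth_geno,
        ibd_blocks=ibd,
    )
    return matrix, truth


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Truth table as TSV with the locus in header comments; round-trippable."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#chromosome={truth.chromosome}\n")
        fh.write(f"#position={truth.position}\n")
        fh.write(f"#founder_haplotype={truth.founder_haplotype}\n")
        fh.write("sample\tmutation_dosage\tibd_start\tibd_end\n")
        for sid, g in truth.genotypes.items():
            lo, hi = truth.ibd_blocks.get(sid, ("", ""))
            fh.write(f"{sid}\t{g}\t{lo}\t{hi}\n")


def read_truth(path: str | Path) -> SimTruth:
    meta = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, v = line[1:].split("=", 1)
            meta[k] = v
        elif line and not line.startswith("sample\t"):
            rows.append(line.split("\t"))
    genotypes = {r[0]: int(r[1]) for r in rows}
    ibd = {r[0]: (int(r[2]), int(r[3])) for r in rows if r[2] != ""}
    return SimTruth(
        chromosome=meta["chromosome"],
        position=int(meta["position"]),
        founder_haplotype=int(meta["founder_haplotype"]),
        genotypes=genotypes,
        ibd_blocks=ibd,
    )


# -- gene/genome fixture ---------------------------------------------------

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]

# published domain coordinates (protein residues) of the 819 aa protein
DEFAULT_DOMAIN_TABLE: list[tuple[str, int, int]] = [
    ("signal_peptide", 1, 28),
    ("pro_domain", 29, 211),
    ("metalloprotease", 212, 404),
    ("disintegrin", 414, 501),
    ("cysteine_rich", 505, 634),
    ("egf_like", 644, 698),
    ("transmembrane", 698, 718),
    ("cytoplasmic_tail", 719, 819),
]


@dataclass
class FixtureSpec:
    """Structural constraints the gene fixture must satisfy."""

    utr5_length: int = 29
    cds_length: int = 2460
    utr3_length: int = 292
    n_exons: int = 22
    deleted_exons: tuple[int, int] = (15, 16)
    deleted_exon_total: int = 290
    coding_in_exons_1_14: int = 1593
    stop_exon: int = 17
    stop_end_offset: int = 6
    repeat_length: int = 1278
    n_repeat_mismatches: int = 6
    repeat_start_delta: int = 23221
    rtpcr_product_normal: int = 573
    rtpcr_product_affected: int = 283
    strand: str = "-"
    domain_table: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_DOMAIN_TABLE)
    )

    @property
    def transcript_length(self) -> int:
        return self.utr5_length + self.cds_length + self.utr3_length

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - 1

    def validate(self) -> None:
        problems = []
        if self.cds_length % 3:
            problems.append("CDS length not divisible by 3")
        if self.coding_in_exons_1_14 % 3:
            problems.append("coding content of exons 1-14 not divisible by 3")
        if self.deleted_exon_total % 3 == 0:
            problems.append("deleted-exon total must not be divisible by 3 (frameshift)")
        if self.rtpcr_product_normal - self.rtpcr_product_affected != self.deleted_exon_total:
            problems.append("RT-PCR product difference does not equal the deleted-exon total")
        if self.transcript_length != 2781 and self.transcript_length <= 0:
            problems.append("nonpositive transcript length")
        if problems:
            raise ValueError("fixture constraints violated: " + "; ".join(problems))


@dataclass
class GeneFixture:
    """A generated gene model with its genome and engineered deletion."""

    spec: FixtureSpec
    gene: GeneModel
    chromosome: str
    genome: dict[str, str]
    repeat_pair: RepeatPair
    deletion: DeletionEvent
    crossover_offset: int
    chimera: str
    mutant_genome: dict[str, str]
    normal_assay: tuple[str, str, int]  # fwd, rev, expected product on normal allele
    mutant_assay: tuple[str, str, int]  # fwd, rev, expected product on mutant allele

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(self.genome, outdir / "genome.fa")
        _write_fasta(self.mutant_genome, outdir / "genome.mutant.fa")
        write_gene_gff3(self.gene, outdir / "gene.gff3")
        write_domain_table(self.gene.domain_table, outdir / "domains.tsv")
        rp = self.repeat_pair
        pd.DataFrame(
            [
                ("upstream_in_transcript", rp.upstream_in_transcript.start,
                 rp.upstream_in_transcript.end),
                ("downstream_in_transcript", rp.downstream_in_transcript.start,
                 rp.downstream_in_transcript.end),
            ],
            columns=["copy", "start", "end"],
        ).assign(mismatch_offsets=",".join(map(str, rp.mismatch_offsets))).to_csv(
            outdir / "repeats.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                ("normal_allele", *self.normal_assay),
                ("mutant_allele", *self.mutant_assay),
            ],
            columns=["assay", "forward", "reverse", "expected_product"],
        ).to_csv(outdir / "assays.tsv", sep="\t", index=False)


def _write_fasta(genome: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=n)])


def generate_gene_fixture(
    spec: FixtureSpec | None = None, seed: int = 0
) -> GeneFixture:
    """Build the ADAM9-like fixture on a synthetic ~33 kb chromosome.

    The gene sits on the minus strand.  Exon lengths (transcript order) are
    chosen so every structural constraint in ``spec`` holds; the two repeat
    copies flank exons 15–16 with genomic starts 23,221 bp apart; the stop
    codon in the shifted frame is patched in and then re-verified by a
    validation pass over the finished sequences.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    chrom = "chr16s"

    # transcript-order exon lengths (nt), built to the spec's totals
    exon_lengths = (
        [spec.utr5_length + 93]
        + [120] * 12
        + [60]
        + [145, 145]
        + [100] * 5
        + [77 + spec.utr3_length]
    )
    if len(exon_lengths) != spec.n_exons or sum(exon_lengths) != spec.transcript_length:
        raise ValueError("fixture exon plan inconsistent with spec totals")

    # transcript sequence: UTR5 + (ATG + sense codons + TAA) + UTR3
    n_codons = spec.cds_length // 3
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    cds = "ATG" + "".join(body) + "TAA"
    transcript = list(_random_seq(rng, spec.utr5_length) + cds + _random_seq(rng, spec.utr3_length))

    # patch the first 7 bases of exon 17 to CAATGAC: in the post-deletion
    # frame this reads CAA|TGA (stop ends at base 6); in the normal frame
    # the affected codons stay sense (..C | AAT | GAC)
    spans = []
    off = 0
    for ln in exon_lengths:
        spans.append((off + 1, off + ln))
        off += ln
    e17_start = spans[16][0]
    transcript[e17_start - 1 : e17_start + 6] = list("CAATGAC")
    transcript = "".join(transcript)
    exon_seqs = [transcript[lo - 1 : hi] for lo, hi in spans]

    # repeats and intron plan (ascending genomic orientation)
    ltr_low = _random_seq(rng, spec.repeat_length)
    offsets = (150, 420, 650, 800, 1000, 1200)[: spec.n_repeat_mismatches]
    ltr_high = list(ltr_low)
    for o in offsets:
        ltr_high[o - 1] = {"A": "G", "G": "A", "C": "T", "T": "C"}[ltr_high[o - 1]]
    ltr_high = "".join(ltr_high)

    gap_a, gap_b = 10_000, 0
    interior = (
        spec.repeat_length + gap_a + exon_lengths[15] + 700 + exon_lengths[14]
    )
    gap_b = spec.repeat_start_delta - interior
    if gap_b <= 0:
        raise ValueError("repeat_start_delta too small for the exon/intron plan")

    from Bio.Seq import Seq as _Seq

    def rc(s: str) -> str:
        return str(_Seq(s).reverse_complement())

    # assemble ascending: flank, exon22 .. exon1 with introns, flank
    parts: list[tuple[str, str]] = [("flank_l", _random_seq(rng, 1000))]
    for i in range(spec.n_exons, 0, -1):
        parts.append((f"exon{i}", rc(exon_seqs[i - 1])))
        if i > 1:
            intron_no = i - 1
            if intron_no == 16:
                seq = _random_seq(rng, 300) + ltr_low + _random_seq(rng, gap_a)
            elif intron_no == 15:
                seq = _random_seq(rng, 700)
            elif intron_no == 14:
                seq = _random_seq(rng, gap_b) + ltr_high + _random_seq(rng, 300)
            else:
                seq = _random_seq(rng, 200)
            parts.append((f"intron{intron_no}", seq))
    parts.append(("flank_r", _random_seq(rng, 1000)))

    starts: dict[str, int] = {}
    pos = 1
    chunks = []
    for name, seq in parts:
        starts[name] = pos
        chunks.append(seq)
        pos += len(seq)
    genome_seq = "".join(chunks)

    exon_intervals = {
        i: GenomicInterval(chrom, starts[f"exon{i}"], starts[f"exon{i}"] + exon_lengths[i - 1] - 1)
        for i in range(1, spec.n_exons + 1)
    }
    s1 = starts["intron16"] + 300
    s2 = starts["intron14"] + gap_b
    if s2 - s1 != spec.repeat_start_delta:
        raise ValueError("repeat placement does not satisfy the start-coordinate delta")

    gene = GeneModel(
        chromosome=chrom,
        strand=spec.strand,
        exons=[exon_intervals[i] for i in range(1, spec.n_exons + 1)],
        cds_start=spec.utr5_length + 1,
        cds_end=spec.utr5_length + spec.cds_length,
        domain_table=list(spec.domain_table),
        name="adam9_like",
    )
    pair = RepeatPair(
        upstream_in_transcript=GenomicInterval(chrom, s2, s2 + spec.repeat_length - 1),
        downstream_in_transcript=GenomicInterval(chrom, s1, s1 + spec.repeat_length - 1),
        mismatch_offsets=offsets,
        strand=spec.strand,
    )
    deletion = nahr_deletion(pair)

    crossover = (offsets[0] + offsets[1]) // 2
    chimera = ltr_low[:crossover] + ltr_high[crossover:]
    mutant_seq = apply_deletion(
        genome_seq, GenomicInterval(chrom, s1 + crossover, s2 + crossover - 1)
    )

    # multiplex assays: normal-allele primers inside intron 15 (deleted in
    # mutants, 602 bp product); mutant-allele primers flanking the repeats
    # (1,515 bp product only after the collapse)
    i15 = starts["intron15"]
    f_norm_start = i15 + 9
    fwd_norm = genome_seq[f_norm_start - 1 : f_norm_start + 19]
    r_norm_end = f_norm_start + 601
    rev_norm = rc(genome_seq[r_norm_end - 20 : r_norm_end])
    normal_assay = (fwd_norm, rev_norm, 602)

    f_mut_start = s1 - 132
    fwd_mut = genome_seq[f_mut_start - 1 : f_mut_start + 19]
    r_mut_end = s2 + 1382
    rev_mut = rc(genome_seq[r_mut_end - 20 : r_mut_end])
    mutant_assay = (fwd_mut, rev_mut, (r_mut_end - f_mut_start + 1) - spec.repeat_start_delta)

    fixture = GeneFixture(
        spec=spec,
        gene=gene,
        chromosome=chrom,
        genome={chrom: genome_seq},
        repeat_pair=pair,
        deletion=deletion,
        crossover_offset=crossover,
        chimera=chimera,
        mutant_genome={chrom: mutant_seq},
        normal_assay=normal_assay,
        mutant_assay=mutant_assay,
    )
    _validate_fixture(fixture)
    return fixture


def _validate_fixture(fx: GeneFixture) -> None:
    """Re-derive every structural invariant from the emitted model."""
    spec, gene = fx.spec, fx.gene
    problems = []
    if gene.transcript_length != spec.transcript_length:
        problems.append(f"transcript length {gene.transcript_length}")
    if gene.protein_length != spec.protein_length:
        problems.append(f"protein length {gene.protein_length}")
    mrna = gene.splice(fx.genome)
    if len(mrna) != spec.transcript_length:
        problems.append("spliced mRNA length mismatch")
    protein = gene.protein(fx.genome)
    if len(protein) != spec.protein_length or not protein.startswith("M"):
        problems.append("normal translation does not give the full-length protein")
    if fx.deletion.size != spec.repeat_start_delta:
        problems.append(f"deletion size {fx.deletion.size}")
    cons = transcript_consequence(gene, fx.deletion, fx.genome)
    if sorted(cons.deleted_exons) != sorted(spec.deleted_exons):
        problems.append(f"deleted exons {cons.deleted_exons}")
    expect_mut_len = spec.transcript_length - spec.deleted_exon_total
    if cons.mutant_transcript_length != expect_mut_len:
        problems.append(f"mutant transcript {cons.mutant_transcript_length}")
    if not cons.frameshift:
        problems.append("no frameshift")
    if cons.stop_exon_index != spec.stop_exon or cons.stop_end_offset_in_exon != spec.stop_end_offset:
        problems.append(
            f"stop at exon {cons.stop_exon_index} base {cons.stop_end_offset_in_exon}"
        )
    if problems:
        raise ValueError("fixture validation failed: " + "; ".join(problems))
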