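"""Homozygosity-block detection among affected samples.

A SNP *conforms* at stringency k when at least k of the affected dogs carry
non-missing calls homozygous for one common allele.  Missing calls are
block-compatible — they neither break a run nor count toward k.  A block is
a maximal run of consecutive conforming SNPs on one chromosome; its span is
the positions of the first and last conforming SNP (no +1), so the
published 27,854,074–30,597,700 block measures 2.74 Mb.  At k = n-1 the
non-conforming dog may differ from SNP to SNP, which makes every k = n
block a sub-interval of a k = n-1 block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import HOM_A, HOM_B, MISSING, GenotypeMatrix

__all__ = [
    "HomozygosityBlock",
    "CensusRow",
    "snp_conforms",
    "find_blocks",
    "census",
    "minimal_ld_interval",
    "blocks_to_bed",
]


@dataclass(frozen=True)
class HomozygosityBlock:
    """Maximal run of consecutive conforming SNPs with its genomic span."""

    chromosome: str
    start: int  # position of first conforming SNP, 1-based
    end: int  # position of last conforming SNP, 1-based
    n_snps: int
    stringency: tuple[int, int]  # (k, n)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("block start must not exceed end")
        if self.n_snps < 1:
            raise ValueError("a block contains at least one SNP")

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6

    def contains_position(self, chromosome: str, position: int) -> bool:
        return self.chromosome == chromosome and self.start <= position <= self.end

    def contains_block(self, other: "HomozygosityBlock") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )


def snp_conforms(calls: np.ndarray, k: int) -> tuple[bool, Optional[int]]:
    """Does one SNP conform at stringency k across the affected samples?

    Returns (conforms, shared allele code) where the code is ``HOM_A`` or
    ``HOM_B``.  Only non-missing homozygous calls count toward k (so 19
    homozygotes plus one missing call do *not* conform at k = 20); a tie
    between the two homozygote classes (possible when k <= n/2) resolves to
    the A allele.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if k > calls.size:
        raise ValueError(f"stringency k={k} exceeds the {calls.size} affected samples")
    n_a = int((calls == HOM_A).sum())
    n_b = int((calls == HOM_B).sum())
    best, allele = (n_a, HOM_A) if n_a >= n_b else (n_b, HOM_B)
    if best >= k:
        return True, allele
    return False, None


CONFORM, NEUTRAL, BREAK = 2, 1, 0


def _snp_block_status(calls: np.ndarray, k: int) -> int:
    """Role of one SNP in a run at stringency k.

    CONFORM: >= k non-missing calls homozygous for one shared allele (the
    SNP extends a block and counts toward it).  NEUTRAL: conformity fails
    only because of missing calls (homozygotes + missing >= k); missing data
    are block-compatible, so the SNP neither extends nor terminates a run.
    BREAK: discordant called genotypes exceed n - k; the run ends.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_a = int((calls == HOM_A).sum())
    n_b = int((calls == HOM_B).sum())
    n_m = int((calls == MISSING).sum())
    best = max(n_a, n_b)
    if best >= k:
        return CONFORM
    if best + n_m >= k:
        return NEUTRAL
    return BREAK


def _check_sorted(m: GenotypeMatrix) -> None:
    keys = [loc.sort_key for loc in m.loci]
    if keys != sorted(keys):
        raise ValueError("loci must be sorted by (chromosome, position)")


def find_blocks(
    cases: GenotypeMatrix, k: int, min_size_mb: float = 1.0
) -> list[HomozygosityBlock]:
    """Maximal runs of consecutive conforming SNPs, per chromosome.

    ``cases`` is the genotype matrix restricted to affected samples.  At
    k < n the shared allele may differ from SNP to SNP within a run.  SNPs
    whose conformity fails only through missing calls are neutral: a run
    passes over them but is bounded by its first and last *conforming*
    SNPs, which also provide the SNP count.  Only blocks spanning at least
    ``min_size_mb`` are returned; runs never span chromosome boundaries.
    """
    _check_sorted(cases)
    n = cases.n_samples
    if k > n:
        raise ValueError(f"stringency k={k} exceeds the {n} affected samples")
    status = np.array(
        [_snp_block_status(cases.calls[:, j], k) for j in range(cases.n_loci)]
    )

    blocks: list[HomozygosityBlock] = []
    run: list[int] = []  # indices of conforming SNPs in the current run

    def close_run() -> None:
        if not run:
            return
        first, last = run[0], run[-1]
        blk = HomozygosityBlock(
            chromosome=cases.loci[first].chromosome,
            start=cases.loci[first].position,
            end=cases.loci[last].position,
            n_snps=len(run),
            stringency=(k, n),
        )
        if blk.size_mb >= min_size_mb:
            blocks.append(blk)
        run.clear()

    for j in range(cases.n_loci):
        if run and cases.loci[j].chromosome != cases.loci[run[0]].chromosome:
            close_run()
        if status[j] == BREAK:
            close_run()
        elif status[j] == CONFORM:
            run.append(j)
        # NEUTRAL: run passes over the SNP without counting it
    close_run()
    return blocks


@dataclass
class CensusRow:
    """Blocks above the size threshold at one stringency level."""

    level: str  # "n_of_n" or "n_minus_1_of_n"
    k: int
    n: int
    blocks: list[HomozygosityBlock] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stringency": f"{self.k}/{self.n}",
                    "chromosome": b.chromosome,
                    "start": b.start,
                    "end": b.end,
                    "n_snps": b.n_snps,
                    "size_mb": round(b.size_mb, 2),
                }
                for b in self.blocks
            ]
        )


def census(cases: GenotypeMatrix, min_size_mb: float = 1.0) -> tuple[CensusRow, CensusRow]:
    """Genome-wide block census at n/n and (n-1)/n stringency."""
    n = cases.n_samples
    if n < 2:
        raise ValueError("census requires at least two affected samples")
    full = CensusRow("n_of_n", n, n, find_blocks(cases, n, min_size_mb))
    relaxed = CensusRow(
        "n_minus_1_of_n", n - 1, n, find_blocks(cases, n - 1, min_size_mb)
    )
    return full, relaxed


@dataclass
class MinimalLdInterval:
    """The largest all-case homozygosity block with control conformity."""

    block: HomozygosityBlock
    shared_alleles: dict[int, int]  # locus column index -> shared allele code
    control_conformity: list[bool]  # per control: homozygous-identical across block
    n_conforming_controls: int


def minimal_ld_interval(
    cases: GenotypeMatrix,
    controls: GenotypeMatrix,
    min_size_mb: float = 0.0,
    anchor: Optional[tuple[str, int, int]] = None,
) -> Optional[MinimalLdInterval]:
    """All-case (k = n) homozygosity block, annotated with control conformity.

    The minimal LD interval is the homozygosity block shared by every
    affected dog and absent, as a shared homozygous haplotype, from the
    controls — the region of absolute linkage disequilibrium with the
    trait.  Candidate case blocks are therefore ranked first by how few
    controls carry the blocks' homozygous haplotype (a rare conforming
    control — the dog-17 situation — is tolerated and annotated, never
    used to shrink the interval), then by the association anchor, then by
    size.  The ``anchor`` — (chromosome, start, end), the span of
    genome-wide-significant SNPs around the association peak — restricts
    preference to blocks overlapping the region that yields the peak
    signal.

    A control *conforms* when, at every conforming SNP inside a block, its
    call is homozygous for the case-shared allele or missing.  Returns
    None (with a warning) when the cases carry no block.
    """
    if cases.n_samples < 1:
        raise ValueError("minimal_ld_interval requires at least one case")
    n = cases.n_samples
    blocks = find_blocks(cases, n, min_size_mb)
    if not blocks:
        warnings.warn("no all-case homozygosity block found", stacklevel=2)
        return None

    def control_profile(block: HomozygosityBlock) -> tuple[dict[int, int], list[bool]]:
        shared: dict[int, int] = {}
        for j, loc in enumerate(cases.loci):
            if block.contains_position(loc.chromosome, loc.position):
                ok, allele = snp_conforms(cases.calls[:, j], n)
                if ok:
                    shared[j] = allele
        conformity = [
            bool(
                all(
                    controls.calls[i, j] == allele or controls.calls[i, j] == MISSING
                    for j, allele in shared.items()
                )
            )
            for i in range(controls.n_samples)
        ]
        return shared, conformity

    profiles = {id(b): control_profile(b) for b in blocks}

    def rank(b: HomozygosityBlock) -> tuple:
        n_conf = sum(profiles[id(b)][1])
        in_anchor = 0
        if anchor is not None:
            chrom, lo, hi = anchor
            in_anchor = int(b.chromosome == chrom and b.start <= hi and lo <= b.end)
        # absent from controls (at most one conforming control tolerated,
        # the dog-17 situation) first, then anchored, then larger
        return (int(n_conf <= 1), in_anchor, b.size_mb)

    block = max(blocks, key=rank)
    shared, conformity = profiles[id(block)]
    return MinimalLdInterval(
        block=block,
        shared_alleles=shared,
        control_conformity=conformity,
        n_conforming_controls=int(sum(conformity)),
    )


def blocks_to_bed(blocks: list[HomozygosityBlock], path: str) -> None:
    """Write blocks as BED (0-based half-open) alongside the 1-based TSV."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.start - 1}\t{b.end}\thomozygosity_block\n")
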