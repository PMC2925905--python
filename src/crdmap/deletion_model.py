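"""LTR-mediated deletion model and transcript/protein consequence prediction.

Unbalanced (non-allelic homologous) recombination between two near-identical
dispersed repeats deletes the intervening sequence and leaves a single
chimeric repeat copy.  For equal-length repeats the deletion size is the
absolute difference of their genomic start coordinates — the convention
that reproduces the published 23,221 bp from LTR starts 29,422,135 and
29,398,914.  Consequence prediction splices the remaining exons, translates
from the original start codon, and reports the first stop: the offset
recorded is that of the stop codon's *last* base within its exon, so a stop
occupying bases 4–6 of exon 17 is reported as "base 6 of exon 17".

Gene models are read from GFF3 (via gffutils) with a protein-domain TSV;
genomes from FASTA (via pyfaidx) or any mapping of chromosome name to
sequence string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "RepeatPair",
    "GeneModel",
    "DeletionEvent",
    "BreakpointWindow",
    "TranscriptConsequence",
    "PcrResult",
    "repeat_identity",
    "nahr_deletion",
    "breakpoint_window",
    "transcript_consequence",
    "domain_overlap",
    "insilico_pcr",
    "apply_deletion",
    "read_domain_table",
    "write_domain_table",
    "write_gene_gff3",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _chrom_seq(genome, chromosome: str) -> str:
    """Chromosome sequence from a dict of strings or a pyfaidx Fasta."""
    seq = genome[chromosome]
    return seq if isinstance(seq, str) else str(seq[:])


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} exceeds end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def fetch(self, genome) -> str:
        return _chrom_seq(genome, self.chromosome)[self.start - 1 : self.end]


@dataclass(frozen=True)
class RepeatPair:
    """Two equal-length dispersed repeat copies within one gene.

    ``upstream_in_transcript`` is the copy the transcript meets first (for a
    minus-strand gene that is the copy at *higher* genomic coordinates).
    Mismatch offsets are 1-based positions, counted from each copy's genomic
    start, at which the two copies differ.
    """

    upstream_in_transcript: GenomicInterval
    downstream_in_transcript: GenomicInterval
    mismatch_offsets: tuple[int, ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        up, down = self.upstream_in_transcript, self.downstream_in_transcript
        if up.length != down.length:
            raise ValueError("repeat copies must have equal length")
        object.__setattr__(self, "mismatch_offsets", tuple(sorted(self.mismatch_offsets)))
        for off in self.mismatch_offsets:
            if not 1 <= off <= up.length:
                raise ValueError(f"mismatch offset {off} outside repeat of length {up.length}")

    @property
    def length(self) -> int:
        return self.upstream_in_transcript.length

    @property
    def low(self) -> GenomicInterval:
        """Copy at lower genomic coordinates."""
        pair = (self.upstream_in_transcript, self.downstream_in_transcript)
        return min(pair, key=lambda iv: iv.start)

    @property
    def high(self) -> GenomicInterval:
        pair = (self.upstream_in_transcript, self.downstream_in_transcript)
        return max(pair, key=lambda iv: iv.start)


def repeat_identity(length: int, n_mismatches: int) -> float:
    """Percent identity of two aligned repeat copies: 100 (L - m) / L."""
    if length <= 0:
        raise ValueError("repeat length must be positive")
    if not 0 <= n_mismatches <= length:
        raise ValueError("mismatch count must lie in [0, length]")
    return 100.0 * (length - n_mismatches) / length


@dataclass(frozen=True)
class BreakpointWindow:
    """Open offset interval within the repeat bracketing the crossover."""

    low: int
    high: int
    whole_repeat: bool = False


@dataclass(frozen=True)
class DeletionEvent:
    """A genomic deletion, optionally produced by repeat-pair recombination."""

    removed: GenomicInterval
    size: int
    mechanism: str = "other"  # "NAHR" or "other"
    chimeric_repeat: Optional[GenomicInterval] = None
    breakpoint_window: Optional[BreakpointWindow] = None


def nahr_deletion(pair: RepeatPair) -> DeletionEvent:
    """Deletion produced by unequal crossover between the two repeat copies.

    The event removes one repeat-spacing worth of sequence — canonically the
    segment from the low copy's start to just before the high copy's start —
    leaving a single fused (chimeric) copy.  Size is the absolute difference
    of the two genomic start coordinates; for adjacent identical tandem
    repeats of length L this collapses them to one copy, removing L bases.
    """
    low, high = pair.low, pair.high
    if low.chromosome != high.chromosome:
        raise ValueError("repeat copies must lie on the same chromosome")
    if low.overlaps(high):
        raise ValueError("repeat copies overlap; no clean NAHR deletion")
    size = high.start - low.start
    removed = GenomicInterval(low.chromosome, low.start, high.start - 1)
    if len(pair.mismatch_offsets) >= 2:
        window = BreakpointWindow(pair.mismatch_offsets[0], pair.mismatch_offsets[1])
    else:
        window = BreakpointWindow(1, pair.length, whole_repeat=True)
    chimera = GenomicInterval(low.chromosome, low.start, low.end)
    return DeletionEvent(
        removed=removed,
        size=size,
        mechanism="NAHR",
        chimeric_repeat=chimera,
        breakpoint_window=window,
    )


def breakpoint_window(
    pair: RepeatPair,
    chimera: Optional[str] = None,
    genome=None,
) -> BreakpointWindow:
    """Locate the crossover interval from the repeat-copy mismatches.

    Without a chimeric sequence, the window is the open interval between the
    first and second mismatch offsets (the published two-SNP reasoning).
    Given the observed chimera (plus the genome to fetch both copies), the
    window is narrowed to (last offset carrying the low-copy variant, first
    offset carrying the high-copy variant).  With fewer than two mismatches
    the whole repeat is returned, flagged.
    """
    offsets = pair.mismatch_offsets
    if len(offsets) < 2:
        return BreakpointWindow(1, pair.length, whole_repeat=True)
    if chimera is None:
        return BreakpointWindow(offsets[0], offsets[1])

    if genome is None:
        raise ValueError("a genome is required to interpret the chimeric sequence")
    low_seq = pair.low.fetch(genome)
    high_seq = pair.high.fetch(genome)
    if len(chimera) != pair.length:
        raise ValueError("chimera length must equal the repeat length")

    matches_low = []
    matches_high = []
    for off in offsets:
        base = chimera[off - 1]
        if base == low_seq[off - 1]:
            matches_low.append(off)
        elif base == high_seq[off - 1]:
            matches_high.append(off)
        else:
            raise ValueError(f"chimera base at offset {off} matches neither repeat copy")
    if not matches_low or not matches_high:
        return BreakpointWindow(1, pair.length, whole_repeat=True)
    lo = max(matches_low)
    hi = min(matches_high)
    if lo > hi:
        raise ValueError("chimera variants interleave; not a single crossover")
    return BreakpointWindow(lo, hi)


# -- gene model ------------------------------------------------------------


@dataclass
class GeneModel:
    """Exon structure with CDS bounds in spliced-transcript coordinates.

    Exons are stored in transcript order: ascending genomic coordinates on
    the plus strand, descending on the minus strand.  ``cds_start`` and
    ``cds_end`` are 1-based positions on the spliced mRNA; the CDS length
    (including the stop codon) must be divisible by three.  The domain table
    lists (name, first aa, last aa) in protein coordinates.
    """

    chromosome: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    domain_table: list[tuple[str, int, int]] = field(default_factory=list)
    name: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.overlaps(b):
                raise ValueError("exons overlap")
            if self.strand == "+" and b.start <= a.end:
                raise ValueError("plus-strand exons must ascend genomically")
            if self.strand == "-" and b.end >= a.start:
                raise ValueError("minus-strand exons must descend genomically")
        if not 1 <= self.cds_start <= self.cds_end <= self.transcript_length:
            raise ValueError("CDS bounds outside transcript")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def protein_length(self) -> int:
        """Amino acids encoded, excluding the stop codon."""
        return self.cds_length // 3 - 1

    def exon_offsets(self) -> list[tuple[int, int]]:
        """(first, last) transcript coordinate of each exon, 1-based."""
        spans = []
        off = 0
        for e in self.exons:
            spans.append((off + 1, off + e.length))
            off += e.length
        return spans

    def splice(self, genome) -> str:
        """The mature mRNA: exon sequences in transcript order."""
        parts = []
        for e in self.exons:
            s = e.fetch(genome)
            parts.append(revcomp(s) if self.strand == "-" else s)
        return "".join(parts)

    def coding_sequence(self, genome) -> str:
        return self.splice(genome)[self.cds_start - 1 : self.cds_end]

    def protein(self, genome) -> str:
        """Translation of the CDS, stop codon stripped."""
        aa = str(Seq(self.coding_sequence(genome)).translate())
        return aa.rstrip("*")


# -- consequence prediction ------------------------------------------------


@dataclass
class TranscriptConsequence:
    """Predicted effect of a whole-exon genomic deletion on the transcript."""

    mutant_transcript_length: int
    deleted_exons: list[int]  # 1-based exon numbers
    frameshift: bool
    stop_exon_index: Optional[int]  # 1-based original exon number
    stop_end_offset_in_exon: Optional[int]  # 1-based offset of the stop's last base
    retained_aa: int
    lost_aa: int
    domain_status: dict[str, str]
    flags: set[str] = field(default_factory=set)  # NO_PROTEIN, NONSTOP
    mutant_protein: str = ""


def domain_overlap(
    domain_table: Sequence[tuple[str, int, int]], retained_aa: int
) -> dict[str, str]:
    """Status of each protein domain after C-terminal truncation.

    intact when the domain ends at or before the retained length, lost when
    it starts after it, partial otherwise.
    """
    status = {}
    for name, first, last in domain_table:
        if first > last or first < 1:
            raise ValueError(f"invalid domain bounds for {name}")
        if last <= retained_aa:
            status[name] = "intact"
        elif first > retained_aa:
            status[name] = "lost"
        else:
            status[name] = "partial"
    return status


def transcript_consequence(
    gene: GeneModel, deletion: DeletionEvent, genome
) -> TranscriptConsequence:
    """Splice the post-deletion transcript and translate it.

    The deletion must remove whole exons only (a partial-exon overlap is an
    error; cryptic splicing is out of scope).  Translation starts at the
    original start codon.  If the deletion removes the exon carrying the
    start codon the result is flagged NO_PROTEIN; if no stop codon occurs
    before the transcript end it is flagged NONSTOP.
    """
    removed = deletion.removed
    if removed.chromosome != gene.chromosome:
        raise ValueError("deletion and gene lie on different chromosomes")

    spans = gene.exon_offsets()
    deleted_idx: list[int] = []
    for i, exon in enumerate(gene.exons):
        if removed.contains(exon):
            deleted_idx.append(i)
        elif removed.overlaps(exon):
            raise ValueError(
                f"deletion partially overlaps exon {i + 1}; only whole-exon "
                "deletions are modelled"
            )

    normal_aa = gene.protein_length
    deleted_set = set(deleted_idx)
    kept = [i for i in range(gene.n_exons) if i not in deleted_set]

    # mutant transcript and the mapping from its coordinates to exons
    mutant_parts = []
    mutant_spans: list[tuple[int, int, int]] = []  # (first, last, original exon idx)
    off = 0
    for i in kept:
        exon = gene.exons[i]
        s = exon.fetch(genome)
        mutant_parts.append(revcomp(s) if gene.strand == "-" else s)
        mutant_spans.append((off + 1, off + exon.length, i))
        off += exon.length
    mutant = "".join(mutant_parts)

    # start-codon fate and new CDS start
    start_exon = next(
        i for i, (lo, hi) in enumerate(spans) if lo <= gene.cds_start <= hi
    )
    if start_exon in deleted_set:
        return TranscriptConsequence(
            mutant_transcript_length=len(mutant),
            deleted_exons=[i + 1 for i in deleted_idx],
            frameshift=False,
            stop_exon_index=None,
            stop_end_offset_in_exon=None,
            retained_aa=0,
            lost_aa=normal_aa,
            domain_status=domain_overlap(gene.domain_table, 0),
            flags={"NO_PROTEIN"},
        )

    removed_before_start = sum(
        spans[i][1] - spans[i][0] + 1 for i in deleted_idx if spans[i][1] < gene.cds_start
    )
    new_cds_start = gene.cds_start - removed_before_start

    deleted_coding = sum(
        max(0, min(spans[i][1], gene.cds_end) - max(spans[i][0], gene.cds_start) + 1)
        for i in deleted_idx
    )
    frameshift = deleted_coding % 3 != 0

    # scan codons for the first stop
    retained = 0
    stop_last_pos: Optional[int] = None
    pos = new_cds_start - 1  # 0-based
    while pos + 3 <= len(mutant):
        codon = mutant[pos : pos + 3].upper()
        if codon in STOP_CODONS:
            stop_last_pos = pos + 3  # 1-based coordinate of the stop's last base
            break
        retained += 1
        pos += 3

    flags: set[str] = set()
    stop_exon: Optional[int] = None
    stop_offset: Optional[int] = None
    if stop_last_pos is None:
        flags.add("NONSTOP")
    else:
        premature = retained < normal_aa
        if premature:
            for lo, hi, i in mutant_spans:
                if lo <= stop_last_pos <= hi:
                    stop_exon = i + 1
                    stop_offset = stop_last_pos - lo + 1
                    break

    protein = str(
        Seq(mutant[new_cds_start - 1 : new_cds_start - 1 + 3 * retained]).translate()
    )
    return TranscriptConsequence(
        mutant_transcript_length=len(mutant),
        deleted_exons=[i + 1 for i in deleted_idx],
        frameshift=frameshift,
        stop_exon_index=stop_exon,
        stop_end_offset_in_exon=stop_offset,
        retained_aa=retained,
        lost_aa=normal_aa - retained,
        domain_status=domain_overlap(gene.domain_table, retained),
        flags=flags,
        mutant_protein=protein,
    )


def apply_deletion(sequence: str, removed: GenomicInterval) -> str:
    """Remove a 1-based inclusive interval from a chromosome sequence."""
    return sequence[: removed.start - 1] + sequence[removed.end :]


# -- in-silico PCR ---------------------------------------------------------


@dataclass
class PcrResult:
    """Products of an exact-match in-silico PCR."""

    products: list[int]
    ambiguous: bool

    @property
    def product(self) -> Optional[int]:
        return self.products[0] if len(self.products) == 1 else None


def insilico_pcr(
    template: str, forward: str, reverse: str, max_size: Optional[int] = None
) -> PcrResult:
    """Exact-match PCR product prediction on one template strand.

    The forward primer must match the template verbatim; the reverse primer
    anneals to the plus strand as its reverse complement, downstream of the
    forward site.  Product length is the inclusive span from the forward
    primer's first base to the reverse site's last base.  ``max_size``
    emulates the extension limit of a PCR protocol.  Multiple primer sites
    yield every admissible product with the ambiguity flag set.
    """
    for p in (forward, reverse):
        if len(p) < 15:
            raise ValueError("primers must be at least 15 nt")
    template = template.upper()
    fwd = forward.upper()
    rev_site = revcomp(reverse.upper())

    def sites(seq: str, probe: str) -> list[int]:
        out, i = [], seq.find(probe)
        while i != -1:
            out.append(i)
            i = seq.find(probe, i + 1)
        return out

    f_sites = sites(template, fwd)
    r_sites = sites(template, rev_site)
    products = []
    for f in f_sites:
        for r in r_sites:
            if r < f:
                continue
            length = r + len(rev_site) - f
            if length < max(len(fwd), len(rev_site)):
                continue
            if max_size is not None and length > max_size:
                continue
            products.append(length)
    products.sort()
    return PcrResult(products=products, ambiguous=len(products) > 1)


# -- file formats ----------------------------------------------------------


def write_domain_table(domains: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    pd.DataFrame(domains, columns=["domain", "first_aa", "last_aa"]).to_csv(
        path, sep="\t", index=False
    )


def read_domain_table(path: str | Path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.domain), int(r.first_aa), int(r.last_aa)) for r in df.itertuples()
    ]


def _transcript_coord(gene_exons: list[GenomicInterval], strand: str, gpos: int) -> int:
    """Map a genomic position inside an exon to its spliced-mRNA coordinate."""
    off = 0
    for e in gene_exons:
        if e.start <= gpos <= e.end:
            return off + (gpos - e.start + 1 if strand == "+" else e.end - gpos + 1)
        off += e.length
    raise ValueError(f"genomic position {gpos} is not exonic")


def write_gene_gff3(gene: GeneModel, path: str | Path) -> None:
    """Write the gene model as GFF3 (gene, mRNA, exon and CDS features)."""
    lines = ["##gff-version 3"]
    g_start = min(e.start for e in gene.exons)
    g_end = max(e.end for e in gene.exons)
    gid, tid = gene.name, f"{gene.name}.t1"
    col = gene.chromosome
    lines.append(
        f"{col}\tcrdmap\tgene\t{g_start}\t{g_end}\t.\t{gene.strand}\t.\tID={gid}"
    )
    lines.append(
        f"{col}\tcrdmap\tmRNA\t{g_start}\t{g_end}\t.\t{gene.strand}\t.\t"
        f"ID={tid};Parent={gid}"
    )
    spans = gene.exon_offsets()
    for i, exon in enumerate(gene.exons):
        lines.append(
            f"{col}\tcrdmap\texon\t{exon.start}\t{exon.end}\t.\t{gene.strand}\t.\t"
            f"ID={tid}.exon{i + 1};Parent={tid}"
        )
        lo, hi = spans[i]
        c_lo, c_hi = max(lo, gene.cds_start), min(hi, gene.cds_end)
        if c_lo > c_hi:
            continue
        if gene.strand == "+":
            g_lo = exon.start + (c_lo - lo)
            g_hi = exon.start + (c_hi - lo)
        else:
            g_hi = exon.end - (c_lo - lo)
            g_lo = exon.end - (c_hi - lo)
        phase = (3 - (c_lo - gene.cds_start) % 3) % 3
        lines.append(
            f"{col}\tcrdmap\tCDS\t{g_lo}\t{g_hi}\t.\t{gene.strand}\t{phase}\t"
            f"ID={tid}.cds{i + 1};Parent={tid}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def gene_model_from_gff3(
    path: str | Path,
    domain_table: Sequence[tuple[str, int, int]] | None = None,
) -> GeneModel:
    """Load a single-transcript gene model from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    mrnas = list(db.features_of_type("mRNA"))
    if len(mrnas) != 1:
        raise ValueError(f"expected exactly one mRNA feature, found {len(mrnas)}")
    mrna = mrnas[0]
    strand = mrna.strand
    exon_feats = sorted(
        db.children(mrna, featuretype="exon"),
        key=lambda f: f.start,
        reverse=(strand == "-"),
    )
    exons = [GenomicInterval(f.seqid, f.start, f.end) for f in exon_feats]
    cds_feats = list(db.children(mrna, featuretype="CDS"))
    if not cds_feats:
        raise ValueError("gene model lacks CDS features")
    g_positions = [p for f in cds_feats for p in (f.start, f.end)]
    t_coords = [_transcript_coord(exons, strand, p) for p in g_positions]
    genes = list(db.features_of_type("gene"))
    name = genes[0].id if genes else mrna.id
    return GeneModel(
        chromosome=mrna.seqid,
        strand=strand,
        exons=exons,
        cds_start=min(t_coords),
        cds_end=max(t_coords),
        domain_table=list(domain_table or []),
        name=name,
    )
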