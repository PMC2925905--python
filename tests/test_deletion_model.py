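"""Repeat-mediated deletion modelling, transcript consequences and in-silico
PCR."""

import numpy as np
import pytest
from Bio.Seq import Seq

from crdmap.deletion_model import (
    BreakpointWindow,
    DeletionEvent,
    GeneModel,
    GenomicInterval,
    RepeatPair,
    apply_deletion,
    breakpoint_window,
    domain_overlap,
    gene_model_from_gff3,
    insilico_pcr,
    nahr_deletion,
    read_domain_table,
    repeat_identity,
    transcript_consequence,
    write_domain_table,
    write_gene_gff3,
)

PUBLISHED_DOMAINS = [
    ("signal_peptide", 1, 28),
    ("pro_domain", 29, 211),
    ("metalloprotease", 212, 404),
    ("disintegrin", 414, 501),
    ("cysteine_rich", 505, 634),
    ("egf_like", 644, 698),
    ("transmembrane", 698, 718),
    ("cytoplasmic_tail", 719, 819),
]


class TestRepeatIdentity:
    def test_published_ltr_identity(self):
        assert round(repeat_identity(1278, 6), 1) == 99.5

    def test_perfect_and_null_identity(self):
        assert repeat_identity(100, 0) == 100.0
        assert repeat_identity(1278, 1278) == 0.0

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            repeat_identity(0, 0)


class TestNahrDeletion:
    def test_published_ltr_pair_size(self):
        pair = RepeatPair(
            upstream_in_transcript=GenomicInterval("16", 29_422_135, 29_423_412),
            downstream_in_transcript=GenomicInterval("16", 29_398_914, 29_400_191),
            mismatch_offsets=(150, 420),
            strand="-",
        )
        event = nahr_deletion(pair)
        assert event.size == 23_221
        assert event.mechanism == "NAHR"
        assert pair.length == 1_278

    def test_tandem_repeat_collapse(self):
        pair = RepeatPair(
            upstream_in_transcript=GenomicInterval("1", 21, 30),
            downstream_in_transcript=GenomicInterval("1", 31, 40),
        )
        event = nahr_deletion(pair)
        assert event.size == 10
        assert event.breakpoint_window.whole_repeat

    def test_sequence_surgery_length(self):
        rng = np.random.default_rng(0)
        repeat = "".join(rng.choice(list("ACGT"), 10))
        seq = "A" * 15 + repeat + "C" * 12 + repeat + "G" * 13
        pair = RepeatPair(
            upstream_in_transcript=GenomicInterval("c", 16, 25),
            downstream_in_transcript=GenomicInterval("c", 38, 47),
        )
        event = nahr_deletion(pair)
        mutant = apply_deletion(seq, event.removed)
        assert len(seq) - len(mutant) == event.size

    def test_overlapping_repeats_rejected(self):
        pair = RepeatPair(
            upstream_in_transcript=GenomicInterval("1", 10, 30),
            downstream_in_transcript=GenomicInterval("1", 20, 40),
        )
        with pytest.raises(ValueError):
            nahr_deletion(pair)


class TestBreakpointWindow:
    def _pair(self, offsets):
        return RepeatPair(
            upstream_in_transcript=GenomicInterval("c", 1000, 1999),
            downstream_in_transcript=GenomicInterval("c", 100, 1099),
            mismatch_offsets=offsets,
        )

    def test_first_two_mismatches_without_chimera(self):
        win = breakpoint_window(self._pair((100, 400, 650)))
        assert (win.low, win.high) == (100, 400)
        assert not win.whole_repeat

    def test_single_mismatch_whole_repeat_flagged(self):
        win = breakpoint_window(self._pair((500,)))
        assert win.whole_repeat
        assert (win.low, win.high) == (1, 1000)

    def test_constructed_crossover_contained(self, gene_fixture):
        fx = gene_fixture
        win = breakpoint_window(fx.repeat_pair, chimera=fx.chimera, genome=fx.genome)
        assert win.low < fx.crossover_offset < win.high
        assert (win.low, win.high) == (150, 420)


def _toy_gene(rng, strand, n_exons=6, chrom="c1"):
    """Random small gene with a stop-free CDS, plus its genome."""
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in {"TAA", "TAG", "TGA"}
    ]
    n_codons = int(rng.integers(20, 40))
    cds = "ATG" + "".join(rng.choice(sense, n_codons - 2)) + "TAA"
    utr5 = "".join(rng.choice(list("ACGT"), int(rng.integers(3, 12))))
    utr3 = "".join(rng.choice(list("ACGT"), int(rng.integers(3, 12))))
    transcript = utr5 + cds + utr3

    cuts = sorted(rng.choice(np.arange(1, len(transcript)), n_exons - 1, replace=False))
    bounds = [0, *map(int, cuts), len(transcript)]
    exon_seqs = [transcript[a:b] for a, b in zip(bounds, bounds[1:])]

    pos = 50
    genomic = []
    for seq in exon_seqs:
        genomic.append((pos, pos + len(seq) - 1))
        pos += len(seq) + int(rng.integers(20, 60))
    genome_len = pos + 50

    if strand == "+":
        chrom_seq = ["A"] * genome_len
        for (s, e), seq in zip(genomic, exon_seqs):
            chrom_seq[s - 1 : e] = list(seq)
        exons = [GenomicInterval(chrom, s, e) for s, e in genomic]
    else:
        # transcript order = descending genomic coordinates
        chrom_seq = ["A"] * genome_len
        flipped = []
        for (s, e), seq in zip(genomic, exon_seqs):
            s2, e2 = genome_len - e + 1, genome_len - s + 1
            flipped.append((s2, e2))
            chrom_seq[s2 - 1 : e2] = list(str(Seq(seq).reverse_complement()))
        exons = [GenomicInterval(chrom, s, e) for s, e in flipped]

    gene = GeneModel(
        chromosome=chrom,
        strand=strand,
        exons=exons,
        cds_start=len(utr5) + 1,
        cds_end=len(utr5) + len(cds),
        domain_table=[],
    )
    return gene, {chrom: "".join(chrom_seq)}, transcript


def oracle_consequence(gene, transcript, deleted_idx):
    """Independent splice-and-translate oracle working on the raw transcript."""
    spans = gene.exon_offsets()
    kept = [i for i in range(gene.n_exons) if i not in deleted_idx]
    mutant = "".join(transcript[spans[i][0] - 1 : spans[i][1]] for i in kept)
    start_exon = next(i for i, (lo, hi) in enumerate(spans) if lo <= gene.cds_start <= hi)
    if start_exon in deleted_idx:
        return {"flags": {"NO_PROTEIN"}, "mutant_len": len(mutant)}
    removed_before = sum(
        spans[i][1] - spans[i][0] + 1 for i in deleted_idx if spans[i][1] < gene.cds_start
    )
    new_start = gene.cds_start - removed_before
    peptide = str(Seq(mutant[new_start - 1 :]).translate(to_stop=True))
    tail = len(mutant[new_start - 1 :]) % 3
    has_stop = "*" in str(Seq(mutant[new_start - 1 : len(mutant) - tail]).translate())
    deleted_coding = sum(
        max(0, min(spans[i][1], gene.cds_end) - max(spans[i][0], gene.cds_start) + 1)
        for i in deleted_idx
    )
    return {
        "flags": set() if has_stop else {"NONSTOP"},
        "mutant_len": len(mutant),
        "retained": len(peptide),
        "frameshift": deleted_coding % 3 != 0,
    }


class TestTranscriptConsequence:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_splice_translate_oracle(self, strand, seed):
        rng = np.random.default_rng(seed)
        gene, genome, transcript = _toy_gene(rng, strand)
        assert gene.splice(genome) == transcript  # sanity of the toy builder

        first = int(rng.integers(1, gene.n_exons - 1))
        last = min(gene.n_exons - 2, first + int(rng.integers(0, 2)))
        deleted = set(range(first, last + 1))
        lo = min(gene.exons[i].start for i in deleted)
        hi = max(gene.exons[i].end for i in deleted)
        event = DeletionEvent(
            removed=GenomicInterval(gene.chromosome, lo, hi), size=hi - lo + 1
        )
        cons = transcript_consequence(gene, event, genome)
        want = oracle_consequence(gene, transcript, deleted)

        assert cons.mutant_transcript_length == want["mutant_len"]
        assert cons.flags == want["flags"]
        if "NO_PROTEIN" not in want["flags"]:
            if "NONSTOP" not in want["flags"]:
                assert cons.retained_aa == want["retained"]
                assert cons.retained_aa + cons.lost_aa == gene.protein_length
            assert cons.frameshift == want["frameshift"]

    def test_in_frame_exon_deletion(self):
        rng = np.random.default_rng(99)
        # 4 exons; exon 2 is exactly 9 coding bases with no in-frame stop
        utr5 = "GG"
        cds = "ATG" + "GCTGCA" + "GCCGCTGCA" + "GCTGCAGCT" + "TAA"
        transcript = utr5 + cds
        lens = [2 + 3 + 6, 9, 9, 3]
        pos, genomic = 10, []
        for ln in lens:
            genomic.append((pos, pos + ln - 1))
            pos += ln + 30
        chrom_seq = ["T"] * (pos + 20)
        off = 0
        for (s, e), ln in zip(genomic, lens):
            chrom_seq[s - 1 : e] = list(transcript[off : off + ln])
            off += ln
        gene = GeneModel(
            chromosome="c",
            strand="+",
            exons=[GenomicInterval("c", s, e) for s, e in genomic],
            cds_start=3,
            cds_end=2 + len(cds),
        )
        genome = {"c": "".join(chrom_seq)}
        s, e = genomic[1]
        event = DeletionEvent(removed=GenomicInterval("c", s, e), size=9)
        cons = transcript_consequence(gene, event, genome)
        assert not cons.frameshift
        assert cons.lost_aa == 3
        assert cons.deleted_exons == [2]
        del rng

    def test_zero_exon_deletion_reproduces_normal_protein(self):
        rng = np.random.default_rng(5)
        gene, genome, _ = _toy_gene(rng, "+")
        intron_gap = GenomicInterval(
            gene.chromosome, gene.exons[0].end + 2, gene.exons[0].end + 3
        )
        cons = transcript_consequence(
            gene, DeletionEvent(removed=intron_gap, size=2), genome
        )
        assert cons.deleted_exons == []
        assert cons.retained_aa == gene.protein_length
        assert cons.lost_aa == 0
        assert not cons.frameshift
        assert cons.stop_exon_index is None  # the normal stop is not premature
        assert cons.mutant_protein == gene.protein(genome)

    def test_partial_exon_overlap_rejected(self):
        rng = np.random.default_rng(6)
        gene, genome, _ = _toy_gene(rng, "+")
        exon = gene.exons[2]
        event = DeletionEvent(
            removed=GenomicInterval(gene.chromosome, exon.start + 1, exon.end + 5),
            size=5,
        )
        with pytest.raises(ValueError, match="partially overlaps"):
            transcript_consequence(gene, event, genome)

    def test_start_codon_loss_flagged_no_protein(self):
        rng = np.random.default_rng(8)
        gene, genome, _ = _toy_gene(rng, "+")
        spans = gene.exon_offsets()
        start_exon = next(
            i for i, (lo, hi) in enumerate(spans) if lo <= gene.cds_start <= hi
        )
        exon = gene.exons[start_exon]
        event = DeletionEvent(
            removed=GenomicInterval(gene.chromosome, exon.start, exon.end),
            size=exon.length,
        )
        cons = transcript_consequence(gene, event, genome)
        assert "NO_PROTEIN" in cons.flags
        assert cons.retained_aa == 0 and cons.lost_aa == gene.protein_length

    @pytest.mark.parametrize("seed", range(4))
    def test_strand_invariance(self, seed):
        rng = np.random.default_rng(seed)
        gene, genome, _ = _toy_gene(rng, "+")
        L = len(genome[gene.chromosome])
        flipped_genome = {
            gene.chromosome: str(Seq(genome[gene.chromosome]).reverse_complement())
        }
        flipped_gene = GeneModel(
            chromosome=gene.chromosome,
            strand="-",
            exons=[
                GenomicInterval(gene.chromosome, L - e.end + 1, L - e.start + 1)
                for e in gene.exons
            ],
            cds_start=gene.cds_start,
            cds_end=gene.cds_end,
        )
        d = gene.exons[2]
        ev = DeletionEvent(removed=GenomicInterval(gene.chromosome, d.start, d.end),
                           size=d.length)
        ev_f = DeletionEvent(
            removed=GenomicInterval(gene.chromosome, L - d.end + 1, L - d.start + 1),
            size=d.length,
        )
        a = transcript_consequence(gene, ev, genome)
        b = transcript_consequence(flipped_gene, ev_f, flipped_genome)
        for field in (
            "mutant_transcript_length",
            "deleted_exons",
            "frameshift",
            "stop_exon_index",
            "stop_end_offset_in_exon",
            "retained_aa",
            "lost_aa",
            "mutant_protein",
        ):
            assert getattr(a, field) == getattr(b, field), field


class TestDomainOverlap:
    def test_truncation_at_532_matches_published_report(self):
        status = domain_overlap(PUBLISHED_DOMAINS, 532)
        assert status["cysteine_rich"] == "partial"
        assert status["egf_like"] == "lost"
        assert status["transmembrane"] == "lost"
        assert status["cytoplasmic_tail"] == "lost"
        for name in ("signal_peptide", "pro_domain", "metalloprotease", "disintegrin"):
            assert status[name] == "intact"

    def test_full_length_all_intact(self):
        assert set(domain_overlap(PUBLISHED_DOMAINS, 819).values()) == {"intact"}

    def test_empty_protein_all_lost(self):
        assert set(domain_overlap(PUBLISHED_DOMAINS, 0).values()) == {"lost"}


class TestInsilicoPcr:
    def test_fixture_multiplex_assay_logic(self, gene_fixture):
        fx = gene_fixture
        normal = fx.genome[fx.chromosome]
        mutant = fx.mutant_genome[fx.chromosome]
        fwd_n, rev_n, size_n = fx.normal_assay
        fwd_m, rev_m, size_m = fx.mutant_assay
        # normal-allele assay amplifies inside the deleted region only
        assert insilico_pcr(normal, fwd_n, rev_n).products == [size_n]
        assert insilico_pcr(mutant, fwd_n, rev_n).products == []
        # deletion-flanking assay amplifies only after the collapse
        assert insilico_pcr(mutant, fwd_m, rev_m).products == [size_m]
        assert insilico_pcr(normal, fwd_m, rev_m, max_size=6000).products == []
        assert (size_n, size_m) == (602, 1515)

    def test_reverse_primer_given_in_forward_orientation(self):
        template = "A" * 30 + "ACGTACGTACGTACGTT" + "C" * 30 + "GGCATCATGCATCATGG" + "T" * 30
        fwd = "ACGTACGTACGTACGTT"
        rev_site = "GGCATCATGCATCATGG"
        rev = str(Seq(rev_site).reverse_complement())
        assert insilico_pcr(template, fwd, rev).products  # correct orientation
        assert insilico_pcr(template, fwd, rev_site).products == []

    def test_multiple_sites_flagged_ambiguous(self):
        site = "ACGTACGTACGTACGTT"
        rev_site = "GGCATCATGCATCATGG"
        rev = str(Seq(rev_site).reverse_complement())
        template = "T" * 10 + site + "A" * 20 + site + "C" * 20 + rev_site + "G" * 10
        res = insilico_pcr(template, site, rev)
        assert len(res.products) == 2 and res.ambiguous

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr("ACGT" * 30, "ACGT", "ACGTACGTACGTACG")


class TestGeneModelIO:
    def test_gff3_fasta_round_trip(self, gene_fixture, tmp_path):
        fx = gene_fixture
        fx.write(tmp_path)
        domains = read_domain_table(tmp_path / "domains.tsv")
        gm = gene_model_from_gff3(tmp_path / "gene.gff3", domains)
        assert [(e.start, e.end) for e in gm.exons] == [
            (e.start, e.end) for e in fx.gene.exons
        ]
        assert (gm.cds_start, gm.cds_end) == (fx.gene.cds_start, fx.gene.cds_end)
        assert gm.strand == fx.gene.strand
        assert gm.domain_table == fx.gene.domain_table

        import pyfaidx

        genome = pyfaidx.Fasta(str(tmp_path / "genome.fa"))
        cons = transcript_consequence(gm, fx.deletion, genome)
        assert cons.retained_aa == 532 and cons.lost_aa == 287

    def test_domain_table_round_trip(self, tmp_path):
        path = tmp_path / "dom.tsv"
        write_domain_table(PUBLISHED_DOMAINS, path)
        assert read_domain_table(path) == PUBLISHED_DOMAINS
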