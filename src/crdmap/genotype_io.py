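"""Genotype matrix container and PLINK-style PED/MAP text I/O.

Genotypes are biallelic calls held as a dense int8 sample-by-locus grid.
Per locus the two observed alleles are labelled so that ``HOM_A`` is the
homozygote of the lexicographically smaller allele; downstream association
statistics are invariant to this labelling.  Coordinates are 1-based
inclusive throughout; BED exports elsewhere convert to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "HOM_A",
    "HET",
    "HOM_B",
    "CASE",
    "CONTROL",
    "UNKNOWN",
    "SnpLocus",
    "GenotypeMatrix",
    "QCReport",
    "PedMapError",
    "read_ped_map",
    "write_ped_map",
    "qc_filter",
    "duplicate_concordance",
]

# Genotype call codes (int8).  MISSING is distinct from every called state.
MISSING: int = -1
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2

# Phenotype codes, following the PED convention: 1 = control, 2 = case,
# 0 or -9 = unknown.
UNKNOWN: int = 0
CONTROL: int = 1
CASE: int = 2

_VALID_ALLELES = set("ACGT12")


class PedMapError(ValueError):
    """Raised on malformed PED/MAP input (ragged rows, >2 alleles, ...)."""


def chromosome_sort_key(chrom: str) -> tuple:
    """Sort key placing numeric chromosome labels numerically, others after."""
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass(frozen=True, order=False)
class SnpLocus:
    """One SNP: identifier, chromosome label, and 1-based position."""

    id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1")

    @property
    def sort_key(self) -> tuple:
        return (*chromosome_sort_key(self.chromosome), self.position)


@dataclass
class GenotypeMatrix:
    """Samples x loci grid of biallelic genotype calls with phenotypes.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, row order of ``calls``.
    phenotypes : ndarray of int8
        ``CASE``/``CONTROL``/``UNKNOWN`` per sample.
    loci : list of SnpLocus
        Column order of ``calls``; sorted by (chromosome, position).
    calls : ndarray of int8, shape (n_samples, n_loci)
        ``HOM_A``/``HET``/``HOM_B``/``MISSING`` codes.
    alleles : list of (str, str)
        Per-locus allele labels ``(a, b)`` with ``a < b`` lexicographically.
        A monomorphic locus repeats its single allele; an all-missing locus
        uses the placeholder pair ``("0", "0")``.
    """

    sample_ids: list[str]
    phenotypes: np.ndarray
    loci: list[SnpLocus]
    calls: np.ndarray
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_s, n_l = len(self.sample_ids), len(self.loci)
        if self.calls.shape != (n_s, n_l):
            raise ValueError(
                f"calls grid {self.calls.shape} does not match "
                f"{n_s} samples x {n_l} loci"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("sample ids must be unique")
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != n_l:
            raise ValueError("locus ids must be unique")
        if not self.alleles:
            self.alleles = [("A", "B")] * n_l
        elif len(self.alleles) != n_l:
            raise ValueError("alleles list length must match loci")

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotypes == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotypes == CONTROL

    def restrict_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row subset (boolean mask or index array) as a new matrix."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.phenotypes[idx],
            list(self.loci),
            self.calls[idx, :],
            list(self.alleles),
        )

    def restrict_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Column subset (boolean mask or index array) as a new matrix."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.phenotypes.copy(),
            [self.loci[j] for j in idx],
            self.calls[:, idx],
            [self.alleles[j] for j in idx],
        )

    def cases(self) -> "GenotypeMatrix":
        return self.restrict_samples(self.case_mask)

    def controls(self) -> "GenotypeMatrix":
        return self.restrict_samples(self.control_mask)

    def locus_index(self) -> dict[str, int]:
        return {loc.id: j for j, loc in enumerate(self.loci)}


# -- PED/MAP reading -------------------------------------------------------


def _parse_map(map_path: Path) -> list[SnpLocus]:
    loci = []
    for ln, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PedMapError(f"{map_path}:{ln}: expected 4 MAP columns, got {len(parts)}")
        chrom, snp_id, _cm, bp = parts[0], parts[1], parts[2], parts[3]
        loci.append(SnpLocus(id=snp_id, chromosome=chrom, position=int(bp)))
    return loci


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read whitespace-delimited PED + MAP files into a GenotypeMatrix.

    PED columns: family, sample id, father, mother, sex, phenotype, then two
    allele fields per SNP from ``{A,C,G,T,1,2,0}`` with ``0 0`` meaning a
    missing call.  MAP columns: chromosome, id, cM (ignored), bp.  Loci are
    returned sorted by (chromosome, position); call columns are permuted to
    match.

    Raises
    ------
    PedMapError
        On a ragged PED row (naming the line) or a locus with more than two
        observed alleles (naming the locus).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    loci = _parse_map(map_path)
    n_loci = len(loci)

    sample_ids: list[str] = []
    phenotypes: list[int] = []
    rows: list[list[str]] = []
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_loci:
            raise PedMapError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_loci} fields "
                f"({n_loci} SNPs), got {len(parts)}"
            )
        sample_ids.append(parts[1])
        ph = parts[5]
        phenotypes.append(CASE if ph == "2" else CONTROL if ph == "1" else UNKNOWN)
        rows.append(parts[6:])

    n_samples = len(sample_ids)
    allele_grid = np.array(rows, dtype="U1").reshape(n_samples, n_loci, 2) if rows else (
        np.empty((0, n_loci, 2), dtype="U1")
    )

    calls = np.full((n_samples, n_loci), MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    for j, locus in enumerate(loci):
        pair = allele_grid[:, j, :]
        observed = set(pair.ravel().tolist()) - {"0"}
        bad = observed - _VALID_ALLELES
        if bad:
            raise PedMapError(f"locus {locus.id}: invalid allele field(s) {sorted(bad)}")
        if len(observed) > 2:
            raise PedMapError(
                f"locus {locus.id}: more than two alleles observed ({sorted(observed)})"
            )
        if not observed:
            alleles.append(("0", "0"))
            continue
        ordered = sorted(observed)
        a = ordered[0]
        b = ordered[1] if len(ordered) == 2 else ordered[0]
        alleles.append((a, b))
        called = (pair[:, 0] != "0") & (pair[:, 1] != "0")
        n_a = (pair == a).sum(axis=1)
        # dosage of b = 2 - count of a among called genotypes
        calls[called, j] = (2 - n_a[called]).astype(np.int8)
        if len(ordered) == 1:
            calls[called, j] = HOM_A

    m = GenotypeMatrix(sample_ids, np.array(phenotypes), loci, calls, alleles)
    order = sorted(range(n_loci), key=lambda j: m.loci[j].sort_key)
    return m.restrict_loci(np.array(order, dtype=int))


def write_ped_map(m: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a GenotypeMatrix back to PED/MAP text (cM column written as 0)."""
    ped_path, map_path = Path(ped_path), Path(map_path)
    with open(map_path, "w") as fh:
        for loc in m.loci:
            fh.write(f"{loc.chromosome}\t{loc.id}\t0\t{loc.position}\n")

    with open(ped_path, "w") as fh:
        for i, sid in enumerate(m.sample_ids):
            ph = m.phenotypes[i]
            fields = [sid, sid, "0", "0", "0", str(int(ph) if ph in (CASE, CONTROL) else 0)]
            for j in range(m.n_loci):
                a, b = m.alleles[j]
                c = m.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == HOM_A:
                    fields += [a, a]
                elif c == HET:
                    fields += [a, b]
                else:
                    fields += [b, b]
            fh.write(" ".join(fields) + "\n")


def write_phenotypes(m: GenotypeMatrix, path: str | Path) -> None:
    """Phenotype table as TSV: sample, status in {CASE, CONTROL, UNKNOWN}."""
    name = {CASE: "CASE", CONTROL: "CONTROL", UNKNOWN: "UNKNOWN"}
    df = pd.DataFrame(
        {"sample": m.sample_ids, "status": [name[int(p)] for p in m.phenotypes]}
    )
    df.to_csv(path, sep="\t", index=False)


# -- QC --------------------------------------------------------------------


@dataclass
class QCReport:
    """Counts retained/removed by the call-rate filters."""

    n_loci_in: int
    n_loci_removed: int
    n_samples_in: int
    n_samples_removed: int
    min_locus_call_rate: float
    min_sample_call_rate: float

    @property
    def n_loci_retained(self) -> int:
        return self.n_loci_in - self.n_loci_removed

    @property
    def n_samples_retained(self) -> int:
        return self.n_samples_in - self.n_samples_removed

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                ("loci_in", self.n_loci_in),
                ("loci_removed", self.n_loci_removed),
                ("loci_retained", self.n_loci_retained),
                ("samples_in", self.n_samples_in),
                ("samples_removed", self.n_samples_removed),
                ("samples_retained", self.n_samples_retained),
                ("min_locus_call_rate", self.min_locus_call_rate),
                ("min_sample_call_rate", self.min_sample_call_rate),
            ],
            columns=["metric", "value"],
        ).to_csv(path, sep="\t", index=False)


def qc_filter(
    m: GenotypeMatrix,
    min_locus_call_rate: float = 0.9,
    min_sample_call_rate: float = 0.9,
) -> tuple[GenotypeMatrix, QCReport]:
    """Call-rate QC: drop loci below the locus threshold, then samples below
    the sample threshold (sample rates computed on the retained loci).

    Both thresholds are fractions in [0, 1]; a call rate equal to the
    threshold passes.  An empty result is a warning, not an error.
    """
    for r in (min_locus_call_rate, min_sample_call_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("call-rate thresholds must lie in [0, 1]")

    present = m.calls != MISSING
    locus_rate = present.mean(axis=0) if m.n_samples else np.ones(m.n_loci)
    keep_loci = locus_rate >= min_locus_call_rate
    m2 = m.restrict_loci(keep_loci)

    present2 = m2.calls != MISSING
    sample_rate = present2.mean(axis=1) if m2.n_loci else np.ones(m2.n_samples)
    keep_samples = sample_rate >= min_sample_call_rate
    m3 = m2.restrict_samples(keep_samples)

    report = QCReport(
        n_loci_in=m.n_loci,
        n_loci_removed=int((~keep_loci).sum()),
        n_samples_in=m.n_samples,
        n_samples_removed=int((~keep_samples).sum()),
        min_locus_call_rate=min_locus_call_rate,
        min_sample_call_rate=min_sample_call_rate,
    )
    if m3.n_loci == 0 or m3.n_samples == 0:
        warnings.warn("qc_filter removed every locus or sample", stacklevel=2)
    return m3, report


# -- duplicate concordance -------------------------------------------------


def duplicate_concordance(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> float:
    """Fraction of positions at which two call vectors agree exactly.

    The denominator is all compared positions.  A MISSING call against a
    called genotype counts as discordant; MISSING against MISSING counts as
    concordant.  This is the per-duplicate consistency statistic of a
    genotyping run (e.g. 984 identical calls out of 1,000 gives 0.984).
    """
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty call vectors")
    return float((a == b).mean())


def iter_call_codes() -> Iterable[int]:
    """The four genotype-call states."""
    return (HOM_A, HET, HOM_B, MISSING)
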