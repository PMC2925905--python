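"""Dosage-correlation confirmation and multiplex-assay genotype calls.

Agreement between a candidate SNP and the causal mutation is quantified as
the Pearson correlation of allele-dosage vectors (0/1/2 copies of the
designated allele per dog), computed over samples where both genotypes are
known.  A SNP in complete linkage disequilibrium with the mutation gives
r = 1.  The multiplex classifier reproduces the two-amplicon allele logic:
the normal-allele product is amplified from within the deleted sequence,
the mutant-allele product across the collapsed deletion.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "DosageVector",
    "genotype_r",
    "MultiplexCall",
    "classify_multiplex",
]


class DosageVector:
    """Per-sample counts (0/1/2) of a designated allele; None/NaN = missing."""

    def __init__(self, values: Sequence) -> None:
        arr = np.array(
            [np.nan if v is None else float(v) for v in values], dtype=float
        )
        known = arr[~np.isnan(arr)]
        if known.size and not np.isin(known, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.values = arr

    def __len__(self) -> int:
        return len(self.values)


def genotype_r(
    snp: DosageVector | Sequence, mutation: DosageVector | Sequence
) -> Optional[float]:
    """Pearson correlation between two dosage vectors over complete pairs.

    Returns a value in [-1, 1], or None when the correlation is undefined
    (fewer than two complete pairs, or either vector constant over the
    complete pairs).  None is an explicit "undefined" flag; NaN is never
    returned.
    """
    x = snp.values if isinstance(snp, DosageVector) else DosageVector(snp).values
    y = (
        mutation.values
        if isinstance(mutation, DosageVector)
        else DosageVector(mutation).values
    )
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return None
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return None
    r = float(np.corrcoef(xs, ys)[0, 1])
    return max(-1.0, min(1.0, r))


class MultiplexCall(Enum):
    NORMAL = "NORMAL"
    CARRIER = "CARRIER"
    AFFECTED = "AFFECTED"
    UNCALLED = "UNCALLED"


def classify_multiplex(
    product_sizes: Iterable[int], normal_size: int, mutant_size: int
) -> tuple[MultiplexCall, str]:
    """Classify a dog from the amplicon sizes of a two-allele multiplex PCR.

    With the published assay the normal allele yields a 602 bp product and
    the deletion allele a 1,515 bp product; both bands mark a carrier.
    Returns (call, reason); the reason is empty for a clean call.
    """
    if normal_size == mutant_size:
        raise ValueError("expected product sizes must differ")
    observed = set(int(s) for s in product_sizes)
    expected = {normal_size, mutant_size}
    unexpected = observed - expected
    if unexpected:
        return MultiplexCall.UNCALLED, f"unexpected product size(s): {sorted(unexpected)}"
    if not observed:
        return MultiplexCall.UNCALLED, "no product observed"
    if observed == expected:
        return MultiplexCall.CARRIER, ""
    if observed == {normal_size}:
        return MultiplexCall.NORMAL, ""
    return MultiplexCall.AFFECTED, ""
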