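"""Shared fixtures: small genotype matrices, PED/MAP files on disk, and the
session-scoped gene fixture (generation is deterministic and cheap)."""

from __future__ import annotations

import numpy as np
import pytest

from crdmap.genotype_io import (
    CASE,
    CONTROL,
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    GenotypeMatrix,
    SnpLocus,
)
from crdmap.synthetic_data import FixtureSpec, SimConfig, generate_gene_fixture, simulate_breed


def make_matrix(calls, phenotypes, positions=None, chromosome="1"):
    """Build a GenotypeMatrix from a nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_l = calls.shape
    positions = positions or [1000 * (j + 1) for j in range(n_l)]
    loci = [SnpLocus(f"snp{j}", chromosome, positions[j]) for j in range(n_l)]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_s)],
        phenotypes=np.asarray(phenotypes, dtype=np.int8),
        loci=loci,
        calls=calls,
        alleles=[("A", "G")] * n_l,
    )


@pytest.fixture(scope="session")
def gene_fixture():
    return generate_gene_fixture(FixtureSpec(), seed=0)


@pytest.fixture(scope="session")
def sim_default():
    """One default-config simulated breed (seed 0) with its truth record."""
    return simulate_breed(SimConfig(seed=0))


@pytest.fixture()
def toy_ped_map(tmp_path):
    """Two samples x four SNPs covering HOM_A/HET/HOM_B and a missing call."""
    ped = tmp_path / "toy.ped"
    map_ = tmp_path / "toy.map"
    ped.write_text(
        "f1 d1 0 0 0 2 A A A G G G C C\n"
        "f1 d2 0 0 0 1 A A A A A G 0 0\n"
    )
    map_.write_text(
        "1 snpA 0 100\n"
        "1 snpB 0 200\n"
        "1 snpC 0 300\n"
        "1 snpD 0 400\n"
    )
    return ped, map_


def random_calls(rng, n_samples, n_loci, p_missing=0.05):
    calls = rng.choice([HOM_A, HET, HOM_B], size=(n_samples, n_loci)).astype(np.int8)
    miss = rng.random((n_samples, n_loci)) < p_missing
    calls[miss] = MISSING
    return calls


__all__ = [
    "make_matrix",
    "random_calls",
    "CASE",
    "CONTROL",
    "HET",
    "HOM_A",
    "HOM_B",
    "MISSING",
]
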