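"""Shared fixtures: hand-built genotype tables and reusable simulations."""

import numpy as np
import pytest

from pollenflow.core_io import (Locus, ProgenyArray, SpatialGenotypeTable)
from pollenflow.simgen import SimulationScenario, simulate_dataset


def make_table(genotypes, sex=None, xy=None, n_alleles=None, habitat=None):
    """Build a SpatialGenotypeTable from a nested list of allele-index pairs.

    ``genotypes[i][l]`` is ``(a, b)`` or ``None`` for missing; allele
    catalogues are sized to the observed maximum (or ``n_alleles``).
    """
    n = len(genotypes)
    L = len(genotypes[0])
    geno = np.full((n, L, 2), -1, dtype=np.int32)
    for i, row in enumerate(genotypes):
        for l, pair in enumerate(row):
            if pair is not None:
                geno[i, l] = pair
    if n_alleles is None:
        n_alleles = [max(int(geno[:, l].max()) + 1, 1) for l in range(L)]
    loci = [Locus(f"loc{l + 1}", [str(101 + a) for a in range(n_alleles[l])])
            for l in range(L)]
    if sex is None:
        sex = ["male"] * n
    if xy is None:
        xy = np.column_stack([np.arange(n, dtype=float),
                              np.zeros(n)])
    ids = [f"I{i + 1:03d}" for i in range(n)]
    return SpatialGenotypeTable(ids, sex, np.asarray(xy, float), geno, loci,
                                habitat)


def make_progeny(adults, rows):
    """ProgenyArray from ``rows`` of (mother_id, [(a, b) or None per locus])."""
    L = adults.n_loci
    geno = np.full((len(rows), L, 2), -1, dtype=np.int32)
    mothers = []
    for i, (m, g) in enumerate(rows):
        mothers.append(m)
        for l, pair in enumerate(g):
            if pair is not None:
                geno[i, l] = pair
    ids = [f"S{i + 1:04d}" for i in range(len(rows))]
    return ProgenyArray(ids, mothers, geno, adults.loci)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Moderate-immigration simulation reused by several estimator tests:
    power-exponential kernel (delta 250 m, b 0.5), skewed fecundities."""
    scenario = SimulationScenario(
        n_males=80, n_females=15, n_sampled_mothers=15,
        allele_counts=(12, 12, 12, 12, 12, 12, 12), immigration=0.3,
        delta=250.0, shape_b=0.5, fecundity_cv=1.5, seeds_per_mother=20)
    adults, progeny, ledger = simulate_dataset(scenario, 20260101)
    return scenario, adults, progeny, ledger
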