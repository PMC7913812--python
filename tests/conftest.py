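"""Shared fixtures: small deterministic synthetic populations and maps."""

import numpy as np
import pandas as pd
import pytest

from csslkit import (
    BreedingScheme,
    GenomeSpec,
    simulate_cssl_population,
    simulate_parents,
)
from csslkit.containers import GenotypeMatrix
from csslkit.segmap import PhysicalMap, SNPLDBMarker


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec.regular(n_chrom=2, chrom_length=10_000_000, sites_per_chrom=50)


@pytest.fixture(scope="session")
def small_population(small_genome):
    parents = simulate_parents(small_genome, seed=11)
    matrix, truth = simulate_cssl_population(
        parents, BreedingScheme(n_backcross=3, n_self=6), n_lines=40, seed=12
    )
    return matrix, truth


def make_matrix(calls, positions=None, chrom="Gm01", qual=60.0, mean_dp=10.0,
                chrom_length=None):
    """Single-chromosome genotype matrix from a (lines x sites) code array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites = calls.shape[1]
    if positions is None:
        positions = (np.arange(1, n_sites + 1) * 10_000).astype(np.int64)
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": positions,
        "qual": [qual] * n_sites,
        "mean_dp": [mean_dp] * n_sites,
    })
    lines = [f"L{i + 1:02d}" for i in range(calls.shape[0])]
    lengths = {chrom: chrom_length or int(positions[-1])}
    return GenotypeMatrix(sites=sites, lines=lines, calls=calls,
                         chrom_lengths=lengths)


def make_map(codes, bounds, chrom="Gm01", lines=None, chrom_length=None):
    """PhysicalMap from a (lines x markers) code array and marker end bounds."""
    codes = np.asarray(codes, dtype=np.int8)
    starts = [1] + [b + 1 for b in bounds[:-1]]
    markers = [SNPLDBMarker(id=f"{chrom}_LDB_{k + 1}", chrom=chrom,
                            start=s, end=e)
               for k, (s, e) in enumerate(zip(starts, bounds))]
    lines = lines or [f"L{i + 1:02d}" for i in range(codes.shape[0])]
    return PhysicalMap(markers=markers, lines=list(lines), codes=codes,
                       chrom_lengths={chrom: chrom_length or bounds[-1]})
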