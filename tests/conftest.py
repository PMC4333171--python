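"""Shared fixtures: small maps and a reusable simulated study."""

import numpy as np
import pandas as pd
import pytest

from gpimpute import (
    GeneticMap,
    GenotypeMatrix,
    filter_loci,
    recode_by_major_allele,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    return GeneticMap.uniform(n_chromosomes=2, loci_per_chromosome=10, spacing_cM=5.0)


@pytest.fixture(scope="session")
def study():
    """One default-scale simulated study (600 individuals x 300 loci)."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def qc_study(study):
    """The same study after QC and major-allele recoding, with aligned haplotypes."""
    filtered, _report = filter_loci(study.genotypes)
    kept = np.array([study.genotypes.locus_ids.index(l) for l in filtered.locus_ids])
    geno, flipped = recode_by_major_allele(filtered)
    haps = study.haplotypes[:, kept, :]
    haps = np.where(flipped[None, :, None], 1 - haps, haps)
    return {"study": study, "genotypes": geno, "haplotypes": haps}


def random_genotypes(rng: np.random.Generator, n: int, p: int, missing: float = 0.0) -> GenotypeMatrix:
    codes = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    if missing > 0:
        codes[rng.random((n, p)) < missing] = -1
    loci = pd.DataFrame(
        {"locus_id": [f"m{j}" for j in range(p)], "chromosome": 1, "position_cM": np.arange(p, dtype=float)}
    )
    return GenotypeMatrix(codes=codes, individual_ids=[f"i{i}" for i in range(n)], loci=loci)
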