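"""Shared fixtures: small simulated matrices and hand-built genotype data."""

import numpy as np
import pytest

from wingscan import GenotypeMatrix, MCMCConfig, SimParams, filter_loci, simulate_genotypes


def make_gm(calls, groups, locus_ids=None):
    """Build a GenotypeMatrix from a plain nested list of calls."""
    calls = np.asarray(calls)
    n, m = calls.shape
    return GenotypeMatrix(
        [f"ind{i}" for i in range(n)],
        locus_ids or [f"{100 + j}_1" for j in range(m)],
        calls,
        groups,
    )


@pytest.fixture(scope="session")
def planted_sim():
    """Balanced-size two-group simulation with one near-fixed planted locus."""
    params = SimParams(
        n_group1=34, n_group2=31, n_loci=300, n_assoc=1,
        p_assoc_g1=0.05, p_assoc_g2=0.95, seed=5,
    )
    gm, truth = simulate_genotypes(params)
    return filter_loci(gm, one_per_tag=False), truth


@pytest.fixture(scope="session")
def paper_scale_sim():
    """Study-geometry simulation: 34/62 individuals, 2000 loci, 3 planted."""
    gm, truth = simulate_genotypes(SimParams(n_loci=2000, n_assoc=3, seed=42))
    return filter_loci(gm, one_per_tag=False), truth


@pytest.fixture(scope="session")
def fast_cfg():
    return MCMCConfig.reduced(seed=9)
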