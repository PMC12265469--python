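"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pestgs.core import SimCohortSpec
from pestgs.simdata import generate_leaf_image, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_cohort():
    """A small structured cohort with planted QTLs (n=120, m=600)."""
    spec = SimCohortSpec(n_samples=120, n_snps=600, n_qtl=10, h2=0.6, seed=42)
    G = simulate_genotypes(spec)
    pheno, qtl = simulate_phenotypes(G, spec)
    return spec, G, pheno, qtl


@pytest.fixture(scope="session")
def unstructured_cohort():
    """One panmictic population without LD (independent SNPs)."""
    spec = SimCohortSpec(
        n_samples=200, n_snps=800, n_pops=1, fst=0.0, ld_block_len=1, seed=7
    )
    return spec, simulate_genotypes(spec)


@pytest.fixture(scope="session")
def leaf_batch():
    """Thirty small leaves spanning the damage range, with ground truth."""
    rng = np.random.default_rng(11)
    leaves = []
    for i in range(30):
        f = float(rng.uniform(0.0, 0.95))
        leaves.append(generate_leaf_image(f, size=48, seed=1000 + i))
    return leaves
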