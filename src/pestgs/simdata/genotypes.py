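"""Structured diploid cohorts with local LD, plus additive phenotypes.

Genotypes follow a Balding-Nichols divergence model: each SNP has an
ancestral frequency drawn from the requested MAF range, and each
sub-population draws its own frequency from a Beta distribution whose
variance is set by the target F_ST. Local LD comes from an AR(1) Gaussian
copula over haplotypes: within a block, adjacent latent variables share
correlation ``ld_rho``, so indicator (allele) correlation decays with
distance and resets at block boundaries.

Phenotypes are additive-liability traits: a handful of planted QTLs with
normal effects give the genetic value, environmental noise is scaled to the
requested heritability, the continuous record is an affine map of liability
onto the 0-5 damage scale, and the binary record thresholds the standardised
liability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from pestgs.core import MISSING, GenotypeMatrix, PhenotypeTable, SimCohortSpec

_N_CHROM = 5
_SNP_SPACING_BP = 500


def _population_sizes(n: int, k: int) -> np.ndarray:
    base = n // k
    sizes = np.full(k, base, dtype=int)
    sizes[: n - base * k] += 1
    return sizes


def simulate_genotypes(spec: SimCohortSpec) -> GenotypeMatrix:
    """Simulate a cohort of diploid dosages under the spec's conditions."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 202]))
    n, m, k = spec.n_samples, spec.n_snps, spec.n_pops

    anc = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    if spec.fst > 0 and k > 1:
        F = spec.fst
        a = anc * (1.0 - F) / F
        b = (1.0 - anc) * (1.0 - F) / F
        pop_freq = rng.beta(a[None, :], b[None, :], size=(k, m))
    else:
        pop_freq = np.tile(anc, (k, 1))
    pop_freq = np.clip(pop_freq, 1e-3, 1.0 - 1e-3)

    sizes = _population_sizes(n, k)
    pop_labels = np.repeat(np.arange(k), sizes)

    # Chromosome layout: SNPs split as evenly as possible over _N_CHROM
    # chromosomes, evenly spaced; LD blocks never span a chromosome break.
    chrom_sizes = _population_sizes(m, min(_N_CHROM, m))
    chrom = np.repeat(np.arange(1, len(chrom_sizes) + 1), chrom_sizes)
    pos = np.concatenate(
        [np.arange(1, sz + 1, dtype=np.int64) * _SNP_SPACING_BP for sz in chrom_sizes]
    )

    # Block starts: every ld_block_len SNPs, re-anchored at chromosome starts.
    new_block = np.zeros(m, dtype=bool)
    offset = 0
    for sz in chrom_sizes:
        local = np.arange(sz)
        new_block[offset + local[local % spec.ld_block_len == 0]] = True
        offset += sz
    new_block[0] = True

    # AR(1) latent Gaussians over 2n haplotypes.
    z = np.empty((2 * n, m), dtype=np.float64)
    eps = rng.standard_normal(size=(2 * n, m))
    rho = float(spec.ld_rho)
    carry = np.sqrt(max(0.0, 1.0 - rho**2))
    z[:, 0] = eps[:, 0]
    for j in range(1, m):
        if new_block[j]:
            z[:, j] = eps[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + carry * eps[:, j]

    hap_pop = np.repeat(pop_labels, 2)
    thresh = stats.norm.ppf(pop_freq)  # k x m
    alleles = (z < thresh[hap_pop, :]).astype(np.int16)
    dosages = alleles[0::2, :] + alleles[1::2, :]

    if spec.missing_rate > 0:
        miss = rng.random(size=dosages.shape) < spec.missing_rate
        dosages[miss] = MISSING

    snp_ids = np.array([f"snp_{c}_{p}" for c, p in zip(chrom, pos)])
    sample_ids = np.array([f"acc_{i:04d}" for i in range(n)])
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chrom=chrom.astype(np.int32),
        pos=pos,
        ref=np.full(m, "A"),
        alt=np.full(m, "T"),
        sample_ids=sample_ids,
        pop_labels=pop_labels,
    )


def simulate_phenotypes(
    G: GenotypeMatrix, spec: SimCohortSpec
) -> tuple[PhenotypeTable, np.ndarray]:
    """Plant additive QTLs on ``G`` and emit binary + continuous phenotypes.

    Returns the phenotype table (with ``true_genetic_value``) and the sorted
    causal SNP column indices, for recovery tests downstream.
    """
    if spec.n_qtl > G.n_snps:
        raise ValueError("n_qtl cannot exceed the number of SNPs")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 707]))
    qtl = np.sort(rng.choice(G.n_snps, size=spec.n_qtl, replace=False))
    beta = rng.standard_normal(spec.n_qtl)

    X = G.dosages[:, qtl].astype(np.float64)
    obs = X != MISSING
    col_mean = np.where(obs, X, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    X = np.where(obs, X, col_mean[None, :])
    g = X @ beta
    g = g - g.mean()

    var_g = float(g.var())
    h2 = spec.h2
    if h2 >= 1.0:
        liability = g.copy()
    elif h2 <= 0.0 or var_g == 0.0:
        # No heritable share: liability is pure environment on unit scale;
        # true_genetic_value still records g for recovery checks.
        liability = rng.standard_normal(G.n_samples)
    else:
        noise = rng.normal(0.0, np.sqrt(var_g * (1.0 - h2) / h2), size=G.n_samples)
        liability = g + noise

    z = (liability - liability.mean()) / max(liability.std(), 1e-12)
    binary = (z > spec.liability_threshold).astype(int)
    span = liability.max() - liability.min()
    continuous = np.clip(
        5.0 * (liability - liability.min()) / (span if span > 0 else 1.0), 0.0, 5.0
    )

    frame = pd.DataFrame(
        {
            "accession_id": G.sample_ids,
            "binary_pheno": binary,
            "continuous_pheno": continuous,
            "true_genetic_value": g,
        }
    )
    return PhenotypeTable(frame=frame), qtl
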