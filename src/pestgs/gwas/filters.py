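"""Quality filters on the genotype matrix."""

from __future__ import annotations

from pestgs.core import GenotypeMatrix


class EmptyFilterResult(RuntimeError):
    """Every SNP was removed by the quality filters."""


def filter_snps(
    G: GenotypeMatrix, max_missing: float = 0.05, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Drop SNPs with too much missingness or too little minor-allele frequency.

    A SNP is retained when its missing-call rate is at most ``max_missing``
    and its minor allele frequency is at least ``min_maf`` — both boundaries
    kept, since exclusion applies strictly beyond them. Idempotent; marker
    map and genomic order are preserved.
    """
    keep = (G.missing_rate() <= max_missing) & (G.maf() >= min_maf)
    if not keep.any():
        raise EmptyFilterResult("all SNPs removed by missingness/MAF filters")
    import numpy as np

    return G.take_snps(np.nonzero(keep)[0])
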