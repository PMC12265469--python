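"""Sliding-window LD pruning of a genotype matrix."""

from __future__ import annotations

import numpy as np

from pestgs.core import GenotypeMatrix
from pestgs.gwas.popgen import r2_matrix


def ld_prune(
    G: GenotypeMatrix,
    window: int = 100,
    step: int = 50,
    r2_max: float = 0.2,
    verify: bool = True,
) -> np.ndarray:
    """Indices of SNPs surviving window/step/r^2 pruning, in genomic order.

    Windows of ``window`` SNPs advance by ``step`` SNPs along each
    chromosome. Within a window, while any retained pair exceeds ``r2_max``,
    the pair with the largest r^2 loses one member: the SNP with the lower
    minor allele frequency, or at equal frequency the one at the later
    position. With ``verify`` the final set is re-scanned over the same
    windows and a violation raises (it cannot occur by construction; the
    scan is the executable post-condition).
    """
    if window < 2:
        raise ValueError("window must span at least 2 SNPs")
    if step < 1:
        raise ValueError("step must be >= 1")
    keep = np.ones(G.n_snps, dtype=bool)
    maf = G.maf()

    def prune_window(idx: np.ndarray) -> None:
        live = idx[keep[idx]]
        if len(live) < 2:
            return
        R = r2_matrix(G, live)
        np.fill_diagonal(R, 0.0)
        R = np.nan_to_num(R, nan=0.0)
        alive = np.ones(len(live), dtype=bool)
        while True:
            sub = np.where(np.outer(alive, alive), R, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] <= r2_max:
                break
            a, b = live[i], live[j]
            # victim: lower MAF, ties to the later genomic position
            if (maf[a], -G.pos[a]) <= (maf[b], -G.pos[b]):
                victim, vloc = a, i
            else:
                victim, vloc = b, j
            keep[victim] = False
            alive[vloc] = False

    for c in np.unique(G.chrom):
        snps_c = np.nonzero(G.chrom == c)[0]
        for start in range(0, len(snps_c), step):
            prune_window(snps_c[start : start + window])
            if start + window >= len(snps_c):
                break

    retained = np.nonzero(keep)[0]
    if verify:
        for c in np.unique(G.chrom):
            snps_c = np.nonzero(G.chrom == c)[0]
            for start in range(0, len(snps_c), step):
                idx = snps_c[start : start + window]
                live = idx[keep[idx]]
                if len(live) >= 2:
                    R = np.nan_to_num(r2_matrix(G, live), nan=0.0)
                    np.fill_diagonal(R, 0.0)
                    if R.max() > r2_max + 1e-12:
                        raise RuntimeError("pruning post-condition violated")
                if start + window >= len(snps_c):
                    break
    return retained
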