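"""Genomic relationship matrix from centred dosages."""

from __future__ import annotations

import numpy as np

from pestgs.core import MISSING, GenotypeMatrix


def kinship(G: GenotypeMatrix) -> np.ndarray:
    """Centred GRM: K = Z Z' / m with Z the column-centred dosage matrix.

    Missing dosages are replaced by the SNP mean for this computation only
    (so they contribute zero after centring). K is symmetric positive
    semidefinite by construction.
    """
    if G.n_snps == 0:
        raise ValueError("no SNPs")
    Z = G.dosages.astype(np.float64)
    obs = Z != MISSING
    mean = np.where(obs, Z, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    Z = np.where(obs, Z, mean[None, :]) - mean[None, :]
    K = (Z @ Z.T) / G.n_snps
    return (K + K.T) / 2.0
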