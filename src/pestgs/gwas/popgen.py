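"""Windowed F_ST and nucleotide diversity, and pairwise LD r^2.

F_ST uses Hudson's estimator as a ratio of averages: numerator and
denominator are summed over the SNPs of a window before dividing. Diversity
is per-window expected heterozygosity per base pair with the standard
finite-sample correction. LD r^2 is the squared Pearson correlation of
dosage vectors over samples non-missing at both SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from pestgs.core import MISSING, GenotypeMatrix


@dataclass
class WindowStat:
    chrom: int
    start: int  # 1-based inclusive
    end: int
    n_snps: int
    value: float

    def to_dict(self) -> dict:
        return {
            "chrom": int(self.chrom),
            "start": int(self.start),
            "end": int(self.end),
            "n_snps": int(self.n_snps),
            "value": round(float(self.value), 8),
        }


def _freq_and_n(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    obs = D != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.where(obs, D, 0).sum(axis=0) / (2.0 * n_obs), np.nan)
    return p, n_obs


def _windows(pos: np.ndarray, window_bp: int, step_bp: int):
    """Sliding [start, start + window_bp - 1] windows covering the SNP span."""
    last = int(pos.max())
    start = 1
    while start <= last:
        yield start, start + window_bp - 1
        start += step_bp


def hudson_fst_components(G: GenotypeMatrix, pop_labels=None):
    """Per-SNP Hudson numerator/denominator for every population pair."""
    labels = G.pop_labels if pop_labels is None else np.asarray(pop_labels)
    if labels is None:
        raise ValueError("population labels are required")
    pops = np.unique(labels)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    stats = {}
    for pa, pb in combinations(pops, 2):
        Da = G.dosages[labels == pa]
        Db = G.dosages[labels == pb]
        if Da.shape[0] < 2 or Db.shape[0] < 2:
            raise ValueError("each population needs at least 2 samples")
        p1, n1 = _freq_and_n(Da)
        p2, n2 = _freq_and_n(Db)
        # allele counts: 2 * diploid sample counts
        a1, a2 = 2.0 * n1, 2.0 * n2
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(a1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(a2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        stats[(pa, pb)] = (num, den)
    return stats


def window_fst(
    G: GenotypeMatrix,
    pop_labels=None,
    window_bp: int = 100_000,
    step_bp: int | None = None,
) -> list[WindowStat]:
    """Hudson F_ST per sliding window (ratio of averages, clipped to [0, 1]).

    With more than two populations the window value is the mean of the
    pairwise ratio-of-averages estimates. Windows without SNPs are omitted.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    step_bp = step_bp or window_bp
    comps = hudson_fst_components(G, pop_labels)
    out = []
    for c in np.unique(G.chrom):
        on_c = G.chrom == c
        pos_c = G.pos[on_c]
        idx_c = np.nonzero(on_c)[0]
        for start, end in _windows(pos_c, window_bp, step_bp):
            in_w = idx_c[(pos_c >= start) & (pos_c <= end)]
            if len(in_w) == 0:
                continue
            ratios = []
            for num, den in comps.values():
                dsum = np.nansum(den[in_w])
                if dsum > 0:
                    ratios.append(np.nansum(num[in_w]) / dsum)
            if not ratios:
                continue
            val = float(np.clip(np.mean(ratios), 0.0, 1.0))
            out.append(WindowStat(int(c), start, end, len(in_w), val))
    return out


def window_pi(
    G: GenotypeMatrix, window_bp: int = 100_000, step_bp: int | None = None
) -> list[WindowStat]:
    """Nucleotide diversity per window: sum of 2p(1-p) * 2n/(2n-1), per bp."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    step_bp = step_bp or window_bp
    p, n_obs = _freq_and_n(G.dosages)
    alleles = 2.0 * n_obs
    per_snp = 2.0 * p * (1.0 - p) * alleles / np.maximum(alleles - 1.0, 1.0)
    out = []
    for c in np.unique(G.chrom):
        on_c = G.chrom == c
        pos_c = G.pos[on_c]
        idx_c = np.nonzero(on_c)[0]
        for start, end in _windows(pos_c, window_bp, step_bp):
            in_w = idx_c[(pos_c >= start) & (pos_c <= end)]
            if len(in_w) == 0:
                continue
            out.append(
                WindowStat(
                    int(c),
                    start,
                    end,
                    len(in_w),
                    float(np.nansum(per_snp[in_w]) / window_bp),
                )
            )
    return out


def ld_r2(G: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Squared dosage correlation over samples non-missing at both SNPs."""
    xi = G.dosages[:, snp_i].astype(float)
    xj = G.dosages[:, snp_j].astype(float)
    both = (xi != MISSING) & (xj != MISSING)
    xi, xj = xi[both], xj[both]
    if len(xi) < 2 or xi.std() == 0 or xj.std() == 0:
        raise ValueError("r^2 undefined: monomorphic or insufficient overlap")
    r = np.corrcoef(xi, xj)[0, 1]
    return float(r * r)


def r2_matrix(G: GenotypeMatrix, idx) -> np.ndarray:
    """Pairwise r^2 among the SNP columns ``idx`` (missing mean-imputed)."""
    idx = np.asarray(idx)
    D = G.dosages[:, idx].astype(float)
    obs = D != MISSING
    mean = np.where(obs, D, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    D = np.where(obs, D, mean[None, :])
    Z = D - D.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = np.nan
    C = (Z.T @ Z) / len(Z)
    R = C / np.outer(sd, sd)
    return R * R
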