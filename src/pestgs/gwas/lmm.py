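"""Exact linear-mixed-model association scan with per-SNP REML profiling.

Model: y = W a + x b + u + e with u ~ N(0, s2_g K) and e ~ N(0, s2_e I).
One eigendecomposition of K rotates the problem to independent residuals
with variances proportional to (lambda * s_i + 1), lambda = s2_g / s2_e.
For every SNP the restricted likelihood is profiled over lambda on a
100-point log grid followed by golden-section refinement, then b and its
standard error come from GLS at the optimum and the Wald statistic
(b / se)^2 is referred to chi-square with 1 df.

Binary phenotypes are analysed as quantitative 0/1 under the same model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pestgs.core import MISSING, GenotypeMatrix

_LAMBDA_GRID = np.logspace(-5, 5, 100)
_GOLDEN_ITERS = 25
_INV_PHI = (np.sqrt(5.0) - 1.0) / 2.0


def _profile(w, a0, y, X, Xsq):
    """REML profile pieces for all SNP columns at shared weights ``w`` (n,)."""
    A = float(np.sum(w * a0 * a0))
    D = float(np.sum(w * a0 * y))
    F = float(np.sum(w * y * y))
    wa0 = w * a0
    wy = w * y
    B = wa0 @ X
    C = w @ Xsq
    E = wy @ X
    det = A * C - B * B
    beta1 = (A * E - B * D) / det
    beta0 = (C * D - B * E) / det
    rss = F - beta0 * D - beta1 * E
    return det, beta1, rss, A


def _profile_perSNP(lam, s, a0, y, X, Xsq):
    """Same pieces with a separate lambda per SNP column (vectorised)."""
    d = lam[None, :] * s[:, None] + 1.0
    w = 1.0 / d
    A = (w * (a0 * a0)[:, None]).sum(axis=0)
    D = (w * (a0 * y)[:, None]).sum(axis=0)
    F = (w * (y * y)[:, None]).sum(axis=0)
    B = (w * a0[:, None] * X).sum(axis=0)
    C = (w * Xsq).sum(axis=0)
    E = (w * y[:, None] * X).sum(axis=0)
    det = A * C - B * B
    with np.errstate(invalid="ignore", divide="ignore"):
        beta1 = (A * E - B * D) / det
        beta0 = (C * D - B * E) / det
    rss = F - beta0 * D - beta1 * E
    sumlog = np.log(d).sum(axis=0)
    return det, beta1, rss, A, sumlog


def _reml_ll_perSNP(lam, s, a0, y, X, Xsq, n):
    det, _, rss, _, sumlog = _profile_perSNP(lam, s, a0, y, X, Xsq)
    with np.errstate(invalid="ignore", divide="ignore"):
        return -sumlog - np.log(det) - (n - 2) * np.log(np.maximum(rss, 1e-300))


def _null_reml(s, a0, y):
    """Profile REML of the covariate-only model; returns (lambda, s2_g, s2_e)."""
    n = len(y)

    def ll(lam):
        d = lam * s + 1.0
        w = 1.0 / d
        A = np.sum(w * a0 * a0)
        D = np.sum(w * a0 * y)
        F = np.sum(w * y * y)
        rss = F - D * D / A
        return -np.log(d).sum() - np.log(A) - (n - 1) * np.log(max(rss, 1e-300))

    vals = [ll(l) for l in _LAMBDA_GRID]
    k = int(np.argmax(vals))
    lo = _LAMBDA_GRID[max(0, k - 1)]
    hi = _LAMBDA_GRID[min(len(_LAMBDA_GRID) - 1, k + 1)]
    for _ in range(_GOLDEN_ITERS):
        m1 = hi - (hi - lo) * _INV_PHI
        m2 = lo + (hi - lo) * _INV_PHI
        if ll(m1) < ll(m2):
            lo = m1
        else:
            hi = m2
    lam = (lo + hi) / 2.0
    d = lam * s + 1.0
    w = 1.0 / d
    A = np.sum(w * a0 * a0)
    D = np.sum(w * a0 * y)
    F = np.sum(w * y * y)
    s2e = max(F - D * D / A, 1e-300) / (n - 1)
    return lam, lam * s2e, s2e


def lmm_assoc(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray,
    W: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP Wald tests under the exact mixed model.

    Parameters
    ----------
    y
        Phenotype vector (continuous, or 0/1 treated as quantitative).
    G
        Filtered genotype matrix; SNPs with missing calls are tested on the
        non-missing subset of samples.
    K
        Kinship matrix (n x n, positive semidefinite).
    W
        Fixed-effect covariates. Default: intercept only. Extra columns
        (e.g. principal components) are supported via a slower per-SNP path.

    Returns a GEMMA-like table (chrom, pos, snp_id, n_used, maf, beta, se,
    p_wald, lambda_reml) with the null-model variance components in
    ``DataFrame.attrs``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    if n != G.n_samples:
        raise ValueError("phenotype length does not match the genotype matrix")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if K.shape != (n, n):
        raise ValueError("kinship shape mismatch")

    s, U = np.linalg.eigh((K + K.T) / 2.0)
    s = np.clip(s, 0.0, None)

    yr = U.T @ y
    ones = U.T @ np.ones(n)

    if W is not None:
        W = np.atleast_2d(np.asarray(W, dtype=np.float64))
        if W.shape[0] != n:
            W = W.T
        if np.linalg.matrix_rank(W) < W.shape[1]:
            raise ValueError("covariate matrix W is singular")
        return _lmm_assoc_general(y, G, s, U, W)

    lam0, s2g, s2e = _null_reml(s, ones, yr)

    D = G.dosages
    has_missing = (D == MISSING).any(axis=0)
    X_all = D.astype(np.float64)

    maf = G.maf()
    beta = np.full(G.n_snps, np.nan)
    se = np.full(G.n_snps, np.nan)
    p_wald = np.full(G.n_snps, np.nan)
    lam_hat = np.full(G.n_snps, np.nan)
    n_used = np.where(has_missing, (D != MISSING).sum(axis=0), n)

    complete = np.nonzero(~has_missing)[0]
    if len(complete):
        X = np.ascontiguousarray(U.T @ X_all[:, complete])
        Xsq = X * X
        # Coarse grid: shared weights per lambda, vectorised across SNPs.
        ll_grid = np.empty((len(_LAMBDA_GRID), len(complete)))
        for gi, lam in enumerate(_LAMBDA_GRID):
            d = lam * s + 1.0
            w = 1.0 / d
            det, _, rss, _ = _profile(w, ones, yr, X, Xsq)
            with np.errstate(invalid="ignore", divide="ignore"):
                ll = (
                    -np.log(d).sum() - np.log(det) - (n - 2) * np.log(np.maximum(rss, 1e-300))
                )
            # monomorphic / degenerate SNPs: det <= 0 -> no likelihood
            ll_grid[gi] = np.where(np.isfinite(ll), ll, -np.inf)
        k = np.argmax(ll_grid, axis=0)
        lo = _LAMBDA_GRID[np.maximum(k - 1, 0)]
        hi = _LAMBDA_GRID[np.minimum(k + 1, len(_LAMBDA_GRID) - 1)]
        for _ in range(_GOLDEN_ITERS):
            m1 = hi - (hi - lo) * _INV_PHI
            m2 = lo + (hi - lo) * _INV_PHI
            f1 = _reml_ll_perSNP(m1, s, ones, yr, X, Xsq, n)
            f2 = _reml_ll_perSNP(m2, s, ones, yr, X, Xsq, n)
            takes = f1 < f2
            lo = np.where(takes, m1, lo)
            hi = np.where(takes, hi, m2)
        lam_c = (lo + hi) / 2.0
        det, b1, rss, A, _ = _profile_perSNP(lam_c, s, ones, yr, X, Xsq)
        s2e_hat = np.maximum(rss, 1e-300) / (n - 2)
        var_b = s2e_hat * A / det
        ok = (det > 0) & (var_b > 0)
        stat = np.where(ok, b1 * b1 / np.maximum(var_b, 1e-300), np.nan)
        beta[complete] = b1
        se[complete] = np.sqrt(np.maximum(var_b, 0))
        p_wald[complete] = np.where(ok, stats.chi2.sf(stat, df=1), np.nan)
        lam_hat[complete] = lam_c

    for j in np.nonzero(has_missing)[0]:
        obs = D[:, j] != MISSING
        if obs.sum() < 3:
            continue
        sub = _lmm_single(
            y[obs], D[obs, j].astype(np.float64), K[np.ix_(obs, obs)]
        )
        beta[j], se[j], p_wald[j], lam_hat[j] = sub

    out = pd.DataFrame(
        {
            "chrom": G.chrom,
            "pos": G.pos,
            "snp_id": G.snp_ids,
            "n_used": n_used,
            "maf": maf,
            "beta": beta,
            "se": se,
            "p_wald": np.clip(p_wald, np.nextafter(0, 1), 1.0),
            "lambda_reml": lam_hat,
        }
    )
    pve = s2g * float(s.mean()) / (s2g * float(s.mean()) + s2e)
    out.attrs["null_lambda"] = float(lam0)
    out.attrs["null_s2g"] = float(s2g)
    out.attrs["null_s2e"] = float(s2e)
    out.attrs["null_pve"] = float(pve)
    return out


def _lmm_single(y, x, K):
    """Exact LMM for one SNP on its non-missing sample subset."""
    n = len(y)
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    s = np.clip(s, 0.0, None)
    yr, ones, xr = U.T @ y, U.T @ np.ones(n), U.T @ x
    X = xr[:, None]
    Xsq = X * X

    def ll(lam):
        return float(
            _reml_ll_perSNP(np.array([lam]), s, ones, yr, X, Xsq, n)[0]
        )

    vals = [ll(l) for l in _LAMBDA_GRID]
    k = int(np.argmax(vals))
    lo, hi = _LAMBDA_GRID[max(0, k - 1)], _LAMBDA_GRID[min(len(_LAMBDA_GRID) - 1, k + 1)]
    for _ in range(_GOLDEN_ITERS):
        m1 = hi - (hi - lo) * _INV_PHI
        m2 = lo + (hi - lo) * _INV_PHI
        if ll(m1) < ll(m2):
            lo = m1
        else:
            hi = m2
    lam = (lo + hi) / 2.0
    det, b1, rss, A, _ = _profile_perSNP(np.array([lam]), s, ones, yr, X, Xsq)
    s2e = max(float(rss[0]), 1e-300) / (n - 2)
    var_b = s2e * float(A[0]) / float(det[0])
    if var_b <= 0:
        return np.nan, np.nan, np.nan, lam
    stat = float(b1[0]) ** 2 / var_b
    return float(b1[0]), float(np.sqrt(var_b)), float(stats.chi2.sf(stat, df=1)), lam


def _lmm_assoc_general(y, G, s, U, W):
    """Per-SNP loop supporting arbitrary covariates (GLS at profiled lambda)."""
    n = len(y)
    yr = U.T @ y
    Wr = U.T @ W
    c = W.shape[1] + 1
    D = G.dosages

    def reml_ll(lam, Xf):
        d = lam * s + 1.0
        w = 1.0 / d
        XtWX = (Xf * w[:, None]).T @ Xf
        XtWy = (Xf * w[:, None]).T @ yr
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return -np.inf, None, None
        beta = np.linalg.solve(XtWX, XtWy)
        rss = float(np.sum(w * yr * yr) - XtWy @ beta)
        ll = -np.log(d).sum() - logdet - (n - c) * np.log(max(rss, 1e-300))
        return ll, beta, (XtWX, rss)

    rows = []
    for j in range(G.n_snps):
        obs = D[:, j] != MISSING
        x = D[:, j].astype(np.float64)
        if not obs.all():
            K_full = (U * s) @ U.T
            b, e_, p, lam = _lmm_single(y[obs], x[obs], K_full[np.ix_(obs, obs)])
            rows.append((b, e_, p, lam))
            continue
        Xf = np.column_stack([Wr, U.T @ x])
        vals = [reml_ll(l, Xf)[0] for l in _LAMBDA_GRID]
        k = int(np.argmax(vals))
        lo, hi = _LAMBDA_GRID[max(0, k - 1)], _LAMBDA_GRID[min(len(_LAMBDA_GRID) - 1, k + 1)]
        for _ in range(_GOLDEN_ITERS):
            m1 = hi - (hi - lo) * _INV_PHI
            m2 = lo + (hi - lo) * _INV_PHI
            if reml_ll(m1, Xf)[0] < reml_ll(m2, Xf)[0]:
                lo = m1
            else:
                hi = m2
        lam = (lo + hi) / 2.0
        ll, beta, aux = reml_ll(lam, Xf)
        XtWX, rss = aux
        s2e = max(rss, 1e-300) / (n - c)
        cov = s2e * np.linalg.inv(XtWX)
        b, var_b = beta[-1], cov[-1, -1]
        if var_b <= 0:
            rows.append((np.nan, np.nan, np.nan, lam))
            continue
        stat = b * b / var_b
        rows.append((b, np.sqrt(var_b), float(stats.chi2.sf(stat, df=1)), lam))

    arr = np.array(rows, dtype=float)
    return pd.DataFrame(
        {
            "chrom": G.chrom,
            "pos": G.pos,
            "snp_id": G.snp_ids,
            "n_used": (D != MISSING).sum(axis=0),
            "maf": G.maf(),
            "beta": arr[:, 0],
            "se": arr[:, 1],
            "p_wald": np.clip(arr[:, 2], np.nextafter(0, 1), 1.0),
            "lambda_reml": arr[:, 3],
        }
    )


@dataclass
class QtlHit:
    """A cluster of significant SNPs merged by genomic proximity."""

    lead_snp: str
    chrom: int
    pos_lo: int
    pos_hi: int
    lead_p: float
    members: list[str]

    def to_dict(self) -> dict:
        return {
            "lead_snp": self.lead_snp,
            "chrom": int(self.chrom),
            "pos_lo": int(self.pos_lo),
            "pos_hi": int(self.pos_hi),
            "lead_p": float(f"{self.lead_p:.8g}"),
            "members": list(self.members),
        }


def significant_hits(
    assoc: pd.DataFrame, threshold: float = 1e-5, merge_kb: float = 100.0
) -> list[QtlHit]:
    """Group SNPs below ``threshold`` into QTLs by merging nearby hits.

    Hits on the same chromosome within ``merge_kb`` kilobases of the running
    cluster edge join the same QTL; the lead SNP is the minimum-p member.
    """
    if len(assoc) == 0:
        raise ValueError("empty association table")
    hits = assoc[assoc["p_wald"] < threshold].sort_values(["chrom", "pos"])
    if hits.empty:
        return []
    out: list[QtlHit] = []
    cur: list[tuple] = []
    gap = merge_kb * 1000.0

    def flush(rows):
        lead = min(rows, key=lambda r: r[3])
        return QtlHit(
            lead_snp=str(lead[2]),
            chrom=int(lead[0]),
            pos_lo=int(min(r[1] for r in rows)),
            pos_hi=int(max(r[1] for r in rows)),
            lead_p=float(lead[3]),
            members=[str(r[2]) for r in rows],
        )

    for row in hits[["chrom", "pos", "snp_id", "p_wald"]].itertuples(index=False):
        if cur and (row[0] != cur[-1][0] or row[1] - cur[-1][1] > gap):
            out.append(flush(cur))
            cur = []
        cur.append(tuple(row))
    out.append(flush(cur))
    return out


def genomic_lambda(p_values) -> float:
    """Genomic-control inflation factor of a set of 1-df Wald p-values."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
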