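"""Shared domain containers for the phenotyping / GWAS / selection pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing diploid genotype call ("./." in VCF).
#: Kept distinct end-to-end; missing calls are never imputed in the stored
#: matrix (association drops them per SNP, kinship mean-imputes on the fly).
MISSING: int = -9


@dataclass
class LeafImage:
    """A rendered leaf photograph with ground truth attached.

    ``pixels`` is H x W x 3 float in [0, 1]; ``leaf_mask`` marks leaf (not
    background) pixels; ``damage_fraction`` is removed leaf area divided by
    total leaf area. ``binary_label`` (damage > 25%) and ``severity_class``
    (1..5 in 20% steps) follow the labelling rules used for training.
    """

    pixels: np.ndarray
    leaf_mask: np.ndarray
    damage_fraction: float
    binary_label: int
    severity_class: int
    accession_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if float(self.pixels.min()) < 0.0 or float(self.pixels.max()) > 1.0:
            raise ValueError("pixels must lie in [0, 1]")


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (n_samples x n_snps) with a marker map.

    Dosages count alternate alleles: 0, 1, 2, or :data:`MISSING`. Positions
    are 1-based and strictly increasing within each chromosome.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    sample_ids: np.ndarray
    pop_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.pop_labels is not None:
            self.pop_labels = np.asarray(self.pop_labels)
        n, m = self.dosages.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        for arr, name in [
            (self.snp_ids, "snp_ids"),
            (self.chrom, "chrom"),
            (self.pos, "pos"),
            (self.ref, "ref"),
            (self.alt, "alt"),
        ]:
            if len(arr) != m:
                raise ValueError(f"{name} length {len(arr)} != n_snps {m}")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or the MISSING sentinel")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p.astype(np.int64)) > 0):
                raise ValueError(f"positions not strictly increasing on chrom {c}")

    @property
    def n_samples(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def n_snps(self) -> int:
        return int(self.dosages.shape[1])

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to the SNP columns ``idx`` (genomic order preserved by caller)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            sample_ids=self.sample_ids,
            pop_labels=self.pop_labels,
        )

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls."""
        d = self.dosages
        obs = d != MISSING
        cnt = np.where(obs, d, 0).sum(axis=0)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, cnt / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)


@dataclass
class SimCohortSpec:
    """Parameters of one simulated cohort (genotypes + phenotypes).

    Defaults emulate a structured germplasm panel: a few hundred accessions in
    three sub-populations with moderate divergence, blocky local LD, and an
    additive polygenic trait observed on a 0-5 scale plus a thresholded
    binary version of the same liability.
    """

    n_samples: int = 231
    n_snps: int = 5000
    n_pops: int = 3
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_len: int = 10
    ld_rho: float = 0.9
    missing_rate: float = 0.0
    n_qtl: int = 50
    h2: float = 0.6
    liability_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if self.fst < 0:
            raise ValueError("fst must be >= 0")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.ld_block_len < 1:
            raise ValueError("ld_block_len must be >= 1")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass
class PhenotypeTable:
    """Per-accession phenotypes: one row per accession."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"accession_id", "binary_pheno", "continuous_pheno"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        if self.frame["accession_id"].duplicated().any():
            raise ValueError("one row per accession required")
        cont = self.frame["continuous_pheno"].to_numpy(dtype=float)
        if np.nanmin(cont) < 0.0 or np.nanmax(cont) > 5.0:
            raise ValueError("continuous_pheno must lie in [0, 5]")

    @property
    def accession_ids(self) -> np.ndarray:
        return self.frame["accession_id"].to_numpy()

    @property
    def binary(self) -> np.ndarray:
        return self.frame["binary_pheno"].to_numpy(dtype=int)

    @property
    def continuous(self) -> np.ndarray:
        return self.frame["continuous_pheno"].to_numpy(dtype=float)


@dataclass
class OrderedTree:
    """A Newick tree plus its ladderised tip order (top-to-bottom)."""

    newick: str
    tip_order: list[str]

    def __post_init__(self) -> None:
        if len(set(self.tip_order)) != len(self.tip_order):
            raise ValueError("tip_order must not contain duplicates")
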