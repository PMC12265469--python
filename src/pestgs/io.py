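"""File I/O: minimal VCF 4.2, phenotype/score TSVs, Newick, leaf datasets.

All writers emit byte-stable output for a given input (fixed column order,
fixed float formatting, ``\n`` line endings) so that pipeline stages rerun
with the same seed produce identical files.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

import numpy as np
import pandas as pd

from pestgs.core import MISSING, GenotypeMatrix, LeafImage, PhenotypeTable

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a GT-only VCF 4.2 file (uncompressed text)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(int(x) for x in G.chrom)):
            max_pos = int(G.pos[G.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={max_pos + 1000}>\n")
        cols = "\t".join(str(s) for s in G.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j in range(G.n_snps):
            gts = "\t".join(_GT_CODE[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{int(G.chrom[j])}\t{int(G.pos[j])}\t{G.snp_ids[j]}\t"
                f"{G.ref[j]}\t{G.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF (GT field) into a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples)
    dos, sid, chrom, pos, ref, alt = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic subset only
        g = var.gt_types.astype(np.int16)  # 0,1,2 dose; 3 = unknown
        g[g == 3] = MISSING
        dos.append(g)
        sid.append(var.ID if var.ID not in (None, ".") else f"snp_{var.CHROM}_{var.POS}")
        chrom.append(int(str(var.CHROM).lstrip("chr") or 0))
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    vcf.close()
    return GenotypeMatrix(
        dosages=np.asarray(dos, dtype=np.int16).T,
        snp_ids=np.asarray(sid),
        chrom=np.asarray(chrom, dtype=np.int32),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref),
        alt=np.asarray(alt),
        sample_ids=samples,
    )


def write_phenotypes(pheno: PhenotypeTable, path: str | os.PathLike) -> None:
    df = pheno.frame.copy()
    cols = ["accession_id", "binary_pheno", "continuous_pheno"]
    if "true_genetic_value" in df.columns:
        cols.append("true_genetic_value")
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"accession_id": str})
    return PhenotypeTable(frame=df)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Deterministic TSV dump used for score tables, association results, etc."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_json(obj: dict, path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_leaf_dataset(
    leaves: Iterable[LeafImage], out_dir: str | os.PathLike, prefix: str = "leaf"
) -> pd.DataFrame:
    """Write leaves as PNGs plus the sidecar TSV; returns the sidecar frame."""
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, leaf in enumerate(leaves):
        name = f"{prefix}_{i:05d}.png"
        arr = np.clip(np.rint(leaf.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(os.path.join(out_dir, name))
        rows.append(
            {
                "image_path": name,
                "accession_id": leaf.accession_id,
                "damage_fraction": round(float(leaf.damage_fraction), 6),
                "binary_label": int(leaf.binary_label),
                "severity_class": int(leaf.severity_class),
            }
        )
    df = pd.DataFrame(rows)
    write_table(df, os.path.join(out_dir, "labels.tsv"))
    return df


def read_leaf_dataset(data_dir: str | os.PathLike) -> tuple[np.ndarray, pd.DataFrame]:
    """Load a PNG folder + ``labels.tsv`` sidecar into an image stack."""
    from PIL import Image

    df = pd.read_csv(os.path.join(data_dir, "labels.tsv"), sep="\t")
    imgs = []
    for name in df["image_path"]:
        with Image.open(os.path.join(data_dir, name)) as im:
            imgs.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
    return np.stack(imgs), df


def write_newick(newick: str, path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(newick.rstrip("\n") + "\n")
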