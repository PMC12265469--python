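"""Aggregate per-image network scores into per-accession phenotypes.

Each accession is photographed several times; the binary phenotype is the
thresholded mean severe-probability over its images, and the continuous
phenotype is the arithmetic mean of its per-image damage scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pestgs.core import PhenotypeTable


def aggregate_binary(probs) -> int:
    """0 (mild) iff the mean severe-probability is below 0.5, else 1.

    A mean of exactly 0.5 maps to severe: the labelling rule assigns mild
    only strictly below 0.5, so the boundary goes to 1.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("need at least one per-image probability")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return 0 if float(probs.mean()) < 0.5 else 1


def aggregate_continuous(scores) -> float:
    """Arithmetic mean of per-image damage scores (each in [0, 5])."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one per-image score")
    if scores.min() < 0 or scores.max() > 5:
        raise ValueError("scores must lie in [0, 5]")
    return float(scores.mean())


def aggregate_scores(
    binary_table: pd.DataFrame | None, pds_table: pd.DataFrame
) -> PhenotypeTable:
    """Collapse per-image score tables to one phenotype row per accession.

    ``pds_table`` needs columns (accession_id, pds_score); ``binary_table``
    needs (accession_id, prob_severe) and may be None, in which case the
    binary phenotype falls back to thresholding the mean damage score at
    half the scale (2.5).
    """
    cont = (
        pds_table.groupby("accession_id", sort=True)["pds_score"]
        .apply(lambda s: aggregate_continuous(s.to_numpy()))
        .rename("continuous_pheno")
    )
    if binary_table is not None:
        binary = (
            binary_table.groupby("accession_id", sort=True)["prob_severe"]
            .apply(lambda s: aggregate_binary(s.to_numpy()))
            .rename("binary_pheno")
        )
    else:
        binary = (cont >= 2.5).astype(int).rename("binary_pheno")
    frame = pd.concat([binary, cont], axis=1).dropna().reset_index()
    return PhenotypeTable(frame=frame[["accession_id", "binary_pheno", "continuous_pheno"]])


@dataclass
class GroupStats:
    """Distribution statistics of the continuous phenotype across groups."""

    summary: pd.DataFrame  # per group: n, mean, median, shapiro_p
    bartlett_p: float
    pairwise_wilcoxon_p: pd.DataFrame  # symmetric matrix of rank-sum p-values
    flags: list[str]


def group_stats(values, groups) -> GroupStats:
    """Shapiro-Wilk per group, Bartlett across groups, pairwise rank-sum tests.

    All tests are the stock implementations; groups with fewer than 3
    observations are flagged and skipped rather than failing the whole call.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    flags: list[str] = []
    rows = []
    usable: dict = {}
    for g in labels:
        x = values[groups == g]
        if len(x) < 3:
            flags.append(f"group {g!r} has n={len(x)} < 3; tests skipped")
            shapiro_p = np.nan
        else:
            shapiro_p = float(stats.shapiro(x).pvalue)
            usable[g] = x
        rows.append(
            {
                "group": g,
                "n": int(len(x)),
                "mean": float(x.mean()) if len(x) else np.nan,
                "median": float(np.median(x)) if len(x) else np.nan,
                "shapiro_p": shapiro_p,
            }
        )
    bartlett_p = (
        float(stats.bartlett(*usable.values()).pvalue) if len(usable) >= 2 else np.nan
    )
    keys = list(usable)
    pw = pd.DataFrame(np.ones((len(keys), len(keys))), index=keys, columns=keys)
    for i, gi in enumerate(keys):
        for j in range(i + 1, len(keys)):
            gj = keys[j]
            p = float(stats.ranksums(usable[gi], usable[gj]).pvalue)
            pw.iloc[i, j] = pw.iloc[j, i] = p
    return GroupStats(
        summary=pd.DataFrame(rows),
        bartlett_p=bartlett_p,
        pairwise_wilcoxon_p=pw,
        flags=flags,
    )
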