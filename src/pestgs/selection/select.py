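"""P-value-ranked stepwise marker selection and the marker-count grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MarkerGrid:
    """Ordered marker counts to sweep for one trait type.

    ``significant_placeholder`` marks the grid entry that stands for "all
    significant SNPs" in the reference protocol; on a new cohort it is
    replaced by the cohort's actual significant-hit count.
    """

    trait_type: str
    counts: list[int] = field(default_factory=list)
    include_all: bool = True
    significant_placeholder: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError("trait_type must be 'binary' or 'continuous'")
        if any(b <= a for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be strictly increasing")


def default_grids() -> tuple[MarkerGrid, MarkerGrid]:
    """The reference marker-count grids for binary and continuous traits."""
    binary = MarkerGrid(
        trait_type="binary",
        counts=[1, 10, 50, 100, 500, 2000, 5000],
        include_all=True,
        significant_placeholder=50,
    )
    continuous = MarkerGrid(
        trait_type="continuous",
        counts=[10, 52, 100, 500, 2000, 5000, 10000],
        include_all=True,
        significant_placeholder=52,
    )
    return binary, continuous


def resolve_grid(grid: MarkerGrid, n_markers: int, n_significant: int | None = None) -> list[int]:
    """Concrete counts for a cohort: substitute the all-significant entry,
    drop counts beyond the available markers, and append the ALL entry."""
    counts = list(grid.counts)
    if grid.significant_placeholder is not None and n_significant:
        counts = [n_significant if c == grid.significant_placeholder else c for c in counts]
    counts = sorted({c for c in counts if 0 < c <= n_markers})
    if grid.include_all and n_markers not in counts:
        counts.append(n_markers)
    return counts


def rank_and_select(assoc: pd.DataFrame, pruned_idx, k: int) -> np.ndarray:
    """Top-k pruned markers by ascending Wald p; ties broken by (chrom, pos).

    ``assoc`` rows must align with the genotype columns that ``pruned_idx``
    indexes. Returns genotype column indices, best first.
    """
    pruned_idx = np.asarray(pruned_idx)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(pruned_idx):
        raise ValueError("k exceeds the number of pruned markers")
    sub = assoc.iloc[pruned_idx][["p_wald", "chrom", "pos"]].copy()
    sub["col"] = pruned_idx
    sub = sub.sort_values(["p_wald", "chrom", "pos"], kind="mergesort")
    return sub["col"].to_numpy()[:k]
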