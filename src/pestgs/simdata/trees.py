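"""Ladder trees whose tip order tracks the phenotype with tunable strength."""

from __future__ import annotations

import numpy as np

from pestgs.core import OrderedTree, PhenotypeTable


def phenotype_order(pheno: PhenotypeTable) -> list[str]:
    """Accessions sorted by continuous phenotype; ties broken by accession id."""
    df = pheno.frame.sort_values(
        ["continuous_pheno", "accession_id"], kind="mergesort"
    )
    return list(df["accession_id"])


def _ladder_newick(tips: list[str]) -> str:
    """Caterpillar topology whose top-to-bottom tip order equals ``tips``."""
    node = f"{tips[-1]}:1"
    for t in reversed(tips[:-1]):
        node = f"({t}:1,{node}:1)"
    return node + ";"


def simulate_ordered_tree(
    pheno: PhenotypeTable, signal: float, seed: int = 0
) -> OrderedTree:
    """Build a ladder tree whose tip order correlates with phenotype rank.

    ``signal`` interpolates between a uniform random permutation (0) and the
    exact phenotype rank order (1) by partial shuffling: each tip is marked
    for shuffling with probability ``1 - signal`` and the marked tips are
    randomly permuted among their own positions.
    """
    if not 0.0 <= signal <= 1.0:
        raise ValueError("signal must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 311]))
    order = np.asarray(phenotype_order(pheno), dtype=object)
    n = len(order)
    marked = rng.random(n) < (1.0 - signal)
    idx = np.nonzero(marked)[0]
    order[idx] = order[rng.permutation(idx)]
    tips = [str(t) for t in order]
    return OrderedTree(newick=_ladder_newick(tips), tip_order=tips)
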