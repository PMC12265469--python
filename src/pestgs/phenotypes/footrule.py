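"""Spearman's footrule between a tree's tip order and the phenotype order.

The footrule distance between two rankings of the same n elements is the sum
of absolute position differences; it ranges from 0 (identical orders) to
floor(n^2 / 2) (reversal). Under a uniformly random permutation its mean is
(n^2 - 1) / 3. The association test compares the observed distance against
footrule distances from randomly drawn orders with a one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class FootruleResult:
    """Observed footrule statistics plus two complementary p-values.

    ``p_value`` is the one-sample two-sided t-test of the random-order null
    sample against the observed distance — the protocol statistic. Note its
    null behaviour: it tests whether the observed distance equals the null
    *mean*, so under no association it still rejects most of the time (the
    t denominator shrinks with n_perm while the observed value keeps the
    full null spread). ``empirical_p`` is the one-sided permutation p-value
    P(null <= observed), which is uniform under no association and small
    when the orders agree more than chance.
    """

    observed_distance: int
    observed_correlation: float
    null_mean: float
    null_sd: float
    n_perm: int
    t_stat: float
    p_value: float
    empirical_p: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_distance": int(self.observed_distance),
            "observed_correlation": round(float(self.observed_correlation), 8),
            "null_mean": round(float(self.null_mean), 8),
            "null_sd": round(float(self.null_sd), 8),
            "n_perm": int(self.n_perm),
            "t_stat": round(float(self.t_stat), 8),
            "p_value": float(f"{self.p_value:.8g}"),
            "empirical_p": float(f"{self.empirical_p:.8g}"),
            "seed": int(self.seed),
        }


def _positions(order) -> dict:
    order = list(order)
    if len(set(order)) != len(order):
        raise ValueError("order contains duplicate elements")
    return {e: i for i, e in enumerate(order)}


def footrule_distance(order_a, order_b) -> int:
    """Sum over elements of |position in A - position in B|."""
    pos_a = _positions(order_a)
    pos_b = _positions(order_b)
    if set(pos_a) != set(pos_b):
        raise ValueError("orders must rank the same element set")
    return int(sum(abs(pos_a[e] - pos_b[e]) for e in pos_a))


def expected_null_distance(n: int) -> float:
    """Mean footrule distance between a fixed order and a uniform permutation."""
    return (n * n - 1) / 3.0


def footrule_permutation_test(
    tree_order, pheno_order, n_perm: int = 1000, seed: int = 0
) -> FootruleResult:
    """Test whether the tree's ladder order tracks the phenotype order.

    The null sample holds footrule distances between ``tree_order`` and
    ``n_perm`` uniformly random orders of the same elements; the one-sample
    two-sided t-test compares that sample against the observed distance.
    Also reports the Spearman correlation between the two observed orders.
    """
    tree_order = list(tree_order)
    pheno_order = list(pheno_order)
    n = len(tree_order)
    if n < 3:
        raise ValueError("need at least 3 elements")
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    observed = footrule_distance(tree_order, pheno_order)

    pos_t = np.array([_positions(tree_order)[e] for e in pheno_order])
    rho = float(stats.spearmanr(pos_t, np.arange(n)).statistic)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 433]))
    base = np.arange(n)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        null[i] = int(np.abs(base - rng.permutation(n)).sum())
    t_stat, p_value = stats.ttest_1samp(null, popmean=observed)
    empirical_p = (1.0 + np.sum(null <= observed)) / (n_perm + 1.0)
    return FootruleResult(
        observed_distance=observed,
        observed_correlation=rho,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        n_perm=int(n_perm),
        t_stat=float(t_stat),
        p_value=float(p_value),
        empirical_p=float(empirical_p),
        seed=int(seed),
    )
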