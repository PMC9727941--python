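"""Closed-form expectations for sample-centered correlation estimators.

These calculators give the exact expectation of scGRM-type quantities as
a function of the *true* pairwise genotype correlation structure, under
known per-SNP variances.  They serve both as user-facing bias predictors
and as oracles for the Monte-Carlo tests: centering by the observed mean
couples every pair's estimate to the whole cohort, producing a
deterministic negative shift whose sum over pairs is
``(n - 1)(rho_bar - 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CorrelationStructure",
    "expected_scgrm_pair",
    "expected_pair_sum",
    "expected_family_average_kinship",
]


@dataclass
class CorrelationStructure:
    """True pairwise genotype correlations ``rho = 2 phi`` (diagonal 1)."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.rho.shape[0]
        if self.rho.shape != (n, n):
            raise ValueError("rho must be square")
        if not np.allclose(self.rho, self.rho.T):
            raise ValueError("rho must be symmetric")
        np.fill_diagonal(self.rho, 1.0)

    @property
    def n(self) -> int:
        return self.rho.shape[0]

    @property
    def rho_bar(self) -> float:
        """Average off-diagonal correlation (in [0, 1] for valid cohorts)."""
        n = self.n
        off = self.rho.sum() - np.trace(self.rho)
        return float(off / (n * (n - 1)))


def expected_scgrm_pair(structure: CorrelationStructure, i: int,
                        i2: int) -> float:
    """Expected per-SNP centered cross-product for pair ``(i, i2)``.

    On the correlation scale, assuming known variances::

        rho_ii' - (1/n) sum_{a != i} rho_ia - (1/n) sum_{a != i'} rho_ai'
        - 1/n + ((n - 1)/n) rho_bar
    """
    if i == i2:
        raise ValueError("expectation is defined for pairs (i != i')")
    rho = structure.rho
    n = structure.n
    row_i = rho[i].sum() - rho[i, i]
    row_i2 = rho[i2].sum() - rho[i2, i2]
    return float(rho[i, i2] - row_i / n - row_i2 / n - 1.0 / n
                 + (n - 1) / n * structure.rho_bar)


def expected_pair_sum(n: int, rho_bar: float) -> float:
    """Expected sum of the centered cross-products over all pairs.

    ``(n - 1)(rho_bar - 1) / 2``: non-positive whenever ``rho_bar <= 1``,
    which forces a negative average estimate in any cohort that is not
    perfectly correlated.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 <= rho_bar <= 1.0:
        raise ValueError("rho_bar must lie in [0, 1]")
    return (n - 1) * (rho_bar - 1) / 2.0


def expected_family_average_kinship(n: int, rho_bar: float) -> float:
    """Expected all-pairs mean scGRM *kinship* in a cohort of size ``n``.

    ``(rho_bar - 1) / (2 n)``: the pair-sum expectation divided by the
    number of pairs, halved to move from the correlation to the kinship
    scale.  For one family of 500 full sibs (``rho_bar = 0.5``) this is
    -5e-4 even though every true kinship is 0.25.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    return (rho_bar - 1.0) / (2.0 * n)
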