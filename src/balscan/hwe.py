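"""Heterozygote-excess exact test and the genotype QC filter.

Genotyping artifacts (e.g. collapsed paralogs) inflate heterozygote counts;
sites with a significant excess of heterozygotes are removed before a scan.
The test conditions on the allele-count margins: given ``N`` diploid
individuals with ``n_A`` copies of one allele, the number of heterozygotes
under Hardy–Weinberg equilibrium follows the exact conditional (Levene)
distribution

    P(n_Aa = h) ∝ 2**h / ( ((n_A - h)/2)! * h! * ((n_a - h)/2)! ),

over ``h`` with the parity of ``n_A``.  The one-tailed P-value sums the
upper tail ``h >= observed``; an alternative 2x2 Fisher construction on the
allele-pairing table is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import fisher_exact

__all__ = ["GenotypeTable", "hwe_excess_het_test", "filter_sites", "FilterLog"]


@dataclass(frozen=True)
class GenotypeTable:
    """Diploid genotype counts at one site."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self):
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be nonnegative")
        if self.n_AA + self.n_Aa + self.n_aa < 1:
            raise ValueError("at least one individual required")


def _levene_log_weights(n_A: int, n_a: int) -> Tuple[np.ndarray, np.ndarray]:
    """Support and unnormalized log-probabilities of the heterozygote count."""
    h_max = min(n_A, n_a)
    hs = np.arange(n_A % 2, h_max + 1, 2)
    logw = (
        hs * np.log(2.0)
        - gammaln((n_A - hs) / 2 + 1)
        - gammaln(hs + 1.0)
        - gammaln((n_a - hs) / 2 + 1)
    )
    return hs, logw


def hwe_excess_het_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "conditional") -> float:
    """One-tailed P-value for heterozygote excess under Hardy–Weinberg.

    ``method="conditional"`` (default) uses the exact conditional
    distribution of the heterozygote count given the allele-count margins;
    ``method="fisher2x2"`` runs Fisher's exact test on the 2x2
    allele-pairing table ``[[2*n_AA, n_Aa], [n_Aa, 2*n_aa]]`` (an
    approximate alternative construction).  Monomorphic sites return 1.
    """
    tab = GenotypeTable(n_AA, n_Aa, n_aa)
    n_A = 2 * tab.n_AA + tab.n_Aa
    n_a = 2 * tab.n_aa + tab.n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    if method == "conditional":
        hs, logw = _levene_log_weights(n_A, n_a)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        return float(w[hs >= tab.n_Aa].sum())
    if method == "fisher2x2":
        _, p = fisher_exact(
            [[2 * tab.n_AA, tab.n_Aa], [tab.n_Aa, 2 * tab.n_aa]], alternative="less"
        )
        return float(p)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class FilterLog:
    n_retained: int = 0
    n_removed: int = 0
    removed: List[Tuple[int, float]] = None  # (phys_pos, P) of removed sites

    def __post_init__(self):
        if self.removed is None:
            self.removed = []


def filter_sites(
    tables: Iterable[Tuple[int, int, int, int]],
    threshold: float,
    method: str = "conditional",
) -> Tuple[Iterator[Tuple[int, int, int, int]], FilterLog]:
    """Remove sites with significant heterozygote excess (``P < threshold``).

    ``tables`` yields ``(phys_pos, n_AA, n_Aa, n_aa)`` rows.  Returns the
    retained rows (as a list) and a log of removal counts.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    log = FilterLog()
    retained = []
    for pos, n_AA, n_Aa, n_aa in tables:
        p = hwe_excess_het_test(n_AA, n_Aa, n_aa, method=method)
        if p < threshold:
            log.n_removed += 1
            log.removed.append((pos, p))
        else:
            log.n_retained += 1
            retained.append((pos, n_AA, n_Aa, n_aa))
    return retained, log
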