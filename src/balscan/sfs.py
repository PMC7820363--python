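"""Genome-wide background site frequency spectra and their normalized forms.

The scan's null hypothesis is that allele counts at informative sites follow
the genome-wide site frequency spectrum (SFS).  This module aggregates raw
per-site counts into a :class:`BackgroundSFS` (``xi_n(k)`` for derived
polarity, ``eta_n(k)`` for minor polarity, stratified by sample size ``n``)
and normalizes it into the null distribution ``g_n(k)`` appropriate for each
model variant:

``"2"``
    derived counts including substitutions, support ``k = 1..n``;
``"0"``
    derived polymorphisms only, support ``k = 1..n-1``;
``"1"``
    polymorphism/substitution dichotomy (no frequency information);
``"2MAF"``
    minor counts including substitutions (``k = 0``), support ``k = 0..n//2``;
``"0MAF"``
    minor polymorphisms only, support ``k = 1..n//2``.

Because the background conditions on the exact sample size, every ``n``
observed at scan time must have its own stratum here; there is no projection
across sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np

from .sites import SiteRecord, validate_k

__all__ = [
    "VARIANTS",
    "variant_polarity",
    "variant_support",
    "BackgroundSFS",
    "NeutralSpectrum",
    "build_background",
    "normalize_background",
    "fold_background",
    "expected_neutral_background",
]

VARIANTS = ("2", "2MAF", "1", "0", "0MAF")

_POLARITY = {"2": "derived", "1": "derived", "0": "derived", "2MAF": "minor", "0MAF": "minor"}


def variant_polarity(variant: str) -> str:
    """Input polarity required by a model variant."""
    try:
        return _POLARITY[variant]
    except KeyError:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}") from None


def variant_support(variant: str, n: int) -> np.ndarray:
    """Allele counts ``k`` in the support of a variant at sample size ``n``.

    Variant ``"1"`` is dichotomous; its two categories are indexed 0
    (polymorphic) and 1 (substitution) and represented here as ``[-1, n]``
    with ``-1`` a stand-in for "any polymorphic count".
    """
    if variant == "2":
        return np.arange(1, n + 1)
    if variant == "0":
        return np.arange(1, n)
    if variant == "2MAF":
        return np.arange(0, n // 2 + 1)
    if variant == "0MAF":
        return np.arange(1, n // 2 + 1)
    if variant == "1":
        return np.array([-1, n])
    raise ValueError(f"unknown model variant {variant!r}")


def variant_index(variant: str, n: int, k) -> np.ndarray:
    """Map allele counts to indices into the variant's probability table."""
    k = np.asarray(k)
    if variant == "2":
        return k - 1
    if variant == "0":
        return k - 1
    if variant == "2MAF":
        return k
    if variant == "0MAF":
        return k - 1
    if variant == "1":
        return (k == n).astype(int)
    raise ValueError(f"unknown model variant {variant!r}")


@dataclass
class BackgroundSFS:
    """Raw genome-wide counts of informative sites, stratified by sample size.

    ``counts[(n, k)]`` is the number of informative sites with allele count
    ``k`` out of ``n`` sampled alleles, genome-wide.
    """

    polarity: str
    counts: Dict[Tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        if self.polarity not in ("derived", "minor"):
            raise ValueError(f"polarity must be 'derived' or 'minor', got {self.polarity!r}")
        for (n, k), c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for (n={n}, k={k})")
            validate_k(k, n, self.polarity)

    @property
    def sample_sizes(self) -> Tuple[int, ...]:
        return tuple(sorted({n for n, _ in self.counts}))

    def total(self, n: int | None = None) -> int:
        if n is None:
            return sum(self.counts.values())
        return sum(c for (m, _), c in self.counts.items() if m == n)

    def stratum(self, n: int) -> Dict[int, int]:
        return {k: c for (m, k), c in self.counts.items() if m == n}


class NeutralSpectrum:
    """Normalized null distribution ``g_n(k)`` for one model variant.

    Holds one probability vector per sample-size stratum, indexed over the
    variant's support, plus the per-stratum raw totals (used to weight sample
    sizes when drawing synthetic neutral data).
    """

    def __init__(self, variant: str, tables: Dict[int, np.ndarray], n_weights: Dict[int, float] | None = None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}")
        self.variant = variant
        self._tables = {int(n): np.asarray(t, dtype=float) for n, t in tables.items()}
        for n, t in self._tables.items():
            if len(t) != len(variant_support(variant, n)):
                raise ValueError(f"table length mismatch for n={n}")
            if abs(t.sum() - 1.0) > 1e-12:
                raise ValueError(f"probabilities for n={n} sum to {t.sum()!r}, not 1")
        self.n_weights = dict(n_weights) if n_weights else {n: 1.0 for n in self._tables}

    @property
    def sample_sizes(self) -> Tuple[int, ...]:
        return tuple(sorted(self._tables))

    def has_stratum(self, n: int) -> bool:
        return int(n) in self._tables

    def table(self, n: int) -> np.ndarray:
        try:
            return self._tables[int(n)]
        except KeyError:
            raise KeyError(
                f"no background stratum for sample size n={n}; "
                "build the background from the dataset being scanned"
            ) from None

    def prob(self, n: int, k) -> np.ndarray | float:
        """``g_n(k)``, vectorized over ``k``."""
        t = self.table(n)
        idx = variant_index(self.variant, n, k)
        return t[idx]


def build_background(sites: Iterable[SiteRecord], polarity: str) -> BackgroundSFS:
    """Tally informative sites into per-(n, k) genome-wide counts.

    Records whose allele count lies outside the stated polarity's support are
    rejected with the offending position in the message.
    """
    counts: Dict[Tuple[int, int], int] = {}
    n_records = 0
    for rec in sites:
        try:
            validate_k(rec.k, rec.n, polarity)
        except ValueError as exc:
            raise ValueError(f"site at physPos {rec.phys_pos}: {exc}") from exc
        key = (rec.n, rec.k)
        counts[key] = counts.get(key, 0) + 1
        n_records += 1
    if n_records == 0:
        raise ValueError("no informative sites")
    return BackgroundSFS(polarity=polarity, counts=counts)


def normalize_background(bg: BackgroundSFS, variant: str) -> NeutralSpectrum:
    """Normalize raw counts into the null distribution for one variant.

    Poly-only variants ("0", "0MAF") exclude the substitution category from
    the normalization denominator; variant "1" dichotomizes counts into
    substitution versus polymorphic.
    """
    need = variant_polarity(variant)
    if bg.polarity != need:
        raise ValueError(
            f"variant {variant!r} requires {need} polarity background, got {bg.polarity}"
        )
    tables: Dict[int, np.ndarray] = {}
    weights: Dict[int, float] = {}
    for n in bg.sample_sizes:
        stratum = bg.stratum(n)
        if variant == "1":
            total = sum(stratum.values())
            sub = stratum.get(n, 0)
            t = np.array([(total - sub) / total, sub / total])
        else:
            support = variant_support(variant, n)
            raw = np.array([stratum.get(int(k), 0) for k in support], dtype=float)
            total = raw.sum()
            if total == 0:
                raise ValueError(
                    f"variant {variant!r}: no sites in support for sample size n={n} "
                    "(all sites in this stratum are substitutions?)"
                )
            t = raw / total
        tables[n] = t
        weights[n] = float(total)
    return NeutralSpectrum(variant, tables, n_weights=weights)


def fold_background(bg: BackgroundSFS) -> BackgroundSFS:
    """Fold a derived-polarity background into minor polarity.

    ``eta_n(min(k, n-k))`` accumulates ``xi_n(k)``; substitutions
    (``k == n``) land in ``eta_n(0)``.
    """
    if bg.polarity != "derived":
        raise ValueError("fold_background requires a derived-polarity background")
    counts: Dict[Tuple[int, int], int] = {}
    for (n, k), c in bg.counts.items():
        kk = min(k, n - k)
        counts[(n, kk)] = counts.get((n, kk), 0) + c
    return BackgroundSFS(polarity="minor", counts=counts)


def expected_neutral_background(
    n: int,
    *,
    theta_sites: float = 1000.0,
    substitution_ratio: float = 2.8,
    seed: int | None = None,
) -> BackgroundSFS:
    """Construct a neutral derived-polarity background with standard-neutral shape.

    Under the standard neutral coalescent the expected unfolded SFS is
    ``E[xi_n(k)] ∝ theta / k`` for ``k = 1..n-1``; substitutions against the
    outgroup contribute an additional mass at ``k = n`` set by the divergence
    time.  Defaults emulate a human-like dataset (per-site ``theta ≈ 1e-3``
    and ~5 Myr of divergence give roughly 2.8 substitutions per segregating
    site).

    ``theta_sites`` scales the expected number of polymorphic sites per
    frequency class (``xi_n(k) = theta_sites / k``).  With ``seed`` given,
    counts are drawn Poisson around the expectation instead of being rounded.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    ks = np.arange(1, n)
    expect = theta_sites / ks
    poly_total = expect.sum()
    sub_expect = substitution_ratio * poly_total
    mean = np.append(expect, sub_expect)
    if seed is None:
        raw = np.rint(mean).astype(int)
    else:
        raw = np.random.default_rng(seed).poisson(mean)
    counts = {(n, int(k)): int(c) for k, c in zip(np.arange(1, n + 1), raw) if c > 0}
    return BackgroundSFS(polarity="derived", counts=counts)
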