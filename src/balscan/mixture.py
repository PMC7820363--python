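"""Closed-form components of the balancing-selection mixture model.

A site ``d`` cM from a balanced locus is treated as completely linked to one
of the balanced allelic classes with probability ``alpha_A(d) = exp(-A d)``
(``A > 0`` per cM sets the footprint size), in which case its allele count is
binomial around the class's equilibrium frequency; otherwise it follows the
genome-wide background.  The per-site probability is the two-component
mixture

    f(k, d) = alpha_A(d) * h(k) + (1 - alpha_A(d)) * g(k),

where ``h`` is the balanced component (variant-specific truncation/folding of
the binomial, averaged over allelic classes) and ``g`` the normalized
background spectrum.

For ``m`` balanced allelic classes with frequencies ``x_1..x_m`` on the
simplex, each class's binomial is normalized/folded over the variant support
first and the per-class components are then averaged with uniform weight
``1/m``; with ``m = 2`` and classes ``(x, 1-x)`` this reproduces the
biallelic composition ``(h_x + h_{1-x}) / 2`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple, Union

import numpy as np
from scipy.special import gammaln

from .sfs import NeutralSpectrum, variant_index, variant_polarity, variant_support

__all__ = [
    "linkage_weight",
    "inclusion_radius",
    "BalancedComponent",
    "MixtureParams",
    "balanced_component",
    "site_probability",
]


def linkage_weight(A: float, d) -> Union[float, np.ndarray]:
    """Mixing weight ``alpha_A(d) = exp(-A d)``: probability of complete linkage.

    ``A`` is the exponential decay rate per centimorgan, ``d`` the distance in
    centimorgans.  Strictly decreasing in both; ``alpha(0) = 1``.
    """
    if A <= 0:
        raise ValueError(f"decay parameter A must be > 0, got {A}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance d must be >= 0")
    out = np.exp(-A * d)
    return float(out) if out.ndim == 0 else out


def inclusion_radius(A: float, alpha_cutoff: float) -> float:
    """Distance (cM) at which the mixing weight falls to ``alpha_cutoff``.

    Sites beyond this radius contribute (numerically) identical terms to the
    null and alternative composite likelihoods and can be skipped.
    """
    if not 0 < alpha_cutoff < 1:
        raise ValueError("alpha_cutoff must be in (0, 1)")
    return math.log(1.0 / alpha_cutoff) / A


def _binom_pmf(n: int, x: float) -> np.ndarray:
    """Binomial pmf over ``k = 0..n``, computed in log space for stability."""
    k = np.arange(n + 1)
    logp = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * math.log(x)
        + (n - k) * math.log1p(-x)
    )
    return np.exp(logp)


def _fold(pmf: np.ndarray, n: int) -> np.ndarray:
    """Fold a pmf over 0..n onto minor counts 0..n//2 (no double count at n/2)."""
    half = n // 2
    out = pmf[: half + 1].copy()
    for k in range(half + 1):
        if k != n - k:
            out[k] += pmf[n - k]
    return out


@lru_cache(maxsize=100_000)
def _class_table(variant: str, n: int, x: float) -> np.ndarray:
    """Normalized balanced component for a single allelic class at frequency x."""
    if not 0.0 < x < 1.0:
        raise ValueError(f"class frequency x={x} outside (0, 1)")
    pmf = _binom_pmf(n, x)
    if variant == "2":
        t = pmf[1:] / (1.0 - pmf[0])
    elif variant == "0":
        denom = 1.0 - pmf[0] - pmf[n]
        if denom <= 0:
            raise ValueError(f"degenerate polymorphic mass for n={n}, x={x}")
        t = pmf[1:n] / denom
    elif variant == "2MAF":
        # the folded numerator already sums to 1 over minor counts
        t = _fold(pmf, n)
    elif variant == "0MAF":
        # numerator Bin(k) + Bin(n-k)*1{k != n/2} over k = 1..n//2 sums to
        # sum_{j=1..n-1} Bin(j), which is exactly the printed denominator
        denom = 1.0 - pmf[0] - pmf[n]
        if denom <= 0:
            raise ValueError(f"degenerate polymorphic mass for n={n}, x={x}")
        t = _fold(pmf, n)[1:] / denom
    elif variant == "1":
        p_sub = pmf[n] / (1.0 - pmf[0])
        t = np.array([1.0 - p_sub, p_sub])
    else:
        raise ValueError(f"unknown model variant {variant!r}")
    t.setflags(write=False)
    return t


@dataclass(frozen=True)
class BalancedComponent:
    """Balanced mixture component ``h`` for one (variant, n, class set)."""

    variant: str
    n: int
    x: Union[float, Tuple[float, ...]]
    probs: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return variant_support(self.variant, self.n)

    def prob(self, k) -> Union[float, np.ndarray]:
        idx = variant_index(self.variant, self.n, k)
        out = self.probs[idx]
        return float(out) if np.ndim(out) == 0 else out


def _canonical_classes(x, m: int) -> Tuple[float, ...]:
    """Validate and canonicalize the equilibrium-frequency parameter.

    A scalar ``x`` denotes the biallelic model (classes ``x`` and ``1-x``),
    canonicalized to ``(0, 0.5]``.  A sequence denotes ``m`` explicit class
    frequencies on the open simplex, canonicalized in nondecreasing order
    (class labels are exchangeable).
    """
    if np.ndim(x) == 0:
        x = float(x)
        if not 0.0 < x < 1.0:
            raise ValueError(f"equilibrium frequency x={x} outside (0, 1)")
        if m != 2:
            raise ValueError("scalar x implies m=2 balanced classes")
        x = min(x, 1.0 - x)
        return (x, 1.0 - x)
    xs = tuple(sorted(float(v) for v in np.asarray(x, dtype=float)))
    if len(xs) != m:
        raise ValueError(f"expected {m} class frequencies, got {len(xs)}")
    if any(not 0.0 < v < 1.0 for v in xs):
        raise ValueError("class frequencies must lie in (0, 1)")
    if abs(sum(xs) - 1.0) > 1e-9:
        raise ValueError(f"class frequencies must sum to 1, got {sum(xs)}")
    return xs


def balanced_component(n: int, x, variant: str = "2", m: int = 2) -> BalancedComponent:
    """Balanced allele-frequency component ``h`` over the variant support.

    Parameters
    ----------
    n : int
        Haploid sample size (>= 2).
    x : float or sequence of float
        Scalar equilibrium frequency (biallelic) or ``m`` class frequencies
        summing to 1 (multiallelic).
    variant : str
        Model variant, one of ``{"2", "2MAF", "1", "0", "0MAF"}``.
    m : int
        Number of balanced allelic classes; must match a vector ``x``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    scalar = np.ndim(x) == 0
    classes = _canonical_classes(x, m)
    if scalar:
        # biallelic composition as printed: average the per-class normalized
        # components for the derived and ancestral haplotype classes
        xa, xb = classes
        if variant_polarity(variant) == "minor":
            probs = _class_table(variant, n, xa).copy()
        else:
            probs = 0.5 * _class_table(variant, n, xa) + 0.5 * _class_table(variant, n, xb)
        x_out: Union[float, Tuple[float, ...]] = xa
    else:
        tables = [_class_table(variant, n, xc) for xc in classes]
        probs = np.mean(tables, axis=0)
        x_out = classes
    return BalancedComponent(variant=variant, n=n, x=x_out, probs=probs)


@dataclass(frozen=True)
class MixtureParams:
    """Free parameters of the alternative model: decay ``A`` and frequency ``x``."""

    A: float
    x: Union[float, Tuple[float, ...]]
    variant: str = "2"
    m: int = 2

    def __post_init__(self):
        if self.A <= 0:
            raise ValueError(f"decay parameter A must be > 0, got {self.A}")
        classes = _canonical_classes(self.x, self.m)
        if np.ndim(self.x) == 0:
            object.__setattr__(self, "x", classes[0])
        else:
            object.__setattr__(self, "x", classes)

    @property
    def classes(self) -> Tuple[float, ...]:
        x = self.x
        return (x, 1.0 - x) if np.ndim(x) == 0 else x


def site_probability(params: MixtureParams, g: NeutralSpectrum, n: int, k: int, d: float) -> float:
    """Mixture probability ``f(k, d)`` of observing allele count ``k`` at distance ``d``.

    Convex combination of the balanced component and the background; equals
    the balanced component at ``d = 0`` and tends to the background as
    ``d -> inf``.
    """
    if g.variant != params.variant:
        raise ValueError(f"spectrum variant {g.variant!r} != params variant {params.variant!r}")
    alpha = linkage_weight(params.A, d)
    comp = balanced_component(n, params.x, params.variant, params.m)
    h = comp.prob(k)
    gk = float(g.prob(n, k))
    return alpha * h + (1.0 - alpha) * gk
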