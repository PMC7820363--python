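"""Deterministic overdominance dynamics and synthetic scan datasets.

Two independent roles:

* infinite-population viability-selection recursions that compute the
  equilibrium allele frequencies implied by a heterozygote-advantage fitness
  scheme (fitnesses 1, ``1 + h*s``, ``1 + s`` for ancestral homozygote,
  heterozygote and mutant homozygote; ``h > 1`` gives an interior
  equilibrium at mutant frequency ``h / (2h - 1)``), including the
  multiallelic case where distinct mutant alleles at one site combine
  multiplicatively, so a mutant/mutant heterozygote has fitness
  ``(1 + h*s)**2``;
* generators that draw scan-ready site datasets from the mixture model
  itself — neutral draws from the background spectrum, or a balanced
  "footprint" whose allele counts follow ``f(k, d)`` exactly — so that
  parameter recovery can be tested without forward simulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .mixture import balanced_component, linkage_weight
from .sfs import NeutralSpectrum, variant_support
from .sites import SiteTable

__all__ = [
    "FitnessScheme",
    "EquilibriumResult",
    "MultiallelicEquilibrium",
    "overdominance_equilibrium",
    "multiallelic_equilibrium",
    "biallelic_trajectory",
    "FootprintSpec",
    "synth_footprint",
    "neutral_dataset",
]


@dataclass(frozen=True)
class FitnessScheme:
    """Overdominant fitness parameterization.

    Genotype fitnesses: ancestral/ancestral 1; ancestral/mutant ``1 + h*s``;
    mutant_i/mutant_i ``1 + s``; mutant_i/mutant_j (i != j)
    ``(1 + h*s)**2`` under the multiplicative multi-mutation rule.
    """

    s: float
    h_dom: float
    m_alleles: int = 1

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("selective coefficient s must be > 0")
        if self.m_alleles < 1:
            raise ValueError("m_alleles must be >= 1")

    def matrix(self) -> np.ndarray:
        """(m+1) x (m+1) genotype fitness matrix, allele 0 = ancestral."""
        m = self.m_alleles
        w_het = 1.0 + self.h_dom * self.s
        W = np.full((m + 1, m + 1), w_het * w_het)
        W[0, :] = w_het
        W[:, 0] = w_het
        W[0, 0] = 1.0
        for i in range(1, m + 1):
            W[i, i] = 1.0 + self.s
        return W


@dataclass(frozen=True)
class EquilibriumResult:
    derived_freq: float
    minor_freq: float
    n_iter: int


@dataclass(frozen=True)
class MultiallelicEquilibrium:
    mutant_freqs: Tuple[float, ...]
    ancestral_freq: float
    ancestral_lost: bool
    n_iter: int


def _biallelic_step(p: float, s: float, h_dom: float) -> float:
    """One generation of the deterministic viability recursion p' = p * wbar_mut / wbar."""
    q = 1.0 - p
    w_het = 1.0 + h_dom * s
    w_mut = 1.0 + s
    w_marg = p * w_mut + q * w_het  # marginal fitness of the mutant allele
    wbar = p * p * w_mut + 2.0 * p * q * w_het + q * q
    return p * w_marg / wbar


def biallelic_trajectory(s: float, h_dom: float, p0: float = 1e-3, steps: int = 100) -> np.ndarray:
    """Raw recursion trajectory of the mutant allele frequency (length steps+1)."""
    traj = np.empty(steps + 1)
    traj[0] = p = p0
    for i in range(steps):
        p = _biallelic_step(p, s, h_dom)
        traj[i + 1] = p
    return traj


def overdominance_equilibrium(
    s: float, h_dom: float, p0: float = 0.5, tol: float = 1e-12, max_iter: int = 100_000
) -> EquilibriumResult:
    """Equilibrium frequency of a single overdominant mutation.

    Iterates the deterministic single-locus viability recursion to a fixed
    point.  Because the plain map contracts only at rate ``1 - O(s)``,
    Steffensen (Aitken delta-squared) acceleration is applied to the same
    step function, which converges quadratically and matches the closed form
    ``h / (2h - 1)`` to well below 1e-9 regardless of the magnitude of ``s``.

    Returns both the derived (mutant) equilibrium frequency and the minor
    allele frequency ``min(p, 1-p)``.
    """
    if s <= 0:
        raise ValueError("selective coefficient s must be > 0")
    if h_dom <= 1:
        raise ValueError(
            f"no interior equilibrium for h_dom={h_dom}: overdominance requires h_dom > 1"
        )
    p = float(p0)
    # walk into the contraction zone of the interior fixed point first: near
    # the repelling boundary equilibria the deltas grow and Aitken would
    # extrapolate toward the wrong (unstable) fixed point
    prev_delta = None
    for _ in range(max_iter):
        p1 = _biallelic_step(p, s, h_dom)
        delta = abs(p1 - p)
        p = p1
        if prev_delta is not None and delta < prev_delta:
            break
        prev_delta = delta
    for it in range(1, max_iter + 1):
        p1 = _biallelic_step(p, s, h_dom)
        p2 = _biallelic_step(p1, s, h_dom)
        denom = p2 - 2.0 * p1 + p
        if denom == 0.0:
            p_new = p2
        else:
            p_new = p - (p1 - p) ** 2 / denom  # Aitken extrapolation
            if not 0.0 < p_new < 1.0:
                p_new = p2
        if abs(p_new - p) < tol:
            p = _polish_fixed_point(p_new, s, h_dom)
            return EquilibriumResult(derived_freq=p, minor_freq=min(p, 1.0 - p), n_iter=it)
        p = p_new
    raise RuntimeError(f"equilibrium recursion did not converge in {max_iter} iterations")


def _polish_fixed_point(p: float, s: float, h_dom: float) -> float:
    """Refine the recursion's fixed point by root-solving its displacement.

    The accelerated iteration stalls at ~1e-9 accuracy for very weak
    selection because the per-generation displacement suffers catastrophic
    cancellation; a bracketed root solve on ``step(p) - p`` recovers the
    fixed point to near machine precision.
    """
    from scipy.optimize import brentq

    def disp(q):
        return _biallelic_step(q, s, h_dom) - q

    width = 1e-6
    while width < 0.5:
        lo, hi = max(p - width, 1e-12), min(p + width, 1 - 1e-12)
        if disp(lo) > 0 > disp(hi):
            return float(brentq(disp, lo, hi, xtol=1e-15))
        width *= 10
    return p


def multiallelic_equilibrium(
    s: float,
    h_dom: float,
    m_alleles: int,
    eps: float = 1e-3,
    perturb: Optional[np.ndarray] = None,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> MultiallelicEquilibrium:
    """Deterministic equilibrium with ``m`` mutant alleles at one site.

    State holds the ancestral allele plus the ``m`` mutants; each generation
    applies the marginal-fitness update ``x_i' = x_i (W x)_i / (x' W x)``.
    Initialization is near-symmetric: mutants at ``(1 - eps)/m`` each and the
    ancestral allele at ``eps`` (it is driven out when the mutant/mutant
    heterozygote fitness exceeds the ancestral marginal fitness, as it does
    under the multiplicative rule with ``h_dom > 1``).
    """
    if m_alleles < 2:
        raise ValueError("m_alleles must be >= 2")
    scheme = FitnessScheme(s=s, h_dom=h_dom, m_alleles=m_alleles)
    W = scheme.matrix()
    x = np.empty(m_alleles + 1)
    x[0] = eps
    x[1:] = (1.0 - eps) / m_alleles
    if perturb is not None:
        x[1:] += np.asarray(perturb, dtype=float)
        if np.any(x <= 0):
            raise ValueError("perturbation drove a frequency nonpositive")
        x /= x.sum()
    trajectory_tail = []
    for it in range(1, max_iter + 1):
        marg = W @ x
        wbar = x @ marg
        x_new = x * marg / wbar
        delta = float(np.max(np.abs(x_new - x)))
        x = x_new
        if delta < tol:
            anc = float(x[0])
            return MultiallelicEquilibrium(
                mutant_freqs=tuple(float(v) for v in x[1:]),
                ancestral_freq=anc,
                ancestral_lost=anc < 1e-8,
                n_iter=it,
            )
        if it > max_iter - 5:
            trajectory_tail.append((it, delta, tuple(np.round(x, 6))))
    raise RuntimeError(
        f"multiallelic recursion did not converge in {max_iter} iterations; "
        f"trajectory tail: {trajectory_tail}"
    )


@dataclass
class FootprintSpec:
    """Parameters of a synthetic balancing-selection footprint.

    ``x0`` is the true equilibrium frequency (scalar, or a class vector for
    multiallelic truth), ``A0`` the true linkage-decay rate per cM; sites are
    laid out at regular ``site_spacing`` (bp) centered on ``center``, with
    genetic positions ``phys * rate`` (cM/bp).  The seed is mandatory.
    """

    x0: Union[float, Tuple[float, ...]]
    A0: float
    center: int = 25_000
    n_sites: int = 2_000
    n_samples: int = 50
    site_spacing: int = 25
    rate: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.A0 <= 0:
            raise ValueError("A0 must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.seed is None:
            raise ValueError("seed must be explicit")


def synth_footprint(
    spec: FootprintSpec, g: NeutralSpectrum, m: int = 2
) -> Tuple[SiteTable, Dict]:
    """Draw a scan-ready dataset whose allele counts follow the mixture exactly.

    Each site at distance ``d`` from the center draws its allele count from
    ``f(k, d) = alpha_{A0}(d) h_{x0}(k) + (1 - alpha) g(k)`` in the variant of
    the supplied spectrum.  Returns the site table and a metadata dict
    recording the distributional truth (suitable for a JSON sidecar).
    """
    n = spec.n_samples
    if not g.has_stratum(n):
        raise ValueError(f"background spectrum has no stratum for n={n}")
    variant = g.variant
    rng = np.random.default_rng(spec.seed)
    support = variant_support(variant, n)
    gvec = np.asarray(g.table(n), dtype=float)
    hvec = balanced_component(n, spec.x0, variant, m).probs
    half = spec.n_sites // 2
    offsets = np.arange(spec.n_sites) - half
    phys = spec.center + offsets * spec.site_spacing
    if phys[0] < 1:
        raise ValueError("footprint extends below position 1; move the center right")
    gen = phys * spec.rate
    d = np.abs(phys - spec.center) * spec.rate
    alpha = linkage_weight(spec.A0, d)
    ks = np.empty(spec.n_sites, dtype=np.int64)
    for i in range(spec.n_sites):
        f = alpha[i] * hvec + (1.0 - alpha[i]) * gvec
        ks[i] = support[rng.choice(len(support), p=f / f.sum())]
    # dichotomous variant: the polymorphic category (placeholder -1 in the
    # support) carries no frequency information; record it as k = 1
    ks[ks < 0] = 1
    table = SiteTable(phys, ks, np.full(spec.n_sites, n), gen)
    meta = {
        "generator": "synth_footprint",
        "variant": variant,
        "m": m,
        "truth": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
    }
    return table, meta


def neutral_dataset(
    n_sites: int,
    g: NeutralSpectrum,
    seed: int,
    n: Optional[int] = None,
    site_spacing: int = 25,
    start: int = 1,
    rate: float = 1e-6,
) -> SiteTable:
    """i.i.d. draws from the background spectrum, laid out at regular spacing.

    With ``n`` unspecified, each site's sample size is drawn from the
    spectrum's per-stratum totals (multinomial across strata).
    """
    rng = np.random.default_rng(seed)
    sizes = list(g.sample_sizes)
    if n is not None:
        ns = np.full(n_sites, int(n))
        if not g.has_stratum(int(n)):
            raise ValueError(f"background spectrum has no stratum for n={n}")
    else:
        w = np.array([g.n_weights[s] for s in sizes], dtype=float)
        ns = np.asarray(sizes)[rng.choice(len(sizes), size=n_sites, p=w / w.sum())]
    ks = np.empty(n_sites, dtype=np.int64)
    for size in np.unique(ns):
        sel = np.flatnonzero(ns == size)
        support = variant_support(g.variant, int(size))
        t = np.asarray(g.table(int(size)))
        draws = rng.choice(len(support), size=len(sel), p=t / t.sum())
        ks[sel] = support[draws]
    ks[ks < 0] = 1  # variant "1" polymorphic placeholder
    phys = start + np.arange(n_sites) * site_spacing
    gen = phys * rate
    return SiteTable(phys, ks, ns, gen)


def write_sidecar(meta: Dict, path) -> None:
    """Write generator metadata as a JSON sidecar file."""
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
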