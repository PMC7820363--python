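"""Per-site polymorphism/substitution records and the table container used by scans.

An *informative site* is either a polymorphic site or a substitution (the
sample is fixed for an allele that differs from the outgroup).  Allele counts
follow one of two polarities:

derived
    ``k`` counts derived alleles, ``1 <= k <= n``; ``k == n`` marks a
    substitution.
minor
    ``k`` counts minor alleles, ``0 <= k <= n // 2``; ``k == 0`` marks a
    substitution (the folded spectrum cannot distinguish fixation from
    monomorphism against the outgroup).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = ["SiteRecord", "SiteTable", "validate_k"]


def validate_k(k: int, n: int, polarity: str) -> None:
    """Raise ``ValueError`` if allele count ``k`` is outside the polarity support."""
    if n < 2:
        raise ValueError(f"sample size n={n} < 2")
    if polarity == "derived":
        if not 1 <= k <= n:
            raise ValueError(f"derived allele count k={k} outside [1, {n}]")
    elif polarity == "minor":
        if not 0 <= k <= n // 2:
            raise ValueError(f"minor allele count k={k} outside [0, {n // 2}]")
    else:
        raise ValueError(f"unknown polarity {polarity!r}")


@dataclass(frozen=True)
class SiteRecord:
    """One informative site.

    Parameters
    ----------
    phys_pos : int
        1-based physical position in base pairs.
    k : int
        Derived or minor allele count, depending on the dataset polarity.
    n : int
        Number of sampled alleles (haploid sample size) at this site.
    gen_pos : float, optional
        Genetic position in centimorgans.  When absent, distances are derived
        from physical positions via a uniform recombination rate.
    """

    phys_pos: int
    k: int
    n: int
    gen_pos: Optional[float] = None

    def validate(self, polarity: str) -> None:
        validate_k(self.k, self.n, polarity)

    def is_substitution(self, polarity: str) -> bool:
        return self.k == (self.n if polarity == "derived" else 0)


class SiteTable:
    """Column-oriented container for a sorted run of informative sites.

    Thin wrapper over numpy arrays; convertible to/from a pandas DataFrame
    with columns ``physPos``, ``genPos`` (optional), ``x`` (the allele count
    ``k``, matching the on-disk column convention) and ``n``.
    """

    def __init__(self, phys_pos, k, n, gen_pos=None):
        self.phys_pos = np.asarray(phys_pos, dtype=np.int64)
        self.k = np.asarray(k, dtype=np.int64)
        self.n = np.asarray(n, dtype=np.int64)
        if gen_pos is None:
            self.gen_pos = None
        else:
            self.gen_pos = np.asarray(gen_pos, dtype=float)
        L = len(self.phys_pos)
        if not (len(self.k) == len(self.n) == L):
            raise ValueError("column length mismatch")
        if self.gen_pos is not None and len(self.gen_pos) != L:
            raise ValueError("column length mismatch")

    def __len__(self) -> int:
        return len(self.phys_pos)

    def __iter__(self) -> Iterator[SiteRecord]:
        for i in range(len(self)):
            gp = None if self.gen_pos is None else float(self.gen_pos[i])
            yield SiteRecord(int(self.phys_pos[i]), int(self.k[i]), int(self.n[i]), gp)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SiteTable):
            return NotImplemented
        if (self.gen_pos is None) != (other.gen_pos is None):
            return False
        same = (
            np.array_equal(self.phys_pos, other.phys_pos)
            and np.array_equal(self.k, other.k)
            and np.array_equal(self.n, other.n)
        )
        if same and self.gen_pos is not None:
            same = np.allclose(self.gen_pos, other.gen_pos, rtol=0, atol=0)
        return same

    @classmethod
    def from_records(cls, records: Iterable[SiteRecord]) -> "SiteTable":
        recs = list(records)
        gen = [r.gen_pos for r in recs]
        has_gen = any(g is not None for g in gen)
        if has_gen and any(g is None for g in gen):
            raise ValueError("mixed presence of genetic positions")
        return cls(
            [r.phys_pos for r in recs],
            [r.k for r in recs],
            [r.n for r in recs],
            gen if has_gen else None,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SiteTable":
        gen = df["genPos"].to_numpy(float) if "genPos" in df.columns else None
        return cls(df["physPos"].to_numpy(), df["x"].to_numpy(), df["n"].to_numpy(), gen)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"physPos": self.phys_pos}
        if self.gen_pos is not None:
            cols["genPos"] = self.gen_pos
        cols["x"] = self.k
        cols["n"] = self.n
        return pd.DataFrame(cols)

    def genetic_positions(self, rate: float = 1e-6) -> np.ndarray:
        """Genetic positions in cM; falls back to ``phys_pos * rate`` (cM/bp)."""
        if self.gen_pos is not None:
            return self.gen_pos
        return self.phys_pos * float(rate)

    def validate_sorted(self) -> None:
        """Require strictly increasing physical positions (single scaffold)."""
        d = np.diff(self.phys_pos)
        if np.any(d < 0):
            i = int(np.argmax(d < 0))
            raise ValueError(f"positions not sorted at row {i + 1} (physPos {self.phys_pos[i + 1]})")
        if np.any(d == 0):
            i = int(np.argmax(d == 0))
            raise ValueError(f"duplicate position {self.phys_pos[i]} at row {i + 1}")
        if self.gen_pos is not None and np.any(np.diff(self.gen_pos) < 0):
            raise ValueError("genetic positions decrease with physical position")

    def validate_polarity(self, polarity: str) -> None:
        for i in range(len(self)):
            try:
                validate_k(int(self.k[i]), int(self.n[i]), polarity)
            except ValueError as exc:
                raise ValueError(f"site at physPos {self.phys_pos[i]}: {exc}") from exc

    def subset(self, mask) -> "SiteTable":
        mask = np.asarray(mask)
        return SiteTable(
            self.phys_pos[mask],
            self.k[mask],
            self.n[mask],
            None if self.gen_pos is None else self.gen_pos[mask],
        )
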