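"""Readers and writers for the package's TSV dialects.

Three plain-text formats:

* **site file** — header ``physPos[<TAB>genPos]<TAB>x<TAB>n``; one row per
  informative site, ``x`` being the allele count ``k`` and ``genPos`` the
  genetic position in cM (omit the column to derive distances from a uniform
  recombination rate);
* **spect file** — genome-wide background counts; a ``#polarity=`` line,
  then ``n<TAB>k<TAB>count`` rows (raw counts, so any model variant can be
  normalized from one file);
* **scan file** — ``physPos genPos CLR x_hat A_hat n_sites``, floats at six
  significant digits.

All readers validate headers strictly and report malformed rows with line
numbers; ``read(write(x)) == x`` holds for each format.
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Iterable, List

import numpy as np
import pandas as pd

from .scan import ScanRow
from .sfs import BackgroundSFS
from .sites import SiteTable

__all__ = [
    "read_sites",
    "write_sites",
    "read_spect",
    "write_spect",
    "read_scan",
    "write_scan",
    "read_genotype_table",
    "write_genotype_table",
    "file_sha256",
    "write_run_log",
]


def _fmt(v: float) -> str:
    if isinstance(v, float) and math.isnan(v):
        return "nan"
    return f"{v:.6g}"


def read_sites(path) -> SiteTable:
    """Read a site TSV (``physPos [genPos] x n``) into a :class:`SiteTable`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = list(df.columns)
    if cols not in (["physPos", "genPos", "x", "n"], ["physPos", "x", "n"]):
        raise ValueError(
            f"{path}: bad header {cols}; expected physPos [genPos] x n"
        )
    for col in ("physPos", "x", "n"):
        if df[col].isna().any():
            row = int(np.argmax(df[col].isna().to_numpy())) + 2
            raise ValueError(f"{path}: missing {col} at line {row}")
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            frac = np.mod(vals, 1) != 0
            if np.any(frac):
                row = int(np.argmax(frac)) + 2
                raise ValueError(f"{path}: non-integer {col} at line {row}")
            df[col] = vals.astype(np.int64)
    table = SiteTable.from_dataframe(df)
    try:
        table.validate_sorted()
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return table


def write_sites(dataset: SiteTable, path) -> None:
    cols = ["physPos"] + (["genPos"] if dataset.gen_pos is not None else []) + ["x", "n"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(len(dataset)):
            row = [str(int(dataset.phys_pos[i]))]
            if dataset.gen_pos is not None:
                row.append(repr(float(dataset.gen_pos[i])))
            row += [str(int(dataset.k[i])), str(int(dataset.n[i]))]
            fh.write("\t".join(row) + "\n")


def read_spect(path) -> BackgroundSFS:
    """Read a spect file of raw background counts."""
    counts = {}
    polarity = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#polarity="):
                    polarity = line.split("=", 1)[1].strip()
                continue
            parts = line.split("\t")
            if parts == ["n", "k", "count"]:
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                n, k, c = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer field in {parts}") from None
            if c < 0:
                raise ValueError(f"{path}: line {lineno}: negative count {c}")
            if (n, k) in counts:
                raise ValueError(f"{path}: line {lineno}: duplicate (n={n}, k={k})")
            counts[(n, k)] = c
    if polarity is None:
        raise ValueError(f"{path}: missing '#polarity=' header line")
    try:
        return BackgroundSFS(polarity=polarity, counts=counts)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_spect(bg: BackgroundSFS, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#polarity={bg.polarity}\n")
        fh.write("n\tk\tcount\n")
        for (n, k) in sorted(bg.counts):
            fh.write(f"{n}\t{k}\t{bg.counts[(n, k)]}\n")


def write_scan(rows: Iterable[ScanRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("physPos\tgenPos\tCLR\tx_hat\tA_hat\tn_sites\n")
        for r in rows:
            if np.ndim(r.x_hat) == 0:
                x = _fmt(r.x_hat)
            else:
                x = ",".join(_fmt(v) for v in r.x_hat)
            fh.write(
                f"{r.phys_pos}\t{_fmt(r.gen_pos)}\t{_fmt(r.B)}\t{x}\t{_fmt(r.A_hat)}\t{r.L_sites}\n"
            )


def _parse_x_hat(text: str):
    if "," in text:
        return tuple(float(v) for v in text.split(","))
    return float(text)


def read_scan(path) -> List[ScanRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["physPos", "genPos", "CLR", "x_hat", "A_hat", "n_sites"]:
            raise ValueError(f"{path}: bad scan header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            rows.append(
                ScanRow(
                    phys_pos=int(parts[0]),
                    gen_pos=float(parts[1]),
                    B=float(parts[2]),
                    x_hat=_parse_x_hat(parts[3]),
                    A_hat=float(parts[4]),
                    L_sites=int(parts[5]),
                )
            )
    return rows


def read_genotype_table(path) -> List[tuple]:
    """Read a genotype-count TSV (``physPos nAA nAa naa``) for the HWE filter."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["physPos", "nAA", "nAa", "naa"]:
            raise ValueError(f"{path}: bad header {header}; expected physPos nAA nAa naa")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            try:
                out.append(tuple(int(v) for v in parts))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from None
    return out


def write_genotype_table(rows: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("physPos\tnAA\tnAa\tnaa\n")
        for pos, a, b, c in rows:
            fh.write(f"{pos}\t{a}\t{b}\t{c}\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(path, command: str, params: dict, inputs: Iterable = (), counts: dict | None = None) -> None:
    """Append a structured JSON line describing one CLI run (reproducibility log)."""
    entry = {
        "command": command,
        "params": params,
        "inputs": [{"path": str(p), "sha256": file_sha256(p)} for p in inputs],
        "counts": counts or {},
    }
    with open(path, "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
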