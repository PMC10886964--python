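"""Readers and writers for the plain-text formats the pipeline consumes.

Edge lists are TSV/whitespace files with one pair per line (SIF ``A rel B``
is accepted on read); gene/miRNA lists are one symbol per line with ``#``
comments.  Symbol matching downstream is exact string matching after
whitespace trimming and gene uppercasing, so normalisation happens here, at
the boundary.  miRNA identifiers (detected by a ``-miR-``/``-let-``
substring) keep their case, miRBase-style.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list files."""


def _is_mirna(symbol: str) -> bool:
    low = symbol.lower()
    return "-mir-" in low or "-let-" in low


def normalize_symbol(symbol: str) -> str:
    """Trim whitespace; uppercase genes, preserve miRBase-style miRNA names."""
    s = symbol.strip()
    return s if _is_mirna(s) else s.upper()


def read_edge_list(path: str | Path, directed: bool = False):
    """Read a TSV/SIF edge list.

    Returns ``(edges, self_loops)``: for undirected input ``edges`` is a set
    of frozensets of size 2 and ``self_loops`` a set of nodes; for directed
    (bipartite) input ``edges`` is a set of ``(source, target)`` tuples and
    self-loops are impossible by construction (kept empty).

    A line with a single token is malformed; a third column (SIF relation in
    the middle, or an edge weight at the end) is ignored.
    """
    path = Path(path)
    edges: set = set()
    self_loops: set[str] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) < 2:
                raise EdgeListError(f"{path}:{lineno}: expected at least two columns, got {raw!r}")
            if len(parts) == 3 and not directed:
                # SIF: "A relation B" — relation is the middle token
                a, b = parts[0], parts[2]
            else:
                a, b = parts[0], parts[1]
            a, b = normalize_symbol(a), normalize_symbol(b)
            n_lines += 1
            if directed:
                edges.add((a, b))
            elif a == b:
                self_loops.add(a)
            else:
                edges.add(frozenset((a, b)))
    if n_lines == 0:
        raise EdgeListError(f"{path}: empty edge list")
    return edges, self_loops


def write_edge_list(path: str | Path, edges: Iterable, header: tuple[str, str] | None = None) -> None:
    """Write edges as two-column TSV, deterministically sorted."""
    rows = []
    for e in edges:
        if isinstance(e, frozenset):
            a, b = sorted(e)
        else:
            a, b = e
        rows.append((a, b))
    rows.sort()
    with open(path, "w") as fh:
        if header is not None:
            fh.write(f"{header[0]}\t{header[1]}\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line list; genes uppercased, miRNAs preserved."""
    symbols: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            symbols.add(normalize_symbol(line))
    if not symbols:
        warnings.warn(f"{path}: empty symbol list", stacklevel=2)
    return symbols


def write_gene_list(path: str | Path, symbols: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for s in sorted(symbols):
            fh.write(s + "\n")


DE_COLUMNS = ("probe", "symbol", "logFC", "FC", "p", "adjP", "mean_expr")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV (header row required).

    Expected columns: ``probe``, ``symbol``, one of ``logFC`` (log2 units,
    microarray) or ``FC`` (linear fold change, proteomics), ``p``, ``adjP``,
    optional ``mean_expr``.  p and adjP are validated to lie in [0,1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "symbol": str})
    if "probe" not in df.columns or "symbol" not in df.columns:
        raise ValueError(f"{path}: DE table needs 'probe' and 'symbol' columns")
    if "logFC" not in df.columns and "FC" not in df.columns:
        raise ValueError(f"{path}: DE table needs a 'logFC' or 'FC' column")
    for col in ("p", "adjP"):
        if col not in df.columns:
            raise ValueError(f"{path}: DE table needs a '{col}' column")
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: column '{col}' outside [0,1]")
    df["symbol"] = df["symbol"].fillna("").map(normalize_symbol)
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
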