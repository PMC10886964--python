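"""Differential-expression preprocessing.

Applies the study's significance filters (microarray: adjusted p <= 0.05 and
|log2FC| >= 0.5; proteomics: p <= 0.05 and symmetrised linear fold change
>= 1.2, both boundaries inclusive), collapses multi-probe features to one
row per symbol, unions the filtered datasets, and partitions the union into
known-disease DE genes (HDEGs) versus other DE genes (ODEGs) against a
curated disease-gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DEUnion:
    """Union of filtered DE tables with the HDEG/ODEG partition.

    ``direction`` maps ``(symbol, dataset_index)`` to ``"up"``, ``"down"``
    or ``"mixed"`` (proteomics rows flagged as dataset-internally
    discordant).  ``hdegs`` and ``odegs`` partition ``symbols`` by
    membership in the supplied disease-gene list.
    """

    symbols: set[str]
    direction: dict[tuple[str, int], str]
    hdegs: set[str]
    odegs: set[str]


def _require_columns(table: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing required column(s): {missing}")


def filter_microarray(table: pd.DataFrame, fdr_max: float = 0.05, abs_logfc_min: float = 0.5) -> pd.DataFrame:
    """Keep rows with adjP <= fdr_max and |logFC| >= abs_logfc_min.

    Adds a ``direction`` column from the sign of logFC (logFC = 0 counts as
    up only when abs_logfc_min is 0; it cannot pass otherwise).
    """
    _require_columns(table, ("logFC", "adjP"))
    keep = (table["adjP"] <= fdr_max) & (table["logFC"].abs() >= abs_logfc_min)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["logFC"] >= 0, "up", "down")
    return out


def filter_proteomics(table: pd.DataFrame, fc_min: float = 1.2, p_max: float = 0.05) -> pd.DataFrame:
    """Keep rows with p <= p_max and max(FC, 1/FC) >= fc_min.

    ``FC`` is a linear ratio; values below 1 mean down-regulation, so the
    magnitude is symmetrised by the reciprocal before thresholding.
    """
    _require_columns(table, ("FC", "p"))
    fc = table["FC"]
    if (fc <= 0).any():
        bad = table.loc[fc <= 0, "FC"].iloc[0]
        raise ValueError(f"linear fold changes must be positive, got {bad}")
    sym = np.maximum(fc, 1.0 / fc)
    keep = (table["p"] <= p_max) & (sym >= fc_min)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["FC"] >= 1.0, "up", "down")
    return out


def collapse_probes(table: pd.DataFrame) -> pd.DataFrame:
    """One row per symbol: drop unannotated probes, keep the best probe.

    The kept probe is the one with the highest mean expression; when
    ``mean_expr`` is absent the fallback chain is highest |logFC| (or
    symmetrised |FC|), then lowest adjusted p, then lexicographically
    smallest probe id — a fixed, documented tie-break so the collapse is
    deterministic and idempotent.
    """
    t = table.copy()
    t["symbol"] = t["symbol"].fillna("").astype(str).str.strip()
    t = t[t["symbol"] != ""]
    if t.empty:
        return t.reset_index(drop=True)

    if "mean_expr" in t.columns and t["mean_expr"].notna().any():
        primary = t["mean_expr"].fillna(-np.inf)
    elif "logFC" in t.columns:
        primary = t["logFC"].abs()
    else:
        fc = t["FC"].astype(float)
        primary = np.maximum(fc, 1.0 / fc)
    adjp = t["adjP"] if "adjP" in t.columns else pd.Series(1.0, index=t.index)
    probe = t["probe"].astype(str) if "probe" in t.columns else pd.Series("", index=t.index)

    order = pd.DataFrame({
        "symbol": t["symbol"],
        "_primary": -np.asarray(primary, dtype=float),  # ascending sort -> highest first
        "_adjp": np.asarray(adjp, dtype=float),
        "_probe": probe,
    }, index=t.index)
    idx = order.sort_values(["symbol", "_primary", "_adjp", "_probe"], kind="mergesort") \
               .groupby("symbol", sort=True).head(1).index
    return t.loc[idx].sort_values("symbol", kind="mergesort").reset_index(drop=True)


def union_and_partition(filtered_tables: list[pd.DataFrame], disease_genes: set[str]) -> DEUnion:
    """Union collapsed, filtered tables and split by the disease-gene list."""
    symbols: set[str] = set()
    direction: dict[tuple[str, int], str] = {}
    for k, t in enumerate(filtered_tables):
        for _, row in t.iterrows():
            sym = row["symbol"]
            symbols.add(sym)
            d = row.get("direction", "up")
            key = (sym, k)
            if key in direction and direction[key] != d:
                direction[key] = "mixed"
            else:
                direction[key] = d
    hdegs = symbols & disease_genes
    return DEUnion(symbols=symbols, direction=direction, hdegs=hdegs, odegs=symbols - hdegs)


def overlap_report(filtered_tables: list[pd.DataFrame]) -> tuple[dict[frozenset, int], list[str]]:
    """Venn-region counts over the datasets plus cross-dataset discordance.

    Returns ``(regions, discordant)`` where ``regions`` maps a frozenset of
    dataset indices to the count of symbols present in exactly those
    datasets, and ``discordant`` lists symbols whose up/down direction
    differs across datasets.  Rows carrying direction ``"mixed"`` are
    excluded from discordance reporting.
    """
    if len(filtered_tables) < 2:
        raise ValueError("overlap report needs at least two tables")
    membership: dict[str, set[int]] = {}
    dirs: dict[str, set[str]] = {}
    for k, t in enumerate(filtered_tables):
        for _, row in t.iterrows():
            sym = row["symbol"]
            membership.setdefault(sym, set()).add(k)
            d = row.get("direction", "up")
            if d != "mixed":
                dirs.setdefault(sym, set()).add(d)
    regions: dict[frozenset, int] = {}
    for sym, ks in membership.items():
        key = frozenset(ks)
        regions[key] = regions.get(key, 0) + 1
    discordant = sorted(s for s, ds in dirs.items() if len(ds) > 1)
    return regions, discordant
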