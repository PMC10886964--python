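"""Bipartite miRNA-target biclustering and disease-miRNA relevance scoring.

Each miRNA-target interaction (MTI) source is a bipartite graph.  It is
biclustered by folding onto the miRNA side (two miRNAs connected when the
Jaccard similarity of their target sets reaches ``sim_min``), running the
overlapping density clustering on the folded graph, and attaching to each
miRNA cluster every gene targeted by at least ``attach_ratio`` of its
miRNAs.  The resulting biclusters are the miRNA-regulatory modules (MRMs);
an MRM whose gene side contains a known disease gene is a sub-MRM.

Per dataset, a miRNA in at least one sub-MRM gets a relevance score
``RS = n_disease_attached x n_sub_mrms`` — the number of disease genes it
directly targets within its sub-MRMs times the number of sub-MRMs
containing it.
The total relevance score averages the per-dataset scores after
normalising each by that dataset's module count:

    TRS_i = ( sum_n RS_ni / C_n ) / ( sum_n E_ni )

where ``E_ni`` indicates whether miRNA i occurs in dataset n.  miRNAs with
TRS above the calling threshold (default: strictly positive) are the
predicted disease-associated miRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .ppi import dpcluso_cluster


@dataclass
class BipartiteMTI:
    """A named bipartite miRNA-target edge set."""

    source_name: str
    edges: set[tuple[str, str]]  # (miRNA, gene)

    @property
    def mirna_nodes(self) -> set[str]:
        return {m for m, _ in self.edges}

    @property
    def gene_nodes(self) -> set[str]:
        return {g for _, g in self.edges}

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna}


@dataclass
class Bicluster:
    mirnas: frozenset
    genes: frozenset
    fill: float
    is_sub_mrm: bool = False


def build_mti(edges: set[tuple[str, str]], query_genes: set[str],
              source_name: str = "mti") -> BipartiteMTI:
    """Restrict an MTI edge set to edges whose gene endpoint is queried."""
    if not query_genes:
        raise ValueError("query gene set must be non-empty")
    kept = {(m, g) for m, g in edges if g in query_genes}
    if not kept:
        warnings.warn(f"{source_name}: no MTI edge matches the query gene set", stacklevel=2)
    return BipartiteMTI(source_name=source_name, edges=kept)


def _fold_mirna_side(mti: BipartiteMTI, sim_min: float) -> nx.Graph:
    """miRNA-miRNA graph: edge iff Jaccard similarity of target sets >= sim_min."""
    targets = {m: set() for m in mti.mirna_nodes}
    for m, g in mti.edges:
        targets[m].add(g)
    folded = nx.Graph()
    folded.add_nodes_from(targets)
    mirnas = sorted(targets)
    for i, a in enumerate(mirnas):
        for b in mirnas[i + 1:]:
            inter = len(targets[a] & targets[b])
            if inter == 0:
                continue
            jac = inter / len(targets[a] | targets[b])
            if jac >= sim_min:
                folded.add_edge(a, b)
    return folded


def bicluso_bicluster(mti: BipartiteMTI, sim_min: float = 0.33,
                      density_threshold: float = 0.5,
                      attach_ratio: float = 0.5) -> list[Bicluster]:
    """Fold, cluster the miRNA side, and attach co-targeted genes.

    Folded-isolated miRNAs (no partner reaches ``sim_min``) are still
    emitted as 1 x k biclusters of their own targets, so low-similarity
    sources are not silently dropped.  Biclusters with an empty gene side
    are discarded; overlaps are allowed.
    """
    for name, v in (("sim_min", sim_min), ("density_threshold", density_threshold),
                    ("attach_ratio", attach_ratio)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0,1], got {v}")
    if not mti.edges:
        return []
    targets: dict[str, set[str]] = {m: set() for m in mti.mirna_nodes}
    for m, g in mti.edges:
        targets[m].add(g)
    folded = _fold_mirna_side(mti, sim_min)
    mirna_sets = [set(c.members) for c in
                  dpcluso_cluster(folded, min(density_threshold, 1.0 - 1e-9), min_size=2)]
    for m in folded.nodes:
        if folded.degree(m) == 0:
            mirna_sets.append({m})
    out: list[Bicluster] = []
    seen: set[tuple[frozenset, frozenset]] = set()
    for mset in mirna_sets:
        need = attach_ratio * len(mset)
        counts: dict[str, int] = {}
        for m in mset:
            for g in targets[m]:
                counts[g] = counts.get(g, 0) + 1
        genes = {g for g, c in counts.items() if c >= need}
        if not genes:
            continue
        n_edges = sum(1 for m in mset for g in targets[m] & genes)
        key = (frozenset(mset), frozenset(genes))
        if key in seen:
            continue
        seen.add(key)
        out.append(Bicluster(mirnas=key[0], genes=key[1],
                             fill=n_edges / (len(mset) * len(genes))))
    return out


def mark_sub_mrms(mrms: list[Bicluster], disease_genes: set[str]) -> list[Bicluster]:
    """Flag MRMs whose gene side intersects the disease-gene set."""
    for b in mrms:
        b.is_sub_mrm = bool(b.genes & disease_genes)
    return mrms


@dataclass
class MiRNAScore:
    mirna: str
    rs: dict[str, float]            # per-dataset RS
    n_disease_attached: dict[str, int]  # disease genes attached within sub-MRMs
    n_sub_mrms: dict[str, int]          # sub-MRMs containing the miRNA
    c: dict[str, int]               # per-dataset normalising module count
    e: dict[str, int]               # presence indicator per dataset
    trs: float


def relevance_scores(mrms_by_source: dict[str, list[Bicluster]],
                     mtis: dict[str, BipartiteMTI],
                     disease_genes: set[str],
                     normalize_by: str = "mrm") -> list[MiRNAScore]:
    """Per-miRNA RS per dataset and the normalised total TRS.

    A miRNA inside a sub-MRM but with no *direct* edge to a disease gene
    co-occurring with it in a sub-MRM scores RS = 0.  ``normalize_by``
    chooses the per-dataset denominator ``C_n``: all MRMs (default) or
    sub-MRMs only.  miRNAs absent from every dataset are omitted (TRS
    undefined).
    """
    if normalize_by not in ("mrm", "sub_mrm"):
        raise ValueError("normalize_by must be 'mrm' or 'sub_mrm'")
    if set(mrms_by_source) != set(mtis):
        raise ValueError("mrms_by_source and mtis must cover the same sources")
    sources = sorted(mtis)
    all_mirnas = sorted(set().union(*(mtis[s].mirna_nodes for s in sources)))
    edge_sets = {s: mtis[s].edges for s in sources}
    out: list[MiRNAScore] = []
    for m in all_mirnas:
        rs, nh, nc, cc, ee = {}, {}, {}, {}, {}
        for s in sources:
            mrms = mrms_by_source[s]
            subs = [b for b in mrms if b.is_sub_mrm]
            present = m in mtis[s].mirna_nodes
            ee[s] = int(present)
            cc[s] = len(mrms) if normalize_by == "mrm" else len(subs)
            my_subs = [b for b in subs if m in b.mirnas]
            nc[s] = len(my_subs)
            attached: set[str] = set()
            for b in my_subs:
                for g in b.genes & disease_genes:
                    if (m, g) in edge_sets[s]:
                        attached.add(g)
            nh[s] = len(attached)
            rs[s] = float(nh[s] * nc[s])
        denom = sum(ee.values())
        if denom == 0:
            continue
        trs = sum(rs[s] / cc[s] for s in sources if cc[s] > 0) / denom
        out.append(MiRNAScore(mirna=m, rs=rs, n_disease_attached=nh, n_sub_mrms=nc,
                              c=cc, e=ee, trs=trs))
    return out


def predict_mirnas(scores: list[MiRNAScore], trs_min: float = 0.0) -> list[MiRNAScore]:
    """miRNAs with TRS strictly above the threshold, ranked TRS desc then
    name asc."""
    hits = [s for s in scores if s.trs > trs_min]
    hits.sort(key=lambda s: (-s.trs, s.mirna))
    return hits


def attachment_ratio(predicted: list[MiRNAScore], k: int,
                     union_edges: set[tuple[str, str]],
                     disease_genes: set[str]) -> float:
    """Disease-gene attachment enrichment of the top-k predicted miRNAs.

    Attachments are counted per miRNA as distinct disease genes with a
    direct edge in the union MTI network; the ratio compares the mean
    attachment of the top-k (by TRS rank) with the mean over all
    predictions.
    """
    if not 1 <= k <= len(predicted):
        raise ValueError(f"k must lie in [1, {len(predicted)}], got {k}")
    attach = {s.mirna: len({g for m, g in union_edges
                            if m == s.mirna and g in disease_genes})
              for s in predicted}
    top = sum(attach[s.mirna] for s in predicted[:k])
    total = sum(attach.values())
    if total == 0:
        raise ValueError("no predicted miRNA has a disease-gene attachment")
    return (top / k) / (total / len(predicted))
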