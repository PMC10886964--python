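"""Disease PPI network construction, topology, overlapping density-based
clustering, enrichment scoring and module calling.

The clustering stage grows one candidate cluster from every node of the
network (seeds in descending degree order), admitting at each step the
neighbouring node with the most edges into the current cluster, subject to
two constraints: the cluster density ``d = 2|E|/(|c|(|c|-1))`` after
admission must stay at or above the density threshold, and the cluster
property ``cp = |E_nc|/(d*|c|)`` — the candidate's edges into the cluster
relative to what the current density demands — must reach ``cp_min``.
Clusters are overlapping (nodes are never removed between seeds); exact
duplicates are collapsed and clusters below ``min_size`` dropped.

Each cluster is scored by a one-sided Fisher exact test for enrichment of
known-disease DE genes (HDEGs); the per-gene significance score
``SScore = -log10(p)`` of the best containing cluster feeds a ROC analysis
(HDEG vs non-HDEG over all network genes) whose AUC selects the optimal
density threshold.  Modules are called at BH-adjusted p < 0.05 and their
non-HDEG members proposed as new candidate disease genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .de import DEUnion

P_FLOOR = 1e-300  # cap for -log10 of an exactly-zero p-value


# ---------------------------------------------------------------------------
# network construction

def build_disease_network(reference_edges: set, de_union: DEUnion,
                          disease_genes: set[str] | None = None) -> nx.Graph:
    """Induce the disease-relevant network from a reference interactome.

    Keeps every DE gene present in the reference, all their direct
    interaction partners, and every reference edge among the retained
    nodes.  Node label: ``HDEG`` (DE and curated disease gene), ``ODEG``
    (other DE gene), ``OG`` (interactor-only "other gene").
    """
    ref = nx.Graph()
    for e in reference_edges:
        a, b = tuple(sorted(e)) if isinstance(e, frozenset) else e
        if a != b:
            ref.add_edge(a, b)
    de_present = de_union.symbols & set(ref.nodes)
    if not de_present:
        raise ValueError("no DE gene appears in the reference interactome")
    keep = set(de_present)
    for g in de_present:
        keep.update(ref.neighbors(g))
    graph = ref.subgraph(keep).copy()
    hdegs = de_union.hdegs if disease_genes is None else de_union.symbols & disease_genes
    for node in graph.nodes:
        if node in de_union.symbols:
            graph.nodes[node]["label"] = "HDEG" if node in hdegs else "ODEG"
        else:
            graph.nodes[node]["label"] = "OG"
    return graph


# ---------------------------------------------------------------------------
# topology

@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    n_self_loops: int
    diameter: int
    avg_path_length: float
    avg_eccentricity: float
    clustering_coefficient: float
    modularity: float
    avg_eigenvector_centrality: float
    avg_neighbors: float
    centralization_degree: float
    centralization_betweenness: float
    fit_power_law: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _power_law_fit(degrees: list[int], r2_min: float = 0.8) -> bool:
    """Heavy-tail check: least-squares fit of the log survival function of
    the degree distribution on log-degree over degrees >= 2; declared
    power-law when R^2 >= ``r2_min`` with a negative slope.  The cumulative
    form is used because the raw log-log histogram is dominated by
    single-count noise in its tail at desk-scale network sizes."""
    ks, counts = np.unique(degrees, return_counts=True)
    surv = np.cumsum(counts[::-1])[::-1] / len(degrees)
    mask = ks >= 2
    if mask.sum() < 3:
        return False
    x, y = np.log10(ks[mask]), np.log10(surv[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return False
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return bool(r2 >= r2_min and slope < 0)


def topology(graph: nx.Graph) -> TopologyReport:
    """Standard topology metrics; path-based metrics use the largest
    connected component."""
    if graph.number_of_nodes() == 0:
        raise ValueError("topology of an empty graph is undefined")
    self_loops = list(nx.selfloop_edges(graph))
    g = graph.copy()
    g.remove_edges_from(self_loops)
    n = g.number_of_nodes()

    lcc_nodes = max(nx.connected_components(g), key=len)
    lcc = g.subgraph(lcc_nodes)
    ecc = nx.eccentricity(lcc)
    diameter = max(ecc.values())
    apl = nx.average_shortest_path_length(lcc) if lcc.number_of_nodes() > 1 else 0.0

    degrees = [d for _, d in g.degree()]
    communities = nx.community.greedy_modularity_communities(g)
    modularity = nx.community.modularity(g, communities) if g.number_of_edges() else 0.0
    eig = _eigenvector_centrality(lcc)

    # Freeman centralization with normalised centralities
    deg_c = nx.degree_centrality(g)
    bet_c = nx.betweenness_centrality(g, normalized=True)
    cent_deg = _freeman(deg_c, n, denom=n - 2) if n > 2 else 0.0
    cent_bet = _freeman(bet_c, n, denom=n - 1) if n > 1 else 0.0

    return TopologyReport(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        n_self_loops=len(self_loops),
        diameter=int(diameter),
        avg_path_length=float(apl),
        avg_eccentricity=float(np.mean(list(ecc.values()))),
        clustering_coefficient=float(nx.average_clustering(g)),
        modularity=float(modularity),
        avg_eigenvector_centrality=float(np.mean(list(eig.values()))),
        avg_neighbors=float(np.mean(degrees)) if degrees else 0.0,
        centralization_degree=float(cent_deg),
        centralization_betweenness=float(cent_bet),
        fit_power_law=_power_law_fit(degrees),
    )


def _eigenvector_centrality(graph: nx.Graph) -> dict:
    """Leading-eigenvector centrality via a dense symmetric decomposition
    with a fixed node order — fully deterministic, unlike iterative solvers
    started from a random vector."""
    if graph.number_of_edges() == 0:
        return {v: 0.0 for v in graph}
    nodes = sorted(graph.nodes, key=str)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    w, v = np.linalg.eigh(a)
    lead = np.abs(v[:, int(np.argmax(w))])
    lead /= np.linalg.norm(lead)
    return dict(zip(nodes, lead))


def _freeman(centrality: dict, n: int, denom: int) -> float:
    cmax = max(centrality.values())
    return sum(cmax - c for c in centrality.values()) / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# overlapping density clustering

@dataclass
class Cluster:
    members: frozenset
    density: float
    seed_node: str
    p_value: float = 1.0
    adj_p: float = 1.0

    def __len__(self) -> int:
        return len(self.members)


def _density(n_edges: int, n_nodes: int) -> float:
    return 1.0 if n_nodes < 2 else 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def dpcluso_cluster(graph: nx.Graph, density_threshold: float,
                    cp_min: float = 0.5, min_size: int = 2) -> list[Cluster]:
    """Grow one overlapping dense cluster from every node.

    Seeds are taken in descending degree order (ties lexicographic).  At
    each growth step the neighbour with the most edges into the cluster
    among those passing both admission conditions is added; growth stops
    when no neighbour qualifies.  Ties on edges-into-cluster break toward
    the candidate with the most edges into the cluster's current frontier
    (its other neighbours), which keeps growth cohesive, then toward the
    lexicographically smaller name.  Duplicate member sets are collapsed
    (first seed wins) and clusters smaller than ``min_size`` dropped.
    """
    if not 0.0 < density_threshold < 1.0:
        raise ValueError(f"density_threshold must lie in (0,1), got {density_threshold}")
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    seeds = sorted(g.nodes, key=lambda v: (-g.degree(v), str(v)))
    seen: set[frozenset] = set()
    clusters: list[Cluster] = []
    for seed in seeds:
        members, n_edges = _grow(g, seed, density_threshold, cp_min)
        if len(members) < min_size:
            continue
        fs = frozenset(members)
        if fs in seen:
            continue
        seen.add(fs)
        clusters.append(Cluster(members=fs, density=_density(n_edges, len(members)), seed_node=seed))
    return clusters


def _grow(g: nx.Graph, seed, density_threshold: float, cp_min: float) -> tuple[set, int]:
    members = {seed}
    n_edges = 0
    # edges into the cluster, per frontier node
    frontier: dict = {v: 1 for v in g.neighbors(seed)}
    while frontier:
        cur_density = _density(n_edges, len(members))
        best = None
        best_key = None
        for v, e_in in frontier.items():
            new_d = _density(n_edges + e_in, len(members) + 1)
            cp = e_in / (cur_density * len(members))
            if new_d >= density_threshold and cp >= cp_min:
                e_frontier = sum(1 for w in g.neighbors(v) if w in frontier)
                key = (-e_in, -e_frontier, str(v))
                if best_key is None or key < best_key:
                    best, best_key = v, key
        if best is None:
            break
        e_in = frontier.pop(best)
        members.add(best)
        n_edges += e_in
        for w in g.neighbors(best):
            if w not in members:
                frontier[w] = frontier.get(w, 0) + 1
    return members, n_edges


# ---------------------------------------------------------------------------
# enrichment, SScore, ROC, density selection

def fisher_cluster_enrichment(cluster: Cluster, graph: nx.Graph) -> float:
    """One-sided Fisher exact p for HDEG enrichment in the cluster.

    2x2 table: in-cluster / out-of-cluster x HDEG / non-HDEG over the full
    node universe of the network.
    """
    hdegs = {v for v, d in graph.nodes(data=True) if d.get("label") == "HDEG"}
    in_h = len(cluster.members & hdegs)
    in_o = len(cluster.members) - in_h
    out_h = len(hdegs) - in_h
    out_o = graph.number_of_nodes() - len(cluster.members) - out_h
    _, p = stats.fisher_exact([[in_h, in_o], [out_h, out_o]], alternative="greater")
    return float(p)


def sscore(p_value: float) -> float:
    """Cluster significance score ``-log10(p)``; p is capped at 1e-300."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value outside [0,1]: {p_value}")
    return -math.log10(max(p_value, P_FLOOR))


@dataclass
class GeneScore:
    symbol: str
    sscore: float
    is_hdeg: bool


def gene_scores(clusters: list[Cluster], graph: nx.Graph,
                aggregate: str = "max", universe: str = "all") -> list[GeneScore]:
    """Propagate cluster scores to genes.

    Each gene receives the best (or, optionally, summed) SScore over the
    clusters containing it; genes in no cluster score 0.  ``universe`` is
    ``"all"`` network genes (default, keeps the AUC comparable across
    densities with different cluster coverage) or ``"clustered"`` only.
    """
    per_gene: dict[str, float] = {}
    for c in clusters:
        s = sscore(c.p_value)
        for gsym in c.members:
            if aggregate == "sum":
                per_gene[gsym] = per_gene.get(gsym, 0.0) + s
            else:
                per_gene[gsym] = max(per_gene.get(gsym, 0.0), s)
    nodes = graph.nodes if universe == "all" else per_gene
    return [
        GeneScore(symbol=v, sscore=per_gene.get(v, 0.0),
                  is_hdeg=graph.nodes[v].get("label") == "HDEG")
        for v in sorted(nodes)
    ]


def roc_auc(scores: list[GeneScore]) -> float:
    """AUC of SScore for HDEG vs non-HDEG, i.e. the tie-corrected
    Mann-Whitney pairwise-ordering probability (ties count 1/2)."""
    pos = [s.sscore for s in scores if s.is_hdeg]
    neg = [s.sscore for s in scores if not s.is_hdeg]
    if not pos or not neg:
        raise ValueError("ROC needs at least one HDEG and one non-HDEG score")
    ranks = stats.rankdata(pos + neg)  # mid-ranks
    r_pos = float(np.sum(ranks[: len(pos)]))
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


@dataclass
class ClusteringRun:
    density_threshold: float
    clusters: list[Cluster]
    auc: float = float("nan")

    @property
    def total_cluster(self) -> int:
        return len(self.clusters)

    @property
    def max_size(self) -> int:
        return max((len(c) for c in self.clusters), default=0)

    @property
    def avg_size(self) -> float:
        return float(np.mean([len(c) for c in self.clusters])) if self.clusters else 0.0

    @property
    def significant_count(self) -> int:
        return sum(1 for c in self.clusters if c.adj_p < 0.05)


def cluster_grid(graph: nx.Graph, density_grid, cp_min: float = 0.5, min_size: int = 2,
                 aggregate: str = "max", universe: str = "all") -> list[ClusteringRun]:
    """Cluster at each density threshold, score clusters by HDEG enrichment
    and attach the ROC AUC of the resulting gene scores."""
    runs = []
    for d in density_grid:
        clusters = dpcluso_cluster(graph, d, cp_min=cp_min, min_size=min_size)
        for c in clusters:
            c.p_value = fisher_cluster_enrichment(c, graph)
        scores = gene_scores(clusters, graph, aggregate=aggregate, universe=universe)
        auc = roc_auc(scores)
        runs.append(ClusteringRun(density_threshold=d, clusters=clusters, auc=auc))
    return runs


def select_density(runs: list[ClusteringRun]) -> ClusteringRun:
    """Run with the highest AUC; ties break to the lower density (larger,
    fewer clusters)."""
    if not runs:
        raise ValueError("no clustering runs supplied")
    return min(runs, key=lambda r: (-r.auc, r.density_threshold))


def call_modules_and_candidates(run: ClusteringRun, graph: nx.Graph,
                                fdr_max: float = 0.05) -> tuple[list[Cluster], set[str]]:
    """BH-correct the cluster p-values and call significant disease modules.

    Candidates are the union of significant-module members minus
    HDEG-labelled genes.
    """
    if not run.clusters:
        return [], set()
    raw = np.array([c.p_value for c in run.clusters])
    adj = stats.false_discovery_control(raw, method="bh")
    for c, a in zip(run.clusters, adj):
        c.adj_p = float(a)
    significant = [c for c in run.clusters if c.adj_p < fdr_max]
    members = set().union(*(c.members for c in significant)) if significant else set()
    hdegs = {v for v, d in graph.nodes(data=True) if d.get("label") == "HDEG"}
    return significant, members - hdegs
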