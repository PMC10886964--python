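"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the shape of the study inputs:

* a scale-free background interactome (preferential attachment) with
  planted near-clique modules, a designated subset of which are *disease
  modules*;
* a curated disease-gene list concentrated in the disease modules, with a
  small background leak;
* differential-expression tables whose significant rows are drawn
  preferentially from disease-module members, with duplicate probes
  injected to exercise probe collapse;
* bipartite miRNA-target edge sets with planted miRNA-regulatory modules
  wired to disease genes, served as three partially overlapping "sources"
  (independent 70% subsamples of one master edge set).

Every generator is a pure function of its parameters and seed, and returns
ground-truth labels sufficient to score recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import write_edge_list, write_gene_list, write_table
from .mirna import BipartiteMTI


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic scenario."""

    planted_modules: list[set[str]] = field(default_factory=list)
    module_densities: list[float] = field(default_factory=list)
    disease_module_idx: list[int] = field(default_factory=list)
    disease_genes: set[str] = field(default_factory=set)
    de_genes: list[set[str]] = field(default_factory=list)
    planted_mrms: list[tuple[set[str], set[str]]] = field(default_factory=list)
    tf_genes: set[str] = field(default_factory=set)

    @property
    def disease_module_members(self) -> set[str]:
        return set().union(*(self.planted_modules[i] for i in self.disease_module_idx)) \
            if self.disease_module_idx else set()

    def to_json(self, path: str | Path) -> None:
        data = {
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "module_densities": self.module_densities,
            "disease_module_idx": self.disease_module_idx,
            "disease_genes": sorted(self.disease_genes),
            "de_genes": [sorted(s) for s in self.de_genes],
            "planted_mrms": [[sorted(m), sorted(g)] for m, g in self.planted_mrms],
            "tf_genes": sorted(self.tf_genes),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_ppi(n_nodes: int = 300, n_modules: int = 6, module_size: int = 10,
                 module_density: float = 0.95, background_attach: int = 2,
                 seed: int = 0, n_disease_modules: int | None = None,
                 disease_member_frac: float = 0.7,
                 disease_leak: float = 0.05,
                 module_attach: int = 8) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free background with planted high-density modules.

    A preferential-attachment graph is overlaid with ``n_modules`` disjoint
    near-cliques of ``module_size`` nodes wired to at least
    ``module_density`` internal density.  Each module is then embedded in
    its surroundings: ``module_attach`` distinct background nodes are each
    wired to about half of the module's members, so modules are dense cores
    of a connected periphery rather than isolated near-cliques — at
    permissive cluster densities this periphery rides along with the core
    and dilutes it, at strict densities it cannot.  The first
    ``n_disease_modules`` (default: half)
    are disease modules; the disease-gene list samples
    ``disease_member_frac`` of the members of each disease module plus a
    ``disease_leak`` fraction of background leak genes.
    """
    if module_size < 3:
        raise ValueError("module_size must be >= 3")
    if not 0.0 < module_density <= 1.0:
        raise ValueError("module_density must lie in (0,1]")
    if n_modules * module_size > n_nodes:
        raise ValueError(
            f"{n_modules} modules of size {module_size} exceed {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    g0 = nx.barabasi_albert_graph(n_nodes, background_attach,
                                  seed=int(rng.integers(2**31)))
    mapping = {i: _gene_name(i) for i in g0.nodes}
    graph = nx.relabel_nodes(g0, mapping)

    nodes = np.array(sorted(graph.nodes))
    chosen = rng.choice(len(nodes), size=n_modules * module_size, replace=False)
    truth = SyntheticTruth()
    pair_count = module_size * (module_size - 1) // 2
    need = math.ceil(module_density * pair_count)
    for k in range(n_modules):
        members = sorted(nodes[chosen[k * module_size:(k + 1) * module_size]])
        pairs = [(a, b) for i, a in enumerate(members) for b in members[i + 1:]]
        pick = rng.choice(pair_count, size=need, replace=False)
        graph.add_edges_from(pairs[i] for i in pick)
        sub = graph.subgraph(members)
        truth.planted_modules.append(set(members))
        truth.module_densities.append(2 * sub.number_of_edges() / (module_size * (module_size - 1)))

    planted_all = set().union(*truth.planted_modules) if truth.planted_modules else set()
    background_pool = sorted(set(graph.nodes) - planted_all)
    for members in truth.planted_modules:
        mem = sorted(members)
        hooks = rng.choice(len(background_pool), size=min(module_attach, len(background_pool)),
                           replace=False)
        for h in hooks:
            v = background_pool[h]
            k = int(rng.integers(module_size // 2, module_size // 2 + 2))
            for t in rng.choice(module_size, size=k, replace=False):
                graph.add_edge(v, mem[t])

    if n_disease_modules is None:
        n_disease_modules = max(1, n_modules // 2)
    truth.disease_module_idx = list(range(n_disease_modules))
    # stratified: every disease module contributes the same fraction of its
    # members to the curated list, so none is left effectively unlabelled
    disease: set[str] = set()
    n_core = 0
    for i in truth.disease_module_idx:
        mod = sorted(truth.planted_modules[i])
        n_pick = max(1, round(disease_member_frac * len(mod)))
        n_core += n_pick
        disease |= set(np.array(mod)[rng.choice(len(mod), size=n_pick, replace=False)])
    background = sorted(set(graph.nodes) - set().union(*truth.planted_modules))
    n_leak = round(disease_leak * n_core)
    if n_leak:
        disease |= set(np.array(background)[rng.choice(len(background), size=n_leak,
                                                       replace=False)])
    truth.disease_genes = disease
    return graph, truth


def generate_de_tables(graph: nx.Graph, truth: SyntheticTruth, n_datasets: int = 3,
                       frac_signal: float = 0.9, noise: float = 0.1,
                       seed: int = 0, dup_frac: float = 0.05) -> list[pd.DataFrame]:
    """DE tables whose significant rows concentrate in disease modules.

    Each gene of the graph gets one row per dataset (plus duplicate probes
    for a ``dup_frac`` fraction of genes).  Disease-module members are
    significant with probability ``frac_signal``; background genes with
    probability ``noise``.  Significant rows satisfy adjP <= 0.05 and
    |logFC| >= 0.5 (signal magnitudes |N(1, 0.25)| + 0.5); non-significant
    rows fail at least one threshold.  Flags, not simulated tests, drive
    the p-values: downstream stages consume thresholded flags only.
    """
    if not (0.0 <= frac_signal <= 1.0 and 0.0 <= noise <= 1.0):
        raise ValueError("frac_signal and noise must lie in [0,1]")
    rng = np.random.default_rng(seed)
    signal_pool = truth.disease_module_members
    genes = sorted(graph.nodes)
    tables: list[pd.DataFrame] = []
    truth.de_genes = []
    probe_counter = 0
    for _ in range(n_datasets):
        rows = []
        sig_set: set[str] = set()
        for gsym in genes:
            p_sig = frac_signal if gsym in signal_pool else noise
            n_probes = 1
            if rng.random() < dup_frac:
                n_probes = int(rng.integers(2, 4))
            significant = rng.random() < p_sig
            if significant:
                sig_set.add(gsym)
            for _k in range(n_probes):
                probe_counter += 1
                probe = f"P{probe_counter:06d}"
                if significant:
                    adjp = rng.uniform(0.0, 0.05)
                    p = adjp * rng.uniform(0.0, 1.0)
                    lfc = rng.choice([-1.0, 1.0]) * (abs(rng.normal(1.0, 0.25)) + 0.5)
                else:
                    if rng.random() < 0.5:
                        adjp = rng.uniform(0.0501, 1.0)
                        lfc = rng.uniform(-2.0, 2.0)
                    else:
                        adjp = rng.uniform(0.0, 1.0)
                        lfc = rng.uniform(-0.499, 0.499)
                    p = adjp * rng.uniform(0.0, 1.0)
                rows.append((probe, gsym, round(float(lfc), 4), round(float(p), 6),
                             round(float(adjp), 6), round(float(rng.uniform(4.0, 14.0)), 3)))
        tables.append(pd.DataFrame(rows, columns=["probe", "symbol", "logFC", "p",
                                                  "adjP", "mean_expr"]))
        truth.de_genes.append(sig_set)
    return tables


def _mirna_name(i: int) -> str:
    return f"hsa-miR-{i + 100}-5p"


def generate_mti(n_mirna: int = 60, n_genes: int = 200, n_mrms: int = 8,
                 mrm_shape: tuple[int, int] = (3, 6), mrm_fill: float = 0.9,
                 background_edges: int = 300, disease_overlap: int = 2,
                 seed: int = 0, gene_pool: Sequence[str] | None = None,
                 disease_genes: set[str] | None = None,
                 truth: SyntheticTruth | None = None,
                 n_sources: int = 3, source_keep: float = 0.7
                 ) -> tuple[dict[str, BipartiteMTI], SyntheticTruth]:
    """Bipartite MTI edge sets with planted miRNA-regulatory modules.

    Each planted MRM pairs ``mrm_shape[0]`` miRNAs with ``mrm_shape[1]``
    genes (``disease_overlap`` of them drawn from the disease-gene list)
    at edge fill >= ``mrm_fill``.  The master edge set (planted MRMs plus
    ``background_edges`` random pairs) is served as ``n_sources``
    independent ``source_keep`` subsamples, mimicking partially
    overlapping interaction databases.
    """
    a, b = mrm_shape
    if not 0.0 < mrm_fill <= 1.0:
        raise ValueError("mrm_fill must lie in (0,1]")
    if a > n_mirna or b > n_genes:
        raise ValueError(f"mrm_shape {mrm_shape} exceeds n_mirna={n_mirna} or n_genes={n_genes}")
    if n_mrms * a > n_mirna:
        raise ValueError("planted MRMs need more miRNAs than available")
    if disease_overlap > b:
        raise ValueError("disease_overlap cannot exceed the MRM gene-side size")
    rng = np.random.default_rng(seed)
    if gene_pool is None:
        gene_pool = [f"GM{i:04d}" for i in range(n_genes)]
    gene_pool = sorted(gene_pool)[:n_genes]
    disease_genes = set(disease_genes or set())
    disease_in_pool = sorted(disease_genes & set(gene_pool)) or sorted(disease_genes)
    if disease_overlap > 0 and not disease_in_pool:
        raise ValueError("disease_overlap > 0 requires a disease-gene list")
    nondisease = [g for g in gene_pool if g not in disease_genes]
    mirnas = [_mirna_name(i) for i in range(n_mirna)]

    if truth is None:
        truth = SyntheticTruth(disease_genes=disease_genes)
    master: set[tuple[str, str]] = set()
    mirna_order = rng.permutation(n_mirna)
    for k in range(n_mrms):
        mset = [mirnas[i] for i in mirna_order[k * a:(k + 1) * a]]
        gset: list[str] = []
        if disease_overlap:
            gset += list(np.array(disease_in_pool)[
                rng.choice(len(disease_in_pool), size=min(disease_overlap, len(disease_in_pool)),
                           replace=False)])
        n_rest = b - len(gset)
        gset += list(np.array(nondisease)[rng.choice(len(nondisease), size=n_rest,
                                                     replace=False)])
        pairs = [(m, g) for m in mset for g in gset]
        pick = rng.choice(len(pairs), size=math.ceil(mrm_fill * len(pairs)), replace=False)
        master |= {pairs[i] for i in pick}
        truth.planted_mrms.append((set(mset), set(gset)))
    for _ in range(background_edges):
        m = mirnas[int(rng.integers(n_mirna))]
        g = gene_pool[int(rng.integers(len(gene_pool)))]
        master.add((m, g))

    ordered = sorted(master)
    sources: dict[str, BipartiteMTI] = {}
    for s in range(n_sources):
        keep = rng.random(len(ordered)) < source_keep
        name = f"source{s + 1}"
        sources[name] = BipartiteMTI(source_name=name,
                                     edges={e for e, k in zip(ordered, keep) if k})
    if not truth.tf_genes:
        n_tf = max(1, round(0.15 * len(gene_pool)))
        truth.tf_genes = set(np.array(gene_pool)[rng.choice(len(gene_pool), size=n_tf,
                                                            replace=False)])
    return sources, truth


def write_synthetic_inputs(out_dir: str | Path, seed: int = 0, **kwargs) -> SyntheticTruth:
    """Generate one coherent scenario and write every pipeline input file.

    Writes ``ppi_edges.tsv``, ``de_<k>.tsv``, ``mti_<source>.tsv``,
    ``disease_genes.txt``, ``tf_genes.txt`` and ``truth.json`` under
    ``out_dir``.  Keyword arguments are forwarded to the individual
    generators by prefix (``ppi_``, ``de_``, ``mti_``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pick = lambda prefix: {k[len(prefix):]: v for k, v in kwargs.items()
                           if k.startswith(prefix)}
    graph, truth = generate_ppi(seed=seed, **pick("ppi_"))
    tables = generate_de_tables(graph, truth, seed=seed + 1, **pick("de_"))
    sources, truth = generate_mti(seed=seed + 2, gene_pool=sorted(graph.nodes),
                                  disease_genes=truth.disease_genes, truth=truth,
                                  **pick("mti_"))
    write_edge_list(out / "ppi_edges.tsv", {frozenset(e) for e in graph.edges},
                    header=("proteinA", "proteinB"))
    for k, t in enumerate(tables, start=1):
        write_table(out / f"de_{k}.tsv", t)
    for name, mti in sources.items():
        write_edge_list(out / f"mti_{name}.tsv", mti.edges, header=("mirna", "gene"))
    write_gene_list(out / "disease_genes.txt", truth.disease_genes)
    write_gene_list(out / "tf_genes.txt", truth.tf_genes)
    truth.to_json(out / "truth.json")
    return truth
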