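"""miRNA biomarker screening on a disease-specific MTI reference network.

Two regulatory-pattern statistics are computed per miRNA on the union MTI
network: NSR, the number of single-line regulations (targets whose only
regulator in the network is this miRNA), and TFP, the number (and fraction)
of its targets that are transcription factors.  A candidate miRNA is called
a potential biomarker when both statistics are significantly high relative
to the network-wide distribution, measured by a right-tail empirical
probability p = #{j : value_j >= value_i} / M over all M miRNAs in the
network (ties counted as at-least-as-extreme, so p >= 1/M and a fully tied
statistic gives p = 1 for everyone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mirna import BipartiteMTI


@dataclass
class BiomarkerRecord:
    mirna: str
    out_degree: int
    nsr: int
    tfp_count: int
    tfp_pct: float
    p_nsr: float = float("nan")
    p_tfp: float = float("nan")
    is_candidate: bool = False


def build_reference_network(edge_sets: list[BipartiteMTI],
                            source_name: str = "union") -> BipartiteMTI:
    """Deduplicated union of miRNA-target pair sets."""
    if not edge_sets:
        raise ValueError("at least one MTI edge set is required")
    edges: set[tuple[str, str]] = set()
    for es in edge_sets:
        edges |= es.edges
    return BipartiteMTI(source_name=source_name, edges=edges)


def nsr_tfp(network: BipartiteMTI, tf_genes: set[str]) -> list[BiomarkerRecord]:
    """NSR and TFP statistics for every miRNA of the network.

    NSR(m) counts targets g of m whose regulator count in the whole
    network is exactly 1; summed over miRNAs this equals the number of
    single-regulator targets.  TFP is reported both as a count and as a
    fraction of the miRNA's out-degree, since both conventions circulate.
    """
    if not network.edges:
        raise ValueError("reference MTI network is empty")
    targets: dict[str, set[str]] = {}
    regulators: dict[str, int] = {}
    for m, g in network.edges:
        targets.setdefault(m, set()).add(g)
        regulators[g] = regulators.get(g, 0) + 1
    records = []
    for m in sorted(targets):
        tg = targets[m]
        nsr = sum(1 for g in tg if regulators[g] == 1)
        tfc = len(tg & tf_genes)
        records.append(BiomarkerRecord(
            mirna=m, out_degree=len(tg), nsr=nsr,
            tfp_count=tfc, tfp_pct=tfc / len(tg)))
    return records


def _right_tail_p(values: np.ndarray) -> np.ndarray:
    """Empirical right-tail probability of each value within the vector."""
    m = len(values)
    return np.array([(values >= v).sum() / m for v in values])


def screen(records: list[BiomarkerRecord], candidate_mirnas: set[str],
           alpha: float = 0.05) -> list[BiomarkerRecord]:
    """Screen candidate miRNAs for jointly high NSR and TFP.

    p-values are computed against the full network-wide distributions; the
    returned list contains one record per candidate present in the
    network, sorted by (p_nsr + p_tfp, name), with ``is_candidate`` set
    when both p-values are at or below ``alpha``.
    """
    nsr_vals = np.array([r.nsr for r in records], dtype=float)
    tfp_vals = np.array([r.tfp_count for r in records], dtype=float)
    p_nsr = _right_tail_p(nsr_vals)
    p_tfp = _right_tail_p(tfp_vals)
    by_name: dict[str, BiomarkerRecord] = {}
    for r, pn, pt in zip(records, p_nsr, p_tfp):
        r.p_nsr = float(pn)
        r.p_tfp = float(pt)
        r.is_candidate = bool(pn <= alpha and pt <= alpha)
        by_name[r.mirna] = r
    out = []
    for m in sorted(candidate_mirnas):
        if m not in by_name:
            warnings.warn(f"candidate miRNA {m} absent from the reference network; skipped",
                          stacklevel=2)
            continue
        out.append(by_name[m])
    out.sort(key=lambda r: (r.p_nsr + r.p_tfp, r.mirna))
    return out
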