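"""Gene–drug interaction networks and their biological coherence.

The drug-response-related CSL (or CSV) network joins gene–gene edges from
interactions with drug–gene edges from the pharmacogenomic filter.  Its
coherence is quantified against a protein–protein interaction (PPI) graph by
a permutation null: random gene pairs drawn from the PPI-covered universe,
with the empirical p computed with a +1 pseudocount so it is never zero.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import PPIGraph
from .stats import TestResult, chi_square_2x2

__all__ = [
    "build_network",
    "degree_table",
    "ppi_overlap_test",
    "cancer_gene_enrichment",
    "hub_subnetwork",
    "network_summary",
]


def build_network(records) -> nx.Graph:
    """Union of gene–gene and drug–gene edges from drug-interaction records.

    Node attribute ``kind`` is "gene" or "drug"; gene–gene edges carry
    ``itype`` and ``tissue`` attributes, duplicates are merged.
    """
    g = nx.Graph()
    for rec in records:
        ir = rec.interaction
        for gene in (ir.target, ir.partner):
            g.add_node(gene, kind="gene")
        g.add_edge(ir.target, ir.partner, etype="gene-gene",
                   itype=ir.itype.value, tissue=ir.tissue)
        g.add_node(rec.drug, kind="drug")
        g.add_edge(rec.drug, ir.target, etype="drug-gene")
    return g


def gene_gene_edges(network: nx.Graph):
    return [
        (a, b) for a, b, d in network.edges(data=True) if d.get("etype") == "gene-gene"
    ]


def degree_table(network: nx.Graph) -> pd.Series:
    """Node degree over the union graph, descending (hubs first)."""
    deg = pd.Series(dict(network.degree()), dtype=int)
    return deg.sort_values(ascending=False)


def ppi_overlap_test(
    network: nx.Graph,
    ppi: PPIGraph,
    n_perm: int = 1000,
    seed: int = 0,
    max_indirect: int = 2,
) -> tuple[float, float]:
    """PPI contact rate of the network's gene pairs vs a permutation null.

    A pair is "in contact" when it is a PPI edge or connected by a path of
    length ≤ ``max_indirect`` (default 2: one shared neighbour).  The null
    draws the same number of distinct gene pairs uniformly from the genes
    having at least one PPI edge.  Returns ``(observed_rate, empirical_p)``
    with empirical_p = (1 + #{null rate ≥ observed}) / (1 + n_perm).
    """
    if len(ppi) == 0:
        raise ValueError("PPI graph is empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pairs = gene_gene_edges(network)
    if not pairs:
        raise ValueError("network has no gene-gene edges")

    def contact(a: str, b: str) -> bool:
        if ppi.has_edge(a, b):
            return True
        if max_indirect >= 2:
            na, nb = ppi.neighbors(a), ppi.neighbors(b)
            if na and nb and not na.isdisjoint(nb):
                return True
        return False

    observed = float(np.mean([contact(a, b) for a, b in pairs]))
    universe = sorted(ppi.genes)
    rng = np.random.default_rng(seed)
    k = len(pairs)
    n_ge = 0
    for _ in range(n_perm):
        drawn: set = set()
        while len(drawn) < k:
            i, j = rng.integers(0, len(universe), size=2)
            if i == j:
                continue
            key = (i, j) if i < j else (j, i)
            drawn.add(key)
        rate = float(np.mean([contact(universe[i], universe[j]) for i, j in drawn]))
        if rate >= observed:
            n_ge += 1
    empirical_p = (1 + n_ge) / (1 + n_perm)
    return observed, empirical_p


def cancer_gene_enrichment(network_crs, background_crs, cancer_genes) -> TestResult:
    """Chi-square test: cancer-gene fraction of in-network CRs vs the
    remaining background CRs (2×2, no continuity correction)."""
    network_crs, background_crs = set(network_crs), set(background_crs)
    cancer_genes = set(cancer_genes)
    if not network_crs:
        raise ValueError("empty network CR set")
    if not network_crs <= background_crs:
        raise ValueError("network CRs must be a subset of background CRs")
    rest = background_crs - network_crs
    a = len(network_crs & cancer_genes)
    b = len(network_crs) - a
    c = len(rest & cancer_genes)
    d = len(rest) - c
    return chi_square_2x2(a, b, c, d)


def hub_subnetwork(network: nx.Graph, gene: str) -> nx.Graph:
    """Induced subgraph of a gene, its neighbours, and their incident edges."""
    if gene not in network:
        raise ValueError(f"gene {gene!r} not in network")
    nodes = {gene} | set(network.neighbors(gene))
    return network.subgraph(nodes).copy()


def network_summary(network: nx.Graph) -> dict:
    genes = [n for n, d in network.nodes(data=True) if d.get("kind") == "gene"]
    drugs = [n for n, d in network.nodes(data=True) if d.get("kind") == "drug"]
    gg = gene_gene_edges(network)
    return {
        "n_genes": len(genes),
        "n_drugs": len(drugs),
        "n_gene_gene_edges": len(gg),
        "n_drug_gene_edges": network.number_of_edges() - len(gg),
    }
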