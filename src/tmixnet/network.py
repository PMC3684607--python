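"""Partial-correlation gene networks, subnetworks and biomarker selection.

Each fitted component's inverse scale matrix Omega defines an undirected
graph: the partial correlation between genes j and l given all others is

    rho_jl = -omega_jl / sqrt(omega_jj * omega_ll)

and an edge is drawn when |rho_jl| exceeds a threshold.  A *subnetwork* is a
connected component with at least two genes.  Biomarkers are selected by
three rules, in order of precedence:

  (a) subnetworks containing at least one mean-based discriminative gene
      (nonzero fitted mean in some cluster - on standardized data a nonzero
      mean is exactly a cluster-specific mean);
  (b) remaining subnetworks whose internal edge structure differs between
      clusters (symmetric difference of the edge sets induced by the
      subnetwork's genes is non-empty for some cluster pair);
  (c) isolated discriminative genes, reported as singleton biomarkers.

Every gene occurring in a selected subnetwork or singleton is "selected
informative".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GeneNetwork",
    "Subnetwork",
    "BiomarkerReport",
    "partial_correlations",
    "build_network",
    "find_subnetworks",
    "discriminative_genes",
    "networks_from_model",
    "identify_biomarkers",
]


@dataclass(frozen=True)
class GeneNetwork:
    """Partial-correlation graph of one cluster."""

    cluster: int
    genes: tuple
    edges: dict  # (gene_a, gene_b) with a < b -> partial correlation
    threshold: float

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for (a, b), rho in self.edges.items():
            g.add_edge(a, b, partial_correlation=rho)
        return g

    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            dict(gene_a=a, gene_b=b, cluster=self.cluster, partial_correlation=rho)
            for (a, b), rho in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "cluster", "partial_correlation"])


@dataclass(frozen=True)
class Subnetwork:
    """A connected component of a cluster network (>= 2 genes)."""

    cluster: int
    genes: tuple
    edges: tuple
    has_discriminative: bool = False
    structure_specific: bool = False


@dataclass
class BiomarkerReport:
    """Outcome of the three-rule selection."""

    subnetworks: list = field(default_factory=list)
    singletons: tuple = ()
    rules: dict = field(default_factory=dict)  # gene -> 'a' | 'b' | 'c'

    @property
    def selected_genes(self) -> frozenset:
        return frozenset(self.rules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.rules.items()), columns=["gene", "rule"]
        )


def partial_correlations(omega: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix from a precision matrix; unit diagonal."""
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if (d <= 0).any():
        raise ValueError("precision diagonal must be positive")
    scale = np.sqrt(d)
    rho = -omega / np.outer(scale, scale)
    np.fill_diagonal(rho, 1.0)
    return rho


def build_network(omega, threshold: float = 0.01, gene_ids=None, cluster: int = 0) -> GeneNetwork:
    """Edges where the absolute partial correlation exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    rho = partial_correlations(omega)
    p = rho.shape[0]
    if gene_ids is None:
        gene_ids = tuple(f"gene_{j}" for j in range(p))
    gene_ids = tuple(gene_ids)
    edges = {}
    iu, ju = np.triu_indices(p, k=1)
    hit = np.abs(rho[iu, ju]) > threshold
    for i, j in zip(iu[hit], ju[hit]):
        edges[(gene_ids[i], gene_ids[j])] = float(rho[i, j])
    return GeneNetwork(cluster=cluster, genes=gene_ids, edges=edges, threshold=threshold)


def find_subnetworks(net: GeneNetwork):
    """Connected components with >= 2 genes, plus the isolated genes.

    Returns (subnetworks, isolated_genes).
    """
    g = net.to_graph()
    subs, isolated = [], []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            isolated.extend(comp)
            continue
        genes = tuple(sorted(comp))
        edges = tuple(sorted(e for e in net.edges if e[0] in comp and e[1] in comp))
        subs.append(Subnetwork(cluster=net.cluster, genes=genes, edges=edges))
    return subs, tuple(sorted(isolated))


def discriminative_genes(model, gene_ids=None) -> frozenset:
    """Genes with a nonzero fitted mean in at least one cluster."""
    means = np.asarray(model.means_ if hasattr(model, "means_") else model)
    if gene_ids is None:
        gene_ids = getattr(model, "gene_ids_", None) or tuple(
            f"gene_{j}" for j in range(means.shape[1])
        )
    nz = np.any(means != 0, axis=0)
    return frozenset(g for g, flag in zip(gene_ids, nz) if flag)


def networks_from_model(model, threshold: float = 0.01, gene_ids=None):
    """One :class:`GeneNetwork` per fitted cluster."""
    if gene_ids is None:
        gene_ids = getattr(model, "gene_ids_", None)
    return [
        build_network(model.precisions_[k], threshold=threshold,
                      gene_ids=gene_ids, cluster=k)
        for k in range(model.means_.shape[0])
    ]


def _induced_edges(net: GeneNetwork, genes: frozenset) -> frozenset:
    return frozenset(e for e in net.edges if e[0] in genes and e[1] in genes)


def identify_biomarkers(model, networks, gene_ids=None) -> BiomarkerReport:
    """Three-rule network-based biomarker selection (precedence a > b > c)."""
    if gene_ids is None:
        gene_ids = getattr(model, "gene_ids_", None)
    disc = discriminative_genes(model, gene_ids)
    report = BiomarkerReport()
    isolated_by_cluster = {}
    for net in networks:
        subs, isolated = find_subnetworks(net)
        isolated_by_cluster[net.cluster] = set(isolated)
        for sub in subs:
            genes = frozenset(sub.genes)
            if genes & disc:
                chosen = Subnetwork(sub.cluster, sub.genes, sub.edges,
                                    has_discriminative=True)
            else:
                induced = [_induced_edges(other, genes) for other in networks]
                differs = any(
                    induced[i] != induced[j]
                    for i in range(len(induced))
                    for j in range(i + 1, len(induced))
                )
                if not differs:
                    continue
                chosen = Subnetwork(sub.cluster, sub.genes, sub.edges,
                                    structure_specific=True)
            report.subnetworks.append(chosen)
            rule = "a" if chosen.has_discriminative else "b"
            for g in chosen.genes:
                prev = report.rules.get(g)
                if prev is None or (rule == "a" and prev != "a"):
                    report.rules[g] = rule
    # rule (c): discriminative genes isolated in every cluster network
    singles = []
    for g in sorted(disc):
        if g not in report.rules:
            report.rules[g] = "c"
            singles.append(g)
    report.singletons = tuple(singles)
    return report
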