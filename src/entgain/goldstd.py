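"""Gold-standard network assembly and manipulation.

Reference networks for evaluating inferred gene networks come from
heterogeneous sources — yeast two-hybrid protein-protein assays, Rosetta
stone fusion predictions, KEGG pathway co-membership, combined KEGG+GO
annotation. Before use each is restricted to the genes actually present
in the expression data; pairwise overlaps quantify how much the sources
agree, and edge-set intersections give smaller but higher-confidence
gold standards. Because such networks are typically scale-free, a hub
subnetwork (the top fraction of most-connected genes together with all
their incident edges) supports a separate evaluation of how well the
best-connected part of the network is recovered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import Network


@dataclass(frozen=True)
class OverlapSummary:
    """Pairwise overlap between two networks (genes and edges in common)."""

    shared_genes: int
    shared_edges: int
    genes_a: int
    genes_b: int
    edges_a: int
    edges_b: int


def restrict_to_expressed(net: Network, genes: Iterable[str]) -> Network:
    """Restrict a network to a gene set (e.g. the expressed genes).

    Keeps the genes in both the network and ``genes`` and the edges with
    both endpoints retained.
    """
    keep = set(genes) & set(net.genes)
    edges = {e for e in net.edges if e[0] in keep and e[1] in keep}
    return Network(frozenset(keep), frozenset(edges))


def overlap_stats(a: Network, b: Network) -> OverlapSummary:
    """Count the genes and unordered edges two networks share."""
    return OverlapSummary(
        shared_genes=len(a.genes & b.genes),
        shared_edges=len(a.edges & b.edges),
        genes_a=a.n_genes,
        genes_b=b.n_genes,
        edges_a=a.n_edges,
        edges_b=b.n_edges,
    )


def intersect_networks(nets: Sequence[Network]) -> Network:
    """Edge-set intersection of several networks.

    The result's gene universe is the set of endpoints of surviving
    edges (isolated genes cannot belong to an intersection defined on
    links), so a single-network "intersection" is that network restricted
    to its non-isolated genes.
    """
    if not nets:
        raise ValueError("intersect_networks needs at least one network")
    edges = set(nets[0].edges)
    for net in nets[1:]:
        edges &= net.edges
    genes = {g for e in edges for g in e}
    return Network(frozenset(genes), frozenset(edges))


def hub_genes(net: Network, fraction: float = 0.10) -> list[str]:
    """The ceil(fraction * n_genes) most-connected genes.

    Ties are broken deterministically by (degree descending, gene id
    ascending).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if net.n_genes == 0:
        raise ValueError("cannot take hubs of an empty network")
    deg = net.degrees()
    n_hubs = math.ceil(fraction * net.n_genes)
    ranked = sorted(deg, key=lambda g: (-deg[g], g))
    return ranked[:n_hubs]


def hub_subnetwork(net: Network, fraction: float = 0.10) -> Network:
    """Subnetwork of the hubs and their interactions.

    Hubs are the top ``fraction`` most-connected genes; the subnetwork
    keeps every edge with at least one hub endpoint. The gene universe
    is the endpoints of the kept edges, so with ``fraction=1.0`` it
    returns the input restricted to non-isolated genes.
    """
    hubs = set(hub_genes(net, fraction))
    edges = {e for e in net.edges if e[0] in hubs or e[1] in hubs}
    genes = {g for e in edges for g in e}
    return Network(frozenset(genes), frozenset(edges))
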