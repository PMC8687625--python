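"""Construction of the weighted disease network, the ingredient-target
bipartite network, and their merged disease-target network.

The disease network is the base PPI induced on the evidence genes; each gene
node is weighted by the product degree × relevance score × literature count,
with a multiplicative-identity default of 1.0 where a factor is missing or
zero so that the product never annihilates. The degree entering the weight is
the degree in the induced disease subgraph, not in the full base PPI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ValidationError
from .io import GeneEvidence

ROLE_GENE = "gene"
ROLE_INGREDIENT = "ingredient"


@dataclass
class WeightedNetwork:
    """Undirected simple graph whose nodes carry a role and a nonnegative weight."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node: str, role: str, weight: float = 0.0) -> None:
        if weight < 0:
            raise ValidationError(f"node {node}: negative weight {weight}")
        self.graph.add_node(node, role=role, weight=float(weight))

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValidationError(f"self-loop on {a}")
        if a not in self.graph or b not in self.graph:
            raise ValidationError(f"edge ({a}, {b}) references an unknown node")
        self.graph.add_edge(a, b)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def weight(self, node: str) -> float:
        return self.graph.nodes[node]["weight"]

    def gene_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == ROLE_GENE}

    def ingredient_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == ROLE_INGREDIENT}


@dataclass
class ItNetwork:
    """Strictly bipartite ingredient-target network."""

    ingredients: set[str]
    targets: set[str]
    edges: set[tuple[str, str]]  # (ingredient_id, target_gene)

    def target_counts(self) -> dict[str, int]:
        counts = {i: 0 for i in self.ingredients}
        for iid, _ in self.edges:
            counts[iid] += 1
        return counts

    def targets_of(self, ingredient: str) -> set[str]:
        return {g for i, g in self.edges if i == ingredient}

    def n_associations(self) -> int:
        return len(self.edges)


@dataclass
class DiseaseNetworkResult:
    network: WeightedNetwork
    dropped_genes: list[str]  # evidence genes absent from the base PPI


def build_disease_network(
    base_ppi: Sequence[tuple[str, str]],
    evidence: Sequence[GeneEvidence],
    default_score: float = 1.0,
) -> DiseaseNetworkResult:
    """Induce the base PPI on the evidence genes and weight each node.

    weight(g) = degree_induced(g) × max(relevance, default) × max(n_reports, default);
    a missing relevance score or a zero report count contributes the
    multiplicative identity instead of annihilating the product.
    """
    if not base_ppi:
        raise ValidationError("base PPI is empty")
    G = nx.Graph()
    G.add_edges_from(base_ppi)
    G.remove_edges_from(nx.selfloop_edges(G))

    ev_by_gene = {e.gene: e for e in evidence}
    mapped = [g for g in ev_by_gene if g in G]
    dropped = sorted(g for g in ev_by_gene if g not in G)
    if not mapped:
        raise ValidationError("no mappable genes: evidence and PPI are disjoint")

    induced = G.subgraph(mapped)
    net = WeightedNetwork()
    for g in mapped:
        e = ev_by_gene[g]
        rel = e.relevance_score if e.relevance_score > 0 else default_score
        rep = e.n_reports if e.n_reports > 0 else default_score
        net.add_node(g, ROLE_GENE, weight=induced.degree(g) * rel * rep)
    for a, b in induced.edges:
        net.add_edge(a, b)
    return DiseaseNetworkResult(net, dropped)


def node_weight(degree: int, relevance: float | None, n_reports: int,
                default_score: float = 1.0) -> float:
    """The three-factor node weight on explicit inputs (for reporting/tests)."""
    rel = relevance if (relevance is not None and relevance > 0) else default_score
    rep = n_reports if n_reports > 0 else default_score
    return degree * rel * rep


def build_it_network(
    retained: Iterable[str],
    associations: Sequence[tuple[str, str]],
) -> ItNetwork:
    """Bipartite network over the retained ingredients and their targets.

    Associations naming an unretained but known pattern of ingredient id raise;
    retained ingredients with no association are excluded with a warning.
    """
    retained = list(dict.fromkeys(retained))
    retained_set = set(retained)
    edges: set[tuple[str, str]] = set()
    for iid, gene in associations:
        if iid not in retained_set:
            raise ValidationError(f"association references unknown ingredient {iid!r}")
        edges.add((iid, gene))
    with_targets = {i for i, _ in edges}
    lonely = [i for i in retained if i not in with_targets]
    if lonely:
        warnings.warn(
            f"{len(lonely)} retained ingredient(s) have no predicted target "
            f"and were excluded: {lonely[:5]}...", stacklevel=2,
        )
    targets = {g for _, g in edges}
    return ItNetwork(with_targets, targets, edges)


def mean_targets_per_ingredient(n_associations: int, n_ingredients: int) -> float:
    """Average target count per ingredient, rounded to 2 decimals."""
    if n_ingredients <= 0:
        raise ValidationError("n_ingredients must be positive")
    return round(n_associations / n_ingredients, 2)


def merge_networks(
    disease: WeightedNetwork,
    it: ItNetwork,
    base_ppi: Sequence[tuple[str, str]] | None = None,
) -> WeightedNetwork:
    """Union of the disease network and the I-T network.

    Gene nodes are merged by id and keep their disease weight where present
    (targets absent from the disease network get weight 0); ingredient nodes
    carry role ``ingredient`` and weight 0. When *base_ppi* is given, PPI
    edges among all mapped gene nodes (including targets outside the disease
    set) are retained as well.
    """
    merged = WeightedNetwork()
    for g in disease.gene_nodes():
        merged.add_node(g, ROLE_GENE, disease.weight(g))
    for g in it.targets:
        if g not in merged.graph:
            merged.add_node(g, ROLE_GENE, 0.0)
    for i in it.ingredients:
        merged.add_node(i, ROLE_INGREDIENT, 0.0)
    for a, b in disease.edges:
        merged.add_edge(a, b)
    for iid, g in it.edges:
        merged.add_edge(iid, g)
    if base_ppi is not None:
        genes = merged.gene_nodes()
        for a, b in base_ppi:
            if a != b and a in genes and b in genes:
                merged.add_edge(a, b)
    return merged


def network_summary(net: WeightedNetwork) -> Mapping[str, int]:
    return {
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        "n_gene_nodes": len(net.gene_nodes()),
        "n_ingredient_nodes": len(net.ingredient_nodes()),
    }
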