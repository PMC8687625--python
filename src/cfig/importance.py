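"""Node importance (Nim), functional response space (FRS) extraction, and
key-response-protein classification.

The Nim score of a node *s* is the product of its (unnormalized, undirected)
betweenness centrality and a squared community-proximity factor::

    Nim(s) = B(s) * [ (|C(s)|/|U|) * sum_{w in C(s), w != s} (D_s + 1 - dist(s, w)) / D_s ]^2

where ``C(s)`` is the community containing *s*, ``|U|`` the node count of the
whole network, ``dist`` the shortest-path length and ``D_s`` the eccentricity
of *s* within its community (the maximum of ``dist(s, w)`` over community
members). Unreachable community members are skipped; a singleton community
contributes factor 0. High Nim thus demands both broker position (many
shortest paths through *s*) and proximity to a large community.

The FRS keeps every node whose Nim reaches a threshold derived from the score
distribution: the midpoint of min and max (the literal rule), or the mean or
median (offered because the source narrative says "average"). Kept gene nodes
are classified as essential-common (disease gene and ingredient target),
disease-specific, or ingredient-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .networks import ROLE_GENE, WeightedNetwork

ThresholdMode = Literal["midpoint", "mean", "median"]
CommunityMethod = Literal["connected_components", "modularity"]

SUBTYPE_ESSENTIAL = "essential_common"
SUBTYPE_DISEASE = "disease_specific"
SUBTYPE_INGREDIENT = "ingredient_specific"


@dataclass(frozen=True)
class CommunityAssignment:
    membership: Mapping[str, int]
    method: str

    def community_of(self, node: str) -> frozenset[str]:
        cid = self.membership[node]
        return frozenset(n for n, c in self.membership.items() if c == cid)

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for n, c in self.membership.items():
            out.setdefault(c, set()).add(n)
        return out


@dataclass
class NimTable:
    betweenness_term: dict[str, float]
    community_factor: dict[str, float]
    nim: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": list(self.nim),
            "betweenness_term": [self.betweenness_term[n] for n in self.nim],
            "community_factor": [self.community_factor[n] for n in self.nim],
            "nim": list(self.nim.values()),
        }).sort_values("nim", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass
class FrsResult:
    threshold_value: float
    threshold_mode: str
    kept: set[str]
    subgraph: nx.Graph
    subtypes: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def assign_communities(
    network: WeightedNetwork,
    method: CommunityMethod = "connected_components",
    seed: int = 0,
) -> CommunityAssignment:
    """Total node → community map; components are deterministic, modularity seeded."""
    G = network.graph
    if G.number_of_nodes() == 0:
        raise ValidationError("cannot assign communities on an empty network")
    if method == "connected_components":
        groups = [sorted(c) for c in nx.connected_components(G)]
        groups.sort()
    elif method == "modularity":
        comms = nx.community.louvain_communities(G, seed=seed)
        groups = sorted(sorted(c) for c in comms)
    else:
        raise ValidationError(f"unknown community method {method!r}")
    membership = {n: cid for cid, grp in enumerate(groups) for n in grp}
    return CommunityAssignment(membership, method)


def compute_nim(network: WeightedNetwork, communities: CommunityAssignment) -> NimTable:
    """Per-node Nim scores; every node must appear in the community assignment."""
    G = network.graph
    missing = set(G.nodes) - set(communities.membership)
    if missing:
        raise ValidationError(f"nodes missing from community assignment: {sorted(missing)[:5]}")

    betw = nx.betweenness_centrality(G, normalized=False)

    n_total = G.number_of_nodes()
    factor: dict[str, float] = {}
    for cid, members in communities.communities().items():
        sub_nodes = members
        size = len(sub_nodes)
        for s in sub_nodes:
            others = sub_nodes - {s}
            if not others:
                factor[s] = 0.0
                continue
            dist = nx.single_source_shortest_path_length(G, s)
            reach = {w: d for w, d in dist.items() if w in others}
            if not reach:
                factor[s] = 0.0
                continue
            ecc = max(reach.values())
            total = sum(ecc + 1 - d for d in reach.values())
            factor[s] = (size / n_total) * (total / ecc)
    nim = {s: betw[s] * factor[s] ** 2 for s in G.nodes}
    for s, v in nim.items():
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"non-finite or negative Nim at node {s}")
    return NimTable(
        {s: betw[s] for s in G.nodes},
        {s: factor[s] ** 2 for s in G.nodes},
        nim,
    )


def baseline_centrality(
    network: WeightedNetwork,
    method: Literal["degree", "closeness", "clustering_coefficient"],
) -> dict[str, float]:
    """Textbook baselines the Nim score is compared against."""
    G = network.graph
    if G.number_of_nodes() == 0:
        raise ValidationError("empty network")
    if method == "degree":
        return {n: float(d) for n, d in G.degree()}
    if method == "closeness":
        # Wasserman-Faust component scaling on disconnected graphs (networkx default)
        return nx.closeness_centrality(G)
    if method == "clustering_coefficient":
        return nx.clustering(G)
    raise ValidationError(f"unknown centrality {method!r}")


def frs_threshold(scores: Mapping[str, float], mode: ThresholdMode) -> float:
    vals = np.asarray(list(scores.values()), dtype=float)
    if vals.size == 0:
        raise ValidationError("empty score table")
    if mode == "midpoint":
        return float((vals.min() + vals.max()) / 2.0)
    if mode == "mean":
        return float(vals.mean())
    if mode == "median":
        return float(np.median(vals))
    raise ValidationError(f"unknown threshold mode {mode!r}")


def select_frs(
    nim: NimTable,
    mode: ThresholdMode = "midpoint",
    network: WeightedNetwork | None = None,
    disease_genes: set[str] | None = None,
    target_genes: set[str] | None = None,
) -> FrsResult:
    """Keep nodes with Nim ≥ threshold (ties kept) and induce their subgraph.

    Subtype labels are attached when the disease-gene and target-gene sets
    are supplied along with the network.
    """
    thr = frs_threshold(nim.nim, mode)
    kept = {s for s, v in nim.nim.items() if v >= thr}
    sub = nx.Graph()
    sub.add_nodes_from(kept)
    subtypes: dict[str, str] = {}
    warns: list[str] = []
    if network is not None:
        sub = network.graph.subgraph(kept).copy()
        if disease_genes is not None and target_genes is not None:
            kept_genes = {n for n in kept if network.role(n) == ROLE_GENE}
            subtypes, warns = classify_key_proteins(
                kept_genes, disease_genes, target_genes, network
            )
    return FrsResult(thr, mode, kept, sub, subtypes, warns)


def classify_key_proteins(
    kept_genes: set[str],
    disease_genes: set[str],
    target_genes: set[str],
    network: WeightedNetwork | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Partition kept gene nodes into the three key-response-protein subtypes."""
    subtypes: dict[str, str] = {}
    warns: list[str] = []
    reachable_from_ingredient: set[str] = set()
    if network is not None:
        G = network.graph
        for i in network.ingredient_nodes():
            if i in G:
                reachable_from_ingredient |= nx.node_connected_component(G, i)
    for g in sorted(kept_genes):
        in_d, in_t = g in disease_genes, g in target_genes
        if in_d and in_t:
            subtypes[g] = SUBTYPE_ESSENTIAL
        elif in_d:
            subtypes[g] = SUBTYPE_DISEASE
        elif in_t:
            subtypes[g] = SUBTYPE_INGREDIENT
        else:
            subtypes[g] = SUBTYPE_INGREDIENT
            if network is not None and g not in reachable_from_ingredient:
                warns.append(
                    f"{g}: in neither disease nor target set and not reachable "
                    "from any ingredient"
                )
    return subtypes, warns


def compute_uet(disease_genes: set[str], target_genes: set[str]) -> set[str]:
    """Un-optimized effective targets: the plain intersection of the two sets."""
    if not disease_genes or not target_genes:
        raise ValidationError("both gene sets must be nonempty")
    return set(disease_genes) & set(target_genes)
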