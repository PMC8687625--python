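#!/usr/bin/env python
"""Build the weighted disease network, the ingredient-target bipartite
network, and their merged disease-target network for the simulated study.

Node weight in the disease network is degree × relevance score × report
count; the merged network keeps PPI edges among all mapped genes.
"""

import warnings
from pathlib import Path

import pandas as pd

from cfig import io as cio
from cfig.networks import (
    build_disease_network,
    build_it_network,
    mean_targets_per_ingredient,
    merge_networks,
    network_summary,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    warnings.filterwarnings("ignore", message=".*no predicted target.*")
    study = RESULTS / "study"
    evidence = cio.read_evidence(study / "evidence.tsv")
    base_ppi = cio.read_network(study / "ppi.tsv")
    associations = cio.read_associations(study / "associations.tsv")
    decisions = pd.read_csv(RESULTS / "filter_decisions.tsv", sep="\t")
    retained = list(decisions.loc[decisions["retained"], "ingredient_id"])

    res = build_disease_network(base_ppi, evidence)
    disease = res.network
    print(f"disease network: {network_summary(disease)} "
          f"({len(res.dropped_genes)} evidence genes unmapped)")
    top = max(disease.nodes, key=disease.weight)
    print(f"heaviest node: {top} (weight {disease.weight(top):,.2f})")

    assoc = [(i, g) for i, g in associations if i in set(retained)]
    it = build_it_network(retained, assoc)
    print(f"I-T network: {len(it.ingredients)} ingredients, "
          f"{len(it.targets)} targets, {it.n_associations()} associations "
          f"(mean {mean_targets_per_ingredient(it.n_associations(), len(it.ingredients))} "
          f"targets/ingredient)")

    merged = merge_networks(disease, it, base_ppi)
    print(f"merged disease-target network: {network_summary(merged)}")

    nodes = pd.DataFrame([{"node": n, "role": merged.role(n),
                           "weight": merged.weight(n)} for n in sorted(merged.nodes)])
    nodes.to_csv(RESULTS / "merged_nodes.tsv", sep="\t", index=False)
    edges = sorted((min(a, b), max(a, b)) for a, b in merged.edges)
    pd.DataFrame(edges, columns=["node_a", "node_b"]).to_csv(
        RESULTS / "merged_edges.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
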