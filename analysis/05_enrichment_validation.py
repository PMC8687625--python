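#!/usr/bin/env python
"""Validate the key response proteins against the un-optimized effective
targets (UET): gene-level coverage plus enriched-term coverage over the
study's annotation collection (exact hypergeometric test, p < 0.05).
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from cfig import io as cio
from cfig.enrichment import enrich, evaluate_frs
from cfig.importance import compute_uet

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    warnings.filterwarnings("ignore", message=".*empty reference.*")
    study = RESULTS / "study"
    evidence = cio.read_evidence(study / "evidence.tsv")
    associations = cio.read_associations(study / "associations.tsv")
    annotations = cio.read_gmt(study / "annotations.gmt")
    decisions = pd.read_csv(RESULTS / "filter_decisions.tsv", sep="\t")
    retained = set(decisions.loc[decisions["retained"], "ingredient_id"])
    nim = pd.read_csv(RESULTS / "nim_scores.tsv", sep="\t")

    disease_genes = {e.gene for e in evidence}
    target_genes = {g for i, g in associations if i in retained}
    key_proteins = set(nim.loc[nim["kept"] & (nim["role"] == "gene"), "node"])
    uet = compute_uet(disease_genes, target_genes)
    merged_genes = set(nim.loc[nim["role"] == "gene", "node"])
    background = merged_genes & annotations.gene_universe()

    print(f"UET (disease ∩ targets): {len(uet)} genes; "
          f"key response proteins: {len(key_proteins)}; "
          f"background: {len(background)} genes")

    results = enrich(set(key_proteins), annotations, background)
    pd.DataFrame([{
        "term_id": r.term_id, "term_size": r.term_size, "overlap": r.overlap,
        "p_value": r.p_value, "significant": r.significant,
    } for r in results]).to_csv(RESULTS / "key_protein_enrichment.tsv",
                                sep="\t", index=False)
    print(f"key-protein enrichment: {sum(r.significant for r in results)} "
          f"significant terms of {len(results)} tested")

    indicators = evaluate_frs(key_proteins, uet, {"terms": annotations}, background)
    summary = {name: {"coverage_pct": rep.percentage, "shared": rep.shared,
                      "reference_size": len(rep.reference)}
               for name, rep in indicators.items()}
    (RESULTS / "coverage_indicators.json").write_text(
        json.dumps(summary, indent=1), encoding="utf-8")
    for name, rep in summary.items():
        print(f"indicator[{name}]: {rep['coverage_pct']}% "
              f"({rep['shared']}/{rep['reference_size']})")


if __name__ == "__main__":
    main()
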