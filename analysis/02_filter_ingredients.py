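#!/usr/bin/env python
"""Apply the ADME admission rule (Caco-2 > -0.4, DL >= 0.18, literature
whitelist) to both the synthetic study's ingredient table and the packaged
printed tables, and report retention counts.
"""

from pathlib import Path

import pandas as pd

from cfig import io as cio
from cfig.filtering import filter_ingredients, retained_ids

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    # packaged tables: literature ingredients are whitelisted by definition,
    # and every CFIG member must survive the filter
    lit = cio.load_literature_ingredients()
    cfig_tab = cio.load_cfig_ingredients()
    print(f"literature table: {len(lit)} ingredients, "
          f"{len(retained_ids(filter_ingredients(lit)))} retained (whitelist)")
    print(f"CFIG table: {len(cfig_tab)} ingredients, "
          f"{len(retained_ids(filter_ingredients(cfig_tab)))} retained")
    print(f"potential active ingredients (distinct ADME-selected + literature): "
          f"{cio.potential_active_total()}")

    records = cio.read_ingredients(RESULTS / "study" / "ingredients.tsv")
    decisions = filter_ingredients(records)
    df = pd.DataFrame([{
        "ingredient_id": d.ingredient_id, "passed_adme": d.passed_adme,
        "whitelisted": d.whitelisted, "retained": d.retained, "reason": d.reason,
    } for d in decisions])
    df.to_csv(RESULTS / "filter_decisions.tsv", sep="\t", index=False)
    print(f"synthetic study: {int(df['retained'].sum())}/{len(df)} retained "
          f"({int(df['passed_adme'].sum())} by ADME, "
          f"{int((df['whitelisted'] & ~df['passed_adme']).sum())} whitelist-only)")


if __name__ == "__main__":
    main()
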