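"""End-to-end orchestration: filter → networks → Nim/FRS → UET →
enrichment coverage → ICP selection, with all intermediates written to disk
and a machine-readable run report.

The run is deterministic for a fixed config and seed; the report carries a
timestamp but every other field is a pure function of the inputs.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .enrichment import ALPHA_DEFAULT, evaluate_frs
from .errors import ConfigError, StageError
from .filtering import CACO2_MIN_DEFAULT, DL_MIN_DEFAULT, filter_ingredients, retained_ids
from .importance import (
    assign_communities,
    compute_nim,
    compute_uet,
    select_frs,
)
from .networks import (
    ROLE_GENE,
    build_disease_network,
    build_it_network,
    mean_targets_per_ingredient,
    merge_networks,
    network_summary,
)
from .selection import coverage_curve, icp_select, recovery_score

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    study_dir: str
    output_dir: str
    caco2_min: float = CACO2_MIN_DEFAULT
    dl_min: float = DL_MIN_DEFAULT
    community_method: str = "connected_components"
    threshold_mode: str = "midpoint"
    alpha: float = ALPHA_DEFAULT
    coverage_target: float = 0.90
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.study_dir).is_dir():
            raise ConfigError("study_dir", f"not a directory: {self.study_dir}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha", "must be in (0, 1)")
        if not (0 < self.coverage_target <= 1):
            raise ConfigError("coverage_target", "must be in (0, 1]")
        if self.threshold_mode not in {"midpoint", "mean", "median"}:
            raise ConfigError("threshold_mode", f"unknown mode {self.threshold_mode!r}")
        if self.community_method not in {"connected_components", "modularity"}:
            raise ConfigError("community_method", f"unknown method {self.community_method!r}")


@dataclass
class RunReport:
    config: dict
    counts: dict = field(default_factory=dict)
    coverage_indicators: dict = field(default_factory=dict)
    cfig: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = VERSION
    timestamp: str = ""

    def without_timestamp(self) -> dict:
        d = asdict(self)
        d.pop("timestamp")
        return d


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    study = Path(config.study_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    report = RunReport(config=asdict(config))
    report.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True), encoding="utf-8"
    )

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    # ---- read inputs
    ingredients = _stage("read_inputs", lambda: cio.read_ingredients(study / "ingredients.tsv"))
    evidence = _stage("read_inputs", lambda: cio.read_evidence(study / "evidence.tsv"))
    base_ppi = _stage("read_inputs", lambda: cio.read_network(study / "ppi.tsv"))
    associations = _stage("read_inputs", lambda: cio.read_associations(study / "associations.tsv"))
    annotations = _stage("read_inputs", lambda: cio.read_gmt(study / "annotations.gmt"))
    report.counts.update(
        n_ingredients=len(ingredients), n_evidence_genes=len(evidence),
        n_ppi_edges=len(base_ppi), n_associations=len(associations),
        n_annotation_terms=len(annotations),
    )

    # ---- ADME filter
    decisions = _stage("filter", lambda: filter_ingredients(
        ingredients, config.caco2_min, config.dl_min))
    retained = retained_ids(decisions)
    pd.DataFrame([{
        "ingredient_id": d.ingredient_id, "passed_adme": d.passed_adme,
        "whitelisted": d.whitelisted, "retained": d.retained, "reason": d.reason,
    } for d in decisions]).to_csv(out / "filter_decisions.tsv", sep="\t", index=False)
    report.counts["n_retained_ingredients"] = len(retained)

    # ---- networks
    disease_res = _stage("disease_network", lambda: build_disease_network(base_ppi, evidence))
    disease = disease_res.network
    if disease_res.dropped_genes:
        report.warnings.append(
            f"{len(disease_res.dropped_genes)} evidence gene(s) absent from the base PPI")
    pd.DataFrame(sorted(disease_res.dropped_genes), columns=["gene"]).to_csv(
        out / "dropped_genes.tsv", sep="\t", index=False)

    retained_assoc = [(i, g) for i, g in associations if i in set(retained)]
    it = _stage("it_network", lambda: build_it_network(retained, retained_assoc))
    merged = _stage("merge", lambda: merge_networks(disease, it, base_ppi))
    for label, net in (("disease", disease), ("merged", merged)):
        summ = network_summary(net)
        report.counts.update({f"{label}_{k}": v for k, v in summ.items()})
        _write_network_files(net, out, label)
    report.counts["it_associations"] = it.n_associations()
    report.counts["mean_targets_per_ingredient"] = mean_targets_per_ingredient(
        it.n_associations(), len(it.ingredients)) if it.ingredients else 0.0

    # ---- Nim and FRS
    disease_genes = {e.gene for e in evidence}
    communities = _stage("nim", lambda: assign_communities(
        merged, config.community_method, seed=config.seed))
    nim = _stage("nim", lambda: compute_nim(merged, communities))
    frs = _stage("frs", lambda: select_frs(
        nim, config.threshold_mode, merged, disease_genes, it.targets))
    key_proteins = {n for n in frs.kept if merged.role(n) == ROLE_GENE}
    nim_df = nim.to_frame()
    nim_df["community"] = nim_df["node"].map(communities.membership)
    nim_df["kept"] = nim_df["node"].isin(frs.kept)
    nim_df["subtype"] = nim_df["node"].map(frs.subtypes).fillna("")
    nim_df.to_csv(out / "nim.tsv", sep="\t", index=False)
    report.counts["frs_nodes"] = len(frs.kept)
    report.counts["n_key_proteins"] = len(key_proteins)
    subtype_counts: dict[str, int] = {}
    for sub in frs.subtypes.values():
        subtype_counts[sub] = subtype_counts.get(sub, 0) + 1
    report.counts["subtype_counts"] = dict(sorted(subtype_counts.items()))
    report.warnings.extend(frs.warnings)

    # ---- UET and coverage validation
    uet = _stage("uet", lambda: compute_uet(disease_genes, it.targets))
    report.counts["uet_size"] = len(uet)
    background = merged.gene_nodes() & annotations.gene_universe()
    indicators = _stage("enrichment", lambda: evaluate_frs(
        key_proteins, uet, {"terms": annotations}, background, config.alpha))
    report.coverage_indicators = {
        name: {"shared": rep.shared, "coverage_pct": rep.percentage,
               "reference_size": len(rep.reference)}
        for name, rep in indicators.items()
    }

    # ---- ICP selection
    selection = _stage("icp", lambda: icp_select(it, key_proteins, config.coverage_target))
    picks_df = pd.DataFrame([{
        "rank": r, "ingredient_id": p.ingredient_id,
        "marginal_gain": p.marginal_gain,
        "cumulative_coverage": p.cumulative_coverage,
    } for r, p in enumerate(selection.picks, start=1)])
    picks_df.to_csv(out / "cfig_picks.tsv", sep="\t", index=False)
    pd.DataFrame(coverage_curve(selection), columns=["rank", "cumulative_coverage"]).to_csv(
        out / "coverage_curve.tsv", sep="\t", index=False)
    report.cfig = {
        "size": len(selection.picks),
        "achieved_coverage_pct": round(100 * selection.achieved_coverage, 2),
        "coverage_target": selection.coverage_target,
        "unreachable": selection.unreachable,
        "top_picks": selection.ingredient_ids[:9],
    }

    planted_file = study / "planted.json"
    if planted_file.exists():
        planted = json.loads(planted_file.read_text(encoding="utf-8"))
        ids = set(planted.get("planted_critical_ids", []))
        if ids:
            report.cfig["planted_recovery"] = recovery_score(selection, ids)

    (out / "report.json").write_text(
        json.dumps(asdict(report), indent=1, sort_keys=True), encoding="utf-8")
    return report


def _write_network_files(net, out: Path, label: str) -> None:
    nodes = pd.DataFrame(
        [{"node": n, "role": net.role(n), "weight": net.weight(n)} for n in sorted(net.nodes)]
    )
    nodes.to_csv(out / f"{label}_nodes.tsv", sep="\t", index=False)
    edges = sorted((min(a, b), max(a, b)) for a, b in net.edges)
    pd.DataFrame(edges, columns=["node_a", "node_b"]).to_csv(
        out / f"{label}_edges.tsv", sep="\t", index=False)
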