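"""Synthetic study generator with known planted structure.

A study emulates the full input bundle of the pipeline: a scale-free base
PPI (preferential attachment, reproducing the hub structure literature PPIs
show), a disease module of well-evidenced genes sampled with degree bias
(well-studied disease genes tend to be hubs), heavy-tailed literature counts
(shifted negative binomial: most genes have 1-2 reports, a few far more) and
log-normal relevance scores, a panel of ingredients whose planted "critical"
subset jointly covers a configurable fraction of the disease module while
decoy ingredients target genes diffusely, ADME values drawn so roughly 30%
of decoys fail the admission filter, and GMT annotation terms aligned to
network neighborhoods.

All randomness flows from a single seeded generator, so identical configs
yield byte-identical studies on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ConfigError
from . import io as cio
from .io import AnnotationCollection, GeneEvidence, IngredientRecord

HERB_CODES = ("CS", "CX", "DS", "DG", "HH")


@dataclass(frozen=True)
class SyntheticStudyConfig:
    n_genes: int = 200
    n_disease_genes: int = 100
    n_ingredients: int = 30
    n_planted_critical: int = 5
    n_terms: int = 40
    mean_targets_per_ingredient: float = 10.0
    ppi_attachment: int = 3
    evidence_dispersion: float = 1.5
    planted_coverage: float = 0.90
    decoy_adme_fail_rate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_disease_genes", "n_ingredients", "n_terms"):
            if getattr(self, name) < 1:
                raise ConfigError(name, "must be >= 1")
        if self.n_planted_critical < 0:
            raise ConfigError("n_planted_critical", "must be >= 0")
        if self.n_planted_critical > self.n_ingredients:
            raise ConfigError("n_planted_critical", "exceeds n_ingredients")
        if self.n_disease_genes > self.n_genes:
            raise ConfigError("n_disease_genes", "exceeds n_genes")
        if self.mean_targets_per_ingredient <= 0:
            raise ConfigError("mean_targets_per_ingredient", "must be positive")
        if self.ppi_attachment < 1:
            raise ConfigError("ppi_attachment", "must be a positive integer")
        if self.evidence_dispersion <= 0:
            raise ConfigError("evidence_dispersion", "must be positive")
        if not (0 < self.planted_coverage <= 1):
            raise ConfigError("planted_coverage", "must be in (0, 1]")
        if not (0 <= self.decoy_adme_fail_rate < 1):
            raise ConfigError("decoy_adme_fail_rate", "must be in [0, 1)")


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    base_ppi: list[tuple[str, str]]
    evidence: list[GeneEvidence]
    ingredients: list[IngredientRecord]
    associations: list[tuple[str, str]]
    annotations: AnnotationCollection
    planted_critical_ids: frozenset[str]
    planted_disease_module: frozenset[str]
    degrees: dict[str, int] = field(default_factory=dict)

    def disease_hubs(self, k: int = 3) -> list[str]:
        """Top-k planted-module genes by base-PPI degree (the module's hubs)."""
        return sorted(
            self.planted_disease_module,
            key=lambda g: (-self.degrees.get(g, 0), g),
        )[:k]


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Deterministically generate a study from the config's single seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # -- base PPI: preferential attachment over gene identifiers
    m = min(config.ppi_attachment, max(1, config.n_genes - 1))
    G = nx.barabasi_albert_graph(config.n_genes, m, seed=int(rng.integers(2**31)))
    G = nx.relabel_nodes(G, {i: _gene_name(i) for i in G.nodes})
    base_ppi = sorted((min(a, b), max(a, b)) for a, b in G.edges)
    degrees = {n: int(d) for n, d in G.degree()}
    genes = sorted(G.nodes)

    # -- disease module: degree-biased sample (hubs accumulate evidence)
    deg = np.array([degrees[g] for g in genes], dtype=float)
    probs = deg / deg.sum()
    module = sorted(rng.choice(genes, size=config.n_disease_genes,
                               replace=False, p=probs))

    # -- evidence: shifted negative binomial counts, log-normal relevance,
    #    both mildly increasing with degree so hubs look well studied
    evidence = []
    med_deg = float(np.median(deg)) or 1.0
    for g in module:
        boost = (degrees[g] / med_deg) ** 0.5
        r = config.evidence_dispersion
        mean_extra = 0.8 * boost
        p = r / (r + mean_extra)
        n_rep = 1 + int(rng.negative_binomial(r, p))
        rel = float(np.round(rng.lognormal(mean=0.7, sigma=0.8) * boost, 2))
        sources = {"disgenet"} if rng.random() < 0.5 else {"disgenet", "genecards"}
        evidence.append(GeneEvidence(g, n_rep, max(rel, 0.01), frozenset(sources)))

    # -- ingredients: planted criticals partition the covered module slice,
    #    decoys target genes diffusely (degree-biased, mostly off-module)
    n_cover = int(np.ceil(config.planted_coverage * len(module)))
    covered_slice = list(rng.permutation(module)[:n_cover])
    ingredients: list[IngredientRecord] = []
    associations: list[tuple[str, str]] = []
    planted_ids = []
    for k in range(config.n_ingredients):
        iid = f"ING{k:03d}"
        planted = k < config.n_planted_critical
        if planted:
            planted_ids.append(iid)
            share = covered_slice[k::config.n_planted_critical]
            # concentrate on the disease module: extras come from the module too
            n_extra = max(0, int(rng.poisson(config.mean_targets_per_ingredient)) - len(share))
            n_extra = min(n_extra, len(module))
            extra = list(rng.choice(module, size=n_extra, replace=False)) if n_extra else []
            targets = sorted(set(share) | set(extra))
        else:
            # diffuse decoys: uniform over the whole gene universe
            size = max(1, int(rng.poisson(config.mean_targets_per_ingredient)))
            size = min(size, len(genes))
            targets = sorted(set(rng.choice(genes, size=size, replace=False)))
        associations.extend((iid, t) for t in targets)

        if planted or rng.random() >= config.decoy_adme_fail_rate:
            caco2 = float(np.round(rng.normal(0.7, 0.4), 2))
            caco2 = max(caco2, -0.39)
            dl = float(np.round(rng.uniform(0.18, 0.85), 2))
        elif rng.random() < 0.5:  # fail on permeability
            caco2 = float(np.round(rng.uniform(-2.0, -0.45), 2))
            dl = float(np.round(rng.uniform(0.18, 0.85), 2))
        else:  # fail on drug-likeness
            caco2 = float(np.round(rng.normal(0.7, 0.4), 2))
            dl = float(np.round(rng.uniform(0.01, 0.17), 2))
        herbs = frozenset(rng.choice(HERB_CODES, size=int(rng.integers(1, 3)),
                                     replace=False))
        ingredients.append(IngredientRecord(
            ingredient_id=iid,
            name=f"compound-{k:03d}",
            herbs=herbs,
            caco2=caco2,
            dl=dl,
            literature_flag=bool(rng.random() < 0.1),
        ))

    # -- annotations: neighborhood gene sets, half seeded inside the module
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(config.n_terms):
        if t % 2 == 0 and module:
            seed_gene = str(rng.choice(module))
        else:
            seed_gene = str(rng.choice(genes, p=probs))
        # two-hop neighborhood so terms reach KEGG/GO-like sizes and the
        # collection's universe covers most of the gene set
        ball = {seed_gene} | set(G.neighbors(seed_gene))
        for nb in list(ball - {seed_gene}):
            ball |= set(G.neighbors(nb))
        hood = [seed_gene] + sorted(ball - {seed_gene})
        want = int(rng.integers(8, 21))
        if len(hood) > want:
            keep = rng.choice(hood[1:], size=want - 1, replace=False)
            hood = [seed_gene] + list(keep)
        while len(hood) < 3:  # pad tiny neighborhoods to the minimum term size
            extra = str(rng.choice(genes))
            if extra not in hood:
                hood.append(extra)
        terms[f"T{t:03d}"] = (f"neighborhood of {seed_gene}", frozenset(hood))

    return SyntheticStudy(
        config=config,
        base_ppi=base_ppi,
        evidence=evidence,
        ingredients=ingredients,
        associations=sorted(set(associations)),
        annotations=AnnotationCollection(terms),
        planted_critical_ids=frozenset(planted_ids),
        planted_disease_module=frozenset(module),
        degrees=degrees,
    )


STUDY_FILES = ("ppi.tsv", "evidence.tsv", "ingredients.tsv",
               "associations.tsv", "annotations.gmt")


def write_study(study: SyntheticStudy, directory) -> dict[str, int]:
    """Write the five study files; returns a filename → byte-size manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cio.write_network(study.base_ppi, directory / "ppi.tsv")
    cio.write_evidence(study.evidence, directory / "evidence.tsv")
    cio.write_ingredients(study.ingredients, directory / "ingredients.tsv")
    cio.write_associations(study.associations, directory / "associations.tsv")
    cio.write_gmt(study.annotations, directory / "annotations.gmt")
    (directory / "planted.json").write_text(
        _planted_json(study), encoding="utf-8"
    )
    return {name: (directory / name).stat().st_size for name in STUDY_FILES}


def _planted_json(study: SyntheticStudy) -> str:
    import json

    return json.dumps({
        "planted_critical_ids": sorted(study.planted_critical_ids),
        "planted_disease_module": sorted(study.planted_disease_module),
        "seed": study.config.seed,
    }, indent=1)


def read_study(directory) -> SyntheticStudy:
    """Load a written study back (planted structure from the side-car JSON)."""
    import json

    directory = Path(directory)
    planted = json.loads((directory / "planted.json").read_text(encoding="utf-8"))
    base_ppi = cio.read_network(directory / "ppi.tsv")
    G = nx.Graph(base_ppi)
    return SyntheticStudy(
        config=SyntheticStudyConfig(seed=planted.get("seed", 0)),
        base_ppi=base_ppi,
        evidence=cio.read_evidence(directory / "evidence.tsv"),
        ingredients=cio.read_ingredients(directory / "ingredients.tsv"),
        associations=cio.read_associations(directory / "associations.tsv"),
        annotations=cio.read_gmt(directory / "annotations.gmt"),
        planted_critical_ids=frozenset(planted["planted_critical_ids"]),
        planted_disease_module=frozenset(planted["planted_disease_module"]),
        degrees={n: int(d) for n, d in G.degree()},
    )
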