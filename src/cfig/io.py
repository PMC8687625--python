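"""Readers and writers for the tabular formats the pipeline consumes.

All tables are UTF-8, tab-delimited with a header row; gene-set collections
use the standard GMT layout (term, description, member genes). Gene symbols
are normalized at this boundary: upper-cased, Greek letters transliterated
(IL-1β → IL1B) and internal hyphens removed, so that the mixed symbol styles
found in literature-evidence exports collapse onto one namespace.

Packaged fixtures transcribe the source study's printed ingredient tables:
the 36 literature-detected ingredients, the per-herb ingredient counts, and
the 60-ingredient critical functional ingredients group (CFIG).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError, ValidationError

MISSING_TOKENS = {"", "—", "-", "NA", "na", "N/A"}

#: Printed summary sizes of the source study's ingredient-target network,
#: used as inputs for in-table arithmetic (not recomputed here).
STUDY_CONSTANTS = {
    "it_associations": 8598,
    "it_ingredients": 241,
    "it_targets": 1105,
}

with resources.files("cfig.data").joinpath("greek_map.json").open(encoding="utf-8") as _fh:
    GREEK_MAP = json.load(_fh)


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: transliterate Greek, upper-case, drop hyphens/spaces."""
    out = "".join(GREEK_MAP.get(ch, ch) for ch in symbol.strip())
    return out.upper().replace("-", "").replace(" ", "")


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class IngredientRecord:
    """One chemical ingredient with its ADME properties and provenance.

    ``caco2`` (intestinal permeability) and ``dl`` (drug-likeness) may be
    missing for ingredients admitted purely on literature evidence, which is
    what ``literature_flag`` records.
    """

    ingredient_id: str
    name: str
    herbs: frozenset[str] = frozenset()
    caco2: float | None = None
    dl: float | None = None
    literature_flag: bool = False
    concentration: float | None = None
    conc_unit: str | None = None


@dataclass(frozen=True)
class GeneEvidence:
    """Disease-gene evidence: a literature report count and a relevance score."""

    gene: str
    n_reports: int = 0
    relevance_score: float = 0.0
    sources: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.n_reports <= 0 and self.relevance_score <= 0:
            raise ValidationError(
                f"gene {self.gene}: needs n_reports > 0 or relevance_score > 0"
            )


@dataclass
class AnnotationCollection:
    """Flat term → gene-set map (pathway or GO stand-in; no DAG structure)."""

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def restrict(self, background: set[str]) -> "AnnotationCollection":
        """Intersect every term with *background*, dropping emptied terms."""
        kept = {}
        for tid, (desc, genes) in self.terms.items():
            g = genes & frozenset(background)
            if g:
                kept[tid] = (desc, g)
        return AnnotationCollection(kept)


# ---------------------------------------------------------------------------
# low-level helpers

HERB_DELIMITER = ";"
SOURCE_DELIMITER = ";"


def _read_tsv(path, expected_columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read TSV: {exc}", path=path) from exc
    if list(df.columns) != expected_columns:
        raise ParseError(
            f"expected columns {expected_columns}, found {list(df.columns)}",
            path=path,
            line=1,
        )
    return df


def _parse_float(token: str, path, line: int, col: str) -> float | None:
    if token.strip() in MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"column {col}: not a number: {token!r}", path=path, line=line)


def _parse_bool(token: str, path, line: int, col: str) -> bool:
    t = token.strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no", ""}:
        return False
    raise ParseError(f"column {col}: not a boolean: {token!r}", path=path, line=line)


def _fmt(value) -> str:
    return "—" if value is None else str(value)


# ---------------------------------------------------------------------------
# ingredients

INGREDIENT_COLUMNS = [
    "ingredient_id", "name", "herbs", "caco2", "dl",
    "literature_flag", "concentration", "conc_unit",
]


def read_ingredients(path) -> list[IngredientRecord]:
    """Parse an ingredient table; duplicate ids and malformed rows are errors."""
    df = _read_tsv(path, INGREDIENT_COLUMNS)
    records: list[IngredientRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        iid = row.ingredient_id.strip()
        if not iid:
            raise ParseError("empty ingredient_id", path=path, line=i)
        if iid in seen:
            raise ValidationError(f"duplicate ingredient_id {iid!r} at line {i}")
        seen.add(iid)
        herbs = frozenset(
            h.strip() for h in row.herbs.split(HERB_DELIMITER) if h.strip()
        )
        unit = row.conc_unit.strip()
        records.append(
            IngredientRecord(
                ingredient_id=iid,
                name=row.name.strip(),
                herbs=herbs,
                caco2=_parse_float(row.caco2, path, i, "caco2"),
                dl=_parse_float(row.dl, path, i, "dl"),
                literature_flag=_parse_bool(row.literature_flag, path, i, "literature_flag"),
                concentration=_parse_float(row.concentration, path, i, "concentration"),
                conc_unit=None if unit in MISSING_TOKENS else unit,
            )
        )
    return records


def write_ingredients(records: Iterable[IngredientRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "ingredient_id": r.ingredient_id,
            "name": r.name,
            "herbs": HERB_DELIMITER.join(sorted(r.herbs)),
            "caco2": _fmt(r.caco2),
            "dl": _fmt(r.dl),
            "literature_flag": str(r.literature_flag).lower(),
            "concentration": _fmt(r.concentration),
            "conc_unit": _fmt(r.conc_unit),
        })
    pd.DataFrame(rows, columns=INGREDIENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evidence

EVIDENCE_COLUMNS = ["gene", "n_reports", "relevance_score", "sources"]


def read_evidence(path) -> list[GeneEvidence]:
    df = _read_tsv(path, EVIDENCE_COLUMNS)
    out: list[GeneEvidence] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = normalize_symbol(row.gene)
        if not gene:
            raise ParseError("empty gene symbol", path=path, line=i)
        if gene in seen:
            raise ValidationError(f"duplicate gene {gene!r} at line {i}")
        seen.add(gene)
        n_rep = _parse_float(row.n_reports, path, i, "n_reports") or 0.0
        if n_rep < 0 or int(n_rep) != n_rep:
            raise ParseError(f"n_reports must be a nonnegative integer: {row.n_reports!r}",
                             path=path, line=i)
        rel = _parse_float(row.relevance_score, path, i, "relevance_score") or 0.0
        if rel < 0:
            raise ParseError("relevance_score must be nonnegative", path=path, line=i)
        sources = frozenset(s.strip() for s in row.sources.split(SOURCE_DELIMITER) if s.strip())
        out.append(GeneEvidence(gene, int(n_rep), rel, sources))
    return out


def write_evidence(evidence: Iterable[GeneEvidence], path) -> None:
    rows = [{
        "gene": e.gene,
        "n_reports": e.n_reports,
        "relevance_score": e.relevance_score,
        "sources": SOURCE_DELIMITER.join(sorted(e.sources)),
    } for e in evidence]
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# undirected edge list

NETWORK_COLUMNS = ["gene_a", "gene_b"]


def read_network(path) -> list[tuple[str, str]]:
    """Read an undirected edge list; self-loops dropped (warning), duplicates merged."""
    df = _read_tsv(path, NETWORK_COLUMNS)
    edges: set[tuple[str, str]] = set()
    n_loops = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        a, b = normalize_symbol(row.gene_a), normalize_symbol(row.gene_b)
        if not a or not b:
            raise ParseError("empty node identifier", path=path, line=i)
        if a == b:
            n_loops += 1
            continue
        edges.add((min(a, b), max(a, b)))
    if n_loops:
        warnings.warn(f"{path}: dropped {n_loops} self-loop(s)", stacklevel=2)
    return sorted(edges)


def write_network(edges: Iterable[tuple[str, str]], path) -> None:
    uniq = sorted({(min(a, b), max(a, b)) for a, b in edges if a != b})
    pd.DataFrame(uniq, columns=NETWORK_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ingredient -> target associations

ASSOCIATION_COLUMNS = ["ingredient_id", "target_gene"]


def read_associations(path) -> list[tuple[str, str]]:
    df = _read_tsv(path, ASSOCIATION_COLUMNS)
    pairs: list[tuple[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        iid = row.ingredient_id.strip()
        gene = normalize_symbol(row.target_gene)
        if not iid or not gene:
            raise ParseError("empty field in association", path=path, line=i)
        pairs.append((iid, gene))
    return pairs


def write_associations(pairs: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(sorted(set(pairs)), columns=ASSOCIATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> AnnotationCollection:
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} field(s); need term, description, ≥1 gene",
                    path=path, line=i,
                )
            tid, desc = fields[0].strip(), fields[1].strip()
            if tid in terms:
                raise ValidationError(f"duplicate term {tid!r} at line {i}")
            genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"term {tid!r} has no genes", path=path, line=i)
            terms[tid] = (desc, genes)
    return AnnotationCollection(terms)


def write_gmt(collection: AnnotationCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(collection.terms):
            desc, genes = collection.terms[tid]
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture_path(name: str):
    return resources.files("cfig.data").joinpath(name)


def load_literature_ingredients() -> list[IngredientRecord]:
    """The 36 ingredients detected in the formula by published chemical analyses."""
    with resources.as_file(_fixture_path("table1_literature_ingredients.tsv")) as p:
        return read_ingredients(p)


def load_cfig_ingredients() -> list[IngredientRecord]:
    """The study's selected 60-ingredient critical functional ingredients group."""
    with resources.as_file(_fixture_path("table3_cfig_ingredients.tsv")) as p:
        return read_ingredients(p)


def load_ingredient_counts() -> pd.DataFrame:
    """Per-herb ingredient counts (database totals, ADME-selected, literature)."""
    with resources.as_file(_fixture_path("table2_ingredient_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def potential_active_total(counts: pd.DataFrame | None = None) -> int:
    """ADME-selected plus literature-selected ingredient count (205 + 36).

    Uses the distinct-ingredient totals: the per-herb columns sum higher
    because ingredients shared between herbs are counted once per herb.
    """
    if counts is None:
        counts = load_ingredient_counts()
    sel = counts.loc[counts["category"] == "tcmsp_selected_distinct", "count"].sum()
    lit = counts.loc[counts["category"] == "literature_selected", "count"].sum()
    return int(sel + lit)


def validate_study_dir(directory) -> Mapping[str, int]:
    """Parse all five study files in *directory*; return record counts per file."""
    directory = Path(directory)
    return {
        "ingredients.tsv": len(read_ingredients(directory / "ingredients.tsv")),
        "evidence.tsv": len(read_evidence(directory / "evidence.tsv")),
        "ppi.tsv": len(read_network(directory / "ppi.tsv")),
        "associations.tsv": len(read_associations(directory / "associations.tsv")),
        "annotations.gmt": len(read_gmt(directory / "annotations.gmt")),
    }
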