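"""Hypergeometric term enrichment and coverage indicators.

For a background of N genes, a term with K annotated genes and a query of n
genes overlapping the term in k genes, the enrichment p-value is the exact
upper tail P(X >= k) of the hypergeometric distribution. No multiple-testing
correction is applied by default (Benjamini-Hochberg is available by flag);
significance is strict, p < alpha.

Coverage compares two significant-term (or gene) sets: the fraction of a
reference set recovered by a query set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import AnnotationCollection

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    description: str
    term_size: int      # K, after background restriction
    query_size: int     # n
    overlap: int        # k
    background_size: int  # N
    p_value: float
    significant: bool


@dataclass(frozen=True)
class CoverageReport:
    reference: frozenset[str]
    query: frozenset[str]
    shared: int
    coverage: float

    @property
    def percentage(self) -> float:
        return round(100.0 * self.coverage, 2)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes: set[str],
    annotations: AnnotationCollection,
    background: set[str],
    alpha: float = ALPHA_DEFAULT,
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Test every term with a nonzero background intersection; sort by p ascending.

    Query genes outside the background are dropped before testing. With
    ``correction="bh"`` significance is decided on Benjamini-Hochberg adjusted
    p-values (the reported ``p_value`` stays raw).
    """
    if not query_genes:
        raise ValidationError("empty query gene set")
    if not background:
        raise ValidationError("empty background gene set")
    background = set(background)
    query = set(query_genes) & background
    if not query:
        raise ValidationError("query has no genes in the background")

    N, n = len(background), len(query)
    raw: list[tuple[str, str, int, int, float]] = []
    for tid in sorted(annotations.terms):
        desc, genes = annotations.terms[tid]
        term_bg = genes & background
        if not term_bg:
            continue
        K = len(term_bg)
        k = len(term_bg & query)
        raw.append((tid, desc, K, k, hypergeom_upper_tail(k, N, K, n)))

    pvals = [r[4] for r in raw]
    if correction == "bh" and pvals:
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        sig = list(reject)
    elif correction in (None, "none"):
        sig = [p < alpha for p in pvals]
    else:
        raise ValidationError(f"unknown correction {correction!r}")

    results = [
        EnrichmentResult(tid, desc, K, n, k, N, p, s)
        for (tid, desc, K, k, p), s in zip(raw, sig)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def significant_terms(results: Sequence[EnrichmentResult]) -> frozenset[str]:
    return frozenset(r.term_id for r in results if r.significant)


def coverage(reference: set[str], query: set[str]) -> CoverageReport:
    """Fraction of *reference* recovered by *query* (0 with warning if empty)."""
    reference, query = frozenset(reference), frozenset(query)
    shared = len(reference & query)
    if not reference:
        warnings.warn("empty reference set; coverage reported as 0", stacklevel=2)
        return CoverageReport(reference, query, 0, 0.0)
    return CoverageReport(reference, query, shared, shared / len(reference))


def evaluate_frs(
    key_proteins: set[str],
    uet: set[str],
    annotation_collections: Mapping[str, AnnotationCollection],
    background: set[str],
    alpha: float = ALPHA_DEFAULT,
) -> dict[str, CoverageReport]:
    """The validation indicators comparing key response proteins against the
    un-optimized effective targets (UET) reference.

    Returns a gene-level coverage report under the key ``"genes"`` plus one
    enriched-term coverage report per named annotation collection (the source
    study uses two collections, pathway-like and GO-like, giving its three
    indicators).
    """
    if not key_proteins or not uet:
        raise ValidationError("key proteins and UET must be nonempty")
    out: dict[str, CoverageReport] = {"genes": coverage(set(uet), set(key_proteins))}
    for name, coll in annotation_collections.items():
        ref = significant_terms(enrich(set(uet), coll, background, alpha))
        qry = significant_terms(enrich(set(key_proteins), coll, background, alpha))
        out[name] = coverage(set(ref), set(qry))
    return out
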