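# Methods

## The model

The pipeline treats a multi-herb preparation as a set of chemical
ingredients acting on a disease through a network of protein interactions.
Three data layers are combined:

- **Disease evidence.** Each disease gene carries a literature report count
  (DisGeNET-style) and a relevance score (GeneCards-style). The disease
  network is the base PPI induced on these genes; each node's weight is the
  product *degree × relevance × report count*, computed with the degree in
  the induced subgraph (the gene's connectivity among disease genes, not in
  the whole interactome). A missing relevance or a zero report count
  contributes the multiplicative identity 1.0 so one absent factor never
  annihilates the product. The weight is reported per node; it does not
  enter the Nim score, which is purely topological.
- **Ingredient admission.** An ingredient passes the ADME screen when
  Caco-2 > −0.4 (strict, as printed) and DL ≥ 0.18 (inclusive). Ingredients
  detected in the preparation by chemical analysis are whitelisted: the
  retained set is the union of the two rules, and a whitelisted record may
  lack ADME values entirely. Missing ADME fails the screen.
- **Merged disease–target network.** Node union of the disease network and
  the bipartite ingredient–target network, plus the base-PPI edges among
  *all* mapped genes (including targets outside the disease set). The last
  point is forced by arithmetic: the reference study's merged network has
  more edges than its two parts combined, so PPI edges among targets must
  have been retained.

## Nim and the functional response space

For node *s* in network *U* with community *C(s)*:

```
Nim(s) = B(s) · [ (|C(s)|/|U|) · Σ_{w∈C(s), w≠s} (Δ_s + 1 − dist(s,w)) / Δ_s ]²
```

- **B(s)** is unnormalized betweenness centrality with the undirected
  convention (each unordered pair counted once); pairs in different
  components are skipped. Computed with networkx's Brandes implementation
  and cross-checked in the tests against a Floyd–Warshall + path-counting
  oracle on every connected graph with ≤ 6 nodes (atlas, up to isomorphism)
  and random 7–8-node graphs.
- **Communities** default to connected components, which makes every
  `dist(s, w)` finite; Louvain modularity communities are available
  (seeded). Distances are shortest-path lengths in the full network,
  restricted to community members; unreachable members are skipped.
- **Δ_s** is the eccentricity of *s* within its community — the
  interpretation adopted for the "maximum distance … passing through node
  s" phrase, which is not implementable as written. The denominator
  `max dist(s, w)` equals Δ_s under this reading. A singleton community (or
  one with no reachable peer) contributes factor 0.
- The factor rewards nodes that sit close to a large community: each member
  contributes Δ_s + 1 − dist, so near members count more, scaled by the
  community's share of the network, then squared.

The FRS keeps every node with Nim ≥ threshold (ties kept). Three threshold
modes exist because the source formula and its prose disagree: the literal
rule is the **midpoint** (min+max)/2, the prose says "average". On
heavy-tailed Nim distributions the midpoint keeps only the extreme tail
(a handful of hubs), whereas the reference study retained ~50% of nodes —
the signature of a **median** rule. The API default is the literal
midpoint; the analysis scripts and the acceptance run use `median`, which
reproduces the ~50% retention. The discrepancy is surfaced as a flag, never
silently resolved.

Kept gene nodes (key response proteins) are partitioned by membership:
disease gene and ingredient target → *essential common*; disease only →
*disease-specific*; target only → *ingredient-specific*.

## Enrichment and coverage validation

Term enrichment is the exact hypergeometric upper tail P(X ≥ k) for a term
with K background genes, query size n, overlap k, background N. Terms are
intersected with the background before testing; query genes outside the
background are dropped. Significance is raw p < α (default 0.05) with no
multiple-testing correction, matching the reference procedure;
Benjamini–Hochberg is available by flag. The background is the set of
merged-network genes present in the annotation universe — the least
arbitrary closed choice, and configurable.

The validation indicators compare key response proteins against the UET
(disease ∩ targets): gene coverage |key ∩ UET|/|UET|, plus enriched-term
coverage per annotation collection (with pathway-like and GO-like
collections this yields the three reference indicators; the synthetic study
ships one collection, giving two).

## ICP selection

The ICP ranking is marginal-gain greedy set cover over the key response
proteins: ingredients are seeded in descending raw-target-count order, and
each step picks the ingredient adding the most uncovered key proteins (ties:
higher raw target count, then lexicographic id), stopping at the coverage
target (default 0.90) or when no positive gain remains. The reference
description of the algorithm body is not machine-readable; greedy
marginal-gain is the reconstruction consistent with its reported behaviour —
in particular, an ingredient with a very high raw target count but largely
redundant coverage is never picked, which a pure target-count sort cannot
produce. Greedy set cover carries the (1 − 1/e) approximation guarantee,
verified in the tests against exhaustive optima on small instances.

## Synthetic studies

The generator emulates the input bundle at desk scale with a single seeded
RNG stream:

| parameter | default | rationale |
| --- | --- | --- |
| n_genes | 200 | desk-scale interactome |
| n_disease_genes | 100 | disease genes dominate the merged network in the reference data (~76% of nodes); 50% is a conservative scale-down |
| n_ingredients / n_planted_critical | 30 / 5 | panel with a small planted critical core |
| mean_targets_per_ingredient | 10 | ~5% of the gene universe, comparable to the reference ratio |
| ppi_attachment | 3 | Barabási–Albert preferential attachment; reproduces the hub structure Nim exploits |
| evidence_dispersion | 1.5 | negative-binomial shape: most genes 1–2 reports, few ≫ 10 |
| planted_coverage | 0.90 | planted target sets jointly cover ≥ 90% of the disease module by construction (round-robin partition) |
| decoy_adme_fail_rate | 0.30 | ~30% of decoys fail the ADME screen |
| n_terms | 40 | two-hop-neighborhood gene sets of size 8–20, so the annotation universe covers most genes, as real pathway/GO collections do |

Disease genes are sampled with degree bias (well-studied disease genes are
hubs); literature counts are shifted negative binomial and relevance scores
log-normal, both mildly increasing with degree. Planted-critical target
sets are concentrated on the disease module (their extras are drawn from
the module); decoy targets are uniform over all genes.

What the generator does **not** emulate: real symbol vocabularies, herb-
specific chemistry, correlated target profiles between similar compounds,
annotation-term overlap structure, or edge confidence. Passing tests
therefore demonstrate algorithmic correctness and recoverability of planted
structure at this scale, not performance on real databases. In particular
the enriched-term coverage indicator is high-variance at this scale (the
UET reference often has only 2–4 significant terms, and borderline p-values
flip between query sets); the gene-level indicator is the stable one. The
reference study's headline coverage percentages depend on proprietary
database releases and are treated as narrative, not as reproduction
targets.

## Numerical and degenerate-input choices

- All-equal Nim scores: every threshold mode keeps every node (≥ is
  inclusive).
- Empty coverage reference: coverage 0 with a warning, never a crash.
- Evidence genes absent from the base PPI go to a drop list; an empty
  intersection is an explicit error.
- Retained ingredients without targets are excluded from the I-T network
  with a warning; associations naming unknown ingredients are errors.
- Gene symbols are normalized at the I/O boundary (upper case, Greek
  transliterated via a packaged map, hyphens removed) so mixed styles
  (IL-1β vs IL1B) collapse onto one namespace.
- Reported sizes: the default test suite and acceptance script use 200-gene
  studies, 20-seed replications, exhaustive oracles to 6–8 nodes (graphs),
  15 (hypergeometric background) and 12×20 (set-cover instances).

## Known limitations

- Nim is O(V·E) per network (Brandes); no sampled approximation is
  provided, so very large networks are out of scope.
- The network is undirected: activation vs inhibition is ignored.
- Communities via connected components make the community factor nearly
  constant on a connected network; modularity communities give the factor
  real discriminating power but introduce seed dependence.
- The greedy ICP is a reconstruction; if the original procedure included a
  proportion normalization beyond cumulative coverage, picks beyond the
  forced ones could differ.
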