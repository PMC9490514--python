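# Methods

`herbnet` re-implements, as a tested library, the network-pharmacology
workflow used to infer how a multi-compound herbal extract acts on a
multi-target disease such as type 2 diabetes: screen the identified
phytochemicals for drug-likeness, assemble their protein targets from
heterogeneous databases, intersect them with disease targets, build
compound–target and protein–protein interaction (PPI) networks, distil
the PPI network to a small tier of core targets by centrality
filtering, summarize the mechanism by pathway over-representation and a
tripartite compound–target–pathway network, band externally computed
docking scores, and evaluate the fasting insulin-resistance indices
used in the accompanying animal experiment.

## Compound screening (`adme_screen`)

A compound is retained when its oral-bioavailability (OB) score is at
least 0.55 (inclusive) **and** it passes at least two of the five
drug-likeness rule sets — Lipinski (pass = ≤ 1 violation of mw ≤ 500,
MLOGP ≤ 4.15, N+O ≤ 10, NH+OH ≤ 5), Ghose, Veber, Egan and Muegge —
evaluated with the SwissADME threshold definitions frozen in the module
docstring.  Two user-supplied override lists complete the rule: a
literature keep-list (compounds with demonstrated bioactivity despite
poor predicted pharmacokinetics) and a no-target drop list.  A rule set
that needs an absent descriptor *fails* with a logged reason rather
than guessing a value: with incomplete descriptor tables this can only
under-retain, never over-retain, and is reproducible.  Descriptors are
inputs; computing them from structures is out of scope.

## Target assembly (`target_assembly`, `io_model`)

Gene symbols are normalized deterministically (strip, uppercase,
optional alias→approved lookup; approved symbols map to themselves, so
normalization is idempotent; unmappable symbols are reported, never
dropped).  Per-database cutoffs are boundary-inclusive: BindingDB
affinity ≤ 10,000 nM, SwissTargetPrediction score ≥ 0.5, STITCH ≥ 0.4,
BATMAN ≥ 20, DisGeNET ≥ 0.2; TTD, CTD, OMIM and DrugBank carry no
numeric cutoff.  Merging keeps per-symbol provenance (source databases
and contributing compounds) so compound→target links survive to the
network stages.  The candidate set is the exact herb ∩ disease
intersection, with both set-difference sizes reported for Venn
rendering.

## Networks and centralities (`network_build`)

The compound–target network is a simple bipartite graph.  High-degree
nodes are *flagged* (not filtered) at `max(7, ceil(2 × median degree))`
of their node class, reproducing the reporting convention of mixing a
fixed degree-7 call-out with a two-fold-median rule.

STRING-style edge lists are accepted in both score dialects (0–1 and
0–1000; if any score exceeds 1 the whole file is divided by 1000).  PPI
construction keeps edges with combined score ≥ 0.7 (inclusive), drops
self-loops, keeps the maximum score of duplicated pairs, and retains
candidate genes without surviving edges as declared isolated nodes.

Centrality conventions (frozen; they match the Cytoscape
NetworkAnalyzer defaults this style of analysis relies on):

* degree = neighbor count;
* betweenness = unnormalized shortest-path betweenness over unordered
  node pairs, endpoints excluded, paths unweighted (scores are used
  only for thresholding);
* closeness(v) = r(v) / Σ d(v, u) over the r(v) nodes reachable from v
  — the reciprocal mean distance *within v's component*; isolated
  nodes get 0.

Whether closeness should use the within-component convention cannot be
settled from published text alone; the convention above is fixed and
the test suite pins all three measures to an independent brute-force
enumerator (explicit distance matrices and path counts, not Brandes
accumulation).

## Hub cascade (`hub_cascade`)

Three nested tiers: stage 1 keeps nodes whose degree, closeness and
betweenness are each **strictly greater** than the corresponding median
over all nodes (isolated nodes included in the medians); stage 2
re-runs the same filter on the subgraph induced by stage-1 hubs with
centralities recomputed on that subgraph; stage 3 keeps stage-2 nodes
linked to at least 7 compounds in the compound–target network
(inclusive; a target absent from that network counts 0 and is excluded
with an audit entry).  Two genuinely open choices are resolved
explicitly: the median rule is *conjunctive* (all three centralities),
because conjunctive screening is the convention in this literature and
produces the aggressive ~3× reduction such cascades show — a
disjunctive switch exists but is off by default; and stage-2
centralities are *recomputed on the induced subgraph*, since the hub
tier is conventionally analyzed as its own network.  On any
vertex-transitive graph (cycles, complete graphs) no node strictly
exceeds the median, so all tiers are empty by construction.

## Enrichment and the C-T-P network (`enrichment`)

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n), with Benjamini–Hochberg step-up FDR
(own implementation of the step-up, cross-checked in tests against
statsmodels).  The background universe is explicit configuration —
normally the candidate-target universe, not the genome — because an
implicit background silently changes every p-value.  No combined-score
heuristics are computed.  The C-T-P network links compounds to the core
targets they act on and core targets to the pathways containing them;
per-pathway coverage is count / |core| × 100, rounded **half-up** to
one decimal (matching how printed tables round), ranked by count
descending with ties broken by name.  Pathways with zero core members
stay visible with count 0.

## Docking post-processing (`docking_postproc`)

Binding energies (kcal/mol) are banded: strong < −7; good [−7, −5);
certain [−5, −4.25]; weak > −4.25.  The published band edges overlap at
their boundaries; here each boundary value is assigned to the weaker
neighbouring band (−7 → good, −5 → certain) and −4.25 stays in
certain, so the four bands partition the real line.  "Weak" labels the
region above −4.25 that carries no published name.  Running the docking
itself is out of scope; scores are inputs.

## Insulin-resistance indices and expression (`bioassay_indices`)

Per animal: HOMA-IR = glucose·insulin/405; TyG = ln(TG·glucose/2)
(natural log); QUICKI = 1/(log₁₀ insulin + log₁₀ glucose); HOMA-B =
20·insulin/(glucose − 63), defined only for glucose > 63 mg/dl —
undefined values are flagged, never fabricated.  QUICKI uses base-10
logs and TyG the natural log because those are the standard definitions
of each index.  Group statistics are mean ± SEM (sd/√n, ddof = 1) of
the **per-animal** indices; the alternative (index of the group means)
gives slightly different numbers and is deliberately not used.
Relative expression is 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference)
and ΔΔCt taken against the calibrator group's mean ΔCt.  Group
comparisons (ANOVA/Tukey) are delegated to scipy/statsmodels.

## Synthetic data (`synthetic_data`)

The generators emulate every pipeline input with planted ground truth,
at sizes chosen so the whole suite runs in seconds on one CPU:

* **Compounds**: 62 compounds, 34 drawn to pass the screen
  (flavonoid-like descriptor blocks, OB ∈ {0.55, 0.56, 0.85}) and 28 to
  fail it (heavy glycoside-like blocks, OB ∈ {0.11, 0.17}); 13 of the
  failures literature-kept and 1 passer dropped for lacking targets,
  yielding 46 retained — the proportions of a realistic LC-MS screen.
* **Network**: the candidate set is 60 genes in three planted tiers —
  an 8-gene core clique, a 22-gene shell ring each wired to two core
  genes, and a 30-gene halo hanging off the shell — plus sub-threshold
  decoy edges that the 0.7 cutoff must remove.  Core genes are wired to
  8–12 retained compounds (≥ 7), shell and halo to 1–6 (< 7), so the
  cascade's planted answer is exactly the core.  Herb (250) and disease
  (120) lists intersect exactly in the 60 tier genes; per-database
  exports straddle each cutoff with decoy symbols that every cutoff
  rejects.  15 gene sets cover the core at fractions 0.90 down to 0.20.
* **Animals**: 7 animals per group with group means patterned on a
  high-fat-diet + streptozotocin rat model (NC glucose 89.71 vs DC
  343.86 mg/dl; triglyceride means back-calculated from the
  corresponding TyG values), positive-truncated normal draws, and Ct
  values constructed so planted fold changes (e.g. IL1B ×3 in the
  diabetic group) are recoverable through 2^−ΔΔCt at Ct noise sd 0.2.

Each generator draws from its own RNG stream (`seed` + a fixed
per-generator offset), so adding a generator never perturbs another,
and identical configurations produce byte-identical files.

What the synthetic data does *not* emulate: realistic STRING score
distributions, correlated database errors, scale (hundreds rather than
tens of thousands of targets), symbol-alias noise, or biological
pathway overlap structure.  Passing tests therefore demonstrate that
the algorithms implement their stated contracts and recover planted
structure — not that any particular biological conclusion holds on real
downloads.

## Numerical choices and degenerate inputs

All score cutoffs are boundary-inclusive; median filters use strict
inequality; percentages round half-up; BH enforces monotonicity by
cumulative minimum from the largest p; empty networks yield empty
tables (not errors); empty herb/disease sets warn and intersect to ∅;
an all-missing docking matrix, an empty enrichment background, and
overlapping screening override lists are errors.

## Known limitations

Descriptor computation from SMILES, live database/STRING queries, GO
DAG propagation, Enrichr-style combined scores, weighted-path or
eigenvector centralities, MCODE-style clustering, and docking execution
are all out of scope.  Published headline counts that depend on
supplementary target lists (e.g. a 363-node, 2856-edge PPI reducing
123 → 51 → 40) can be recomputed by feeding those files through
`hubs`/`screen`, but are not reproducible from this repository alone;
the test suite instead proves the operators correct on oracle-checked
and planted inputs.
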