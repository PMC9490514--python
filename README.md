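# herbnet

Network-pharmacology analysis of multi-compound herbal extracts against
multi-target diseases — built for the common study design in which an
extract's phytochemicals (identified by LC-MS/MS) are screened for
drug-likeness, linked to protein targets across several databases,
intersected with disease targets, and distilled through a
protein–protein interaction (PPI) network into a small tier of *core
targets* whose pathway membership explains the mechanism.

The package is a library first (every stage is a plain function over
pandas/networkx objects) with a thin `herbnet` CLI, and ships seeded
synthetic-data generators with planted ground truth so the entire
pipeline is testable without any database downloads.

## What it computes

* **Drug-likeness screen** — retain a compound iff oral-bioavailability
  score ≥ 0.55 and ≥ 2 of the five rule sets (Lipinski, Ghose, Veber,
  Egan, Muegge) pass, with literature keep / no-target drop overrides.
* **Target assembly** — per-database score cutoffs (BindingDB ≤ 10,000
  nM; SwissTargetPrediction ≥ 0.5; STITCH ≥ 0.4; BATMAN ≥ 20; DisGeNET
  ≥ 0.2; TTD/CTD/OMIM/DrugBank unscored), HGNC-style symbol
  normalization, provenance-keeping merge, herb ∩ disease intersection.
* **Networks** — bipartite compound–target graph with high-degree
  flags; STRING-dialect PPI at combined score ≥ 0.7; degree, closeness
  (within-component) and unnormalized betweenness centralities.
* **Hub cascade** — nodes strictly above the median in all three
  centralities (hubs), the same filter recomputed on the hub subgraph
  (major hubs), then a ≥ 7-compound filter (core targets).
* **Enrichment** — one-sided hypergeometric over-representation with an
  explicit background and BH FDR; tripartite
  compound–core-target–pathway network with per-pathway coverage
  percentages.
* **Docking bands** — strong (< −7), good ([−7, −5)), certain
  ([−5, −4.25]), weak (> −4.25) kcal/mol.
* **Bioassay indices** — per-animal HOMA-IR, HOMA-B, TyG, QUICKI and
  2^−ΔΔCt fold changes, with mean ± SEM group summaries.

See `docs/methods.md` for the conventions, defaults and their
rationale.

## Worked example

```python
from herbnet.synthetic_data import SyntheticConfig, generate_network_bundle
from herbnet.network_build import build_ppi_network, build_ct_network
from herbnet.hub_cascade import run_cascade

nb = generate_network_bundle(SyntheticConfig(seed=1))
ppi = build_ppi_network(nb.ppi_edges, candidates=nb.planted_common.symbols)
ct = build_ct_network(nb.compound_ids, sorted(nb.planted_common.symbols), nb.ct_links)
res = run_cascade(ppi, ct)
print(len(res.stage1_hubs), len(res.stage2_major_hubs), len(res.stage3_core_targets))
print(sorted(res.stage3_core_targets.symbols) == sorted(nb.planted_core.symbols))
```

prints

```
30 8 8
True
```

— from the 60 candidate targets, 30 beat all three centrality medians,
8 survive the recomputed filter on the hub subgraph, and all 8 are
backed by ≥ 7 compounds; they are exactly the planted core clique.

The same flow from the shell:

```sh
herbnet simulate --seed 1 --out sim/
herbnet screen --compounds sim/compounds/compounds.tsv \
    --keep sim/compounds/keep_list.txt \
    --drop-no-targets sim/compounds/drop_no_targets.txt --out verdicts.tsv
# -> 62 compounds screened, 46 retained -> verdicts.tsv
herbnet hubs --ppi sim/network/ppi_edges.tsv --ct sim/network/ct_links.tsv --out cascade.json
# -> tiers: 30 hubs / 8 major hubs / 8 core targets -> cascade.json
```

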