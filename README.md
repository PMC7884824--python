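# netpharm

A network-pharmacology analysis toolkit covering the full inference chain
from mass-spectrometric peak tables to candidate therapeutic targets:

- **`netpharm.masslib`** — molecular-formula arithmetic, monoisotopic adduct
  m/z computation (`[M-H]-`, `[M+HCOO]-`, `[M+CH3COO]-`, `[M+H]+`, `[M+Na]+`,
  `[M]+`), ppm-tolerance matching of peaks against a compound library, and
  MS2 neutral-loss assignment (H2O / CO / CO2 / NH3 and combinations).
- **`netpharm.targetmap`** — Tanimoto fingerprint similarity against an
  approved-drug library and transfer of drug targets to query compounds at a
  similarity threshold (default ≥ 0.8).
- **`netpharm.netfilter`** — putative-target / disease-gene interaction
  network at an edge-confidence cutoff (default 0.4, STRING 0–1000 scores
  autodetected), degree / betweenness / closeness centralities, and a
  two-stage median hub filter: degree > 2 × median selects hubs, then nodes
  strictly above the hub-subnetwork median in all three centralities become
  major hubs; major hubs with the putative-target role are candidate targets.
- **`netpharm.enrich`** — hypergeometric over-representation of a gene list
  against GMT gene sets (raw p < 0.05 selection, BH column alongside).
- **`netpharm.qpcr`** — relative expression via the 2^−ΔΔCt method.
- **`netpharm.simdata`** — seeded generators that plant recoverable structure
  (true adducts, source drugs, hub centers, an enriched set, expression
  folds) for every stage, each with a truth map.
- **`netpharm.pipeline`** — end-to-end orchestration with plain-text
  artifacts, per-stage counts, and config-hash stamping.

## CLI

```sh
netpharm simulate --seed 1 --out-dir fixtures/        # synthetic inputs
netpharm annotate --peaks fixtures/peaks.csv \
    --library fixtures/compound_library.tsv --tol 10 --out annotations.tsv
netpharm predict --fingerprints fixtures/query_fingerprints.tsv \
    --drugs fixtures/drug_library.tsv --threshold 0.8 --out predictions.tsv
netpharm network --edges fixtures/edges.tsv --roles fixtures/roles.tsv \
    --min-conf 0.4 --out-dir netout/
netpharm enrich --gmt fixtures/pathways.gmt --genes fixtures/query_genes.txt \
    --out enrichment.tsv
netpharm qpcr --ct-table fixtures/ct_table.csv --ref-gene REF \
    --control-group control --out expression.csv
netpharm run-all --config run.yaml        # keys = RunConfig fields
```

## File formats

Peak table CSV (`rt_min, mz, polarity{pos,neg}[, intensity]`); compound
library TSV (`id, name, formula`); fingerprint TSV (`id <tab> bit,bit,...`,
optional `#length=N` header); drug library TSV (`drug_id, bits, gene;gene`);
edge TSV (`node_a, node_b, combined_score` in 0–1 or 0–1000); GMT; Ct CSV
(`sample, group, gene, ct, replicate`). Lines starting with `#` are treated
as comments everywhere.
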