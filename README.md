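# netenrich

Quantify mutual enrichment between the network neighborhoods ("interactomes")
of seed genes and disease-associated pathway gene sets.

The pipeline:

1. **Interactome extraction** — from a confidence-weighted undirected gene
   network, collect all genes within 1 or 2 hops of a seed gene using only
   edges at or above a confidence threshold. Parameters can be fixed per seed
   or auto-tuned so each interactome lands in a target size window; highly
   similar interactomes (Jaccard) are merged.
2. **Enrichment with resampling calibration** — for every interactome x
   pathway pair, a one-sided hypergeometric over-representation p-value is
   computed and then calibrated against an ensemble of size-matched random
   gene sets (default 1,000): the *empirical p-value* is the fraction of null
   uncorrected p-values at or below the observed one.
3. **Disease scoring** — the empirical p-values of all interactome x
   disease-pathway cells are combined by geometric mean (zeros floored at
   1e-4, or one decade below 1/n_null for smaller ensembles). The
   *sensitivity index* is 1/p_mean; diseases are ranked by descending index
   and summarized per category (nervous / metabolic / null).
4. **Key-gene scoring** — each gene is counted over the (interactome,
   pathway) cross-sections of a disease, normalized by the disease's pathway
   count, and summed across diseases.

A `synthetic_data` module generates fully in-memory study bundles (random
network + pathways + diseases) with *planted* seed-to-pathway signal, so the
whole pipeline is testable offline with known ground truth.

## Test

```sh
python -m pytest -q tests/
```

The suite (unit + property + acceptance tests) runs in about a minute.

## CLI

Full pipeline on a synthetic study:

```sh
netenrich run --synthetic-config synth.yaml --n-null 200 --master-seed 7 --outdir results/
```

where `synth.yaml` holds `SyntheticConfig` fields, e.g.:

```yaml
n_genes: 2000
mean_degree: 20
n_pathways: 60
pathway_size_range: [20, 100]
n_diseases: 20
n_seeds: 10
planted_fraction: 0.5
planted_confidence: 0.9
n_truth_pairs: 2
n_truth_diseases: 2
master_seed: 7
```

Full pipeline on files:

```sh
netenrich run --network network.tsv --gmt pathways.gmt \
    --disease-map disease_map.tsv --seeds seeds.tsv --outdir results/
```

* `network.tsv` — `geneA geneB score` edge list; scores either in [0,1] or
  STRING-style integers 0–999 (auto-detected, or forced with
  `--score-scale`).
* `pathways.gmt` — standard GMT (`id<TAB>description<TAB>gene...`).
* `disease_map.tsv` — `disease<TAB>category<TAB>pathway_id`.
* `seeds.tsv` — `gene<TAB>threshold<TAB>order`, with `auto` to tune against
  `--size-window` (default 100–600).

Outputs: `enrichment_long.tsv`, one `heatmap_<disease>.tsv` per disease,
`disease_scores.tsv`, `category_summary.tsv`, `gene_scores.tsv`, and
`run_config.json`. Runs are reproducible bit-for-bit from
(`run_config.json`, `--master-seed`).

Each stage also runs standalone on files, for partial reruns:

```sh
netenrich simulate --synthetic-config synth.yaml --outdir data/
netenrich extract  --network data/network.tsv --seeds data/seeds.tsv --out interactomes.gmt
netenrich enrich   --interactomes interactomes.gmt --gmt data/pathways.gmt \
                   --network data/network.tsv --n-null 200 --master-seed 7 --out matrix.tsv
netenrich score    --matrix matrix.tsv --gmt data/pathways.gmt \
                   --disease-map data/disease_map.tsv --n-null 200 --outdir scored/
netenrich keygenes --interactomes interactomes.gmt --gmt data/pathways.gmt \
                   --disease-map data/disease_map.tsv --out gene_scores.tsv
```

Staged and in-memory runs produce identical numeric outputs.

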