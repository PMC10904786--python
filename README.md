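# lnpscreen

Analysis toolkit for barcoded high-throughput lipid-nanoparticle (LNP)
screening. It covers the full desk-side workflow of a pooled b-DNA
biodistribution screen:

- **`lnpscreen.lipids`** — the combinatorial cationic-degradable (CAD)
  lipid library: `X-Ay-Z` nomenclature parsing, enumeration of the default
  12-core x 15-tail registries (180 lipids), RLU hit calling
  (aggregated RLU strictly > 100 by default), and per-feature relative
  hit-rate tables (secondary-amine count, branch class, tail number, tail
  length; whole-library or within-group denominator).
- **`lnpscreen.simulate`** — ground-truthed synthetic screens: barcode
  whitelist design with a minimum pairwise Hamming distance, pooled
  biodistribution with planted organ tropism (log-normal per-mouse noise,
  Poisson counts), and per-sample FASTQ with UMIs attached pre-PCR,
  Bernoulli-doubling PCR duplication, and i.i.d. substitution errors.
  Everything is deterministic given one root seed.
- **`lnpscreen.quantify`** — FASTQ to a deduplicated barcode x sample
  count table: positional extraction with a mismatch-tolerant prefix
  anchor, whitelist assignment (exact, then unique 1-mismatch neighbor;
  ambiguous reads are discarded), and directional UMI collapse
  (merge single-base neighbor `v` into `u` when
  `count(u) >= 2*count(v) - 1`).
- **`lnpscreen.enrich`** — pseudocount-stabilized within-sample fractions,
  normalization to the uninjected pool ("basemean"), two-sided Wilcoxon
  rank-sum tests (exact for small tie-free samples), Benjamini–Hochberg
  FDR per organ, enriched/depleted/neutral calls, organ-tropism candidate
  selection, and heatmap/volcano export tables.
- **`lnpscreen.pipeline` / CLI** — orchestration with a single YAML
  config, provenance (config hash + version on every output), and
  byte-identical reruns for a fixed seed.

## CLI

```sh
# simulate a 96-LNP screen (5 organs x 5 mice + pool + naked reference)
lnpscreen simulate --seed 1 --out-dir run --planted-n 10

# quantify + enrichment on the simulated run
lnpscreen quantify --config run/run_config.yaml
lnpscreen enrich   --config run/run_config.yaml

# or everything at once (add --force to overwrite an existing run)
lnpscreen run-all --seed 1 --out-dir run

# in vitro SAR hit-rate analysis from a replicate-level RLU table
lnpscreen sar --rlu-table rlu.tsv --out-dir sar_out
```

All tabular I/O is TSV with headers. Key outputs: `counts.tsv`
(barcode x sample deduplicated molecules), `qc.tsv` (per-sample read
accounting), `enrichment.tsv` (`barcode_id, organ, log2fc, p_value,
q_value, call`), `candidates.tsv`, `heatmap.tsv` /
`heatmap_rowscaled.tsv`, `volcano.tsv`, and `sar_hit_rate_<feature>.tsv`.
Sample sheets use columns `sample_id, mouse, organ, role` with
`role in {tissue, pool, naked}`; whitelists use
`barcode_id, sequence, lnp_name`; RLU tables use
`lipid_name, replicate, rlu`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including the
seeded planted-tropism recovery and null-control simulations (a few
minutes of runtime); the rest of the suite is fast.

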