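# somalu

Detection and quantification of **rare somatic Alu insertions** in
normalization-enriched amplicon sequencing libraries — together with a
full in-silico simulator of the underlying wet-lab protocol, so every
analysis stage is testable against known ground truth without any external
data.

## The problem

A somatic retroelement insertion present in one cell out of tens of
thousands is represented by only a handful of molecules in a
retroelement-flank amplicon library, against ~10⁸–10⁹ molecules from fixed
(germ-line) insertions (≈4,000 AluYa5 loci × 2 copies × 10⁵ cells =
8·10⁸). Normalization with a **duplex-specific nuclease (DSN)** attacks
this haystack: the amplicon is denatured and slowly re-annealed, abundant
species re-form duplexes quickly and are digested, rare species stay
single-stranded and survive. One or two rounds of this dramatically
enrich rare (potentially somatic) flanks. **Unique molecular identifiers
(UMIs)** ligated before any amplification let the number of distinct UMIs
per insertion estimate the number of cells bearing it.

## What the package implements

- `somalu.synthetic_data` — toy reference genome with planted fixed /
  somatic loci, AluI fragmentation, 8-nt degenerate UMIs (3⁸ = 6,561
  design space), subfamily-selective amplification, foreign spike-in
  controls at 1- and 5-cell abundance, and DSN normalization modeled with
  second-order re-annealing kinetics: species *i* of abundance *C·g(GC)*
  survives one round with probability 1 / (1 + k·C·g(GC)).
- `somalu.read_structure` — read-pair anatomy
  (`[11-nt primer][5-bp Ya5 signature GGCCG][flank]` /
  `[27-nt adapter with UMI][flank′]`), parsing, and the ≤1-mismatch
  subfamily-consensus check.
- `somalu.junction_calling` — exact-seed toy mapper (or SAM import),
  merging of identical junction coordinates, subtraction of known-database
  and control-tissue insertions.
- `somalu.artifact_filters` — rule-based flags for ligation chimeras
  (internal AGCT), uncut reference sites, mispriming (primer-like genomic
  11-mer within 4 mismatches near the junction) and template switching
  (12-nt flank prefix identical to a known flank).
- `somalu.umi_quant` — UMI error correction: UMIs are vertices, edges
  connect pairs at Hamming distance ≤ 1, each connected component collapses
  to its highest-count "parental" UMI, and the component count is the
  corrected UMI (cell) count.
- `somalu.enrichment_stats` — normalized Shannon entropy
  H = −Σ pᵢ log₂ pᵢ / log₂|D| of reads-per-insertion, Pearson χ² on 2×2
  composition tables, enrichment folds, ΔΔCt and cycle↔fold conversion,
  spike-in mass/molecule arithmetic, and the binomial mispriming-survival
  fraction.
- `somalu.pipeline` / `somalu.cli` — one reproducible run over the
  three-library design (0, 1 and 2 DSN rounds) with a comparative report.

## Worked example

```python
from somalu.pipeline import ScenarioConfig, run_pipeline

cfg = ScenarioConfig(
    chrom_lengths={"chr1": 100_000}, n_fixed=40, n_other=5, total_cells=200,
    somatic_cell_counts=[1, 2, 3], depth=20_000, error_rate=0.001,
    kct_scale=0.02, leak_rate=0.05, amplification_sigma=0.8, seed=7)
print(run_pipeline(cfg).report_text)
```

prints

```
| library | rounds | reads | somatic reads | somatic fraction | somatic loci | somatic UMIs | multi-UMI loci | entropy | recall |
|---|---|---|---|---|---|---|---|---|---|
| unnormalized | 0 | 20000 | 11 | 5.50e-04 | 3 | 5 | 2 | 0.902 | 1.00 |
| normalization_1 | 1 | 20000 | 94 | 4.70e-03 | 3 | 6 | 2 | 0.976 | 1.00 |
| normalization_2 | 2 | 20000 | 468 | 2.34e-02 | 3 | 6 | 2 | 0.993 | 1.00 |

## Enrichment folds vs round-0
- normalization_1: somatic reads x8.5, somatic loci x1.0
- normalization_2: somatic reads x42.5, somatic loci x1.0

## Spike-in recovery (reads / corrected UMIs)
| spike | unnormalized | normalization_1 | normalization_2 |
|---|---|---|---|
| SP240 | 9 / 5 | 43 / 5 | 230 / 5 |
| SP259 | 0 / 0 | 7 / 1 | 57 / 1 |
| SP389 | 9 / 4 | 69 / 5 | 262 / 5 |
| SP418 | 4 / 1 | 28 / 1 | 138 / 1 |
```

Reads supporting the three planted somatic loci rise 11 → 94 → 468 across
the two normalization rounds while fixed-locus reads shrink; the
reads-per-insertion entropy climbs toward 1 (more even coverage); and the
corrected UMI counts of the spike-ins recover their planted
cell-equivalents (5 / 5 / 1 / 1). The same run is available from the shell:

```sh
somalu run-all --outdir run/ --seed 7
```

with stage subcommands (`simulate`, `parse`, `call`, `filter`, `quantify`,
`stats`, `report`) that re-run any part of the analysis from the
self-describing files a run directory contains.

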