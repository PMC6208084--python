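# Methods

## Model of the experiment

The package treats a retroelement-flank enrichment experiment as a chain of
well-defined transformations on molecule abundances:

1. **Library structure.** Genomic DNA from `total_cells` diploid cells is
   digested completely at AluI sites (AGCT). Each target-subfamily
   insertion contributes one fragment species — the unique genomic flank
   running from the element junction to the first downstream AluI site,
   ending with the full AGCT motif. A fixed insertion contributes
   `2 × total_cells` molecules, a somatic one only
   `cells_bearing × copies_per_cell` (defaults: 2 copies for fixed,
   diploid homozygous; 1 for somatic, a single-allele event). Each ligated
   molecule receives one UMI drawn uniformly from the 6,561-sequence design
   space (8 positions over a 3-letter alphabet, here {A, C, T}; the space
   size is the design constraint, the letter choice is arbitrary).
2. **Selective amplification.** Only loci whose 5-bp 5′ signature is
   within one mismatch of the AluYa5 consensus GGCCG amplify efficiently;
   other subfamilies are retained at a configurable `leak_rate`.
   Per-species PCR efficiency bias is modeled as a lognormal multiplier
   with shape `amplification_sigma` (default 0.8, a moderate bias chosen to
   give visibly uneven coverage — normalized entropy around 0.9 — while
   keeping rare-locus detection meaningful).
3. **Spike-ins.** Foreign fragments (random sequences verified absent from
   the reference and free of internal AGCT, standing in for zebrafish
   sequence) are parameterized by molecule count (`cells × copies`), not
   mass. A mass↔molecule converter (650 g·mol⁻¹ per bp / Avogadro) is
   provided; at 2 copies per cell it reproduces the conventional
   ~0.56×10⁻⁹ ng for a 259-bp one-cell fragment.
4. **DSN normalization.** No kinetic equation is fixed by the protocol
   itself, so the simulator uses the minimal classical form: second-order
   self-hybridization (C₀t kinetics) in which species *i* with abundance
   `C_i` survives one denature–renature–digest round with probability
   `s_i = 1 / (1 + kct_scale · C_i · g(GC_i))`, followed by re-amplification
   to a fixed total. `kct_scale` folds the rate constant and renaturation
   time into one per-molecule factor; the default 10⁻³ makes a
   10,000-molecule species lose ~10× in relative abundance per round at the
   reference scenario scale, matching the order of depletion a single DSN
   round achieves in practice. The optional monotone GC modifier
   `g(GC) = exp(α(GC − 0.5))` reproduces the slower first-round
   normalization of AT-rich fragments qualitatively; it is off (g ≡ 1) by
   default and never fitted. The model guarantees order preservation
   (`C/(1+kC)` is increasing) and pairwise ratio compression toward 1,
   with two rounds compressing more than one.
5. **Sequencing.** Read pairs are drawn multinomially over fragment
   abundances. Read 1 is `[11-nt primer][5-bp signature][flank]`, read 2
   `[10-nt adapter][8-nt UMI][9-nt adapter][reverse-complemented flank]`,
   both truncated to 100 nt; substitutions occur independently per base
   (default 0.1%, a typical modern-instrument average). No indels, no
   position-dependent error profile, no adapter-chemistry modeling.

## Analysis pipeline

Parsing locates the primer and adapter within ≤2 substitutions (no
indels), keeps UMI and signature verbatim, and rejects each failing read
with exactly one reason. Flanks map with an exact-20-mer-seed /
≤2-mismatch-extension toy mapper; only uniquely seeded hits survive, and
junctions are merged only at identical (chrom, position, strand) — the
junction coordinate is the first genomic base of the flank, 0-based,
BED half-open (the flank's right edge on the minus strand). Calls within
±100 bp (configurable) of a known-database insertion are labeled `known`;
control-tissue matches `control` (known takes precedence); the remainder
`putative_somatic`. The intersection window absorbs the fact that database
coordinates and AluI-junction coordinates need not be base-identical.

Artifact rules: (a) internal AGCT in the read flank — a terminal AGCT is
the expected digestion boundary and passes; (b) AGCT strictly inside the
*reference* span the flank covers (rule (b) is interpreted at the
reference level: the molecule should have been cut there, and the read
escaped rule (a) through an error in the site); (c) a genomic 11-mer
within ≤4 mismatches (inclusive) of the primer whose 3′ end lies within
20 bp upstream of the junction on the priming strand — the window and the
single-strand scan are design choices, since a misprimed product's flank
begins exactly at the 3′ end of the annealing site; (d) first 12 flank
bases exactly matching a known-insertion flank (flanks shorter than 12 nt
are flagged conservatively with a distinct sub-reason). Filters only flag,
never delete; the cascade is idempotent and order-independent. Rule (e),
the ≤1-mismatch GGCCG signature check, is applied to putative calls.

UMI correction builds, per insertion, an undirected graph over observed
UMIs with edges at Hamming distance ≤1 and reports the number of connected
components, each collapsed to its highest-count parental UMI (count ties
broken lexicographically). The procedure is deliberately the plain
connected-components reading: deleting components and counting leftover
vertices would undercount, and Hamming distance is symmetric, so
"strongly" connected adds nothing. Components with several local count
maxima are not split, and no count-ratio (directional) edge criterion is
used.

## Statistics

Normalized entropy `H = −Σ pᵢ log₂ pᵢ / log₂ |D|` over reads-per-insertion
(the minus sign makes the uniform distribution score exactly 1; |D| = 1
returns 1 by the uniform-degenerate convention; zero-count entries are
dropped). Pearson's χ² on 2×2 composition tables defaults to
Yates-uncorrected with an opt-in correction flag. Cycle-to-fold conversion
uses perfect doubling (efficiency 2.0) by default, consistent with
10 cycles ≈ 1000-fold and 25 cycles ≈ 33·10⁶-fold. The mispriming
survival fraction is the exact binomial tail
`P(mismatches > 4)` for `Binomial(11, 3/4)` ≈ 99.2%, with an empirical
sampling mode over uniform or user-supplied sequence.

## Implementation notes

- **Pooled fragments.** Loci with more than `explicit_umi_max` (default
  1000) molecules are carried as one pooled fragment per locus; each
  molecule's UMI is resolved lazily at read-emission time by a
  deterministic integer mix of (scenario seed, locus, molecule index),
  which is distributionally identical to drawing all UMIs up front —
  every molecule keeps one uniform UMI, consistent across libraries —
  without materializing millions of objects. Rare loci (somatic,
  spike-in) are always materialized per molecule.
- **Species-level survival.** DSN survival is computed per species
  (summed locus abundance) and applied uniformly to the locus's
  fragments, since re-annealing probability depends on the concentration
  of the nucleotide sequence, not on which UMI a molecule carries.
- **Determinism.** A run is a pure function of its scenario config; all
  stage seeds derive from one master seed via `numpy` seed sequences, and
  reports are byte-identical across repeat runs.
- **Degenerate inputs.** Zero-cell loci emit no fragments; loci without a
  reachable AluI site drop out with a warning (mirroring real dropout);
  empty call sets yield empty outputs, not errors; a zero baseline makes
  an enrichment fold undefined and is reported as such.

## Reference scenario and what the tests show

The default `ScenarioConfig` is a scaled-down version of the three-library
design: 1-Mb uniform-random genome, 500 fixed target loci in 5,000 diploid
cells, ten somatic loci in 1–5 cells each, four spike-ins (two at 5 and
two at 1 cell-equivalents), 200,000 read pairs per library sequenced after
0, 1 and 2 DSN rounds. Problem sizes were chosen so a full 20-replicate
experiment completes in a few minutes on one CPU while keeping the somatic
signal in the statistically interesting regime (round-0 somatic loci at
fractions of a read on average).

Passing tests show that the pipeline recovers exactly what was planted
under the simulator's assumptions — complete digestion, substitution-only
errors, uniform random genome, idealized selective amplification. They do
not demonstrate performance on real data: real genomes contain repeats
that defeat unique seeding, real chimera formation is sequence-biased,
real DSN kinetics include cross-hybridization between related flanks, and
real UMI errors are quality-correlated. The strict-monotonicity result
(somatic fraction and recall increasing over rounds) is a property of the
C₀t survival model's ratio compression and should be read as internal
consistency, not as a quantitative prediction of enrichment folds.

## Known limitations

- The toy mapper requires a unique exact seed; it is for synthetic
  genomes only (external SAM import is provided for real mappings).
- No split-read or target-site-duplication detection; junctions are
  single-ended 5′ calls.
- No indel sequencing errors and no quality scores beyond placeholders.
- Strand-separate junction merging; fuzzy (windowed) merging of nearby
  junctions is intentionally not performed.
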