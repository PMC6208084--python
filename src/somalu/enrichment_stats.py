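"""Statistics of library composition and normalization efficiency.

Covers the quantitative vocabulary of a normalization-enrichment
experiment: the normalized Shannon entropy of the reads-per-insertion
distribution (1 = perfectly even coverage), the Pearson chi-squared test on
2x2 class-composition tables, enrichment folds, qPCR Ct <-> fold
conversions (delta-delta-Ct), spike-in mass/molecule arithmetic, expected
library composition, the random-k-mer mispriming survival fraction that
justifies the 4-mismatch primer filter, and a per-library summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .read_structure import ParsedRead, ReadLayout, DEFAULT_LAYOUT, check_subfamily_signature

__all__ = [
    "normalized_entropy",
    "chi_square_2x2",
    "fold_change",
    "ct_to_fold",
    "delta_delta_ct",
    "spike_in_mass",
    "mass_to_molecules",
    "expected_fixed_molecules",
    "kmer_mismatch_survival",
    "count_multi_umi",
    "LibrarySummary",
    "summarize_library",
]

AVOGADRO = 6.02214076e23
MEAN_BP_MASS_G_PER_MOL = 650.0  # average molar mass of one double-stranded bp


def normalized_entropy(counts: Sequence[float] | np.ndarray) -> float:
    """Normalized Shannon entropy of a reads-per-insertion distribution.

    H_n = -sum(p_i * log2 p_i) / log2 |D| with p_i the read proportion of
    insertion i and |D| the number of insertions.  Equals 1 when every
    insertion has the same read count and approaches 0 as the distribution
    concentrates.  Zero-count entries are dropped (0*log 0 := 0); a
    single-insertion distribution returns 1 by the uniform-degenerate
    convention.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty counts")
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts are zero")
    if c.size == 1:
        return 1.0
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum() / np.log2(c.size))


def chi_square_2x2(
    table: Sequence[Sequence[float]] | np.ndarray, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test of homogeneity on a 2x2 table (df = 1).

    ``yates`` applies the continuity correction (|O-E| reduced by 0.5,
    floored at 0).  Raises on a zero margin, where the statistic is
    undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin: chi-squared statistic undefined")
    expected = np.outer(rows, cols) / t.sum()
    dev = np.abs(t - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def fold_change(before: float, after: float) -> float:
    """after / before enrichment fold; undefined (error) for before = 0."""
    if before <= 0:
        raise ValueError("fold change undefined for a zero/negative baseline")
    return after / before


def ct_to_fold(delta_ct: float, efficiency: float = 2.0) -> float:
    """Concentration fold corresponding to a qPCR cycle difference.

    With perfect doubling (efficiency 2.0), 10 cycles ~ 1000-fold and 25
    cycles ~ 33 million-fold.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    return float(efficiency**delta_ct)


def delta_delta_ct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_base: float,
    ct_ref_base: float,
    efficiency: float = 2.0,
) -> float:
    """Relative quantity of target vs reference, test vs baseline library.

    fold = eff^-[(Ct_t,test - Ct_ref,test) - (Ct_t,base - Ct_ref,base)].
    """
    ddct = (ct_target_test - ct_ref_test) - (ct_target_base - ct_ref_base)
    return float(efficiency**-ddct)


def spike_in_mass(
    length_bp: int,
    cells: int,
    copies_per_cell: int = 2,
    bp_mass_g_per_mol: float = MEAN_BP_MASS_G_PER_MOL,
) -> float:
    """Mass (ng) of a spike-in present at ``cells x copies`` molecules.

    mass = molecules * length * (bp molar mass / Avogadro).  Linear in each
    argument; e.g. a 259-bp fragment at one cell-equivalent and two copies
    weighs ~0.56e-9 ng.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    molecules = cells * copies_per_cell
    grams = molecules * length_bp * bp_mass_g_per_mol / AVOGADRO
    return grams * 1e9


def mass_to_molecules(
    mass_ng: float, length_bp: int, bp_mass_g_per_mol: float = MEAN_BP_MASS_G_PER_MOL
) -> float:
    """Molecule count equivalent to a fragment mass in ng."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    return mass_ng * 1e-9 * AVOGADRO / (length_bp * bp_mass_g_per_mol)


def expected_fixed_molecules(loci_per_genome: int, ploidy: int, cells: int) -> int:
    """Molecules of fixed-insertion flanks in a library: loci x ploidy x cells.

    ~4,000 target-subfamily loci in a diploid 100,000-cell sample give
    800,000,000 molecules — the haystack a several-molecule somatic
    insertion hides in.
    """
    if min(loci_per_genome, ploidy, cells) < 0:
        raise ValueError("arguments must be non-negative")
    return loci_per_genome * ploidy * cells


def kmer_mismatch_survival(
    k: int = 11,
    max_mm: int = 4,
    base_match_prob: float = 0.25,
    sequence: str | None = None,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
    primer: str | None = None,
) -> float:
    """Fraction of random k-mers with more than ``max_mm`` mismatches to a
    fixed k-mer — the survival rate of the mispriming filter on random
    genomic sequence.

    Analytic mode (default): exact binomial tail with per-position match
    probability ``base_match_prob``.  Empirical mode (``n_samples`` given):
    samples k-mers uniformly, or from ``sequence`` when provided, and counts
    Hamming mismatches against ``primer`` (an arbitrary fixed k-mer by
    default; the uniform-random answer does not depend on its identity).
    """
    if not 0 <= max_mm <= k:
        raise ValueError("max_mm must be in [0, k]")
    if not 0.0 < base_match_prob < 1.0:
        raise ValueError("base_match_prob must be in (0, 1)")
    if n_samples is None:
        # mismatches ~ Binomial(k, 1 - q); P(mismatches > max_mm)
        return float(sps.binom.sf(max_mm, k, 1.0 - base_match_prob))
    rng = rng or np.random.default_rng()
    if primer is None:
        primer = ("ACGT" * k)[:k]
    pr = np.frombuffer(primer.encode(), dtype=np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    if sequence is None:
        kmers = bases[rng.integers(0, 4, size=(n_samples, k))]
    else:
        if len(sequence) < k:
            raise ValueError("sequence shorter than k")
        starts = rng.integers(0, len(sequence) - k + 1, size=n_samples)
        arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
        kmers = np.stack([arr[s : s + k] for s in starts])
    mm = (kmers != pr).sum(axis=1)
    return float((mm > max_mm).mean())


def count_multi_umi(corrected_counts: Iterable[int], threshold: int = 1) -> int:
    """Insertions whose corrected UMI count exceeds ``threshold`` (default >1
    UMI, i.e. present in more than one cell)."""
    return sum(1 for c in corrected_counts if c > threshold)


# ---------------------------------------------------------------------------
# per-library summaries
# ---------------------------------------------------------------------------


@dataclass
class LibrarySummary:
    """Read/locus/UMI composition of one sequenced library by class."""

    library_id: str
    total_reads: int = 0
    parsed_reads: int = 0
    mapped_reads: int = 0
    known_target_reads: int = 0
    known_target_loci: int = 0
    other_subfamily_reads: int = 0
    control_reads: int = 0
    somatic_reads: int = 0
    somatic_loci: int = 0
    somatic_umis: int = 0
    somatic_multi_umi_loci: int = 0
    spike_reads: dict[str, int] = field(default_factory=dict)
    spike_umis: dict[str, int] = field(default_factory=dict)
    entropy: float = float("nan")
    somatic_recall: float | None = None
    somatic_precision: float | None = None

    @property
    def somatic_read_fraction(self) -> float:
        return self.somatic_reads / self.total_reads if self.total_reads else 0.0

    def to_row(self) -> dict:
        row = {
            k: getattr(self, k)
            for k in (
                "library_id total_reads parsed_reads mapped_reads known_target_reads "
                "known_target_loci other_subfamily_reads control_reads somatic_reads "
                "somatic_loci somatic_umis somatic_multi_umi_loci entropy "
                "somatic_recall somatic_precision"
            ).split()
        }
        row["somatic_read_fraction"] = self.somatic_read_fraction
        for name, n in sorted(self.spike_reads.items()):
            row[f"spike_reads_{name}"] = n
            row[f"spike_umis_{name}"] = self.spike_umis.get(name, 0)
        return row


def summarize_library(
    library_id: str,
    calls: Sequence,
    parsed: Sequence[ParsedRead],
    spike_hits: Mapping[str, tuple[int, int]] | None = None,
    truth=None,
    layout: ReadLayout = DEFAULT_LAYOUT,
    match_window: int = 5,
) -> LibrarySummary:
    """Aggregate pipeline outputs into a class-composition summary.

    A somatic survivor is a ``putative_somatic`` call with an empty filter
    flag set whose signature passes the subfamily consensus.  ``spike_hits``
    maps spike name to (reads, corrected UMIs).  With a truth registry,
    recall and precision of somatic recovery (junction within
    ``match_window`` bp of a planted somatic locus) are added.
    """
    s = LibrarySummary(library_id=library_id)
    s.total_reads = len(parsed)
    s.parsed_reads = sum(1 for p in parsed if p.accepted)
    read_counts = []
    for call in calls:
        read_counts.append(call.read_count)
        s.mapped_reads += call.read_count
        try:
            sig_ok = check_subfamily_signature(call.signature, layout)
        except ValueError:
            sig_ok = False
        if not sig_ok:
            s.other_subfamily_reads += call.read_count
            continue
        if call.class_label == "known":
            s.known_target_reads += call.read_count
            s.known_target_loci += 1
        elif call.class_label == "control":
            s.control_reads += call.read_count
        elif call.class_label == "putative_somatic" and call.passes_filters:
            s.somatic_reads += call.read_count
            s.somatic_loci += 1
            if call.umi_count_corrected is not None:
                s.somatic_umis += call.umi_count_corrected
                if call.umi_count_corrected > 1:
                    s.somatic_multi_umi_loci += 1
    if read_counts:
        s.entropy = normalized_entropy(read_counts)
    for name, (n_reads, n_umis) in (spike_hits or {}).items():
        s.spike_reads[name] = n_reads
        s.spike_umis[name] = n_umis
    if truth is not None:
        planted = [
            (l.chrom, l.pos, l.strand)
            for l in truth.somatic_loci()
            if l.cells_bearing > 0
        ]
        somatic_calls = [
            c
            for c in calls
            if c.class_label == "putative_somatic" and c.passes_filters
        ]
        hit = 0
        for chrom, pos, strand in planted:
            if any(
                c.chrom == chrom
                and c.strand == strand
                and abs(c.junction_pos - pos) <= match_window
                for c in somatic_calls
            ):
                hit += 1
        s.somatic_recall = hit / len(planted) if planted else None
        if somatic_calls:
            tp = sum(
                1
                for c in somatic_calls
                if any(
                    c.chrom == chrom
                    and c.strand == strand
                    and abs(c.junction_pos - pos) <= match_window
                    for chrom, pos, strand in planted
                )
            )
            s.somatic_precision = tp / len(somatic_calls)
    return s
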