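"""Synthetic amplicon-library generator with ground truth.

Simulates the full wet-lab pathway of a retroelement-flank enrichment
experiment on a toy genome: a random reference with planted fixed (germ-line)
and rare somatic Alu insertions, complete AluI digestion, ligation of
UMI-carrying suppression adapters, subfamily-selective amplification,
addition of foreign spike-in fragments at known cell-equivalent abundances,
and one or more rounds of duplex-specific-nuclease (DSN) normalization
modeled with second-order re-annealing (C0t) kinetics.  Paired-end reads are
then emitted with substitution errors, together with a read-level truth
table, so every downstream analysis stage can be validated against known
ground truth.

Abundances are expressed in molecules: a fixed insertion contributes
``total_cells x copies_per_cell`` molecules (diploid homozygous default 2),
a somatic insertion only ``cells_bearing x copies_per_cell`` (default 1) —
for 50,000 cells a one-cell somatic insertion is outnumbered 100,000:1.

Every ligated molecule carries one UMI drawn uniformly from the 6,561-strong
design space (8 positions x 3-letter alphabet).  The UMI is fixed at
ligation, before any amplification or normalization, so the same molecule
keeps its UMI across all simulated libraries; assignment uses a deterministic
integer mix of (scenario seed, locus, molecule index), which makes the draw
reproducible without materializing millions of molecules.  Loci whose
molecule count exceeds ``explicit_umi_max`` are kept as one pooled fragment
per locus and their molecules' UMIs are resolved lazily at read-emission
time; rare loci (somatic, spike-in) are always materialized per molecule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .read_structure import DEFAULT_LAYOUT, ReadLayout, hamming
from .seq import gc_fraction, revcomp

__all__ = [
    "UMI_ALPHABET",
    "UMI_LENGTH",
    "UMI_SPACE_SIZE",
    "umi_space",
    "ReferenceConfig",
    "ReferenceModel",
    "InsertionLocus",
    "AmpliconFragment",
    "SpikeInDef",
    "NormalizationParams",
    "SimTruth",
    "build_reference",
    "plant_somatic_insertions",
    "fragment_library",
    "add_spike_ins",
    "dsn_normalize",
    "normalize_library",
    "generate_reads",
    "SequencedLibrary",
    "fabricate_artifacts",
    "OTHER_SUBFAMILY_SIGNATURE",
]

RESTRICTION_SITE = "AGCT"  # AluI recognition motif (palindromic)
TARGET_SUBFAMILY = "AluYa5"
OTHER_SUBFAMILY = "AluYb8"
# Two mismatches from the Ya5 consensus, so the subfamily filter rejects it.
OTHER_SUBFAMILY_SIGNATURE = "GATCG"

UMI_ALPHABET = ("A", "C", "T")
UMI_LENGTH = 8
UMI_SPACE_SIZE = len(UMI_ALPHABET) ** UMI_LENGTH  # 6561

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def umi_space() -> list[str]:
    """Enumerate the complete UMI design space (6,561 sequences)."""
    return ["".join(p) for p in itertools.product(UMI_ALPHABET, repeat=UMI_LENGTH)]


def _umi_by_index() -> list[str]:
    global _UMI_BY_INDEX
    if _UMI_BY_INDEX is None:
        _UMI_BY_INDEX = [_umi_from_index(i) for i in range(UMI_SPACE_SIZE)]
    return _UMI_BY_INDEX


_UMI_BY_INDEX: list[str] | None = None


def _umi_from_index(idx: int) -> str:
    digits = []
    for _ in range(UMI_LENGTH):
        idx, d = divmod(idx, 3)
        digits.append(UMI_ALPHABET[d])
    return "".join(digits)


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def _locus_hash(seed: int, locus_id: str) -> int:
    h = _splitmix64(seed & 0xFFFFFFFFFFFFFFFF)
    for ch in locus_id:
        h = _splitmix64(h ^ ord(ch))
    return h


def molecule_umi(seed: int, locus_id: str, molecule_index: int) -> str:
    """UMI ligated to one specific molecule (uniform over the 6,561-space)."""
    h = _splitmix64(_locus_hash(seed, locus_id) ^ molecule_index)
    return _umi_from_index(h % UMI_SPACE_SIZE)


def _molecule_umi_indices(locus_hash: int, molecule_indices: np.ndarray) -> np.ndarray:
    """Vectorized equivalent of :func:`molecule_umi` for one locus."""
    x = np.uint64(locus_hash) ^ molecule_indices.astype(np.uint64)
    x = x + np.uint64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    x = x ^ (x >> np.uint64(31))
    return (x % np.uint64(UMI_SPACE_SIZE)).astype(np.int64)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------


@dataclass
class ReferenceConfig:
    """Parameters for the toy reference genome.

    AluI sites occur at the natural random frequency (~1/256 per position)
    because the genome is uniform random.  Planted loci are required to have
    a flank of ``min_flank``..``max_flank`` bases to the nearest downstream
    AluI site and to be at least ``min_separation`` bp apart.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 100_000}
    )
    n_fixed: int = 50
    n_other: int = 0
    seed: int = 0
    min_flank: int = 30
    max_flank: int = 300
    min_separation: int = 700


@dataclass
class ReferenceModel:
    chromosomes: dict[str, str]
    known_insertions: list[tuple[str, int, str, str]]  # chrom, pos, strand, subfamily
    restriction_site: str = RESTRICTION_SITE

    def __post_init__(self) -> None:
        if len(self.restriction_site) != 4:
            raise ValueError("restriction_site must be a 4-mer")
        for chrom, pos, _strand, _sf in self.known_insertions:
            if not 0 <= pos <= len(self.chromosomes[chrom]):
                raise ValueError(f"insertion at {chrom}:{pos} outside chromosome")

    def flank_of(
        self, chrom: str, pos: int, strand: str, max_distance: int = 600
    ) -> str | None:
        """Genomic flank from the junction to the first AluI site (inclusive).

        Digestion is complete: the flank ends with the restriction motif and
        contains no internal occurrence.  Returns None when no site lies
        within ``max_distance`` of the junction (such loci drop out of the
        library, as they would in the real protocol).
        """
        genome = self.chromosomes[chrom]
        site = self.restriction_site
        if strand == "+":
            i = genome.find(site, pos, pos + max_distance + len(site))
            if i == -1:
                return None
            return genome[pos : i + len(site)]
        i = genome.rfind(site, max(0, pos - max_distance - len(site)), pos)
        if i == -1:
            return None
        return revcomp(genome[i:pos])

    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chromosomes.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_known_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, pos, strand, sf) in enumerate(self.known_insertions):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sf}_{i}\t0\t{strand}\n")


def _place_loci(
    rng: np.random.Generator,
    ref_chroms: dict[str, str],
    n: int,
    cfg: ReferenceConfig,
    occupied: dict[str, list[int]],
) -> list[tuple[str, int, str]]:
    """Sample non-colliding junction positions with a valid flank."""
    names = list(ref_chroms)
    lengths = np.array([len(ref_chroms[c]) for c in names], dtype=float)
    probs = lengths / lengths.sum()
    placed: list[tuple[str, int, str]] = []
    tries = 0
    max_tries = 200 * max(n, 1) + 1000
    tmp_ref = ReferenceModel(ref_chroms, [], RESTRICTION_SITE)
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} loci (placed {len(placed)}): chromosome too "
                "short or too crowded for the requested flank/separation constraints"
            )
        ci = rng.choice(len(names), p=probs)
        chrom = names[ci]
        clen = len(ref_chroms[chrom])
        if clen < 2 * cfg.max_flank + 2:
            raise ValueError(f"chromosome {chrom} shorter than minimum flank span")
        pos = int(rng.integers(cfg.max_flank, clen - cfg.max_flank))
        strand = "+" if rng.random() < 0.5 else "-"
        if any(abs(pos - q) < cfg.min_separation for q in occupied.get(chrom, ())):
            continue
        flank = tmp_ref.flank_of(chrom, pos, strand, cfg.max_flank)
        if flank is None or not (cfg.min_flank <= len(flank) <= cfg.max_flank):
            continue
        occupied.setdefault(chrom, []).append(pos)
        placed.append((chrom, pos, strand))
    return placed


def build_reference(config: ReferenceConfig) -> ReferenceModel:
    """Generate a deterministic toy genome with planted known insertions.

    Known insertions comprise ``n_fixed`` target-subfamily loci plus
    ``n_other`` loci of a non-target Alu subfamily (whose 5' signature fails
    the target consensus and which only enter the library through the
    selective-amplification leak rate).
    """
    rng = np.random.default_rng(config.seed)
    chroms = {
        name: _random_sequence(rng, length)
        for name, length in config.chrom_lengths.items()
    }
    for name, length in config.chrom_lengths.items():
        if length < 2 * config.max_flank + 2:
            raise ValueError(f"chromosome {name} shorter than minimum flank span")
    occupied: dict[str, list[int]] = {}
    known: list[tuple[str, int, str, str]] = []
    for chrom, pos, strand in _place_loci(rng, chroms, config.n_fixed, config, occupied):
        known.append((chrom, pos, strand, TARGET_SUBFAMILY))
    for chrom, pos, strand in _place_loci(rng, chroms, config.n_other, config, occupied):
        known.append((chrom, pos, strand, OTHER_SUBFAMILY))
    return ReferenceModel(chromosomes=chroms, known_insertions=known)


# ---------------------------------------------------------------------------
# loci and truth
# ---------------------------------------------------------------------------


@dataclass
class InsertionLocus:
    id: str
    cls: str  # fixed | polymorphic | somatic | spike_in
    chrom: str
    pos: int
    strand: str
    subfamily_signature: str
    cells_bearing: int
    copies_per_cell: int

    @property
    def molecules(self) -> int:
        return self.cells_bearing * self.copies_per_cell


@dataclass
class SpikeInDef:
    """A foreign control fragment added at a known cell-equivalent abundance."""

    name: str
    length_bp: int
    cells_equivalent: int
    copies_per_cell: int = 1
    mass_ng: float | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.mass_ng is not None and self.mass_ng <= 0:
            raise ValueError("mass_ng must be positive")

    @property
    def molecules(self) -> int:
        return self.cells_equivalent * self.copies_per_cell


@dataclass
class SimTruth:
    """Ground-truth registry of all planted loci and spike-ins."""

    loci: list[InsertionLocus]
    spike_ins: list[SpikeInDef]
    total_cells: int
    seed: int

    def somatic_loci(self) -> list[InsertionLocus]:
        return [l for l in self.loci if l.cls == "somatic"]

    def locus(self, locus_id: str) -> InsertionLocus:
        for l in self.loci:
            if l.id == locus_id:
                return l
        raise KeyError(locus_id)

    def planted_umis(self, locus_id: str) -> list[str]:
        """UMIs ligated to the molecules of one locus (ligation ground truth)."""
        l = self.locus(locus_id)
        return [molecule_umi(self.seed, l.id, m) for m in range(l.molecules)]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus_id\tclass\tchrom\tpos\tstrand\tsignature\t"
                     "cells_bearing\tcopies_per_cell\n")
            for l in self.loci:
                fh.write(
                    f"{l.id}\t{l.cls}\t{l.chrom}\t{l.pos}\t{l.strand}\t"
                    f"{l.subfamily_signature}\t{l.cells_bearing}\t{l.copies_per_cell}\n"
                )


def plant_somatic_insertions(
    ref: ReferenceModel,
    n_somatic: int,
    cell_counts: Sequence[int],
    total_cells: int,
    seed: int = 0,
    copies_per_cell: int = 1,
    layout: ReadLayout = DEFAULT_LAYOUT,
    placement: ReferenceConfig | None = None,
) -> SimTruth:
    """Register known loci and plant rare somatic loci at fresh positions.

    ``cell_counts[i]`` is the number of cells bearing somatic locus ``i``
    (mostly 1, a few more).  A one-cell somatic locus with one copy per cell
    is outnumbered by each fixed locus ``2 * total_cells : 1``.
    """
    if len(cell_counts) != n_somatic:
        raise ValueError("cell_counts must have length n_somatic")
    rng = np.random.default_rng(seed)
    loci: list[InsertionLocus] = []
    counters = {TARGET_SUBFAMILY: 0, OTHER_SUBFAMILY: 0}
    for chrom, pos, strand, sf in ref.known_insertions:
        counters[sf] = counters.get(sf, 0) + 1
        sig = (
            layout.signature_consensus
            if sf == TARGET_SUBFAMILY
            else OTHER_SUBFAMILY_SIGNATURE
        )
        loci.append(
            InsertionLocus(
                id=f"{'fixed' if sf == TARGET_SUBFAMILY else 'other'}_{counters[sf]:05d}",
                cls="fixed",
                chrom=chrom,
                pos=pos,
                strand=strand,
                subfamily_signature=sig,
                cells_bearing=total_cells,
                copies_per_cell=2,
            )
        )
    cfg = placement or ReferenceConfig(
        chrom_lengths={c: len(s) for c, s in ref.chromosomes.items()}
    )
    occupied: dict[str, list[int]] = {}
    for chrom, pos, _strand, _sf in ref.known_insertions:
        occupied.setdefault(chrom, []).append(pos)
    placed = _place_loci(rng, ref.chromosomes, n_somatic, cfg, occupied)
    for i, ((chrom, pos, strand), cells) in enumerate(zip(placed, cell_counts), 1):
        loci.append(
            InsertionLocus(
                id=f"som_{i:04d}",
                cls="somatic",
                chrom=chrom,
                pos=pos,
                strand=strand,
                subfamily_signature=layout.signature_consensus,
                cells_bearing=int(cells),
                copies_per_cell=copies_per_cell,
            )
        )
    return SimTruth(loci=loci, spike_ins=[], total_cells=total_cells, seed=seed)


# ---------------------------------------------------------------------------
# amplicon fragments
# ---------------------------------------------------------------------------


@dataclass
class AmpliconFragment:
    """One UMI-labeled ligated molecule — or a pooled molecule group.

    ``umi is None`` marks a pooled fragment standing for ``pool_size``
    molecules of an abundant locus whose UMIs are resolved lazily at
    read-emission time.  ``abundance`` is a non-negative real molecule
    equivalent (scaled by the subfamily leak rate, PCR bias and DSN
    survival); ``molecule_index`` identifies the source molecule of an
    explicit fragment within its locus.
    """

    locus_id: str
    flank_seq: str
    umi: str | None
    abundance: float
    pool_size: int = 1
    molecule_index: int = 0
    signature: str = "GGCCG"
    is_spike: bool = False

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")

    @property
    def length_bp(self) -> int:
        # 16 bp Alu part (primer + signature) + 27 bp adapter + genomic flank
        return 16 + 27 + len(self.flank_seq)

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.flank_seq)


def fragment_library(
    ref: ReferenceModel,
    truth: SimTruth,
    seed: int = 0,
    layout: ReadLayout = DEFAULT_LAYOUT,
    leak_rate: float = 0.0,
    explicit_umi_max: int = 1000,
    max_site_distance: int = 600,
    amplification_sigma: float = 0.0,
) -> list[AmpliconFragment]:
    """Digest, ligate and selectively amplify the planted loci.

    Each locus yields fragments carrying its flank (junction to first AluI
    site; complete digestion).  Loci whose signature fails the selective
    primer's subfamily consensus are retained at ``leak_rate`` (0 removes
    them entirely).  ``amplification_sigma`` adds per-locus lognormal PCR
    efficiency bias; 0 keeps abundance exactly equal to molecule count.
    Loci with no AluI site within ``max_site_distance`` are dropped with a
    warning, mirroring real locus dropout.
    """
    rng = np.random.default_rng(seed)
    fragments: list[AmpliconFragment] = []
    for locus in truth.loci:
        if locus.cls == "spike_in":
            continue
        mols = locus.molecules
        if mols == 0:
            continue
        flank = ref.flank_of(locus.chrom, locus.pos, locus.strand, max_site_distance)
        if flank is None:
            warnings.warn(
                f"locus {locus.id} has no {ref.restriction_site} site within "
                f"{max_site_distance} bp and was dropped",
                stacklevel=2,
            )
            continue
        on_target = (
            hamming(locus.subfamily_signature, layout.signature_consensus)
            <= layout.signature_max_mismatch
        )
        scale = 1.0 if on_target else leak_rate
        if scale <= 0.0:
            continue
        if amplification_sigma > 0:
            scale *= float(rng.lognormal(0.0, amplification_sigma))
        if mols <= explicit_umi_max:
            for m in range(mols):
                fragments.append(
                    AmpliconFragment(
                        locus_id=locus.id,
                        flank_seq=flank,
                        umi=molecule_umi(truth.seed, locus.id, m),
                        abundance=scale,
                        pool_size=1,
                        molecule_index=m,
                        signature=locus.subfamily_signature,
                    )
                )
        else:
            fragments.append(
                AmpliconFragment(
                    locus_id=locus.id,
                    flank_seq=flank,
                    umi=None,
                    abundance=mols * scale,
                    pool_size=mols,
                    signature=locus.subfamily_signature,
                )
            )
    return fragments


def add_spike_ins(
    fragments: list[AmpliconFragment],
    spike_defs: Sequence[SpikeInDef],
    ref: ReferenceModel,
    truth: SimTruth | None = None,
    seed: int = 0,
    layout: ReadLayout = DEFAULT_LAYOUT,
    amplification_sigma: float = 0.0,
) -> list[AmpliconFragment]:
    """Append foreign spike-in fragments at cells x copies molecule abundance.

    Spike flanks are random sequences absent from the reference (checked by
    20-mer lookup) and free of internal AluI sites, emulating zebrafish-
    derived fragments whose ends are identical to the library's.  The truth
    registry, when given, gains matching ``spike_in`` locus records and the
    spike definitions themselves.
    """
    rng = np.random.default_rng(seed)
    umi_seed = truth.seed if truth is not None else seed
    out = list(fragments)
    for spike in spike_defs:
        flank_len = max(20, spike.length_bp - 16 - 27)
        for _attempt in range(100):
            flank = _random_sequence(rng, flank_len)
            if RESTRICTION_SITE not in flank:
                break
        else:
            raise ValueError(f"could not draw a site-free flank for {spike.name}")
        for i in range(len(flank) - 19):
            kmer = flank[i : i + 20]
            if any(kmer in g or revcomp(kmer) in g for g in ref.chromosomes.values()):
                raise ValueError(
                    f"spike-in {spike.name} flank collides with the reference genome"
                )
        scale = 1.0
        if amplification_sigma > 0:
            scale = float(rng.lognormal(0.0, amplification_sigma))
        for m in range(spike.molecules):
            out.append(
                AmpliconFragment(
                    locus_id=spike.name,
                    flank_seq=flank,
                    umi=molecule_umi(umi_seed, spike.name, m),
                    abundance=scale,
                    pool_size=1,
                    molecule_index=m,
                    signature=layout.signature_consensus,
                    is_spike=True,
                )
            )
        if truth is not None:
            truth.spike_ins.append(spike)
            truth.loci.append(
                InsertionLocus(
                    id=spike.name,
                    cls="spike_in",
                    chrom="*",
                    pos=0,
                    strand="+",
                    subfamily_signature=layout.signature_consensus,
                    cells_bearing=spike.cells_equivalent,
                    copies_per_cell=spike.copies_per_cell,
                )
            )
    return out


# ---------------------------------------------------------------------------
# DSN normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationParams:
    """Second-order re-annealing (C0t) model of one DSN round.

    During renaturation a species of concentration ``C`` re-anneals at a rate
    proportional to ``C``; double-stranded molecules are then destroyed by
    the duplex-specific nuclease.  The surviving single-stranded fraction is
    the classic ``1 / (1 + k*C*t)``, here ``kct_scale`` folds the rate
    constant and renaturation time into one per-molecule factor.
    ``gc_modifier`` optionally scales the effective rate by a monotone
    function of GC fraction (GC-rich duplexes re-anneal faster).  After
    digestion the amplicon is re-amplified to ``reamplification`` total
    molecules (input total when None).
    """

    kct_scale: float = 1e-3
    rounds: int = 1
    gc_modifier: Callable[[float], float] | None = None
    reamplification: float | None = None

    def __post_init__(self) -> None:
        if self.kct_scale < 0:
            raise ValueError("kct_scale must be >= 0")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")


def dsn_normalize(
    abundances: Sequence[float] | np.ndarray,
    params: NormalizationParams,
    gc: Sequence[float] | np.ndarray | None = None,
) -> np.ndarray:
    """Apply ``params.rounds`` DSN rounds to a species-abundance vector.

    Each species ``i`` survives with probability ``1/(1 + kct_scale * C_i *
    g(GC_i))`` and the vector is rescaled to the re-amplification total.
    Order is preserved (``C/(1+kC)`` is increasing in ``C``) and any pairwise
    abundance ratio is compressed toward 1 but never inverted.
    """
    c = np.asarray(abundances, dtype=float).copy()
    if (c < 0).any():
        raise ValueError("abundances must be non-negative")
    if c.size == 0 or params.rounds == 0:
        return c
    if params.gc_modifier is not None and gc is not None:
        g = np.asarray([params.gc_modifier(x) for x in np.asarray(gc, dtype=float)])
    else:
        g = 1.0
    total0 = c.sum()
    target = params.reamplification if params.reamplification is not None else total0
    for _ in range(params.rounds):
        c = c / (1.0 + params.kct_scale * c * g)
        s = c.sum()
        if s > 0:
            c *= target / s
    return c


def normalize_library(
    fragments: Sequence[AmpliconFragment],
    params: NormalizationParams,
    rounds: int | None = None,
) -> list[AmpliconFragment]:
    """DSN-normalize a fragment library, aggregating abundance per species.

    Re-annealing is a property of the nucleotide species, not of individual
    molecules: all fragments of one locus share a survival factor computed
    from their summed abundance.  Returns a new fragment list; input is
    unchanged.
    """
    n_rounds = params.rounds if rounds is None else rounds
    if n_rounds == 0:
        return [replace(f) for f in fragments]
    species: dict[str, float] = {}
    gc_by_species: dict[str, float] = {}
    for f in fragments:
        species[f.locus_id] = species.get(f.locus_id, 0.0) + f.abundance
        gc_by_species.setdefault(f.locus_id, f.gc_fraction)
    keys = sorted(species)
    c_in = np.array([species[k] for k in keys])
    gc = np.array([gc_by_species[k] for k in keys])
    one_round = replace(params, rounds=1)
    total0 = c_in.sum()
    target = params.reamplification if params.reamplification is not None else total0
    out = [replace(f) for f in fragments]
    c = c_in
    for _ in range(n_rounds):
        c_next = dsn_normalize(c, replace(one_round, reamplification=target), gc=gc)
        factor = {
            k: (c_next[i] / c[i] if c[i] > 0 else 0.0) for i, k in enumerate(keys)
        }
        for f in out:
            f.abundance *= factor[f.locus_id]
        c = c_next
    return out


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------


@dataclass
class SequencedLibrary:
    """Paired reads plus the read-level ground truth of their origin."""

    library_id: str
    reads: list[tuple[str, str, str]]  # read_id, r1, r2
    truth: list[tuple[str, str, int, str]]  # read_id, locus_id, molecule, umi

    def write_fastq(self, r1_path, r2_path) -> None:
        import gzip

        def _open(p):
            return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")

        with _open(r1_path) as f1, _open(r2_path) as f2:
            for rid, r1, r2 in self.reads:
                f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tlocus_id\tmolecule_index\tumi\n")
            for rid, locus, mol, umi in self.truth:
                fh.write(f"{rid}\t{locus}\t{mol}\t{umi}\n")


def _inject_errors(
    rng: np.random.Generator, reads: list[str], error_rate: float
) -> list[str]:
    """Independent per-base substitution errors across a read list."""
    if error_rate <= 0:
        return reads
    lengths = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    n_err = rng.binomial(lengths, error_rate)
    out = reads
    hit = np.nonzero(n_err)[0]
    if hit.size == 0:
        return out
    out = list(reads)
    for i in hit:
        s = bytearray(out[i], "ascii")
        for pos in rng.integers(0, len(s), size=int(n_err[i])):
            old = s[pos]
            choices = [b for b in b"ACGT" if b != old]
            s[pos] = choices[int(rng.integers(0, 3))]
        out[i] = s.decode()
    return out


def generate_reads(
    fragments: Sequence[AmpliconFragment],
    depth: int,
    error_rate: float = 0.0,
    layout: ReadLayout = DEFAULT_LAYOUT,
    seed: int = 0,
    library_id: str = "lib",
    umi_seed: int | None = None,
) -> SequencedLibrary:
    """Sample ``depth`` read pairs multinomially over fragment abundances.

    Read 1 is primer + signature + flank, read 2 the adapter (with the
    molecule's UMI) + reverse-complemented flank, both truncated to the
    layout read length.  Substitution errors are applied at ``error_rate``
    per base.  Read identifiers carry no truth information; the mapping of
    read id to source molecule is returned separately.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    abund = np.array([f.abundance for f in fragments], dtype=float)
    total = abund.sum()
    if total <= 0:
        raise ValueError("library has zero total abundance")
    counts = rng.multinomial(depth, abund / total)

    useed = seed if umi_seed is None else umi_seed
    ids: list[str] = []
    r1s: list[str] = []
    r2s: list[str] = []
    truth: list[tuple[str, str, int, str]] = []
    serial = 0
    lazy_umis: dict[str, int] = {}  # locus_id -> precomputed locus hash
    L = layout.read_length
    for frag, n in zip(fragments, counts):
        if n == 0:
            continue
        r1_template = (layout.primer_seq + frag.signature + frag.flank_seq)[:L]
        tail = layout.adapter_suffix + revcomp(frag.flank_seq)
        if frag.umi is not None:
            mols = [frag.molecule_index] * int(n)
            umis = [frag.umi] * int(n)
        else:
            mol_arr = rng.integers(0, frag.pool_size, int(n))
            h = lazy_umis.get(frag.locus_id)
            if h is None:
                h = _locus_hash(useed, frag.locus_id)
                lazy_umis[frag.locus_id] = h
            space = _umi_by_index()
            umis = [space[i] for i in _molecule_umi_indices(h, mol_arr)]
            mols = [int(m) for m in mol_arr]
        for m, u in zip(mols, umis):
            rid = f"{library_id}:{serial:08d}"
            serial += 1
            ids.append(rid)
            r1s.append(r1_template)
            r2s.append((layout.adapter_prefix + u + tail)[:L])
            truth.append((rid, frag.locus_id, m, u))
    r1s = _inject_errors(rng, r1s, error_rate)
    r2s = _inject_errors(rng, r2s, error_rate)
    reads = list(zip(ids, r1s, r2s))
    return SequencedLibrary(library_id=library_id, reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# artifact fabrication (for validating the filter cascade)
# ---------------------------------------------------------------------------


def fabricate_artifacts(
    seed: int = 0, layout: ReadLayout = DEFAULT_LAYOUT
) -> tuple[ReferenceModel, dict[str, dict]]:
    """Build a small reference plus one exemplar of each artifact class.

    Returns records for a clean junction and for the four artifact classes
    the filter cascade must catch: ``ligation_chimera`` (internal AluI site
    in the read flank), ``uncut_site`` (AluI site in the reference span the
    flank covers), ``mispriming`` (primer-like genomic 11-mer abutting the
    junction) and ``template_switch`` (flank prefix copied from a known
    insertion's flank).  Each record holds chrom/pos/strand/flank_seq.
    """
    from .artifact_filters import (
        FilterConfig,
        build_known_flank_index,
        filter_internal_restriction,
        filter_mispriming,
        filter_restriction_region,
        filter_template_switch,
    )

    cfg = ReferenceConfig(
        chrom_lengths={"chrA": 30_000}, n_fixed=5, seed=seed, min_separation=400
    )
    ref = build_reference(cfg)
    genome = ref.chromosomes["chrA"]
    site = ref.restriction_site
    fcfg = FilterConfig(restriction_site=site, primer_seq=layout.primer_seq)
    known_index = build_known_flank_index(ref)

    def _is_clean(pos: int, flank: str) -> bool:
        return not (
            filter_internal_restriction(flank, fcfg)
            or filter_restriction_region(
                ref.chromosomes, "chrA", pos, "+", len(flank), fcfg
            )
            or filter_mispriming(ref.chromosomes, "chrA", pos, "+", fcfg)
            or filter_template_switch(flank, known_index, fcfg) is not None
        )

    def _find_junction(
        min_d: int, max_d: int, lo: int = 0, clean: bool = True
    ) -> tuple[int, str]:
        """Forward-strand junction whose first downstream site is min_d..max_d away."""
        occupied = [p for _c, p, _s, _f in ref.known_insertions]
        pos = lo
        while pos < len(genome) - 1000:
            pos += 97
            if any(abs(pos - q) < 350 for q in occupied):
                continue
            i = genome.find(site, pos, pos + max_d + 4)
            if i == -1 or not (min_d <= i - pos <= max_d):
                continue
            flank = genome[pos : i + 4]
            if clean and not _is_clean(pos, flank):
                continue
            return pos, flank
        raise RuntimeError("no suitable junction found")

    records: dict[str, dict] = {}
    pos, flank = _find_junction(40, 200)
    records["clean"] = {"chrom": "chrA", "pos": pos, "strand": "+", "flank_seq": flank}

    # (a) ligation chimera: two digestion products joined, internal site kept
    pos_b, flank_b = _find_junction(40, 200, lo=pos + 500)
    records["ligation_chimera"] = {
        "chrom": "chrA",
        "pos": pos,
        "strand": "+",
        "flank_seq": flank + flank_b[:30],
    }

    # (b) uncut reference site: read flank runs past a genomic AluI site that
    # sequencing errors have corrupted in the read
    for lo in range(pos_b + 500, len(genome) - 1000, 500):
        pos_u, flank_u = _find_junction(20, 60, lo=lo, clean=False)
        ext = genome[pos_u : pos_u + len(flank_u) + 40]
        i = ext.find(site)
        broken = ext[:i] + "AGAT" + ext[i + 4 :]
        if site in broken:
            broken = broken[: broken.find(site)]  # keep exactly one corrupted site
        if (
            len(broken) >= 20
            and not filter_mispriming(ref.chromosomes, "chrA", pos_u, "+", fcfg)
            and filter_template_switch(broken, known_index, fcfg) is None
        ):
            break
    records["uncut_site"] = {
        "chrom": "chrA",
        "pos": pos_u,
        "strand": "+",
        "flank_seq": broken,
    }

    # (c) mispriming: plant the primer so its 3' end abuts the junction
    pos_c, flank_c = _find_junction(40, 200, lo=pos_u + 500)
    g = bytearray(genome, "ascii")
    g[pos_c - 11 : pos_c] = layout.primer_seq.encode()
    ref.chromosomes["chrA"] = genome = g.decode()
    flank_c = ref.flank_of("chrA", pos_c, "+", 600)
    records["mispriming"] = {
        "chrom": "chrA",
        "pos": pos_c,
        "strand": "+",
        "flank_seq": flank_c,
    }

    # (d) template switch: flank prefix identical to a known insertion's flank
    kc, kp, ks, _sf = ref.known_insertions[0]
    known_flank = ref.flank_of(kc, kp, ks, 600)
    pos_d, flank_d = _find_junction(40, 200, lo=pos_c + 500)
    switched = known_flank[:12] + flank_d[12:]
    if filter_internal_restriction(switched, fcfg):  # seam made a new site; rebuild
        pos_d, flank_d = _find_junction(40, 200, lo=pos_d + 500)
        switched = known_flank[:12] + flank_d[12:]
    records["template_switch"] = {
        "chrom": "chrA",
        "pos": pos_d,
        "strand": "+",
        "flank_seq": switched,
    }
    return ref, records
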