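"""Map genomic flanks, merge junction coordinates, subtract known insertions.

Flanks extracted from the reads are mapped back to the (toy) reference with
an exact-seed mapper; identical junction coordinates are merged into calls;
calls are then intersected with known-insertion databases and with calls
from control tissues of the same individual.  Whatever is left unlabeled is
a putative somatic insertion.

Coordinate convention: the junction position is the first genomic base of
the flank on the mapped strand, 0-based, BED half-open.  On ``+`` the flank
runs rightward from the junction; on ``-`` the flank occupies the interval
ending at the junction and the position reported is its right edge.
Strands are never merged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_structure import ParsedRead
from .seq import revcomp

__all__ = [
    "MappedFlank",
    "JunctionCall",
    "ToyMapper",
    "map_flanks_toy",
    "call_junctions",
    "load_bed",
    "subtract_known",
    "subtract_controls",
    "load_sam_flanks",
    "write_calls_tsv",
    "read_calls_tsv",
]

_MULTI = ("*", -1)  # sentinel for a seed k-mer seen at more than one position


@dataclass
class MappedFlank:
    read_id: str
    chrom: str
    junction_pos: int
    strand: str
    unique: bool
    umi: str
    flank_seq: str = ""
    signature: str = ""


@dataclass
class JunctionCall:
    """Merged insertion-junction coordinate with its supporting evidence."""

    chrom: str
    junction_pos: int
    strand: str
    read_count: int = 0
    umis_raw: Counter = field(default_factory=Counter)
    flank_seq: str = ""  # longest supporting flank (representative)
    signature: str = ""  # most common supporting 5-bp signature
    umi_count_corrected: int | None = None
    filter_flags: set[str] = field(default_factory=set)
    class_label: str = "unlabeled"

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags


class ToyMapper:
    """Exact-seed / bounded-mismatch mapper for synthetic genomes.

    The reference is indexed by every forward ``seed_len``-mer.  A flank maps
    iff the seed of the flank (or of its reverse complement) occurs exactly
    once in the index and full-length extension shows at most
    ``max_mismatch`` substitutions; seeds with multiple index hits, or flanks
    matching in both orientations, are ambiguous and discarded.
    """

    def __init__(self, chromosomes: Mapping[str, str], seed_len: int = 20):
        self.chromosomes = dict(chromosomes)
        self.seed_len = seed_len
        index: dict[str, tuple[str, int]] = {}
        for chrom, seq in self.chromosomes.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if kmer in index:
                    index[kmer] = _MULTI
                else:
                    index[kmer] = (chrom, i)
        self.index = index

    def _extend(self, chrom: str, start: int, query: str, max_mismatch: int) -> bool:
        genome = self.chromosomes[chrom]
        if start + len(query) > len(genome):
            return False
        mm = 0
        for a, b in zip(query, genome[start : start + len(query)]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    return False
        return True

    def map_one(
        self, flank: str, max_mismatch: int = 2
    ) -> tuple[str, int, str] | str:
        """Map one flank; returns (chrom, junction, strand) or a drop reason."""
        if len(flank) < self.seed_len:
            return "too_short"
        hits: list[tuple[str, int, str]] = []
        ambiguous = False
        hit = self.index.get(flank[: self.seed_len])
        if hit is _MULTI:
            ambiguous = True
        elif hit is not None and self._extend(hit[0], hit[1], flank, max_mismatch):
            hits.append((hit[0], hit[1], "+"))
        rc = revcomp(flank)
        hit = self.index.get(rc[: self.seed_len])
        if hit is _MULTI:
            ambiguous = True
        elif hit is not None and self._extend(hit[0], hit[1], rc, max_mismatch):
            hits.append((hit[0], hit[1] + len(flank), "-"))
        if ambiguous or len(hits) > 1:
            return "ambiguous"
        if not hits:
            return "unmapped"
        return hits[0]


def map_flanks_toy(
    parsed: Iterable[ParsedRead],
    ref,
    seed_len: int = 20,
    max_mismatch: int = 2,
    mapper: ToyMapper | None = None,
) -> tuple[list[MappedFlank], Counter]:
    """Map accepted parsed reads; returns unique hits and drop-reason counts.

    ``ref`` is anything with a ``chromosomes`` mapping (or the mapping
    itself).  Results are cached per distinct flank sequence, which collapses
    the dominant case of many reads sharing one fragment.
    """
    chroms = getattr(ref, "chromosomes", ref)
    if mapper is None:
        mapper = ToyMapper(chroms, seed_len)
    cache: dict[str, tuple[str, int, str] | str] = {}
    out: list[MappedFlank] = []
    dropped: Counter = Counter()
    for rec in parsed:
        if rec.qc_flags:
            continue
        res = cache.get(rec.flank_seq)
        if res is None:
            res = mapper.map_one(rec.flank_seq, max_mismatch)
            cache[rec.flank_seq] = res
        if isinstance(res, str):
            dropped[res] += 1
            continue
        chrom, pos, strand = res
        out.append(
            MappedFlank(
                read_id=rec.read_id,
                chrom=chrom,
                junction_pos=pos,
                strand=strand,
                unique=True,
                umi=rec.umi,
                flank_seq=rec.flank_seq,
                signature=rec.signature,
            )
        )
    return out, dropped


def call_junctions(mapped: Iterable[MappedFlank]) -> list[JunctionCall]:
    """Merge identical (chrom, junction, strand) coordinates into calls.

    No fuzzy merging: coordinates one base apart stay distinct calls.
    Output is deterministically sorted by chromosome, position, strand.
    """
    groups: dict[tuple[str, int, str], JunctionCall] = {}
    sigs: dict[tuple[str, int, str], Counter] = {}
    for m in mapped:
        if not m.unique:
            continue
        key = (m.chrom, m.junction_pos, m.strand)
        call = groups.get(key)
        if call is None:
            call = JunctionCall(chrom=m.chrom, junction_pos=m.junction_pos, strand=m.strand)
            groups[key] = call
            sigs[key] = Counter()
        call.read_count += 1
        call.umis_raw[m.umi] += 1
        sigs[key][m.signature] += 1
        if len(m.flank_seq) > len(call.flank_seq):
            call.flank_seq = m.flank_seq
    for key, call in groups.items():
        if sigs[key]:
            call.signature = sigs[key].most_common(1)[0][0]
    return [groups[k] for k in sorted(groups)]


# ---------------------------------------------------------------------------
# known / control subtraction
# ---------------------------------------------------------------------------


def load_bed(path) -> pd.DataFrame:
    """Read a BED6 file, raising with the 1-based line number on bad input."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}: line {lineno}: invalid interval")
            rows.append((parts[0], start, end, parts[3], parts[4], parts[5]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def _position_index(bed: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(sub["start"].to_numpy())
        for chrom, sub in bed.groupby("chrom")
    }


def _near(index: dict[str, np.ndarray], chrom: str, pos: int, window: int) -> bool:
    arr = index.get(chrom)
    if arr is None or arr.size == 0:
        return False
    i = int(np.searchsorted(arr, pos))
    for j in (i - 1, i):
        if 0 <= j < arr.size and abs(int(arr[j]) - pos) <= window:
            return True
    return False


def subtract_known(
    calls: Sequence[JunctionCall], known_bed: pd.DataFrame, window: int = 100
) -> list[JunctionCall]:
    """Label calls within ±window of a known insertion as ``known``."""
    index = _position_index(known_bed)
    for call in calls:
        if call.class_label == "unlabeled" and _near(
            index, call.chrom, call.junction_pos, window
        ):
            call.class_label = "known"
    return list(calls)


def subtract_controls(
    calls: Sequence[JunctionCall],
    control_sets: Sequence[pd.DataFrame],
    window: int = 100,
) -> list[JunctionCall]:
    """Label control-tissue matches; everything still unlabeled is putative.

    ``known`` labels take precedence and are never overwritten.  After this
    step every call carries exactly one of known / control / putative_somatic.
    """
    indices = [_position_index(bed) for bed in control_sets]
    for call in calls:
        if call.class_label != "unlabeled":
            continue
        if any(_near(ix, call.chrom, call.junction_pos, window) for ix in indices):
            call.class_label = "control"
        else:
            call.class_label = "putative_somatic"
    return list(calls)


# ---------------------------------------------------------------------------
# external SAM import and calls TSV round-trip
# ---------------------------------------------------------------------------


def load_sam_flanks(path) -> list[MappedFlank]:
    """Import externally mapped flanks from SAM/BAM.

    Keeps primary, mapped records with MAPQ > 0 (uniqueness proxy).  The UMI
    is taken from the standard ``RX`` tag when present.  The junction is the
    leftmost reference position on forward alignments and the rightmost on
    reverse ones.
    """
    import pysam

    out: list[MappedFlank] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality <= 0:
                continue
            if aln.is_reverse:
                pos, strand = aln.reference_end, "-"
            else:
                pos, strand = aln.reference_start, "+"
            umi = aln.get_tag("RX") if aln.has_tag("RX") else ""
            seq = aln.query_sequence or ""
            if aln.is_reverse:
                seq = revcomp(seq)
            out.append(
                MappedFlank(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    junction_pos=int(pos),
                    strand=strand,
                    unique=True,
                    umi=str(umi),
                    flank_seq=seq,
                )
            )
    return out


def write_calls_tsv(calls: Sequence[JunctionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tjunction_pos\tstrand\tread_count\tumis_raw\tflank_seq\t"
            "signature\tumi_count_corrected\tfilter_flags\tclass_label\n"
        )
        for c in calls:
            umis = ",".join(f"{u}:{n}" for u, n in sorted(c.umis_raw.items()))
            flags = ",".join(sorted(c.filter_flags))
            corrected = "" if c.umi_count_corrected is None else c.umi_count_corrected
            fh.write(
                f"{c.chrom}\t{c.junction_pos}\t{c.strand}\t{c.read_count}\t{umis}\t"
                f"{c.flank_seq}\t{c.signature}\t{corrected}\t{flags}\t{c.class_label}\n"
            )


def read_calls_tsv(path) -> list[JunctionCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for row in df.itertuples(index=False):
        umis = Counter()
        if row.umis_raw:
            for item in row.umis_raw.split(","):
                u, n = item.split(":")
                umis[u] = int(n)
        calls.append(
            JunctionCall(
                chrom=row.chrom,
                junction_pos=int(row.junction_pos),
                strand=row.strand,
                read_count=int(row.read_count),
                umis_raw=umis,
                flank_seq=row.flank_seq,
                signature=row.signature,
                umi_count_corrected=(
                    None if row.umi_count_corrected == "" else int(row.umi_count_corrected)
                ),
                filter_flags=set(row.filter_flags.split(",")) - {""},
                class_label=row.class_label,
            )
        )
    return calls
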