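"""Decompose amplicon read pairs into their designed segments.

Each sequenced molecule in the selective-amplification library has a fixed
anatomy.  Read 1 starts inside the Alu element: an 11-nt subfamily-selective
primer, then the 5-bp 5' terminal Alu fragment (the subfamily signature,
AluYa5 consensus ``GGCCG``), then the unique genomic flank running from the
insertion junction to the nearest AluI site.  Read 2 starts from the ligated
suppression adapter: a 27-nt adapter that embeds the 8-nt unique molecular
identifier (UMI), followed by the reverse complement of the flank.

Parsing strips every library-preparation segment, keeping the UMI and the
signature for downstream quantification and filtering.  The subfamily
consensus check (at most one mismatch to ``GGCCG``) is exposed separately so
the pipeline can apply it as the final artifact filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ReadLayout",
    "ParsedRead",
    "DEFAULT_LAYOUT",
    "hamming",
    "parse_read_pair",
    "check_subfamily_signature",
]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _prefix_mismatches(read: str, ref: str, limit: int) -> int:
    """Mismatches of ``read[:len(ref)]`` vs ``ref``, early-exiting past limit."""
    mm = 0
    for x, y in zip(read, ref):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


@dataclass(frozen=True)
class ReadLayout:
    """Fixed segment layout of a read pair.

    Parameters
    ----------
    primer_seq:
        11-nt subfamily-selective primer at the start of read 1.
    signature_consensus:
        5-bp subfamily consensus immediately after the primer (AluYa5:
        ``GGCCG``).
    signature_max_mismatch:
        Maximum mismatches to the consensus tolerated by the subfamily
        filter (the pipeline's final artifact rule).
    adapter_prefix, adapter_suffix:
        Constant adapter parts flanking the UMI on read 2; prefix length
        defines ``umi_offset``.
    umi_length:
        UMI length; the design space is 3**umi_length sequences (each
        position drawn from a 3-letter alphabet).
    max_fixed_mismatch:
        Mismatch tolerance when locating primer and adapter (no indels).
    read_length:
        Sequencer read length (both mates).
    """

    primer_seq: str = "GGCGCGGTGGC"
    signature_consensus: str = "GGCCG"
    signature_max_mismatch: int = 1
    adapter_prefix: str = "GTGTCAGTCA"
    adapter_suffix: str = "CTGCTGAAC"
    umi_length: int = 8
    max_fixed_mismatch: int = 2
    read_length: int = 100

    def __post_init__(self) -> None:
        if len(self.primer_seq) != 11:
            raise ValueError("primer_seq must be 11 nt")
        if len(self.signature_consensus) != 5:
            raise ValueError("signature_consensus must be 5 nt")
        if self.umi_length != 8:
            raise ValueError("umi_length must be 8")

    @property
    def umi_offset(self) -> int:
        return len(self.adapter_prefix)

    @property
    def adapter_length(self) -> int:
        return len(self.adapter_prefix) + self.umi_length + len(self.adapter_suffix)

    @property
    def r1_prefix_length(self) -> int:
        return len(self.primer_seq) + len(self.signature_consensus)


DEFAULT_LAYOUT = ReadLayout()


@dataclass
class ParsedRead:
    """A read pair reduced to its informative parts.

    ``qc_flags`` is empty for accepted reads; a rejected read carries exactly
    one rejection reason (``too_short``, ``no_primer``, ``no_adapter`` or
    ``no_flank``).
    """

    read_id: str
    umi: str = ""
    signature: str = ""
    flank_seq: str = ""
    qc_flags: set[str] = field(default_factory=set)

    @property
    def accepted(self) -> bool:
        return not self.qc_flags


def parse_read_pair(
    r1: str, r2: str, layout: ReadLayout = DEFAULT_LAYOUT, read_id: str = ""
) -> ParsedRead:
    """Decompose one read pair; never raises on malformed reads.

    The primer must match the start of read 1 and the constant adapter parts
    must match read 2, each within ``layout.max_fixed_mismatch``
    substitutions (no indels).  The UMI and the 5-bp signature are extracted
    verbatim — UMI error correction is deferred to the quantification stage.
    """
    rec = ParsedRead(read_id=read_id)
    if len(r1) < layout.r1_prefix_length or len(r2) < layout.adapter_length:
        rec.qc_flags.add("too_short")
        return rec

    limit = layout.max_fixed_mismatch
    # exact-prefix fast path; count mismatches only when a segment differs
    if not r1.startswith(layout.primer_seq):
        if _prefix_mismatches(r1, layout.primer_seq, limit) > limit:
            rec.qc_flags.add("no_primer")
            return rec

    np_, nu = len(layout.adapter_prefix), layout.umi_length
    suffix_at = r2[np_ + nu : np_ + nu + len(layout.adapter_suffix)]
    if not (r2.startswith(layout.adapter_prefix) and suffix_at == layout.adapter_suffix):
        adapter_mm = _prefix_mismatches(r2, layout.adapter_prefix, limit)
        if adapter_mm <= limit:
            adapter_mm += _prefix_mismatches(
                suffix_at, layout.adapter_suffix, limit - adapter_mm
            )
        if adapter_mm > limit:
            rec.qc_flags.add("no_adapter")
            return rec

    rec.signature = r1[len(layout.primer_seq) : layout.r1_prefix_length]
    rec.flank_seq = r1[layout.r1_prefix_length :]
    rec.umi = r2[np_ : np_ + nu]
    if not rec.flank_seq:
        rec.qc_flags.add("no_flank")
    return rec


def check_subfamily_signature(
    signature: str, layout: ReadLayout = DEFAULT_LAYOUT
) -> bool:
    """True iff the 5-bp signature is within the subfamily-consensus tolerance.

    Accepts at most ``layout.signature_max_mismatch`` (default 1) mismatches
    to the consensus; more than one mismatch marks the read as originating
    from a different Alu subfamily or an artifact.
    """
    if len(signature) != len(layout.signature_consensus):
        raise ValueError(
            f"signature must be {len(layout.signature_consensus)} nt, "
            f"got {len(signature)}"
        )
    return hamming(signature, layout.signature_consensus) <= layout.signature_max_mismatch
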