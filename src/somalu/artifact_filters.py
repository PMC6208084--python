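"""Rule-based removal of library-preparation artifacts.

Four classes of artifactual junctions arise in restriction-ligation amplicon
libraries and are flagged here (the fifth rule, the subfamily-consensus
check on the 5-bp signature, lives with read parsing):

a. ligation chimeras — the read's flank contains an internal AluI site,
   impossible under complete digestion;
b. uncut-site chimeras — the *reference* span covered by the flank contains
   an AluI site closer than the flank end, i.e. the molecule should have
   been cut there (the read escaped rule (a) through a PCR or sequencing
   error in the site);
c. mispriming — a primer-like genomic 11-mer (within 4 mismatches) abuts
   the junction on the priming strand, so the "flank" is likely a primer
   extension product rather than an insertion flank;
d. template switching — the first 12 flank bases are identical to the flank
   of a known insertion.

Filters only flag, never delete: every call keeps a (possibly empty) flag
set, the cascade is idempotent and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .junction_calling import JunctionCall
from .seq import reference_flank, revcomp

__all__ = [
    "FilterConfig",
    "filter_internal_restriction",
    "filter_restriction_region",
    "filter_mispriming",
    "filter_template_switch",
    "build_known_flank_index",
    "apply_filters",
]


@dataclass
class FilterConfig:
    restriction_site: str = "AGCT"
    primer_seq: str = "GGCGCGGTGGC"
    mispriming_max_mismatch: int = 4
    mispriming_window: int = 20
    template_switch_k: int = 12
    region_span: int | None = None  # None: use each call's flank length

    def __post_init__(self) -> None:
        if len(self.restriction_site) != 4:
            raise ValueError("restriction_site must be a 4-mer")
        if len(self.primer_seq) != 11:
            raise ValueError("primer_seq must be 11 nt")


def _internal_site(seq: str, site: str) -> bool:
    """Site occurring strictly inside ``seq`` (a terminal site is the
    expected digestion boundary and passes)."""
    start = 0
    while True:
        i = seq.find(site, start)
        if i == -1:
            return False
        if i + len(site) < len(seq):
            return True
        return False  # occurrence ends exactly at the sequence end


def filter_internal_restriction(flank_seq: str, cfg: FilterConfig) -> bool:
    """Rule (a): True (flagged) iff the flank has an internal AluI site."""
    if not flank_seq:
        raise ValueError("empty flank")
    return _internal_site(flank_seq, cfg.restriction_site)


def filter_restriction_region(
    chromosomes: Mapping[str, str],
    chrom: str,
    junction_pos: int,
    strand: str,
    flank_len: int,
    cfg: FilterConfig,
) -> bool:
    """Rule (b): True iff the reference span the flank covers should have
    been cut — an AluI site ends strictly before the span end.  A site whose
    last base coincides with the span end is the legitimate fragment
    boundary.  Spans running past the chromosome end are truncated first."""
    span = cfg.region_span if cfg.region_span is not None else flank_len
    ref_seq = reference_flank(chromosomes, chrom, junction_pos, strand, span)
    return _internal_site(ref_seq, cfg.restriction_site)


def filter_mispriming(
    chromosomes: Mapping[str, str],
    chrom: str,
    junction_pos: int,
    strand: str,
    cfg: FilterConfig,
) -> bool:
    """Rule (c): True iff a primer-like 11-mer anneals next to the junction.

    A misprimed product's "flank" starts at the 3' end of a genomic primer
    match, so we scan 11-mer windows on the priming strand whose 3' end lies
    within ``mispriming_window`` bp upstream of the junction; a window with
    at most ``mispriming_max_mismatch`` mismatches (inclusive threshold)
    flags the call.
    """
    genome = chromosomes[chrom]
    k = len(cfg.primer_seq)
    w = cfg.mispriming_window
    if strand == "+":
        segment = genome[max(0, junction_pos - w - k) : junction_pos]
    else:
        segment = revcomp(genome[junction_pos : junction_pos + w + k])
    primer = cfg.primer_seq
    limit = cfg.mispriming_max_mismatch
    for i in range(len(segment) - k + 1):
        mm = 0
        window = segment[i : i + k]
        for a, b in zip(window, primer):
            if a != b:
                mm += 1
                if mm > limit:
                    break
        if mm <= limit:
            return True
    return False


def build_known_flank_index(
    ref, known_insertions: Iterable[tuple[str, int, str, str]] | None = None, k: int = 12
) -> set[str]:
    """First ``k`` flank bases of every known insertion (template-switch index)."""
    if known_insertions is None:
        known_insertions = ref.known_insertions
    index: set[str] = set()
    for chrom, pos, strand, _sf in known_insertions:
        prefix = reference_flank(ref.chromosomes, chrom, pos, strand, k)
        if len(prefix) == k:
            index.add(prefix)
    return index


def filter_template_switch(
    flank_seq: str, known_flank_index: set[str], cfg: FilterConfig
) -> str | None:
    """Rule (d): exact-match of the first 12 flank bases against known flanks.

    Returns ``"d"`` when the prefix matches, ``"d_short"`` when the flank is
    shorter than 12 bases (flagged conservatively), None otherwise.
    """
    k = cfg.template_switch_k
    if len(flank_seq) < k:
        return "d_short"
    return "d" if flank_seq[:k] in known_flank_index else None


def apply_filters(
    calls: Sequence[JunctionCall],
    ref,
    known_flank_index: set[str],
    cfg: FilterConfig,
) -> list[JunctionCall]:
    """Run the full cascade (a)–(d) over calls, adding flags in place.

    Idempotent: flags are a set and each rule is a pure predicate of the
    call and reference, so re-application never changes the outcome.
    """
    chroms = getattr(ref, "chromosomes", ref)
    for call in calls:
        if call.flank_seq and filter_internal_restriction(call.flank_seq, cfg):
            call.filter_flags.add("a")
        if filter_restriction_region(
            chroms, call.chrom, call.junction_pos, call.strand, len(call.flank_seq), cfg
        ):
            call.filter_flags.add("b")
        if filter_mispriming(chroms, call.chrom, call.junction_pos, call.strand, cfg):
            call.filter_flags.add("c")
        d = filter_template_switch(call.flank_seq, known_flank_index, cfg)
        if d is not None:
            call.filter_flags.add(d)
    return list(calls)
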