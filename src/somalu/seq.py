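"""Small shared nucleotide-sequence helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def reference_flank(
    chromosomes, chrom: str, junction_pos: int, strand: str, length: int
) -> str:
    """Reference sequence a flank of ``length`` bases would occupy.

    On ``+`` the flank runs rightward from the junction; on ``-`` it runs
    leftward and is returned reverse-complemented (flank orientation).
    Truncated at chromosome ends.
    """
    genome = chromosomes[chrom]
    if strand == "+":
        return genome[junction_pos : junction_pos + length]
    return revcomp(genome[max(0, junction_pos - length) : junction_pos])
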