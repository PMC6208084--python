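"""UMI error correction by Hamming-distance graph clustering.

Sequencing errors turn one true UMI into a cloud of satellites at small
Hamming distance.  For each insertion we build an undirected graph whose
vertices are the observed UMI sequences and whose edges connect UMIs at
Hamming distance <= 1 (one sequencing error); every connected component is
collapsed to its single "parental" UMI — the member with the highest read
count, ties broken lexicographically — and the number of components is the
corrected UMI count, the estimate of how many independent ligation events
(cells) produced the insertion's reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .read_structure import hamming

__all__ = ["UmiComponent", "build_umi_components", "corrected_umi_count", "annotate_calls"]


@dataclass
class UmiComponent:
    members: dict[str, int]  # UMI -> read count
    parental: str


def _graph(umi_counts: Mapping[str, int], max_dist: int) -> nx.Graph:
    umis = list(umi_counts)
    if len({len(u) for u in umis}) > 1:
        raise ValueError("mixed UMI lengths")
    g = nx.Graph()
    g.add_nodes_from(umis)
    for i, u in enumerate(umis):
        for v in umis[i + 1 :]:
            if hamming(u, v) <= max_dist:
                g.add_edge(u, v)
    return g


def build_umi_components(
    umi_counts: Mapping[str, int], max_dist: int = 1
) -> list[UmiComponent]:
    """Cluster a UMI multiset into error-correction components.

    Deterministic: components are returned sorted by their parental UMI, and
    the parental choice breaks read-count ties lexicographically.
    """
    if not umi_counts:
        return []
    g = _graph(umi_counts, max_dist)
    components = []
    for nodes in nx.connected_components(g):
        members = {u: int(umi_counts[u]) for u in sorted(nodes)}
        parental = max(members, key=lambda u: (members[u], [-ord(c) for c in u]))
        components.append(UmiComponent(members=members, parental=parental))
    return sorted(components, key=lambda c: c.parental)


def corrected_umi_count(umi_counts: Mapping[str, int], max_dist: int = 1) -> int:
    """Number of error-corrected UMIs (connected components); 0 when empty."""
    if not umi_counts:
        return 0
    return nx.number_connected_components(_graph(umi_counts, max_dist))


def annotate_calls(calls: Iterable, max_dist: int = 1, labels: Sequence[str] | None = None):
    """Fill ``umi_count_corrected`` on junction calls.

    When ``labels`` is given, only calls whose class_label is listed are
    corrected (the pairwise graph is quadratic in distinct UMIs, and only
    rare-insertion cell counts are biologically meaningful).
    """
    calls = list(calls)
    for call in calls:
        if labels is not None and call.class_label not in labels:
            continue
        call.umi_count_corrected = corrected_umi_count(call.umis_raw, max_dist)
    return calls
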