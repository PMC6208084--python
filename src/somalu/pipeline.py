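"""End-to-end orchestration: simulate -> parse -> call -> filter -> quantify.

``run_pipeline`` reproduces the three-library experimental design in silico:
one amplicon library is simulated, split, and sequenced after 0, 1 and 2
rounds of duplex-specific-nuclease normalization; each library then runs
through the full analysis and the libraries are compared in a report
(enrichment folds, entropy, spike-in recovery, somatic recall against the
planted truth).  A run is fully reproducible from its seed and saved
scenario config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import enrichment_stats as es
from . import junction_calling as jc
from . import synthetic_data as sd
from .artifact_filters import FilterConfig, apply_filters, build_known_flank_index
from .read_structure import DEFAULT_LAYOUT, ReadLayout, check_subfamily_signature, parse_read_pair
from .umi_quant import annotate_calls, corrected_umi_count

__all__ = ["ScenarioConfig", "LibraryResult", "RunResult", "run_pipeline", "analyze_library"]


def _default_spikes() -> list[dict]:
    # two spikes at five cell-equivalents and two at one, as in the real assay
    return [
        {"name": "SP240", "length_bp": 240, "cells_equivalent": 5, "copies_per_cell": 1},
        {"name": "SP389", "length_bp": 389, "cells_equivalent": 5, "copies_per_cell": 1},
        {"name": "SP259", "length_bp": 259, "cells_equivalent": 1, "copies_per_cell": 1},
        {"name": "SP418", "length_bp": 418, "cells_equivalent": 1, "copies_per_cell": 1},
    ]


@dataclass
class ScenarioConfig:
    """One reproducible simulation + analysis scenario.

    Defaults describe the reference in-silico experiment: a 1-Mb genome
    with 500 fixed target-subfamily loci in 5,000 diploid cells, ten somatic
    loci planted in 1-5 cells each, four foreign spike-ins (two at 5 and two
    at 1 cell-equivalents), 200,000 read pairs per library at 0.1%
    substitution error, and libraries sequenced after 0, 1 and 2 DSN rounds.
    """

    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 1_000_000})
    n_fixed: int = 500
    n_other: int = 0
    total_cells: int = 5000
    somatic_cell_counts: list = field(
        default_factory=lambda: [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
    )
    somatic_copies_per_cell: int = 1
    spikes: list = field(default_factory=_default_spikes)
    leak_rate: float = 0.05
    kct_scale: float = 1e-3
    rounds: list = field(default_factory=lambda: [0, 1, 2])
    reamplification: float | None = None
    gc_alpha: float = 0.0  # >0: GC-rich species renature (and deplete) faster
    amplification_sigma: float = 0.8
    depth: int = 200_000
    error_rate: float = 0.001
    explicit_umi_max: int = 1000
    seed_len: int = 20
    map_max_mismatch: int = 2
    intersect_window: int = 100
    mispriming_window: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def normalization_params(self) -> sd.NormalizationParams:
        gc_mod = None
        if self.gc_alpha:
            alpha = self.gc_alpha
            gc_mod = lambda gc: float(np.exp(alpha * (gc - 0.5)))  # noqa: E731
        return sd.NormalizationParams(
            kct_scale=self.kct_scale,
            rounds=1,
            gc_modifier=gc_mod,
            reamplification=self.reamplification,
        )


@dataclass
class LibraryResult:
    library_id: str
    rounds: int
    calls: list
    summary: es.LibrarySummary
    dropped: Mapping[str, int]
    library: sd.SequencedLibrary | None = None


@dataclass
class RunResult:
    config: ScenarioConfig
    ref: sd.ReferenceModel
    truth: sd.SimTruth
    libraries: list[LibraryResult]
    report_text: str = ""

    def library(self, rounds: int) -> LibraryResult:
        for lib in self.libraries:
            if lib.rounds == rounds:
                return lib
        raise KeyError(rounds)


def analyze_library(
    seq_lib: sd.SequencedLibrary,
    ref: sd.ReferenceModel,
    mapper: jc.ToyMapper,
    known_bed: pd.DataFrame,
    control_beds: Sequence[pd.DataFrame],
    known_flank_index: set[str],
    fcfg: FilterConfig,
    spike_registry: Mapping[str, str] | None = None,
    layout: ReadLayout = DEFAULT_LAYOUT,
    window: int = 100,
    map_max_mismatch: int = 2,
    truth: sd.SimTruth | None = None,
):
    """Run one sequenced library through the full analysis.

    Returns (calls, summary, parsed, dropped-reason counts).  Spike-in reads
    are recognized by the first 20 flank bases against the spike registry
    before mapping (their flanks are foreign by construction) and reported
    separately with corrected UMI counts.
    """
    parsed = [
        parse_read_pair(r1, r2, layout, read_id=rid)
        for rid, r1, r2 in seq_lib.reads
    ]
    spike_registry = spike_registry or {}
    spike_reads: dict[str, int] = {}
    spike_umis: dict[str, dict[str, int]] = {}
    to_map = []
    for rec in parsed:
        if not rec.accepted:
            continue
        name = spike_registry.get(rec.flank_seq[:20])
        if name is not None:
            spike_reads[name] = spike_reads.get(name, 0) + 1
            spike_umis.setdefault(name, {})
            spike_umis[name][rec.umi] = spike_umis[name].get(rec.umi, 0) + 1
        else:
            to_map.append(rec)
    mapped, dropped = jc.map_flanks_toy(
        to_map, ref, max_mismatch=map_max_mismatch, mapper=mapper
    )
    calls = jc.call_junctions(mapped)
    jc.subtract_known(calls, known_bed, window)
    jc.subtract_controls(calls, list(control_beds), window)
    apply_filters(calls, ref, known_flank_index, fcfg)
    for call in calls:
        if call.class_label != "putative_somatic":
            continue
        try:
            if not check_subfamily_signature(call.signature, layout):
                call.filter_flags.add("e")
        except ValueError:
            call.filter_flags.add("e")
    annotate_calls(calls, labels=["putative_somatic"])
    spike_hits = {
        name: (spike_reads[name], corrected_umi_count(spike_umis[name]))
        for name in spike_reads
    }
    summary = es.summarize_library(
        seq_lib.library_id, calls, parsed, spike_hits=spike_hits, truth=truth,
        layout=layout,
    )
    return calls, summary, parsed, dropped


def _derive_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(x) & 0x7FFFFFFF for x in state]


def build_report(config: ScenarioConfig, results: list[LibraryResult]) -> str:
    """Comparative markdown report across normalization rounds."""
    lines = ["# Normalization enrichment report", ""]
    lines.append(
        "| library | rounds | reads | somatic reads | somatic fraction | "
        "somatic loci | somatic UMIs | multi-UMI loci | entropy | recall |"
    )
    lines.append("|---|---|---|---|---|---|---|---|---|---|")
    for r in results:
        s = r.summary
        recall = "-" if s.somatic_recall is None else f"{s.somatic_recall:.2f}"
        lines.append(
            f"| {s.library_id} | {r.rounds} | {s.total_reads} | {s.somatic_reads} | "
            f"{s.somatic_read_fraction:.2e} | {s.somatic_loci} | {s.somatic_umis} | "
            f"{s.somatic_multi_umi_loci} | {s.entropy:.3f} | {recall} |"
        )
    if len(results) > 1:
        base = results[0].summary
        lines.append("")
        lines.append("## Enrichment folds vs round-" + str(results[0].rounds))
        for r in results[1:]:
            s = r.summary
            fold_reads = (
                f"{es.fold_change(base.somatic_reads, s.somatic_reads):.1f}"
                if base.somatic_reads
                else "undefined (0 baseline)"
            )
            fold_loci = (
                f"{es.fold_change(base.somatic_loci, s.somatic_loci):.1f}"
                if base.somatic_loci
                else "undefined (0 baseline)"
            )
            lines.append(
                f"- {s.library_id}: somatic reads x{fold_reads}, "
                f"somatic loci x{fold_loci}"
            )
    spike_names = sorted({n for r in results for n in r.summary.spike_reads})
    if spike_names:
        lines.append("")
        lines.append("## Spike-in recovery (reads / corrected UMIs)")
        lines.append("| spike | " + " | ".join(r.summary.library_id for r in results) + " |")
        lines.append("|---|" + "---|" * len(results))
        for name in spike_names:
            cells = [
                f"{r.summary.spike_reads.get(name, 0)} / "
                f"{r.summary.spike_umis.get(name, 0)}"
                for r in results
            ]
            lines.append(f"| {name} | " + " | ".join(cells) + " |")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    config: ScenarioConfig | None = None,
    outdir=None,
    seed: int | None = None,
    control_beds: Sequence[pd.DataFrame] = (),
    write_fastq: bool = False,
    keep_reads: bool = False,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> RunResult:
    """Simulate the scenario and analyze every normalization round.

    ``seed`` overrides ``config.seed``.  With ``outdir``, writes the
    reference FASTA, known-insertion BED, truth TSV, per-library calls and
    summary TSVs, the comparative report and the scenario YAML (and FASTQs
    when requested), making the run re-executable from disk.
    """
    config = config or ScenarioConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    s_ref, s_truth, s_frag, s_spike, s_reads = _derive_seeds(config.seed, 5)

    ref = sd.build_reference(
        sd.ReferenceConfig(
            chrom_lengths=dict(config.chrom_lengths),
            n_fixed=config.n_fixed,
            n_other=config.n_other,
            seed=s_ref,
        )
    )
    truth = sd.plant_somatic_insertions(
        ref,
        n_somatic=len(config.somatic_cell_counts),
        cell_counts=list(config.somatic_cell_counts),
        total_cells=config.total_cells,
        seed=s_truth,
        copies_per_cell=config.somatic_copies_per_cell,
        layout=layout,
    )
    fragments = sd.fragment_library(
        ref,
        truth,
        seed=s_frag,
        layout=layout,
        leak_rate=config.leak_rate,
        explicit_umi_max=config.explicit_umi_max,
        amplification_sigma=config.amplification_sigma,
    )
    spikes = [sd.SpikeInDef(**d) for d in config.spikes]
    fragments = sd.add_spike_ins(
        fragments, spikes, ref, truth=truth, seed=s_spike, layout=layout,
        amplification_sigma=config.amplification_sigma,
    )
    spike_registry = {
        f.flank_seq[:20]: f.locus_id for f in fragments if f.is_spike
    }

    mapper = jc.ToyMapper(ref.chromosomes, seed_len=config.seed_len)
    known_rows = [
        (chrom, pos, pos + 1, f"{sf}_{i}", "0", strand)
        for i, (chrom, pos, strand, sf) in enumerate(ref.known_insertions)
    ]
    known_bed = pd.DataFrame(
        known_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    known_index = build_known_flank_index(ref)
    fcfg = FilterConfig(
        restriction_site=ref.restriction_site,
        primer_seq=layout.primer_seq,
        mispriming_window=config.mispriming_window,
    )
    params = config.normalization_params()

    results: list[LibraryResult] = []
    for i, rounds in enumerate(config.rounds):
        lib_id = {0: "unnormalized"}.get(rounds, f"normalization_{rounds}")
        normalized = sd.normalize_library(fragments, params, rounds=rounds)
        seq_lib = sd.generate_reads(
            normalized,
            depth=config.depth,
            error_rate=config.error_rate,
            layout=layout,
            seed=s_reads + i,
            library_id=lib_id,
            umi_seed=truth.seed,
        )
        calls, summary, parsed, dropped = analyze_library(
            seq_lib,
            ref,
            mapper,
            known_bed,
            control_beds,
            known_index,
            fcfg,
            spike_registry=spike_registry,
            layout=layout,
            window=config.intersect_window,
            map_max_mismatch=config.map_max_mismatch,
            truth=truth,
        )
        results.append(
            LibraryResult(
                library_id=lib_id,
                rounds=rounds,
                calls=calls,
                summary=summary,
                dropped=dict(dropped),
                library=seq_lib if (keep_reads or write_fastq) else None,
            )
        )

    report = build_report(config, results)
    run = RunResult(config=config, ref=ref, truth=truth, libraries=results,
                    report_text=report)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "scenario.yaml")
        ref.write_fasta(out / "reference.fa")
        ref.write_known_bed(out / "known_insertions.bed")
        truth.write_tsv(out / "truth_loci.tsv")
        rows = [r.summary.to_row() for r in results]
        pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "report.md").write_text(report)
        for r in results:
            jc.write_calls_tsv(r.calls, out / f"calls_{r.library_id}.tsv")
            somatic = [
                c
                for c in r.calls
                if c.class_label == "putative_somatic" and c.passes_filters
            ]
            with open(out / f"putative_somatic_{r.library_id}.bed", "w") as fh:
                for j, c in enumerate(somatic):
                    fh.write(
                        f"{c.chrom}\t{c.junction_pos}\t{c.junction_pos + 1}\t"
                        f"som_{j}\t{c.read_count}\t{c.strand}\n"
                    )
            if write_fastq and r.library is not None:
                r.library.write_fastq(
                    out / f"{r.library_id}_R1.fastq.gz",
                    out / f"{r.library_id}_R2.fastq.gz",
                )
                r.library.write_truth_tsv(out / f"{r.library_id}_truth_reads.tsv")
    return run
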