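"""Toy mapping, junction merging and known/control subtraction."""

from collections import Counter

import pytest

from somalu.junction_calling import (
    JunctionCall,
    MappedFlank,
    ToyMapper,
    call_junctions,
    load_bed,
    load_sam_flanks,
    subtract_controls,
    subtract_known,
)
from somalu.read_structure import ParsedRead
from somalu.seq import revcomp
import somalu.junction_calling as jc

import numpy as np


def _genome(seed=0, n=5000):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestToyMapper:
    def setup_method(self):
        self.genome = _genome(1)
        self.mapper = ToyMapper({"c1": self.genome})

    def test_exact_forward_match(self):
        flank = self.genome[1000:1060]
        assert self.mapper.map_one(flank) == ("c1", 1000, "+")

    def test_reverse_match_reports_right_edge_junction(self):
        flank = revcomp(self.genome[1000:1060])
        assert self.mapper.map_one(flank) == ("c1", 1060, "-")

    def test_mismatch_threshold(self):
        flank = list(self.genome[2000:2060])
        for p in (30, 40):
            flank[p] = "A" if flank[p] != "A" else "C"
        assert self.mapper.map_one("".join(flank), max_mismatch=2) == ("c1", 2000, "+")
        flank[50] = "A" if flank[50] != "A" else "C"
        assert self.mapper.map_one("".join(flank), max_mismatch=2) == "unmapped"

    def test_duplicated_seed_is_ambiguous(self):
        seg = self.genome[3000:3040]
        genome = self.genome + seg  # second copy of the whole 40-mer
        mapper = ToyMapper({"c1": genome})
        assert mapper.map_one(seg) == "ambiguous"

    def test_short_flank_discarded(self):
        assert self.mapper.map_one("ACGTACGT") == "too_short"


class TestCallJunctions:
    def _mapped(self, pos, umi, rid="r"):
        return MappedFlank(rid, "c1", pos, "+", True, umi, flank_seq="A" * 30)

    def test_aggregation_of_identical_coordinates(self):
        calls = call_junctions(
            [self._mapped(100, "AAAAAAAA"), self._mapped(100, "AAAAAAAA"),
             self._mapped(100, "AACCAACC")]
        )
        assert len(calls) == 1
        assert calls[0].read_count == 3
        assert calls[0].umis_raw == Counter({"AAAAAAAA": 2, "AACCAACC": 1})

    def test_one_base_apart_stays_distinct(self):
        calls = call_junctions([self._mapped(100, "AAAAAAAA"), self._mapped(101, "AAAAAAAA")])
        assert [c.junction_pos for c in calls] == [100, 101]

    def test_empty_input(self):
        assert call_junctions([]) == []

    def test_strands_never_merged(self):
        plus = self._mapped(100, "AAAAAAAA")
        minus = MappedFlank("r", "c1", 100, "-", True, "AAAAAAAA")
        assert len(call_junctions([plus, minus])) == 2


def _bed_df(rows):
    import pandas as pd

    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


class TestSubtraction:
    def _call(self, pos):
        return JunctionCall(chrom="c1", junction_pos=pos, strand="+")

    def test_window_semantics(self):
        known = _bed_df([("c1", 5050, 5051, "k", "0", "+")])
        call = self._call(5000)
        subtract_known([call], known, window=100)
        assert call.class_label == "known"
        call2 = self._call(5000)
        subtract_known([call2], known, window=10)
        assert call2.class_label == "unlabeled"

    def test_empty_known_set(self):
        call = self._call(1)
        subtract_known([call], _bed_df([]), window=100)
        assert call.class_label == "unlabeled"

    def test_control_and_putative_partition(self):
        controls = [_bed_df([("c1", 900, 901, "ctl", "0", "+")])]
        calls = [self._call(905), self._call(5000)]
        subtract_controls(calls, controls, window=100)
        assert [c.class_label for c in calls] == ["control", "putative_somatic"]

    def test_known_precedence_over_control(self):
        known = _bed_df([("c1", 100, 101, "k", "0", "+")])
        controls = [_bed_df([("c1", 100, 101, "ctl", "0", "+")])]
        call = self._call(100)
        subtract_known([call], known, 100)
        subtract_controls([call], controls, 100)
        assert call.class_label == "known"

    def test_every_call_gets_exactly_one_label(self):
        known = _bed_df([("c1", 100, 101, "k", "0", "+")])
        calls = [self._call(p) for p in (100, 1000, 2000)]
        subtract_known(calls, known, 50)
        subtract_controls(calls, [_bed_df([("c1", 1000, 1001, "c", "0", "+")])], 50)
        labels = [c.class_label for c in calls]
        assert sorted(labels) == ["control", "known", "putative_somatic"]


class TestBedIO:
    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("c1\t10\t11\tx\t0\t+\nc1\tnope\t20\ty\t0\t-\n")
        with pytest.raises(ValueError, match="line 2"):
            load_bed(p)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "ok.bed"
        p.write_text("c1\t10\t11\tx\t0\t+\n# comment\nc2\t5\t6\ty\t0\t-\n")
        df = load_bed(p)
        assert list(df.chrom) == ["c1", "c2"]
        assert list(df.start) == [10, 5]


class TestSamImport:
    def test_positions_strands_and_umis(self, tmp_path):
        sam = tmp_path / "flanks.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:c1\tLN:10000\n"
            "f\t0\tc1\t101\t42\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\tRX:Z:AACCTTAA\n"
            "r\t16\tc1\t201\t42\t30M\t*\t0\t0\t" + "C" * 30 + "\t*\tRX:Z:TTAACCTT\n"
            "low\t0\tc1\t301\t0\t30M\t*\t0\t0\t" + "G" * 30 + "\t*\n"
            "unm\t4\t*\t0\t0\t*\t*\t0\t0\t" + "T" * 30 + "\t*\n"
        )
        flanks = load_sam_flanks(sam)
        assert [(f.read_id, f.junction_pos, f.strand) for f in flanks] == [
            ("f", 100, "+"),   # SAM is 1-based; junction is 0-based start
            ("r", 230, "-"),   # reverse: junction at the right edge
        ]
        assert flanks[0].umi == "AACCTTAA"


class TestSimulatedPartition(object):
    def test_fixed_known_somatic_putative(self, tiny_run):
        lib = tiny_run.library(0)
        labels = {c.class_label for c in lib.calls}
        assert labels <= {"known", "putative_somatic", "control"}
        known_calls = [c for c in lib.calls if c.class_label == "known"]
        assert len(known_calls) >= tiny_run.config.n_fixed  # all fixed loci seen
        som = [c for c in lib.calls if c.class_label == "putative_somatic"]
        planted = {(l.chrom, l.pos) for l in tiny_run.truth.somatic_loci()}
        for c in som:
            if c.passes_filters:
                assert (c.chrom, c.junction_pos) in planted
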