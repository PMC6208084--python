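"""Simulator contracts: reference, fragments, spike-ins, DSN kinetics, reads."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somalu.read_structure import DEFAULT_LAYOUT, parse_read_pair
from somalu.synthetic_data import (
    NormalizationParams,
    ReferenceConfig,
    SpikeInDef,
    UMI_SPACE_SIZE,
    add_spike_ins,
    build_reference,
    dsn_normalize,
    fragment_library,
    generate_reads,
    normalize_library,
    plant_somatic_insertions,
    umi_space,
)

SITE = "AGCT"


def _truth(ref, cells=50_000, cell_counts=(1,), seed=5, copies=1):
    return plant_somatic_insertions(
        ref, len(cell_counts), list(cell_counts), cells, seed=seed,
        copies_per_cell=copies,
    )


class TestReference:
    def test_deterministic_and_in_bounds(self):
        cfg = ReferenceConfig(chrom_lengths={"chr1": 100_000}, n_fixed=50, seed=1)
        ref1, ref2 = build_reference(cfg), build_reference(cfg)
        assert ref1.chromosomes == ref2.chromosomes
        assert ref1.known_insertions == ref2.known_insertions
        assert len(ref1.known_insertions) == 50
        assert all(0 <= p < 100_000 for _c, p, _s, _f in ref1.known_insertions)

    def test_zero_loci_is_a_valid_genome(self):
        ref = build_reference(ReferenceConfig(n_fixed=0, seed=2))
        assert ref.known_insertions == []
        assert len(ref.chromosomes["chr1"]) == 100_000

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_reference(ReferenceConfig(chrom_lengths={"c": 300}, n_fixed=1))

    def test_restriction_site_frequency_is_natural(self, small_ref):
        genome = small_ref.chromosomes["chrA"]
        freq = genome.count(SITE) / len(genome)
        assert 0.5 / 256 < freq < 2 / 256


class TestFragments:
    def test_flanks_end_at_first_site(self, small_ref):
        truth = _truth(small_ref, cells=10)
        for frag in fragment_library(small_ref, truth, seed=1):
            assert frag.flank_seq.endswith(SITE)
            # complete digestion: no occurrence strictly inside
            assert frag.flank_seq.find(SITE) == len(frag.flank_seq) - 4

    def test_abundance_ratio_somatic_vs_fixed(self, small_ref):
        truth = _truth(small_ref, cells=50_000, cell_counts=(1, 5))
        som = truth.somatic_loci()
        fixed = [l for l in truth.loci if l.cls == "fixed"][0]
        assert som[0].molecules / fixed.molecules == 1 / 100_000
        assert som[1].molecules / fixed.molecules == 5 / 100_000

    def test_zero_cells_yields_no_fragments(self, small_ref):
        truth = _truth(small_ref, cells=10, cell_counts=(0,))
        frags = fragment_library(small_ref, truth, seed=1, explicit_umi_max=100)
        assert not any(f.locus_id.startswith("som_") for f in frags)

    def test_explicit_fragments_are_per_molecule(self, small_ref):
        truth = _truth(small_ref, cells=1000, cell_counts=(3,))
        frags = fragment_library(small_ref, truth, seed=1, explicit_umi_max=10)
        som = [f for f in frags if f.locus_id.startswith("som_")]
        assert len(som) == 3 and all(f.abundance == 1.0 for f in som)
        pooled = [f for f in frags if f.umi is None]
        assert all(f.pool_size == 2000 and f.abundance == 2000.0 for f in pooled)

    def test_leak_rate_zero_removes_off_target(self):
        ref = build_reference(
            ReferenceConfig(chrom_lengths={"chr1": 100_000}, n_fixed=5, n_other=5, seed=4)
        )
        truth = _truth(ref, cells=10)
        none_leaked = fragment_library(ref, truth, seed=1, leak_rate=0.0)
        assert not any(f.locus_id.startswith("other_") for f in none_leaked)
        leaked = fragment_library(ref, truth, seed=1, leak_rate=0.1)
        other = [f for f in leaked if f.locus_id.startswith("other_")]
        assert other and all(f.abundance == pytest.approx(0.1) for f in other)

    def test_umis_come_from_design_space(self, small_ref):
        space = set(umi_space())
        assert len(space) == UMI_SPACE_SIZE == 6561
        truth = _truth(small_ref, cells=200, cell_counts=(2, 3))
        for f in fragment_library(small_ref, truth, seed=1, explicit_umi_max=1000):
            assert f.umi in space


class TestSpikeIns:
    def test_molecule_count_parameterization(self, small_ref):
        truth = _truth(small_ref, cells=10)
        spikes = [
            SpikeInDef("SP240", 240, cells_equivalent=5),
            SpikeInDef("SP259", 259, cells_equivalent=1),
        ]
        frags = add_spike_ins([], spikes, small_ref, truth=truth, seed=9)
        by_name = {}
        for f in frags:
            by_name.setdefault(f.locus_id, []).append(f)
        assert sum(f.abundance for f in by_name["SP240"]) == 5
        assert sum(f.abundance for f in by_name["SP259"]) == 1
        assert all(SITE not in f.flank_seq for f in frags)

    def test_equal_definitions_equal_abundance(self, small_ref):
        spikes = [SpikeInDef("A", 300, 2), SpikeInDef("B", 300, 2)]
        frags = add_spike_ins([], spikes, small_ref, seed=1)
        tot = {}
        for f in frags:
            tot[f.locus_id] = tot.get(f.locus_id, 0) + f.abundance
        assert tot["A"] == tot["B"]

    def test_empty_spike_list_is_noop(self, small_ref):
        assert add_spike_ins([], [], small_ref, seed=1) == []

    def test_invalid_definitions_rejected(self):
        with pytest.raises(ValueError):
            SpikeInDef("bad", 0, 1)
        with pytest.raises(ValueError):
            SpikeInDef("bad", 100, 1, mass_ng=-1.0)


class TestDsnNormalize:
    def test_no_digestion_is_proportional(self):
        c = np.array([100.0, 10.0, 1.0])
        out = dsn_normalize(c, NormalizationParams(kct_scale=0.0, rounds=1))
        assert np.allclose(out, c)

    def test_two_species_closed_form(self):
        # survival 100 -> 100/(1+1) = 50, 1 -> 1/1.01; ratio 100:1 -> 50.5:1
        out = dsn_normalize([100.0, 1.0], NormalizationParams(kct_scale=0.01, rounds=1))
        assert out[0] / out[1] == pytest.approx(50 / (1 / 1.01), rel=1e-12)
        assert out[0] / out[1] == pytest.approx(50.5, rel=1e-9)

    def test_equal_species_keep_composition(self):
        out = dsn_normalize([7.0] * 5, NormalizationParams(kct_scale=0.3, rounds=2))
        assert np.allclose(out, out[0])

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            dsn_normalize([-1.0, 2.0], NormalizationParams())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(1e-3, 1e6, allow_nan=False)),
            min_size=2,
            max_size=20,
        ),
        st.floats(1e-6, 1.0),
        st.integers(1, 3),
    )
    def test_order_and_ratio_compression(self, abund, k, rounds):
        c = np.asarray(abund)
        out = dsn_normalize(c, NormalizationParams(kct_scale=k, rounds=rounds))
        order = np.argsort(c, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-9)  # order preserved
        pos = c > 0
        if pos.sum() >= 2:
            i, j = np.argmax(c), np.argmin(np.where(pos, c, np.inf))
            if c[i] > c[j] > 0:
                assert out[i] / out[j] <= c[i] / c[j] + 1e-9
                assert out[i] / out[j] >= 1 - 1e-9

    def test_second_round_compresses_further(self):
        c = [1e5, 1e3, 10.0, 1.0]
        p1 = NormalizationParams(kct_scale=1e-3, rounds=1)
        p2 = NormalizationParams(kct_scale=1e-3, rounds=2)
        r0 = max(c) / min(c)
        out1 = dsn_normalize(c, p1)
        out2 = dsn_normalize(c, p2)
        assert out2.max() / out2.min() < out1.max() / out1.min() < r0

    def test_gc_modifier_depletes_gc_rich_faster(self):
        params = NormalizationParams(
            kct_scale=0.01, rounds=1, gc_modifier=lambda gc: np.exp(2 * (gc - 0.5))
        )
        out = dsn_normalize([100.0, 100.0], params, gc=[0.3, 0.7])
        assert out[0] > out[1]

    def test_library_level_matches_species_level(self, small_ref):
        truth = _truth(small_ref, cells=100, cell_counts=(2,))
        frags = fragment_library(small_ref, truth, seed=1, explicit_umi_max=10)
        params = NormalizationParams(kct_scale=0.005, rounds=1)
        normalized = normalize_library(frags, params)
        species: dict[str, float] = {}
        for f in frags:
            species[f.locus_id] = species.get(f.locus_id, 0.0) + f.abundance
        keys = sorted(species)
        expected = dsn_normalize(
            [species[k] for k in keys], params
        )
        got: dict[str, float] = {}
        for f in normalized:
            got[f.locus_id] = got.get(f.locus_id, 0.0) + f.abundance
        assert np.allclose([got[k] for k in keys], expected)


class TestGenerateReads:
    def _frags(self, ref, cells=50, cell_counts=(2,)):
        truth = _truth(ref, cells=cells, cell_counts=cell_counts)
        return truth, fragment_library(ref, truth, seed=1, explicit_umi_max=10_000)

    def test_depth_must_be_positive(self, small_ref):
        _, frags = self._frags(small_ref)
        with pytest.raises(ValueError):
            generate_reads(frags, depth=0)

    def test_deterministic_for_fixed_seed(self, small_ref):
        _, frags = self._frags(small_ref)
        a = generate_reads(frags, depth=500, error_rate=0.01, seed=11)
        b = generate_reads(frags, depth=500, error_rate=0.01, seed=11)
        assert a.reads == b.reads and a.truth == b.truth

    def test_zero_abundance_fragment_never_sequenced(self, small_ref):
        truth, frags = self._frags(small_ref)
        frags[0].abundance = 0.0
        lib = generate_reads(frags, depth=2000, seed=2)
        assert all(t[1] != frags[0].locus_id or t[2] != frags[0].molecule_index
                   for t in lib.truth)

    def test_error_free_reads_parse_back_exactly(self, small_ref):
        truth, frags = self._frags(small_ref, cells=20, cell_counts=(1, 2))
        by_locus = {}
        for f in frags:
            by_locus.setdefault(f.locus_id, f)
        lib = generate_reads(frags, depth=1000, error_rate=0.0, seed=3)
        layout = DEFAULT_LAYOUT
        for (rid, r1, r2), (tid, locus, _mol, umi) in zip(lib.reads, lib.truth):
            assert rid == tid
            rec = parse_read_pair(r1, r2, layout, read_id=rid)
            assert rec.accepted
            assert rec.umi == umi
            frag = by_locus[locus]
            expect = frag.flank_seq[: layout.read_length - layout.r1_prefix_length]
            assert rec.flank_seq == expect
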