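"""Generator correctness: divergence targets, merging, fragments, alignments, truth."""

import numpy as np
import pysam
import pytest

from homoeophase import (
    SimulationConfig,
    build_merged_reference,
    generate_homoeolog_pair,
    simulate_dataset,
    simulate_fragments,
    write_dataset,
    write_truth,
)
from homoeophase.synthetic_data import (
    read_fragment_origins,
    read_phase_table,
    revcomp,
    _gene_rng,
)


def fixed_pair(length, identity, seed=0, gene_index=0, **kwargs):
    config = SimulationConfig(n_genes=1, gene_length_mean=length, gene_length_sd=0.0,
                              gene_length_min=min(300, length),
                              identity_mean=identity, identity_sd=0.0,
                              identity_bounds=(0.0, 100.0), seed=seed, **kwargs)
    return config, generate_homoeolog_pair(config, gene_index)


class TestGenerateHomoeologPair:
    def test_identity_100_yields_identical_sequences(self):
        _, pair = fixed_pair(1000, 100.0)
        assert pair.seq_a == pair.seq_b
        assert pair.variant_positions == []
        assert pair.realized_identity == 100.0

    def test_substitution_count_is_rounded_expectation(self):
        # 1199 bp at 97.26% identity -> round(32.85) = 33 substitutions
        _, pair = fixed_pair(1199, 97.26)
        assert len(pair.variant_positions) == 33
        assert pair.realized_identity == pytest.approx(100 * (1 - 33 / 1199))

    def test_realized_identity_within_rounding_bound(self):
        config = SimulationConfig(n_genes=1, seed=11)
        pair = generate_homoeolog_pair(config, 0)
        L = pair.length
        n = round(L * (1 - pair.target_identity / 100))
        assert abs(pair.realized_identity - 100 * (1 - n / L)) <= 100 / (2 * L)

    def test_b_allele_differs_from_a_at_every_variant(self):
        _, pair = fixed_pair(2000, 95.0, seed=5)
        for pos, (a, b) in zip(pair.variant_positions, pair.alleles):
            assert pair.seq_a[pos] == a
            assert pair.seq_b[pos] == b
            assert a != b
        positions = pair.variant_positions
        assert positions == sorted(set(positions))

    def test_bad_identity_bounds_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(identity_bounds=(90.0, 101.0))

    def test_gc_content_recovered(self):
        # >= 100 kb of ancestral sequence within 1 point of the 49% target
        config = SimulationConfig(n_genes=100, gene_length_mean=1199, seed=2)
        pairs = [generate_homoeolog_pair(config, i) for i in range(100)]
        seq = "".join(p.seq_a for p in pairs)
        assert len(seq) >= 100_000
        gc = sum(c in "GC" for c in seq) / len(seq)
        assert abs(gc - 0.49) < 0.01


class TestBuildMergedReference:
    def test_switch_prob_zero_is_single_origin(self):
        _, pair = fixed_pair(2000, 95.0, seed=1)
        merged = build_merged_reference(pair, 0.0, np.random.default_rng(0))
        assert len(set(merged.ref_origin)) == 1
        assert merged.n_switches == 0 and not merged.is_chimeric

    def test_switch_prob_one_alternates(self):
        _, pair = fixed_pair(2000, 95.0, seed=1)
        merged = build_merged_reference(pair, 1.0, np.random.default_rng(0))
        n = len(pair.variant_positions)
        assert merged.n_switches == n - 1
        assert all(a != b for a, b in zip(merged.ref_origin, merged.ref_origin[1:]))

    def test_reference_base_matches_recorded_origin(self):
        _, pair = fixed_pair(2000, 95.0, seed=4)
        merged = build_merged_reference(pair, 0.3, np.random.default_rng(3))
        for pos, (a, b), origin in zip(pair.variant_positions, pair.alleles,
                                       merged.ref_origin):
            assert merged.sequence[pos] == (a if origin == "A" else b)
        for i, (ca, cb) in enumerate(zip(pair.seq_a, merged.sequence)):
            if i not in pair.variant_positions:
                assert ca == cb

    def test_mean_switch_count_matches_binomial_expectation(self):
        # 10 variants, p = 0.3 -> E[switches] = 9 x 0.3 = 2.7
        _, pair = fixed_pair(1000, 99.0, seed=6)
        assert len(pair.variant_positions) == 10
        rng = np.random.default_rng(42)
        switches = [build_merged_reference(pair, 0.3, rng).n_switches
                    for _ in range(1000)]
        se = np.sqrt(9 * 0.3 * 0.7 / 1000)
        assert abs(np.mean(switches) - 2.7) < 3 * se


class TestSimulateFragments:
    def test_fragment_count_formula(self):
        # coverage 30, L = 1200, 100 bp reads -> 180 fragments per homoeolog
        config, pair = fixed_pair(1200, 97.0, seed=7)
        frags = simulate_fragments(pair, config, np.random.default_rng(0))
        per_homoeolog = {"A": 0, "B": 0}
        for f in frags:
            per_homoeolog[f.source_homoeolog] += 1
        assert per_homoeolog == {"A": 180, "B": 180}

    def test_error_free_mates_are_exact_substrings(self):
        config, pair = fixed_pair(1200, 97.0, seed=8, base_error_rate=0.0)
        frags = simulate_fragments(pair, config, np.random.default_rng(1))
        for f in frags[:50]:
            source = pair.seq_a if f.source_homoeolog == "A" else pair.seq_b
            window = source[f.start:f.start + f.fragment_length]
            assert f.mate1_seq == window[:100]
            assert f.mate2_seq == revcomp(window[-100:])
            assert f.error_positions == []

    def test_errors_substitute_a_different_base(self):
        config = SimulationConfig(n_genes=1, base_error_rate=0.05, seed=9)
        pair = generate_homoeolog_pair(config, 0)
        frags = simulate_fragments(pair, config, np.random.default_rng(2))
        checked = 0
        for f in frags:
            source = pair.seq_a if f.source_homoeolog == "A" else pair.seq_b
            window = source[f.start:f.start + f.fragment_length]
            clean = {1: window[:100], 2: revcomp(window[-100:])}
            for mate, off in f.error_positions:
                seq = f.mate1_seq if mate == 1 else f.mate2_seq
                assert seq[off] != clean[mate][off]
                checked += 1
        assert checked > 0

    def test_mean_depth_near_twice_per_homoeolog_coverage(self):
        config, pair = fixed_pair(1200, 97.0, seed=10)
        frags = simulate_fragments(pair, config, np.random.default_rng(3))
        depth = np.zeros(pair.length)
        for f in frags:
            depth[f.start:f.start + 100] += 1
            depth[f.start + f.fragment_length - 100:f.start + f.fragment_length] += 1
        assert abs(depth.mean() - 60.0) / 60.0 < 0.10


class TestAlignments:
    def test_sam_nm_reconciles_with_truth(self, tmp_path):
        # Error-free reads: NM equals the number of spanned variant columns
        # whose reference origin differs from the read's source homoeolog.
        config = SimulationConfig(n_genes=3, base_error_rate=0.0, seed=12)
        ds = simulate_dataset(config)
        frag_by_id = {f.fragment_id: f for f in ds.all_fragments()}
        path = tmp_path / "aln.sam"
        with pysam.AlignmentFile(path, "w", header=ds.header) as fh:
            for rec in ds.alignments:
                fh.write(rec)
        n_checked = 0
        with pysam.AlignmentFile(path) as fh:
            for rec in fh:
                frag = frag_by_id[rec.query_name]
                pair = next(p for p in ds.pairs if p.gene_id == frag.gene_id)
                merged = ds.merged[frag.gene_id]
                span = range(rec.reference_start, rec.reference_end)
                expected = sum(
                    1 for pos, origin in zip(pair.variant_positions, merged.ref_origin)
                    if pos in span and origin != frag.source_homoeolog)
                assert rec.get_tag("NM") == expected
                n_checked += 1
        assert n_checked == len(ds.alignments)

    def test_proper_pair_flags_and_tlen(self):
        ds = simulate_dataset(SimulationConfig(n_genes=1, seed=13))
        by_name = {}
        for rec in ds.alignments:
            by_name.setdefault(rec.query_name, []).append(rec)
        for records in by_name.values():
            first = next(r for r in records if r.is_read1)
            second = next(r for r in records if r.is_read2)
            assert first.is_proper_pair and not first.is_reverse
            assert second.is_proper_pair and second.is_reverse
            assert first.template_length == -second.template_length > 0


class TestTruthFiles:
    def test_round_trip_and_vcf_positions(self, tmp_path):
        config = SimulationConfig(n_genes=2, seed=14)
        ds = simulate_dataset(config)
        paths = write_dataset(ds, str(tmp_path / "out"))
        table = read_phase_table(paths["phase_table"])
        assert table == ds.phase_table()
        origins = read_fragment_origins(paths["fragment_origins"])
        assert origins == ds.fragment_origins()
        with pysam.VariantFile(paths["truth_vcf"]) as vcf:
            records = list(vcf)
        truth = ds.phase_table()
        assert len(records) == len(truth)
        for rec in records:
            a, b, origin = truth[(rec.contig, rec.pos)]
            assert rec.alleles == ((a, b) if origin == "A" else (b, a))

    def test_refuses_overwrite_without_force(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(n_genes=1, seed=15))
        write_truth(ds, str(tmp_path))
        with pytest.raises(FileExistsError):
            write_truth(ds, str(tmp_path))
        write_truth(ds, str(tmp_path), force=True)

    def test_zero_genes_gives_header_only_truth(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(n_genes=0, seed=16))
        paths = write_truth(ds, str(tmp_path))
        assert read_phase_table(paths["phase_table"]) == {}
        assert read_fragment_origins(paths["fragment_origins"]) == {}


def test_per_gene_rng_streams_are_order_independent():
    config = SimulationConfig(n_genes=5, seed=17)
    later = generate_homoeolog_pair(config, 3)
    again = generate_homoeolog_pair(config, 3)
    assert later.seq_a == again.seq_a and later.variant_positions == again.variant_positions
    assert _gene_rng(config, 2, 0).integers(10) == _gene_rng(config, 2, 0).integers(10)
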