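"""Fragment extraction, block partitioning, MEC phasing and its exact oracle."""

import numpy as np
import pytest

from conftest import make_header, make_record
from homoeophase import (
    FragmentMatrix,
    FragmentObservation,
    PhasedBlock,
    VariantSite,
    brute_force_phase,
    classify_chimerism,
    extract_fragments,
    partition_blocks,
    phase_block,
    read_blocks,
    write_blocks,
)
from homoeophase.phaser import _mec_of

HEADER = make_header([("c1", 40)])
REF = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"


def site(pos, ref, alt):
    return VariantSite("c1", pos, ref, alt, 10, 10, 20, 0.5)


def matrix_from_rows(rows, n_sites):
    """Rows are strings over {0,1,-} giving each fragment's observations."""
    sites = [site(i + 1, "A", "C") for i in range(n_sites)]
    fragments = []
    for i, row in enumerate(rows):
        obs = {j: int(ch) for j, ch in enumerate(row) if ch != "-"}
        fragments.append(FragmentObservation(f"f{i}", obs, 60))
    return FragmentMatrix("c1", sites, fragments)


class TestExtractFragments:
    SITES = [site(5, "A", "T"), site(9, "A", "G")]   # ref A at both (0-based 4, 8)

    def test_low_mapq_record_excluded_and_tallied(self):
        rec = make_record(HEADER, "f", REF[:10], 0, mapq=29)
        matrix = extract_fragments([rec], self.SITES)
        assert matrix.fragments == []
        assert matrix.excluded_counts["mapq"] == 1

    def test_indel_and_duplicate_records_excluded(self):
        indel = make_record(HEADER, "a", REF[:10], 0, cigar="5M1I4M")
        dup = make_record(HEADER, "b", REF[:10], 0, flag=0x1 | 0x2 | 0x40 | 0x400)
        matrix = extract_fragments([indel, dup], self.SITES)
        assert matrix.excluded_counts["indel"] == 1
        assert matrix.excluded_counts["duplicate"] == 1

    def test_allele_encoding(self):
        # read carries alt T at site 0 (0-based col 4) and ref A at site 1 (col 8)
        seq = list(REF[:10])
        seq[4] = "T"
        rec = make_record(HEADER, "f", "".join(seq), 0)
        matrix = extract_fragments([rec], self.SITES)
        assert matrix.fragments[0].observations == {0: 1, 1: 0}

    def test_conflicting_mates_yield_missing(self):
        s1 = list(REF[:10]); s1[4] = "T"
        s2 = list(REF[:10]); s2[4] = "A"
        recs = [make_record(HEADER, "f", "".join(s1), 0),
                make_record(HEADER, "f", "".join(s2), 0,
                            flag=0x1 | 0x2 | 0x10 | 0x80)]
        matrix = extract_fragments(recs, self.SITES)
        assert 0 not in matrix.fragments[0].observations
        assert matrix.fragments[0].observations == {1: 0}

    def test_third_allele_recorded_as_offsite(self):
        seq = list(REF[:10]); seq[4] = "G"   # neither A nor T
        rec = make_record(HEADER, "f", "".join(seq), 0)
        matrix = extract_fragments([rec], self.SITES)
        frag = matrix.fragments[0]
        assert 0 in frag.offsite_sites and 0 not in frag.observations
        assert matrix.excluded_counts["offsite_allele"] == 1

    def test_empty_site_list_gives_empty_matrix(self):
        rec = make_record(HEADER, "f", REF[:10], 0)
        matrix = extract_fragments([rec], [])
        assert matrix.sites == [] and matrix.fragments == []


class TestPartitionBlocks:
    def test_no_spanning_fragments_gives_singletons(self):
        matrix = matrix_from_rows(["0--", "-1-", "--0"], 3)
        assert partition_blocks(matrix) == [[0], [1], [2]]

    def test_chain_links_transitively(self):
        matrix = matrix_from_rows(["01-", "-10"], 3)
        assert partition_blocks(matrix) == [[0, 1, 2]]

    def test_unbridged_clusters_stay_separate(self):
        matrix = matrix_from_rows(["01--", "--10"], 4)
        assert partition_blocks(matrix) == [[0, 1], [2, 3]]


class TestPhaseBlock:
    def test_noise_free_recovery_with_zero_mec(self):
        truth = "01101"
        comp = "10010"
        rows = [truth, comp, truth[:3] + "--", "--" + comp[2:]]
        matrix = matrix_from_rows(rows, 5)
        block = phase_block(matrix, list(range(5)), seed=0)
        assert block.mec == 0
        assert block.hap0 in ([int(c) for c in truth], [int(c) for c in comp])

    def test_single_flipped_allele_costs_one(self):
        rows = ["0000", "1111", "0000", "1111", "0001"]
        matrix = matrix_from_rows(rows, 4)
        block = phase_block(matrix, list(range(4)), seed=1)
        brute_mec, _ = brute_force_phase(matrix, list(range(4)))
        assert block.mec == brute_mec == 1

    def test_single_site_block(self):
        matrix = matrix_from_rows(["0", "1"], 1)
        block = phase_block(matrix, [0], seed=2)
        assert block.hap0 == [0] and block.mec == 0
        assert not block.chimeric and block.n_switches == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            k = int(rng.integers(2, 9))
            rows = []
            truth = rng.integers(0, 2, k)
            for _ in range(int(rng.integers(2, 15))):
                hap = truth if rng.random() < 0.5 else 1 - truth
                row = "".join(str(int(a)) if rng.random() < 0.8 else "-" for a in hap)
                rows.append(row)
            matrix = matrix_from_rows(rows, k)
            block = phase_block(matrix, list(range(k)), seed=int(rng.integers(2**31)))
            brute_mec, _ = brute_force_phase(matrix, list(range(k)))
            assert block.mec == brute_mec


class TestBruteForce:
    def test_one_site(self):
        matrix = matrix_from_rows(["0"], 1)
        assert brute_force_phase(matrix, [0]) == (0, [0])

    def test_two_sites_majority(self):
        matrix = matrix_from_rows(["00", "00", "01"], 2)
        assert brute_force_phase(matrix, [0, 1]) == (1, [0, 0])

    def test_guard_on_large_blocks(self):
        matrix = matrix_from_rows([], 25)
        with pytest.raises(ValueError):
            brute_force_phase(matrix, list(range(25)))

    def test_never_above_heuristic(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            k = int(rng.integers(2, 7))
            rows = ["".join(rng.choice(list("01-"), k)) for _ in range(8)]
            matrix = matrix_from_rows(rows, k)
            block = phase_block(matrix, list(range(k)), seed=3)
            brute_mec, _ = brute_force_phase(matrix, list(range(k)))
            assert brute_mec <= block.mec


class TestMecInvariance:
    def test_complement_invariance(self):
        rng = np.random.default_rng(13)
        m = rng.integers(-1, 2, size=(20, 6)).astype(np.int8)
        hap = rng.integers(0, 2, 6).astype(np.int8)
        assert _mec_of(m, hap) == _mec_of(m, 1 - hap)


class TestClassifyChimerism:
    @pytest.mark.parametrize("hap0, chimeric, switches", [
        ([0, 0, 0], False, 0),
        ([0, 0, 1, 1], True, 1),
        ([0, 1, 0, 1], True, 3),
        ([0], False, 0),
    ])
    def test_switch_counting(self, hap0, chimeric, switches):
        block = PhasedBlock("c1.b0", "c1", list(range(len(hap0))), hap0, 0, len(hap0))
        assert classify_chimerism(block) == (chimeric, switches)


class TestBlockFile:
    def make_blocks(self):
        sites = {"c1": [site(3, "A", "C"), site(9, "G", "T"), site(15, "T", "A")]}
        blocks = [PhasedBlock("c1.b0", "c1", [0, 1], [0, 1], 2, 2, True, 1),
                  PhasedBlock("c1.b1", "c1", [2], [0], 0, 0)]
        return blocks, sites

    def test_round_trip_is_bit_exact(self, tmp_path):
        blocks, sites = self.make_blocks()
        path1 = tmp_path / "blocks.txt"
        write_blocks(blocks, sites, str(path1))
        text = path1.read_text()
        lines = text.splitlines()
        assert lines[0] == "BLOCK: contig=c1 block=0 sites=2 mec=2"
        assert lines[3] == "********"
        back, info = read_blocks(str(path1))
        path2 = tmp_path / "again.txt"
        rebuilt_sites = {"c1": [site(pos, ref, alt)
                                for _, (pos, ref, alt) in sorted(info["c1"].items())]}
        write_blocks(back, rebuilt_sites, str(path2))
        assert path2.read_text() == text

    def test_empty_block_list_gives_empty_file(self, tmp_path):
        path = tmp_path / "blocks.txt"
        write_blocks([], {}, str(path))
        assert path.read_text() == ""
        assert read_blocks(str(path)) == ([], {})

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("BLOCK: contig=c1 block=0 sites=1 mec=0\nnot a site line\n")
        with pytest.raises(ValueError, match=":2:"):
            read_blocks(str(path))


def test_phased_fraction_on_default_simulation(bench30):
    """At 30x most called homoeo-SNPs should land in multi-site phased blocks."""
    metrics, _ = bench30
    assert metrics["phased_snp_fraction"] >= 0.85
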