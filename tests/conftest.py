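import pysam
import pytest
from hypothesis import HealthCheck, settings

from homoeophase import SimulationConfig, end_to_end_benchmark, run_pipeline

settings.register_profile("suite", derandomize=True, max_examples=50,
                          suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bench30():
    """End-to-end run at the study's default conditions: 30 homoeolog pairs,
    identity ~ N(97.26, 1.20), 2x100 bp reads at 30x per homoeolog, 0.2%
    base error, fixed seed."""
    return end_to_end_benchmark(SimulationConfig(n_genes=30, seed=1))


@pytest.fixture(scope="session")
def noise_free():
    """Error-free 10-gene pipeline run: every stage should be exact."""
    return run_pipeline(SimulationConfig(n_genes=10, base_error_rate=0.0, seed=3))


def make_header(contigs):
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs],
    })


def make_record(header, name, seq, pos, *, contig_index=0, flag=0x1 | 0x2 | 0x40,
                mapq=60, cigar=None, nm=None, quals=None):
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.flag = flag
    rec.reference_id = contig_index
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = cigar or f"{len(seq)}M"
    rec.query_qualities = pysam.qualitystring_to_array(
        quals if quals is not None else "I" * len(seq))
    if nm is not None:
        rec.set_tag("NM", nm)
    return rec
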