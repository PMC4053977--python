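"""Small shared helpers over pysam alignment records."""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
import pysam

# CIGAR ops that consume query/reference (pysam numeric codes)
_MATCH_OPS = {0, 7, 8}        # M, =, X
_QUERY_OPS = {0, 1, 4, 7, 8}  # consume query
_REF_OPS = {0, 2, 3, 7, 8}    # consume reference

BASE_CODES = np.full(128, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    BASE_CODES[ord(b)] = i
    BASE_CODES[ord(b.lower())] = i


def seq_codes(seq: str) -> np.ndarray:
    """Sequence as uint8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def aligned_blocks(record: pysam.AlignedSegment) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (query_positions, reference_positions) arrays per aligned (M/=/X)
    CIGAR block. Faster than get_aligned_pairs for long all-match reads."""
    qpos = 0
    rpos = record.reference_start
    for op, length in record.cigartuples or ():
        if op in _MATCH_OPS:
            yield (np.arange(qpos, qpos + length),
                   np.arange(rpos, rpos + length))
        if op in _QUERY_OPS:
            qpos += length
        if op in _REF_OPS:
            rpos += length


def has_indel(record: pysam.AlignedSegment) -> bool:
    return any(op in (1, 2) for op, _ in record.cigartuples or ())


def group_fragments(alignments: Iterable[pysam.AlignedSegment]
                    ) -> dict[str, list[pysam.AlignedSegment]]:
    """Group records by query name (fragment); insertion-ordered."""
    groups: dict[str, list[pysam.AlignedSegment]] = {}
    for rec in alignments:
        groups.setdefault(rec.query_name, []).append(rec)
    return groups


def read_sam(path: str) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        header = fh.header
        records = [r for r in fh if not r.is_unmapped]
    return header, records
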