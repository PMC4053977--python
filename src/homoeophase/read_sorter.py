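"""Phase-aware read sorting.

Every sequenced fragment that survives the mapping filters is assigned to one
haplotype of one phased block — or set aside. Assignment is strict: a fragment
joins phase 0 or phase 1 only if *all* of its allele observations at the
block's phased sites agree with that haplotype. Fragments carrying
out-of-phase combinations or third alleles (sequencing error, tri-allelic
sites, more than two real haplotypes from recent duplications) are written to
a separate "inconsistent" set with reasons, since some of those variants are
biologically interesting. Strictness trades recall for purity of the
downstream per-phase assemblies, exactly as removing every out-of-phase read
does at corpus scale.

Mates are never split: the fragment is the unit of assignment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pysam

from .phaser import FragmentObservation, PhasedBlock, build_fragment_matrices
from .samutil import group_fragments, has_indel
from .variant_caller import VariantSite

CATEGORIES = ("phase0", "phase1", "inconsistent", "uninformative",
              "filtered_mapq", "filtered_indel", "filtered_duplicate")


@dataclass
class SortReport:
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    per_block: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, category: str, block_id: str | None = None) -> None:
        self.counts[category] += 1
        if block_id is not None:
            block_counts = self.per_block.setdefault(
                block_id, {c: 0 for c in CATEGORIES})
            block_counts[category] += 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def assign_fragment(fragment: FragmentObservation, block: PhasedBlock,
                    mode: str = "strict") -> str:
    """Category of one fragment within one phased block.

    Third-allele evidence at any phased site makes the fragment inconsistent;
    otherwise no observations inside the block means uninformative. In the
    default "strict" mode, unanimity with hap0 or hap1 assigns the phase and
    any mixture is inconsistent; in "majority" mode the phase with more
    matching observations wins and only exact ties are inconsistent.
    """
    if mode not in ("strict", "majority"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    in_block = set(block.site_indices)
    if fragment.offsite_sites & in_block:
        return "inconsistent"
    hap0 = dict(zip(block.site_indices, block.hap0))
    observed = {s: a for s, a in fragment.observations.items() if s in in_block}
    if not observed:
        return "uninformative"
    matches0 = sum(1 for s, a in observed.items() if a == hap0[s])
    if mode == "majority":
        if 2 * matches0 > len(observed):
            return "phase0"
        if 2 * matches0 < len(observed):
            return "phase1"
        return "inconsistent"
    if matches0 == len(observed):
        return "phase0"
    if matches0 == 0:
        return "phase1"
    return "inconsistent"


def sort_fragments(alignments: list[pysam.AlignedSegment],
                   blocks: list[PhasedBlock],
                   sites_by_contig: dict[str, list[VariantSite]],
                   min_mapq: int = 30, min_baseq: int = 20,
                   mode: str = "strict"
                   ) -> tuple[dict[str, tuple[str, str | None]], SortReport]:
    """Assign every fragment in the alignments to a category.

    Returns (fragment_id -> (category, block_id or None), report). Category
    counts sum exactly to the number of distinct fragments. When a fragment
    fails several record-level filters the precedence is duplicate > mapping
    quality > indel; when its observations touch several blocks it is judged
    in the block where it observes the most sites.
    """
    matrices = build_fragment_matrices(alignments, sites_by_contig,
                                       min_mapq=min_mapq, min_baseq=min_baseq)
    obs_by_fragment: dict[str, FragmentObservation] = {}
    for matrix in matrices.values():
        for frag in matrix.fragments:
            obs_by_fragment[frag.fragment_id] = frag
    blocks_by_contig: dict[str, list[PhasedBlock]] = {}
    for block in blocks:
        blocks_by_contig.setdefault(block.contig, []).append(block)

    assignments: dict[str, tuple[str, str | None]] = {}
    report = SortReport()
    for name, records in group_fragments(alignments).items():
        mapped = [r for r in records if not r.is_unmapped]
        if any(r.is_duplicate for r in mapped):
            category, block_id = "filtered_duplicate", None
        elif any(r.mapping_quality < min_mapq for r in mapped):
            category, block_id = "filtered_mapq", None
        elif any(has_indel(r) for r in mapped):
            category, block_id = "filtered_indel", None
        else:
            frag = obs_by_fragment.get(name)
            contig = mapped[0].reference_name if mapped else None
            candidates = blocks_by_contig.get(contig, [])
            block = None
            if frag is not None and candidates:
                touched = frag.observations.keys() | frag.offsite_sites
                best = max(candidates,
                           key=lambda b: len(touched & set(b.site_indices)))
                if touched & set(best.site_indices):
                    block = best
            if block is None:
                category, block_id = "uninformative", None
            else:
                category, block_id = assign_fragment(frag, block, mode), block.block_id
        assignments[name] = (category, block_id)
        report.add(category, block_id)
    return assignments, report


def _load_fastq(path: str) -> dict[str, tuple[str, str]]:
    reads: dict[str, tuple[str, str]] = {}
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            name = entry.name
            if name.endswith("/1") or name.endswith("/2"):
                name = name[:-2]
            reads[name] = (entry.sequence, entry.quality or "I" * len(entry.sequence))
    return reads


def sort_reads(alignments: list[pysam.AlignedSegment],
               blocks: list[PhasedBlock],
               sites_by_contig: dict[str, list[VariantSite]],
               fastq1: str, fastq2: str, outdir: str,
               min_mapq: int = 30, min_baseq: int = 20,
               mode: str = "strict", emit_uninformative: bool = False
               ) -> tuple[dict[str, tuple[str, str | None]], SortReport]:
    """Sort fragments and write per-(block, phase) paired FASTQ files plus an
    inconsistent-fragment FASTQ with a reason sidecar and a TSV report.

    Fragments covering no phased site are not written by default (phase files
    hold only haplotype-informative reads); ``emit_uninformative`` co-assigns
    them to both phase files of the first block on their contig so per-phase
    assemblies see full coverage. Raises if a fragment seen in the alignments
    is missing from the FASTQ.
    """
    assignments, report = sort_fragments(alignments, blocks, sites_by_contig,
                                         min_mapq=min_mapq, min_baseq=min_baseq,
                                         mode=mode)
    reads1 = _load_fastq(fastq1)
    reads2 = _load_fastq(fastq2)
    missing = [n for n in assignments if n not in reads1 or n not in reads2]
    if missing:
        raise KeyError(f"fragment {missing[0]} present in alignments but absent "
                       f"from the FASTQ pair")
    os.makedirs(outdir, exist_ok=True)

    handles: dict[str, tuple] = {}

    def _write(key: str, fname_base: str, name: str) -> None:
        if key not in handles:
            handles[key] = (open(os.path.join(outdir, fname_base + "_1.fastq"), "w"),
                            open(os.path.join(outdir, fname_base + "_2.fastq"), "w"))
        f1, f2 = handles[key]
        s1, q1 = reads1[name]
        s2, q2 = reads2[name]
        f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
        f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")

    first_block_on: dict[str, str] = {}
    for block in blocks:
        first_block_on.setdefault(block.contig, block.block_id)
    contig_of_fragment: dict[str, str] = {}
    if emit_uninformative:
        for rec in alignments:
            if not rec.is_unmapped:
                contig_of_fragment.setdefault(rec.query_name, rec.reference_name)

    with open(os.path.join(outdir, "inconsistent_reasons.tsv"), "w") as reasons:
        reasons.write("fragment_id\tblock_id\treason\n")
        for name, (category, block_id) in assignments.items():
            if category in ("phase0", "phase1"):
                _write(f"{block_id}.{category}", f"{block_id}.{category}", name)
            elif category == "inconsistent":
                _write("inconsistent", "inconsistent", name)
                reasons.write(f"{name}\t{block_id}\tout_of_phase_or_third_allele\n")
            elif category == "uninformative" and emit_uninformative:
                target = first_block_on.get(contig_of_fragment.get(name, ""))
                if target is not None:
                    for phase in ("phase0", "phase1"):
                        _write(f"{target}.{phase}", f"{target}.{phase}", name)
    for f1, f2 in handles.values():
        f1.close()
        f2.close()

    with open(os.path.join(outdir, "sort_report.tsv"), "w") as fh:
        fh.write("scope\t" + "\t".join(CATEGORIES) + "\n")
        fh.write("all\t" + "\t".join(str(report.counts[c]) for c in CATEGORIES) + "\n")
        for block_id in sorted(report.per_block):
            row = report.per_block[block_id]
            fh.write(block_id + "\t" + "\t".join(str(row[c]) for c in CATEGORIES) + "\n")
    return assignments, report
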