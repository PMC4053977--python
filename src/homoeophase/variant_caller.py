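"""Homoeo-SNP detection from read pileups on merged contigs.

On a collapsed contig, reads from the two homoeologs stack on top of each
other, so every fixed A/B difference appears as an apparently heterozygous
biallelic site with roughly balanced allele counts. The caller mirrors the
classic RNA-seq small-variant contract — minimum coverage 4, minimum
alternate observations 2 — with an allele-fraction window standing in for a
diploid genotype likelihood, plus a fragment-level mismatch cap (default 10
per 2x100 bp pair, i.e. a ~95% identity floor) applied before piling up.

Only SNPs are called; adjacent substitutions stay separate sites, and
positions where three or more alleles qualify are skipped but logged so the
read sorter can still treat third alleles as evidence of extra haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .samutil import aligned_blocks, group_fragments, seq_codes

_BASES = "ACGT"


@dataclass(frozen=True)
class CallerConfig:
    min_coverage: int = 4
    min_alt_count: int = 2
    min_baseq: int = 20
    min_mapq: int = 20
    min_alt_fraction: float = 0.2
    max_alt_fraction: float = 0.8
    max_fragment_mismatches: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_alt_fraction <= self.max_alt_fraction <= 1.0):
            raise ValueError("require 0 <= min_alt_fraction <= max_alt_fraction <= 1")
        if min(self.min_coverage, self.min_alt_count, self.min_baseq,
               self.min_mapq, self.max_fragment_mismatches) < 0:
            raise ValueError("counts and quality thresholds must be non-negative")


@dataclass
class VariantSite:
    """A biallelic homoeo-SNP candidate. ``pos`` is 1-based."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int
    depth: int
    alt_fraction: float
    flags: frozenset[str] = frozenset()


@dataclass
class Pileup:
    """Per-contig base counts after quality filtering and mate de-duplication."""

    contig: str
    length: int
    counts: np.ndarray          # shape (4, length): A,C,G,T observations
    triallelic_positions: list[int] = field(default_factory=list)  # filled by call_variants

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def filter_fragments_by_nm(alignments: list[pysam.AlignedSegment],
                           max_fragment_mismatches: int = 10,
                           missing_nm: str = "fail") -> list[pysam.AlignedSegment]:
    """Drop whole fragments whose summed NM across mates exceeds the cap.

    Mirrors a fragment-identity mapping floor: 10 mismatches per 2x100 bp pair
    corresponds to >95% identity. Singletons are judged on their own NM;
    unmapped mates contribute 0. ``missing_nm`` is "fail" (raise) or "pass"
    (treat a record without NM as 0 mismatches).
    """
    def nm_of(rec: pysam.AlignedSegment) -> int:
        if rec.is_unmapped:
            return 0
        if not rec.has_tag("NM"):
            if missing_nm == "pass":
                return 0
            raise ValueError(f"record {rec.query_name} lacks an NM tag")
        return int(rec.get_tag("NM"))

    kept: list[pysam.AlignedSegment] = []
    for name, records in group_fragments(alignments).items():
        if sum(nm_of(r) for r in records) <= max_fragment_mismatches:
            kept.extend(records)
    return kept


def build_pileup(alignments: list[pysam.AlignedSegment],
                 reference: dict[str, str],
                 config: CallerConfig = CallerConfig()) -> dict[str, Pileup]:
    """Column-wise base counts per contig.

    Counts aligned (M/=/X) bases from records with mapq >= min_mapq that are
    not duplicate-flagged, at base quality >= min_baseq. The two mates of a
    fragment contribute a single observation at columns they both cover —
    one if they agree, zero if they disagree — so fragments are never counted
    twice.
    """
    for rec in alignments:
        if rec.reference_name is not None and rec.reference_name not in reference:
            raise KeyError(f"contig {rec.reference_name} in alignments but not in reference")

    pileups = {name: Pileup(name, len(seq), np.zeros((4, len(seq)), dtype=np.int32))
               for name, seq in reference.items()}
    for name, records in group_fragments(alignments).items():
        per_contig: dict[str, tuple[list[np.ndarray], list[np.ndarray]]] = {}
        for rec in records:
            if rec.is_unmapped or rec.is_duplicate or rec.mapping_quality < config.min_mapq:
                continue
            codes = seq_codes(rec.query_sequence)
            quals = np.asarray(rec.query_qualities, dtype=np.int16)
            rlist, blist = per_contig.setdefault(rec.reference_name, ([], []))
            for qpos, rpos in aligned_blocks(rec):
                ok = (quals[qpos] >= config.min_baseq) & (codes[qpos] < 4)
                rlist.append(rpos[ok])
                blist.append(codes[qpos[ok]])
        for contig, (rlist, blist) in per_contig.items():
            r_all = np.concatenate(rlist) if rlist else np.empty(0, dtype=int)
            if r_all.size == 0:
                continue
            b_all = np.concatenate(blist)
            order = np.argsort(r_all, kind="stable")
            r_s, b_s = r_all[order], b_all[order]
            starts = np.nonzero(np.r_[True, r_s[1:] != r_s[:-1]])[0]
            # mates covering the same column count once if they agree, zero if not
            bmin = np.minimum.reduceat(b_s, starts)
            bmax = np.maximum.reduceat(b_s, starts)
            keep = bmin == bmax
            counts = pileups[contig].counts
            np.add.at(counts, (bmin[keep], r_s[starts][keep]), 1)
    return pileups


def call_variants(pileups: dict[str, Pileup], reference: dict[str, str],
                  config: CallerConfig = CallerConfig()) -> dict[str, list[VariantSite]]:
    """Emit biallelic SNP sites from pileups.

    A column is called when depth >= min_coverage, the second-most-frequent
    base has >= min_alt_count observations, the alternate fraction (alt/depth)
    falls inside [min_alt_fraction, max_alt_fraction], exactly two bases reach
    min_alt_count, and the reference base is one of them. Columns with three
    or more qualifying bases are recorded on the pileup as triallelic and
    skipped.
    """
    sites: dict[str, list[VariantSite]] = {}
    for contig, pile in pileups.items():
        ref_codes = seq_codes(reference[contig])
        out: list[VariantSite] = []
        pile.triallelic_positions = []
        depth = pile.depth
        candidates = np.nonzero(depth >= config.min_coverage)[0]
        for col in candidates:
            counts = pile.counts[:, col]
            order = np.argsort(counts, kind="stable")[::-1]
            qualifying = [int(b) for b in order if counts[b] >= config.min_alt_count]
            if len(qualifying) < 2:
                continue
            if len(qualifying) > 2:
                pile.triallelic_positions.append(int(col) + 1)
                continue
            ref_code = int(ref_codes[col])
            if ref_code not in qualifying:
                pile.triallelic_positions.append(int(col) + 1)
                continue
            alt_code = qualifying[0] if qualifying[1] == ref_code else qualifying[1]
            alt_count = int(counts[alt_code])
            total = int(depth[col])
            alt_fraction = alt_count / total
            if not (config.min_alt_fraction <= alt_fraction <= config.max_alt_fraction):
                continue
            out.append(VariantSite(
                contig=contig,
                pos=int(col) + 1,
                ref_allele=_BASES[ref_code],
                alt_allele=_BASES[alt_code],
                ref_count=int(counts[ref_code]),
                alt_count=alt_count,
                depth=total,
                alt_fraction=alt_fraction,
            ))
        sites[contig] = out
    return sites


def write_variants(sites: dict[str, list[VariantSite]], reference: dict[str, str],
                   path: str) -> None:
    """Write called sites as VCF v4.2 with 0/1 genotypes and count INFO fields."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">')
    header.add_line('##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference allele observations">')
    header.add_line('##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele observations">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig, seq in reference.items():
        header.contigs.add(contig, length=len(seq))
    header.add_sample("merged")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for contig in reference:
            for site in sites.get(contig, []):
                rec = vcf.new_record(contig=site.contig, start=site.pos - 1,
                                     stop=site.pos,
                                     alleles=(site.ref_allele, site.alt_allele))
                rec.info["DP"] = site.depth
                rec.info["RO"] = site.ref_count
                rec.info["AO"] = site.alt_count
                rec.samples["merged"]["GT"] = (0, 1)
                vcf.write(rec)


def read_variants(path: str) -> dict[str, list[VariantSite]]:
    """Read a VCF written by write_variants back into VariantSite lists."""
    sites: dict[str, list[VariantSite]] = {}
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: malformed VCF: {exc}") from exc
    with vcf:
        for contig in vcf.header.contigs:
            sites[contig] = []
        for i, rec in enumerate(vcf, start=1):
            if len(rec.alleles) != 2 or any(len(a) != 1 for a in rec.alleles):
                raise ValueError(f"{path}: record {i}: expected a biallelic SNP")
            depth = int(rec.info["DP"])
            ref_count = int(rec.info["RO"])
            alt_count = int(rec.info["AO"])
            sites.setdefault(rec.contig, []).append(VariantSite(
                contig=rec.contig, pos=rec.pos,
                ref_allele=rec.alleles[0], alt_allele=rec.alleles[1],
                ref_count=ref_count, alt_count=alt_count, depth=depth,
                alt_fraction=alt_count / depth if depth else 0.0,
            ))
    return sites
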