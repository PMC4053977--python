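"""Synthetic tetraploid transcriptome generator with truth tracking.

Emulates the situation a de novo assembler leaves behind in an allopolyploid:
each gene exists as an A-genome and a B-genome homoeolog (~97% identical),
but the assembly collapsed both into a single "merged" contig whose sequence
is a mosaic of the two copies. Paired-end reads from both homoeologs map back
onto that merged contig, so every homoeo-SNP looks like a heterozygous site.

All divergence is placed on the B branch (A equals the ancestral draw): the
downstream pipeline only ever sees the A/B difference pattern, and one-sided
divergence keeps the truth bookkeeping trivial.

Coordinates are 0-based half-open in memory; SAM/VCF output is 1-based.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pysam

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated study.

    Defaults mirror the tetraploid wheat setting: mean coding length 1199 bp,
    homoeolog identity ~ Normal(97.26, 1.20) truncated to [90, 100], GC 0.49,
    2x100 bp paired ends at 30x per homoeolog from ~300 bp fragments.
    """

    n_genes: int = 30
    gene_length_mean: float = 1199.0
    gene_length_sd: float = 300.0
    gene_length_min: int = 300
    identity_mean: float = 97.26
    identity_sd: float = 1.20
    identity_bounds: tuple[float, float] = (90.0, 100.0)
    gc_content: float = 0.49
    chimera_switch_prob: float = 0.3
    coverage_per_homoeolog: float = 30.0
    read_length: int = 100
    fragment_size_mean: float = 300.0
    fragment_size_sd: float = 30.0
    base_error_rate: float = 0.002
    indel_rate: float = 0.0
    low_mapq_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.identity_bounds
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError(f"identity_bounds must lie within [0, 100]: {self.identity_bounds}")
        for name in ("chimera_switch_prob", "base_error_rate", "indel_rate",
                     "low_mapq_fraction", "duplicate_fraction", "gc_content"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.fragment_size_mean > self.gene_length_min:
            raise ValueError("fragment_size_mean must not exceed gene_length_min "
                             f"({self.fragment_size_mean} > {self.gene_length_min})")
        if self.read_length <= 0 or self.gene_length_min <= 0 or self.n_genes < 0:
            raise ValueError("read_length, gene_length_min must be positive; n_genes >= 0")
        if self.coverage_per_homoeolog < 0:
            raise ValueError("coverage_per_homoeolog must be non-negative")

    @property
    def base_quality(self) -> int:
        """Constant phred quality implied by the base error rate (40 if error-free)."""
        if self.base_error_rate <= 0:
            return 40
        return int(round(-10.0 * math.log10(self.base_error_rate)))


@dataclass
class HomoeologPairTruth:
    """A simulated homoeolog pair and the exact A/B difference pattern."""

    gene_id: str
    seq_a: str
    seq_b: str
    target_identity: float
    realized_identity: float
    variant_positions: list[int]          # 0-based, strictly increasing
    alleles: list[tuple[str, str]]        # (base in A, base in B) per position

    @property
    def length(self) -> int:
        return len(self.seq_a)


@dataclass
class MergedContig:
    """Collapsed reference contig: A sequence with B alleles spliced in wherever
    the simulated assembler picked the B copy (a chimeric mosaic)."""

    contig_id: str
    sequence: str
    ref_origin: list[str]                 # 'A' or 'B' per variant position

    @property
    def n_switches(self) -> int:
        return sum(1 for a, b in zip(self.ref_origin, self.ref_origin[1:]) if a != b)

    @property
    def is_chimeric(self) -> bool:
        return self.n_switches > 0


@dataclass
class SimulatedFragment:
    fragment_id: str
    gene_id: str
    source_homoeolog: str                 # 'A' or 'B'
    start: int                            # 0-based on the gene
    fragment_length: int
    mate1_seq: str
    mate2_seq: str                        # as sequenced (reverse strand)
    error_positions: list[tuple[int, int]]  # (mate 1|2, offset in sequenced read)


def _gene_rng(config: SimulationConfig, gene_index: int, stream: int) -> np.random.Generator:
    # Per-gene substreams keyed on (seed, gene_index, stage) so gene sets are
    # reproducible regardless of generation order.
    return np.random.default_rng([config.seed, gene_index, stream])


def generate_homoeolog_pair(config: SimulationConfig, gene_index: int) -> HomoeologPairTruth:
    """Draw one homoeolog pair: ancestral sequence at the configured GC, length
    ~ Normal(gene_length_mean, sd) clipped below, percent identity from the
    truncated normal, and that many substitutions placed uniformly without
    replacement on the B copy.

    Uniform placement yields asymptotically exponential inter-SNP spacing,
    matching the near-Poisson spacing seen between real homoeologs.
    """
    rng = _gene_rng(config, gene_index, 0)
    length = max(config.gene_length_min, int(round(rng.normal(config.gene_length_mean,
                                                              config.gene_length_sd))))
    p_gc = config.gc_content / 2.0
    p_at = (1.0 - config.gc_content) / 2.0
    seq_a = "".join(rng.choice(list(_BASES), size=length, p=[p_at, p_gc, p_gc, p_at]))

    lo, hi = config.identity_bounds
    for _ in range(10_000):
        identity = rng.normal(config.identity_mean, config.identity_sd)
        if lo <= identity <= hi:
            break
    else:
        raise ValueError("identity_bounds reject virtually all draws; widen the interval")
    n_sub = int(round(length * (1.0 - identity / 100.0)))
    if n_sub < 0:
        raise ValueError("identity above 100% would imply a negative substitution count")

    positions = sorted(int(p) for p in rng.choice(length, size=n_sub, replace=False))
    b_chars = list(seq_a)
    alleles: list[tuple[str, str]] = []
    for pos in positions:
        ref = b_chars[pos]
        alt = rng.choice([b for b in _BASES if b != ref])
        b_chars[pos] = alt
        alleles.append((ref, alt))
    return HomoeologPairTruth(
        gene_id=f"gene{gene_index:04d}",
        seq_a=seq_a,
        seq_b="".join(b_chars),
        target_identity=float(identity),
        realized_identity=100.0 * (1.0 - n_sub / length),
        variant_positions=positions,
        alleles=alleles,
    )


def build_merged_reference(pair: HomoeologPairTruth, switch_prob: float,
                           rng: np.random.Generator) -> MergedContig:
    """Collapse a pair into one reference contig.

    The assembler's choice of copy is a two-state Markov chain along the
    variant positions: the first variant's origin is Bernoulli(1/2), and each
    subsequent variant switches origin with probability ``switch_prob``.
    switch_prob = 0 gives a pure single-copy reference; higher values give
    chimeric mosaics.
    """
    origins: list[str] = []
    for i in range(len(pair.variant_positions)):
        if i == 0:
            origins.append("A" if rng.random() < 0.5 else "B")
        elif rng.random() < switch_prob:
            origins.append("B" if origins[-1] == "A" else "A")
        else:
            origins.append(origins[-1])
    chars = list(pair.seq_a)
    for pos, (a, b), origin in zip(pair.variant_positions, pair.alleles, origins):
        chars[pos] = a if origin == "A" else b
    return MergedContig(contig_id=pair.gene_id, sequence="".join(chars), ref_origin=origins)


def simulate_fragments(pair: HomoeologPairTruth, config: SimulationConfig,
                       rng: np.random.Generator) -> list[SimulatedFragment]:
    """Simulate paired-end fragments from both homoeologs of one gene.

    Per homoeolog the fragment count is round(coverage x L / (2 x read_length));
    fragment lengths are redrawn until they fit both the read length and the
    gene; sequencing errors are iid per base at ``base_error_rate``, always
    substituting a different base.
    """
    length = pair.length
    n_frags = int(round(config.coverage_per_homoeolog * length / (2.0 * config.read_length)))
    fragments: list[SimulatedFragment] = []
    counter = 0
    for source, seq in (("A", pair.seq_a), ("B", pair.seq_b)):
        for _ in range(n_frags):
            while True:
                fraglen = int(round(rng.normal(config.fragment_size_mean,
                                               config.fragment_size_sd)))
                if config.read_length <= fraglen <= length:
                    break
            start = int(rng.integers(0, length - fraglen + 1))
            frag = seq[start:start + fraglen]
            mate1 = frag[:config.read_length]
            mate2 = revcomp(frag[-config.read_length:])
            errors: list[tuple[int, int]] = []
            if config.base_error_rate > 0:
                mates = [list(mate1), list(mate2)]
                for mate_idx, chars in enumerate(mates, start=1):
                    hits = np.nonzero(rng.random(len(chars)) < config.base_error_rate)[0]
                    for off in hits:
                        chars[off] = rng.choice([b for b in _BASES if b != chars[off]])
                        errors.append((mate_idx, int(off)))
                mate1, mate2 = "".join(mates[0]), "".join(mates[1])
            fragments.append(SimulatedFragment(
                fragment_id=f"{pair.gene_id}:frag{counter:05d}",
                gene_id=pair.gene_id,
                source_homoeolog=source,
                start=start,
                fragment_length=fraglen,
                mate1_seq=mate1,
                mate2_seq=mate2,
                error_positions=errors,
            ))
            counter += 1
    return fragments


def make_sam_header(merged: dict[str, MergedContig]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c.contig_id, "LN": len(c.sequence)} for c in merged.values()],
    })


def _md_and_nm(read_seq: str, ref_seq: str) -> tuple[str, int]:
    """MD tag and NM count for an all-match alignment."""
    md: list[str] = []
    run = 0
    nm = 0
    for q, r in zip(read_seq, ref_seq):
        if q == r:
            run += 1
        else:
            md.append(str(run))
            md.append(r)
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def emit_alignments(fragments: list[SimulatedFragment], merged: MergedContig,
                    config: SimulationConfig, header: pysam.AlignmentHeader,
                    rng: np.random.Generator) -> list[pysam.AlignedSegment]:
    """Place fragments at their known truth coordinates on the merged contig.

    Stands in for a real aligner: all-match CIGARs, exact NM/MD against the
    merged reference, proper-pair flags, signed TLEN. MAPQ is 60 except for a
    configurable fraction of fragments demoted to 20 (and another fraction
    flagged as duplicates) so downstream filters can be exercised.
    """
    records: list[pysam.AlignedSegment] = []
    tid = header.get_tid(merged.contig_id)
    ref = merged.sequence
    rl = config.read_length
    qual = pysam.qualitystring_to_array(chr(config.base_quality + 33) * rl)
    for frag in fragments:
        end = frag.start + frag.fragment_length
        if end > len(ref):
            raise ValueError(f"fragment {frag.fragment_id} extends past contig "
                             f"{merged.contig_id} ({end} > {len(ref)})")
        mapq = 20 if rng.random() < config.low_mapq_fraction else 60
        dup = rng.random() < config.duplicate_fraction
        pos1 = frag.start
        pos2 = end - rl
        aligned2 = revcomp(frag.mate2_seq)
        for which, pos, seq, flag in (
            (1, pos1, frag.mate1_seq, 0x1 | 0x2 | 0x20 | 0x40),
            (2, pos2, aligned2, 0x1 | 0x2 | 0x10 | 0x80),
        ):
            a = pysam.AlignedSegment(header)
            a.query_name = frag.fragment_id
            a.query_sequence = seq
            a.flag = flag | (0x400 if dup else 0)
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{rl}M"
            a.next_reference_id = tid
            a.next_reference_start = pos2 if which == 1 else pos1
            a.template_length = frag.fragment_length if which == 1 else -frag.fragment_length
            a.query_qualities = qual
            md, nm = _md_and_nm(seq, ref[pos:pos + rl])
            a.set_tag("NM", nm)
            a.set_tag("MD", md)
            records.append(a)
    return records


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, truth included."""

    config: SimulationConfig
    pairs: list[HomoeologPairTruth]
    merged: dict[str, MergedContig]
    fragments: dict[str, list[SimulatedFragment]]   # gene_id -> fragments
    header: pysam.AlignmentHeader
    alignments: list[pysam.AlignedSegment]

    def all_fragments(self) -> list[SimulatedFragment]:
        return [f for frags in self.fragments.values() for f in frags]

    def fragment_origins(self) -> dict[str, str]:
        return {f.fragment_id: f.source_homoeolog for f in self.all_fragments()}

    def phase_table(self) -> dict[tuple[str, int], tuple[str, str, str]]:
        """(contig, 1-based pos) -> (A allele, B allele, reference origin)."""
        table: dict[tuple[str, int], tuple[str, str, str]] = {}
        for pair in self.pairs:
            origins = self.merged[pair.gene_id].ref_origin
            for pos, (a, b), origin in zip(pair.variant_positions, pair.alleles, origins):
                table[(pair.gene_id, pos + 1)] = (a, b, origin)
        return table


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator: pairs, merged contigs, fragments, alignments."""
    pairs = [generate_homoeolog_pair(config, i) for i in range(config.n_genes)]
    merged: dict[str, MergedContig] = {}
    fragments: dict[str, list[SimulatedFragment]] = {}
    for i, pair in enumerate(pairs):
        merged[pair.gene_id] = build_merged_reference(
            pair, config.chimera_switch_prob, _gene_rng(config, i, 1))
        fragments[pair.gene_id] = simulate_fragments(pair, config, _gene_rng(config, i, 2))
    header = make_sam_header(merged)
    alignments: list[pysam.AlignedSegment] = []
    for i, pair in enumerate(pairs):
        alignments.extend(emit_alignments(fragments[pair.gene_id], merged[pair.gene_id],
                                          config, header, _gene_rng(config, i, 3)))
    alignments.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    return SimulatedDataset(config, pairs, merged, fragments, header, alignments)


# ---------------------------------------------------------------------------
# file output / truth round-trip

def _check_paths(paths: list[str], force: bool) -> None:
    clashes = [p for p in paths if os.path.exists(p)]
    if clashes and not force:
        raise FileExistsError(f"refusing to overwrite {clashes[0]}; pass force=True")


def write_fasta(path: str, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_dataset(dataset: SimulatedDataset, outdir: str, force: bool = False) -> dict[str, str]:
    """Write reference FASTA, paired FASTQ, SAM and truth files; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference": os.path.join(outdir, "merged_reference.fasta"),
        "homoeologs": os.path.join(outdir, "truth_homoeologs.fasta"),
        "reads1": os.path.join(outdir, "reads_1.fastq"),
        "reads2": os.path.join(outdir, "reads_2.fastq"),
        "alignments": os.path.join(outdir, "alignments.sam"),
    }
    _check_paths(list(paths.values()), force)
    write_fasta(paths["reference"],
                [(c.contig_id, c.sequence) for c in dataset.merged.values()])
    write_fasta(paths["homoeologs"],
                [(f"{p.gene_id}|{h}", s) for p in dataset.pairs
                 for h, s in (("A", p.seq_a), ("B", p.seq_b))])
    qchar = chr(dataset.config.base_quality + 33)
    with open(paths["reads1"], "w") as f1, open(paths["reads2"], "w") as f2:
        for frag in dataset.all_fragments():
            f1.write(f"@{frag.fragment_id}/1\n{frag.mate1_seq}\n+\n{qchar * len(frag.mate1_seq)}\n")
            f2.write(f"@{frag.fragment_id}/2\n{frag.mate2_seq}\n+\n{qchar * len(frag.mate2_seq)}\n")
    with pysam.AlignmentFile(paths["alignments"], "w", header=dataset.header) as sam:
        for rec in dataset.alignments:
            sam.write(rec)
    paths.update(write_truth(dataset, outdir, force=force))
    return paths


def write_truth(dataset: SimulatedDataset, outdir: str, force: bool = False) -> dict[str, str]:
    """Emit the truth VCF, the per-variant phase table, and per-fragment origins."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "truth_vcf": os.path.join(outdir, "truth_variants.vcf"),
        "phase_table": os.path.join(outdir, "truth_phases.tsv"),
        "fragment_origins": os.path.join(outdir, "truth_fragments.tsv"),
    }
    _check_paths(list(paths.values()), force)

    vcf_header = pysam.VariantHeader()
    vcf_header.add_line('##INFO=<ID=ORIGIN,Number=1,Type=String,Description='
                        '"Homoeolog that supplied the reference allele">')
    for contig in dataset.merged.values():
        vcf_header.contigs.add(contig.contig_id, length=len(contig.sequence))
    with pysam.VariantFile(paths["truth_vcf"], "w", header=vcf_header) as vcf:
        for pair in dataset.pairs:
            contig = dataset.merged[pair.gene_id]
            for pos, (a, b), origin in zip(pair.variant_positions, pair.alleles,
                                           contig.ref_origin):
                ref, alt = (a, b) if origin == "A" else (b, a)
                rec = vcf.new_record(contig=pair.gene_id, start=pos, stop=pos + 1,
                                     alleles=(ref, alt))
                rec.info["ORIGIN"] = origin
                vcf.write(rec)

    with open(paths["phase_table"], "w") as fh:
        fh.write("contig\tpos\tallele_a\tallele_b\tref_origin\n")
        for (contig, pos), (a, b, origin) in sorted(dataset.phase_table().items()):
            fh.write(f"{contig}\t{pos}\t{a}\t{b}\t{origin}\n")

    with open(paths["fragment_origins"], "w") as fh:
        fh.write("fragment_id\tgene_id\tsource_homoeolog\tstart\tfragment_length\n")
        for frag in dataset.all_fragments():
            fh.write(f"{frag.fragment_id}\t{frag.gene_id}\t{frag.source_homoeolog}\t"
                     f"{frag.start}\t{frag.fragment_length}\n")
    return paths


def read_phase_table(path: str) -> dict[tuple[str, int], tuple[str, str, str]]:
    table: dict[tuple[str, int], tuple[str, str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise ValueError(f"{path}: not a phase table")
        for line in fh:
            contig, pos, a, b, origin = line.rstrip("\n").split("\t")
            table[(contig, int(pos))] = (a, b, origin)
    return table


def read_fragment_origins(path: str) -> dict[str, str]:
    origins: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("fragment_id\t"):
            raise ValueError(f"{path}: not a fragment-origin table")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            origins[fields[0]] = fields[2]
    return origins
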