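# Methods

## The separation model

A collapsed contig in a homozygous allotetraploid carries reads from two
near-identical sequences. Because the organism is homozygous within each
subgenome, every well-supported biallelic site on a contig is interpreted as
a fixed A/B homoeolog difference, not an allelic polymorphism. Phasing those
sites into two haplotypes and splitting the reads accordingly reconstructs
the two gene copies. Three assumptions underlie the pipeline:

- **Homozygosity within subgenomes** — heterozygous sites within A or B
  would appear as extra haplotypes; such evidence (third alleles,
  out-of-phase reads) is quarantined, never forced into a phase.
- **Colinearity** — reads with insertions or deletions relative to the
  contig are excluded before phasing, so phased reads can be stacked
  column-wise against the reference.
- **Biallelism** — sites with three or more qualifying alleles (close
  paralogs, recent duplications) are skipped by the caller but logged, and
  fragments showing a third allele at a phased site are sorted to the
  inconsistent set.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `max_fragment_mismatches` | 10 | mismatches / read pair | 200 bp at ≥95% identity ⇒ ≤10 homoeo-SNPs; the one knob to adjust for other divergence levels |
| `min_coverage` | 4 | reads | minimum pileup depth to consider a column |
| `min_alt_count` | 2 | reads | both alleles must be seen twice; a single error read never creates a site |
| `min_alt_fraction`–`max_alt_fraction` | 0.2–0.8 | fraction | heterozygosity window standing in for a diploid genotype likelihood; widen for skewed homoeolog expression |
| `min_mapq` (phasing/sorting) | 30 | phred | reads that map ambiguously between paralogs do not inform phase |
| `min_baseq` | 20 | phred | bases below the floor are treated as missing, keeping MEC unweighted |
| `restarts` | 20 | — | local-search restarts per block |

The caller's mapq floor is 20 (calling tolerates mildly ambiguous mappings;
phasing does not). The allele-fraction window is a deliberate simplification
of genotype likelihoods: monotone, directly testable, and adequate when both
homoeologs are expressed within a 4:1 ratio.

## Phasing algorithm

Sites co-observed by at least one fragment (mate pairs pooled) form the
linkage graph; connected components are blocks. Contigs whose SNPs are
farther apart than a fragment span split into several blocks that cannot be
phased relative to each other — at 30× with ~300 bp fragments and ~37 bp
mean SNP spacing this is rare, at low coverage it is the dominant loss mode.

Per block the two-haplotype assignment minimizes unweighted MEC by
alternating local search: (i) assign each fragment to the haplotype with
fewer mismatches (ties stay put), (ii) reset each site to the majority
allele among assigned fragments (ties keep the current allele), iterate to a
fixed point, restart 20 times from seeded random vectors, keep the best MEC
with ties broken toward the lexicographically smaller of hap0 and its
complement. The greedy max-cut heuristics traditional in haplotype assembly
were deliberately replaced: at transcript scale (tens of sites, hundreds of
fragments per block) the local search reaches the exhaustive-search optimum
essentially always, and `brute_force_phase` (2^(k−1) enumeration, guarded to
k ≤ 20) verifies this directly in the test suite — 100% agreement on
noise-free random instances, ≥95% with 5% observation noise.

MEC is unweighted because a base-quality floor plus constant simulated
qualities make weights uninformative here, and unweighted MEC keeps the
oracle exact. Since the reference allele is code 0 at every site, hap0
restricted to a block is the reference's origin pattern: any adjacent change
in hap0 marks a chimeric junction in the original contig, which is how
blocks are classified chimeric/non-chimeric and how switch counts are
recovered.

## Read sorting

Strict unanimity, not majority vote: a fragment joins a phase only if every
observation at the block's sites matches that haplotype (a majority mode
exists behind a flag, default off). This maximizes the purity of per-phase
read sets at the cost of recall, mirroring the corpus-scale practice of
excluding every out-of-phase read. Filter precedence when a fragment fails
several record-level filters: duplicate, then mapping quality, then indel.
Category counts are conserved exactly — each fragment lands in exactly one
of {phase0, phase1, inconsistent, uninformative, filtered_*} — and the
invariant is asserted on every run.

## Consensus

Reference-guided column-majority consensus replaces de novo re-assembly of
each phased read set: upstream indel filtering makes phased reads colinear
with the reference, so majority-per-column (quality ≥ 20) is exact on clean
data; ties resolve to the phased allele at phased sites and the reference
base elsewhere. Zero-coverage columns split segments, which makes the
"fraction of the original contig recovered by phased sequence" metric well
defined. Users wanting a real assembler feed it the exported per-phase
FASTQ.

## The synthetic generator

What it emulates: homoeolog pairs with percent identity drawn from
Normal(97.26, 1.20) truncated to [90, 100]; gene lengths Normal(1199, 300)
clipped at 300 bp; ancestral GC 0.49; substitutions placed uniformly without
replacement (asymptotically exponential spacing — uniform order statistics
are a binomial point process); chimeric merged references whose per-variant
origin follows a two-state Markov chain with switch probability 0.3
(essentially every multi-SNP contig chimeric, the hard case); 2×100 bp
paired reads from Normal(300, 30) fragments at 30× per homoeolog with 0.2%
uniform base error and constant base quality round(−10·log10(e)).

All divergence sits on the B branch; only the difference pattern matters
downstream, and one-sided divergence keeps truth bookkeeping exact.
Per-gene RNG substreams are keyed on (seed, gene index, stage), so any gene
is reproducible in isolation.

What it does not emulate — and what passing tests therefore do not show
about real data: SNP clustering (real homoeo-SNP spacing is overdispersed
relative to Poisson, with more very short gaps), indels between homoeologs
(an optional indel mode exists only to exercise the filters), quality decay
along reads and machine-specific error profiles, expression-level variation
between genes and between homoeologs, paralogous multi-mapping, splice
variants, and real aligner behavior (alignments are emitted at known truth
coordinates with exact NM/MD). Accuracy on real libraries is bounded above
by these results.

## Numerical and statistical choices

- **Exponential-spacing check.** Inter-SNP gaps are positive integers, so a
  KS test against a continuous exponential rejects on discreteness alone
  (no mass below 1). The check applies the standard U(0,1) continuity
  correction, and standardizes each gene's gaps by its own SNP density
  before pooling: pooled raw gaps across genes of differing identity form a
  rate mixture of exponentials, which is not exponential, while the
  exponential law being asserted holds within genes. The pooled sample is
  capped at a seeded 2000 gaps, where the continuous approximation is
  accurate.
- **The 32.9 figure** produced by `expected_snp_count(1199, 97.26)` is an
  expected substitution count; it is close to, but conceptually distinct
  from, the mean inter-SNP distance, and the docstring says so.
- **Inclusion fractions** come from the normal CDF; empirical retention on
  small curated gene sets can run below the model value (97.0% vs an
  empirically reported ~95% at a 95% threshold) — the model value is
  reported, never silently adjusted.
- **Ties** break deterministically everywhere (documented per function);
  every stochastic component consumes an explicit seed, and a full
  `run-all` is byte-reproducible.
- **Degenerate inputs**: zero genes produce header-only outputs; empty site
  lists produce empty matrices with filter tallies; single-site blocks are
  emitted unphased (hap0 = [0], MEC 0); identity 100 produces variant-free
  pairs.

## Problem sizes

The benchmark configuration is 30 genes (~1000 homoeo-SNPs, ~21,000 read
pairs), which gives the phasing-accuracy estimate a resolution of roughly
0.1 percentage points — comfortably sharper than the 98.7% benchmark it is
compared against. Property suites use 10-gene noise-free runs, 100 random
MEC instances of up to 10 sites, and 500-gene generator-recovery samples.

## Known limitations

- Two phases only: a third real haplotype is detected (and quarantined) but
  never reconstructed; hexaploids need a generalization.
- Blocks on one contig are phased independently; A/B assignments are not
  linked across blocks or contigs.
- The consensus cannot recover sequence where a phase has no coverage, and
  indel differences between homoeologs are invisible by construction.
- Strict sorting discards fragments that span a sequencing error at a
  phased site; recall (not precision) pays for this.
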