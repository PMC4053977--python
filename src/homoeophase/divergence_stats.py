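"""Divergence statistics between homoeologs and the threshold arithmetic they imply.

The pipeline's mapping and calling thresholds derive from two empirical
quantities: the distribution of percent identity between A and B homoeologs
(approximately Normal(97.26, 1.20) in tetraploid wheat coding regions) and the
spacing between adjacent homoeo-SNPs (near-exponential). These functions
compute those summaries and the back-of-envelope quantities used to set
mapping mismatch allowances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

_UNAMBIGUOUS = set("ACGT")


@dataclass
class DivergenceSummary:
    n_pairs: int
    identity_mean: float
    identity_sd: float
    normality_p: float | None       # Shapiro-Wilk p on identities; None if n < 3 or sd == 0
    snp_gap_mean: float
    snp_gap_sd: float
    snp_gap_median: float
    n_gaps: int


def gapless_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity over alignment columns with no gap in either sequence.

    Case-insensitive; ambiguity codes (anything outside ACGT) never match.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}")
    a = aligned_a.upper()
    b = aligned_b.upper()
    columns = 0
    matches = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        columns += 1
        if x == y and x in _UNAMBIGUOUS:
            matches += 1
    if columns == 0:
        raise ValueError("no gap-free columns to compare")
    return 100.0 * matches / columns


def inter_snp_distances(variant_positions: Sequence[int]) -> list[int]:
    """Successive differences between sorted variant positions (bp)."""
    positions = list(variant_positions)
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("variant positions must be strictly increasing")
    return [b - a for a, b in zip(positions, positions[1:])]


def expected_snp_count(length: float, identity: float) -> float:
    """Expected substitutions on a stretch of ``length`` bp at the given percent
    identity: L x (1 - identity/100), rounded to one decimal.

    This is the arithmetic behind fragment-level mismatch allowances (200 bp
    paired-end fragment at a 94% identity floor -> 12 mismatches; at 95% -> 10)
    and, applied to a mean coding length, the expected homoeo-SNP count per
    gene. Note it is a substitution *count*, not a spacing, even though the
    per-gene number is sometimes read as an average SNP distance.
    """
    if not (0.0 <= identity <= 100.0):
        raise ValueError(f"identity must be in [0, 100], got {identity}")
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    return round(length * (1.0 - identity / 100.0), 1)


def inclusion_fraction(identity_mean: float, identity_sd: float, threshold: float) -> float:
    """Percent of homoeolog pairs whose identity exceeds ``threshold`` under the
    normal model: 100 x Phi((mean - threshold) / sd).

    At (97.26, 1.20) a 94% floor keeps ~99.7% of pairs and a 95% floor ~97.0%;
    empirical counts on small curated gene sets can run a little lower.
    """
    if identity_sd <= 0:
        raise ValueError("identity_sd must be positive")
    z = (identity_mean - threshold) / identity_sd
    return 100.0 * float(stats.norm.cdf(z))


def summarize_divergence(pairs: Iterable) -> DivergenceSummary:
    """Aggregate identity and SNP-spacing statistics over homoeolog pairs.

    Accepts objects with ``realized_identity`` and ``variant_positions``
    attributes (e.g. simulated truth) or (identity, positions) tuples.
    """
    identities: list[float] = []
    gaps: list[int] = []
    for pair in pairs:
        if hasattr(pair, "realized_identity"):
            identities.append(pair.realized_identity)
            positions = pair.variant_positions
        else:
            identity, positions = pair
            identities.append(float(identity))
        gaps.extend(inter_snp_distances(positions))
    n = len(identities)
    if n == 0:
        raise ValueError("no pairs supplied")
    ids = np.asarray(identities, dtype=float)
    sd = float(np.std(ids, ddof=1)) if n > 1 else 0.0
    if n >= 3 and sd > 0:
        normality_p = float(stats.shapiro(ids).pvalue)
    else:
        normality_p = None
    garr = np.asarray(gaps, dtype=float)
    return DivergenceSummary(
        n_pairs=n,
        identity_mean=float(np.mean(ids)),
        identity_sd=sd,
        normality_p=normality_p,
        snp_gap_mean=float(np.mean(garr)) if gaps else float("nan"),
        snp_gap_sd=float(np.std(garr, ddof=1)) if len(gaps) > 1 else 0.0,
        snp_gap_median=float(np.median(garr)) if gaps else float("nan"),
        n_gaps=len(gaps),
    )


def snp_gap_exponential_ks(gaps: Sequence[int], max_n: int = 2000,
                           seed: int = 0) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of inter-SNP gaps against an exponential law with
    the empirical mean; returns (statistic, p-value).

    Gaps are positive integers (a geometric-type law), so testing them
    directly against a continuous exponential rejects on discreteness alone:
    integer gaps have no mass below 1 where the exponential does. The
    standard continuity correction is applied — a seeded U(0, 1) subtraction
    maps each integer gap back onto the continuous scale (the inverse of the
    ceiling that discretized it) — and the sample is capped at a seeded
    subsample of ``max_n`` where the approximation is accurate.
    """
    arr = np.asarray(gaps, dtype=float)
    if arr.size < 10:
        raise ValueError("need at least 10 gaps for a meaningful KS test")
    rng = np.random.default_rng(seed)
    if arr.size > max_n:
        arr = rng.choice(arr, size=max_n, replace=False)
    arr = arr - rng.random(arr.size)
    res = stats.kstest(arr, stats.expon(scale=arr.mean()).cdf)
    return float(res.statistic), float(res.pvalue)


def standardized_gap_ks(pairs: Iterable, max_n: int = 2000,
                        seed: int = 0) -> tuple[float, float]:
    """KS test of per-gene rate-standardized inter-SNP gaps against an
    exponential with the empirical mean; returns (statistic, p-value).

    Pooling raw gaps across genes of different percent identity yields a rate
    *mixture* of exponentials, which is not itself exponential; the
    exponential-spacing law holds within each gene. Each gene's gaps are
    therefore multiplied by its own SNP density (n / L) after the continuity
    correction of :func:`snp_gap_exponential_ks`, then pooled, capped at
    ``max_n`` (seeded), and tested.

    ``pairs`` holds objects with ``variant_positions`` and a sequence length
    (``length`` attribute or len of ``seq_a``).
    """
    rng = np.random.default_rng(seed)
    chunks = []
    for pair in pairs:
        positions = pair.variant_positions
        n = len(positions)
        if n < 2:
            continue
        length = getattr(pair, "length", None) or len(pair.seq_a)
        g = np.asarray(inter_snp_distances(positions), dtype=float)
        chunks.append((g - rng.random(g.size)) * (n / length))
    if not chunks:
        raise ValueError("no gene with >= 2 variants")
    arr = np.concatenate(chunks)
    if arr.size < 10:
        raise ValueError("need at least 10 gaps for a meaningful KS test")
    if arr.size > max_n:
        arr = rng.choice(arr, size=max_n, replace=False)
    res = stats.kstest(arr, stats.expon(scale=arr.mean()).cdf)
    return float(res.statistic), float(res.pvalue)
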