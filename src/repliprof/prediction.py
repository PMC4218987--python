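"""Peak-based origin prediction and its binomial enrichment statistic.

Profile peaks are treated as predicted origins.  A prediction is
counted as a hit if a reference origin lies within ``d`` bp (default
5000, inclusive) on the same chromosome.  Under the null that the N
predictions fall uniformly on the genome, each is a hit independently
with probability ``p`` = the fraction of the genome covered by the
union of the +-d windows around the reference origins, so the tail
probability of observing K or more hits is the binomial sum

    P(X >= K) = sum_{i=K}^{N} C(N, i) p^i (1-p)^(N-i),

reported as log10 and computed so that values near 1e-100 keep at
least six significant digits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import mpmath as mp
import numpy as np
from scipy.special import betainc

from ._errors import ConfigError
from .denoise import ReplicationProfile
from .metrics import find_extrema

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionResult",
    "window_coverage_fraction",
    "match_peaks",
    "binom_tail_pvalue",
    "evaluate_prediction",
]

Point = tuple[str, float]


@dataclass
class PredictionResult:
    n_predicted: int
    n_matched: int
    max_dist: float
    coverage: float
    log10_p_value: float
    matched_pairs: list[tuple[Point, Point]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "N": self.n_predicted,
            "K": self.n_matched,
            "d": self.max_dist,
            "p": self.coverage,
            "log10_p_value": self.log10_p_value,
        }


def _merged_windows(
    origins: list[Point], lengths: dict[str, int], half_width: float
) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos in origins:
        if chrom not in lengths:
            raise ConfigError(f"origin chromosome {chrom!r} not in genome")
        if not 0 <= pos < lengths[chrom]:
            raise ConfigError(f"origin {chrom}:{pos} out of bounds")
        lo = max(0, int(pos - half_width))
        hi = min(lengths[chrom], int(pos + half_width))
        by_chrom.setdefault(chrom, []).append((lo, hi))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out: list[tuple[int, int]] = []
        for lo, hi in ivals:
            if out and lo <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], hi))
            else:
                out.append((lo, hi))
        merged[chrom] = out
    return merged


def window_coverage_fraction(origins: list[Point], genome, half_width: float = 5000.0) -> float:
    """Fraction of the genome covered by the union of +-half_width windows.

    Windows ``[x - half_width, x + half_width)`` are clipped to
    chromosome bounds and merged before measuring.  Empty origin list
    gives 0.
    """
    if not origins:
        return 0.0
    lengths = dict(genome.chromosomes)
    merged = _merged_windows(origins, lengths, half_width)
    covered = sum(hi - lo for ivals in merged.values() for lo, hi in ivals)
    return covered / genome.total_length


def match_peaks(
    peaks: list[Point], origins: list[Point], max_dist: float = 5000.0
) -> tuple[int, int, list[tuple[Point, Point]]]:
    """Count peaks with a reference origin within ``max_dist`` (inclusive).

    Each peak is evaluated independently: several peaks near a single
    origin all count, and a peak with several nearby origins counts
    once (its nearest origin is reported in the matched pairs).
    """
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in origins:
        by_chrom.setdefault(chrom, [])
        by_chrom[chrom].append(pos)
    by_chrom = {c: np.asarray(v, dtype=float) for c, v in by_chrom.items()}
    matched: list[tuple[Point, Point]] = []
    for chrom, pos in peaks:
        if chrom not in by_chrom:
            continue
        d = np.abs(by_chrom[chrom] - pos)
        j = int(np.argmin(d))
        if d[j] <= max_dist:
            matched.append(((chrom, pos), (chrom, float(by_chrom[chrom][j]))))
    return len(peaks), len(matched), matched


def binom_tail_pvalue(n: int, k: int, p: float) -> float:
    """log10 of the upper binomial tail P(X >= k), X ~ Binomial(n, p).

    Uses the regularized incomplete beta identity
    ``P(X >= k) = I_p(k, n - k + 1)`` in double precision, falling back
    to arbitrary-precision mpmath when the double result underflows or
    is degenerate, so that even tails near 1e-300 and below retain at
    least six significant digits.
    """
    if not (isinstance(n, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise ConfigError("n and k must be integers")
    if k < 0 or k > n:
        raise ConfigError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ConfigError(f"require 0 < p < 1, got p={p}")
    if k == 0:
        return 0.0  # tail is the whole sample space
    tail = float(betainc(k, n - k + 1, p))
    if tail > 0.0 and np.isfinite(tail) and tail >= 1e-290:
        return float(np.log10(tail))
    with mp.workdps(60):
        val = mp.betainc(k, n - k + 1, 0, p, regularized=True)
        return float(mp.log10(val))


def evaluate_prediction(
    profile: ReplicationProfile,
    origins: list[Point],
    genome,
    half_width: float = 5000.0,
    min_prominence: float = 0.2,
    refine_half: int | None = 50,
) -> PredictionResult:
    """find_extrema -> match_peaks -> coverage -> binomial tail, as one report."""
    extrema = find_extrema(profile, min_prominence=min_prominence, refine_half=refine_half)
    peaks = extrema.peak_positions()
    n, k, pairs = match_peaks(peaks, origins, max_dist=half_width)
    coverage = window_coverage_fraction(origins, genome, half_width=half_width)
    if n == 0:
        log10p = 0.0
    else:
        if not 0.0 < coverage < 1.0:
            raise ConfigError(f"degenerate coverage fraction {coverage}")
        log10p = binom_tail_pvalue(n, k, coverage)
    return PredictionResult(n, k, half_width, coverage, log10p, pairs)
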