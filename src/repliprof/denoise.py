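"""Signal conditioning: low-rank SVD reconstruction and Savitzky-Golay smoothing."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from ._errors import ConfigError
from .processing import CountMatrix, FragmentTable

logger = logging.getLogger(__name__)

__all__ = ["ReplicationProfile", "svd_denoise", "savgol_smooth", "strain_profile"]


@dataclass
class ReplicationProfile:
    """Per-fragment smoothed DNA-abundance signal for one strain.

    ``values`` is indexed by fragment id; higher values mean earlier /
    more efficient replication.  ``fragments`` is the full table the
    ids point into (rows may be a filtered subset of it).
    """

    values: pd.Series
    fragments: FragmentTable
    strain: str = "strain"

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ConfigError("profile contains non-finite values")

    def row_fragments(self) -> pd.DataFrame:
        return self.fragments.df.loc[self.values.index]

    def midpoints(self) -> np.ndarray:
        frag = self.row_fragments()
        return (frag["start"].to_numpy() + frag["end"].to_numpy()) / 2.0

    def by_chromosome(self):
        """Yield (chrom, midpoints, values, row positions) per chromosome block."""
        frag = self.row_fragments()
        vals = self.values.to_numpy(dtype=float)
        mids = (frag["start"].to_numpy() + frag["end"].to_numpy()) / 2.0
        chroms = frag["chrom"].to_numpy()
        start = 0
        for chrom, sub in frag.groupby("chrom", sort=False):
            n = len(sub)
            sl = slice(start, start + n)
            yield chrom, mids[sl], vals[sl], np.arange(start, start + n)
            start += n

    def with_values(self, values: np.ndarray) -> "ReplicationProfile":
        return ReplicationProfile(
            pd.Series(values, index=self.values.index), self.fragments, self.strain
        )


def svd_denoise(matrix: CountMatrix, k: int = 50) -> CountMatrix:
    """Best rank-``min(k, rank)`` approximation of the value matrix.

    Keeps the leading singular triplets (singular values non-increasing),
    so by Eckart-Young the Frobenius reconstruction error equals the
    root sum of squares of the discarded singular values.  ``k`` larger
    than the matrix rank reproduces the input (logged, not an error).
    """
    if k <= 0:
        raise ConfigError("k must be >= 1")
    a = matrix.values.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    if k >= len(s):
        logger.info("svd_denoise: k=%d >= min dimension %d; matrix reproduced", k, len(s))
        recon = a
    else:
        recon = (u[:, :k] * s[:k]) @ vt[:k]
    out = pd.DataFrame(recon, index=matrix.values.index, columns=matrix.values.columns)
    return CountMatrix(out, matrix.fragments, matrix.meta)


def _smooth_block(vals: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    n = len(vals)
    w = window
    if w > n:
        w = n if n % 2 == 1 else n - 1
        logger.warning("savgol_smooth: window shrunk to %d for a %d-fragment chromosome", w, n)
    if w <= polyorder:
        logger.warning("savgol_smooth: chromosome too short to smooth (%d fragments); passthrough", n)
        return vals.copy()
    return savgol_filter(vals, window_length=w, polyorder=polyorder, mode="interp")


def savgol_smooth(
    profile: ReplicationProfile, window: int = 9, polyorder: int = 3
) -> ReplicationProfile:
    """Savitzky-Golay smoothing in fragment-index space, per chromosome.

    The filter fits a degree-``polyorder`` polynomial in each
    ``window``-fragment neighbourhood (uniform taps over fragment
    indices, not base pairs); edges are handled by evaluating the
    polynomial fitted to the terminal window ("interp" mode).  Never
    smooths across chromosome boundaries.
    """
    if window % 2 == 0:
        raise ConfigError("window must be odd")
    if window <= polyorder:
        raise ConfigError("window must exceed polyorder")
    out = np.empty(len(profile.values))
    for _, _, vals, rows in profile.by_chromosome():
        out[rows] = _smooth_block(vals, window, polyorder)
    return profile.with_values(out)


def strain_profile(
    matrix: CountMatrix,
    strain: str,
    agg: str = "mean",
    window: int = 9,
    polyorder: int = 3,
    smooth: bool = True,
) -> ReplicationProfile:
    """Average a strain's S-phase replicate columns into one smoothed profile."""
    cols = matrix.meta.index[
        (matrix.meta["strain"] == strain) & (matrix.meta.get("gate", "S") != "G1G2")
    ]
    if len(cols) == 0:
        raise ConfigError(f"no S-phase experiments for strain {strain!r}")
    sub = matrix.values[list(cols)].astype(float)
    series = sub.mean(axis=1) if agg == "mean" else sub.median(axis=1)
    profile = ReplicationProfile(series, matrix.fragments, strain)
    if smooth:
        profile = savgol_smooth(profile, window=window, polyorder=polyorder)
    return profile
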