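"""Profile-shape statistics: extrema, activation heights, sharpness, ACF.

Quantifies how "sharp" a replication profile is: a sharper profile has
more/higher local maxima (more origins contributing), deeper minima,
and a faster-decaying spatial autocorrelation.  Comparisons between a
mutant-like and a reference strain are made via the per-position
difference ``f_strain(x_i) - f_ref(x_i)`` evaluated at the reference
strain's extrema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._errors import ConfigError
from .denoise import ReplicationProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ExtremaSet",
    "OriginActivationTable",
    "SharpnessSummary",
    "AutocorrelationResult",
    "find_extrema",
    "activation_heights",
    "activation_table",
    "sharpness_summary",
    "autocorrelation",
    "correlation_matrix",
]


@dataclass
class ExtremaSet:
    """Alternating local maxima/minima: columns chrom, position, value, kind."""

    df: pd.DataFrame  # kind in {"max", "min"}

    def maxima(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "max"].reset_index(drop=True)

    def minima(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "min"].reset_index(drop=True)

    @property
    def n_maxima(self) -> int:
        return int((self.df["kind"] == "max").sum())

    def peak_positions(self) -> list[tuple[str, float]]:
        m = self.maxima()
        return list(zip(m["chrom"], m["position"]))


@dataclass
class OriginActivationTable:
    """Profile heights f_strain(x_i) per reference position x_i.

    ``df`` has one row per reference position (columns chrom, position)
    and one value column per strain; missing flags are NaN.
    """

    df: pd.DataFrame

    def strains(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("chrom", "position")]


@dataclass
class AutocorrelationResult:
    lags: np.ndarray
    acf: np.ndarray  # length-weighted mean across chromosomes, acf[0] == 1
    half_decay_lag: int | None  # first lag with acf < 0.5


@dataclass
class SharpnessSummary:
    """Differences f_strain - f_ref at reference maxima/minima, summarized."""

    diffs_at_maxima: dict[str, np.ndarray]
    diffs_at_minima: dict[str, np.ndarray]
    percentiles_maxima: dict[str, tuple[float, float, float]]  # 25/50/75
    percentiles_minima: dict[str, tuple[float, float, float]]
    histograms_maxima: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    histograms_minima: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Extrema
# ---------------------------------------------------------------------------

def _alternating(df: pd.DataFrame) -> pd.DataFrame:
    """Prune same-kind runs so maxima and minima strictly alternate.

    Independently prominence-thresholded maxima and minima need not
    alternate (a shallow valley between two strong peaks may fail the
    threshold); within each same-kind run keep the most extreme point.
    """
    if df.empty:
        return df
    keep_rows = []
    for _, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("position")
        run: list[int] = []
        run_kind = None
        for row in sub.itertuples():
            if row.kind != run_kind and run:
                keep_rows.append(_best_of_run(sub, run, run_kind))
                run = []
            run_kind = row.kind
            run.append(row.Index)
        if run:
            keep_rows.append(_best_of_run(sub, run, run_kind))
    out = df.loc[keep_rows].sort_values(["chrom", "position"], kind="stable")
    return out.reset_index(drop=True)


def _best_of_run(sub: pd.DataFrame, run: list, kind: str):
    vals = sub.loc[run, "value"]
    return vals.idxmax() if kind == "max" else vals.idxmin()


def _refine_position(mids: np.ndarray, vals: np.ndarray, i: int, half: int, kind: str) -> float:
    """Quadratic sub-sample interpolation of an extremum, in bp space.

    Smoothing with uniform taps over fragment *indices* pulls apexes
    toward locally denser (shorter-fragment) sampling; fitting a
    parabola to value-vs-midpoint over +-half fragments and taking its
    stationary point removes most of that displacement.
    """
    lo, hi = max(0, i - half), min(len(vals), i + half + 1)
    x = mids[lo:hi] - mids[i]
    y = vals[lo:hi]
    c = np.polyfit(x, y, 2)
    concave_ok = c[0] < 0 if kind == "max" else c[0] > 0
    if not concave_ok:
        return float(mids[i])
    return float(mids[i] + np.clip(-c[1] / (2 * c[0]), x[0], x[-1]))


def find_extrema(
    profile: ReplicationProfile,
    min_prominence: float = 0.2,
    refine_half: int | None = None,
) -> ExtremaSet:
    """Call local maxima and minima with a prominence threshold.

    ``min_prominence`` is a fraction of the whole-profile standard
    deviation.  Plateaus yield their centre sample; chromosome-terminal
    points are never extrema.  The returned set is pruned so maxima and
    minima alternate along every chromosome.  With ``refine_half`` set,
    extremum positions are recentred by a quadratic fit over
    +-refine_half fragments in genomic coordinates (values are still
    reported at the called fragment).
    """
    sd = float(np.std(profile.values.to_numpy(dtype=float)))
    threshold = min_prominence * sd if sd > 0 else 0.0
    rows = []
    for chrom, mids, vals, _ in profile.by_chromosome():
        if len(vals) < 3:
            logger.warning("find_extrema: chromosome %r has < 3 fragments; skipped", chrom)
            continue
        for kind, series in (("max", vals), ("min", -vals)):
            idx, _props = find_peaks(series, prominence=threshold if threshold > 0 else None)
            for i in idx:
                pos = (
                    _refine_position(mids, vals, int(i), refine_half, kind)
                    if refine_half
                    else float(mids[i])
                )
                rows.append(
                    {"chrom": chrom, "position": pos, "value": float(vals[i]), "kind": kind}
                )
    df = pd.DataFrame(rows, columns=["chrom", "position", "value", "kind"])
    return ExtremaSet(_alternating(df))


# ---------------------------------------------------------------------------
# Activation heights
# ---------------------------------------------------------------------------

def activation_heights(
    profile: ReplicationProfile,
    origins: list[tuple[str, float]],
    max_gap: float = 5000.0,
) -> OriginActivationTable:
    """Read the profile value at each reference position.

    The value comes from the fragment containing the position; if that
    fragment was filtered out, the nearest retained fragment midpoint
    within ``max_gap`` bp is used, else the row is flagged missing (NaN).
    """
    frag = profile.row_fragments()
    vals = profile.values.to_numpy(dtype=float)
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    offset = 0
    for chrom, sub in frag.groupby("chrom", sort=False):
        n = len(sub)
        per_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0,
            vals[offset : offset + n],
        )
        offset += n

    out_rows = []
    for chrom, pos in origins:
        row = {"chrom": chrom, "position": float(pos), profile.strain: np.nan}
        if chrom in per_chrom:
            starts, ends, mids, v = per_chrom[chrom]
            i = np.searchsorted(starts, pos, side="right") - 1
            if 0 <= i < len(starts) and starts[i] <= pos < ends[i]:
                row[profile.strain] = float(v[i])
            else:
                j = int(np.argmin(np.abs(mids - pos)))
                if abs(mids[j] - pos) <= max_gap:
                    row[profile.strain] = float(v[j])
                else:
                    logger.info(
                        "activation_heights: %s:%s > %g bp from any fragment; missing",
                        chrom, pos, max_gap,
                    )
        out_rows.append(row)
    return OriginActivationTable(pd.DataFrame(out_rows))


def activation_table(
    profiles: dict[str, ReplicationProfile],
    origins: list[tuple[str, float]],
    max_gap: float = 5000.0,
) -> OriginActivationTable:
    """Heights of several strains at shared reference positions."""
    merged: pd.DataFrame | None = None
    for name, profile in profiles.items():
        t = activation_heights(profile, origins, max_gap).df.rename(columns={profile.strain: name})
        merged = t if merged is None else merged.assign(**{name: t[name]})
    assert merged is not None
    return OriginActivationTable(merged)


# ---------------------------------------------------------------------------
# Sharpness
# ---------------------------------------------------------------------------

def sharpness_summary(
    table: OriginActivationTable,
    ref_extrema: ExtremaSet,
    ref: str,
    match_tol: float = 1.0,
    bins: int = 30,
) -> SharpnessSummary:
    """Summarize per-strain differences from ``ref`` at its extrema.

    Table rows are matched to the reference extrema by (chrom,
    position) within ``match_tol`` bp; rows not matching any extremum
    are ignored.  For each strain the differences are histogrammed and
    reduced to 25/50/75 percentiles, separately at maxima and minima.
    """
    if ref not in table.df.columns:
        raise ConfigError(f"reference strain {ref!r} not in activation table")
    if ref_extrema.df.empty:
        raise ConfigError("reference extrema set is empty")

    def rows_at(kind: str) -> pd.DataFrame:
        ex = ref_extrema.df[ref_extrema.df["kind"] == kind]
        picks = []
        for row in table.df.itertuples():
            sub = ex[ex["chrom"] == row.chrom]
            if len(sub) and np.min(np.abs(sub["position"].to_numpy() - row.position)) <= match_tol:
                picks.append(row.Index)
        return table.df.loc[picks]

    strains = [s for s in table.strains() if s != ref]
    d_max: dict[str, np.ndarray] = {}
    d_min: dict[str, np.ndarray] = {}
    p_max: dict[str, tuple[float, float, float]] = {}
    p_min: dict[str, tuple[float, float, float]] = {}
    h_max: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    h_min: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for kind, d_out, p_out, h_out in (
        ("max", d_max, p_max, h_max),
        ("min", d_min, p_min, h_min),
    ):
        at = rows_at(kind)
        for s in strains:
            diffs = (at[s] - at[ref]).dropna().to_numpy(dtype=float)
            d_out[s] = diffs
            if diffs.size:
                q = np.percentile(diffs, [25, 50, 75])
                p_out[s] = (float(q[0]), float(q[1]), float(q[2]))
                counts, edges = np.histogram(diffs, bins=bins)
                h_out[s] = (counts, edges)
            else:
                p_out[s] = (np.nan, np.nan, np.nan)
    return SharpnessSummary(d_max, d_min, p_max, p_min, h_max, h_min)


# ---------------------------------------------------------------------------
# Autocorrelation and correlation
# ---------------------------------------------------------------------------

def autocorrelation(profile: ReplicationProfile, max_lag: int = 200) -> AutocorrelationResult:
    """Normalized autocorrelation in fragment-lag space.

    Each chromosome's series is mean-removed and its ACF normalized to
    1 at lag 0; chromosome ACFs are averaged weighted by series length
    (never concatenated, to avoid spurious boundary correlation).  The
    decay is summarized by the first lag where the ACF drops below 0.5.
    """
    blocks = [(chrom, vals) for chrom, _, vals, _ in profile.by_chromosome()]
    shortest = min(len(v) for _, v in blocks)
    if max_lag >= shortest:
        logger.warning("autocorrelation: max_lag %d >= shortest series %d; reduced", max_lag, shortest)
        max_lag = shortest - 1
    if max_lag < 1:
        raise ConfigError("profile too short for autocorrelation")
    acc = np.zeros(max_lag + 1)
    wsum = 0.0
    for chrom, vals in blocks:
        x = vals - vals.mean()
        denom = float(np.dot(x, x))
        if denom <= 0:
            logger.warning("autocorrelation: constant series on %r skipped", chrom)
            continue
        acf = np.empty(max_lag + 1)
        acf[0] = 1.0
        for k in range(1, max_lag + 1):
            acf[k] = float(np.dot(x[:-k], x[k:])) / denom
        w = float(len(vals))
        acc += w * acf
        wsum += w
    if wsum == 0:
        raise ConfigError("all chromosome series constant")
    acf = acc / wsum
    below = np.nonzero(acf < 0.5)[0]
    half = int(below[0]) if below.size else None
    return AutocorrelationResult(np.arange(max_lag + 1), acf, half)


def correlation_matrix(profiles: dict[str, ReplicationProfile]) -> pd.DataFrame:
    """Pearson correlation between strains over their shared fragments."""
    if len(profiles) < 2:
        raise ConfigError("need at least 2 profiles")
    names = list(profiles)
    shared = profiles[names[0]].values.index
    for name in names[1:]:
        shared = shared.intersection(profiles[name].values.index)
    if len(shared) < 2:
        raise ConfigError("fewer than 2 shared fragments between profiles")
    data = np.stack([profiles[n].values.loc[shared].to_numpy(dtype=float) for n in names])
    corr = np.corrcoef(data)
    return pd.DataFrame(corr, index=names, columns=names)
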