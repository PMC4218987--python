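"""Fragment-level read counting, filtering and normalization.

The quantification unit is the restriction fragment: the interval
between consecutive occurrences of a recognition site (default GATC)
on a chromosome, 0-based half-open.  A :class:`CountMatrix` holds raw
or normalized values for a *subset* of the fragments of a
:class:`FragmentTable` (rows are dropped by filters; the table itself
always describes the full digestion and keeps tiling the genome).

The canonical processing order, applied by the pipeline driver, is

    filter_experiments -> filter_fragments -> correct_cnv
    -> remove_length_bias -> ratio_to_control -> zscore_experiments

Note the control ratio is taken on positive-scale signal and the
z-scoring happens last; dividing an already mean-zero signal would
invite division artifacts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from ._errors import ConfigError, StageError

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentTable",
    "CountMatrix",
    "FilterReport",
    "digest_genome",
    "count_reads_per_fragment",
    "build_count_matrix",
    "filter_fragments",
    "filter_experiments",
    "correct_cnv",
    "zscore_experiments",
    "remove_length_bias",
    "ratio_to_control",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentTable:
    """Restriction fragments: (chrom, start, end, length), 0-based half-open.

    Fragments of one chromosome must be sorted, non-overlapping and
    stored as one contiguous block of rows.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ConfigError(f"fragment table needs columns {sorted(required)}")
        if "length" not in df.columns:
            df = df.assign(length=df["end"] - df["start"])
            object.__setattr__(self, "df", df)
        if (df["length"] <= 0).any():
            raise ConfigError("fragment table contains non-positive-length fragments")
        if (df["length"] != df["end"] - df["start"]).any():
            raise ConfigError("length column inconsistent with start/end")
        chroms = df["chrom"].to_numpy()
        if len(chroms):
            n_runs = 1 + int((chroms[1:] != chroms[:-1]).sum())
            if n_runs != len(pd.unique(chroms)):
                raise ConfigError("fragments of a chromosome must form one contiguous block")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not np.all(np.diff(starts) > 0) or np.any(ends[:-1] > starts[1:]):
                raise ConfigError(f"fragments on {chrom!r} are unsorted or overlapping")

    def __len__(self) -> int:
        return len(self.df)

    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) / 2.0

    def lengths(self) -> np.ndarray:
        return self.df["length"].to_numpy()

    def tiles_genome(self, genome) -> bool:
        """True iff fragments exactly tile [0, length) of every chromosome."""
        lengths = dict(genome.chromosomes)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != lengths.get(chrom):
                return False
            if np.any(starts[1:] != ends[:-1]):
                return False
        return set(self.df["chrom"]) == set(lengths)


@dataclass
class CountMatrix:
    """Fragments x experiments values with per-experiment metadata.

    ``values`` is indexed by fragment id (integer row position in the
    originating :class:`FragmentTable`); ``meta`` is indexed by
    experiment id and carries at least ``strain`` and ``gate``
    ("S" or "G1G2") columns.
    """

    values: pd.DataFrame
    fragments: FragmentTable
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.columns.equals(self.meta.index):
            raise ConfigError("experiment columns and metadata index disagree")
        if not self.values.index.isin(self.fragments.df.index).all():
            raise ConfigError("matrix rows reference unknown fragment ids")

    @property
    def n_fragments(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    def row_fragments(self) -> pd.DataFrame:
        """Fragment coordinates for the retained rows, in matrix order."""
        return self.fragments.df.loc[self.values.index]

    def select_experiments(self, experiments: Iterable[str]) -> "CountMatrix":
        cols = list(experiments)
        return CountMatrix(self.values[cols], self.fragments, self.meta.loc[cols])

    def hstack(self, other: "CountMatrix") -> "CountMatrix":
        """Column-wise concatenation over a shared fragment table/rows."""
        if not self.values.index.equals(other.values.index):
            raise ConfigError("cannot hstack matrices with different row sets")
        return CountMatrix(
            pd.concat([self.values, other.values], axis=1),
            self.fragments,
            pd.concat([self.meta, other.meta], axis=0),
        )


@dataclass
class FilterReport:
    """Per-rule removal accounting; removed + retained = input, per axis."""

    axis: str  # "fragments" | "experiments"
    input_size: int
    removed: dict[str, list] = field(default_factory=dict)
    retained: int = 0

    @property
    def n_removed(self) -> int:
        return self.input_size - self.retained

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "input_size": self.input_size,
            "retained": self.retained,
            "removed": {rule: [str(x) for x in ids] for rule, ids in self.removed.items()},
        }


# ---------------------------------------------------------------------------
# Digestion and counting
# ---------------------------------------------------------------------------

def digest_genome(genome, site: str = "GATC") -> FragmentTable:
    """In-silico restriction digestion of a genome with sequence.

    Cut positions are the start coordinates of every (possibly
    overlapping) occurrence of ``site``, case-insensitive, forward
    strand only — sufficient for palindromic sites like GATC.
    Fragments are the intervals between consecutive cuts plus the
    leading ``[0, first_cut)`` and trailing ``[last_cut, length)``
    pieces; zero-length pieces are dropped.  A chromosome without any
    site yields one fragment spanning it.  Characters outside ACGT
    (e.g. N) simply never match the site.
    """
    if genome.sequences is None:
        raise ConfigError("digest_genome requires a genome with sequences")
    if not site:
        raise ConfigError("empty recognition site")
    pattern = re.compile(f"(?={re.escape(site.upper())})")
    rows = []
    for chrom, length in genome.chromosomes:
        seq = genome.sequences[chrom].upper()
        cuts = [m.start() for m in pattern.finditer(seq)]
        bounds = [0] + cuts + [length]
        for start, end in zip(bounds[:-1], bounds[1:]):
            if end > start:
                rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["length"] = df["end"] - df["start"]
    df.index = pd.RangeIndex(len(df))
    return FragmentTable(df)


def count_reads_per_fragment(
    alignments: Iterable[tuple[str, int]],
    fragments: FragmentTable,
) -> tuple[np.ndarray, int]:
    """Assign each read's 5'-most position to the fragment containing it.

    Returns ``(counts, unassigned)`` where ``counts`` follows fragment
    table order.  Reads on unknown chromosomes or outside the fragment
    span are tallied as unassigned (logged, never fatal), so that
    ``counts.sum() + unassigned`` equals the number of input reads.
    """
    df = fragments.df
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts[chrom] = sub["start"].to_numpy()
        ends[chrom] = sub["end"].to_numpy()
        offsets[chrom] = int(df.index.get_indexer([sub.index[0]])[0])

    counts = np.zeros(len(df), dtype=np.int64)
    unassigned = 0
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in alignments:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, positions in by_chrom.items():
        pos = np.asarray(positions, dtype=np.int64)
        if chrom not in starts:
            unassigned += len(pos)
            logger.info("count_reads: %d reads on unknown chromosome %r unassigned", len(pos), chrom)
            continue
        idx = np.searchsorted(starts[chrom], pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[chrom][np.minimum(idx, len(ends[chrom]) - 1)])
        # a position in a gap between fragments of a filtered table would fail pos < end
        bad = int((~ok).sum())
        if bad:
            unassigned += bad
            logger.info("count_reads: %d reads outside fragment span on %r", bad, chrom)
        np.add.at(counts, offsets[chrom] + idx[ok], 1)
    return counts, unassigned


def build_count_matrix(
    columns: dict[str, Iterable[tuple[str, int]]],
    fragments: FragmentTable,
    meta: pd.DataFrame | None = None,
) -> CountMatrix:
    """Count several alignment streams into one matrix (one column each)."""
    values = {}
    totals = {}
    for name, alignments in columns.items():
        counts, unassigned = count_reads_per_fragment(alignments, fragments)
        values[name] = counts
        totals[name] = int(counts.sum())
        if unassigned:
            logger.info("experiment %s: %d unassigned reads", name, unassigned)
    vdf = pd.DataFrame(values, index=fragments.df.index)
    if meta is None:
        meta = pd.DataFrame(
            {"strain": "unknown", "gate": "S"}, index=pd.Index(list(columns), name="experiment")
        )
    meta = meta.copy()
    meta["total_reads"] = pd.Series(totals)
    return CountMatrix(vdf, fragments, meta)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def default_max_zero_experiments(n_experiments: int) -> int:
    """300 for collections of >= 300 experiments, else 75% of columns."""
    return 300 if n_experiments >= 300 else int(0.75 * n_experiments)


def filter_fragments(
    matrix: CountMatrix,
    min_length: int = 150,
    max_zero_experiments: int | None = None,
    blacklist: frozenset | set | None = None,
) -> tuple[CountMatrix, FilterReport]:
    """Row filters, all evaluated on the input matrix (hence commuting):

    - fragments strictly shorter than ``min_length`` bp;
    - fragments with zero reads in strictly more than
      ``max_zero_experiments`` experiments;
    - fragments whose id is in ``blacklist`` (e.g. unalignable regions).
    """
    if max_zero_experiments is None:
        max_zero_experiments = default_max_zero_experiments(matrix.n_experiments)
    blacklist = frozenset(blacklist or ())
    frag = matrix.row_fragments()
    report = FilterReport(axis="fragments", input_size=matrix.n_fragments)

    short = frag.index[frag["length"] < min_length]
    zeros = (matrix.values == 0).sum(axis=1)
    pervasive = matrix.values.index[zeros > max_zero_experiments]
    listed = matrix.values.index[matrix.values.index.isin(blacklist)]
    report.removed["short_fragment"] = list(short)
    report.removed["pervasive_zero"] = list(pervasive)
    report.removed["blacklist"] = list(listed)

    drop = set(short) | set(pervasive) | set(listed)
    keep = matrix.values.index[~matrix.values.index.isin(drop)]
    report.retained = len(keep)
    for rule, ids in report.removed.items():
        if ids:
            logger.info("filter_fragments/%s: removed %d rows", rule, len(ids))
    if report.retained == 0:
        raise StageError("filter_fragments", f"all fragments removed; report: {report.to_dict()}")
    out = CountMatrix(matrix.values.loc[keep], matrix.fragments, matrix.meta)
    return out, report


def filter_experiments(
    matrix: CountMatrix, min_reads: int = 100_000
) -> tuple[CountMatrix, FilterReport]:
    """Drop experiments with strictly fewer than ``min_reads`` total reads."""
    totals = matrix.values.sum(axis=0)
    report = FilterReport(axis="experiments", input_size=matrix.n_experiments)
    low = list(totals.index[totals < min_reads])
    report.removed["low_depth"] = low
    keep = [c for c in matrix.values.columns if c not in set(low)]
    report.retained = len(keep)
    if low:
        logger.info("filter_experiments: removed %d low-depth experiments", len(low))
    if not keep:
        raise StageError("filter_experiments", f"all experiments removed; report: {report.to_dict()}")
    return matrix.select_experiments(keep), report


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def correct_cnv(matrix: CountMatrix) -> CountMatrix:
    """Equalize per-chromosome median signal within each experiment.

    Whole-chromosome (or large segmental) duplications shift every
    fragment of the chromosome by a common factor; rescaling each
    chromosome block so its median matches the experiment's global
    median removes that copy-number effect while being robust to the
    origin-driven skew of the abundance signal.  A chromosome with a
    non-positive median is left untouched (factor 1, warning).
    """
    chroms = matrix.row_fragments()["chrom"]
    out = matrix.values.astype(float).copy()
    for exp in out.columns:
        col = out[exp]
        global_med = float(col.median())
        for chrom, sub in col.groupby(chroms.to_numpy()):
            med = float(sub.median())
            if med <= 0:
                logger.warning("correct_cnv: %s on %s has non-positive median; factor 1", exp, chrom)
                continue
            factor = global_med / med
            out.loc[sub.index, exp] = sub * factor
            logger.debug("correct_cnv: %s %s factor %.4f", exp, chrom, factor)
    return CountMatrix(out, matrix.fragments, matrix.meta)


def zscore_experiments(matrix: CountMatrix, tol: float = 1e-12) -> CountMatrix:
    """Normalize each experiment column to mean 0, population std 1."""
    if matrix.n_fragments < 2:
        raise ConfigError("zscore requires at least 2 fragments")
    vals = matrix.values.astype(float)
    mean = vals.mean(axis=0)
    std = vals.std(axis=0, ddof=0)
    bad = std.index[std <= tol]
    if len(bad):
        raise StageError("zscore", f"constant experiment column(s): {list(bad)}")
    return CountMatrix((vals - mean) / std, matrix.fragments, matrix.meta)


def remove_length_bias(
    matrix: CountMatrix,
    bandwidth: int | None = None,
    bandwidth_fraction: float = 0.05,
) -> CountMatrix:
    """Subtract the smoothed signal-vs-fragment-length trend, per experiment.

    Fragments are ranked by length; a centred running mean of width
    ``bandwidth`` (default 5% of rows, minimum 3) over the ranked
    signal estimates the length trend, which is subtracted after being
    centred itself so the column mean is preserved and the signal stays
    on its original scale.
    """
    n = matrix.n_fragments
    if bandwidth is None:
        bandwidth = max(3, int(round(bandwidth_fraction * n)))
    if bandwidth > n:
        logger.warning("remove_length_bias: bandwidth %d > %d rows; shrinking", bandwidth, n)
        bandwidth = n
    lengths = matrix.row_fragments()["length"].to_numpy()
    order = np.argsort(lengths, kind="stable")
    vals = matrix.values.astype(float).to_numpy().copy()
    for j in range(vals.shape[1]):
        ranked = vals[order, j]
        trend = uniform_filter1d(ranked, size=bandwidth, mode="nearest")
        ranked_corrected = ranked - (trend - trend.mean())
        vals[order, j] = ranked_corrected
    out = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return CountMatrix(out, matrix.fragments, matrix.meta)


def ratio_to_control(
    matrix: CountMatrix,
    control_columns: Iterable[str] | None = None,
    floor_quantile: float = 0.01,
    rezscore: bool = True,
    keep_controls: bool = False,
) -> CountMatrix:
    """Divide each value by the across-control mean signal of its fragment.

    The per-fragment control mean corrects residual per-fragment
    effects (mappability, copy number) common to all gates.  Fragments
    whose control mean falls below the ``floor_quantile`` quantile of
    positive control means are flagged missing and dropped (logged)
    rather than allowed to blow up.  Must run on positive-scale signal;
    output is re-z-scored by default.
    """
    if control_columns is None:
        control_columns = list(matrix.meta.index[matrix.meta["gate"] == "G1G2"])
    control_columns = list(control_columns)
    if not control_columns:
        raise ConfigError("ratio_to_control needs at least one control column")
    missing_cols = [c for c in control_columns if c not in matrix.values.columns]
    if missing_cols:
        raise ConfigError(f"control column(s) not in matrix: {missing_cols}")

    control_mean = matrix.values[control_columns].astype(float).mean(axis=1)
    positive = control_mean[control_mean > 0]
    if positive.empty:
        raise StageError("ratio_to_control", "all control means are non-positive")
    floor = float(np.quantile(positive.to_numpy(), floor_quantile))
    ok = control_mean >= max(floor, np.finfo(float).tiny)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "ratio_to_control: %d fragments with control mean < %.4g flagged missing and dropped",
            n_dropped,
            floor,
        )

    target_cols = list(matrix.values.columns) if keep_controls else [
        c for c in matrix.values.columns if c not in set(control_columns)
    ]
    if not target_cols:
        raise StageError("ratio_to_control", "no non-control columns to normalize")
    ratio = matrix.values.loc[ok, target_cols].astype(float).div(control_mean[ok], axis=0)

    # columns rendered (near-)constant by the division are flagged and dropped
    std = ratio.std(axis=0, ddof=0)
    flat = list(std.index[std <= 1e-12])
    if flat:
        logger.warning("ratio_to_control: dropping constant column(s) after division: %s", flat)
        ratio = ratio.drop(columns=flat)
    if ratio.shape[1] == 0:
        raise StageError("ratio_to_control", "every column became constant after division")

    out = CountMatrix(ratio, matrix.fragments, matrix.meta.loc[ratio.columns])
    if rezscore:
        out = zscore_experiments(out)
    return out
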