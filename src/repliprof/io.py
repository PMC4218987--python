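"""File-format boundaries: FASTA, BED, bedGraph, TSV matrices, SAM.

Internally all coordinates are 0-based half-open (BED convention);
1-based formats (SAM) are converted at this boundary.  Only plain-text
formats are produced so runs stay portable and diffable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .processing import CountMatrix, FragmentTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed_points(path: str | Path) -> list[tuple[str, float]]:
    """Read a BED file as point positions (interval midpoints)."""
    out: list[tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ConfigError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out.append((chrom, (start + end) / 2.0))
    return out


def write_points_bed(
    path: str | Path,
    points: Iterable[tuple[str, float]],
    names: Iterable[str] | None = None,
    scores: Iterable[float] | None = None,
) -> None:
    """Write points as 6-column BED (1 bp intervals, '+' strand)."""
    points = list(points)
    names = list(names) if names is not None else [f"pt{i}" for i in range(len(points))]
    scores = list(scores) if scores is not None else [0.0] * len(points)
    with open(path, "w") as fh:
        for (chrom, pos), name, score in zip(points, names, scores):
            start = int(pos)
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{name}\t{score:g}\t+\n")


def write_bedgraph(
    path: str | Path,
    intervals: Iterable[tuple[str, int, int]],
    values: Iterable[float],
) -> None:
    with open(path, "w") as fh:
        for (chrom, start, end), v in zip(intervals, values):
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a bedGraph as (intervals DataFrame, values array)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    return df[["chrom", "start", "end"]], df["value"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Fragment tables and count matrices (TSV)
# ---------------------------------------------------------------------------

def write_fragment_table(path: str | Path, fragments: FragmentTable) -> None:
    df = fragments.df.reset_index().rename(columns={"index": "fragment_id"})
    df.to_csv(path, sep="\t", index=False)


def read_fragment_table(path: str | Path) -> FragmentTable:
    df = pd.read_csv(path, sep="\t")
    if "fragment_id" in df.columns:
        df = df.set_index("fragment_id")
        df.index.name = None
    return FragmentTable(df)


def write_count_matrix(path: str | Path, matrix: CountMatrix) -> None:
    """Matrix TSV (fragment_id + one column per experiment) + .meta.tsv sidecar."""
    path = Path(path)
    out = matrix.values.reset_index().rename(columns={"index": "fragment_id"})
    out.to_csv(path, sep="\t", index=False)
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    matrix.meta.reset_index().rename(columns={"index": "experiment"}).to_csv(
        meta_path, sep="\t", index=False
    )


def read_count_matrix(
    path: str | Path, fragments: FragmentTable, meta_path: str | Path | None = None
) -> CountMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t").set_index("fragment_id")
    values.index.name = None
    if meta_path is None:
        meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    if Path(meta_path).exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("experiment")
    else:
        logger.warning("no metadata sidecar at %s; assuming all columns are S-phase", meta_path)
        meta = pd.DataFrame({"strain": "unknown", "gate": "S"}, index=values.columns)
        meta.index.name = "experiment"
    meta.index.name = None
    return CountMatrix(values, fragments, meta.loc[values.columns])


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> Iterator[tuple[str, int]]:
    """Yield (chromosome, 5'-most position) from BED or SAM.

    BED: column 2 (0-based start).  SAM: ``reference_start`` of mapped
    records via pysam.  Format chosen by file extension.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam"):
        import pysam

        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                yield rec.reference_name, rec.reference_start
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                yield parts[0], int(parts[1])
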