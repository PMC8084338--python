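"""Text-format I/O: chromosome sizes, BED, BEDGRAPH, and extended BED.

All on-disk interval formats are 0-based half-open (the BED convention);
the in-memory :class:`AlignmentRecord` is 1-based inclusive, matching the
coordinate system the Fenwick-track arithmetic is written in. The "extended
BED" is the intermediate the read-preparation step emits: one line per
candidate alignment of a read pair, carrying the two mate alignment scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, TextIO, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecord",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "bedgraph_to_dense",
    "write_extended_bed",
    "read_extended_bed",
]

PathOrHandle = Union[str, TextIO]


@dataclass(frozen=True)
class AlignmentRecord:
    """One candidate placement of one read pair.

    ``start``/``stop`` are 1-based inclusive fragment coordinates;
    ``score_read``/``score_mate`` are the aligner's AS/YS scores (<= 0).
    """

    contig: str
    start: int
    stop: int
    read_id: str
    score_read: float = 0.0
    score_mate: float = 0.0
    strand: str | None = None

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"start {self.start} < 1 (coordinates are 1-based)")
        if self.stop < self.start:
            raise ValueError(f"stop {self.stop} < start {self.start}")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    @property
    def pair_score(self) -> float:
        return self.score_read + self.score_mate


def _opened(path_or_handle: PathOrHandle, mode: str = "r"):
    if isinstance(path_or_handle, (str,)):
        return open(path_or_handle, mode), True
    return path_or_handle, False


def read_chrom_sizes(source: PathOrHandle) -> Dict[str, int]:
    """Two-column (name, length) whitespace-separated table."""
    fh, close = _opened(source)
    try:
        sizes: Dict[str, int] = {}
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed chrom-sizes line: {line!r}")
            sizes[parts[0]] = int(parts[1])
        return sizes
    finally:
        if close:
            fh.close()


def read_bed(source: PathOrHandle) -> pd.DataFrame:
    """BED3+ -> DataFrame with columns contig, start0, end (+ name if present)."""
    fh, close = _opened(source)
    try:
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            row = {"contig": parts[0], "start0": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 3:
                row["name"] = parts[3]
            rows.append(row)
        if not rows:
            return pd.DataFrame(columns=["contig", "start0", "end"])
        return pd.DataFrame(rows)
    finally:
        if close:
            fh.close()


def write_bed(df: pd.DataFrame, dest: PathOrHandle) -> None:
    fh, close = _opened(dest, "w")
    try:
        cols = [c for c in ("contig", "start0", "end", "name") if c in df.columns]
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(str(x) for x in row) + "\n")
    finally:
        if close:
            fh.close()


def read_bedgraph(source: PathOrHandle) -> pd.DataFrame:
    """BEDGRAPH -> DataFrame (contig, start0, end, value); zeros implied elsewhere."""
    fh, close = _opened(source)
    try:
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e, v = line.split("\t")[:4]
            rows.append((c, int(s), int(e), float(v)))
        return pd.DataFrame(rows, columns=["contig", "start0", "end", "value"])
    finally:
        if close:
            fh.close()


def bedgraph_to_dense(
    bedgraph: pd.DataFrame, chrom_sizes: Mapping[str, int]
) -> Dict[str, np.ndarray]:
    """Expand a BEDGRAPH table to one per-base float array per contig.

    Index 0 of each array is base 1 of the contig (0-based internally);
    bases with no record are 0.
    """
    dense = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}
    for row in bedgraph.itertuples(index=False):
        if row.contig not in dense:
            raise KeyError(f"bedgraph contig {row.contig!r} not in chrom sizes")
        arr = dense[row.contig]
        if row.end > arr.shape[0] or row.start0 < 0:
            raise ValueError(
                f"bedgraph interval {row.contig}:{row.start0}-{row.end} out of bounds"
            )
        arr[row.start0 : row.end] += row.value
    return dense


# -- extended BED ------------------------------------------------------------

_BASE_COLS = ["contig", "start0", "end", "read_id"]


def write_extended_bed(
    records: Iterable[AlignmentRecord], dest: PathOrHandle, stranded: bool = False
) -> int:
    """Write alignment records as extended BED; returns the number written.

    Columns: contig, start0, end, read_id[, strand], AS, YS — coordinates
    converted to 0-based half-open.
    """
    fh, close = _opened(dest, "w")
    n = 0
    try:
        for rec in records:
            fields = [rec.contig, str(rec.start - 1), str(rec.stop), rec.read_id]
            if stranded:
                fields.append(rec.strand or ".")
            fields.append(f"{rec.score_read:g}")
            fields.append(f"{rec.score_mate:g}")
            fh.write("\t".join(fields) + "\n")
            n += 1
        return n
    finally:
        if close:
            fh.close()


def read_extended_bed(
    source: PathOrHandle, stranded: bool = False
) -> List[AlignmentRecord]:
    fh, close = _opened(source)
    try:
        out: List[AlignmentRecord] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            contig, start0, end, read_id = parts[:4]
            if stranded:
                strand, as_, ys = parts[4], parts[5], parts[6]
            else:
                strand, (as_, ys) = None, parts[4:6]
            out.append(
                AlignmentRecord(
                    contig=contig,
                    start=int(start0) + 1,
                    stop=int(end),
                    read_id=read_id,
                    score_read=float(as_),
                    score_mate=float(ys),
                    strand=strand if strand != "." else None,
                )
            )
        return out
    finally:
        if close:
            fh.close()
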