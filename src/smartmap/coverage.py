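"""Interval arithmetic over coverage tracks: per-locus mean depth, k-mer
mappability, tiled-window statistics, and replicate log ratios."""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "average_depth_over_loci",
    "umap_like_score",
    "bin_loci_by_score",
    "count_high_signal_windows",
    "depth_normalized_log_ratio",
]

DenseTrack = Mapping[str, np.ndarray]


def _cumsum_with_zero(arr: np.ndarray) -> np.ndarray:
    out = np.empty(arr.shape[0] + 1, dtype=np.float64)
    out[0] = 0.0
    np.cumsum(arr, out=out[1:])
    return out


def average_depth_over_loci(dense: DenseTrack, loci: pd.DataFrame) -> pd.DataFrame:
    """Mean per-base signal of each locus (bases without signal count as 0).

    ``dense`` maps contig -> per-base array (index 0 = first base); ``loci``
    needs columns contig, start0, end (0-based half-open). Overlapping loci
    are conceptually merged before the per-base partition, but each original
    locus still receives its own mean, so the result is the per-locus mean
    directly. Returns the loci with a ``mean`` column appended, input order.
    """
    prefix = {c: _cumsum_with_zero(np.asarray(a, dtype=np.float64)) for c, a in dense.items()}
    means = np.empty(len(loci), dtype=np.float64)
    for i, row in enumerate(loci.itertuples(index=False)):
        if row.contig not in prefix:
            raise KeyError(f"locus contig {row.contig!r} not in track")
        p = prefix[row.contig]
        s, e = int(row.start0), int(row.end)
        if not (0 <= s < e <= p.shape[0] - 1):
            raise ValueError(f"locus {row.contig}:{s}-{e} out of contig bounds")
        means[i] = (p[e] - p[s]) / (e - s)
    out = loci.copy()
    out["mean"] = means
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def umap_like_score(
    genome: Mapping[str, str], k: int = 50, canonical: bool = False
) -> Dict[str, np.ndarray]:
    """Per-base k-mer uniqueness track, computed exactly.

    score(b) = (number of unique k-mers among those covering base b) /
    (number of k-mers covering b). A k-mer is unique if its sequence occurs
    once in the whole genome (forward strand only by default; with
    ``canonical`` each k-mer is pooled with its reverse complement before
    counting). Contigs shorter than k get an all-zero track with a warning.
    """
    counts: Dict[str, int] = {}
    starts: Dict[str, List[str]] = {}
    for name, seq in genome.items():
        seq = seq.upper()
        n = len(seq) - k + 1
        kmers = [seq[i : i + k] for i in range(max(n, 0))]
        starts[name] = kmers
        for km in kmers:
            key = min(km, _revcomp(km)) if canonical else km
            counts[key] = counts.get(key, 0) + 1
    scores: Dict[str, np.ndarray] = {}
    for name, seq in genome.items():
        L = len(seq)
        if L < k:
            logger.warning("contig %r shorter than k=%d; mappability set to 0", name, k)
            scores[name] = np.zeros(L, dtype=np.float64)
            continue
        uniq = np.empty(L - k + 1, dtype=np.float64)
        for i, km in enumerate(starts[name]):
            key = min(km, _revcomp(km)) if canonical else km
            uniq[i] = 1.0 if counts[key] == 1 else 0.0
        # base b (0-based) is covered by k-mers starting in
        # [max(0, b-k+1), min(b, L-k)]
        p = _cumsum_with_zero(uniq)
        b = np.arange(L)
        lo = np.maximum(0, b - k + 1)
        hi = np.minimum(b, L - k) + 1  # exclusive
        covered = (hi - lo).astype(np.float64)
        scores[name] = (p[hi] - p[lo]) / covered
    return scores


def bin_loci_by_score(
    table: pd.DataFrame,
    score_col: str = "score",
    value_col: Optional[str] = None,
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Histogram loci by a [0, 1] score in fixed-width bins.

    Returns per-bin rows (bin_left, count) plus median/mean of ``value_col``
    when given. Bin edges sit at multiples of ``bin_width``; each bin is
    [left, left + width) except the last, which closes at 1.0 so a score of
    exactly 1 lands in the top bin.
    """
    scores = np.asarray(table[score_col], dtype=np.float64)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    n_bins = int(math.ceil(round(1.0 / bin_width, 9)))
    idx = np.minimum((scores / bin_width).astype(np.int64), n_bins - 1)
    df = pd.DataFrame({"bin": idx})
    if value_col is not None:
        df["value"] = np.asarray(table[value_col], dtype=np.float64)
        g = df.groupby("bin")["value"]
        out = pd.DataFrame(
            {"count": g.size(), "median": g.median(), "mean": g.mean()}
        ).reset_index()
    else:
        out = df.groupby("bin").size().rename("count").reset_index()
    out.insert(0, "bin_left", out.pop("bin") * bin_width)
    return out


def count_high_signal_windows(
    dense: DenseTrack, thresholds: Sequence[float], window: int = 200
) -> Dict[float, int]:
    """Count fixed windows whose mean signal exceeds each threshold.

    Contigs are tiled with non-overlapping ``window``-bp windows from base 1;
    a final partial window is kept and averaged over its true length. Counts
    are non-increasing in the threshold.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be ascending")
    means: List[np.ndarray] = []
    for arr in dense.values():
        arr = np.asarray(arr, dtype=np.float64)
        p = _cumsum_with_zero(arr)
        starts = np.arange(0, arr.shape[0], window)
        ends = np.minimum(starts + window, arr.shape[0])
        means.append((p[ends] - p[starts]) / (ends - starts))
    allm = np.concatenate(means) if means else np.empty(0)
    return {float(t): int((allm > t).sum()) for t in thresholds}


def depth_normalized_log_ratio(
    depth_a: pd.DataFrame,
    depth_b: pd.DataFrame,
    total_a: float,
    total_b: float,
    pseudocount: float = 0.0,
    log_base: float = math.e,
) -> Tuple[pd.DataFrame, float, int]:
    """Per-locus log ratios of depth-normalised signal between replicates.

    Inputs are per-locus mean-depth tables (``mean`` column) over the same
    locus set, and each replicate's normalising total (retained read count).
    ratio = log( ((a + pc)/total_a) / ((b + pc)/total_b) ). With pseudocount
    0, loci where either replicate is 0 are skipped and tallied. Returns
    (table with ``log_ratio``, mean |ratio|, n_skipped).
    """
    if len(depth_a) != len(depth_b):
        raise ValueError("replicate tables must cover the same loci")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("normalising totals must be positive")
    a = np.asarray(depth_a["mean"], dtype=np.float64) + pseudocount
    b = np.asarray(depth_b["mean"], dtype=np.float64) + pseudocount
    ok = (a > 0) & (b > 0)
    n_skipped = int((~ok).sum())
    ratios = np.full(a.shape, np.nan)
    ratios[ok] = (np.log((a[ok] / total_a) / (b[ok] / total_b))) / math.log(log_base)
    out = depth_a.copy()
    out["log_ratio"] = ratios
    mean_abs = float(np.nanmean(np.abs(ratios))) if ok.any() else float("nan")
    return out, mean_abs, n_skipped
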