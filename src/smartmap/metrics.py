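"""Accuracy metrics against the simulator's Gold Standard: per-locus depth
errors, alignment-vs-truth overlap scores, and allocation-strategy
comparisons (uniread / random selection / no reweighting / reweighting)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bedio import AlignmentRecord
from .coverage import average_depth_over_loci
from .fenwick import GenomeWeightTrack
from .reweight import ReweightConfig, build_read_groups, run_smartmap

__all__ = [
    "locus_errors",
    "LocusErrorSummary",
    "overlap_metrics",
    "strategy_compare",
    "random_select",
]

DenseTrack = Mapping[str, np.ndarray]


@dataclass
class LocusErrorSummary:
    table: pd.DataFrame  # per-locus gold, analysis, error, abs_error
    mean_error: float
    mae: float


def locus_errors(
    gold_dense: DenseTrack, analysis_dense: DenseTrack, loci: pd.DataFrame
) -> LocusErrorSummary:
    """Per-locus mean-depth error of an analysis track against the truth.

    error = analysis mean - gold mean per locus; summaries are the signed
    mean error and the mean absolute error (MAE).
    """
    if len(loci) == 0:
        raise ValueError("empty locus list")
    gold = average_depth_over_loci(gold_dense, loci)["mean"].to_numpy()
    ana = average_depth_over_loci(analysis_dense, loci)["mean"].to_numpy()
    err = ana - gold
    table = loci.copy()
    table["gold"] = gold
    table["analysis"] = ana
    table["error"] = err
    table["abs_error"] = np.abs(err)
    return LocusErrorSummary(
        table=table,
        mean_error=float(err.mean()),
        mae=float(np.abs(err).mean()),
    )


def overlap_metrics(
    weighted_alignments: Iterable[Tuple[AlignmentRecord, float]],
    gold_fragments: pd.DataFrame,
    weight_bin_width: float = 0.05,
) -> pd.DataFrame:
    """Overlap of each alignment with its read's true origin, binned by weight.

    For an alignment intersecting the true interval, the unweighted overlap
    proportion score is the geometric mean of (overlap / alignment length)
    and (overlap / true length); the weighted score multiplies it by the
    alignment's weight. Alignments of reads absent from the truth count as
    non-intersecting. Returns per-weight-bin rows: bin_left, n, intersect
    fraction, mean weighted score, mean unweighted score.
    """
    truth: Dict[str, Tuple[str, int, int]] = {
        r.read_id: (r.contig, int(r.start0) + 1, int(r.end))
        for r in gold_fragments.itertuples(index=False)
    }
    rows = []
    for aln, w in weighted_alignments:
        hit = truth.get(aln.read_id)
        unweighted = 0.0
        intersects = False
        if hit is not None and hit[0] == aln.contig:
            _, ts, te = hit
            ov = min(aln.stop, te) - max(aln.start, ts) + 1
            if ov > 0:
                intersects = True
                unweighted = math.sqrt(
                    (ov / aln.length) * (ov / (te - ts + 1))
                )
        rows.append((w, intersects, unweighted, w * unweighted))
    df = pd.DataFrame(rows, columns=["weight", "intersects", "unweighted", "weighted"])
    n_bins = int(round(1.0 / weight_bin_width))
    idx = np.minimum((df["weight"] / weight_bin_width).astype(int), n_bins - 1)
    df["bin_left"] = idx * weight_bin_width
    g = df.groupby("bin_left")
    out = pd.DataFrame(
        {
            "n": g.size(),
            "intersect_fraction": g["intersects"].mean(),
            "mean_weighted_score": g["weighted"].mean(),
            "mean_unweighted_score": g["unweighted"].mean(),
        }
    ).reset_index()
    return out


def random_select(
    records: Sequence[AlignmentRecord], seed: int
) -> List[AlignmentRecord]:
    """Pick one alignment per read uniformly at random (qualities ignored)."""
    rng = np.random.default_rng(seed)
    by_read: Dict[str, List[AlignmentRecord]] = {}
    order: List[str] = []
    for rec in records:
        if rec.read_id not in by_read:
            by_read[rec.read_id] = []
            order.append(rec.read_id)
        by_read[rec.read_id].append(rec)
    out = []
    for rid in order:
        group = by_read[rid]
        out.append(group[int(rng.integers(0, len(group)))])
    return out


def _track_dense(track: GenomeWeightTrack) -> Dict[str, np.ndarray]:
    return {c: track.to_dense(c) for c in track.chrom_sizes}


def strategy_compare(
    records: Sequence[AlignmentRecord],
    uniread_records: Sequence[AlignmentRecord],
    chrom_sizes: Mapping[str, int],
    gold_dense: DenseTrack,
    loci: pd.DataFrame,
    config: Optional[ReweightConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """MAE and track mass of the four allocation strategies on one input.

    Strategies: uniread (k = 1 reads only), random one-alignment-per-read
    selection, no reweighting (iteration 0 priors), and the configured
    reweighting run. All consume identical inputs; the random pick uses
    ``seed``.
    """
    if config is None:
        config = ReweightConfig()
    rows = []

    def _run(name: str, recs: Sequence[AlignmentRecord], iters: int) -> None:
        cfg = ReweightConfig(
            iterations=iters, rate=config.rate, scored=config.scored,
            read_length=config.read_length, s_min=config.s_min,
            strand_mode=config.strand_mode, online=config.online,
        )
        res = run_smartmap(build_read_groups(recs), chrom_sizes, cfg)
        summ = locus_errors(gold_dense, _track_dense(res.track), loci)
        rows.append((name, summ.mae, summ.mean_error, res.track.total_mass()))

    _run("uniread", uniread_records, 0)
    _run("random_select", random_select(records, seed), 0)
    _run("iter0", records, 0)
    _run(f"iter{config.iterations}", records, config.iterations)
    return pd.DataFrame(rows, columns=["strategy", "mae", "mean_error", "track_mass"])
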