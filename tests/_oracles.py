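"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's Fenwick-tree code paths: the genome
weight field is a dense per-base NumPy array, and every range sum or
increment is a direct slice operation.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np


class DenseTrackOracle:
    """Dense-array equivalent of the dual-BIT track (1-based API)."""

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.arrays = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}

    def range_increment(self, contig: str, l: int, r: int, v: float) -> None:
        assert 1 <= l < r
        self.arrays[contig][l - 1 : r - 1] += v

    def point_sum(self, contig: str, i: int) -> float:
        return float(self.arrays[contig][:i].sum())

    def locus_sum(self, contig: str, l: int, r: int) -> float:
        return float(self.arrays[contig][l - 1 : r - 1].sum())

    def value_at(self, contig: str, b: int) -> float:
        return float(self.arrays[contig][b - 1])


def brute_force_smartmap(
    records,
    chrom_sizes: Mapping[str, int],
    iterations: int = 1,
    rate: float = 1.0,
    scored: bool = True,
    s_min: float = -60.6,
    online: bool = True,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray], Dict[str, List]]:
    """Direct dense-array implementation of the reweighting equations.

    Returns (per-read weight arrays, dense coverage per contig, per-read
    alignment lists). Quality: q = 1 - 10^(-z/10) with z from the ratio
    s / s_min binned at (0.2, 0.3, 0.4, 0.5, 0.6, 0.7]; unscored q = 1.
    """

    def quality(score: float) -> float:
        if not scored:
            return 1.0
        ratio = score / s_min - 1e-9  # same edge convention as the package
        if ratio > 1.0:
            raise ValueError("score below minimum")
        if ratio <= 0.2:
            z = 42
        elif ratio <= 0.3:
            z = 40
        elif ratio <= 0.4:
            z = 24
        elif ratio <= 0.5:
            z = 23
        elif ratio <= 0.6:
            z = 8
        elif ratio <= 0.7:
            z = 3
        else:
            z = 0
        return 1.0 - 10.0 ** (-z / 10.0)

    # group by read id, preserving first-seen order
    groups: Dict[str, List] = {}
    order: List[str] = []
    for rec in records:
        if rec.read_id not in groups:
            groups[rec.read_id] = []
            order.append(rec.read_id)
        groups[rec.read_id].append(rec)

    cov = {c: np.zeros(int(n), dtype=np.float64) for c, n in chrom_sizes.items()}
    weights: Dict[str, np.ndarray] = {}
    kept: Dict[str, List] = {}
    for rid in order:
        alns = groups[rid]
        q = np.array([quality(a.pair_score) for a in alns])
        if q.sum() <= 0:
            continue
        w = q / q.sum()
        keep = w > 0
        alns = [a for a, k in zip(alns, keep) if k]
        q, w = q[keep], w[keep]
        w = w / w.sum()
        kept[rid] = alns
        weights[rid] = w
        for a, wj in zip(alns, w):
            cov[a.contig][a.start - 1 : a.stop] += wj

    multis = [rid for rid in order if rid in kept and len(kept[rid]) > 1]
    for _ in range(iterations):
        if rate == 0.0:
            continue
        if online:
            for rid in multis:
                alns, w = kept[rid], weights[rid]
                q = np.array([quality(a.pair_score) for a in alns])
                cq = np.array(
                    [cov[a.contig][a.start - 1 : a.stop].mean() for a in alns]
                ) * q
                if cq.sum() <= 0:
                    continue
                new_w = rate * cq / cq.sum() + (1.0 - rate) * w
                for a, dj in zip(alns, new_w - w):
                    cov[a.contig][a.start - 1 : a.stop] += dj
                weights[rid] = new_w
        else:
            snapshot = {c: a.copy() for c, a in cov.items()}
            for rid in multis:
                alns, w = kept[rid], weights[rid]
                q = np.array([quality(a.pair_score) for a in alns])
                cq = np.array(
                    [snapshot[a.contig][a.start - 1 : a.stop].mean() for a in alns]
                ) * q
                if cq.sum() <= 0:
                    continue
                new_w = rate * cq / cq.sum() + (1.0 - rate) * w
                for a, dj in zip(alns, new_w - w):
                    cov[a.contig][a.start - 1 : a.stop] += dj
                weights[rid] = new_w
    return weights, cov, kept


def random_alignment_records(
    rng: np.random.Generator,
    genome_length: int,
    n_reads: int,
    max_k: int = 4,
    frag_len_range: Tuple[int, int] = (80, 250),
    scored: bool = True,
):
    """Random multi-mapping input for oracle-equivalence checks."""
    from smartmap.bedio import AlignmentRecord

    records = []
    for i in range(n_reads):
        k = int(rng.integers(1, max_k + 1))
        flen = int(rng.integers(*frag_len_range))
        for j in range(k):
            start = int(rng.integers(1, genome_length - flen + 1))
            if scored:
                a_s = -6.0 * int(rng.integers(0, 4))
                y_s = -6.0 * int(rng.integers(0, 4))
            else:
                a_s = y_s = 0.0
            records.append(
                AlignmentRecord(
                    contig="c", start=start, stop=start + flen - 1,
                    read_id=f"r{i}", score_read=a_s, score_mate=y_s,
                )
            )
    return records
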