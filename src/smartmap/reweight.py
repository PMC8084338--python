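"""Iterative Bayesian reweighting of multi-mapping read pairs.

Each read pair ``r_i`` carries a set of candidate alignments with weights
``w_{i,j}`` interpreted as ``Pr(alignment j is the true origin)``. Weights are
initialised from alignment-score-derived qualities and then iteratively
updated: the posterior for each alignment is proportional to its quality and
to the mean total weight ``C_{i,j}`` already sitting on its genomic interval,

    w'_{i,j} = r * C_{i,j} q_{i,j} / sum_j C_{i,j} q_{i,j} + (1 - r) * w_{i,j}

with learning rate ``r`` (``r = 1`` is the full Bayes update, ``r = 0``
freezes the weights). The genome-wide weight field lives in a
:class:`~smartmap.fenwick.GenomeWeightTrack`, so each ``C_{i,j}`` is one
O(log L) range sum and each weight change one O(log L) range increment.

Scored mode converts the pair alignment score ``s = AS + YS`` into a binned
pseudo-MAPQ ``z`` (the values Bowtie2 assigns to uniquely mapping reads) via
the ratio ``s / s_min``, where ``s_min = -0.6 - 0.6 * (2 * read_length)`` is
the end-to-end minimum reportable pair score; the alignment quality is then
``q = 1 - 10^(-z/10)``. Unscored mode sets every ``q = 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .bedio import AlignmentRecord
from .fenwick import GenomeWeightTrack

logger = logging.getLogger(__name__)

__all__ = [
    "ReweightConfig",
    "ReadGroup",
    "min_pair_score",
    "pseudo_mapq",
    "alignment_quality",
    "build_read_groups",
    "initialize_weights",
    "mean_track_weight",
    "reweight_read",
    "run_smartmap",
    "SmartMapResult",
]

# pseudo-MAPQ bins: (upper edge of s/s_min ratio, z). Lower edge is the
# previous entry's upper edge, open; the first bin [0, 0.2] is closed.
_PSEUDO_MAPQ_BINS: Tuple[Tuple[float, int], ...] = (
    (0.2, 42),
    (0.3, 40),
    (0.4, 24),
    (0.5, 23),
    (0.6, 8),
    (0.7, 3),
    (1.0, 0),
)


def min_pair_score(read_length: int) -> float:
    """Minimum reportable pair alignment score for end-to-end alignment.

    ``-0.6 - 0.6 * (2 * read_length)``: the per-read minimum evaluated at the
    combined length of both mates, e.g. -60.6 for 50 bp reads.
    """
    if read_length < 1:
        raise ValueError("read_length must be positive")
    return -0.6 - 0.6 * (2 * read_length)


def pseudo_mapq(s: float, s_min: float) -> int:
    """Binned pseudo-MAPQ ``z`` for a pair score ``s`` given minimum ``s_min``.

    The ratio ``s / s_min`` falls in [0, 1] for any score the aligner may
    report; a ratio above 1 (score below the aligner minimum) is an error.
    """
    if s_min >= 0:
        raise ValueError("s_min must be negative")
    if s > 0:
        raise ValueError(f"pair score {s} > 0")
    ratio = s / s_min
    # bin edges are exact decimals; guard against float round-off when the
    # ratio lands on an edge (e.g. 0.7 * s_min / s_min)
    eps = 1e-9
    if ratio > 1.0 + eps:
        raise ValueError(
            f"pair score {s} below minimum {s_min} (ratio {ratio:.3f} > 1)"
        )
    for upper, z in _PSEUDO_MAPQ_BINS:
        if ratio <= upper + eps:
            return z
    return 0  # unreachable; ratio <= 1 always hits the last bin


def alignment_quality(z: int, scored: bool = True) -> float:
    """Probability of correct placement implied by pseudo-MAPQ ``z``.

    ``q = 1 - 10^(-z/10)`` in scored mode; exactly 1 in unscored mode.
    """
    if not scored:
        return 1.0
    return 1.0 - 10.0 ** (-z / 10.0)


@dataclass
class ReweightConfig:
    """Knobs of the reweighting run.

    iterations: number of full reweighting passes after initialisation.
    rate: learning rate ``r`` in [0, 1] (1 = full Bayes posterior).
    scored: derive qualities from alignment scores (else all q = 1).
    read_length: mate length in bp, drives the default minimum pair score.
    s_min: override for the minimum pair score (must be negative).
    strand_mode: keep one weight field per strand.
    online: update the track after every read (the default schedule);
        False recomputes all posteriors from the iteration-start track
        and applies them at the end of the pass (synchronous/batch).
    """

    iterations: int = 1
    rate: float = 1.0
    scored: bool = True
    read_length: int = 50
    s_min: Optional[float] = None
    strand_mode: bool = False
    online: bool = True

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.s_min is None:
            self.s_min = min_pair_score(self.read_length)
        if self.s_min >= 0:
            raise ValueError("s_min must be negative")


@dataclass
class ReadGroup:
    """All retained alignments of one read pair with their evolving weights."""

    read_id: str
    alignments: List[AlignmentRecord]
    qualities: np.ndarray = field(default_factory=lambda: np.empty(0))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    frozen: bool = False

    @property
    def k(self) -> int:
        return len(self.alignments)


def build_read_groups(
    records: Iterable[AlignmentRecord],
) -> List[ReadGroup]:
    """Group alignment records by read id, preserving first-seen read order."""
    by_read: Dict[str, List[AlignmentRecord]] = {}
    order: List[str] = []
    for rec in records:
        if rec.read_id not in by_read:
            by_read[rec.read_id] = []
            order.append(rec.read_id)
        by_read[rec.read_id].append(rec)
    return [ReadGroup(read_id=rid, alignments=by_read[rid]) for rid in order]


def initialize_weights(
    group: ReadGroup,
    track: Optional[GenomeWeightTrack],
    config: ReweightConfig,
) -> Optional[ReadGroup]:
    """Assign prior weights ``w = q / sum(q)`` and push them onto the track.

    Returns the group, or None if the read is discarded (all qualities zero
    in scored mode, or a rejected score). Alignments whose weight is zero are
    dropped; single-alignment reads get weight 1 and are frozen out of the
    iteration.
    """
    qs = np.empty(len(group.alignments), dtype=np.float64)
    for j, aln in enumerate(group.alignments):
        if config.scored:
            try:
                z = pseudo_mapq(aln.pair_score, config.s_min)
            except ValueError:
                logger.warning(
                    "read %s: alignment score %s below minimum %s; rejected",
                    group.read_id, aln.pair_score, config.s_min,
                )
                return None
            qs[j] = alignment_quality(z, scored=True)
        else:
            qs[j] = 1.0
    total = qs.sum()
    if total <= 0.0:
        return None  # scored mode, every alignment at q = 0
    w = qs / total
    keep = w > 0.0
    if not keep.all():
        group.alignments = [a for a, k in zip(group.alignments, keep) if k]
        qs, w = qs[keep], w[keep]
        w = w / w.sum()
    group.qualities = qs
    group.weights = w
    group.frozen = group.k == 1
    if track is not None:
        for aln, wj in zip(group.alignments, group.weights):
            track.range_increment(
                aln.contig, aln.start, aln.stop + 1, float(wj),
                strand=aln.strand if config.strand_mode else None,
            )
    return group


def mean_track_weight(
    track: GenomeWeightTrack,
    alignment: AlignmentRecord,
    strand_mode: bool = False,
) -> float:
    """Mean total weight over the alignment's interval (C_{i,j}).

    The sum at each base includes every alignment's current weight there —
    including this alignment's own contribution.
    """
    length = alignment.length
    if length <= 0:
        raise ValueError("zero-length alignment interval")
    s = track.locus_sum(
        alignment.contig, alignment.start, alignment.stop + 1,
        strand=alignment.strand if strand_mode else None,
    )
    return s / length


def _posterior(group: ReadGroup, track: GenomeWeightTrack, config: ReweightConfig) -> Optional[np.ndarray]:
    """Posterior weights for one read from the current track, or None if the
    denominator vanishes (weights then stay unchanged)."""
    cq = np.empty(group.k, dtype=np.float64)
    for j, aln in enumerate(group.alignments):
        cq[j] = mean_track_weight(track, aln, config.strand_mode) * group.qualities[j]
    denom = cq.sum()
    if denom <= 0.0:
        logger.warning("read %s: vanishing posterior denominator; weights kept", group.read_id)
        return None
    return cq / denom


def reweight_read(
    group: ReadGroup, track: GenomeWeightTrack, config: ReweightConfig
) -> ReadGroup:
    """One posterior update of one read, applied to the track immediately."""
    if group.frozen:
        return group
    r = config.rate
    if r == 0.0:
        return group  # exact fixed point: w' = w
    post = _posterior(group, track, config)
    if post is None:
        return group
    new_w = r * post + (1.0 - r) * group.weights
    for j, aln in enumerate(group.alignments):
        delta = float(new_w[j] - group.weights[j])
        if delta != 0.0:
            track.range_increment(
                aln.contig, aln.start, aln.stop + 1, delta,
                strand=aln.strand if config.strand_mode else None,
            )
    group.weights = new_w
    return group


@dataclass
class SmartMapResult:
    track: GenomeWeightTrack
    groups: List[ReadGroup]
    n_discarded: int = 0

    def weighted_alignments(self) -> List[Tuple[AlignmentRecord, float]]:
        out: List[Tuple[AlignmentRecord, float]] = []
        for g in self.groups:
            for aln, w in zip(g.alignments, g.weights):
                out.append((aln, float(w)))
        return out


def run_smartmap(
    groups: Sequence[ReadGroup],
    chrom_sizes: Mapping[str, int],
    config: Optional[ReweightConfig] = None,
    after_iteration: Optional[Callable[[int, GenomeWeightTrack, List[ReadGroup]], None]] = None,
) -> SmartMapResult:
    """Initialise weights and run the configured number of reweighting passes.

    ``after_iteration(i, track, groups)`` is invoked after initialisation
    (i = 0) and after each completed pass (i = 1..iterations), which lets a
    caller snapshot per-iteration coverage without rerunning.

    Reads are processed sequentially in stable input order. In online mode
    (default) the track is updated immediately after each read, so later
    reads in the same pass see the earlier updates; batch mode computes all
    posteriors against the iteration-start track.
    """
    if config is None:
        config = ReweightConfig()
    track = GenomeWeightTrack(chrom_sizes, strand_mode=config.strand_mode)
    live: List[ReadGroup] = []
    n_discarded = 0
    for g in groups:
        res = initialize_weights(g, track, config)
        if res is None:
            n_discarded += 1
        else:
            live.append(res)
    if after_iteration is not None:
        after_iteration(0, track, live)

    iterable = [g for g in live if not g.frozen]
    for it in range(1, config.iterations + 1):
        if config.online:
            for g in iterable:
                reweight_read(g, track, config)
        else:
            updates: List[Tuple[ReadGroup, np.ndarray]] = []
            r = config.rate
            for g in iterable:
                if r == 0.0:
                    break
                post = _posterior(g, track, config)
                if post is None:
                    continue
                updates.append((g, r * post + (1.0 - r) * g.weights))
            for g, new_w in updates:
                for j, aln in enumerate(g.alignments):
                    delta = float(new_w[j] - g.weights[j])
                    if delta != 0.0:
                        track.range_increment(
                            aln.contig, aln.start, aln.stop + 1, delta,
                            strand=aln.strand if config.strand_mode else None,
                        )
                g.weights = new_w
        if after_iteration is not None:
            after_iteration(it, track, live)
    return SmartMapResult(track=track, groups=live, n_discarded=n_discarded)
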