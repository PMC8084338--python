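"""SAM/BAM to extended-BED preparation of paired-end alignments.

The reweighting core consumes one record per candidate alignment of a read
pair. Aligner output is filtered to records whose FLAG is one of 99, 163,
355 or 419 — read paired, mapped in a proper pair, mate on the reverse
strand. These four flags select exactly the leftmost mate of each reported
alignment (primary or secondary), so one SAM record per alignment suffices
and the reverse-strand mate is deliberately dropped: the pair's fragment is
the interval [POS, POS + TLEN - 1] (1-based inclusive).

Reads are then binned by multiplicity k (number of alignments); reads that
hit the aligner's reporting cap (e.g. -k 51) are excluded outright, since
the reported set may be incomplete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pysam

from .bedio import AlignmentRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RETAINED_FLAGS",
    "filter_proper_pairs",
    "extract_fragment",
    "bin_by_multiplicity",
    "prepare_sam",
    "MultiplicityBins",
]

#: FLAG whitelist: paired + proper pair + mate reverse, primary (99, 163)
#: and secondary (355, 419) alignments of the forward-placed mate.
RETAINED_FLAGS = frozenset({99, 163, 355, 419})

#: default strand inference for strand-specific work: the whitelisted flags
#: with the read on the forward strand (99/355, first-in-pair) map to "+",
#: those where the read is the second mate (163/419) map to "-". The rule is
#: configurable because aligner/library conventions differ.
DEFAULT_STRAND_RULE: Dict[int, str] = {99: "+", 355: "+", 163: "-", 419: "-"}


def filter_proper_pairs(records: Iterable) -> Iterator:
    """Keep exactly the records whose FLAG is whitelisted, preserving order.

    Works on anything exposing an integer ``.flag`` (pysam AlignedSegment);
    records without one are rejected with a warning and skipped.
    """
    for rec in records:
        flag = getattr(rec, "flag", None)
        if flag is None:
            logger.warning("record without FLAG field rejected: %r", rec)
            continue
        if flag in RETAINED_FLAGS:
            yield rec


def extract_fragment(
    rec: pysam.AlignedSegment,
    strand_mode: bool = False,
    require_scores: bool = True,
    strand_rule: Optional[Dict[int, str]] = None,
) -> AlignmentRecord:
    """Extract the fragment interval and scores from a whitelisted record.

    The fragment is [POS, POS + TLEN - 1], 1-based inclusive; TLEN must be
    positive (the whitelist selects the leftmost mate). AS/YS are read from
    the optional tags; missing tags raise in scored workflows and fall back
    to 0 otherwise.
    """
    tlen = rec.template_length
    if tlen <= 0:
        raise ValueError(
            f"read {rec.query_name}: non-positive TLEN {tlen} on a retained flag"
        )
    pos1 = rec.reference_start + 1  # pysam is 0-based
    strand = None
    if strand_mode:
        rule = strand_rule or DEFAULT_STRAND_RULE
        strand = rule.get(rec.flag)

    def _tag(name: str) -> float:
        try:
            return float(rec.get_tag(name))
        except KeyError:
            if require_scores:
                raise ValueError(
                    f"read {rec.query_name}: missing {name} tag in scored workflow"
                ) from None
            return 0.0

    return AlignmentRecord(
        contig=rec.reference_name,
        start=pos1,
        stop=pos1 + tlen - 1,
        read_id=rec.query_name,
        score_read=_tag("AS"),
        score_mate=_tag("YS"),
        strand=strand,
    )


@dataclass
class MultiplicityBins:
    """Alignment records grouped by per-read alignment count."""

    by_k: Dict[int, List[List[AlignmentRecord]]] = field(default_factory=dict)
    discarded_reads: int = 0  # reads at the reporting cap

    @property
    def retained_reads(self) -> int:
        return sum(len(v) for v in self.by_k.values())

    def records(self, k_min: int = 1, k_max: Optional[int] = None) -> List[AlignmentRecord]:
        """Flatten retained records with k in [k_min, k_max], input order."""
        out: List[AlignmentRecord] = []
        for k in sorted(self.by_k):
            if k < k_min or (k_max is not None and k > k_max):
                continue
            for group in self.by_k[k]:
                out.extend(group)
        return out

    def uniread_records(self) -> List[AlignmentRecord]:
        return self.records(k_min=1, k_max=1)


def bin_by_multiplicity(
    records: Iterable[AlignmentRecord], k_cap: int
) -> MultiplicityBins:
    """Group records by read and split by alignment count.

    Reads with exactly ``k_cap`` alignments (the aligner's reporting limit)
    are excluded and counted — their alignment set may be truncated. A read
    with more than ``k_cap`` alignments is inconsistent with the stated
    aligner settings and raises.
    """
    if k_cap < 2:
        raise ValueError("k_cap must be >= 2")
    by_read: Dict[str, List[AlignmentRecord]] = {}
    order: List[str] = []
    for rec in records:
        if rec.read_id not in by_read:
            by_read[rec.read_id] = []
            order.append(rec.read_id)
        by_read[rec.read_id].append(rec)
    bins = MultiplicityBins()
    for rid in order:
        group = by_read[rid]
        k = len(group)
        if k > k_cap:
            raise ValueError(
                f"read {rid} has {k} alignments > reporting cap {k_cap}"
            )
        if k == k_cap:
            bins.discarded_reads += 1
            continue
        bins.by_k.setdefault(k, []).append(group)
    return bins


def prepare_sam(
    path: str,
    k_cap: int = 51,
    strand_mode: bool = False,
    require_scores: bool = True,
    strand_rule: Optional[Dict[int, str]] = None,
) -> MultiplicityBins:
    """Full preparation pipeline: SAM/BAM file -> multiplicity-binned records."""
    mode = "rb" if path.endswith(".bam") else "r"
    dropped = 0
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.flag not in RETAINED_FLAGS:
                dropped += 1
                continue
            try:
                records.append(
                    extract_fragment(rec, strand_mode, require_scores, strand_rule)
                )
            except ValueError as exc:
                logger.warning("%s; record skipped", exc)
    logger.info("dropped %d non-whitelisted records", dropped)
    return bin_by_multiplicity(records, k_cap)
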