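"""Synthetic repetitive-genome simulator with a known Gold Standard.

Replaces the aligner-plus-reference stack at desk scale: a random genome
seeded with repeat families (segments duplicated at configurable copy number
and per-copy divergence), paired-end fragments sampled from 200 bp target
loci with ~Normal(175, 10) insert lengths and per-base substitution errors,
and an exhaustive all-occurrence mapper that emits one scored alignment
record per genomic placement where both mates match within a mismatch
budget. Because every fragment's true origin is recorded, the exact coverage
implied by the truth (the Gold Standard) is available for error metrics.

The mapper is exact, not heuristic: a pigeonhole seed index (any placement
of a mate with at most m mismatches must contain one of its m+1 disjoint
seed k-mers exactly) generates candidates, which are then verified by direct
comparison. Scores mimic end-to-end alignment: AS = -penalty * (mate-1
mismatches), YS the same for mate 2. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bedio import AlignmentRecord

__all__ = [
    "RepeatFamily",
    "SimulationConfig",
    "GoldStandard",
    "SimulatedDataset",
    "make_repetitive_genome",
    "sample_fragments",
    "enumerate_alignments",
    "simulate",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatFamily:
    """One family of duplicated segments."""

    unit_length: int
    copies: int
    divergence: float = 0.0  # per-base substitution rate applied per copy

    def __post_init__(self):
        if self.unit_length < 1 or self.copies < 1:
            raise ValueError("unit_length and copies must be positive")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")


# Default repeat content: ~16% of a 1 Mb contig duplicated at copy numbers
# spanning 2-100x with per-copy divergence 0-2%, emulating the young-repeat
# landscape of a mammalian genome at desk scale: a realistic minority
# (~10-14%) of read pairs are multireads, the 100x family mostly exceeds a
# 51-alignment reporting cap (unanalyzable), and most of the genome stays
# uniquely mappable.
_DEFAULT_FAMILIES: Tuple[RepeatFamily, ...] = (
    RepeatFamily(unit_length=300, copies=100, divergence=0.005),
    RepeatFamily(unit_length=500, copies=40, divergence=0.0),
    RepeatFamily(unit_length=600, copies=30, divergence=0.001),
    RepeatFamily(unit_length=700, copies=25, divergence=0.003),
    RepeatFamily(unit_length=1000, copies=20, divergence=0.002),
    RepeatFamily(unit_length=2000, copies=15, divergence=0.005),
    RepeatFamily(unit_length=800, copies=15, divergence=0.01),
    RepeatFamily(unit_length=3000, copies=4, divergence=0.02),
    RepeatFamily(unit_length=1500, copies=2, divergence=0.0),
)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults mirror the validation design: 200 bp target loci sampled
    uniformly, 30-fold target coverage, insert length Normal(175, 10),
    50 bp mates, ~1% substitution error, a small off-target fragment
    fraction, and an alignment-reporting cap of 51.
    """

    seed: int
    genome_length: int = 1_000_000
    contig: str = "chrS"
    repeat_families: Tuple[RepeatFamily, ...] = _DEFAULT_FAMILIES
    n_target_loci: int = 1200
    locus_length: int = 200
    target_coverage: float = 30.0
    insert_mean: float = 175.0
    insert_sd: float = 10.0
    read_length: int = 50
    gap_max: int = 150  # max unsequenced gap between mates
    error_rate: float = 0.01
    off_target_fraction: float = 0.02
    k_cap: int = 51
    max_mismatches: int = 3  # per mate
    mismatch_penalty: float = 6.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("genome_length", "n_target_loci", "locus_length",
                     "read_length", "k_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("error_rate", "off_target_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        total_repeat = sum(f.unit_length * f.copies for f in self.repeat_families)
        if total_repeat > self.genome_length:
            raise ValueError(
                f"repeat content {total_repeat} bp exceeds genome length"
            )

    @property
    def n_fragments_on_target(self) -> int:
        return int(round(
            self.target_coverage * self.n_target_loci * self.locus_length
            / self.insert_mean
        ))


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a different base)."""
    if rate <= 0.0:
        return codes.copy()
    out = codes.copy()
    hit = rng.random(out.shape[0]) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def make_repetitive_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Random genome with embedded repeat copies.

    Returns ({contig: base codes 0-3}, annotation) where the annotation has
    one row per placed copy (contig, start0, end, name = family.copy).
    Copies never overlap each other.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome_length
    g = rng.integers(0, 4, size=L, dtype=np.uint8)
    occupied: List[Tuple[int, int]] = []
    rows = []
    for fi, fam in enumerate(config.repeat_families):
        unit = rng.integers(0, 4, size=fam.unit_length, dtype=np.uint8)
        for ci in range(fam.copies):
            # rejection-sample a placement clear of previous copies
            for _ in range(10_000):
                s = int(rng.integers(0, L - fam.unit_length + 1))
                e = s + fam.unit_length
                if all(e <= os or s >= oe for os, oe in occupied):
                    break
            else:
                raise RuntimeError("could not place repeat copy without overlap")
            g[s:e] = _mutate(unit, fam.divergence, rng)
            occupied.append((s, e))
            rows.append((config.contig, s, e, f"family{fi}.copy{ci}"))
    ann = pd.DataFrame(rows, columns=["contig", "start0", "end", "name"])
    ann = ann.sort_values(["start0"]).reset_index(drop=True)
    return {config.contig: g}, ann


@dataclass
class GoldStandard:
    """True origin of every simulated fragment and the coverage it implies."""

    fragments: pd.DataFrame  # contig, start0, end, read_id
    coverage: Dict[str, np.ndarray]  # exact per-base depth
    target_loci: pd.DataFrame  # contig, start0, end (as sampled)
    true_origin_loci: pd.DataFrame  # target loci with nonzero gold depth

    @property
    def total_mass(self) -> float:
        return float(sum(a.sum() for a in self.coverage.values()))


@dataclass
class _FragmentSet:
    contig: str
    starts: np.ndarray  # 0-based fragment starts
    lengths: np.ndarray
    mate1: np.ndarray  # (n, R) base codes as sequenced
    mate2_fwd: np.ndarray  # (n, R) mate-2 codes on the forward strand
    read_ids: List[str]


def sample_fragments(
    genome: Mapping[str, np.ndarray],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[_FragmentSet, GoldStandard]:
    """Sample paired-end fragments from target loci plus off-target noise.

    Target loci are drawn uniformly; each on-target fragment overlaps its
    locus by at least one base, with insert length ~Normal(mean, sd) clamped
    to [read_length, 2*read_length + gap_max]. Off-target fragments are
    uniform over the genome. The Gold Standard records every fragment.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    contig = config.contig
    g = genome[contig]
    L = g.shape[0]
    R = config.read_length
    ll = config.locus_length
    if ll >= L:
        raise ValueError("locus_length must be smaller than the genome")

    locus_starts = np.sort(rng.integers(0, L - ll + 1, size=config.n_target_loci))
    target_loci = pd.DataFrame(
        {"contig": contig, "start0": locus_starts, "end": locus_starts + ll}
    )

    n_on = config.n_fragments_on_target
    f_off = config.off_target_fraction
    n_total = int(round(n_on / (1.0 - f_off))) if f_off < 1.0 else n_on
    n_off = n_total - n_on

    lo, hi = R, 2 * R + config.gap_max
    lengths = np.clip(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_total)),
        lo, min(hi, L),
    ).astype(np.int64)

    starts = np.empty(n_total, dtype=np.int64)
    which_locus = rng.integers(0, config.n_target_loci, size=n_on)
    for i in range(n_on):
        ls = int(locus_starts[which_locus[i]])
        flen = int(lengths[i])
        a = max(0, ls - flen + 1)
        b = min(ls + ll - 1, L - flen)  # inclusive upper bound for start
        starts[i] = rng.integers(a, max(a, b) + 1)
    if n_off:
        starts[n_on:] = rng.integers(0, L - lengths[n_on:] + 1)

    # shuffle so on/off-target fragments are interleaved in read-id order
    perm = rng.permutation(n_total)
    starts, lengths = starts[perm], lengths[perm]

    mate1 = np.empty((n_total, R), dtype=np.uint8)
    mate2_fwd = np.empty((n_total, R), dtype=np.uint8)
    for i in range(n_total):
        s, flen = int(starts[i]), int(lengths[i])
        mate1[i] = _mutate(g[s : s + R], config.error_rate, rng)
        mate2_fwd[i] = _mutate(g[s + flen - R : s + flen], config.error_rate, rng)
    read_ids = [f"sim{i}" for i in range(n_total)]

    cov = np.zeros(L, dtype=np.float64)
    np.add.at(cov, starts, 1.0)
    ends = starts + lengths
    inside = ends < L
    np.subtract.at(cov, ends[inside], 1.0)
    cov = np.cumsum(cov)

    frag_df = pd.DataFrame(
        {"contig": contig, "start0": starts, "end": ends, "read_id": read_ids}
    )
    dense = {contig: cov}
    p = np.concatenate(([0.0], np.cumsum(cov)))
    locus_mass = p[target_loci["end"].to_numpy()] - p[target_loci["start0"].to_numpy()]
    true_origin = target_loci.loc[locus_mass > 0].reset_index(drop=True)

    gold = GoldStandard(
        fragments=frag_df,
        coverage=dense,
        target_loci=target_loci,
        true_origin_loci=true_origin,
    )
    frags = _FragmentSet(
        contig=contig, starts=starts, lengths=lengths,
        mate1=mate1, mate2_fwd=mate2_fwd, read_ids=read_ids,
    )
    return frags, gold


class _SeedIndex:
    """Exact-match index of all length-``s`` windows of one contig."""

    def __init__(self, g: np.ndarray, s: int):
        self.s = s
        self.L = g.shape[0]
        windows = np.lib.stride_tricks.sliding_window_view(g, s).astype(np.int64)
        powers = 4 ** np.arange(s - 1, -1, -1, dtype=np.int64)
        codes = windows @ powers
        self.order = np.argsort(codes, kind="stable").astype(np.int64)
        self.sorted_codes = codes[self.order]
        self.powers = powers

    def encode(self, window: np.ndarray) -> int:
        return int(window.astype(np.int64) @ self.powers)

    def lookup(self, window: np.ndarray) -> np.ndarray:
        code = self.encode(window)
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return self.order[lo:hi]


def enumerate_alignments(
    frags: _FragmentSet,
    genome: Mapping[str, np.ndarray],
    config: SimulationConfig,
) -> Tuple[List[AlignmentRecord], Dict[str, int]]:
    """All genomic placements of each fragment within the mismatch budget.

    A placement is reported when both mates match with at most
    ``max_mismatches`` substitutions at the fragment's exact insert length.
    Per fragment, at most ``k_cap`` placements are emitted (leftmost first,
    deterministically), mirroring an aligner reporting limit. Returns the
    records plus tallies (n_unaligned, n_capped).
    """
    g = genome[frags.contig]
    L = g.shape[0]
    R = config.read_length
    m = config.max_mismatches
    pen = config.mismatch_penalty
    seed_len = R // (m + 1)
    if seed_len < 8:
        raise ValueError(
            f"seed length {seed_len} too short for exact lookup; "
            "reduce max_mismatches or increase read_length"
        )
    index = _SeedIndex(g, seed_len)
    offsets = [t * seed_len for t in range(m + 1)]
    span = np.arange(R)

    records: List[AlignmentRecord] = []
    tallies = {"n_unaligned": 0, "n_capped": 0}
    n = frags.starts.shape[0]
    for i in range(n):
        flen = int(frags.lengths[i])
        m1 = frags.mate1[i]
        m2 = frags.mate2_fwd[i]
        cands: List[np.ndarray] = []
        for off in offsets:
            hits = index.lookup(m1[off : off + seed_len])
            if hits.shape[0]:
                cands.append(hits - off)
        if not cands:
            tallies["n_unaligned"] += 1
            continue
        x = np.unique(np.concatenate(cands))
        x = x[(x >= 0) & (x + flen <= L)]
        if not x.shape[0]:
            tallies["n_unaligned"] += 1
            continue
        mm1 = (g[x[:, None] + span] != m1).sum(axis=1)
        mm2 = (g[(x + flen - R)[:, None] + span] != m2).sum(axis=1)
        ok = (mm1 <= m) & (mm2 <= m)
        x, mm1, mm2 = x[ok], mm1[ok], mm2[ok]
        if not x.shape[0]:
            tallies["n_unaligned"] += 1
            continue
        if x.shape[0] > config.k_cap:
            tallies["n_capped"] += 1
            x, mm1, mm2 = x[: config.k_cap], mm1[: config.k_cap], mm2[: config.k_cap]
        rid = frags.read_ids[i]
        for xx, a, b in zip(x.tolist(), mm1.tolist(), mm2.tolist()):
            records.append(
                AlignmentRecord(
                    contig=frags.contig,
                    start=xx + 1,
                    stop=xx + flen,
                    read_id=rid,
                    score_read=-pen * a,
                    score_mate=-pen * b,
                )
            )
    return records, tallies


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: Dict[str, np.ndarray]  # base codes 0-3
    chrom_sizes: Dict[str, int]
    repeats: pd.DataFrame
    gold: GoldStandard
    alignments: List[AlignmentRecord]
    tallies: Dict[str, int]

    def genome_str(self) -> Dict[str, str]:
        return {c: _codes_to_str(a) for c, a in self.genome.items()}

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for contig, seq in self.genome_str().items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end seeded simulation: genome, fragments, alignments, truth."""
    rng = np.random.default_rng(config.seed)
    genome, repeats = make_repetitive_genome(config, rng)
    frags, gold = sample_fragments(genome, config, rng)
    alignments, tallies = enumerate_alignments(frags, genome, config)
    return SimulatedDataset(
        config=config,
        genome=genome,
        chrom_sizes={c: a.shape[0] for c, a in genome.items()},
        repeats=repeats,
        gold=gold,
        alignments=alignments,
        tallies=tallies,
    )
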