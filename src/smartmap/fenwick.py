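"""Dual binary-indexed-tree (Fenwick) genome weight track.

Each contig of length ``L`` is stored as a pair of Fenwick trees ``(T1, T2)``
with ``L + 1`` nodes each, supporting range increment and range sum of
real-valued weights in ``O(log L)``:

* ``T1`` is a Fenwick tree over the difference array of the per-base values,
  so the value at base ``b`` is ``BITSum(T1, b)``.
* ``T2`` carries the boundary correction terms so that the prefix sum over
  bases ``[1, i]`` is ``PointSum(i) = BITSum(T1, i) * i - BITSum(T2, i)``.

Incrementing every base in the half-open range ``[l, r)`` by ``v`` is then

    BITUpdate(T1, l, +v)        BITUpdate(T2, l, +v * (l - 1))
    BITUpdate(T1, r, -v)        BITUpdate(T2, r, -v * (r - 1))

All indices on this API are 1-based (base 1 is the first base of the contig);
conversion to the 0-based half-open convention happens only at BED/BEDGRAPH
boundaries.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, Mapping, TextIO, Tuple

import numpy as np

__all__ = [
    "FenwickTree",
    "GenomeWeightTrack",
    "bit_update",
    "bit_sum",
]


def bit_update(tree: np.ndarray, i: int, v: float) -> None:
    """Increment index ``i`` of the Fenwick tree ``tree`` by ``v``.

    ``tree`` is a flat 1-indexed array of ``n_nodes + 1`` floats (slot 0
    unused); the walk adds ``lsb(i)`` until it leaves the tree.
    """
    n = tree.shape[0] - 1
    if not 1 <= i <= n:
        raise IndexError(f"Fenwick update index {i} out of bounds [1, {n}]")
    while i <= n:
        tree[i] += v
        i += i & (-i)


def bit_sum(tree: np.ndarray, i: int) -> float:
    """Prefix sum of the underlying array over indices ``[1, i]`` (0 -> 0)."""
    n = tree.shape[0] - 1
    if not 0 <= i <= n:
        raise IndexError(f"Fenwick query index {i} out of bounds [0, {n}]")
    s = 0.0
    while i > 0:
        s += tree[i]
        i -= i & (-i)
    return s


def _bulk_bit_sum(tree: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorised ``bit_sum`` for an array of query indices."""
    out = np.zeros(idx.shape[0], dtype=np.float64)
    i = idx.astype(np.int64).copy()
    while True:
        live = i > 0
        if not live.any():
            break
        out[live] += tree[i[live]]
        i[live] -= i[live] & (-i[live])
    return out


class FenwickTree:
    """A single Fenwick tree over a 1-based dataset of length ``length``.

    Thin object wrapper used where a bare tree (not the dual pair) is wanted,
    e.g. in unit tests of the update/sum primitives.
    """

    def __init__(self, length: int):
        if length < 1:
            raise ValueError("length must be >= 1")
        self.length = length
        # nodes 1..length+1, slot 0 unused
        self.nodes = np.zeros(length + 2, dtype=np.float64)

    def update(self, i: int, v: float) -> None:
        bit_update(self.nodes, i, v)

    def sum(self, i: int) -> float:
        return bit_sum(self.nodes, i)


class _ContigTrack:
    """The (T1, T2) pair for one contig."""

    __slots__ = ("length", "t1", "t2")

    def __init__(self, length: int):
        self.length = length
        self.t1 = np.zeros(length + 2, dtype=np.float64)  # nodes 1..L+1
        self.t2 = np.zeros(length + 2, dtype=np.float64)

    def range_increment(self, l: int, r: int, v: float) -> None:
        if l >= r:
            raise ValueError(f"empty or inverted range [{l}, {r})")
        if l < 1 or r > self.length + 1:
            raise IndexError(
                f"range [{l}, {r}) outside contig bounds [1, {self.length + 1})"
            )
        t1, t2 = self.t1, self.t2
        n = self.length + 1
        i = l
        while i <= n:
            t1[i] += v
            i += i & (-i)
        i = r
        while i <= n:
            t1[i] -= v
            i += i & (-i)
        vl = v * (l - 1)
        i = l
        while i <= n:
            t2[i] += vl
            i += i & (-i)
        vr = v * (r - 1)
        i = r
        while i <= n:
            t2[i] -= vr
            i += i & (-i)

    def point_sum(self, i: int) -> float:
        if not 0 <= i <= self.length:
            raise IndexError(f"point_sum index {i} outside [0, {self.length}]")
        if i == 0:
            return 0.0
        t1, t2 = self.t1, self.t2
        s1 = 0.0
        s2 = 0.0
        j = i
        while j > 0:
            s1 += t1[j]
            s2 += t2[j]
            j -= j & (-j)
        return s1 * i - s2

    def locus_sum(self, l: int, r: int) -> float:
        if l >= r:
            raise ValueError(f"empty or inverted range [{l}, {r})")
        return self.point_sum(r - 1) - self.point_sum(l - 1)

    def value_at(self, b: int) -> float:
        if not 1 <= b <= self.length:
            raise IndexError(f"base {b} outside contig [1, {self.length}]")
        return bit_sum(self.t1, b)

    def to_dense(self) -> np.ndarray:
        """Per-base values, index 0 = base 1. O(L log L) but fully vectorised."""
        idx = np.arange(1, self.length + 1, dtype=np.int64)
        return _bulk_bit_sum(self.t1, idx)


class GenomeWeightTrack:
    """Per-contig dual Fenwick trees holding fractional read weights.

    In strand-specific mode each contig carries two independent (T1, T2)
    pairs, one per strand; all query/update methods then require ``strand``.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], strand_mode: bool = False):
        if not chrom_sizes:
            raise ValueError("chrom_sizes is empty")
        self.strand_mode = strand_mode
        self.chrom_sizes: Dict[str, int] = dict(chrom_sizes)
        self._contigs: Dict[Tuple[str, str], _ContigTrack] = {}
        strands = ("+", "-") if strand_mode else (".",)
        for name, length in self.chrom_sizes.items():
            if length < 1:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
            for s in strands:
                self._contigs[(name, s)] = _ContigTrack(int(length))

    # -- key handling -------------------------------------------------------

    def _get(self, contig: str, strand: str | None) -> _ContigTrack:
        if self.strand_mode:
            if strand not in ("+", "-"):
                raise ValueError("strand_mode track requires strand '+' or '-'")
            key = (contig, strand)
        else:
            key = (contig, ".")
        try:
            return self._contigs[key]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None

    # -- core operations ----------------------------------------------------

    def range_increment(
        self, contig: str, l: int, r: int, v: float, strand: str | None = None
    ) -> None:
        """Add ``v`` to every base in the half-open 1-based range ``[l, r)``."""
        self._get(contig, strand).range_increment(l, r, v)

    def point_sum(self, contig: str, i: int, strand: str | None = None) -> float:
        """Prefix sum of per-base values over bases ``[1, i]``."""
        return self._get(contig, strand).point_sum(i)

    def locus_sum(
        self, contig: str, l: int, r: int, strand: str | None = None
    ) -> float:
        """Sum of per-base values over the half-open range ``[l, r)``."""
        return self._get(contig, strand).locus_sum(l, r)

    def value_at(self, contig: str, b: int, strand: str | None = None) -> float:
        return self._get(contig, strand).value_at(b)

    def to_dense(self, contig: str, strand: str | None = None) -> np.ndarray:
        return self._get(contig, strand).to_dense()

    def total_mass(self) -> float:
        """Sum of value_at over every base of every contig (and strand)."""
        return float(
            sum(ct.point_sum(ct.length) for ct in self._contigs.values())
        )

    # -- export -------------------------------------------------------------

    def iter_bedgraph(
        self,
        strand: str | None = None,
        include_zero: bool = False,
        decimals: int = 6,
    ) -> Iterator[Tuple[str, int, int, float]]:
        """Yield merged (contig, start0, end, value) runs, BEDGRAPH convention.

        Adjacent equal values are merged; zero runs are omitted unless
        ``include_zero``. Values are rounded to ``decimals`` places before
        merging so the text round-trips losslessly at that precision.
        """
        for contig in self.chrom_sizes:
            dense = np.round(self.to_dense(contig, strand), decimals)
            if dense.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(dense[1:] != dense[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [dense.size]))
            for s, e in zip(starts, ends):
                v = float(dense[s])
                if v == 0.0 and not include_zero:
                    continue
                yield contig, int(s), int(e), v

    def export_bedgraph(
        self,
        writer: TextIO,
        strand: str | None = None,
        include_zero: bool = False,
        decimals: int = 6,
    ) -> None:
        for contig, s, e, v in self.iter_bedgraph(strand, include_zero, decimals):
            if v == 0.0:
                text = "0"
            else:
                text = f"{v:.{decimals}f}".rstrip("0").rstrip(".")
            writer.write(f"{contig}\t{s}\t{e}\t{text}\n")
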