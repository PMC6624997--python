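"""Aggregation of adjacent bedgraph intervals into signal blocks.

A *signal block* is a maximal run of bookended nonzero intervals on one
chromosome — the unit at which peaks are called. Each block carries its
total signal

    t = sum_i (end_i - start_i) * signal_i

over its component intervals (summed left to right in genomic order, so
totals are bit-reproducible), its maximum component signal, and the span
of the component attaining that maximum (leftmost on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from seacr.genomic_io import BedgraphInterval


@dataclass(frozen=True, slots=True)
class SignalBlock:
    chrom: str
    start: int
    end: int
    total_signal: float
    max_signal: float
    max_subregion: tuple[int, int]
    n_components: int = 1

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class BlockSet:
    """Chromosome-sorted collection of signal blocks."""

    blocks: list[SignalBlock] = field(default_factory=list)
    label: str = "target"

    @property
    def m(self) -> int:
        return len(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


def aggregate_blocks(
    intervals: Sequence[BedgraphInterval],
    merge_gap: int = 0,
    label: str = "target",
) -> BlockSet:
    """Merge maximal runs of adjacent intervals into signal blocks.

    Input must be sorted by (chrom, start), non-overlapping within a
    chromosome, with strictly positive signal everywhere; a violation
    raises ``ValueError``. Two consecutive intervals join the same block
    when they share a chromosome and the gap between them is at most
    ``merge_gap`` bases (default 0: strict bookended adjacency).
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    blocks: list[SignalBlock] = []
    cur: SignalBlock | None = None
    prev: BedgraphInterval | None = None
    for iv in intervals:
        if iv.signal <= 0:
            raise ValueError(f"non-positive signal in {iv.chrom}:{iv.start}-{iv.end}")
        if prev is not None and (iv.chrom, iv.start) < (prev.chrom, prev.start):
            raise ValueError("intervals not sorted by (chrom, start)")
        if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
            raise ValueError(
                f"overlapping intervals on {iv.chrom}: "
                f"{prev.start}-{prev.end} and {iv.start}-{iv.end}"
            )
        contrib = (iv.end - iv.start) * iv.signal
        if (
            cur is not None
            and iv.chrom == cur.chrom
            and iv.start - cur.end <= merge_gap
        ):
            cur = replace(
                cur,
                end=iv.end,
                total_signal=cur.total_signal + contrib,
                # leftmost component wins ties, so only a strict improvement moves it
                max_signal=max(cur.max_signal, iv.signal),
                max_subregion=(
                    (iv.start, iv.end)
                    if iv.signal > cur.max_signal
                    else cur.max_subregion
                ),
                n_components=cur.n_components + 1,
            )
        else:
            if cur is not None:
                blocks.append(cur)
            cur = SignalBlock(
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                total_signal=contrib,
                max_signal=iv.signal,
                max_subregion=(iv.start, iv.end),
            )
        prev = iv
    if cur is not None:
        blocks.append(cur)
    return BlockSet(blocks=blocks, label=label)


def block_totals(block_set: BlockSet) -> np.ndarray:
    """Vector of per-block total signal, in block order."""
    return np.array([b.total_signal for b in block_set.blocks], dtype=float)
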