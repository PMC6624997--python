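"""Reading and writing of UCSC bedgraph and BED interval files.

All coordinates are 0-based half-open (UCSC convention): an interval
``[start, end)`` covers ``end - start`` bases, and two intervals are
*adjacent* (bookended) when ``end_i == start_{i+1}``. Bedgraph input is
expected to omit zero-signal regions; explicit zero rows are tolerated
and dropped, which makes them semantically identical to gaps.

Parsing is line oriented rather than delegated to a table reader so
that malformed lines can be reported (strict mode) or skipped with a
counted warning (lenient mode) by line number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("track", "browser", "#")


class BedParseError(ValueError):
    """A malformed line encountered while parsing in strict mode."""


@dataclass(frozen=True, slots=True)
class BedgraphInterval:
    """One nonzero-coverage row of a bedgraph file."""

    chrom: str
    start: int
    end: int
    signal: float

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class BedInterval:
    """A BED interval with optional name and numeric score."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split()


def read_bedgraph(path: str | Path, strict: bool = True) -> list[BedgraphInterval]:
    """Read a 4-column bedgraph into sorted, validated intervals.

    Rows with zero signal are dropped (they are equivalent to gaps in
    the format's contract). Output is sorted by (chrom, start); within
    a chromosome the intervals must be non-overlapping.

    Parameters
    ----------
    path
        Bedgraph file; ``track``/``browser``/``#`` lines are skipped and
        columns may be separated by any whitespace.
    strict
        If True, any malformed or overlapping row raises
        :class:`BedParseError` naming the line number. If False, such
        rows are skipped with a logged warning and count.
    """
    rows: list[tuple[str, int, int, float, int]] = []
    n_skipped = 0
    for lineno, fields in _data_lines(path):
        try:
            if len(fields) < 4:
                raise ValueError(f"expected >= 4 columns, got {len(fields)}")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            signal = float(fields[3])
            if start < 0:
                raise ValueError(f"negative start {start}")
            if end <= start:
                raise ValueError(f"end {end} <= start {start}")
            if signal < 0:
                raise ValueError(f"negative signal {signal}")
        except ValueError as exc:
            if strict:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from None
            n_skipped += 1
            logger.warning("%s: line %d skipped: %s", path, lineno, exc)
            continue
        if signal == 0.0:
            continue
        rows.append((chrom, start, end, signal, lineno))

    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    out: list[BedgraphInterval] = []
    for chrom, start, end, signal, lineno in rows:
        if out and out[-1].chrom == chrom and start < out[-1].end:
            msg = (
                f"{path}: line {lineno}: interval {chrom}:{start}-{end} "
                f"overlaps {chrom}:{out[-1].start}-{out[-1].end}"
            )
            if strict:
                raise BedParseError(msg)
            n_skipped += 1
            logger.warning("%s (skipped)", msg)
            continue
        out.append(BedgraphInterval(chrom, start, end, signal))
    if n_skipped:
        logger.warning("%s: %d malformed/overlapping rows skipped", path, n_skipped)
    return out


def read_bed(
    path: str | Path, score_col: int = 4, strict: bool = True
) -> list[BedInterval]:
    """Read a BED3+ file into sorted intervals with optional score.

    ``score_col`` is the 0-based column index holding the numeric score
    (default 4, the standard BED score column; pass e.g. 8 for the
    q-value column of narrowPeak). Missing or non-numeric score fields
    yield ``score=None``.
    """
    out: list[BedInterval] = []
    n_skipped = 0
    for lineno, fields in _data_lines(path):
        try:
            if len(fields) < 3:
                raise ValueError(f"expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            if start < 0:
                raise ValueError(f"negative start {start}")
            if end <= start:
                raise ValueError(f"end {end} <= start {start}")
        except ValueError as exc:
            if strict:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from None
            n_skipped += 1
            logger.warning("%s: line %d skipped: %s", path, lineno, exc)
            continue
        name = fields[3] if len(fields) > 3 else None
        score = None
        if len(fields) > score_col:
            try:
                score = float(fields[score_col])
            except ValueError:
                score = None
        out.append(BedInterval(chrom, start, end, name=name, score=score))
    if n_skipped:
        logger.warning("%s: %d malformed rows skipped", path, n_skipped)
    out.sort(key=lambda b: (b.chrom, b.start, b.end))
    return out


def format_signal(value: float) -> str:
    """Shortest decimal that round-trips; integral values print with no point."""
    value = float(value)
    if value.is_integer() and abs(value) < 1e16:
        return str(int(value))
    return repr(value)


def write_peaks_bed(path: str | Path, peaks: Sequence) -> Path:
    """Write called peaks as a 6-column tab-delimited BED dialect.

    Columns: chrom, start, end, total signal, max signal, and the
    max-signal subregion as ``chrom:start-end``. Peaks must already be
    sorted by (chrom, start) and non-overlapping within a chromosome;
    a violation indicates a caller bug and raises ``RuntimeError``.
    """
    path = Path(path)
    prev = None
    lines = []
    for p in peaks:
        if prev is not None:
            if (p.chrom, p.start) < (prev.chrom, prev.start):
                raise RuntimeError("peaks not sorted by (chrom, start)")
            if p.chrom == prev.chrom and p.start < prev.end:
                raise RuntimeError(
                    f"overlapping retained peaks on {p.chrom}: "
                    f"{prev.start}-{prev.end} and {p.start}-{p.end}"
                )
        prev = p
        sub_start, sub_end = p.max_subregion
        lines.append(
            "\t".join(
                (
                    p.chrom,
                    str(p.start),
                    str(p.end),
                    format_signal(p.total_signal),
                    format_signal(p.max_signal),
                    f"{p.chrom}:{sub_start}-{sub_end}",
                )
            )
        )
    path.write_text("".join(line + "\n" for line in lines))
    return path


def write_bed(path: str | Path, intervals: Sequence[BedInterval]) -> Path:
    """Write BED intervals (3-5 columns depending on name/score presence)."""
    path = Path(path)
    lines = []
    for b in sorted(intervals, key=lambda b: (b.chrom, b.start, b.end)):
        fields = [b.chrom, str(b.start), str(b.end)]
        if b.name is not None or b.score is not None:
            fields.append(b.name if b.name is not None else ".")
        if b.score is not None:
            fields.append(format_signal(b.score))
        lines.append("\t".join(fields))
    path.write_text("".join(line + "\n" for line in lines))
    return path


def write_bedgraph(path: str | Path, intervals: Sequence[BedgraphInterval]) -> Path:
    """Write intervals as a 4-column bedgraph (zero-signal rows omitted)."""
    path = Path(path)
    lines = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{format_signal(iv.signal)}"
        for iv in intervals
        if iv.signal != 0
    ]
    path.write_text("".join(line + "\n" for line in lines))
    return path
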