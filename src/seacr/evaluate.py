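"""Overlap-based evaluation of a called peak set against a reference.

Precision is the fraction of called peaks sharing >= 1 bp with a
reference peak; recall is the fraction of reference peaks overlapped
by a called peak (each interval counted once, the semantics of
``bedtools intersect -u`` in both directions); F1 = 2PR/(P+R).

For a ranked peak set (total signal for blocks-based calls), a full
precision-recall curve is swept over the distinct ranking-metric
values: at cutoff v, the called subset is {metric >= v}. A reference
peak counts as recalled at cutoff v when the best (largest) metric
among called peaks overlapping it is >= v — equivalent to re-running
the -u overlap on each subset. The area under the curve is the
trapezoidal area over (recall, precision) points, anchored at recall 0
with the precision of the top cutoff (so a ranking whose every peak is
a true positive scores exactly its maximum recall, and a single-point
curve scores precision x recall); no extrapolation toward recall 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from seacr.genomic_io import BedInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class PRPoint:
    cutoff: float
    precision: float
    recall: float


@dataclass(frozen=True)
class PRCurve:
    """Rank-swept precision/recall points (descending cutoff) and AUPR."""

    points: list[PRPoint]
    aupr: float


def _by_chrom(intervals: Sequence[BedInterval]) -> dict[str, np.ndarray]:
    """Per-chromosome (n, 2) arrays of [start, end), sorted by start."""
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: np.array(sorted(spans), dtype=np.int64)
        for chrom, spans in out.items()
    }


def _merge(spans: np.ndarray) -> np.ndarray:
    """Merge sorted spans into disjoint sorted spans (union)."""
    merged = [list(spans[0])]
    for start, end in spans[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=np.int64)


def _overlap_flags(
    queries: Sequence[BedInterval], subjects: Sequence[BedInterval]
) -> np.ndarray:
    """For each query (input order), whether it overlaps any subject >= 1 bp."""
    subj = {chrom: _merge(spans) for chrom, spans in _by_chrom(subjects).items()}
    flags = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        spans = subj.get(q.chrom)
        if spans is None:
            continue
        # disjoint sorted spans: only the last span starting before q.end can overlap
        j = int(np.searchsorted(spans[:, 0], q.end, side="left")) - 1
        flags[i] = j >= 0 and spans[j, 1] > q.start
    return flags


def overlap_counts(
    called: Sequence[BedInterval], reference: Sequence[BedInterval]
) -> tuple[int, int]:
    """(# called overlapping a reference peak, # reference overlapped)."""
    if not called or not reference:
        return 0, 0
    return (
        int(_overlap_flags(called, reference).sum()),
        int(_overlap_flags(reference, called).sum()),
    )


def precision_recall_f1(
    called: Sequence[BedInterval], reference: Sequence[BedInterval]
) -> tuple[float, float, float]:
    """Directed-overlap precision and recall, and their harmonic mean F1.

    An empty called set yields precision 0 with a warning; F1 is 0
    whenever P + R == 0.
    """
    if not called:
        logger.warning("empty called set; precision reported as 0")
        return 0.0, 0.0, 0.0
    if not reference:
        raise ValueError("reference peak set is empty; recall is undefined")
    n_called_hit, n_ref_hit = overlap_counts(called, reference)
    p = n_called_hit / len(called)
    r = n_ref_hit / len(reference)
    f1 = 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def _best_score_per_reference(
    called: Sequence[BedInterval],
    scores: np.ndarray,
    reference: Sequence[BedInterval],
) -> np.ndarray:
    """Max ranking metric among called peaks overlapping each reference peak.

    References overlapped by no called peak get -inf.
    """
    called_idx: dict[str, list[int]] = {}
    for i, c in enumerate(called):
        called_idx.setdefault(c.chrom, []).append(i)
    best = np.full(len(reference), -np.inf)
    for j, ref in enumerate(reference):
        for i in called_idx.get(ref.chrom, ()):
            c = called[i]
            if c.start < ref.end and ref.start < c.end and scores[i] > best[j]:
                best[j] = scores[i]
    return best


def pr_curve(
    called: Sequence[BedInterval],
    reference: Sequence[BedInterval],
    scores: Sequence[float] | None = None,
    n_cutoffs: int | str = "all",
) -> PRCurve:
    """Precision-recall curve swept over the ranking metric.

    ``scores`` defaults to each called interval's ``score`` field;
    every called interval must carry one. ``n_cutoffs`` limits the
    sweep to that many evenly spaced distinct metric values (always
    including the extremes).
    """
    if not reference:
        raise ValueError("reference peak set is empty; cannot build a PR curve")
    if not called:
        raise ValueError("called peak set is empty; cannot build a PR curve")
    if scores is None:
        if any(c.score is None for c in called):
            raise ValueError("every called interval needs a ranking metric")
        scores = [c.score for c in called]
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(called),):
        raise ValueError("scores length must match called intervals")

    hits = _overlap_flags(called, reference)
    best_ref = _best_score_per_reference(called, scores, reference)

    cutoffs = np.unique(scores)[::-1]  # descending
    if cutoffs.size == 1:
        logger.warning("constant ranking metric: single-point PR curve")
    if n_cutoffs != "all":
        k = int(n_cutoffs)
        if k < 1:
            raise ValueError("n_cutoffs must be >= 1")
        if k < cutoffs.size:
            idx = np.unique(np.linspace(0, cutoffs.size - 1, k).round().astype(int))
            cutoffs = cutoffs[idx]

    n_ref = len(reference)
    points = []
    for v in cutoffs:
        subset = scores >= v
        precision = float(hits[subset].sum() / subset.sum())
        recall = float((best_ref >= v).sum() / n_ref)
        points.append(PRPoint(cutoff=float(v), precision=precision, recall=recall))

    recalls = np.array([0.0] + [p.recall for p in points])
    precisions = np.array([points[0].precision] + [p.precision for p in points])
    aupr = float(np.trapezoid(precisions, recalls))
    aupr = min(max(aupr, 0.0), 1.0)
    return PRCurve(points=points, aupr=aupr)
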