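"""Independent brute-force reference implementations used by the tests.

These deliberately use per-base / quadratic / exhaustive computation so
they stay independent of the production code paths they check.
"""

import numpy as np

from seacr.genomic_io import BedgraphInterval


def per_base_blocks(intervals):
    """Per-base oracle for block aggregation.

    Materializes an integer-indexed coverage array per chromosome,
    finds maximal nonzero runs, and sums coverage within each run.
    Returns a list of (chrom, start, end, total, max_signal,
    max_subregion) tuples in (chrom, start) order.
    """
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        length = max(iv.end for iv in ivs)
        cov = np.zeros(length, dtype=float)
        for iv in ivs:
            cov[iv.start : iv.end] += iv.signal
        nonzero = cov > 0
        # maximal nonzero runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], nonzero.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            total = float(cov[s:e].sum())
            max_sig = float(cov[s:e].max())
            # leftmost constant-coverage run attaining the max
            pos = s + int(np.argmax(cov[s:e]))
            ms = pos
            while ms > s and cov[ms - 1] == cov[pos]:
                ms -= 1
            me = pos
            while me < e and cov[me] == cov[pos]:
                me += 1
            out.append((chrom, int(s), int(e), total, max_sig, (int(ms), int(me))))
    return out


def random_bedgraph(rng, genome_size=10_000, max_intervals=40):
    """Random sorted non-overlapping nonzero intervals on one chromosome."""
    n = int(rng.integers(0, max_intervals + 1))
    cuts = np.sort(rng.choice(genome_size, size=min(2 * n, genome_size), replace=False))
    intervals = []
    for s, e in zip(cuts[::2], cuts[1::2]):
        if e > s:
            signal = float(rng.integers(1, 6)) if rng.random() < 0.7 else float(
                np.round(rng.uniform(0.1, 5.0), 3)
            )
            intervals.append(BedgraphInterval("chr1", int(s), int(e), signal))
    return intervals


def exhaustive_stringent(target_totals, control_totals):
    """Exhaustive scan over {0} plus every distinct total: (f_max, t_stringent)."""
    r = list(map(float, target_totals))
    s = list(map(float, control_totals))
    best_f, best_t = None, None
    for t in sorted({0.0, *r, *s}):
        p_t = sum(x > t for x in r) / len(r)
        p_c = sum(x > t for x in s) / len(s)
        if p_t + p_c == 0:
            continue
        f = p_t / (p_t + p_c)
        if best_f is None or f > best_f:  # strict: keeps the smallest maximizer
            best_f, best_t = f, t
    return best_f, best_t


def brute_overlap_counts(called, reference):
    """Quadratic double-loop version of directed -u overlap counts."""

    def hits(queries, subjects):
        n = 0
        for q in queries:
            if any(
                q.chrom == s.chrom and q.start < s.end and s.start < q.end
                for s in subjects
            ):
                n += 1
        return n

    return hits(called, reference), hits(reference, called)


def brute_pr_points(called, scores, reference):
    """Precision/recall at every distinct cutoff by re-filtering and re-counting."""
    points = []
    for v in sorted(set(scores), reverse=True):
        subset = [c for c, sc in zip(called, scores) if sc >= v]
        n_called_hit, n_ref_hit = brute_overlap_counts(subset, reference)
        points.append((v, n_called_hit / len(subset), n_ref_hit / len(reference)))
    return points


def random_intervals(rng, n_max=20, genome_size=2_000, chroms=("chr1", "chr2")):
    from seacr.genomic_io import BedInterval

    n = int(rng.integers(1, n_max + 1))
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, genome_size - 10))
        width = int(rng.integers(1, 120))
        out.append(BedInterval(chrom, start, min(start + width, genome_size)))
    return sorted(out, key=lambda b: (b.chrom, b.start, b.end))
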