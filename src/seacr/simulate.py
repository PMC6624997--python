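"""Seeded generator of paired target/IgG bedgraph fixtures with known truth.

The generator emulates the sparse regime of paired-end CUT&RUN
coverage: background is a thin Poisson scatter of independent
fragments over the genome (identical law for target and IgG), so most
background signal blocks are single fragments separated by long zero
runs, while planted enrichment — narrow peaks or multi-kilobase
domains — stacks many fragments into high-total contiguous blocks.

Fragment lengths are drawn on a 10 bp grid within the configured
range, a coarse model of size-selected libraries (sub-nucleosomal vs
nucleosomal ladders); a block's total signal then equals the summed
lengths of its fragments, reproducing the discrete tie structure of
real sparse background.

In ``null_mode`` the target is drawn from exactly the background law
of the IgG control (independent draw, empty truth set) — the
unexpressed-factor gold standard used to measure specificity.

Everything is driven by one integer seed through
``numpy.random.default_rng``, so fixtures are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from seacr.genomic_io import BedgraphInterval, BedInterval, write_bed, write_bedgraph

FRAGMENT_GRID = 10  # bp quantization of fragment lengths


@dataclass
class SimConfig:
    """Parameters of one synthetic target/IgG pair.

    ``peak_fragments`` is the Poisson mean number of fragments planted
    per peak; ``background_fragments_per_mb`` applies identically to
    target and IgG; ``broad_domains`` entries are
    (chrom, start, end, fold) with fragment density fold x background.
    """

    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 5_000_000)])
    n_peaks: int = 20
    peak_width: tuple[int, int] = (200, 700)
    peak_fragments: float = 50.0
    background_fragments_per_mb: float = 200.0
    fragment_length: tuple[int, int] = (120, 250)
    broad_domains: list[tuple[str, int, int, float]] | None = None
    null_mode: bool = False
    seed: int = 0


PRESETS: dict[str, dict] = {
    # transcription-factor-like: narrow peaks, short fragments
    "tf": {},
    # histone-modification-like: kilobase peaks, nucleosomal fragments
    "histone": {
        "n_peaks": 10,
        "peak_width": (2_000, 10_000),
        "peak_fragments": 300.0,
        "fragment_length": (150, 500),
    },
    # one contiguous 50 kb domain (broad-mark regime)
    "broad": {
        "n_peaks": 0,
        "broad_domains": [("chr1", 2_000_000, 2_050_000, 200.0)],
        "fragment_length": (150, 500),
    },
    # target exchangeable with IgG: specificity gold standard
    "null": {
        "n_peaks": 0,
        "null_mode": True,
    },
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A :class:`SimConfig` for one of the named presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SimConfig(seed=seed, **{**PRESETS[name], **overrides})


@dataclass(frozen=True)
class TruthSet:
    """Planted peaks/domains with their expected fold enrichment."""

    intervals: list[BedInterval]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def coverage_from_fragments(
    fragments: Sequence[tuple[str, int, int]],
) -> list[BedgraphInterval]:
    """Run-length encode exact per-base fragment depth into bedgraph rows.

    Adjacent equal-depth runs are merged and zero-depth runs omitted,
    so this is the exact inverse of block decomposition.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in fragments:
        if start < 0 or end <= start:
            raise ValueError(f"bad fragment span {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    out: list[BedgraphInterval] = []
    for chrom in sorted(by_chrom):
        spans = np.array(by_chrom[chrom], dtype=np.int64)
        length = int(spans[:, 1].max())
        delta = np.zeros(length + 1, dtype=np.int64)
        np.add.at(delta, spans[:, 0], 1)
        np.add.at(delta, spans[:, 1], -1)
        depth = np.cumsum(delta)[:-1]
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [length]))
        for s, e in zip(starts, ends):
            d = int(depth[s])
            if d > 0:
                out.append(BedgraphInterval(chrom, int(s), int(e), float(d)))
    return out


def _sample_fragment_lengths(rng, law: tuple[int, int], n: int) -> np.ndarray:
    """Bell-shaped fragment lengths on the grid within [lo, hi].

    A binomial draw over the grid indices gives a symmetric unimodal
    size distribution peaked at the range midpoint, emulating
    size-selected libraries with a characteristic fragment size; the
    resulting block-total density then has a well-defined mode for
    normalization to anchor on.
    """
    lo, hi = law
    if lo < FRAGMENT_GRID or hi < lo:
        raise ValueError(f"bad fragment length range {law}")
    choices = np.arange(lo, hi + 1, FRAGMENT_GRID)
    if choices.size == 1:
        return np.full(n, choices[0])
    idx = rng.binomial(choices.size - 1, 0.5, size=n)
    return choices[idx]


def _plant_peaks(rng, config: SimConfig) -> list[BedInterval]:
    """Non-overlapping planted peak intervals, rejection sampled."""
    wmin, wmax = config.peak_width
    chroms = config.genome
    capacity = sum(length for _, length in chroms)
    pad = 2 * config.fragment_length[1]
    if config.n_peaks * (wmax + 2 * pad) > capacity:
        raise ValueError("infeasible config: planted peaks exceed genome capacity")
    lengths = np.array([length for _, length in chroms], dtype=float)
    placed: list[BedInterval] = []
    attempts = 0
    while len(placed) < config.n_peaks:
        attempts += 1
        if attempts > 1000 * max(config.n_peaks, 1):
            raise ValueError("infeasible config: could not place peaks without overlap")
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        chrom, clen = chroms[ci]
        width = int(rng.integers(wmin, wmax + 1))
        if clen <= width + 2 * pad:
            continue
        start = int(rng.integers(pad, clen - width - pad))
        cand = BedInterval(chrom, start, start + width, name=f"peak{len(placed) + 1}")
        if any(
            b.chrom == cand.chrom and b.start - pad < cand.end and cand.start < b.end + pad
            for b in placed
        ):
            continue
        placed.append(cand)
    placed.sort(key=lambda b: (b.chrom, b.start))
    return placed


def _background_fragments(rng, config: SimConfig) -> list[tuple[str, int, int]]:
    frags: list[tuple[str, int, int]] = []
    for chrom, clen in config.genome:
        n = rng.poisson(config.background_fragments_per_mb * clen / 1e6)
        if n == 0:
            continue
        lengths = _sample_fragment_lengths(rng, config.fragment_length, n)
        starts = rng.integers(0, np.maximum(clen - lengths, 1))
        frags.extend(
            (chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)
        )
    return frags


def _enrichment_fragments(
    rng, config: SimConfig, peaks: Sequence[BedInterval]
) -> list[tuple[str, int, int]]:
    frags: list[tuple[str, int, int]] = []
    chrom_len = dict(config.genome)
    for peak in peaks:
        n = rng.poisson(config.peak_fragments)
        lengths = _sample_fragment_lengths(rng, config.fragment_length, n)
        centers = rng.integers(peak.start, peak.end, size=n)
        for c, l in zip(centers, lengths):
            s = max(0, int(c) - int(l) // 2)
            e = min(chrom_len[peak.chrom], s + int(l))
            frags.append((peak.chrom, s, e))
    for chrom, start, end, fold in config.broad_domains or ():
        if chrom not in chrom_len or start < 0 or end > chrom_len[chrom]:
            raise ValueError(f"broad domain {chrom}:{start}-{end} outside genome")
        density = fold * config.background_fragments_per_mb / 1e6
        n = rng.poisson(density * (end - start))
        lengths = _sample_fragment_lengths(rng, config.fragment_length, n)
        starts = rng.integers(start, end, size=n)
        for s, l in zip(starts, lengths):
            frags.append((chrom, int(s), min(chrom_len[chrom], int(s + l))))
    return frags


def simulate_pair(
    config: SimConfig,
) -> tuple[list[BedgraphInterval], list[BedgraphInterval], TruthSet]:
    """Draw one (target bedgraph, IgG bedgraph, truth set) triple.

    IgG is always background only. The target adds planted peak and
    domain fragments on top of an independent background draw, except
    in ``null_mode`` where it too is background only and the truth set
    is empty. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    peaks = [] if config.null_mode else _plant_peaks(rng, config)

    target_frags = _background_fragments(rng, config)
    if not config.null_mode:
        target_frags += _enrichment_fragments(rng, config, peaks)
    igg_frags = _background_fragments(rng, config)

    target = coverage_from_fragments(target_frags) if target_frags else []
    igg = coverage_from_fragments(igg_frags) if igg_frags else []

    truth_intervals = list(peaks)
    if not config.null_mode:
        # fold is fragment-start density relative to background density
        bg_per_bp = config.background_fragments_per_mb / 1e6
        for i, p in enumerate(truth_intervals):
            frag_density = config.peak_fragments / (p.end - p.start)
            fold = frag_density / bg_per_bp if bg_per_bp > 0 else float("inf")
            truth_intervals[i] = dataclasses.replace(p, score=round(fold, 1))
        for j, (chrom, start, end, fold) in enumerate(config.broad_domains or ()):
            truth_intervals.append(
                BedInterval(chrom, start, end, name=f"domain{j + 1}", score=fold)
            )
        truth_intervals.sort(key=lambda b: (b.chrom, b.start))
    return target, igg, TruthSet(intervals=truth_intervals)


def write_fixture(config: SimConfig, prefix: str | Path) -> dict[str, Path]:
    """Simulate and write ``<prefix>.{target,igg}.bedgraph``, truth BED, config JSON."""
    prefix = Path(prefix)
    target, igg, truth = simulate_pair(config)
    paths = {
        "target": write_bedgraph(Path(f"{prefix}.target.bedgraph"), target),
        "igg": write_bedgraph(Path(f"{prefix}.igg.bedgraph"), igg),
        "truth": write_bed(Path(f"{prefix}.truth.bed"), truth.intervals),
    }
    config_path = Path(f"{prefix}.config.json")
    config_path.write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=list) + "\n"
    )
    paths["config"] = config_path
    return paths
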