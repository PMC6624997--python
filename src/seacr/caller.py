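"""End-to-end peak calling pipeline.

Stages: read bedgraphs -> aggregate signal blocks -> (normalize control
totals) -> F-curve threshold selection (stringent/relaxed) or numeric
global quantile -> retain target blocks strictly above the threshold ->
drop retained blocks overlapping an above-threshold control block ->
write the 6-column peak BED. Every stage is deterministic, so identical
inputs and flags give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from seacr.blocks import BlockSet, SignalBlock, aggregate_blocks, block_totals
from seacr.genomic_io import read_bedgraph, write_peaks_bed
from seacr.threshold import (
    EmpiricalFDR,
    compute_f_curve,
    empirical_fdr,
    global_threshold,
    normalize_control,
    select_relaxed,
)

logger = logging.getLogger(__name__)

MODES = ("stringent", "relaxed")


@dataclass
class PeakCallResult:
    """Outcome of one peak-calling run."""

    peaks: list[SignalBlock]
    threshold: float
    mode: str
    scaling_factor: float = 1.0
    fdr: EmpiricalFDR | None = None
    n_input_blocks: int = 0
    n_control_filtered: int = 0
    output_path: Path | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def filter_by_threshold(block_set: BlockSet, t: float) -> BlockSet:
    """Blocks with total signal strictly above t, order preserved."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    kept = [b for b in block_set.blocks if b.total_signal > t]
    if not kept:
        logger.warning("no block exceeds threshold %g; empty call", t)
    return BlockSet(blocks=kept, label=block_set.label)


def remove_control_overlaps(
    target_peaks: BlockSet, control_blocks: BlockSet, t: float
) -> tuple[BlockSet, int]:
    """Drop target peaks sharing >= 1 bp with an above-threshold control block.

    Control totals must already be scaled in normalized mode. Overlap
    is half-open: bookended blocks (end == start) do not overlap. This
    removes spurious peaks at multi-mapping or artifact-prone loci that
    show enrichment in the non-specific control as well.
    """
    strong = [c for c in control_blocks.blocks if c.total_signal > t]
    by_chrom: dict[str, list[SignalBlock]] = {}
    for c in strong:
        by_chrom.setdefault(c.chrom, []).append(c)
    kept: list[SignalBlock] = []
    removed = 0
    for peak in target_peaks.blocks:
        controls = by_chrom.get(peak.chrom, ())
        if any(c.start < peak.end and peak.start < c.end for c in controls):
            removed += 1
        else:
            kept.append(peak)
    return BlockSet(blocks=kept, label=target_peaks.label), removed


def _scale_totals(block_set: BlockSet, factor: float) -> BlockSet:
    return BlockSet(
        blocks=[replace(b, total_signal=b.total_signal * factor) for b in block_set],
        label=block_set.label,
    )


def call_peaks(
    target: str | Path,
    control: str | Path | float,
    mode: str = "stringent",
    norm: bool | None = None,
    output_prefix: str | Path | None = None,
    f_variant: str = "remaining",
    merge_gap: int = 0,
) -> PeakCallResult:
    """Run the full pipeline on a target bedgraph.

    Parameters
    ----------
    target
        Target-experiment bedgraph path.
    control
        Either an IgG-control bedgraph path, or a float in (0, 1): the
        top fraction of target blocks to retain in control-free global
        mode (no normalization, IgG filtering or FDR in that case).
    mode
        ``"stringent"`` (threshold at the F-curve maximum) or
        ``"relaxed"`` (halfway in F between maximum and knee). Ignored
        in global mode.
    norm
        Scale control block totals so their density mode matches the
        target's. Defaults to True when a control bedgraph is given.
    output_prefix
        When set, peaks are written to ``<prefix>.<mode>.bed``.
    f_variant
        ``"remaining"`` (canonical) or ``"removed"`` F definition.
    """
    target = Path(target)
    target_intervals = read_bedgraph(target)
    if not target_intervals:
        raise ValueError(f"{target}: no nonzero intervals after parsing")
    target_blocks = aggregate_blocks(target_intervals, merge_gap=merge_gap)
    target_totals = block_totals(target_blocks)
    n_input = target_blocks.m
    logger.info("target: %d intervals -> %d signal blocks", len(target_intervals), n_input)

    if isinstance(control, (int, float)) and not isinstance(control, bool):
        q = float(control)
        if not 0.0 < q < 1.0:
            raise ValueError("numeric control threshold must lie in (0, 1)")
        t = global_threshold(target_totals, q)
        retained = filter_by_threshold(target_blocks, t)
        result = PeakCallResult(
            peaks=retained.blocks,
            threshold=t,
            mode="global",
            n_input_blocks=n_input,
        )
    else:
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if norm is None:
            norm = True
        control_intervals = read_bedgraph(Path(control))
        if not control_intervals:
            raise ValueError(f"{control}: no nonzero intervals after parsing")
        control_blocks = aggregate_blocks(control_intervals, label="control")
        factor = 1.0
        if norm:
            norm_result = normalize_control(target_totals, block_totals(control_blocks))
            factor = norm_result.scaling_factor
            logger.info(
                "normalization: target mode %.3g / control mode %.3g -> factor %.4g",
                norm_result.target_mode,
                norm_result.control_mode,
                factor,
            )
        scaled_control = _scale_totals(control_blocks, factor)
        scaled_control_totals = block_totals(scaled_control)

        curve = compute_f_curve(target_totals, scaled_control_totals, variant=f_variant)
        if mode == "relaxed":
            curve = select_relaxed(curve)
            t = curve.t_relaxed
        else:
            t = curve.t_stringent
        logger.info("mode %s: threshold %.6g (f_max %.4f)", mode, t, curve.f_max)

        retained = filter_by_threshold(target_blocks, t)
        retained, n_removed = remove_control_overlaps(retained, scaled_control, t)
        fdr = empirical_fdr(target_totals, scaled_control_totals, t)
        logger.info(
            "retained %d/%d blocks (%d removed by control overlap); empirical FDR %.4f",
            retained.m,
            n_input,
            n_removed,
            fdr.value,
        )
        result = PeakCallResult(
            peaks=retained.blocks,
            threshold=float(t),
            mode=mode,
            scaling_factor=factor,
            fdr=fdr,
            n_input_blocks=n_input,
            n_control_filtered=n_removed,
        )

    if output_prefix is not None:
        out = Path(f"{output_prefix}.{result.mode}.bed")
        write_peaks_bed(out, result.peaks)
        result.output_path = out
        logger.info("wrote %d peaks to %s", result.n_peaks, out)
    return result


def summary_dict(result: PeakCallResult) -> dict:
    """Machine-readable run summary (for ``--summary`` JSON output)."""
    return {
        "mode": result.mode,
        "threshold": result.threshold,
        "scaling_factor": result.scaling_factor,
        "n_input_blocks": result.n_input_blocks,
        "n_peaks": result.n_peaks,
        "n_control_filtered": result.n_control_filtered,
        "empirical_fdr": result.fdr.value if result.fdr is not None else None,
        "output": str(result.output_path) if result.output_path else None,
    }
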