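"""Empirical total-signal threshold selection.

The method is model free: instead of fitting a background distribution,
it compares the empirical distributions of block totals between a
target experiment and an IgG control.

Definitions (m target blocks with totals r_i, n control blocks with
totals s_j, already scaled in normalized mode):

* ``p_T(t)`` — fraction of target blocks with total strictly above t,
  ``p_C(t)`` — same for control.
* ``F(t) = p_T(t) / (p_T(t) + p_C(t))``, the fraction of all remaining
  above-threshold blocks that come from the target. F is a step
  function changing only at observed totals, so candidates are
  ``{0} U {distinct totals}`` and the sweep is exact.
* stringent threshold — smallest t maximizing F (ties broken toward
  small t to maximize recall at equal F).
* relaxed threshold — the t at which F first reaches the value halfway
  between the curve's maximum and its negatively inflected knee.
* empirical FDR at t — fraction of above-threshold blocks (target and
  control pooled) that are control blocks.

Strict inequality ``total > t`` is used everywhere (curve, filtering,
FDR), so the three stages agree exactly.

An alternative F, formed from counts of blocks *removed* at t rather
than remaining, is available as ``variant="removed"``; the remaining
form is canonical because it is the one consistent with the curve the
threshold schematic describes and it has a well-behaved maximizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

_VARIANTS = ("remaining", "removed")


@dataclass(frozen=True, slots=True)
class NormalizationResult:
    """Control-to-target scaling derived from total-signal density modes."""

    scaling_factor: float
    target_mode: float
    control_mode: float


@dataclass(frozen=True, slots=True)
class EmpiricalFDR:
    """Fraction of above-threshold blocks contributed by the control."""

    value: float
    n_target_above: int
    n_control_above: int


@dataclass(frozen=True)
class ThresholdCurve:
    """F(t) over candidate thresholds, with selected thresholds.

    ``knee_f`` and ``t_relaxed`` are populated by :func:`select_relaxed`.
    """

    candidates: np.ndarray
    f_values: np.ndarray
    frac_target_remaining: np.ndarray
    frac_control_remaining: np.ndarray
    f_max: float
    t_stringent: float
    T: float
    variant: str = "remaining"
    knee_f: float | None = None
    t_relaxed: float | None = None


def _density_mode(values: np.ndarray, grid_size: int = 512) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a uniform grid.

    The evaluation points are a uniform grid over [0, max(values)]
    plus the observed values themselves; the latter keep the mode
    anchored to the bulk of the sample even when one extreme block
    total stretches the grid (every evaluation point scales linearly
    with the sample, so the mode location does too). Degenerate
    samples (fewer than two distinct values) return that value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot locate the density mode of an empty sample")
    if np.unique(values).size < 2:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.union1d(np.linspace(0.0, float(values.max()), grid_size), values)
    return float(grid[np.argmax(kde(grid))])


def normalize_control(
    target_totals: np.ndarray, control_totals: np.ndarray
) -> NormalizationResult:
    """Scaling factor aligning the control total-signal mode to the target's.

    The mode of each block-total density is located by KDE and the
    factor is ``target_mode / control_mode``; the caller multiplies all
    control totals by it before curve construction and overlap
    filtering. Because background blocks dominate both samples, the
    mode tracks sequencing-depth differences rather than enrichment.
    """
    target_totals = np.asarray(target_totals, dtype=float)
    control_totals = np.asarray(control_totals, dtype=float)
    if target_totals.size == 0 or control_totals.size == 0:
        raise ValueError("normalization requires both datasets")
    target_mode = _density_mode(target_totals)
    control_mode = _density_mode(control_totals)
    if target_mode <= 0 or control_mode <= 0:
        raise ValueError("density modes must be positive for scaling")
    return NormalizationResult(
        scaling_factor=target_mode / control_mode,
        target_mode=target_mode,
        control_mode=control_mode,
    )


def _count_above(sorted_values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Number of values strictly above each threshold (vectorized)."""
    return sorted_values.size - np.searchsorted(sorted_values, thresholds, side="right")


def compute_f_curve(
    target_totals: np.ndarray,
    control_totals: np.ndarray,
    variant: str = "remaining",
) -> ThresholdCurve:
    """Sweep F over all candidate thresholds and select the stringent one.

    Candidates are 0 plus every distinct observed total from either set
    (control totals must already be scaled in normalized mode).
    Candidates where F is undefined (no block remaining, or in the
    removed variant no block yet removed) are excluded. The stringent
    threshold is the smallest candidate attaining the maximum F.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    r = np.sort(np.asarray(target_totals, dtype=float))
    s = np.sort(np.asarray(control_totals, dtype=float))
    if r.size == 0:
        raise ValueError("target block set is empty")
    if s.size == 0:
        raise ValueError(
            "control block set is empty; use global-threshold mode instead"
        )
    m, n = r.size, s.size
    candidates = np.unique(np.concatenate(([0.0], r, s)))
    T = float(max(r[-1], s[-1]))

    above_r = _count_above(r, candidates)
    above_s = _count_above(s, candidates)
    p_t = above_r / m
    p_c = above_s / n

    if variant == "remaining":
        denom = p_t + p_c
        keep = denom > 0
        f = np.zeros_like(candidates)
        f[keep] = p_t[keep] / denom[keep]
    else:
        pooled = np.sort(np.concatenate((r, s)))
        removed_r = m - above_r
        removed_pool = pooled.size - _count_above(pooled, candidates)
        keep = removed_pool > 0
        f = np.zeros_like(candidates)
        f[keep] = removed_r[keep] / removed_pool[keep]

    candidates, f, p_t, p_c = candidates[keep], f[keep], p_t[keep], p_c[keep]
    if candidates.size == 0:
        raise ValueError("no candidate threshold with a defined F value")
    i_max = int(np.argmax(f))  # argmax returns the first (smallest t) maximizer
    return ThresholdCurve(
        candidates=candidates,
        f_values=f,
        frac_target_remaining=p_t,
        frac_control_remaining=p_c,
        f_max=float(f[i_max]),
        t_stringent=float(candidates[i_max]),
        T=T,
        variant=variant,
    )


def select_relaxed(curve: ThresholdCurve) -> ThresholdCurve:
    """Locate the curve's knee and derive the relaxed threshold.

    The knee is found on F versus candidate index via discrete second
    differences ``d2[i] = F[i+1] - 2 F[i] + F[i-1]``: among interior
    candidates with ``d2 < 0`` and ``F < f_max``, the one with the
    largest F (nearest below the maximum; rightmost on ties) is the
    knee value k. The relaxed operating point is
    ``F_relaxed = f_max - (f_max - k)/2`` and ``t_relaxed`` is where F
    first reaches it, by linear interpolation between the flanking
    candidates. With no qualifying knee (or fewer than three
    candidates) the relaxed threshold falls back to the stringent one.
    """
    f = curve.f_values
    t = curve.candidates
    if t.size < 3:
        logger.info("fewer than 3 candidate thresholds; relaxed falls back to stringent")
        return replace(curve, knee_f=None, t_relaxed=curve.t_stringent)
    d2 = f[2:] - 2.0 * f[1:-1] + f[:-2]
    interior = np.arange(1, t.size - 1)
    qualifying = interior[(d2 < 0) & (f[interior] < curve.f_max)]
    if qualifying.size == 0:
        return replace(curve, knee_f=None, t_relaxed=curve.t_stringent)
    best = np.max(f[qualifying])
    knee_idx = int(qualifying[f[qualifying] == best][-1])  # rightmost on ties
    k = float(f[knee_idx])
    f_relaxed = curve.f_max - (curve.f_max - k) / 2.0

    # first index where F reaches the relaxed operating point
    reach = np.flatnonzero(f >= f_relaxed - 1e-12)
    i = int(reach[0])
    if i == 0:
        t_relaxed = float(t[0])
    else:
        f0, f1 = f[i - 1], f[i]
        if f1 == f0:
            t_relaxed = float(t[i])
        else:
            frac = (f_relaxed - f0) / (f1 - f0)
            t_relaxed = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return replace(curve, knee_f=k, t_relaxed=t_relaxed)


def global_threshold(target_totals: np.ndarray, q: float) -> float:
    """Control-free threshold retaining roughly the top fraction q of blocks.

    Returns the empirical (1-q)-quantile of the target totals (lower
    interpolation), so blocks with total strictly above it — about the
    top q fraction — are retained. With all totals equal no block
    strictly exceeds the threshold and a warning is emitted.
    """
    target_totals = np.asarray(target_totals, dtype=float)
    if not 0.0 < q < 1.0:
        raise ValueError("global threshold fraction must lie in (0, 1)")
    if target_totals.size == 0:
        raise ValueError("target block set is empty")
    threshold = float(np.quantile(target_totals, 1.0 - q, method="lower"))
    if not np.any(target_totals > threshold):
        logger.warning(
            "no block total strictly exceeds the global threshold %g; "
            "the call will be empty",
            threshold,
        )
    return threshold


def empirical_fdr(
    target_totals: np.ndarray,
    scaled_control_totals: np.ndarray,
    t: float,
) -> EmpiricalFDR:
    """Fraction of above-threshold blocks coming from the control.

    ``value = n_control_above / (n_target_above + n_control_above)``,
    defined as 0 when no block at all exceeds t.
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    target_totals = np.asarray(target_totals, dtype=float)
    scaled_control_totals = np.asarray(scaled_control_totals, dtype=float)
    n_target = int(np.count_nonzero(target_totals > t))
    n_control = int(np.count_nonzero(scaled_control_totals > t))
    denom = n_target + n_control
    value = n_control / denom if denom else 0.0
    return EmpiricalFDR(value=value, n_target_above=n_target, n_control_above=n_control)
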