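"""Core marker-frequency computation: binning, normalization, loess.

The profile is the per-window log2 ratio of library-size-scaled sample
counts over a control track, smoothed by a circular locally weighted
polynomial regression (loess).  The loess is fit on the log2 ratios, on
the circular window grid, so there are no edge artifacts at coordinate 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeSpec, masked_window_mask, window_of
from .simulate import CoverageTrack

__all__ = [
    "NormalizedProfile",
    "LoessFit",
    "bin_reads",
    "normalize_to_control",
    "log2_profile",
    "loess_smooth",
]

log = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_CONTROL_FLOOR = 5.0


@dataclass
class NormalizedProfile:
    """Per-window log2(sample/control) after library-size scaling."""

    genome: GenomeSpec
    log2_ratio: np.ndarray  # NaN where excluded
    pseudocount: float
    excluded: np.ndarray  # bool: masked windows or control below floor
    label: str = ""

    @property
    def n_bins(self) -> int:
        return self.log2_ratio.size


@dataclass
class LoessFit:
    """A circular loess curve evaluated at every window."""

    fitted: np.ndarray
    span: float
    degree: int
    robust_iters: int
    genome: GenomeSpec | None = None


def bin_reads(
    read_positions,
    genome: GenomeSpec,
    n_bins: int = 10_000,
    scores=None,
    min_score: float | None = None,
    label: str = "",
) -> CoverageTrack:
    """Count read start positions into equal circular windows.

    Positions falling in masked intervals are dropped (those windows are
    NaN); out-of-range positions are skipped with a logged warning count.
    An optional per-read ``scores`` array supports MAPQ-style filtering
    via ``min_score``.
    """
    pos = np.asarray(read_positions, dtype=float)
    if scores is not None and min_score is not None:
        keep = np.asarray(scores, dtype=float) >= min_score
        n_low = int((~keep).sum())
        if n_low:
            log.warning("bin_reads: dropped %d reads below score %s", n_low, min_score)
        pos = pos[keep]
    valid = np.isfinite(pos) & (pos >= 0) & (pos < genome.length)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("bin_reads: skipped %d malformed/out-of-range positions", n_bad)
    pos = pos[valid]
    counts = np.zeros(n_bins)
    if pos.size:
        idx = window_of(pos.astype(np.int64), n_bins, genome.length)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
    mask = masked_window_mask(genome, n_bins)
    n_masked_reads = int(counts[mask].sum())
    if n_masked_reads:
        log.warning("bin_reads: %d reads fell in masked intervals and were dropped", n_masked_reads)
    counts[mask] = np.nan
    return CoverageTrack(genome=genome, counts=counts, label=label)


def _check_compatible(sample: CoverageTrack, control: CoverageTrack) -> None:
    if sample.n_bins != control.n_bins:
        raise ValueError("sample and control binning differ")
    if sample.genome.length != control.genome.length:
        raise ValueError("sample and control genomes differ")


def normalize_to_control(
    sample: CoverageTrack,
    control: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    control_floor: float = DEFAULT_CONTROL_FLOOR,
) -> NormalizedProfile:
    """log2 of the ratio of library-scaled sample over control counts.

    ``r_w = log2(((s_w + pc) / S) / ((c_w + pc) / C))`` with ``S``, ``C``
    the total present counts.  Windows missing in either track, or whose
    raw control count falls below ``control_floor``, are excluded (NaN).
    The pseudocount treatment is symmetric, so
    ``normalize(A, B) == -normalize(B, A)`` window-wise.
    """
    _check_compatible(sample, control)
    s, c = sample.counts, control.counts
    present = np.isfinite(s) & np.isfinite(c)
    S = np.nansum(s[present])
    C = np.nansum(c[present])
    if S <= 0 or C <= 0:
        raise ValueError("cannot normalize an empty track")
    excluded = ~present | (np.nan_to_num(c, nan=-1.0) < control_floor)
    r = np.full(s.shape, np.nan)
    ok = ~excluded
    r[ok] = np.log2(((s[ok] + pseudocount) / S) / ((c[ok] + pseudocount) / C))
    return NormalizedProfile(
        genome=sample.genome,
        log2_ratio=r,
        pseudocount=pseudocount,
        excluded=excluded,
        label=sample.label,
    )


def log2_profile(track: CoverageTrack, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> NormalizedProfile:
    """Control-free mode: log2 of library-scaled counts (flat track ~ 0)."""
    s = track.counts
    present = np.isfinite(s)
    S = np.nansum(s[present])
    if S <= 0:
        raise ValueError("cannot profile an empty track")
    n_present = int(present.sum())
    r = np.full(s.shape, np.nan)
    r[present] = np.log2((s[present] + pseudocount) / S * n_present)
    return NormalizedProfile(
        genome=track.genome,
        log2_ratio=r,
        pseudocount=pseudocount,
        excluded=~present,
        label=track.label,
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3


def loess_smooth(
    values,
    span: float = 0.1,
    degree: int = 1,
    robust_iters: int = 2,
    genome: GenomeSpec | None = None,
) -> LoessFit:
    """Circular loess over equispaced windows.

    For each window the ``span`` fraction of present windows nearest by
    circular window distance is fit with a tricube-weighted polynomial of
    ``degree`` (0 or 1) and evaluated at the window center.  Missing
    (NaN) windows get zero weight as predictors but still receive a
    fitted (interpolated) value.  Optional robustness iterations
    reweight by the bisquare of scaled residuals.

    The tricube distance is normalized by ``half + 1`` (one window beyond
    the farthest neighbor) so every neighbor keeps positive weight.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    present = np.isfinite(y)
    n_present = int(present.sum())
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if n_present < degree + 2:
        raise ValueError("need at least degree + 2 present windows")
    half = int(round(span * n_present / 2.0))
    half = max(half, degree + 1)
    if 2 * half + 1 > n:
        half = (n - 1) // 2
    offsets = np.arange(-half, half + 1)
    kernel = _tricube(offsets / (half + 1.0))

    idx = (np.arange(n)[:, None] + offsets[None, :]) % n
    Y = y[idx]
    finite_nb = np.isfinite(Y)
    Y0 = np.where(finite_nb, Y, 0.0)
    base_w = kernel[None, :] * finite_nb

    x = offsets.astype(float)[None, :]
    robust = np.ones(n)

    fitted = np.full(n, np.nan)
    for iteration in range(robust_iters + 1):
        W = base_w * robust[idx]
        if degree == 0:
            s0 = W.sum(axis=1)
            with np.errstate(invalid="ignore"):
                fitted = (W * Y0).sum(axis=1) / s0
        elif degree == 1:
            s0 = W.sum(axis=1)
            s1 = (W * x).sum(axis=1)
            s2 = (W * x * x).sum(axis=1)
            t0 = (W * Y0).sum(axis=1)
            t1 = (W * x * Y0).sum(axis=1)
            det = s0 * s2 - s1 * s1
            with np.errstate(divide="ignore", invalid="ignore"):
                beta0 = (s2 * t0 - s1 * t1) / det
                fallback = t0 / s0
            degenerate = ~np.isfinite(beta0) | (np.abs(det) <= 1e-12 * np.maximum(s0 * s2, 1e-300))
            fitted = np.where(degenerate, fallback, beta0)
        else:  # local quadratic: solve the 3x3 normal equations per window
            xs = x / half  # scale offsets to [-1, 1] for conditioning
            s0 = W.sum(axis=1)
            s1 = (W * xs).sum(axis=1)
            s2 = (W * xs**2).sum(axis=1)
            s3 = (W * xs**3).sum(axis=1)
            s4 = (W * xs**4).sum(axis=1)
            t0 = (W * Y0).sum(axis=1)
            t1 = (W * xs * Y0).sum(axis=1)
            t2 = (W * xs**2 * Y0).sum(axis=1)
            A = np.stack(
                [
                    np.stack([s0, s1, s2], axis=-1),
                    np.stack([s1, s2, s3], axis=-1),
                    np.stack([s2, s3, s4], axis=-1),
                ],
                axis=-2,
            )
            b = np.stack([t0, t1, t2], axis=-1)
            det = np.linalg.det(A)
            with np.errstate(divide="ignore", invalid="ignore"):
                sol = np.linalg.solve(
                    np.where(np.abs(det)[:, None, None] > 1e-10, A, np.eye(3)), b[..., None]
                )
                beta0 = sol[..., 0, 0]
                fallback = t0 / s0
            degenerate = (np.abs(det) <= 1e-10) | ~np.isfinite(beta0)
            fitted = np.where(degenerate, fallback, beta0)
        if iteration == robust_iters:
            break
        resid = np.where(present, y - fitted, 0.0)
        s = np.median(np.abs(resid[present]))
        if s <= 0:
            break
        robust = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
        robust[~present] = 0.0
    return LoessFit(fitted=fitted, span=span, degree=degree, robust_iters=robust_iters, genome=genome)
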