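"""Interpretive feature extraction from smoothed replication profiles.

Four feature families: cSDR-origin peaks (circular local maxima of the
loess curve), amplified segments (thresholded runs with changepoint edge
refinement), polar-trap asymmetry around Ter sites, and head-on
transcription "steps" across annotated operons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .genome import (
    CLOCKWISE,
    COUNTERCLOCKWISE,
    GenomeSpec,
    TerSite,
    window_midpoints,
    window_starts,
)
from .mfa import LoessFit

__all__ = [
    "PeakCall",
    "AmpCall",
    "TerAsymmetry",
    "call_peaks",
    "segment_amplification",
    "ter_asymmetry",
    "step_score",
]

DEFAULT_MIN_PROMINENCE = 0.15
PEAK_BUMP_FACTOR = 2.0
DEFAULT_AMP_THRESHOLD = 0.5
DEFAULT_AMP_MIN_LENGTH = 50_000


@dataclass
class PeakCall:
    """A circular local maximum of the smoothed profile."""

    position: float  # bp, window midpoint
    window: int
    height: float  # log2 units above the profile median
    prominence: float
    classification: str  # "peak" | "bump"


@dataclass
class AmpCall:
    """A contiguous amplified segment."""

    start: int  # bp
    end: int  # bp
    mean_log2: float  # mean profile level inside, relative to flanks
    copy_factor: float  # 2 ** mean_log2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TerAsymmetry:
    """Signed copy-number drop across a polar Ter site.

    Positive drop means higher fitted values on the side the site blocks
    forks arriving from (the pile-up side).
    """

    site: str
    drop: float
    flank_bp: int


def _fit_values(fit) -> np.ndarray:
    if isinstance(fit, LoessFit):
        return np.asarray(fit.fitted, dtype=float)
    return np.asarray(fit, dtype=float)


def _interpolate_gaps(y: np.ndarray) -> np.ndarray:
    """Circular linear interpolation over NaN runs (peak finding needs
    finite input)."""
    out = y.copy()
    bad = ~np.isfinite(out)
    if not bad.any():
        return out
    if bad.all():
        return out
    n = y.size
    x = np.arange(n)
    good = ~bad
    # wrap by tiling one period on each side
    xg = np.concatenate([x[good] - n, x[good], x[good] + n])
    yg = np.tile(out[good], 3)
    out[bad] = np.interp(x[bad], xg, yg)
    return out


def call_peaks(
    fit,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    genome: GenomeSpec | None = None,
    masked: np.ndarray | None = None,
    refine_profile=None,
    refine_span_windows: int = 60,
    refine_halfwin: int = 150,
) -> list[PeakCall]:
    """Circular local maxima with prominence >= ``min_prominence``.

    Calls are sorted by prominence (descending), ties broken by leftmost
    coordinate; classification is "peak" when prominence reaches twice
    the threshold, else "bump".  Calls in masked windows are dropped.

    The wide smoothing span used for detection biases the argmax of
    sharp peaks (neighboring-feature tails tilt the local fit), so when
    ``refine_profile`` (raw per-window log2 values) is given, each
    call's position is re-estimated as the argmax of a narrow local
    loess (half-width ``refine_span_windows``) of the raw profile within
    ``refine_halfwin`` windows of the detected maximum.
    """
    from .mfa import loess_smooth  # local import: mfa does not depend on features

    y = _fit_values(fit)
    n = y.size
    if not np.isfinite(y).any():
        return []
    yi = _interpolate_gaps(y)
    tiled = np.tile(yi, 3)
    peaks, props = signal.find_peaks(tiled, prominence=min_prominence)
    sel = (peaks >= n) & (peaks < 2 * n)
    windows = peaks[sel] - n
    proms = props["prominences"][sel]
    if masked is not None and windows.size:
        keep = ~np.asarray(masked)[windows]
        windows, proms = windows[keep], proms[keep]

    refined_fit = None
    if refine_profile is not None and windows.size:
        rp = np.asarray(refine_profile, dtype=float)
        n_present = max(int(np.isfinite(rp).sum()), 1)
        span = min(1.0, 2.0 * refine_span_windows / n_present)
        refined_fit = loess_smooth(rp, span=span, degree=2, robust_iters=0).fitted

    length = genome.length if genome is not None else n
    mids = window_midpoints(n, length)
    baseline = float(np.nanmedian(y))
    calls = []
    for w, p in zip(windows, proms):
        w = int(w)
        if refined_fit is not None:
            idx = np.arange(w - refine_halfwin, w + refine_halfwin + 1) % n
            seg = refined_fit[idx]
            if np.isfinite(seg).any():
                w = int(idx[np.nanargmax(seg)])
                if masked is not None and np.asarray(masked)[w]:
                    continue
        calls.append(
            PeakCall(
                position=float(mids[w]),
                window=w,
                height=float(yi[w] - baseline),
                prominence=float(p),
                classification="peak" if p >= PEAK_BUMP_FACTOR * min_prominence else "bump",
            )
        )
    calls.sort(key=lambda c: (-c.prominence, c.position))
    return calls


def _circular_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array, as inclusive
    [i0, i1] window ranges.  Runs wrapping through 0 are split at 0 so
    every returned range satisfies i0 <= i1."""
    n = above.size
    if above.all():
        return [(0, n - 1)]
    if not above.any():
        return []
    # rotate so position 0 is False, then find plain runs
    first_false = int(np.argmax(~above))
    rot = np.roll(above, -first_false)
    d = np.diff(rot.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if rot[-1]:
        ends.append(rot.size - 1)
    runs: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        i0, i1 = (s + first_false) % n, (e + first_false) % n
        if i0 <= i1:
            runs.append((i0, i1))
        else:  # wrapped through 0
            runs.append((i0, n - 1))
            runs.append((0, i1))
    return runs


def _two_segment_changepoint(values: np.ndarray, lo: int, hi: int) -> int:
    """Best split j in (lo, hi]: minimizes SSE of two constant segments
    over values[lo:hi]; returns the first index of the right segment."""
    seg = values[lo:hi]
    finite = np.isfinite(seg)
    x = np.where(finite, seg, 0.0)
    cnt = finite.astype(float)
    cs, cn = np.cumsum(x), np.cumsum(cnt)
    cs2 = np.cumsum(x * x)
    total_s, total_n, total_s2 = cs[-1], cn[-1], cs2[-1]
    best_j, best_sse = lo + 1, np.inf
    for j in range(1, seg.size):
        nl, nr = cn[j - 1], total_n - cn[j - 1]
        if nl < 1 or nr < 1:
            continue
        sl, sr = cs[j - 1], total_s - cs[j - 1]
        s2l, s2r = cs2[j - 1], total_s2 - cs2[j - 1]
        sse = (s2l - sl * sl / nl) + (s2r - sr * sr / nr)
        if sse < best_sse:
            best_sse, best_j = sse, lo + j
    return best_j


def segment_amplification(
    profile,
    fit=None,
    threshold_log2: float = DEFAULT_AMP_THRESHOLD,
    min_length_bp: int = DEFAULT_AMP_MIN_LENGTH,
    genome: GenomeSpec | None = None,
    masked: np.ndarray | None = None,
    refine_windows: int = 500,
    flank_windows: int = 100,
) -> list[AmpCall]:
    """Detect amplified segments and refine their boundaries.

    Candidate segments are maximal runs of windows whose smoothed level
    is at least ``threshold_log2`` above the genome median and at least
    ``min_length_bp`` long.  Each edge is then refined by a two-segment
    changepoint fit on the raw profile values within ``refine_windows``
    of the initial edge (the loess smear makes threshold crossings
    biased; the changepoint on raw values is not).  Masked windows never
    enter a call.
    """
    raw = _fit_values(profile)
    smooth = _fit_values(fit) if fit is not None else raw
    n = raw.size
    length = genome.length if genome is not None else n
    bin_bp = length / n
    med = np.nanmedian(smooth)
    above = np.nan_to_num(smooth - med, nan=-np.inf) >= threshold_log2
    if masked is not None:
        above &= ~np.asarray(masked)
    min_windows = max(1, int(round(min_length_bp / bin_bp)))
    calls: list[AmpCall] = []
    starts_bp = window_starts(n, length)
    for i0, i1 in _circular_runs(above):
        run_len = (i1 - i0) % n + 1
        if run_len < min_windows:
            continue
        # refine each edge on the raw profile (linear, non-wrapped search);
        # the search never crosses a masked window, so a refined edge
        # cannot jump over a masked gap
        lo = max(0, i0 - refine_windows)
        hi = min(n, i0 + min(refine_windows, run_len // 2) + 1)
        lo2 = max(0, i1 - min(refine_windows, run_len // 2))
        hi2 = min(n, i1 + refine_windows + 1)
        if masked is not None:
            m = np.asarray(masked)
            blocked = np.where(m[lo:i0])[0]
            if blocked.size:
                lo = lo + int(blocked[-1]) + 1
            blocked = np.where(m[i1 + 1 : hi2])[0]
            if blocked.size:
                hi2 = i1 + 1 + int(blocked[0])
        left = _two_segment_changepoint(raw, lo, hi) if hi - lo > 2 else i0
        right = _two_segment_changepoint(raw, lo2, hi2) if hi2 - lo2 > 2 else i1 + 1
        if right <= left:
            left, right = i0, i1 + 1
        if masked is not None:
            # shrink to avoid masked windows at the edges
            m = np.asarray(masked)
            while left < right and m[left]:
                left += 1
            while right > left and m[right - 1]:
                right -= 1
            if right <= left:
                continue
        inside = raw[left:right]
        fl = np.concatenate(
            [raw[max(0, left - flank_windows) : left], raw[right : min(n, right + flank_windows)]]
        )
        mean_inside = float(np.nanmean(inside))
        mean_flank = float(np.nanmean(fl)) if np.isfinite(fl).any() else float(np.nanmedian(raw))
        mean_log2 = mean_inside - mean_flank
        if mean_log2 < threshold_log2:
            continue
        calls.append(
            AmpCall(
                start=int(starts_bp[left]),
                end=int(starts_bp[right]),
                mean_log2=mean_log2,
                copy_factor=float(2.0**mean_log2),
            )
        )
    calls.sort(key=lambda c: c.start)
    return calls


def _window_range_mean(y: np.ndarray, lo_bp: float, hi_bp: float, n: int, length: float) -> float:
    mids = window_midpoints(n, length)
    lo_bp %= length
    hi_bp %= length
    if lo_bp <= hi_bp:
        sel = (mids >= lo_bp) & (mids < hi_bp)
    else:  # wrapped range
        sel = (mids >= lo_bp) | (mids < hi_bp)
    vals = y[sel]
    return float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan


def ter_asymmetry(
    fit,
    ter_sites,
    flank_bp: int = 100_000,
    genome: GenomeSpec | None = None,
) -> list[TerAsymmetry]:
    """Mean-fit difference across each Ter site, oriented by polarity.

    For a site blocking counterclockwise forks the pile-up side is the
    clockwise (higher-coordinate) flank, so
    ``drop = mean(fit[pos, pos+flank)) - mean(fit[pos-flank, pos))``;
    the sign convention is mirrored for clockwise-blocking sites, so a
    pile-up always yields a positive drop.
    """
    y = _fit_values(fit)
    n = y.size
    length = genome.length if genome is not None else n
    out = []
    for site in ter_sites:
        upper = _window_range_mean(y, site.position, site.position + flank_bp, n, length)
        lower = _window_range_mean(y, site.position - flank_bp, site.position, n, length)
        drop = (upper - lower) if site.blocks == COUNTERCLOCKWISE else (lower - upper)
        out.append(TerAsymmetry(site=site.name, drop=float(drop), flank_bp=flank_bp))
    return out


def step_score(
    fit,
    intervals,
    flank_bp: int = 50_000,
    genome: GenomeSpec | None = None,
) -> dict[str, float]:
    """Signed profile difference across candidate head-on-collision intervals.

    ``intervals`` is an iterable of ``(name, start, end, strand)`` with
    strand "+" (transcription clockwise) or "-".  The score is the mean
    fit beyond the interval in the head-on fork's direction of travel
    (opposite the strand) minus the mean before it; a negative score
    indicates a replication step across the interval.
    """
    y = _fit_values(fit)
    n = y.size
    length = genome.length if genome is not None else n
    scores: dict[str, float] = {}
    for name, start, end, strand in intervals:
        if strand not in ("+", "-"):
            raise ValueError(f"bad strand {strand!r} for interval {name!r}")
        fork_dir = COUNTERCLOCKWISE if strand == "+" else CLOCKWISE
        if fork_dir == CLOCKWISE:
            beyond = _window_range_mean(y, end, end + flank_bp, n, length)
            before = _window_range_mean(y, start - flank_bp, start, n, length)
        else:
            beyond = _window_range_mean(y, start - flank_bp, start, n, length)
            before = _window_range_mean(y, end, end + flank_bp, n, length)
        scores[name] = float(beyond - before)
    return scores
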