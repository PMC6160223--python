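"""Independent test oracles.

These deliberately re-derive quantities by routes that do not share code
with the package: a Monte-Carlo chromosome-population sampler for
expected copy numbers, and a brute-force weighted-least-squares solve
for single-window loess values.
"""

from __future__ import annotations

import numpy as np

from mfakit.genome import CLOCKWISE, COUNTERCLOCKWISE, window_midpoints


def _distance_along(origin: int, mids: np.ndarray, direction: str, length: int) -> np.ndarray:
    if direction == CLOCKWISE:
        return (mids - origin) % length
    return (origin - mids) % length


def _trap_distance(origin: int, direction: str, ter_sites, length: int) -> float:
    best = np.inf
    for t in ter_sites:
        if t.blocks != direction:
            continue
        d = (t.position - origin) % length if direction == CLOCKWISE else (origin - t.position) % length
        best = min(best, d)
    return best


def mc_expected_copies(scenario, n_chrom: int = 100_000, seed: int = 0, chunk: int = 20_000) -> np.ndarray:
    """Monte-Carlo population oracle for runout-mode scenarios.

    Samples explicit chromosomes: each oriK fires per chromosome with its
    firing fraction; each fork draws an exponential extent, can stall at
    each head-on barrier entry edge with probability 1 - transmission,
    and is truncated at the first blocking Ter site.  A window gains a
    copy when either fork of a firing covers it.  Amplifications scale
    the one pre-existing template copy.
    """
    assert scenario.mode in ("runout", "stationary")
    g = scenario.genome
    L, n = g.length, scenario.n_bins
    mids = window_midpoints(n, L)
    amp = np.ones(n)
    for a in scenario.amplifications:
        inside = (mids >= a.start) & (mids < a.end)
        amp[inside] *= a.copy_factor
    total = amp.copy()
    rng = np.random.default_rng(seed)
    for o in scenario.origins:
        if o.kind != "oriK":
            continue
        fire = rng.random(n_chrom) < o.firing_fraction
        stops = {}
        for direction in (CLOCKWISE, COUNTERCLOCKWISE):
            extents = rng.exponential(o.extent_scale, n_chrom)
            tdist = _trap_distance(o.position, direction, scenario.ter_sites, L)
            stop = np.minimum(extents, tdist)
            edges = []
            for b in scenario.barriers:
                if b.blocks != direction:
                    continue
                edge = b.start if direction == CLOCKWISE else b.end
                e = (edge - o.position) % L if direction == CLOCKWISE else (o.position - edge) % L
                edges.append((e, b.transmission))
            for e, trans in sorted(edges):
                blocked = (stop > e) & (rng.random(n_chrom) >= trans)
                stop[blocked] = e
            stops[direction] = stop
        d_cw = _distance_along(o.position, mids, CLOCKWISE, L)
        d_ccw = _distance_along(o.position, mids, COUNTERCLOCKWISE, L)
        count = np.zeros(n)
        for lo in range(0, n_chrom, chunk):
            hi = min(lo + chunk, n_chrom)
            f = fire[lo:hi]
            cov = (d_cw[None, :] <= stops[CLOCKWISE][lo:hi, None]) | (
                d_ccw[None, :] <= stops[COUNTERCLOCKWISE][lo:hi, None]
            )
            count += cov[f].sum(axis=0)
        total = total + count / n_chrom
    return total


def brute_loess_at(y: np.ndarray, i: int, span: float, degree: int) -> float:
    """Single-window loess value by explicit weighted least squares.

    Mirrors the documented contract (tricube over circular window
    offsets, distance normalized by half + 1) but solves the regression
    with ``numpy.linalg.lstsq`` on the weighted design matrix instead of
    closed-form normal equations.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    n_present = int(np.isfinite(y).sum())
    half = max(int(round(span * n_present / 2.0)), degree + 1)
    if 2 * half + 1 > n:
        half = (n - 1) // 2
    offs = np.arange(-half, half + 1)
    idx = (i + offs) % n
    w = (1.0 - (np.abs(offs) / (half + 1.0)) ** 3) ** 3
    yy = y[idx]
    ok = np.isfinite(yy)
    X = np.vander(offs[ok].astype(float), degree + 1, increasing=True)
    sw = np.sqrt(w[ok])
    beta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * yy[ok], rcond=None)
    return float(beta[0])
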