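"""Synthetic replication-dynamics generator for circular chromosomes.

The population model is a firing-fraction / fork-extent mixture: at
sampling time a fraction of chromosomes carries one active bidirectional
replication event per origin, and each fork of that event has progressed a
random (exponential by default) distance, truncated at the first polar Ter
site that arrests its direction of travel.  Expected per-window copy
number is computed in closed form; an explicit Monte-Carlo chromosome
sampler lives in the test suite as an independent oracle.

Modes:

* ``log_phase`` — a baseline exponential-culture gradient
  ``2^(k_ct * (1 - u(x)))`` from the oriC-type origin (``u`` is the
  normalized fork-arrival time with Ter trapping), plus additive oriK
  contributions.
* ``runout`` / ``stationary`` — baseline 1 (initiation from the main
  origin has stopped and ongoing rounds have completed); only oriK-type
  origins contribute structure.

Barrier intervals emulate head-on collisions with heavily transcribed
operons: a fork that reaches a barrier stalling its direction passes with
probability ``transmission``, otherwise it stops at the barrier's entry
edge, producing step-like drops beyond the barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import (
    CLOCKWISE,
    COUNTERCLOCKWISE,
    Amplification,
    GenomeSpec,
    Inversion,
    TerSite,
    map_through_inversion,
    masked_window_mask,
    window_midpoints,
    window_of,
)

__all__ = [
    "OriginSpec",
    "Barrier",
    "ScenarioConfig",
    "TruthRecord",
    "CoverageTrack",
    "fork_stop",
    "trap_distance",
    "expected_copy_number",
    "simulate_with_inversion",
    "simulate_truth",
    "sample_coverage",
    "simulate_ct",
]

MODES = ("log_phase", "runout", "stationary")


@dataclass(frozen=True)
class OriginSpec:
    """A replication origin in the population mixture.

    ``firing_fraction`` is the probability that a chromosome carries one
    active bidirectional replication event from this origin at sampling
    time; ``extent_scale`` is the mean of the per-fork progress
    distribution (bp).
    """

    name: str
    position: int
    kind: str = "oriK"  # "oriC" | "oriK"
    firing_fraction: float = 0.5
    extent_scale: float = 150_000.0
    extent_dist: str = "exponential"  # "exponential" | "uniform"

    def __post_init__(self) -> None:
        if self.kind not in ("oriC", "oriK"):
            raise ValueError("origin kind must be 'oriC' or 'oriK'")
        if not (0.0 <= self.firing_fraction <= 1.0):
            raise ValueError("firing_fraction must be in [0, 1]")
        if self.extent_scale <= 0:
            raise ValueError("extent_scale must be positive")
        if self.extent_dist not in ("exponential", "uniform"):
            raise ValueError("extent_dist must be 'exponential' or 'uniform'")


@dataclass(frozen=True)
class Barrier:
    """An interval where forks moving in the ``blocks`` direction stall.

    A stalling fork stops at the barrier's entry edge with probability
    ``1 - transmission``.  Forks moving in the opposite (co-directional)
    direction are unaffected.
    """

    start: int
    end: int
    blocks: str = CLOCKWISE
    transmission: float = 0.6
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("barrier requires 0 <= start < end")
        if not (0.0 < self.transmission <= 1.0):
            raise ValueError("transmission must be in (0, 1]")

    def entry_edge(self, direction: str) -> int:
        """Coordinate first encountered by a fork travelling ``direction``."""
        return self.start if direction == CLOCKWISE else self.end


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generative description of one simulated sample."""

    genome: GenomeSpec
    origins: tuple[OriginSpec, ...] = ()
    ter_sites: tuple[TerSite, ...] = ()
    amplifications: tuple[Amplification, ...] = ()
    inversions: tuple[Inversion, ...] = ()
    barriers: tuple[Barrier, ...] = ()
    mode: str = "runout"
    k_ct: float = 0.8
    n_bins: int = 10_000
    depth: float = 100.0
    bias_sd: float = 0.05
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.k_ct < 0:
            raise ValueError("k_ct must be >= 0")
        L = self.genome.length
        for o in self.origins:
            if not (0 <= o.position < L):
                raise ValueError(f"origin {o.name} out of range")
            if self.genome.is_masked(o.position):
                warnings.warn(f"origin {o.name} lies inside a masked interval")
        for t in self.ter_sites:
            if not (0 <= t.position < L):
                raise ValueError(f"Ter site {t.name} out of range")

    def replaced(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass
class TruthRecord:
    """Ground truth for one scenario: expected relative copies per window."""

    copies: np.ndarray  # expected relative copy number, NaN in masked windows
    scenario: ScenarioConfig
    origin_positions: dict[str, int] = field(default_factory=dict)
    coordinate_frame: str = "reference"

    @property
    def n_bins(self) -> int:
        return self.copies.size

    @property
    def midpoints(self) -> np.ndarray:
        return window_midpoints(self.n_bins, self.scenario.genome.length)


@dataclass
class CoverageTrack:
    """Per-window read counts over the circular genome (NaN = masked)."""

    genome: GenomeSpec
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        present = self.counts[np.isfinite(self.counts)]
        if np.any(present < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total_reads(self) -> float:
        return float(np.nansum(self.counts))


# ---------------------------------------------------------------------------
# fork geometry


def trap_distance(origin: int, direction: str, ter_sites, length: int) -> float:
    """Distance from ``origin`` to the first Ter site arresting ``direction``.

    Ter sites of the opposite polarity are passed through.  Returns +inf
    when no site of matching polarity exists.
    """
    best = np.inf
    for t in ter_sites:
        if t.blocks != direction:
            continue
        if direction == CLOCKWISE:
            d = (t.position - origin) % length
        else:
            d = (origin - t.position) % length
        best = min(best, d)
    return best


def fork_stop(origin: int, direction: str, extent: float, ter_sites, length: int) -> int:
    """Endpoint reached by a fork of given ``extent``, truncated at Ter."""
    if extent < 0:
        raise ValueError("extent must be >= 0")
    travelled = min(float(extent), trap_distance(origin, direction, ter_sites, length))
    if direction == CLOCKWISE:
        return int((origin + travelled) % length)
    return int((origin - travelled) % length)


def _survival(d: np.ndarray, origin: OriginSpec) -> np.ndarray:
    """P(fork extent >= d)."""
    if origin.extent_dist == "exponential":
        return np.exp(-d / origin.extent_scale)
    # uniform on [0, 2 * scale]
    return np.clip(1.0 - d / (2.0 * origin.extent_scale), 0.0, 1.0)


def _arm_cover_probability(
    mids: np.ndarray,
    origin: OriginSpec,
    direction: str,
    ter_sites,
    barriers,
    length: int,
) -> np.ndarray:
    """P(the ``direction`` fork of one firing replicates each window midpoint)."""
    if direction == CLOCKWISE:
        d = (mids - origin.position) % length
    else:
        d = (origin.position - mids) % length
    p = _survival(d, origin)
    tdist = trap_distance(origin.position, direction, ter_sites, length)
    p[d > tdist] = 0.0
    for b in barriers:
        if b.blocks != direction:
            continue
        edge = b.entry_edge(direction)
        if direction == CLOCKWISE:
            e = (edge - origin.position) % length
        else:
            e = (origin.position - edge) % length
        p[d > e] *= b.transmission
    return p


def _origin_cover_probability(mids, origin, ter_sites, barriers, length) -> np.ndarray:
    """P(window replicated by either fork of one firing) — arms independent."""
    p_cw = _arm_cover_probability(mids, origin, CLOCKWISE, ter_sites, barriers, length)
    p_ccw = _arm_cover_probability(mids, origin, COUNTERCLOCKWISE, ter_sites, barriers, length)
    return p_cw + p_ccw - p_cw * p_ccw


def _oric_base(mids: np.ndarray, scenario: ScenarioConfig) -> np.ndarray:
    """Log-phase baseline 2^(k_ct * (1 - u)) with Ter-trapped arrival times."""
    oric = [o for o in scenario.origins if o.kind == "oriC"]
    if not oric:
        return np.ones_like(mids)
    L = scenario.genome.length
    arrival = np.full_like(mids, np.inf)
    for o in oric:
        for direction in (CLOCKWISE, COUNTERCLOCKWISE):
            if direction == CLOCKWISE:
                d = (mids - o.position) % L
            else:
                d = (o.position - mids) % L
            t = trap_distance(o.position, direction, scenario.ter_sites, L)
            reach = np.where(d <= t, d, np.inf)
            arrival = np.minimum(arrival, reach)
    finite = np.isfinite(arrival)
    amax = arrival[finite].max() if finite.any() else 1.0
    u = np.where(finite, arrival / amax, 1.0)
    return 2.0 ** (scenario.k_ct * (1.0 - u))


def _amp_factor(mids: np.ndarray, amplifications) -> np.ndarray:
    amp = np.ones_like(mids)
    for a in amplifications:
        inside = (mids >= a.start) & (mids < a.end)
        amp[inside] *= a.copy_factor
    return amp


def expected_copy_number(scenario: ScenarioConfig) -> TruthRecord:
    """Closed-form expected relative copy number per window.

    ``copies(x) = base(x) * amp(x) + sum_i ff_i * P[x covered by origin i]``
    where the sum runs over oriK-type origins.  Masked windows are NaN.
    Inversions are ignored here; use :func:`simulate_truth` to dispatch.
    """
    g = scenario.genome
    mids = window_midpoints(scenario.n_bins, g.length)
    base = _oric_base(mids, scenario) if scenario.mode == "log_phase" else np.ones_like(mids)
    copies = base * _amp_factor(mids, scenario.amplifications)
    for o in scenario.origins:
        if o.kind != "oriK":
            continue
        copies = copies + o.firing_fraction * _origin_cover_probability(
            mids, o, scenario.ter_sites, scenario.barriers, g.length
        )
    copies[masked_window_mask(g, scenario.n_bins)] = np.nan
    return TruthRecord(
        copies=copies,
        scenario=scenario,
        origin_positions={o.name: o.position for o in scenario.origins},
    )


def _map_interval(start: int, end: int, inv: Inversion):
    """Image of the half-open interval [start, end) through an inversion.

    Intervals must lie fully inside or fully outside the inverted segment.
    """
    inside_s, inside_e = inv.contains(start), inv.contains(end - 1)
    if inside_s != inside_e:
        raise ValueError("interval straddles an inversion boundary (unsupported)")
    if not inside_s:
        return start, end
    a = map_through_inversion(end - 1, inv)
    b = map_through_inversion(start, inv)
    return a, b + 1


def physical_scenario(scenario: ScenarioConfig) -> ScenarioConfig:
    """Rewrite annotations onto the physical (inverted) chromosome.

    Elements inside the inverted segment move to their image coordinate;
    polar elements (Ter sites, barriers) flip polarity.  The inversion
    list is cleared: the result describes the physical genome directly.
    """
    if len(scenario.inversions) != 1:
        raise ValueError("physical_scenario requires exactly one inversion")
    inv = scenario.inversions[0]
    origins = tuple(
        replace(o, position=map_through_inversion(o.position, inv)) for o in scenario.origins
    )
    ters = tuple(
        t.flipped(map_through_inversion(t.position, inv)) if inv.contains(t.position) else t
        for t in scenario.ter_sites
    )
    barriers = []
    for b in scenario.barriers:
        if inv.contains(b.start) and inv.contains(b.end - 1):
            s, e = _map_interval(b.start, b.end, inv)
            flipped = COUNTERCLOCKWISE if b.blocks == CLOCKWISE else CLOCKWISE
            barriers.append(replace(b, start=s, end=e, blocks=flipped))
        else:
            barriers.append(b)
    amps = tuple(
        replace(a, start=_map_interval(a.start, a.end, inv)[0], end=_map_interval(a.start, a.end, inv)[1])
        for a in scenario.amplifications
    )
    return scenario.replaced(
        origins=origins,
        ter_sites=ters,
        barriers=tuple(barriers),
        amplifications=amps,
        inversions=(),
    )


def inversion_window_permutation(inv: Inversion, n_bins: int, length: int) -> np.ndarray:
    """Window-index permutation realizing the inversion: a block reversal.

    Windows ``window_of(start) .. window_of(end)`` are reversed in place;
    all other windows map to themselves.  Applied to a physical-genome
    track it yields the reference-coordinate report (and vice versa —
    the permutation is an involution).
    """
    ws = window_of(inv.start, n_bins, length)
    we = window_of(inv.end, n_bins, length)
    perm = np.arange(n_bins, dtype=np.int64)
    perm[ws : we + 1] = perm[ws : we + 1][::-1]
    return perm


def simulate_with_inversion(scenario: ScenarioConfig) -> TruthRecord:
    """Expected copies for a scenario carrying one inversion.

    Replication dynamics are computed on the physical (inverted) genome
    with every in-segment element relocated and polarity-flipped; the
    per-window expectation is then reported back in reference coordinates
    by reversing the inverted block of windows.
    """
    if len(scenario.inversions) == 0:
        return expected_copy_number(scenario)
    if len(scenario.inversions) > 1:
        raise ValueError("nested/overlapping or multiple inversions are unsupported")
    inv = scenario.inversions[0]
    for other in scenario.inversions[1:]:
        if not (other.end < inv.start or other.start > inv.end):
            raise ValueError("overlapping inversions are unsupported")
    phys = physical_scenario(scenario)
    phys_truth = expected_copy_number(phys)
    perm = inversion_window_permutation(inv, scenario.n_bins, scenario.genome.length)
    ref_copies = phys_truth.copies[perm]
    # masking is defined in reference coordinates
    ref_copies_mask = masked_window_mask(scenario.genome, scenario.n_bins)
    ref_copies = ref_copies.copy()
    ref_copies[ref_copies_mask] = np.nan
    return TruthRecord(
        copies=ref_copies,
        scenario=scenario,
        origin_positions={o.name: o.position for o in scenario.origins},
        coordinate_frame="reference",
    )


def simulate_truth(scenario: ScenarioConfig) -> TruthRecord:
    """Dispatch to the plain or inversion-aware expectation."""
    if scenario.inversions:
        return simulate_with_inversion(scenario)
    return expected_copy_number(scenario)


def sample_coverage(
    truth: TruthRecord,
    depth: float | None = None,
    bias_sd: float | None = None,
    seed: int | None = None,
    label: str | None = None,
) -> CoverageTrack:
    """Sample a Poisson coverage track from expected copies.

    ``count_w ~ Poisson(depth * copies_w * bias_w / mean(copies))`` with a
    lognormal(0, bias_sd) per-window bias.  Masked windows are NaN.
    Identical seeds give identical tracks.
    """
    sc = truth.scenario
    depth = sc.depth if depth is None else depth
    bias_sd = sc.bias_sd if bias_sd is None else bias_sd
    seed = sc.seed if seed is None else seed
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    copies = truth.copies
    present = np.isfinite(copies)
    lam = np.zeros_like(copies)
    mean_copies = np.nanmean(copies)
    bias = rng.lognormal(mean=0.0, sigma=bias_sd, size=copies.size) if bias_sd > 0 else 1.0
    lam[present] = depth * (copies[present] / mean_copies)
    if bias_sd > 0:
        lam[present] *= np.asarray(bias)[present]
    counts = np.full(copies.shape, np.nan)
    counts[present] = rng.poisson(lam[present]).astype(float)
    return CoverageTrack(genome=sc.genome, counts=counts, label=label or sc.name)


def simulate_ct(
    copies_a: float,
    copies_b: float,
    ct_noise_sd: float = 0.0,
    replicates: int = 2,
    seed: int = 0,
    c0: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate paired qPCR Ct replicates for two loci.

    ``Ct = c0 - log2(copies) + Normal(0, ct_noise_sd)``; the shared
    threshold constant ``c0`` cancels in downstream 2^-dCt ratios.
    """
    if copies_a <= 0 or copies_b <= 0:
        raise ValueError("copies must be positive")
    rng = np.random.default_rng(seed)
    ct_a = c0 - np.log2(copies_a) + rng.normal(0.0, ct_noise_sd, size=replicates)
    ct_b = c0 - np.log2(copies_b) + rng.normal(0.0, ct_noise_sd, size=replicates)
    return ct_a, ct_b
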