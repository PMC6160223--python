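"""Coordinate system and annotations for a circular bacterial chromosome.

Everything downstream works on integer base-pair coordinates, 0-based,
half-open intervals, on a circle of fixed length.  Windows are ``n_bins``
equal-width, circularly adjacent bins.  User-facing reports convert to Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CLOCKWISE",
    "COUNTERCLOCKWISE",
    "GenomeSpec",
    "TerSite",
    "Inversion",
    "Amplification",
    "map_through_inversion",
    "circular_distance",
    "window_of",
    "window_midpoints",
    "window_starts",
    "masked_window_mask",
    "default_genome",
]

#: Fork / polarity direction constants.  Clockwise means increasing
#: coordinate; counterclockwise means decreasing coordinate.
CLOCKWISE = "clockwise"
COUNTERCLOCKWISE = "counterclockwise"

_DIRECTIONS = (CLOCKWISE, COUNTERCLOCKWISE)

#: Default marker loci (bp) on the W3110-like default chromosome.
DEFAULT_MARKERS = {
    "ydcM": 1_505_000,
    "lepA": 2_705_000,
    "qseC": 3_169_000,
    "parC": 3_162_000,
    "parE": 3_172_000,
    "oriC": 3_925_000,
}

DEFAULT_LENGTH = 4_640_000

#: Default masked interval: a deletion gap near 0.3 Mb (~40 kb wide).
DEFAULT_MASKED = ((290_000, 330_000),)


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; expected one of {_DIRECTIONS}")


@dataclass(frozen=True)
class GenomeSpec:
    """A circular chromosome with masked intervals and named marker loci."""

    name: str = "W3110-like"
    length: int = DEFAULT_LENGTH
    masked_intervals: tuple[tuple[int, int], ...] = DEFAULT_MASKED
    markers: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MARKERS))

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        norm = []
        for start, end in self.masked_intervals:
            if not (0 <= start < end <= self.length):
                raise ValueError(f"masked interval [{start}, {end}) out of range")
            norm.append((int(start), int(end)))
        norm.sort()
        for (s0, e0), (s1, e1) in zip(norm, norm[1:]):
            if s1 < e0:
                raise ValueError("masked intervals overlap after normalization")
        object.__setattr__(self, "masked_intervals", tuple(norm))
        for name, pos in self.markers.items():
            if not (0 <= pos < self.length):
                raise ValueError(f"marker {name!r} position {pos} out of range")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")

    def marker_position(self, name: str) -> int:
        try:
            return self.markers[name]
        except KeyError:
            raise KeyError(f"unknown marker {name!r}; known: {sorted(self.markers)}") from None

    def is_masked(self, p: int) -> bool:
        return any(s <= p < e for s, e in self.masked_intervals)

    def with_markers(self, **extra: int) -> "GenomeSpec":
        markers = dict(self.markers)
        markers.update(extra)
        return replace(self, markers=markers)


@dataclass(frozen=True)
class TerSite:
    """A polar replication-arrest site.

    ``blocks`` is the single fork direction that the site arrests;
    forks moving in the opposite direction pass through.
    """

    name: str
    position: int
    blocks: str

    def __post_init__(self) -> None:
        _check_direction(self.blocks)
        if self.position < 0:
            raise ValueError("Ter position must be nonnegative")

    def flipped(self, new_position: int | None = None) -> "TerSite":
        other = COUNTERCLOCKWISE if self.blocks == CLOCKWISE else CLOCKWISE
        pos = self.position if new_position is None else new_position
        return TerSite(self.name, pos, other)


@dataclass(frozen=True)
class Inversion:
    """An inverted chromosomal segment [start, end] (both coordinates in bp)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("inversion requires 0 <= start < end")

    def contains(self, p: int) -> bool:
        return self.start <= p <= self.end


@dataclass(frozen=True)
class Amplification:
    """A tandem-amplified segment [start, end) with copy factor >= 1."""

    start: int
    end: int
    copy_factor: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("amplification requires 0 <= start < end")
        if self.copy_factor < 1:
            raise ValueError("copy_factor must be >= 1")


def map_through_inversion(p: int, inv: Inversion, length: int | None = None):
    """Map a coordinate through an inversion (an involution).

    Coordinates inside ``[inv.start, inv.end]`` map to ``start + end - p``;
    coordinates outside are unchanged.  Accepts scalars or arrays.
    """
    arr = np.asarray(p)
    if length is not None and (np.any(arr < 0) or np.any(arr >= length)):
        raise ValueError("coordinate out of range [0, length)")
    inside = (arr >= inv.start) & (arr <= inv.end)
    out = np.where(inside, inv.start + inv.end - arr, arr)
    if np.isscalar(p) or arr.ndim == 0:
        return out.item()
    return out


def circular_distance(p: int, q: int, direction: str, length: int):
    """Distance from ``p`` to ``q`` along the circle in the stated direction.

    ``direction`` is one of clockwise, counterclockwise, or ``"shortest"``
    (the lesser of the two arcs, always <= length / 2).
    """
    parr, qarr = np.asarray(p), np.asarray(q)
    if np.any(parr < 0) or np.any(parr >= length) or np.any(qarr < 0) or np.any(qarr >= length):
        raise ValueError("coordinates out of range [0, length)")
    cw = (qarr - parr) % length
    if direction == CLOCKWISE:
        out = cw
    elif direction == COUNTERCLOCKWISE:
        out = (parr - qarr) % length
    elif direction == "shortest":
        out = np.minimum(cw, length - cw)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if np.isscalar(p) and np.isscalar(q):
        return out.item()
    return out


def window_of(p, n_bins: int, length: int):
    """Return the equal-width window index of coordinate ``p``.

    Windows are 0-based half-open and circularly adjacent (window
    ``n_bins - 1`` neighbors window 0).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    arr = np.asarray(p)
    if np.any(arr < 0) or np.any(arr >= length):
        raise ValueError("coordinate out of range [0, length)")
    idx = (arr.astype(np.int64) * n_bins) // length
    if np.isscalar(p) or np.asarray(p).ndim == 0:
        return int(idx)
    return idx.astype(np.int64)


def window_starts(n_bins: int, length: int) -> np.ndarray:
    """Integer bp start of every window (end of window w is start of w+1)."""
    w = np.arange(n_bins + 1, dtype=np.int64)
    # ceil(w * L / n) gives exact half-open boundaries consistent with window_of
    return -((-w * length) // n_bins)


def window_midpoints(n_bins: int, length: int) -> np.ndarray:
    """Float bp midpoint of every window."""
    return (np.arange(n_bins) + 0.5) * (length / n_bins)


def masked_window_mask(genome: GenomeSpec, n_bins: int) -> np.ndarray:
    """Boolean array: True for windows whose midpoint lies in a masked interval."""
    mids = window_midpoints(n_bins, genome.length)
    mask = np.zeros(n_bins, dtype=bool)
    for s, e in genome.masked_intervals:
        mask |= (mids >= s) & (mids < e)
    return mask


def default_genome() -> GenomeSpec:
    """The default W3110-like chromosome used throughout."""
    return GenomeSpec()


def default_ter_sites() -> tuple[TerSite, TerSite]:
    """Default TerA/TerB polar traps flanking the terminus region.

    TerA arrests counterclockwise-moving forks; TerB arrests
    clockwise-moving forks, so forks entering from either side of the
    terminus are confined between the two sites.
    """
    return (
        TerSite("TerA", 1_340_000, COUNTERCLOCKWISE),
        TerSite("TerB", 1_680_000, CLOCKWISE),
    )
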