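"""Locus copy-ratio statistics: NGS window ratios and qPCR 2^-dCt ratios.

The NGS ratio averages coverage over a small window centered on each
marker (a single-locus read count would be too noisy at desk-scale
depth); the qPCR ratio applies ``2 ** -(CtA - CtB)`` per matched
replicate pair and then aggregates, so the shared threshold constant
cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec, window_midpoints
from .simulate import CoverageTrack

__all__ = [
    "MarkerRatio",
    "CtTable",
    "Concordance",
    "ngs_marker_ratio",
    "delta_ct_ratio",
    "compare_methods",
]

DEFAULT_MARKER_WINDOW_BP = 5_000


@dataclass
class MarkerRatio:
    marker_a: str
    marker_b: str
    position_a: int
    position_b: int
    ratio: float
    sd: float
    method: str  # "NGS" | "qPCR"
    n: int
    window_bp: int | None = None

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class Concordance:
    marker_a: str
    marker_b: str
    ngs_ratio: float
    qpcr_ratio: float
    ratio_of_ratios: float
    log2_difference: float
    abs_difference: float
    discordant: bool


class CtTable:
    """Replicate qPCR Ct values, one row per (marker, replicate) tube.

    Columns: marker, replicate, input_ng, ct.
    """

    COLUMNS = ("marker", "replicate", "input_ng", "ct")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise ValueError("Ct table is empty")
        if (frame["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def from_replicates(cls, ct_by_marker: dict[str, np.ndarray], input_ng: float = 8.0) -> "CtTable":
        rows = []
        for marker, cts in ct_by_marker.items():
            for i, ct in enumerate(np.atleast_1d(cts)):
                rows.append({"marker": marker, "replicate": i, "input_ng": input_ng, "ct": float(ct)})
        return cls(pd.DataFrame(rows))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def replicates(self, marker: str) -> pd.DataFrame:
        sub = self.frame[self.frame["marker"] == marker]
        if len(sub) == 0:
            raise ValueError(f"marker {marker!r} not in Ct table")
        return sub


def _window_mean_counts(track: CoverageTrack, center: int, window_bp: int) -> tuple[float, float]:
    """(mean, sum) of present counts in a circular window around center."""
    n, L = track.n_bins, track.genome.length
    mids = window_midpoints(n, L)
    lo = (center - window_bp / 2) % L
    hi = (center + window_bp / 2) % L
    if lo <= hi:
        sel = (mids >= lo) & (mids < hi)
    else:
        sel = (mids >= lo) | (mids < hi)
    vals = track.counts[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no unmasked coverage windows around position {center}")
    return float(vals.mean()), float(vals.sum())


def ngs_marker_ratio(
    track: CoverageTrack,
    marker_a: str,
    marker_b: str,
    window_bp: int = DEFAULT_MARKER_WINDOW_BP,
) -> MarkerRatio:
    """Ratio of mean coverage in windows centered on two markers.

    Library-size scaling cancels within a single track.  The sd is a
    Poisson-propagation estimate: ``ratio * sqrt(1/NA + 1/NB)`` with NA,
    NB the summed counts in each window.
    """
    g = track.genome
    pos_a, pos_b = g.marker_position(marker_a), g.marker_position(marker_b)
    bin_bp = g.length / track.n_bins
    if window_bp < bin_bp:
        raise ValueError("window_bp must be at least one bin wide")
    mean_a, sum_a = _window_mean_counts(track, pos_a, window_bp)
    mean_b, sum_b = _window_mean_counts(track, pos_b, window_bp)
    if mean_b <= 0:
        raise ValueError(f"zero coverage around marker {marker_b!r}")
    ratio = mean_a / mean_b
    sd = ratio * np.sqrt((1.0 / sum_a if sum_a > 0 else 0.0) + (1.0 / sum_b if sum_b > 0 else 0.0))
    return MarkerRatio(
        marker_a=marker_a,
        marker_b=marker_b,
        position_a=pos_a,
        position_b=pos_b,
        ratio=float(ratio),
        sd=float(sd),
        method="NGS",
        n=1,
        window_bp=window_bp,
    )


def delta_ct_ratio(
    ct_table: CtTable,
    marker_a: str,
    marker_b: str,
    genome: GenomeSpec | None = None,
) -> MarkerRatio:
    """Per-replicate 2^-dCt ratios, aggregated as mean and sample sd.

    Replicates are matched by (input mass, replicate index); unpairable
    rows raise.  The ratio is computed per pair and then averaged (not
    from averaged Cts), with sd over the per-pair values (ddof=1, 0 for
    a single pair).
    """
    a = ct_table.replicates(marker_a).set_index(["input_ng", "replicate"])["ct"]
    b = ct_table.replicates(marker_b).set_index(["input_ng", "replicate"])["ct"]
    if a.index.has_duplicates or b.index.has_duplicates:
        raise ValueError("ambiguous replicate pairing (duplicate input_ng/replicate keys)")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError(f"no pairable replicates for {marker_a!r}/{marker_b!r}")
    ratios = 2.0 ** -(a.loc[common].to_numpy() - b.loc[common].to_numpy())
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    pos_a = genome.marker_position(marker_a) if genome else -1
    pos_b = genome.marker_position(marker_b) if genome else -1
    return MarkerRatio(
        marker_a=marker_a,
        marker_b=marker_b,
        position_a=pos_a,
        position_b=pos_b,
        ratio=mean,
        sd=sd,
        method="qPCR",
        n=int(ratios.size),
    )


def compare_methods(ngs: MarkerRatio, qpcr: MarkerRatio, tolerance_log2: float = 0.5) -> Concordance:
    """Concordance between an NGS and a qPCR ratio for the same pair."""
    if (ngs.marker_a, ngs.marker_b) != (qpcr.marker_a, qpcr.marker_b):
        raise ValueError("marker pairs differ between the two ratios")
    rr = ngs.ratio / qpcr.ratio
    l2 = float(np.log2(rr))
    return Concordance(
        marker_a=ngs.marker_a,
        marker_b=ngs.marker_b,
        ngs_ratio=ngs.ratio,
        qpcr_ratio=qpcr.ratio,
        ratio_of_ratios=float(rr),
        log2_difference=l2,
        abs_difference=float(abs(ngs.ratio - qpcr.ratio)),
        discordant=abs(l2) > tolerance_log2,
    )
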