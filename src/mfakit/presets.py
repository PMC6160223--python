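"""Named scenario presets.

Each preset builds a :class:`~mfakit.simulate.ScenarioConfig` emulating
one of the canonical profile shapes: a log-phase gradient, a flat
protein-synthesis run-out, multi-origin cSDR run-outs with polar Ter
traps and transcription barriers, and variants carrying a large
amplification or inversion.  Origin firing fractions and fork extent
scales are free model parameters chosen to give clearly resolvable
peaks at the annotated coordinates; they are not measured quantities.
"""

from __future__ import annotations

from .genome import (
    CLOCKWISE,
    COUNTERCLOCKWISE,
    Amplification,
    GenomeSpec,
    Inversion,
    default_genome,
    default_ter_sites,
)
from .simulate import Barrier, OriginSpec, ScenarioConfig

__all__ = ["PRESETS", "build_scenario", "default_barriers"]


def default_barriers() -> tuple[Barrier, ...]:
    """Heavily transcribed rRNA operons as head-on stall intervals.

    Operons are transcribed codirectionally with the forks arriving from
    the main origin (at 3.925 Mb), so the stalled (head-on) direction is
    clockwise for operons counterclockwise of the origin and
    counterclockwise for the one beyond it.
    """
    return (
        Barrier(2_727_000, 2_733_000, blocks=CLOCKWISE, transmission=0.6, name="rrnG"),
        Barrier(3_417_000, 3_423_000, blocks=CLOCKWISE, transmission=0.7, name="rrnD"),
        Barrier(3_507_000, 3_513_000, blocks=CLOCKWISE, transmission=0.7, name="rrnB"),
        Barrier(3_597_000, 3_603_000, blocks=CLOCKWISE, transmission=0.7, name="rrnA"),
        Barrier(3_687_000, 3_693_000, blocks=CLOCKWISE, transmission=0.7, name="rrnC"),
        Barrier(4_207_000, 4_213_000, blocks=COUNTERCLOCKWISE, transmission=0.7, name="rrnE"),
    )


def _oric(genome: GenomeSpec) -> OriginSpec:
    return OriginSpec("oriC", genome.marker_position("oriC"), kind="oriC", firing_fraction=1.0)


def _ter_origin(firing: float) -> OriginSpec:
    # Terminus-region cSDR origin between the TerA/TerB traps.  The short
    # extent scale keeps most forks inside the trap region, so the peak
    # stays symmetric about the origin despite the asymmetric trap
    # distances (180 kb vs 160 kb), and keeps the cusp sharp enough to
    # localize precisely at desk-scale depth.
    return OriginSpec("oriK-1.52", 1_520_000, kind="oriK", firing_fraction=firing, extent_scale=30_000)


def wt_log(genome: GenomeSpec) -> ScenarioConfig:
    return ScenarioConfig(
        genome=genome,
        origins=(_oric(genome),),
        ter_sites=default_ter_sites(),
        barriers=default_barriers(),
        mode="log_phase",
        k_ct=0.8,
        name="wt_log",
    )


def wt_runout(genome: GenomeSpec) -> ScenarioConfig:
    return ScenarioConfig(
        genome=genome,
        origins=(),
        ter_sites=default_ter_sites(),
        barriers=default_barriers(),
        mode="runout",
        name="wt_runout",
    )


def wt_stationary(genome: GenomeSpec) -> ScenarioConfig:
    return wt_runout(genome).replaced(mode="stationary", name="wt_stationary")


def rnha_runout(genome: GenomeSpec) -> ScenarioConfig:
    """Multi-origin cSDR run-out: one trapped terminus origin plus three
    origins outside the trap region."""
    origins = (
        _ter_origin(0.8),
        OriginSpec("oriK-1.83", 1_830_000, firing_fraction=0.6, extent_scale=40_000),
        OriginSpec("oriK-2.23", 2_230_000, firing_fraction=0.6, extent_scale=40_000),
        OriginSpec("oriK-2.54", 2_540_000, firing_fraction=0.6, extent_scale=40_000),
    )
    return ScenarioConfig(
        genome=genome,
        origins=origins,
        ter_sites=default_ter_sites(),
        barriers=default_barriers(),
        mode="runout",
        name="rnhA_runout",
    )


def topatopb_runout(genome: GenomeSpec) -> ScenarioConfig:
    """Dominant terminus origin, smaller bumps, and a x3 amplification."""
    origins = (
        _ter_origin(0.95),
        OriginSpec("oriK-1.88", 1_880_000, firing_fraction=0.25, extent_scale=40_000),
        OriginSpec("oriK-2.23", 2_230_000, firing_fraction=0.25, extent_scale=40_000),
        OriginSpec("oriK-2.56", 2_560_000, firing_fraction=0.25, extent_scale=40_000),
    )
    return ScenarioConfig(
        genome=genome,
        origins=origins,
        ter_sites=default_ter_sites(),
        barriers=default_barriers(),
        amplifications=(Amplification(2_990_000, 3_240_000, 3.0),),
        mode="runout",
        name="topAtopB_runout",
    )


def rnha_inv(genome: GenomeSpec) -> ScenarioConfig:
    """The multi-origin run-out on a chromosome carrying a large inversion."""
    return rnha_runout(genome).replaced(
        inversions=(Inversion(1_390_000, 2_280_000),),
        name="rnhA_inv",
    )


PRESETS = {
    "wt_log": wt_log,
    "wt_runout": wt_runout,
    "wt_stationary": wt_stationary,
    "rnhA_runout": rnha_runout,
    "topAtopB_runout": topatopb_runout,
    "rnhA_inv": rnha_inv,
}


def build_scenario(
    name: str,
    genome: GenomeSpec | None = None,
    seed: int = 0,
    depth: float | None = None,
    n_bins: int | None = None,
) -> ScenarioConfig:
    """Instantiate a named preset, optionally overriding seed/depth/bins."""
    try:
        builder = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
    sc = builder(genome or default_genome()).replaced(seed=seed)
    if depth is not None:
        sc = sc.replaced(depth=depth)
    if n_bins is not None:
        sc = sc.replaced(n_bins=n_bins)
    return sc
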