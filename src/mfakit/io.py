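"""File formats and provenance plumbing.

Plain-text interchange only: bedGraph for coverage, BED for annotations
and feature calls, TSV for profiles / Ct tables / ratios, JSON for truth
and feature records, YAML for scenario configuration.  All coordinates
on disk are 0-based half-open bp.  Every writer emits a provenance
comment (tool version, config hash, seed) so outputs are reproducible
byte-for-byte from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import AmpCall, PeakCall
from .genome import (
    Amplification,
    GenomeSpec,
    Inversion,
    TerSite,
    masked_window_mask,
    window_starts,
)
from .mfa import LoessFit, NormalizedProfile
from .simulate import Barrier, CoverageTrack, OriginSpec, ScenarioConfig, TruthRecord

__all__ = [
    "provenance_block",
    "read_bedgraph",
    "write_bedgraph",
    "read_annotations_bed",
    "write_annotations_bed",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_truth_json",
    "write_features_json",
    "scenario_to_dict",
    "scenario_from_dict",
    "read_scenario_yaml",
    "write_scenario_yaml",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# provenance


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def provenance_block(seed: int | None = None, config=None) -> dict:
    block = {"tool": "mfakit", "version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        block["config_sha256"] = _config_hash(config)
    return block


def _provenance_comment(provenance: dict | None) -> str:
    if not provenance:
        provenance = provenance_block()
    return "# provenance: " + json.dumps(provenance, sort_keys=True)


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: CoverageTrack, path, provenance: dict | None = None) -> None:
    """Write a window-aligned 4-column bedGraph (masked windows skipped)."""
    n = track.n_bins
    starts = window_starts(n, track.genome.length)
    with open(path, "w") as fh:
        fh.write(_provenance_comment(provenance) + "\n")
        fh.write(f"# genome={track.genome.name} length={track.genome.length} n_bins={n}\n")
        name = track.genome.name
        for w in range(n):
            v = track.counts[w]
            if not np.isfinite(v):
                continue
            fh.write(f"{name}\t{starts[w]}\t{starts[w + 1]}\t{v:g}\n")


def read_bedgraph(path, genome: GenomeSpec, n_bins: int | None = None, label: str = "") -> CoverageTrack:
    """Read 4-column bedGraph coverage into a window track.

    Window-aligned intervals round-trip exactly.  Intervals that do not
    match the window grid are re-binned by length-weighted allocation
    (with a logged notice).  Overlapping intervals and negative values
    are errors; malformed lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}: expected 4 columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}: {exc}") from None
            if value < 0:
                raise ValueError(f"{path}: negative value on line {lineno}")
            if not (0 <= start < end <= genome.length):
                raise ValueError(f"{path}: interval out of range on line {lineno}")
            rows.append((start, end, value))
    rows.sort()
    for (s0, e0, _), (s1, _, _) in zip(rows, rows[1:]):
        if s1 < e0:
            raise ValueError(f"{path}: overlapping intervals at {s1}")
    if n_bins is None:
        if not rows:
            raise ValueError(f"{path}: empty bedGraph")
        widths = [e - s for s, e, _ in rows]
        common = int(np.median(widths))
        n_bins = int(round(genome.length / common))
    starts = window_starts(n_bins, genome.length)
    counts = np.zeros(n_bins)
    n_rebinned = 0
    for s, e, v in rows:
        w0 = int(np.searchsorted(starts, s, side="right") - 1)
        if starts[w0] == s and starts[w0 + 1] == e:
            counts[w0] += v
            continue
        n_rebinned += 1
        # length-weighted allocation across the spanned windows
        w = w0
        while w < n_bins and starts[w] < e:
            ov = min(e, starts[w + 1]) - max(s, starts[w])
            if ov > 0:
                counts[w] += v * ov / (e - s)
            w += 1
    if n_rebinned:
        log.info("read_bedgraph: re-binned %d non-window-aligned intervals", n_rebinned)
    counts[masked_window_mask(genome, n_bins)] = np.nan
    return CoverageTrack(genome=genome, counts=counts, label=label)


# ---------------------------------------------------------------------------
# BED annotations


def write_annotations_bed(items, path, genome: GenomeSpec, provenance: dict | None = None) -> None:
    """Write annotations as BED6.

    Ter sites encode polarity in the strand column: ``+`` blocks
    clockwise forks, ``-`` blocks counterclockwise forks.  Peak and
    amplification calls carry prominence / mean log2 in the score column.
    """
    with open(path, "w") as fh:
        fh.write(_provenance_comment(provenance) + "\n")
        chrom = genome.name
        for item in items:
            if isinstance(item, TerSite):
                strand = "+" if item.blocks == "clockwise" else "-"
                fh.write(f"{chrom}\t{item.position}\t{item.position + 1}\t{item.name}\t0\t{strand}\n")
            elif isinstance(item, PeakCall):
                p = int(item.position)
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{item.classification}\t{item.prominence:.4f}\t.\n")
            elif isinstance(item, AmpCall):
                fh.write(f"{chrom}\t{item.start}\t{item.end}\tamp\t{item.mean_log2:.4f}\t.\n")
            else:
                name, start, end, strand = item
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_annotations_bed(path):
    """Read BED rows as (name, start, end, strand) tuples; Ter-style
    single-bp rows can be converted by the caller."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature{lineno}"
            strand = parts[5] if len(parts) > 5 else "."
            out.append((name, start, end, strand))
    return out


def ter_sites_from_bed(path) -> tuple[TerSite, ...]:
    """BED rows to Ter sites (+ blocks clockwise, - counterclockwise)."""
    sites = []
    for name, start, _end, strand in read_annotations_bed(path):
        if strand not in ("+", "-"):
            raise ValueError(f"Ter site {name!r} needs an explicit strand")
        blocks = "clockwise" if strand == "+" else "counterclockwise"
        sites.append(TerSite(name, start, blocks))
    return tuple(sites)


# ---------------------------------------------------------------------------
# profile TSV


def write_profile_tsv(
    profile: NormalizedProfile,
    fit: LoessFit | None,
    path,
    raw_log2=None,
    provenance: dict | None = None,
) -> None:
    n = profile.n_bins
    starts = window_starts(n, profile.genome.length)
    df = pd.DataFrame(
        {
            "window": np.arange(n),
            "start": starts[:-1],
            "end": starts[1:],
            "log2_ratio": profile.log2_ratio,
        }
    )
    if raw_log2 is not None:
        df.insert(3, "log2_raw", np.asarray(raw_log2))
    if fit is not None:
        df["loess"] = fit.fitted
    with open(path, "w") as fh:
        fh.write(_provenance_comment(provenance) + "\n")
        fh.write(
            f"# genome={profile.genome.name} length={profile.genome.length} "
            f"n_bins={n} pseudocount={profile.pseudocount}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep="nan")


def read_profile_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# truth / features JSON


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def write_truth_json(truth: TruthRecord, path, provenance: dict | None = None) -> None:
    sc = truth.scenario
    payload = {
        "provenance": provenance or provenance_block(seed=sc.seed),
        "coordinate_frame": truth.coordinate_frame,
        "n_bins": truth.n_bins,
        "genome_length": sc.genome.length,
        "origins": [_asdict(o) for o in sc.origins],
        "ter_sites": [_asdict(t) for t in sc.ter_sites],
        "amplifications": [_asdict(a) for a in sc.amplifications],
        "inversions": [_asdict(i) for i in sc.inversions],
        "barriers": [_asdict(b) for b in sc.barriers],
        "expected_copies": [None if not np.isfinite(v) else round(float(v), 8) for v in truth.copies],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_features_json(path, peaks=(), amps=(), asymmetries=(), steps=None, provenance=None) -> None:
    payload = {
        "provenance": provenance or provenance_block(),
        "peaks": [_asdict(p) for p in peaks],
        "amplifications": [_asdict(a) for a in amps],
        "ter_asymmetry": [_asdict(t) for t in asymmetries],
        "step_scores": steps or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# scenario YAML


def scenario_to_dict(sc: ScenarioConfig) -> dict:
    return {
        "name": sc.name,
        "mode": sc.mode,
        "k_ct": sc.k_ct,
        "n_bins": sc.n_bins,
        "depth": sc.depth,
        "bias_sd": sc.bias_sd,
        "seed": sc.seed,
        "genome": {
            "name": sc.genome.name,
            "length": sc.genome.length,
            "masked_intervals": [list(iv) for iv in sc.genome.masked_intervals],
            "markers": dict(sc.genome.markers),
        },
        "origins": [_asdict(o) for o in sc.origins],
        "ter_sites": [_asdict(t) for t in sc.ter_sites],
        "amplifications": [_asdict(a) for a in sc.amplifications],
        "inversions": [_asdict(i) for i in sc.inversions],
        "barriers": [_asdict(b) for b in sc.barriers],
    }


def scenario_from_dict(d: dict) -> ScenarioConfig:
    g = d.get("genome", {})
    genome = GenomeSpec(
        name=g.get("name", "W3110-like"),
        length=g.get("length", 4_640_000),
        masked_intervals=tuple(tuple(iv) for iv in g.get("masked_intervals", [])),
        markers=dict(g.get("markers", {})),
    )
    return ScenarioConfig(
        genome=genome,
        origins=tuple(OriginSpec(**o) for o in d.get("origins", [])),
        ter_sites=tuple(TerSite(**t) for t in d.get("ter_sites", [])),
        amplifications=tuple(Amplification(**a) for a in d.get("amplifications", [])),
        inversions=tuple(Inversion(**i) for i in d.get("inversions", [])),
        barriers=tuple(Barrier(**b) for b in d.get("barriers", [])),
        mode=d.get("mode", "runout"),
        k_ct=d.get("k_ct", 0.8),
        n_bins=d.get("n_bins", 10_000),
        depth=d.get("depth", 100.0),
        bias_sd=d.get("bias_sd", 0.05),
        seed=d.get("seed", 0),
        name=d.get("name", "scenario"),
    )


def write_scenario_yaml(sc: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=True)


def read_scenario_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
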