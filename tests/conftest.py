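import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from mfakit import (
    OriginSpec,
    ScenarioConfig,
    default_genome,
    default_ter_sites,
    sample_coverage,
    simulate_truth,
)
from mfakit.genome import masked_window_mask
from mfakit.mfa import log2_profile, loess_smooth, normalize_to_control
from mfakit.presets import build_scenario

N_BINS = 10_000
CONTROL_SEED_OFFSET = 10_000


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def mask(genome):
    return masked_window_mask(genome, N_BINS)


@pytest.fixture(scope="session")
def ter_sites():
    return default_ter_sites()


def run_pipeline(scenario, seed, degree=2, depth=None, bias_sd=None):
    """simulate -> sample -> normalize against a wt run-out control -> loess.

    Returns (truth, track, profile, raw_log2_profile, fit).
    """
    sc = scenario.replaced(seed=seed)
    if depth is not None:
        sc = sc.replaced(depth=depth)
    if bias_sd is not None:
        sc = sc.replaced(bias_sd=bias_sd)
    truth = simulate_truth(sc)
    track = sample_coverage(truth, seed=seed)
    ctrl_sc = build_scenario("wt_runout", genome=sc.genome, seed=seed + CONTROL_SEED_OFFSET)
    ctrl_sc = ctrl_sc.replaced(n_bins=sc.n_bins, depth=sc.depth, bias_sd=sc.bias_sd)
    control = sample_coverage(simulate_truth(ctrl_sc), seed=seed + CONTROL_SEED_OFFSET)
    profile = normalize_to_control(track, control)
    raw = log2_profile(track)
    fit = loess_smooth(profile.log2_ratio, degree=degree, robust_iters=1)
    return truth, track, profile, raw, fit


@pytest.fixture(scope="session")
def single_origin_scenario(genome, ter_sites):
    """One trapped terminus-region origin, run-out mode (the t1 shape)."""
    return ScenarioConfig(
        genome=genome,
        origins=(OriginSpec("oriK-1.52", 1_520_000, firing_fraction=0.8, extent_scale=30_000),),
        ter_sites=ter_sites,
        mode="runout",
        name="single-ter-origin",
    )


@pytest.fixture(scope="session")
def rnha_pipeline():
    """Cached full-pipeline run of the rnhA preset at seed 1."""
    return run_pipeline(build_scenario("rnhA_runout"), seed=1)


@pytest.fixture(scope="session")
def topatopb_pipeline():
    return run_pipeline(build_scenario("topAtopB_runout"), seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
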