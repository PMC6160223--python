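import numpy as np
import pytest

from mfakit import (
    Amplification,
    Inversion,
    OriginSpec,
    ScenarioConfig,
    TerSite,
    default_genome,
    default_ter_sites,
    expected_copy_number,
    fork_stop,
    sample_coverage,
    simulate_ct,
    simulate_truth,
    simulate_with_inversion,
    window_of,
)
from mfakit.genome import CLOCKWISE, COUNTERCLOCKWISE, GenomeSpec, masked_window_mask
from mfakit.simulate import Barrier, physical_scenario, trap_distance

from oracles import mc_expected_copies

L = 4_640_000


def plain_genome(length=L):
    return GenomeSpec(name="plain", length=length, masked_intervals=(), markers={})


class TestForkStop:
    def test_arrested_at_matching_ter(self):
        ters = default_ter_sites()
        assert fork_stop(1_520_000, COUNTERCLOCKWISE, 1_000_000, ters, L) == 1_340_000

    def test_passes_opposite_polarity_ter(self):
        # counterclockwise fork from 1.83 Mb passes TerB (blocks clockwise)
        # and is arrested at TerA
        ters = default_ter_sites()
        assert fork_stop(1_830_000, COUNTERCLOCKWISE, 1_000_000, ters, L) == 1_340_000

    def test_no_ter(self):
        assert fork_stop(100_000, CLOCKWISE, 50_000, (), L) == 150_000

    def test_short_extent_stops_before_ter(self):
        ters = default_ter_sites()
        assert fork_stop(1_520_000, CLOCKWISE, 10_000, ters, L) == 1_530_000

    def test_negative_extent_raises(self):
        with pytest.raises(ValueError):
            fork_stop(0, CLOCKWISE, -1, (), L)

    def test_trap_distance_wraps(self):
        ters = (TerSite("T", 100, CLOCKWISE),)
        assert trap_distance(200, CLOCKWISE, ters, 1000) == 900
        assert trap_distance(200, COUNTERCLOCKWISE, ters, 1000) == np.inf


class TestExpectedCopyNumber:
    def test_runout_no_orik_is_flat(self):
        sc = ScenarioConfig(genome=default_genome(), mode="runout")
        truth = expected_copy_number(sc)
        present = np.isfinite(truth.copies)
        assert np.max(np.abs(np.log2(truth.copies[present]))) == 0.0

    def test_log_phase_oric_gradient_ratio(self):
        # k_ct = 1, no traps: copies at oriC / copies at antipode = 2
        g = plain_genome()
        sc = ScenarioConfig(
            genome=g,
            origins=(OriginSpec("oriC", 1_000_000, kind="oriC"),),
            mode="log_phase",
            k_ct=1.0,
        )
        truth = expected_copy_number(sc)
        at = truth.copies[window_of(1_000_000, sc.n_bins, g.length)]
        anti = truth.copies[window_of(1_000_000 + g.length // 2, sc.n_bins, g.length)]
        assert at / anti == pytest.approx(2.0, rel=1e-3)

    def test_trapped_orik_peak_and_plateau(self):
        sc = ScenarioConfig(
            genome=default_genome(),
            origins=(OriginSpec("k", 1_520_000, firing_fraction=0.8, extent_scale=80_000),),
            ter_sites=default_ter_sites(),
            mode="runout",
        )
        truth = expected_copy_number(sc)
        n = sc.n_bins
        assert int(np.nanargmax(truth.copies)) == window_of(1_520_000, n, L)
        # beyond the traps the expectation returns to baseline exactly
        left = truth.copies[window_of(1_000_000, n, L)]
        right = truth.copies[window_of(2_000_000, n, L)]
        assert left == pytest.approx(1.0, abs=1e-12)
        assert right == pytest.approx(1.0, abs=1e-12)

    def test_monotone_decay_from_single_origin(self):
        g = plain_genome(1_000_000)
        sc = ScenarioConfig(
            genome=g,
            origins=(OriginSpec("k", 500_000, firing_fraction=0.5, extent_scale=50_000),),
            mode="runout",
            n_bins=1000,
        )
        c = expected_copy_number(sc).copies
        peak = window_of(500_000, 1000, g.length)
        # non-increasing as distance from the origin grows, on each side
        assert np.all(np.diff(c[peak : peak + 400]) <= 1e-12)
        assert np.all(np.diff(c[peak - 400 : peak + 1][::-1]) <= 1e-12)

    def test_circular_equivariance(self):
        g = plain_genome(1_000_000)
        n = 500
        shift_bins = 100
        shift = shift_bins * (g.length // n)

        def scen(offset):
            return ScenarioConfig(
                genome=g,
                origins=(OriginSpec("k", (200_000 + offset) % g.length, firing_fraction=0.7, extent_scale=60_000),),
                ter_sites=(TerSite("T", (400_000 + offset) % g.length, CLOCKWISE),),
                barriers=(Barrier((300_000 + offset) % g.length, (306_000 + offset) % g.length, CLOCKWISE, 0.5),),
                amplifications=(Amplification((50_000 + offset) % g.length, (80_000 + offset) % g.length, 2.0),),
                mode="runout",
                n_bins=n,
            )

        c0 = expected_copy_number(scen(0)).copies
        c1 = expected_copy_number(scen(shift)).copies
        assert np.allclose(np.roll(c0, shift_bins), c1)

    def test_origin_in_masked_interval_warns(self):
        with pytest.warns(UserWarning):
            ScenarioConfig(
                genome=default_genome(),
                origins=(OriginSpec("bad", 300_000),),
                mode="runout",
            )

    def test_masked_windows_nan(self):
        sc = ScenarioConfig(genome=default_genome(), mode="runout")
        truth = expected_copy_number(sc)
        assert np.isnan(truth.copies[masked_window_mask(sc.genome, sc.n_bins)]).all()


class TestMonteCarloOracle:
    def test_trapped_origin_matches_mc(self):
        sc = ScenarioConfig(
            genome=default_genome(),
            origins=(OriginSpec("k", 1_520_000, firing_fraction=0.8, extent_scale=80_000),),
            ter_sites=default_ter_sites(),
            mode="runout",
            n_bins=500,
        )
        analytic = expected_copy_number(sc).copies
        mc = mc_expected_copies(sc, n_chrom=200_000, seed=42)
        ok = np.isfinite(analytic)
        rel = np.abs(analytic[ok] - mc[ok]) / analytic[ok]
        assert rel.max() < 0.02

    def test_traps_barriers_variants_match_mc(self):
        sc = ScenarioConfig(
            genome=default_genome(),
            origins=(
                OriginSpec("k1", 1_520_000, firing_fraction=0.8, extent_scale=80_000),
                OriginSpec("k2", 2_540_000, firing_fraction=0.5, extent_scale=150_000),
            ),
            ter_sites=default_ter_sites(),
            barriers=(Barrier(2_727_000, 2_733_000, CLOCKWISE, 0.5),),
            amplifications=(Amplification(2_990_000, 3_240_000, 3.0),),
            mode="runout",
            n_bins=500,
        )
        analytic = expected_copy_number(sc).copies
        mc = mc_expected_copies(sc, n_chrom=200_000, seed=7)
        ok = np.isfinite(analytic)
        rel = np.abs(analytic[ok] - mc[ok]) / analytic[ok]
        assert rel.max() < 0.02


class TestInversion:
    def test_empty_inversion_identical(self):
        sc = ScenarioConfig(
            genome=default_genome(),
            origins=(OriginSpec("k", 1_520_000, firing_fraction=0.5, extent_scale=50_000),),
            mode="runout",
        )
        a = expected_copy_number(sc).copies
        b = simulate_with_inversion(sc).copies
        assert np.array_equal(a[np.isfinite(a)], b[np.isfinite(b)])

    def test_element_mapping(self):
        inv = Inversion(1_390_000, 2_280_000)
        sc = ScenarioConfig(
            genome=default_genome(),
            origins=(OriginSpec("k", 1_520_000),),
            ter_sites=default_ter_sites(),
            inversions=(inv,),
            mode="runout",
        )
        phys = physical_scenario(sc)
        assert phys.origins[0].position == 2_150_000
        terb = next(t for t in phys.ter_sites if t.name == "TerB")
        assert terb.position == 1_990_000
        assert terb.blocks == COUNTERCLOCKWISE  # polarity flipped
        tera = next(t for t in phys.ter_sites if t.name == "TerA")
        assert tera.position == 1_340_000  # outside the segment: unchanged
        assert tera.blocks == COUNTERCLOCKWISE

    def test_reference_peak_window_preserved(self):
        sc = ScenarioConfig(
            genome=default_genome(),
            origins=(OriginSpec("k", 1_520_000, firing_fraction=0.8, extent_scale=30_000),),
            ter_sites=default_ter_sites(),
            inversions=(Inversion(1_390_000, 2_280_000),),
            mode="runout",
        )
        truth = simulate_with_inversion(sc)
        w = int(np.nanargmax(truth.copies))
        assert abs(w - window_of(1_520_000, sc.n_bins, L)) <= 1

    def test_multiset_conservation(self):
        sc = ScenarioConfig(
            genome=default_genome(),
            origins=(OriginSpec("k", 1_520_000, firing_fraction=0.8, extent_scale=60_000),),
            ter_sites=default_ter_sites(),
            inversions=(Inversion(1_390_000, 2_280_000),),
            mode="runout",
        )
        ref = simulate_with_inversion(sc).copies
        phys = expected_copy_number(physical_scenario(sc)).copies
        # reference mask (near 0.3 Mb) lies outside the segment, so it is
        # the same set of windows in both frames
        a = np.sort(ref[np.isfinite(ref)])
        b = np.sort(phys[np.isfinite(phys)])
        assert np.allclose(a, b)

    def test_physical_truth_matches_mc(self):
        sc = ScenarioConfig(
            genome=default_genome(),
            origins=(OriginSpec("k", 1_520_000, firing_fraction=0.8, extent_scale=80_000),),
            ter_sites=default_ter_sites(),
            inversions=(Inversion(1_390_000, 2_280_000),),
            mode="runout",
            n_bins=500,
        )
        phys = physical_scenario(sc)
        analytic = expected_copy_number(phys).copies
        mc = mc_expected_copies(phys, n_chrom=200_000, seed=3)
        ok = np.isfinite(analytic)
        rel = np.abs(analytic[ok] - mc[ok]) / analytic[ok]
        assert rel.max() < 0.02

    def test_multiple_inversions_unsupported(self):
        sc = ScenarioConfig(
            genome=default_genome(),
            inversions=(Inversion(10, 20), Inversion(30, 40)),
            mode="runout",
        )
        with pytest.raises(ValueError):
            simulate_with_inversion(sc)


class TestSampleCoverage:
    def test_flat_moments(self):
        sc = ScenarioConfig(genome=plain_genome(), mode="runout", depth=100.0, bias_sd=0.0)
        truth = expected_copy_number(sc)
        track = sample_coverage(truth, seed=5)
        assert track.counts.mean() == pytest.approx(100.0, rel=0.02)
        assert track.counts.var() == pytest.approx(100.0, rel=0.1)

    def test_total_count_within_3se(self):
        sc = ScenarioConfig(genome=default_genome(), mode="runout", depth=100.0, bias_sd=0.0)
        truth = expected_copy_number(sc)
        track = sample_coverage(truth, seed=11)
        n_present = int(np.isfinite(track.counts).sum())
        expected = 100.0 * n_present
        se = np.sqrt(expected)
        assert abs(track.total_reads - expected) < 3 * se

    def test_amplification_ratio(self):
        sc = ScenarioConfig(
            genome=plain_genome(),
            amplifications=(Amplification(1_000_000, 2_000_000, 3.0),),
            mode="runout",
            depth=1000.0,
            bias_sd=0.0,
        )
        truth = expected_copy_number(sc)
        track = sample_coverage(truth, seed=2)
        mids = truth.midpoints
        inside = (mids >= 1_000_000) & (mids < 2_000_000)
        ratio = track.counts[inside].mean() / track.counts[~inside].mean()
        assert ratio == pytest.approx(3.0, rel=0.02)

    def test_seed_determinism(self):
        sc = ScenarioConfig(genome=default_genome(), mode="runout", seed=9)
        truth = expected_copy_number(sc)
        a = sample_coverage(truth)
        b = sample_coverage(truth)
        assert np.array_equal(a.counts, b.counts, equal_nan=True)

    def test_masked_windows_missing(self):
        sc = ScenarioConfig(genome=default_genome(), mode="runout")
        track = sample_coverage(expected_copy_number(sc), seed=1)
        assert np.isnan(track.counts[masked_window_mask(sc.genome, sc.n_bins)]).all()

    def test_bad_depth(self):
        sc = ScenarioConfig(genome=default_genome(), mode="runout")
        with pytest.raises(ValueError):
            sample_coverage(expected_copy_number(sc), depth=0.0)


class TestSimulateCt:
    def test_equal_copies_equal_ct(self):
        a, b = simulate_ct(2.0, 2.0, ct_noise_sd=0.0, replicates=3)
        assert np.allclose(a, b)

    def test_one_cycle_per_doubling(self):
        a, b = simulate_ct(2.0, 1.0, ct_noise_sd=0.0, replicates=2)
        assert np.allclose(a, b - 1.0)

    def test_noisy_recovery_within_10pct(self):
        from mfakit.ratios import CtTable, delta_ct_ratio

        a, b = simulate_ct(3.0, 1.0, ct_noise_sd=0.1, replicates=6, seed=21)
        table = CtTable.from_replicates({"A": a, "B": b})
        mr = delta_ct_ratio(table, "A", "B")
        assert mr.ratio == pytest.approx(3.0, rel=0.10)

    def test_positive_copies_required(self):
        with pytest.raises(ValueError):
            simulate_ct(0.0, 1.0)
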