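"""Velocity ratio, wavefront calibration, pausing index/time, profile groups."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from ttkinetics.intervals import Gene, GenomicInterval
from ttkinetics.simulate import SimulationConfig, simulate_cdk9i_timecourse, simulate_tracks
from ttkinetics.tracks import CoverageTrack
from ttkinetics.velocity import (
    calibrate_velocity,
    estimate_velocity,
    fit_wavefronts,
    pausing_index,
    pausing_time,
    profile_groups,
    velocity_table,
)

SIZES = {"chr1": 50_000}


def uniform_track(level_plus, bin_size=200, library="other"):
    track = CoverageTrack.zeros(SIZES, bin_size, library=library)
    track.values["+"]["chr1"][:] = level_plus
    return track


class TestEstimateVelocity:
    def test_ratio_of_densities(self):
        lrna, s5p = uniform_track(10.0), uniform_track(5.0)
        iv = GenomicInterval("chr1", 1000, 9000, "+")
        assert estimate_velocity(lrna, s5p, iv) == pytest.approx(2.0)

    def test_scale_invariance(self):
        iv = GenomicInterval("chr1", 1000, 9000, "+")
        v1 = estimate_velocity(uniform_track(10.0), uniform_track(5.0), iv)
        v2 = estimate_velocity(uniform_track(20.0), uniform_track(10.0), iv)
        assert v1 == pytest.approx(v2)

    def test_low_occupancy_gives_missing_not_zero(self):
        iv = GenomicInterval("chr1", 1000, 9000, "+")
        v = estimate_velocity(uniform_track(10.0), uniform_track(0.0), iv)
        assert np.isnan(v)


def grid_config(seed=21):
    """16 genes on a 4x4 (initiation, velocity) grid, fixed half-life."""
    inits = [0.2, 0.5, 1.0, 2.0]
    vels = [0.5, 1.0, 2.0, 4.0]
    params = pd.DataFrame(
        [
            {"init_rate": i, "velocity": v, "half_life": 60.0, "d_term": 2000.0,
             "length": 30_000}
            for i in inits
            for v in vels
        ]
    )
    return SimulationConfig(seed=seed, gene_params=params, n_genes=len(params))


class TestWavefronts:
    def test_ols_slope_and_intercept(self, two_gene_annotation):
        # closed form: distances (10, 20, 30) kb at (5, 10, 15) min
        import statsmodels.api as sm

        fit = sm.OLS([10, 20, 30], sm.add_constant([5.0, 10.0, 15.0])).fit()
        assert fit.params[1] == pytest.approx(2.0)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-9)
        fit2 = sm.OLS([8, 18, 28], sm.add_constant([5.0, 10.0, 15.0])).fit()
        assert fit2.params[1] == pytest.approx(2.0)
        assert fit2.params[0] == pytest.approx(-2.0)  # one-minute response delay

    def test_noiseless_timecourse_recovers_slopes_exactly(self):
        sim = simulate_tracks(grid_config())
        times = [2.0, 4.0, 6.0]
        tracks, _ = simulate_cdk9i_timecourse(sim, times, t0=1.0, noiseless=True)
        fits = fit_wavefronts(tracks, times, sim.annotation)
        merged = fits.merge(sim.truth[["gene_id", "velocity"]], on="gene_id")
        assert len(merged) == 16
        np.testing.assert_allclose(merged["velocity_kb_min"], merged["velocity"], rtol=1e-9)
        np.testing.assert_allclose(merged["intercept_kb"], -merged["velocity"], rtol=1e-6)

    def test_noisy_recovery_and_calibration(self):
        sim = simulate_tracks(grid_config())
        vel = velocity_table(sim.lrna, sim.s5p, sim.annotation)
        merged = vel.merge(sim.truth[["gene_id", "velocity"]], on="gene_id")
        ok = merged.dropna(subset=["vhat"])
        assert spearmanr(ok["vhat"], ok["velocity"]).statistic >= 0.9
        times = [2.0, 4.0, 6.0]
        tracks, _ = simulate_cdk9i_timecourse(sim, times, t0=1.0)
        fits = fit_wavefronts(tracks, times, sim.annotation)
        scale, scaled = calibrate_velocity(vel, fits, min_matched=16)
        m = scaled.merge(sim.truth[["gene_id", "velocity"]], on="gene_id").dropna(
            subset=["v_scaled_kb_min"]
        )
        rel = np.abs(m["v_scaled_kb_min"] - m["velocity"]) / m["velocity"]
        assert rel.median() <= 0.15

    def test_calibration_median_ratio(self):
        vhat = pd.DataFrame({"gene_id": [f"g{i}" for i in range(25)], "vhat": np.ones(25)})
        measured = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(25)], "velocity_kb_min": np.full(25, 2.0)}
        )
        scale, out = calibrate_velocity(vhat, measured)
        assert scale == pytest.approx(2.0)
        assert (out["v_scaled_kb_min"] == 2.0).all()

    def test_calibration_needs_enough_matches(self):
        vhat = pd.DataFrame({"gene_id": ["g0"], "vhat": [1.0]})
        measured = pd.DataFrame({"gene_id": ["g0"], "velocity_kb_min": [2.0]})
        with pytest.raises(ValueError):
            calibrate_velocity(vhat, measured, min_matched=20)


class TestPausing:
    def make_gene(self):
        return Gene("g", GenomicInterval("chr1", 10_000, 20_000, "+"))

    def test_flat_profile_gives_unit_index(self):
        s5p = uniform_track(4.0)
        gene = self.make_gene()
        pause = GenomicInterval("chr1", 10_000, 10_200, "+")
        assert pausing_index(s5p, pause, gene) == pytest.approx(1.0)

    def test_ratio_of_densities(self):
        s5p = uniform_track(2.0)
        s5p.values["+"]["chr1"][50] = 10.0  # pause bin [10_000, 10_200)
        gene = self.make_gene()
        pause = GenomicInterval("chr1", 10_000, 10_200, "+")
        assert pausing_index(s5p, pause, gene) == pytest.approx(5.0)

    def test_simulated_dwell_factor_recovered(self, default_sim):
        pis = []
        for row in default_sim.truth.itertuples(index=False):
            gene = default_sim.annotation[row.gene_id]
            if row.strand == "-":
                pause = GenomicInterval(row.chrom, gene.tss - 200, gene.tss, "-")
            else:
                pause = GenomicInterval(row.chrom, gene.tss, gene.tss + 200, "+")
            pi = pausing_index(default_sim.s5p, pause, gene)
            if np.isfinite(pi):
                pis.append(pi)
        assert np.median(pis) == pytest.approx(default_sim.config.dwell_factor, rel=0.2)

    def test_pausing_time_arithmetic(self):
        assert pausing_time(52, 0.1486) == pytest.approx(21.0, abs=0.01)
        assert pausing_time(100, 1.0) == pytest.approx(6.0)
        assert pausing_time(100, 2.0) == pytest.approx(pausing_time(100, 1.0) / 2)


class TestProfileGroups:
    def test_well_separated_clusters_recovered(self, rng):
        levels = [0.5, 2.0, 8.0]
        truth, profiles = [], []
        for g, level in enumerate(levels):
            for _ in range(20):
                profiles.append(level * (1 + 0.05 * rng.standard_normal(50)))
                truth.append(g)
        labels, means = profile_groups(np.array(profiles), k=3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        # relabeling orders groups slow -> fast
        assert means[0].mean() < means[1].mean() < means[2].mean()

    def test_single_group_is_grand_mean(self, rng):
        profiles = rng.random((10, 30)) + 0.5
        labels, means = profile_groups(profiles, k=1, seed=0)
        assert (labels == 0).all()
        np.testing.assert_allclose(means[0], profiles.mean(axis=0))

    def test_seed_invariance_after_relabeling(self, rng):
        profiles = np.concatenate(
            [np.full((15, 20), 1.0), np.full((15, 20), 10.0)]
        ) * (1 + 0.02 * rng.standard_normal((30, 20)))
        l1, _ = profile_groups(profiles, k=2, seed=0)
        l2, _ = profile_groups(profiles, k=2, seed=99)
        assert (l1 == l2).all()

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            profile_groups(rng.random((3, 10)), k=5)
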