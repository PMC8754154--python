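"""The generator's contracts: determinism, model identities, expectations."""

import numpy as np
import pandas as pd
import pytest

from ttkinetics.simulate import (
    SimulationConfig,
    draw_gene_params,
    simulate_cdk9i_timecourse,
    simulate_labeling_counts,
    simulate_spikeins,
    simulate_tracks,
)


def tracks_equal(a, b):
    return all(
        np.array_equal(a.values[s][c], b.values[s][c])
        for s in a.strands
        for c in a.chrom_sizes
    )


class TestDeterminism:
    def test_same_seed_identical_tracks(self):
        s1 = simulate_tracks(SimulationConfig(seed=42, n_genes=12))
        s2 = simulate_tracks(SimulationConfig(seed=42, n_genes=12))
        assert tracks_equal(s1.lrna, s2.lrna)
        assert tracks_equal(s1.s5p, s2.s5p)
        pd.testing.assert_frame_equal(s1.truth, s2.truth)

    def test_different_seed_differs(self):
        s1 = simulate_tracks(SimulationConfig(seed=1, n_genes=12))
        s2 = simulate_tracks(SimulationConfig(seed=2, n_genes=12))
        assert not tracks_equal(s1.lrna, s2.lrna)

    def test_noise_seed_keeps_geometry_but_not_noise(self):
        a = simulate_tracks(SimulationConfig(seed=5, n_genes=12, noise_seed=10))
        b = simulate_tracks(SimulationConfig(seed=5, n_genes=12, noise_seed=11))
        pd.testing.assert_frame_equal(
            a.truth[["gene_id", "chrom", "strand", "start", "end"]],
            b.truth[["gene_id", "chrom", "strand", "start", "end"]],
        )
        assert not tracks_equal(a.lrna, b.lrna)


class TestGroundTruth:
    def test_steady_state_identity_by_construction(self, default_sim):
        truth = default_sim.truth
        np.testing.assert_allclose(
            truth["copies"], truth["init_rate"] * truth["half_life"] / np.log(2)
        )

    def test_genes_do_not_overlap(self, default_sim):
        for chrom in default_sim.annotation.chrom_sizes:
            genes = sorted(
                default_sim.annotation.on_chrom(chrom), key=lambda g: g.interval.start
            )
            for a, b in zip(genes, genes[1:]):
                assert a.interval.end <= b.interval.start

    def test_half_lives_within_configured_range(self, default_sim):
        lo, hi = default_sim.config.half_life_range
        assert default_sim.truth["half_life"].between(lo, hi).all()


class TestSignalModel:
    def body_mean(self, sim, track, gene_id):
        gene = sim.annotation[gene_id]
        arr = track.values[gene.strand][gene.chrom]
        bs = track.bin_size
        b0, b1 = gene.interval.start // bs, gene.interval.end // bs
        return arr[b0:b1].mean()

    def grid_sim(self, velocities, seed=13):
        params = pd.DataFrame(
            {"init_rate": 1.0, "velocity": velocities, "half_life": 60.0,
             "d_term": 2000.0, "length": 10_000}
        )
        return simulate_tracks(SimulationConfig(seed=seed, gene_params=params, n_ncrna=0))

    def test_doubling_velocity_halves_s5p_not_lrna(self):
        sim = self.grid_sim([1.0, 2.0] * 8)
        truth = sim.truth
        s5p_slow = np.mean([self.body_mean(sim, sim.s5p, g) for g in truth[truth.velocity == 1.0].gene_id])
        s5p_fast = np.mean([self.body_mean(sim, sim.s5p, g) for g in truth[truth.velocity == 2.0].gene_id])
        lrna_slow = np.mean([self.body_mean(sim, sim.lrna, g) for g in truth[truth.velocity == 1.0].gene_id])
        lrna_fast = np.mean([self.body_mean(sim, sim.lrna, g) for g in truth[truth.velocity == 2.0].gene_id])
        assert s5p_slow / s5p_fast == pytest.approx(2.0, rel=0.15)
        assert lrna_slow / lrna_fast == pytest.approx(1.0, rel=0.15)

    def test_zero_decay_length_drops_to_background_after_tes(self):
        params = pd.DataFrame(
            {"init_rate": [2.0] * 8, "velocity": 2.0, "half_life": 60.0,
             "d_term": 0.0, "length": 8000}
        )
        sim = simulate_tracks(SimulationConfig(seed=7, gene_params=params, n_ncrna=0))
        cfg = sim.config
        for row in sim.truth.itertuples(index=False):
            gene = sim.annotation[row.gene_id]
            arr = sim.lrna.values[gene.strand][gene.chrom]
            bs = cfg.bin_size
            if gene.strand == "-":
                tail = arr[gene.interval.start // bs - 10 : gene.interval.start // bs]
            else:
                tail = arr[gene.interval.end // bs : gene.interval.end // bs + 10]
            # pure background: expected 0.02 reads per bin
            assert tail.mean() < 1.0

    def test_fine_track_sums_to_coarse(self, default_sim):
        ratio = default_sim.config.bin_size // default_sim.config.fine_bin_size
        for chrom in default_sim.annotation.chrom_sizes:
            fine = default_sim.lrna_fine.values["+"][chrom]
            coarse = default_sim.lrna.values["+"][chrom]
            np.testing.assert_allclose(
                np.add.reduceat(fine, np.arange(0, len(fine), ratio)), coarse
            )


class TestSpikeins:
    def test_expected_ratios_across_replicates(self, rng):
        """Monte-Carlo means follow concentration x rate within 3 SE."""
        cfg = SimulationConfig(seed=0)
        reps = [simulate_spikeins(cfg, rng=rng) for _ in range(40)]
        mean_labeled = (
            pd.concat(reps).groupby("spikein_id", sort=False)["labeled"].mean()
        )
        # equal concentration, rates 100% vs 10% -> labeled ratio ~10:1
        ratio = mean_labeled["Sp2"] / mean_labeled["Sp5"]
        lam2 = mean_labeled["Sp2"]
        se = 3 * np.sqrt(lam2 / 40) / mean_labeled["Sp5"]
        assert ratio == pytest.approx(10.0, abs=max(3 * se, 0.3))

    def test_zero_rate_zero_contamination_gives_zero_labeled(self):
        cfg = SimulationConfig(seed=3, contamination=0.0)
        table = simulate_spikeins(cfg)
        assert (table.loc[table.labeling_rate == 0, "labeled"] == 0).all()

    def test_contamination_only_for_unlabeled_species(self):
        cfg = SimulationConfig(seed=3, contamination=0.01)
        table = simulate_spikeins(cfg)
        unl = table[table.labeling_rate == 0]
        # leakage ~ 1% of the species' labeled-library share
        assert unl["labeled"].sum() > 0
        assert unl["labeled"].sum() < 0.05 * table["labeled"].sum()

    def test_gene_counts_share_the_spike_mass_scale(self):
        spikeins, genes = simulate_labeling_counts(SimulationConfig(seed=8))
        # reads per gram must agree between spikes and genes in expectation
        from ttkinetics.kinetics import spikein_weights_per_cell

        w = spikein_weights_per_cell(SimulationConfig().spikein_design)
        spike_rpg = spikeins["total"].sum() / w.sum()
        gene_rpg = genes["total"].sum() / genes["weight_true"].sum()
        assert gene_rpg == pytest.approx(spike_rpg, rel=0.05)


class TestTimecourse:
    def test_clearing_geometry(self):
        params = pd.DataFrame(
            {"init_rate": [1.0] * 4, "velocity": 2.0, "half_life": 60.0,
             "d_term": 1000.0, "length": 30_000}
        )
        sim = simulate_tracks(SimulationConfig(seed=2, gene_params=params, n_ncrna=0))
        tracks, wf = simulate_cdk9i_timecourse(sim, [5.0, 10.0], t0=0.0, noiseless=True)
        # v = 2 kb/min, t = 10 -> cleared through TSS + 20 kb
        assert (wf.loc[wf.time == 10.0, "distance_bp"] == 20_000).all()
        gene = sim.annotation["gene000"]
        arr = tracks[1].values[gene.strand][gene.chrom]
        bs = sim.config.bin_size
        if gene.strand == "+":
            cleared = arr[gene.interval.start // bs : (gene.interval.start + 20_000) // bs]
        else:
            cleared = arr[(gene.interval.end - 20_000) // bs : gene.interval.end // bs]
        np.testing.assert_allclose(cleared, 0.0, atol=1e-12)

    def test_no_clearing_before_response_delay(self):
        sim = simulate_tracks(SimulationConfig(seed=2, n_genes=8))
        _, wf = simulate_cdk9i_timecourse(sim, [1.0, 5.0], t0=2.0, noiseless=True)
        assert (wf.loc[wf.time == 1.0, "distance_bp"] == 0.0).all()

    def test_unsorted_times_rejected(self, default_sim):
        with pytest.raises(ValueError):
            simulate_cdk9i_timecourse(default_sim, [5.0, 2.0])


def test_gene_params_override_used_verbatim():
    params = pd.DataFrame(
        {"init_rate": [1.0, 2.0], "velocity": [1.0, 3.0], "half_life": [20.0, 50.0],
         "d_term": [500.0, 1500.0], "length": [4000, 6000]}
    )
    sim = simulate_tracks(SimulationConfig(seed=0, gene_params=params))
    assert sim.truth["init_rate"].tolist() == [1.0, 2.0]
    assert sim.truth["velocity"].tolist() == [1.0, 3.0]


def test_missing_override_columns_rejected(rng):
    cfg = SimulationConfig(gene_params=pd.DataFrame({"init_rate": [1.0]}))
    with pytest.raises(ValueError):
        draw_gene_params(cfg, rng)
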