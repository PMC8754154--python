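"""Termination windows, CUSUM change points, change classes, R2 shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttkinetics.intervals import Gene, GenomeAnnotation, GenomicInterval
from ttkinetics.simulate import SimulationConfig, simulate_sequences, simulate_tracks
from ttkinetics.termination import (
    call_gene_termination,
    call_termination_site,
    classify_changes,
    gc_contrast,
    r2_decomposition,
    standardize_features,
    termination_window,
)


def split_point_oracle(values, pseudocount=1.0, log=True):
    """Exhaustive search over split points k of k * (mean(x_1..k) - mean(x))."""
    x = np.log(np.asarray(values, dtype=float) + pseudocount) if log else np.asarray(values, dtype=float)
    n = len(x)
    best_k, best = None, -np.inf
    for k in range(1, n + 1):
        contrast = k * (x[:k].mean() - x.mean())
        if contrast > best + 1e-12:
            best, best_k = contrast, k
    return best_k


class TestTerminationWindow:
    def annotation(self, next_tss=None):
        genes = [Gene("g1", GenomicInterval("chr1", 10_000, 20_000, "+"))]
        if next_tss is not None:
            genes.append(Gene("g2", GenomicInterval("chr1", next_tss, next_tss + 5_000, "+")))
        return GenomeAnnotation(genes, {"chr1": 200_000})

    def test_isolated_gene_gets_full_window(self):
        ann = self.annotation()
        win = termination_window(ann["g1"], ann)
        assert (win.start, win.end) == (20_000, 35_000)

    def test_clipped_at_next_tss(self):
        ann = self.annotation(next_tss=26_000)
        win = termination_window(ann["g1"], ann)
        assert (win.start, win.end) == (20_000, 26_000)

    def test_too_close_gene_excluded(self):
        ann = self.annotation(next_tss=20_500)
        assert termination_window(ann["g1"], ann) is None

    def test_minus_strand_window_extends_leftward(self):
        gene = Gene("g", GenomicInterval("chr1", 50_000, 60_000, "-"))
        ann = GenomeAnnotation([gene], {"chr1": 200_000})
        win = termination_window(gene, ann)
        assert (win.start, win.end) == (35_000, 50_000)


class TestCusum:
    def test_hand_example(self):
        # centered x = [1,1,1,-1,-1,-1] -> S = [1,2,3,2,1,0]; site after bin 3
        values = np.exp([2.0, 2.0, 2.0, 0.0, 0.0, 0.0]) - 1.0  # log1p inverse
        dist, cusum, flag = call_termination_site(values, scan_bin=50, pseudocount=1.0)
        np.testing.assert_allclose(cusum, [1, 2, 3, 2, 1, 0], atol=1e-12)
        assert dist == 150.0 and not flag

    def test_constant_coverage_flagged_at_start(self):
        dist, cusum, flag = call_termination_site(np.full(10, 3.0), scan_bin=50)
        assert flag and dist == 0.0
        np.testing.assert_allclose(cusum, 0.0, atol=1e-12)

    def test_matches_split_point_oracle_on_random_windows(self, rng):
        for _ in range(200):
            values = rng.poisson(rng.uniform(0.1, 20), size=300).astype(float)
            dist, _, flag = call_termination_site(values, scan_bin=50)
            if flag:
                continue
            assert dist == split_point_oracle(values) * 50

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 50), min_size=5, max_size=60))
    def test_oracle_agreement_property(self, counts):
        values = np.asarray(counts, dtype=float)
        dist, _, flag = call_termination_site(values, scan_bin=1)
        if not flag:
            assert dist == split_point_oracle(values)

    def test_called_distance_tracks_decay_length(self):
        """Genes with longer simulated read-through get longer called distances."""
        d_terms = np.repeat([500.0, 1000.0, 2000.0, 4000.0], 4)
        params = pd.DataFrame(
            {"init_rate": 1.0, "velocity": 2.0, "half_life": 60.0,
             "d_term": d_terms, "length": 8000}
        )
        sim = simulate_tracks(SimulationConfig(seed=9, gene_params=params))
        calls = call_gene_termination(sim.lrna_fine, sim.annotation)
        merged = calls.merge(sim.truth[["gene_id", "d_term"]], on="gene_id")
        from scipy.stats import spearmanr

        assert spearmanr(merged["distance"], merged["d_term"]).statistic >= 0.9


class TestClassifyChanges:
    def calls(self, distances):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(distances))], "distance": distances}
        )

    def test_shortening_extending_unchanged(self):
        ref = self.calls([5_000, 5_000, 5_000, 5_000])
        alt = self.calls([4_400, 5_200, 5_501, 4_500])
        out = classify_changes(ref, alt)
        assert out["change_class"].tolist() == [
            "shortening", "unchanged", "extending", "unchanged"
        ]

    def test_boundary_is_inclusive_for_unchanged(self):
        out = classify_changes(self.calls([1_000]), self.calls([1_500]))
        assert out["change_class"].iloc[0] == "unchanged"
        out = classify_changes(self.calls([1_000]), self.calls([1_501]))
        assert out["change_class"].iloc[0] == "extending"

    def test_missing_genes_counted(self):
        ref, alt = self.calls([1_000, 2_000]), self.calls([1_000])
        out = classify_changes(ref, alt)
        assert len(out) == 1 and out.attrs["n_excluded"] == 1


class TestGcContrast:
    def test_pure_gc_flank(self):
        assert gc_contrast("G" * 400, 200) == 1.0

    def test_balanced_sequence(self):
        assert gc_contrast("GCAT" * 100, 200) == 0.0

    def test_simulated_gc_patch_peaks_at_termination_site(self, default_sim):
        calls = call_gene_termination(default_sim.lrna_fine, default_sim.annotation)
        seqs = simulate_sequences(
            default_sim,
            site_distances=calls[["gene_id", "distance"]],
        )
        truth = default_sim.truth.set_index("gene_id")
        at_site, away = [], []
        for row in calls.itertuples(index=False):
            t = truth.loc[row.gene_id]
            seq = seqs[t.chrom]
            at_site.append(gc_contrast(seq, int(row.site)))
            away.append(gc_contrast(seq, int(row.site) + 5_000))
        assert np.mean(at_site) > np.mean(away) + 0.3


class TestR2Decomposition:
    def test_orthonormal_closed_form(self, rng):
        n = 4000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x1, x2 = (x1 - x1.mean()) / x1.std(), (x2 - x2.mean()) / x2.std()
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # orthogonalize
        x2 /= x2.std()
        y = 0.6 * x1 + 0.8 * x2
        shares, total = r2_decomposition(y, pd.DataFrame({"a": x1, "b": x2}))
        assert shares["a"] == pytest.approx(0.36, abs=1e-9)
        assert shares["b"] == pytest.approx(0.64, abs=1e-9)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_uncorrelated_feature_has_zero_share(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        x -= y * (y @ x) / (y @ y)  # exact zero correlation
        shares, _ = r2_decomposition(y, pd.DataFrame({"x": x}))
        assert shares["x"] == pytest.approx(0.0, abs=1e-9)

    def test_shares_sum_to_total_r2(self, rng):
        X = pd.DataFrame(rng.standard_normal((500, 5)), columns=list("abcde"))
        y = rng.standard_normal(500)
        shares, total = r2_decomposition(y, X)
        assert shares.sum() == pytest.approx(total, abs=1e-9)

    def test_standardize_features_contract(self, rng):
        raw = pd.DataFrame({"f": np.exp(rng.standard_normal(1000) * 2)})
        out = standardize_features(raw)
        assert out["f"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["f"].std(ddof=0) == pytest.approx(1.0, abs=1e-6)
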