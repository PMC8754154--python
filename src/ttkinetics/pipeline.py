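"""End-to-end orchestration of the synthetic demo pipeline.

``run_all`` executes simulate -> TU annotation -> kinetics -> velocity ->
termination -> QC on a synthetic experiment with known ground truth, writes
each stage's table as TSV plus a manifest recording seed and parameters,
and returns the results in memory. Re-running with the same config is
bit-identical for every deterministic stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import __version__
from .kinetics import (
    fit_labeling_model,
    fit_weight_model,
    predict_kinetics,
    size_factors,
    spikein_weights_per_cell,
    cross_contamination,
)
from .qc import conversion_enrichment, neighborhood_correlation
from .simulate import (
    SimulationConfig,
    simulate_cdk9i_timecourse,
    simulate_labeling_counts,
    simulate_neighbor_pairs,
    simulate_read_stats,
    simulate_tracks,
)
from .termination import call_gene_termination, classify_changes
from .tu import annotate_tus, quantify_tus
from .velocity import calibrate_velocity, fit_wavefronts, velocity_table


@dataclasses.dataclass
class RunConfig:
    """Parameters of one demo run; everything else uses stage defaults."""

    seed: int = 0
    outdir: str = "ttk_results"
    t_label: float = 5.0
    min_tu_bins: int = 1
    expression_floor: float = 10.0
    change_threshold: float = 500.0
    termination_pseudocount: float = 1.0
    timecourse_times: tuple = (2.0, 4.0, 6.0)
    sim_overrides: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _normalized_spike_counts(spikeins: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-normalize labeled/total spike counts (single sample: factors 1)."""
    out = spikeins.copy()
    for col, subset in (("total", None), ("labeled", spikeins["labeling_rate"] > 0)):
        mat = spikeins.pivot_table(index="spikein_id", columns="sample", values=col)
        if subset is not None:
            mat = mat.loc[spikeins.loc[subset, "spikein_id"].unique()]
        if mat.shape[1] > 1:
            sf = size_factors(mat)
            out[col] = out.apply(lambda r: r[col] / sf[r["sample"]], axis=1)
    return out


def run_kinetics_stage(config: SimulationConfig, seed: int):
    """Spike-in models + per-gene kinetics on count-level synthetic data."""
    rng = np.random.default_rng(seed)
    spikeins, genes = simulate_labeling_counts(config, rng=rng)
    spikeins_norm = _normalized_spike_counts(spikeins)
    rate_model = fit_labeling_model(spikeins_norm, seed=seed)
    weights = spikein_weights_per_cell(config.spikein_design)
    weight_model = fit_weight_model(spikeins_norm, weights)
    table = predict_kinetics(rate_model, weight_model, genes, t_label=config.t_label)
    table = table.merge(
        genes[["gene_id", "half_life_true", "theta_true", "copies_true"]], on="gene_id"
    )
    return spikeins, rate_model, weight_model, table


def run_all(config: RunConfig) -> dict:
    """Run every stage on one synthetic experiment; write TSVs under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimulationConfig(seed=config.seed, t_label=config.t_label,
                               **config.sim_overrides)
    results: dict = {}

    sim = simulate_tracks(sim_cfg)
    results["truth"] = sim.truth

    tus, hmm_model = annotate_tus(sim.lrna, sim.annotation, min_bins=config.min_tu_bins)
    tus = quantify_tus(tus, {"lrna": sim.lrna})
    results["tus"] = tus

    spikeins, rate_model, weight_model, kin = run_kinetics_stage(sim_cfg, config.seed)
    results["spikeins"] = spikeins
    results["kinetics"] = kin

    vel = velocity_table(sim.lrna, sim.s5p, sim.annotation,
                         min_reads=config.expression_floor)
    tracks, _ = simulate_cdk9i_timecourse(sim, list(config.timecourse_times), t0=1.0)
    wavefronts = fit_wavefronts(tracks, list(config.timecourse_times), sim.annotation)
    scale, vel = calibrate_velocity(vel, wavefronts, min_matched=10)
    vel = vel.merge(sim.truth[["gene_id", "velocity"]], on="gene_id")
    results["velocity"] = vel
    results["velocity_scale"] = scale

    calls_ref = call_gene_termination(
        sim.lrna_fine, sim.annotation, pseudocount=config.termination_pseudocount
    )
    alt_cfg = dataclasses.replace(sim_cfg, seed=sim_cfg.seed + 1)
    alt_params = sim.truth[["length", "init_rate", "velocity", "half_life", "d_term"]].copy()
    alt_params["d_term"] = alt_params["d_term"] / 2.0
    alt_cfg = dataclasses.replace(alt_cfg, gene_params=alt_params)
    sim_alt = simulate_tracks(alt_cfg)
    calls_alt = call_gene_termination(
        sim_alt.lrna_fine, sim_alt.annotation, pseudocount=config.termination_pseudocount
    )
    changes = classify_changes(calls_ref, calls_alt, threshold=config.change_threshold)
    results["termination"] = calls_ref
    results["termination_changes"] = changes

    rng = np.random.default_rng(config.seed + 3)
    lrna_stats, frna_stats = simulate_read_stats(rng=rng)
    pairs = simulate_neighbor_pairs(rng=rng)
    qc = {
        "conversion_enrichment": conversion_enrichment(lrna_stats, frna_stats),
        "cross_contamination_pct": cross_contamination(spikeins)[0],
        "velocity_truth_spearman": float(
            spearmanr(vel.dropna(subset=["vhat"])["vhat"],
                      vel.dropna(subset=["vhat"])["velocity"]).statistic
        ),
    }
    results["qc"] = qc
    results["neighborhood"] = neighborhood_correlation(
        pairs, np.linspace(-100_000, 100_000, 9), stratify_by="relative_strand"
    )

    for name in ("truth", "tus", "spikeins", "kinetics", "velocity",
                 "termination", "termination_changes", "neighborhood"):
        results[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "velocity_scale_kb_min_per_unit": scale,
        "qc": qc,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "sim_overrides"
        },
        "hmm_rates": list(map(float, hmm_model.rates)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
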