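"""Relative elongation velocity, wavefront calibration and pausing.

The LRNA / Pol II S5p density ratio is a relative velocity; wavefront
regressions on a simulated CDK9-inhibition time course anchor it to kb/min.
"""

import numpy as np
from scipy.stats import spearmanr

from ttkinetics.simulate import SimulationConfig, simulate_cdk9i_timecourse, simulate_tracks
from ttkinetics.velocity import calibrate_velocity, fit_wavefronts, pausing_time, velocity_table

sim = simulate_tracks(SimulationConfig(seed=7))
vel = velocity_table(sim.lrna, sim.s5p, sim.annotation)

times = [2.0, 4.0, 6.0]  # minutes after CDK9 inhibition
tracks, _ = simulate_cdk9i_timecourse(sim, times, t0=1.0)
wavefronts = fit_wavefronts(tracks, times, sim.annotation)
scale, vel = calibrate_velocity(vel, wavefronts, min_matched=10)

merged = vel.merge(sim.truth[["gene_id", "velocity"]], on="gene_id").dropna(subset=["vhat"])
rho = spearmanr(merged["vhat"], merged["velocity"]).statistic
rel = np.abs(merged["v_scaled_kb_min"] - merged["velocity"]) / merged["velocity"]
print(f"{len(merged)} expressed genes; calibration scale {scale:.2f} kb/min per ratio unit")
print(f"median velocity {merged['v_scaled_kb_min'].median():.2f} kb/min "
      f"(truth {merged['velocity'].median():.2f})")
print(f"rank agreement with truth: Spearman rho = {rho:.3f}; "
      f"median relative error {100 * rel.median():.1f}%")

v_med = merged["v_scaled_kb_min"].median()
print(f"a 52-bp pausing interval at a 4-fold dwell takes "
      f"{pausing_time(52, v_med / sim.config.dwell_factor):.0f} s at the median gene")
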