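# ttkinetics

Transcription kinetics from TT-seq and quantitative Pol II ChIP.

A brief 4-thiouridine (4sU) pulse labels newly synthesized RNA; TT-seq
sequences the purified labeled fraction (LRNA) alongside fragmented total
RNA (FRNA), and quantitative (MINUTE-style) Pol II S5p ChIP measures
chromatin-engaged polymerase occupancy on a comparable scale across
samples. Combining the three readouts, `ttkinetics` estimates — per gene —
how much RNA is made, how fast it turns over, how fast Pol II elongates,
how long it pauses, and where it terminates. The package is aimed at
computational genomics groups analyzing nascent-transcription experiments,
and every estimator ships with a synthetic-data generator that knows the
ground truth, so recovery is tested end to end.

## What it computes

**Transcription units.** Binned LRNA coverage (200-bp bins, per strand) is
segmented with a two-state hidden Markov model with Poisson emissions
(optionally overdispersed via a log-normal rate mixture). Active runs become
TU fragments; fragments overlapping a gene's exons are joined into one mRNA
TU, and the rest are classified by the position of their 5′ end relative to
nearby genes: uaRNA (antisense, within 1 kb upstream of a TSS), conRNA
(antisense, within 1 kb downstream of a TSS), asRNA (antisense, inside the
body), dsRNA / daRNA (sense / antisense within 1 kb past the TES), or
intergenic.

**RNA synthesis kinetics.** Six ERCC spike-in species at known
concentrations and labeling rates (100/100/10/10/0/0 %) calibrate two
log-linear models fitted on size-factor-normalized counts:

    log2(r) ~ log2(X_F) + log2(X_L)      (labeled species)
    log2(w) ~ log2(X_F) + log2(X_L)      (all species)

predicting each transcript's labeling rate θ and mass per cell w. Under
exponential turnover θ = 1 − e^(−k·t_label), so t½ = ln 2 / k; copy number
c = w·N_A / (L·340 g/mol); synthesis rate s = θ·c / t_label (copies per
cell per minute).

**Elongation velocity and pausing.** LRNA density is proportional to
initiation rate I, Pol II occupancy to I/v, so v̂ = RPK_LRNA / RPK_S5p is a
relative elongation velocity. Wavefront regressions on a CDK9-inhibition
time course (cleared distance ~ time; the slope is velocity, the intercept
absorbs response delay) anchor v̂ to kb/min by a median ratio. The pausing
index is pause-interval S5p density over gene-body (TSS+500..+1500)
density; pausing time is pause length divided by local velocity.

**Termination sites.** In the up-to-15-kb window past each gene's last
exon end (clipped at the next downstream TSS), the cumulative sum of
mean-centered log LRNA coverage peaks at the position of the strongest
before/after density contrast — the called termination site. Sites from
two conditions are classified shortening / extending / unchanged with a
±500 bp rule; GC−AT contrast at the site and a through-the-origin R²
decomposition relate termination distance to sequence and chromatin
features.

## Worked example

```python
from ttkinetics.simulate import SimulationConfig, simulate_tracks, simulate_cdk9i_timecourse
from ttkinetics.velocity import velocity_table, fit_wavefronts, calibrate_velocity

sim = simulate_tracks(SimulationConfig(seed=7))          # 60 genes, known truth
vel = velocity_table(sim.lrna, sim.s5p, sim.annotation)  # v-hat per gene
times = [2.0, 4.0, 6.0]
tracks, _ = simulate_cdk9i_timecourse(sim, times, t0=1.0)
scale, vel = calibrate_velocity(vel, fit_wavefronts(tracks, times, sim.annotation),
                                min_matched=10)
```

Running `python examples/03_elongation_velocity.py` prints:

```
60 expressed genes; calibration scale 1.63 kb/min per ratio unit
median velocity 1.97 kb/min (truth 1.99)
rank agreement with truth: Spearman rho = 0.989; median relative error 2.7%
```

i.e. the calibrated velocities recover the simulated per-gene elongation
rates to within a few percent at a realistic 2×10⁵-read depth. The other
examples cover TU annotation (`01`), spike-in kinetics (`02`; e.g. median
half-life 56 min with 8.6% median error against truth), termination-site
shifts between conditions (`04`) and sequencing QC plus neighborhood
co-regulation (`05`). A one-command end-to-end run with a results manifest:

```bash
ttk demo --seed 7 --outdir ttk_demo
```

## Layout

- `src/ttkinetics/` — `tracks`/`io` (coverage, formats), `simulate`
  (ground-truth generator), `hmm`/`tu` (segmentation and classification),
  `kinetics`, `velocity`, `termination`, `qc`, `pipeline`/`cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, assumptions, parameter defaults, numerical
  choices and known limitations.
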