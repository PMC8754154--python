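"""Synthetic genomes, coverage tracks, spike-ins and time courses with known truth.

The generator emulates the statistical structure of a TT-seq + quantitative
Pol II ChIP experiment on a toy genome so that every downstream estimator
has a parameter-recovery test:

- labeled RNA (LRNA): uniform over the gene body, proportional to the
  labeled pool c * (1 - e^(-k t_label)); exponential post-TES read-through
  decay with per-gene length d_term; Poisson read sampling per bin.
- total RNA (FRNA): proportional to copy number c over exons.
- Pol II S5p: proportional to I / v over the body, elevated by a dwell
  factor inside the promoter-proximal pausing interval, same post-TES decay.
- spike-ins: six species at the design concentrations and labeling rates
  (100/100/10/10/0/0 %), counts proportional to mass x labeling fraction,
  with a small unlabeled-into-labeled-library contamination rate.
- CDK9-inhibition time course: body signal cleared over [TSS, TSS + v (t - t0)),
  with fractional clearing of the boundary bin.

Ground truth (per-gene I, v, half-life, copy number, decay length, pausing
time) is returned alongside; copy number = I * half-life / ln 2 holds
exactly by construction. A fixed seed makes every output reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import Gene, GenomeAnnotation, GenomicInterval
from .kinetics import (
    AVOGADRO,
    DEFAULT_SPIKEIN_DESIGN,
    NT_MASS_G_PER_MOL,
    spikein_weights_per_cell,
)
from .tracks import CoverageTrack

LN2 = math.log(2.0)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults are a 60-gene toy genome on two chromosomes at roughly 2e5
    read pairs per library: large enough for stable parameter recovery,
    small enough that full-pipeline runs finish in seconds.
    """

    n_genes: int = 60
    n_chroms: int = 2
    gene_length_log_mean: float = math.log(8000.0)
    gene_length_log_sd: float = 0.5
    min_gene_length: int = 3000
    gap_range: tuple[int, int] = (25_000, 40_000)
    # per-gene kinetic parameters (log-normal draws)
    init_rate_log_mean: float = math.log(0.5)  # events/min
    init_rate_log_sd: float = 0.7
    velocity_log_mean: float = math.log(2.0)  # kb/min
    velocity_log_sd: float = 0.5
    half_life_log_mean: float = math.log(60.0)  # min
    half_life_log_sd: float = 0.8
    half_life_range: tuple[float, float] = (5.0, 500.0)
    d_term_log_mean: float = math.log(2000.0)  # bp
    d_term_log_sd: float = 0.4
    pause_len: int = 200  # bp
    dwell_factor: float = 4.0
    t_label: float = 5.0  # min of 4sU labeling
    # tracks
    bin_size: int = 200
    fine_bin_size: int = 50  # termination-scan resolution
    lrna_depth: float = 2e5
    frna_depth: float = 2e5
    s5p_depth: float = 2e5
    background_per_bin: float = 0.02  # expected stray reads per 200-bp bin
    n_ncrna: int = 10
    ncrna_length: tuple[int, int] = (1000, 3000)
    # spike-ins
    spikein_design: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_SPIKEIN_DESIGN.copy()
    )
    spike_depth_labeled: float = 5e4
    spike_depth_total: float = 5e4
    contamination: float = 0.001
    seed: int = 0
    noise_seed: int | None = None  # decouples read noise from gene placement
    # optional explicit per-gene parameter overrides
    gene_params: pd.DataFrame | None = None

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimResult:
    """Tracks, annotation and ground truth from one simulated experiment."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    lrna: CoverageTrack
    lrna_fine: CoverageTrack
    frna: CoverageTrack
    s5p: CoverageTrack
    truth: pd.DataFrame
    ncrnas: pd.DataFrame
    expected: dict  # noiseless per-bin expected weights


def draw_gene_params(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene kinetic parameters: explicit overrides or log-normal draws."""
    if config.gene_params is not None:
        df = config.gene_params.copy()
        required = {"init_rate", "velocity", "half_life", "d_term"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene_params missing columns {sorted(missing)}")
        if "length" not in df.columns:
            df["length"] = np.full(len(df), 8000)
        return df.reset_index(drop=True)
    n = config.n_genes
    lengths = np.maximum(
        rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, n),
        config.min_gene_length,
    )
    half_life = np.clip(
        rng.lognormal(config.half_life_log_mean, config.half_life_log_sd, n),
        *config.half_life_range,
    )
    return pd.DataFrame(
        {
            "length": lengths,
            "init_rate": rng.lognormal(config.init_rate_log_mean, config.init_rate_log_sd, n),
            "velocity": rng.lognormal(config.velocity_log_mean, config.velocity_log_sd, n),
            "half_life": half_life,
            "d_term": rng.lognormal(config.d_term_log_mean, config.d_term_log_sd, n),
        }
    )


def _place_genes(
    params: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Lay genes head-to-tail with intergenic gaps; snap to bin boundaries.

    Genes never overlap (any strand), so ground truth stays unambiguous and
    each termination window is clean read-through.
    """
    bs = config.bin_size
    rows = []
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chroms)}
    chroms = list(cursors)
    genes: list[Gene] = []
    for i, p in params.iterrows():
        chrom = chroms[i % len(chroms)]
        gap = int(rng.integers(*config.gap_range) // bs * bs)
        start = cursors[chrom] + gap
        length = int(max(p.length // bs, config.min_gene_length // bs) * bs)
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, start, end, strand)
        exon_len = max(int(length // 4 // bs * bs), bs)
        exons = [
            GenomicInterval(chrom, start, start + exon_len, strand),
            GenomicInterval(chrom, end - exon_len, end, strand),
        ]
        gene_id = f"gene{i:03d}"
        genes.append(Gene(gene_id, iv, exons))
        cursors[chrom] = end
        rows.append((gene_id, chrom, strand, iv.start, iv.end, length))
    chrom_sizes = {c: cur + config.gap_range[1] for c, cur in cursors.items()}
    placed = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "start", "end", "length"]
    )
    return GenomeAnnotation(genes, chrom_sizes), placed


def _place_ncrnas(
    annotation: GenomeAnnotation,
    placed: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Inject non-coding TUs with their own expression level.

    Kinds cycle through upstream-antisense (5' end within 1 kb upstream of a
    host TSS, antisense), cis-antisense (5' end inside the host body,
    antisense) and intergenic (>=15 kb from any TES/TSS, so termination
    windows stay clean). ``weight`` is the uniform per-bp LRNA weight, on
    the same scale as the genes' copies * theta.
    """
    bs = config.bin_size
    kinds = ["uaRNA", "asRNA", "intergenic"]
    rows = []
    prev_end = {c: 0 for c in annotation.chrom_sizes}
    k = 0
    for row in placed.itertuples(index=False):
        if k >= config.n_ncrna:
            break
        gene = annotation[row.gene_id]
        gap = row.start - prev_end[row.chrom]
        prev_end[row.chrom] = row.end
        kind = kinds[k % len(kinds)]
        length = int(rng.integers(*config.ncrna_length) // bs * bs)
        anti = "-" if gene.strand == "+" else "+"
        if kind == "uaRNA":
            # antisense, 5' end one bin upstream of the host TSS
            if gene.strand == "+":
                start, end = gene.tss - bs - length, gene.tss - bs
            else:
                start, end = gene.tss + bs, gene.tss + bs + length
            strand = anti
        elif kind == "asRNA":
            length = min(length, (len(gene.interval) // 2) // bs * bs)
            mid = (row.start + row.end) // 2 // bs * bs
            # keep the antisense 5' end >1 kb from the host TSS (conRNA zone)
            if gene.strand == "+":
                start, end = mid - length, mid
            else:
                start, end = mid, mid + length
            strand = anti
        else:  # intergenic, only in wide gaps, clear of termination windows
            if gap < 34_000 or row.start - 16_000 - length < 0:
                continue
            start, end = row.start - 16_000 - length, row.start - 16_000
            strand = "+" if rng.random() < 0.5 else "-"
        if start < 0:
            continue
        rows.append(
            (f"nc{k:03d}", row.chrom, int(start), int(end), strand, kind,
             row.gene_id if kind != "intergenic" else None,
             rng.lognormal(math.log(0.5), 0.5))
        )
        k += 1
    return pd.DataFrame(
        rows,
        columns=["nc_id", "chrom", "start", "end", "strand", "kind",
                 "host_gene_id", "weight"],
    )


def _add_tail(arr: np.ndarray, tes_bin_edge: float, direction: int, level: float,
              d_term: float, bs: int) -> None:
    """Exponential post-TES decay, per-bin midpoint approximation."""
    if d_term <= 0:  # no read-through: signal drops to background at the TES
        return
    n_tail = min(int(6 * d_term // bs) + 1, len(arr))
    for j in range(n_tail):
        x_mid = (j + 0.5) * bs
        b = int(tes_bin_edge) + direction * j + (0 if direction > 0 else -1)
        if 0 <= b < len(arr):
            arr[b] += level * math.exp(-x_mid / d_term)


def _expected_weights(
    annotation: GenomeAnnotation, truth: pd.DataFrame, config: SimulationConfig, bs: int,
    ncrnas: pd.DataFrame | None = None,
) -> dict[str, dict[str, dict[str, np.ndarray]]]:
    """Unnormalized expected per-bin weights for LRNA / FRNA / S5p."""
    weights = {
        lib: {
            s: {c: np.zeros(-(-size // bs)) for c, size in annotation.chrom_sizes.items()}
            for s in ("+", "-")
        }
        for lib in ("lrna", "frna", "s5p")
    }
    by_id = {r.gene_id: r for r in truth.itertuples(index=False)}
    for gene in annotation:
        t = by_id[gene.gene_id]
        b0, b1 = gene.interval.start // bs, gene.interval.end // bs
        strand = gene.strand
        chrom = gene.chrom
        m_lrna = t.copies * t.theta  # labeled pool per bp
        m_s5p = t.init_rate / t.velocity  # occupancy per bp
        lw = weights["lrna"][strand][chrom]
        sw = weights["s5p"][strand][chrom]
        lw[b0:b1] += m_lrna * bs
        sw[b0:b1] += m_s5p * bs
        # promoter-proximal pause: dwell-factor elevation over pause_len at the TSS
        pause_bins = max(config.pause_len // bs, 1)
        if strand == "-":
            sw[b1 - pause_bins : b1] += m_s5p * bs * (t.dwell_factor - 1.0)
        else:
            sw[b0 : b0 + pause_bins] += m_s5p * bs * (t.dwell_factor - 1.0)
        # post-TES exponential read-through
        direction = 1 if strand != "-" else -1
        tes_edge = b1 if strand != "-" else b0
        _add_tail(lw, tes_edge, direction, m_lrna * bs, t.d_term, bs)
        _add_tail(sw, tes_edge, direction, m_s5p * bs, t.d_term, bs)
        fw = weights["frna"][strand][chrom]
        for ex in gene.exons:
            fw[ex.start // bs : ex.end // bs] += t.copies * bs
    if ncrnas is not None:
        for nc in ncrnas.itertuples(index=False):
            arr = weights["lrna"][nc.strand][nc.chrom]
            arr[nc.start // bs : nc.end // bs] += nc.weight * bs
    return weights


def _sample_track(
    weights: dict[str, dict[str, np.ndarray]],
    chrom_sizes: dict[str, int],
    bs: int,
    depth: float,
    background_per_bin: float,
    rng: np.random.Generator,
    library: str,
    noiseless: bool = False,
) -> CoverageTrack:
    total_w = sum(arr.sum() for d in weights.values() for arr in d.values())
    scale = depth / total_w if total_w > 0 else 0.0
    values = {}
    for strand, per_chrom in weights.items():
        values[strand] = {}
        for chrom, arr in per_chrom.items():
            lam = np.maximum(arr * scale + background_per_bin, 0.0)
            values[strand][chrom] = lam if noiseless else rng.poisson(lam).astype(float)
    return CoverageTrack(dict(chrom_sizes), bs, values, library=library)


def simulate_tracks(config: SimulationConfig | None = None) -> SimResult:
    """Simulate LRNA / FRNA / Pol II S5p tracks plus annotation and truth.

    LRNA is drawn once at the fine (termination-scan) resolution and summed
    to the coarse TU-calling bins, so the two views are consistent Poisson
    samples of one experiment. Fixed seed + config give identical output.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    params = draw_gene_params(config, rng)
    annotation, placed = _place_genes(params, config, rng)
    truth = pd.concat([placed.reset_index(drop=True), params.drop(columns=["length"])], axis=1)
    k = LN2 / truth["half_life"]
    truth["theta"] = 1.0 - np.exp(-k * config.t_label)
    truth["copies"] = truth["init_rate"] * truth["half_life"] / LN2
    truth["dwell_factor"] = config.dwell_factor
    truth["pause_len"] = config.pause_len
    # true pausing time: pause_len at velocity v / dwell_factor, in seconds
    truth["pausing_time_s"] = (
        config.pause_len / 1000.0 / (truth["velocity"] / truth["dwell_factor"]) * 60.0
    )

    ncrnas = _place_ncrnas(annotation, placed, config, rng)
    if config.noise_seed is not None:
        rng = np.random.default_rng(config.noise_seed)
    fine = config.fine_bin_size
    if config.bin_size % fine != 0:
        raise ValueError("bin_size must be a multiple of fine_bin_size")
    w_fine = _expected_weights(annotation, truth, config, fine, ncrnas)
    w_coarse = _expected_weights(annotation, truth, config, config.bin_size, ncrnas)
    ratio = config.bin_size // fine
    bg_fine = config.background_per_bin / ratio
    lrna_fine = _sample_track(
        w_fine["lrna"], annotation.chrom_sizes, fine, config.lrna_depth,
        bg_fine, rng, "LRNA",
    )
    # coarse LRNA = sum of fine bins (consistent single experiment)
    coarse_vals = {
        s: {c: arr.reshape(-1, ratio).sum(axis=1) if len(arr) % ratio == 0
            else np.add.reduceat(arr, np.arange(0, len(arr), ratio))
            for c, arr in d.items()}
        for s, d in lrna_fine.values.items()
    }
    lrna = CoverageTrack(dict(annotation.chrom_sizes), config.bin_size,
                         coarse_vals, library="LRNA")
    frna = _sample_track(
        w_coarse["frna"], annotation.chrom_sizes, config.bin_size,
        config.frna_depth, config.background_per_bin, rng, "FRNA",
    )
    s5p = _sample_track(
        w_coarse["s5p"], annotation.chrom_sizes, config.bin_size,
        config.s5p_depth, config.background_per_bin, rng, "PolII_S5p",
    )
    expected = {"fine_weights": w_fine, "coarse_weights": w_coarse}
    return SimResult(config, annotation, lrna, lrna_fine, frna, s5p, truth, ncrnas, expected)


def expected_lrna_fine(sim: SimResult) -> CoverageTrack:
    """Noiseless expected LRNA track at the fine resolution."""
    cfg = sim.config
    ratio = cfg.bin_size // cfg.fine_bin_size
    return _sample_track(
        sim.expected["fine_weights"]["lrna"], sim.annotation.chrom_sizes,
        cfg.fine_bin_size, cfg.lrna_depth, cfg.background_per_bin / ratio,
        np.random.default_rng(0), "LRNA", noiseless=True,
    )


def simulate_spikeins(
    config: SimulationConfig | None = None,
    n_samples: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Poisson spike-in counts for the six-species design, per sample.

    Total counts are proportional to species mass; labeled counts to mass x
    (labeling rate + contamination x (1 - rate)). With contamination and
    rate both zero, labeled counts are exactly zero. Per-sample depth jitter
    makes multi-sample size factors non-trivial.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    design = config.spikein_design
    share = (design["concentration"] / design["concentration"].sum()).to_numpy()
    rates = design["labeling_rate"].to_numpy()
    rows = []
    for s in range(n_samples):
        jitter = rng.lognormal(0.0, 0.3) if n_samples > 1 else 1.0
        lam_total = config.spike_depth_total * jitter * share
        eff_rate = rates + config.contamination * (1.0 - rates)
        lam_labeled = config.spike_depth_labeled * jitter * share * eff_rate
        total = rng.poisson(lam_total)
        labeled = np.where(lam_labeled > 0, rng.poisson(lam_labeled), 0)
        for i, sp in enumerate(design.itertuples(index=False)):
            rows.append(
                (f"sample{s + 1}", sp.spikein_id, sp.concentration, sp.labeling_rate,
                 int(labeled[i]), int(total[i]))
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "spikein_id", "concentration", "labeling_rate", "labeled", "total"],
    )


def simulate_labeling_counts(
    config: SimulationConfig | None = None,
    n_genes: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level labeled/total counts tied to the spike-in mass scale.

    Both spike-ins and genes are sequenced at a common reads-per-gram depth
    in each library, so the spike-in-trained labeling and weight models are
    exactly the right calibration for the genes. Returns (spikeins, genes);
    genes carry their true theta / half-life / copies / weight.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n_genes if n_genes is not None else config.n_genes
    spike_w = spikein_weights_per_cell(config.spikein_design)
    design = config.spikein_design
    rates = design["labeling_rate"].to_numpy()
    w_arr = spike_w.to_numpy()
    d_total = config.spike_depth_total / w_arr.sum()  # reads per gram, FRNA library
    d_labeled = config.spike_depth_labeled / w_arr.sum()
    eff = rates + config.contamination * (1.0 - rates)
    sp_total = rng.poisson(w_arr * d_total)
    lam_sp_lab = w_arr * d_labeled * eff
    sp_labeled = np.where(lam_sp_lab > 0, rng.poisson(lam_sp_lab), 0)
    spikeins = pd.DataFrame(
        {
            "sample": "sample1",
            "spikein_id": design["spikein_id"],
            "concentration": design["concentration"],
            "labeling_rate": rates,
            "labeled": sp_labeled,
            "total": sp_total,
        }
    )
    half_life = np.clip(
        rng.lognormal(config.half_life_log_mean, config.half_life_log_sd, n),
        *config.half_life_range,
    )
    theta = 1.0 - np.exp(-LN2 / half_life * config.t_label)
    copies = rng.lognormal(math.log(10.0), 1.0, n)
    lengths = rng.lognormal(math.log(2000.0), 0.5, n)
    weight = copies * lengths * NT_MASS_G_PER_MOL / AVOGADRO
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i:03d}" for i in range(n)],
            "eff_length": lengths,
            "half_life_true": half_life,
            "theta_true": theta,
            "copies_true": copies,
            "weight_true": weight,
            "total": rng.poisson(weight * d_total),
            "labeled": rng.poisson(weight * theta * d_labeled),
        }
    )
    return spikeins, genes


def simulate_cdk9i_timecourse(
    sim: SimResult,
    times: list[float],
    t0: float | np.ndarray = 1.0,
    depth: float | None = None,
    noiseless: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[list[CoverageTrack], pd.DataFrame]:
    """Occupancy-like tracks after CDK9 inhibition at each time point.

    At time t the body signal of each gene is cleared on
    [TSS, TSS + v * max(0, t - t0)) (capped at the TES), with the boundary
    bin cleared fractionally so the wavefront position is recoverable to
    sub-bin precision. Returns the tracks and a gene x time table of true
    wavefront distances (bp).
    """
    if sorted(times) != list(times) or len(times) < 2:
        raise ValueError("times must be >= 2 sorted values")
    cfg = sim.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    t0_arr = np.broadcast_to(np.asarray(t0, dtype=float), (len(sim.truth),))
    bs = cfg.bin_size
    tracks, truth_rows = [], []
    for t in times:
        weights = {
            s: {c: np.zeros(-(-size // bs)) for c, size in sim.annotation.chrom_sizes.items()}
            for s in ("+", "-")
        }
        for (idx, row), delay in zip(sim.truth.iterrows(), t0_arr):
            gene = sim.annotation[row.gene_id]
            cleared = min(row.velocity * 1000.0 * max(0.0, t - delay), row.length)
            truth_rows.append((row.gene_id, t, cleared))
            arr = weights[gene.strand][gene.chrom]
            level = row.init_rate / row.velocity * bs
            b0, b1 = gene.interval.start // bs, gene.interval.end // bs
            arr[b0:b1] += level
            # clear [TSS, TSS + cleared) in gene orientation, fractional edge
            n_full, frac = divmod(cleared / bs, 1.0)
            n_full = int(n_full)
            if gene.strand == "-":
                arr[b1 - n_full : b1] -= level
                if n_full < b1 - b0 and frac > 0:
                    arr[b1 - n_full - 1] -= level * frac
            else:
                arr[b0 : b0 + n_full] -= level
                if n_full < b1 - b0 and frac > 0:
                    arr[b0 + n_full] -= level * frac
        track = _sample_track(
            weights, sim.annotation.chrom_sizes, bs,
            depth if depth is not None else cfg.s5p_depth,
            0.0 if noiseless else cfg.background_per_bin, rng, "GRO",
            noiseless=noiseless,
        )
        tracks.append(track)
    wavefronts = pd.DataFrame(truth_rows, columns=["gene_id", "time", "distance_bp"])
    return tracks, wavefronts


def simulate_sequences(
    sim: SimResult,
    site_distances: pd.DataFrame | None = None,
    gc_background: float = 0.4,
    gc_patch: float = 0.9,
    patch_len: int = 200,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Random genome sequence with a GC-rich patch at each termination site.

    ``site_distances`` maps gene_id to a termination distance (bp past the
    TES); defaults to each gene's d_term. The patch is centered on the site.
    """
    rng = rng if rng is not None else np.random.default_rng(sim.config.seed + 2)
    seqs = {}
    patches = []
    if site_distances is None:
        site_distances = sim.truth[["gene_id", "d_term"]].rename(columns={"d_term": "distance"})
    dist_by_id = dict(zip(site_distances["gene_id"], site_distances["distance"]))
    for row in sim.truth.itertuples(index=False):
        if row.gene_id not in dist_by_id:
            continue
        d = dist_by_id[row.gene_id]
        site = int(row.end + d) if row.strand != "-" else int(row.start - d)
        patches.append((row.chrom, site))
    for chrom, size in sim.annotation.chrom_sizes.items():
        p_gc = np.full(size, gc_background / 2.0)  # per-base prob of G and of C
        for c, site in patches:
            if c == chrom:
                lo, hi = max(0, site - patch_len // 2), min(size, site + patch_len // 2)
                p_gc[lo:hi] = gc_patch / 2.0
        u = rng.random(size)
        bases = np.where(
            u < p_gc, "G", np.where(u < 2 * p_gc, "C", np.where(u < p_gc + 0.5, "A", "T"))
        )
        seqs[chrom] = "".join(bases)
    return seqs


def simulate_read_stats(
    n_reads: int = 20_000,
    mean_t_positions: float = 15.0,
    conversion_labeled: float = 0.1,
    conversion_background: float = 0.001,
    labeled_fraction_lrna: float = 0.95,
    spliced_fraction: float = 0.25,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read T>C conversion and splice-gap stats for LRNA and FRNA.

    LRNA reads mostly come from 4sU-labeled molecules and convert T>C at
    ``conversion_labeled`` per T position; FRNA reads convert only at the
    sequencing-error background. Returns (lrna_stats, frna_stats).
    """
    rng = rng if rng is not None else np.random.default_rng(0)

    def one(lib: str, labeled_frac: float) -> pd.DataFrame:
        n_t = rng.poisson(mean_t_positions, n_reads)
        labeled = rng.random(n_reads) < labeled_frac
        rate = np.where(labeled, conversion_labeled, conversion_background)
        conv = rng.binomial(n_t, rate)
        gap = rng.random(n_reads) < spliced_fraction
        return pd.DataFrame(
            {"n_t_positions": n_t, "n_t_to_c": conv, "has_splice_gap": gap, "library": lib}
        )

    return one("LRNA", labeled_fraction_lrna), one("FRNA", 0.0)


def simulate_neighbor_pairs(
    n_pairs: int = 2000,
    max_distance: int = 100_000,
    coupling_at_zero: float = 0.8,
    coupling_decay_bp: float = 30_000.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gene/neighbor log2FC pairs with distance-decaying co-regulation.

    The neighbor's log2FC correlates with the gene's with coefficient
    rho(d) = coupling_at_zero * exp(-|d| / coupling_decay_bp).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    dist = rng.integers(-max_distance, max_distance, n_pairs)
    rho = coupling_at_zero * np.exp(-np.abs(dist) / coupling_decay_bp)
    gene_fc = rng.normal(0.0, 1.0, n_pairs)
    neigh_fc = rho * gene_fc + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, n_pairs)
    return pd.DataFrame(
        {
            "gene_log2fc": gene_fc,
            "neighbor_log2fc": neigh_fc,
            "distance": dist,
            "relative_strand": rng.choice(["sense", "antisense"], n_pairs),
            "is_enhancer": rng.random(n_pairs) < 0.3,
        }
    )
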