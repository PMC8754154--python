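"""Relative elongation velocity, calibration, pausing index and time.

The number of polymerases released into elongation per unit time is read out
by labeled-RNA (TT-seq) density, which is proportional to initiation rate I;
Pol II occupancy is proportional to I / v. Their ratio

    v-hat = RPK_LRNA / RPK_PolII-S5p

is therefore a relative elongation velocity, comparable across genes and
conditions as long as both tracks are quantitatively normalized (LRNA by
spike-ins, Pol II by its quantitative ChIP scaling). Absolute wavefront
velocities from a CDK9-inhibition time course (OLS of cleared distance on
time) anchor v-hat to kb/min via a median ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans

from .intervals import Gene, GenomeAnnotation, GenomicInterval
from .tracks import CoverageTrack, interval_density, resize_profile

DEFAULT_BODY_OFFSET = 500  # bp past the TSS excluded from the gene body
PAUSE_BODY_INTERVAL = (500, 1500)  # gene-body window for the pausing index


def estimate_velocity(
    lrna: CoverageTrack,
    s5p: CoverageTrack,
    region: GenomicInterval,
    min_rpk: float = 0.0,
) -> float:
    """v-hat = RPK_LRNA / RPK_S5p over ``region``; NaN when under-expressed.

    An S5p density at or below ``min_rpk`` makes the ratio undefined
    (missing), never zero.
    """
    rpk_l = interval_density(lrna, region)
    rpk_p = interval_density(s5p, region)
    if rpk_p <= min_rpk or rpk_l <= min_rpk:
        return float("nan")
    return rpk_l / rpk_p


def velocity_table(
    lrna: CoverageTrack,
    s5p: CoverageTrack,
    annotation: GenomeAnnotation,
    body_offset: int = DEFAULT_BODY_OFFSET,
    min_reads: float = 10.0,
) -> pd.DataFrame:
    """Per-gene v-hat over the gene body (TSS+offset to TES).

    Genes where either assay carries fewer than ``min_reads`` read
    equivalents over the body fail the expression filter (``expressed`` is
    False and ``vhat`` is NaN).
    """
    rows = []
    for gene in annotation:
        body = gene.body(body_offset)
        kb = len(body) / 1000.0
        rpk_l = interval_density(lrna, body)
        rpk_p = interval_density(s5p, body)
        expressed = rpk_l * kb >= min_reads and rpk_p * kb >= min_reads
        vhat = rpk_l / rpk_p if expressed and rpk_p > 0 else float("nan")
        rows.append((gene.gene_id, rpk_l, rpk_p, expressed, vhat))
    return pd.DataFrame(
        rows, columns=["gene_id", "rpk_lrna", "rpk_s5p", "expressed", "vhat"]
    )


def velocity_profile(
    lrna: CoverageTrack,
    s5p: CoverageTrack,
    gene: Gene,
    n_points: int = 50,
    pseudocount: float = 1e-3,
) -> np.ndarray:
    """Per-position v-hat profile along the gene, 5'->3', resized to ``n_points``."""
    arr_l = _oriented_bins(lrna, gene)
    arr_p = _oriented_bins(s5p, gene)
    ratio = (arr_l + pseudocount) / (arr_p + pseudocount)
    return resize_profile(ratio, n_points)


def _oriented_bins(track: CoverageTrack, gene: Gene) -> np.ndarray:
    arr = track.values[gene.strand][gene.chrom]
    bs = track.bin_size
    first, last = gene.interval.start // bs, (gene.interval.end - 1) // bs
    vals = arr[first : last + 1].copy()
    return vals[::-1] if gene.strand == "-" else vals


def wavefront_distance(
    track: CoverageTrack,
    gene: Gene,
    min_signal_frac: float = 0.1,
    tail_bins: int = 5,
) -> float:
    """Distance (bp) from the TSS to the leading edge of the cleared region.

    After CDK9 inhibition no new polymerases enter elongation, so the signal
    behind the advancing wavefront is cleared. The edge is located at the
    first gene bin (5'->3') whose value reaches half the gene-body level
    (estimated from the 3'-most ``tail_bins`` bins) and refined to sub-bin
    precision through the partially cleared boundary bin, so on noiseless
    input the cleared distance is recovered exactly. NaN when the gene is
    fully cleared or carries no signal.
    """
    vals = _oriented_bins(track, gene)
    bs = track.bin_size
    body = float(np.mean(vals[-tail_bins:]))
    if body <= 0:
        return float("nan")
    above = vals >= 0.5 * body
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    # the partially cleared bin is either i itself or, when more than half of
    # it was cleared, the bin before; min_signal_frac separates leftover
    # signal from the (near-zero) cleared background
    if i > 0 and vals[i - 1] >= min_signal_frac * body:
        i -= 1
    frac = min(vals[i] / body, 1.0)
    return i * bs + (1.0 - frac) * bs


def fit_wavefronts(
    tracks: list[CoverageTrack],
    times: list[float],
    annotation: GenomeAnnotation,
    min_points: int = 2,
) -> pd.DataFrame:
    """OLS of wavefront distance on inhibition time, per gene.

    The slope is the elongation velocity (kb/min when distances are bp and
    times minutes); the intercept absorbs the response-time delay. Genes
    with fewer than ``min_points`` usable time points or non-positive slope
    are dropped (counted in ``df.attrs['n_excluded']``).
    """
    if len(tracks) != len(times):
        raise ValueError("one track per time point required")
    if sorted(times) != list(times):
        raise ValueError("times must be sorted ascending")
    rows, excluded = [], 0
    for gene in annotation:
        pts = [
            (t, wavefront_distance(trk, gene))
            for t, trk in zip(times, tracks)
        ]
        pts = [(t, d) for t, d in pts if np.isfinite(d)]
        if len(pts) < min_points:
            excluded += 1
            continue
        t_arr = np.array([p[0] for p in pts])
        d_kb = np.array([p[1] for p in pts]) / 1000.0
        fit = sm.OLS(d_kb, sm.add_constant(t_arr)).fit()
        slope = float(fit.params[1])
        if slope <= 0:
            excluded += 1
            continue
        rows.append(
            (gene.gene_id, slope, float(fit.params[0]), len(pts), float(fit.rsquared))
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "velocity_kb_min", "intercept_kb", "n_times", "r2"]
    )
    out.attrs["n_excluded"] = excluded
    return out


def calibrate_velocity(
    vhat: pd.DataFrame,
    measured: pd.DataFrame,
    min_matched: int = 20,
) -> tuple[float, pd.DataFrame]:
    """Scale relative velocities to kb/min using wavefront-measured genes.

    scale = median over matched genes of measured / v-hat; applied to all
    genes (matched or not). Robust to outliers by construction.
    """
    merged = vhat.merge(measured[["gene_id", "velocity_kb_min"]], on="gene_id")
    merged = merged[np.isfinite(merged["vhat"])]
    if len(merged) < min_matched:
        raise ValueError(
            f"only {len(merged)} genes have both estimates (need {min_matched})"
        )
    scale = float(np.median(merged["velocity_kb_min"] / merged["vhat"]))
    out = vhat.copy()
    out["v_scaled_kb_min"] = out["vhat"] * scale
    return scale, out


def pausing_index(
    s5p: CoverageTrack,
    pause_iv: GenomicInterval,
    gene: Gene,
    body_interval: tuple[int, int] = PAUSE_BODY_INTERVAL,
) -> float:
    """Pol II density in the pausing interval over the gene-body density.

    The body reference is TSS+500..TSS+1500 in gene orientation. Undefined
    (NaN) when the body carries no signal.
    """
    lo, hi = body_interval
    if len(gene.interval) <= hi:
        raise ValueError(f"gene {gene.gene_id} shorter than the body interval")
    if gene.strand == "-":
        body = GenomicInterval(gene.chrom, gene.tss - hi, gene.tss - lo, gene.strand)
    else:
        body = GenomicInterval(gene.chrom, gene.tss + lo, gene.tss + hi, gene.strand)
    dens_body = interval_density(s5p, body)
    if dens_body <= 0:
        return float("nan")
    return interval_density(s5p, pause_iv) / dens_body


def pausing_time(pause_len_bp: float, v_pause_kb_min: float) -> float:
    """Seconds Pol II needs to traverse the pausing interval at local velocity.

    52 bp at 0.1486 kb/min gives 21 s.
    """
    if not np.isfinite(v_pause_kb_min) or v_pause_kb_min <= 0:
        return float("nan")
    return (pause_len_bp / 1000.0) / v_pause_kb_min * 60.0


def elongation_time(length_bp: float, v_kb_min: float) -> float:
    """Minutes to traverse ``length_bp`` at ``v_kb_min``."""
    if not np.isfinite(v_kb_min) or v_kb_min <= 0:
        return float("nan")
    return (length_bp / 1000.0) / v_kb_min


def profile_groups(
    profiles: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
    log: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means grouping of velocity profiles into slow/medium/fast classes.

    Profiles (genes x positions, already resized to a common length) are
    log-transformed, clustered, and the labels relabeled by ascending mean
    level so label 0 is always the slowest group. Returns (labels,
    mean profiles (k x positions, original scale)).
    """
    profiles = np.asarray(profiles, dtype=float)
    if k > len(profiles):
        raise ValueError("more clusters than profiles")
    X = np.log(profiles + 1e-9) if log else profiles
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    order = np.argsort([X[km.labels_ == g].mean() for g in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    means = np.stack([profiles[labels == g].mean(axis=0) for g in range(k)])
    return labels, means
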