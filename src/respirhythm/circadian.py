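"""Circadian-rhythm characterisation of metabolic time series.

Three layers, matching how diel structure is usually established in
physiological monitoring data:

1. photoperiod phase labelling and light/dark summaries,
2. autocorrelation-based periodicity: a detrended, mean-centred ACF on the
   hourly lag grid (drift removed by a centred 24-h moving-average baseline
   by default, or an OLS line), with the dominant period taken as the best
   positive local maximum in an 18-30 h search band (avoiding harmonics),
3. an unsupervised view: a self-organizing map (SOM) trained on the hourly
   five-parameter profiles (OR, CR, AE, RQ, AQ; z-scored), whose codebook is
   cut into k clusters by Ward's minimum-variance linkage, and the clusters
   associated with photophase or scotophase by majority vote.

The ACF is normalised per lag by the Cauchy-Schwarz bound of the two aligned
segments, which keeps ``|acf| <= 1`` exactly even when missing values are
pairwise-deleted. The SOM is a classic online Kohonen map (Gaussian
neighbourhood, exponentially decaying radius and learning rate) and is
deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .sim import START_CLOCK_H, PhotoperiodSchedule

logger = logging.getLogger(__name__)

#: Default dominant-period search band (hours).
PERIOD_BAND = (18.0, 30.0)


# --- photoperiod phase labelling -------------------------------------------


def label_phases(times_h, schedule: PhotoperiodSchedule | None = None,
                 start_clock: float = START_CLOCK_H) -> np.ndarray:
    """Boolean photophase flag per timestamp (hours since experiment start)."""
    schedule = schedule or PhotoperiodSchedule()
    times_h = np.asarray(times_h, dtype=float)
    clock = (start_clock + times_h) % schedule.cycle_length
    return np.asarray(schedule.is_light(clock))


def phase_summary(values, flags) -> dict[str, tuple[float, float]]:
    """(mean, SD) overall and over the light / dark label subsets."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if values.shape != flags.shape:
        raise ValueError("values and phase flags must align")
    out = {}
    for name, sel in (("overall", np.ones_like(flags)),
                      ("light", flags), ("dark", ~flags)):
        sub = values[sel]
        sub = sub[np.isfinite(sub)]
        if sub.size == 0:
            raise ValueError(f"no data in the {name} phase")
        out[name] = (float(np.mean(sub)), float(np.std(sub, ddof=1)) if sub.size > 1 else 0.0)
    return out


# --- autocorrelation -------------------------------------------------------


def _baseline_trend(x: np.ndarray, valid: np.ndarray, period: int) -> np.ndarray:
    """Centred moving-average baseline over one full period (2 x period/2 MA).

    The classic seasonal-decomposition trend filter: boundary weights of one
    half so the window spans exactly ``period`` samples. Any component with
    that exact period averages to zero, so the filter removes slow drifts of
    arbitrary shape without touching the rhythm itself. NaN-aware; shrinks to
    the available window near the edges.
    """
    half = period // 2
    kernel = np.ones(period + 1)
    kernel[0] = kernel[-1] = 0.5
    w = np.where(valid, 1.0, 0.0)
    xz = np.where(valid, x, 0.0)
    num = np.convolve(xz, kernel, mode="full")
    den = np.convolve(w, kernel, mode="full")
    sl = slice(half, half + x.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        trend = num[sl] / den[sl]
    return trend


def acf(values, max_lag: int = 72, detrend="baseline", period: int = 24) -> np.ndarray:
    """Normalised autocorrelation at integer lags 0..max_lag.

    ``detrend`` selects the drift removal applied before mean-centring:
    ``"baseline"`` (default) subtracts a centred moving-average baseline over
    one ``period`` — exposure drifts in monitoring data are ramp- or
    saturation-shaped, and the baseline filter removes them exactly while
    leaving any ``period``-periodic component untouched; ``"linear"`` (or
    ``True``) fits an ordinary least-squares line; ``False``/``None`` only
    mean-centres. Missing values are pairwise-deleted, and each lag is
    normalised by ``sqrt(sum(x_t^2) * sum(x_{t+k}^2))`` over the valid pairs,
    so ``acf[0] == 1`` and ``|acf[k]| <= 1`` always. Raises on a constant
    (zero-variance) series.
    """
    x = np.asarray(values, dtype=float).copy()
    valid = np.isfinite(x)
    n = x.size
    if valid.sum() < 3:
        raise ValueError("too few finite values for an autocorrelation")
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    scale = float(np.max(np.abs(x[valid])))
    t = np.arange(n, dtype=float)
    if detrend in ("linear", True):
        coef = np.polyfit(t[valid], x[valid], 1)
        x = x - np.polyval(coef, t)
    elif detrend == "baseline":
        x = x - _baseline_trend(x, valid, period)
    elif detrend not in (False, None):
        raise ValueError(f"unknown detrend mode {detrend!r}")
    x = x - np.mean(x[valid])
    if not np.any(np.abs(x[valid]) > 1e-12 * max(1.0, scale)):
        raise ValueError("constant series has no autocorrelation structure")
    x = np.where(valid, x, 0.0)
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        a, b = x[: n - k], x[k:]
        va, vb = valid[: n - k], valid[k:]
        both = va & vb
        if both.sum() < 2:
            out[k] = np.nan
            continue
        num = np.sum(a[both] * b[both])
        den = np.sqrt(np.sum(a[both] ** 2) * np.sum(b[both] ** 2))
        out[k] = num / den if den > 0 else np.nan
    return out


def dominant_period(acf_values, search_band: tuple[float, float] = PERIOD_BAND):
    """Lag (h) of the best positive local ACF maximum in the band, or None.

    ``None`` marks an arrhythmic series (no positive local maximum). The
    band must lie strictly inside the computed lag range so both neighbours
    of every candidate exist.
    """
    r = np.asarray(acf_values, dtype=float)
    lo, hi = search_band
    if hi >= r.size - 1:
        raise ValueError("search band extends beyond the computed lags")
    best_lag, best_val = None, -np.inf
    for k in range(int(np.ceil(lo)), int(np.floor(hi)) + 1):
        trio = r[k - 1: k + 2]
        if not np.all(np.isfinite(trio)):
            continue
        if r[k] > 0 and r[k] >= r[k - 1] and r[k] >= r[k + 1] and r[k] > best_val:
            best_lag, best_val = k, r[k]
    return best_lag


@dataclass
class RhythmSummary:
    """ACF curve plus the dominant period and its ACF amplitude."""

    acf: np.ndarray
    dominant_period: int | None
    amplitude: float  # ACF value at the dominant-period lag (NaN if arrhythmic)
    arrhythmic: bool


def rhythm_summary(values, max_lag: int = 72, detrend="baseline",
                   search_band: tuple[float, float] = PERIOD_BAND) -> RhythmSummary:
    """Full rhythm characterisation of one series; tolerant of flat input."""
    try:
        r = acf(values, max_lag=max_lag, detrend=detrend)
    except ValueError:
        flat = np.full(max_lag + 1, np.nan)
        flat[0] = 1.0
        return RhythmSummary(flat, None, np.nan, True)
    period = dominant_period(r, search_band)
    if period is None:
        return RhythmSummary(r, None, np.nan, True)
    return RhythmSummary(r, period, float(r[period]), False)


# --- self-organizing map ---------------------------------------------------


@dataclass
class SomResult:
    """Trained SOM with Ward clusters and their photoperiod association."""

    codebook: np.ndarray  # (units, features)
    grid: np.ndarray  # (units, 2) integer grid coordinates
    assignments: np.ndarray  # sample -> best-matching unit
    unit_clusters: np.ndarray  # unit -> cluster label (1..k)
    sample_clusters: np.ndarray  # sample -> cluster label
    phase_table: pd.DataFrame  # per-cluster contingency, majority, purity


def som_train(samples, grid: tuple[int, int] = (8, 6), epochs: int = 1000,
              lr: tuple[float, float] = (0.5, 0.01),
              radius: tuple[float | None, float] = (None, 1.0),
              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Train a Kohonen map; returns (codebook, grid coordinates).

    Online training: per step, the best-matching unit (BMU) and its Gaussian
    grid neighbourhood move toward the sample. Learning rate and radius decay
    exponentially from their initial to final values over ``epochs`` passes;
    the initial radius defaults to half the grid diagonal. The codebook is
    initialised uniformly within the per-feature data range. Deterministic
    given ``seed``; ties in the BMU search break toward the lowest unit index.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D sample matrix with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("samples contain non-finite values")
    gx, gy = grid
    if gx < 1 or gy < 1:
        raise ValueError("grid dimensions must be positive")
    n, _ = X.shape
    coords = np.array([(i, j) for i in range(gx) for j in range(gy)], dtype=float)
    rng = np.random.default_rng(seed)
    code = rng.uniform(X.min(axis=0), X.max(axis=0), size=(gx * gy, X.shape[1]))
    lr0, lr1 = lr
    r0 = radius[0] if radius[0] is not None else 0.5 * np.hypot(gx - 1, gy - 1)
    r0 = max(r0, 1e-9)
    r1 = max(radius[1], 1e-9)
    total = max(epochs * n - 1, 1)
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = step / total
            a = lr0 * (lr1 / lr0) ** frac
            r = r0 * (r1 / r0) ** frac
            diff = X[i] - code
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            g2 = np.sum((coords - coords[bmu]) ** 2, axis=1)
            h = np.exp(-g2 / (2.0 * r * r))
            code += (a * h)[:, None] * diff
            step += 1
    return code, coords.astype(int)


def bmu_assign(samples, codebook) -> np.ndarray:
    """Best-matching unit per sample by Euclidean distance (lowest index wins)."""
    X = np.asarray(samples, dtype=float)
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def ward_linkage(codebook) -> np.ndarray:
    """Ward's minimum-variance linkage matrix over codebook vectors."""
    return linkage(np.asarray(codebook, dtype=float), method="ward")


def ward_clusters(codebook, k: int = 6) -> np.ndarray:
    """Cut the Ward dendrogram of the codebook into ``k`` cluster labels (1..k)."""
    codebook = np.asarray(codebook, dtype=float)
    if k > codebook.shape[0]:
        raise ValueError("more clusters requested than codebook units")
    if k == codebook.shape[0]:
        return np.arange(1, k + 1)
    labels = fcluster(ward_linkage(codebook), t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise ValueError("Ward cut produced empty clusters (degenerate codebook)")
    return labels


def cluster_phase_association(sample_clusters, phase_flags) -> pd.DataFrame:
    """Cluster x phase contingency with majority phase and purity per cluster."""
    sample_clusters = np.asarray(sample_clusters)
    phase_flags = np.asarray(phase_flags, dtype=bool)
    if sample_clusters.shape != phase_flags.shape:
        raise ValueError("cluster labels and phase flags must align")
    rows = []
    for c in np.unique(sample_clusters):
        sel = sample_clusters == c
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"cluster {c} is empty")
        n_light = int(phase_flags[sel].sum())
        n_dark = n - n_light
        majority = "photophase" if n_light >= n_dark else "scotophase"
        rows.append({
            "cluster": int(c), "n": n, "n_photophase": n_light,
            "n_scotophase": n_dark, "majority": majority,
            "purity": max(n_light, n_dark) / n,
        })
    return pd.DataFrame(rows).set_index("cluster")


# --- feature assembly and the combined analysis ----------------------------


def hourly_features(hours, param_series: Mapping[str, tuple[np.ndarray, np.ndarray]],
                    parameters: tuple[str, ...] | None = None) -> np.ndarray:
    """Hourly z-scored feature matrix from per-parameter (times, values) series.

    Parameters on coarser grids (the bi-hourly AE and AQ) are linearly
    interpolated onto the hourly grid; interior missing values are dropped
    before interpolation so gaps are bridged, and edges are held constant.
    """
    hours = np.asarray(hours, dtype=float)
    names = tuple(parameters) if parameters is not None else tuple(param_series)
    cols = []
    for name in names:
        times, vals = param_series[name]
        times = np.asarray(times, dtype=float)
        vals = np.asarray(vals, dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            raise ValueError(f"parameter {name!r} has too few finite values")
        col = np.interp(hours, times[ok], vals[ok])
        sd = np.std(col)
        if sd == 0:
            raise ValueError(f"parameter {name!r} is constant; cannot z-score")
        cols.append((col - np.mean(col)) / sd)
    return np.column_stack(cols)


def som_phase_analysis(features, phase_flags, grid: tuple[int, int] = (8, 6),
                       k: int = 6, epochs: int = 1000, seed: int = 0) -> SomResult:
    """Train a SOM, cut its codebook into Ward clusters, associate with phase.

    Cluster ids are relabelled in order of descending scotophase fraction, so
    label 1 is always the most scotophase-dominated cluster.
    """
    codebook, coords = som_train(features, grid=grid, epochs=epochs, seed=seed)
    assignments = bmu_assign(features, codebook)
    unit_clusters = ward_clusters(codebook, k=k)
    sample_clusters = unit_clusters[assignments]
    flags = np.asarray(phase_flags, dtype=bool)
    # relabel by descending scotophase fraction among the samples of each cluster
    present = np.unique(sample_clusters)
    dark_frac = {c: 1.0 - flags[sample_clusters == c].mean() for c in present}
    order = sorted(present, key=lambda c: (-dark_frac[c], c))
    remap = {old: new for new, old in enumerate(order, start=1)}
    # units whose cluster attracted no samples keep a stable label after the rest
    for c in np.unique(unit_clusters):
        if c not in remap:
            remap[c] = len(remap) + 1
    unit_clusters = np.array([remap[c] for c in unit_clusters])
    sample_clusters = unit_clusters[assignments]
    table = cluster_phase_association(sample_clusters, flags)
    logger.info("SOM %sx%s, %d clusters, mean purity %.3f",
                grid[0], grid[1], k, table["purity"].mean())
    return SomResult(codebook, coords, assignments, unit_clusters,
                     sample_clusters, table)
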