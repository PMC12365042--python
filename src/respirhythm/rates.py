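"""Metabolic-rate estimation for intermittent-flow respirometry.

Turns raw chamber concentration traces into mass-specific metabolic rates and
metabolic quotients:

* a weighted central-difference slope per sealed 450-s measurement cycle
  (only the last 300 s of each cycle — the sealed window — carry readings),
* conversion of slopes to oxygen consumption (OR), carbon dioxide excretion
  (CR) and ammonia-N excretion (AE), all in mg per kg of fish per hour,
  using the net chamber volume ``(respir_vol - fish_volume)``,
* the respiratory quotient ``RQ = (VCO2/44) / (VO2/32)`` and ammonia quotient
  ``AQ = (VN/18) / (VO2/32)`` (molar ratios; 44, 32 and 18 g/mol),
* aggregation onto the hourly (gas) and bi-hourly (ammonia) reporting grids.

The slope estimator averages ``n`` central differences around the window
centre with triangular weights — ``{1}``, ``{2, 1}`` and ``{3, 2, 1}`` for
``n = 3, 5, 7`` — normalised by the weight sum so the result stays in
mg/L/s. It is exact for affine concentration traces at any spacing and for
quadratic traces at the centre of a symmetric stencil, which is what makes
the noiseless simulator round-trip recover rates to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

if TYPE_CHECKING:  # geometry types live in the simulator module
    from .sim import ChamberSpec, FishLot

logger = logging.getLogger(__name__)

#: Recognised sensor channels.
CHANNELS = ("O2", "CO2", "NH3N")

#: Slope sign per channel: O2 is depleted in a sealed chamber (negative
#: slope, positive consumption rate); CO2 and ammonia-N accumulate.
CHANNEL_SIGN = {"O2": -1.0, "CO2": 1.0, "NH3N": 1.0}

#: Triangular central-difference weights, outermost term last.
_WEIGHTS = {3: (1.0,), 5: (2.0, 1.0), 7: (3.0, 2.0, 1.0)}


@dataclass(frozen=True)
class MolarConstants:
    """Normalisation constants for the metabolic quotients."""

    co2_molar: float = 44.0
    o2_molar: float = 32.0
    ammonia_divisor: float = 18.0
    seconds_per_hour: float = 3600.0


MOLAR = MolarConstants()


@dataclass
class ConcentrationSeries:
    """Timestamped sensor readings for one channel of one tank.

    Times are seconds since the start of the experiment and must be strictly
    increasing; values are concentrations in mg/L.
    """

    times: np.ndarray
    values: np.ndarray
    channel: str
    tank_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class CycleSlope:
    """One concentration slope (mg/L/s) for one sealed measurement cycle."""

    cycle_index: int
    cycle_mid_time: float  # seconds; midpoint of the measurement window
    slope: float  # signed; NaN when the cycle is missing
    n_used: int  # stencil actually used (3/5/7); 0 when missing
    ok: bool


@dataclass
class MetabolicRateSeries:
    """Per-tank rates: hourly VO2/VCO2 plus bi-hourly VN, all mg/kg/h."""

    times: np.ndarray  # hourly bin centres, hours since start
    vo2: np.ndarray
    vco2: np.ndarray
    vn_times: np.ndarray  # bi-hourly interval midpoints, hours
    vn: np.ndarray
    tank_id: str = ""


@dataclass
class QuotientSeries:
    """Per-tank dimensionless quotients; NaN marks undefined entries."""

    times: np.ndarray  # hourly, aligned with MetabolicRateSeries.times
    rq: np.ndarray
    aq_times: np.ndarray  # bi-hourly, aligned with vn_times
    aq: np.ndarray
    tank_id: str = ""


def weighted_slope(values, times, center_index: int, n: int = 7) -> float:
    """Weighted average of ``n`` central differences at ``center_index``.

    ``n`` must be 3, 5 or 7; weights are 1 / {2,1} / {3,2,1} from the
    innermost difference outward, normalised by the weight sum (1, 3, 6).
    Exact for affine inputs at any spacing.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if n not in _WEIGHTS:
        raise ValueError(f"n must be one of {sorted(_WEIGHTS)}, got {n}")
    i = int(center_index)
    half = n // 2
    if i - half < 0 or i + half >= values.size:
        raise ValueError(
            f"center index {i} needs {half} neighbours on each side "
            f"(series has {values.size} points)"
        )
    weights = _WEIGHTS[n]
    acc = 0.0
    for k, w in enumerate(weights, start=1):
        dt = times[i + k] - times[i - k]
        if dt <= 0:
            raise ValueError("duplicate or non-increasing timestamps in stencil")
        acc += w * (values[i + k] - values[i - k]) / dt
    return acc / sum(weights)


def cycle_slope_series(
    series: ConcentrationSeries, chamber: "ChamberSpec", n: int = 7
) -> list[CycleSlope]:
    """One slope per measurement cycle, evaluated at the window's centre reading.

    Readings are partitioned into consecutive ``cycle_length`` cycles from
    t = 0; within each cycle only the trailing ``measure_window`` seconds are
    used (the sealed phase). The stencil falls back from ``n`` to 5 then 3
    when the window is short; cycles with fewer than 3 usable readings are
    flagged missing rather than fabricated. Ties for the centre reading break
    toward the earlier reading.
    """
    cycle_len = float(chamber.cycle_length)
    window = float(chamber.measure_window)
    t, x = series.times, series.values
    if t.size == 0 or t[-1] < cycle_len - window:
        raise ValueError("series does not span a full measurement cycle")
    n_cycles = int(np.floor(t[-1] / cycle_len)) + 1
    fallbacks = [cand for cand in (7, 5, 3) if cand <= n]
    if not fallbacks:
        raise ValueError(f"n must be one of {sorted(_WEIGHTS)}, got {n}")
    out: list[CycleSlope] = []
    for c in range(n_cycles):
        lo = c * cycle_len + (cycle_len - window)
        hi = (c + 1) * cycle_len
        a = int(np.searchsorted(t, lo, side="left"))
        b = int(np.searchsorted(t, hi, side="left"))
        mid = c * cycle_len + cycle_len - window / 2.0
        m = b - a
        if m < 3:
            out.append(CycleSlope(c, mid, np.nan, 0, False))
            continue
        ic = (m - 1) // 2  # centre reading, ties toward the earlier one
        n_eff = 0
        for cand in fallbacks:
            half = cand // 2
            if ic >= half and (m - 1 - ic) >= half:
                n_eff = cand
                break
        if n_eff == 0:
            out.append(CycleSlope(c, mid, np.nan, 0, False))
            continue
        slope = weighted_slope(x[a:b], t[a:b], ic, n_eff)
        out.append(CycleSlope(c, mid, slope, n_eff, True))
    n_missing = sum(not s.ok for s in out)
    if n_missing:
        logger.info(
            "%s/%s cycles flagged missing for tank %r channel %s",
            n_missing, len(out), series.tank_id, series.channel,
        )
    return out


def rate_from_slope(
    slope: float, chamber: "ChamberSpec", fish: "FishLot", channel: str
) -> float:
    """Convert a concentration slope (mg/L/s) to a rate in mg/kg/h.

    ``rate = sign * slope * (respir_vol - fish_volume) * 3600 / fish_weight``
    with sign -1 for O2 (depletion) and +1 for CO2 / NH3-N (accumulation).
    """
    if channel not in CHANNEL_SIGN:
        raise ValueError(f"unknown channel {channel!r}")
    net_vol = chamber.respir_vol - fish.total_volume
    if net_vol <= 0:
        raise ValueError("respirometer volume must exceed total fish volume")
    if fish.total_weight <= 0:
        raise ValueError("fish weight must be positive")
    return (
        CHANNEL_SIGN[channel]
        * slope
        * net_vol
        * MOLAR.seconds_per_hour
        / fish.total_weight
    )


def cycle_rate_series(
    series: ConcentrationSeries,
    chamber: "ChamberSpec",
    fish: "FishLot",
    n: int = 7,
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle-level rates (times in hours, mg/kg/h; NaN where missing)."""
    slopes = cycle_slope_series(series, chamber, n=n)
    times_h = np.array([s.cycle_mid_time for s in slopes]) / MOLAR.seconds_per_hour
    rates = np.array(
        [
            rate_from_slope(s.slope, chamber, fish, series.channel) if s.ok else np.nan
            for s in slopes
        ]
    )
    return times_h, rates


def ammonia_rate_series(
    series: ConcentrationSeries, chamber: "ChamberSpec", fish: "FishLot"
) -> tuple[np.ndarray, np.ndarray]:
    """AE from bi-hourly tank samples via two-point slopes.

    Ammonia accumulates in the holding tank (no flush), so the slope between
    consecutive samples, fed through the rate equation with the tank water
    volume in place of the chamber volume, gives the excretion rate over that
    interval. Values are reported at the interval midpoints.
    """
    if series.channel != "NH3N":
        raise ValueError("ammonia_rate_series expects an NH3N series")
    if series.n < 2:
        raise ValueError("need at least two ammonia samples")
    t, x = series.times, series.values
    slopes = np.diff(x) / np.diff(t)
    net_vol = chamber.tank_volume - fish.total_volume
    if net_vol <= 0:
        raise ValueError("tank volume must exceed total fish volume")
    vn = slopes * net_vol * MOLAR.seconds_per_hour / fish.total_weight
    mid_h = (t[:-1] + t[1:]) / 2.0 / MOLAR.seconds_per_hour
    return mid_h, vn


def respiratory_quotient(vco2, vo2):
    """``RQ = (VCO2/44) / (VO2/32)``; NaN where VO2 is not positive."""
    vco2 = np.asarray(vco2, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rq = np.where(vo2 > 0, (vco2 / MOLAR.co2_molar) / (vo2 / MOLAR.o2_molar), np.nan)
    return float(rq) if rq.ndim == 0 else rq


def ammonia_quotient(vn, vo2):
    """``AQ = (VN/18) / (VO2/32)``; NaN where VO2 is not positive."""
    vn = np.asarray(vn, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        aq = np.where(
            vo2 > 0, (vn / MOLAR.ammonia_divisor) / (vo2 / MOLAR.o2_molar), np.nan
        )
    return float(aq) if aq.ndim == 0 else aq


def hourly_aggregate(
    cycle_times_h,
    vo2_cycles,
    vco2_cycles,
    vn_times_h=None,
    vn=None,
    n_hours: int | None = None,
    tank_id: str = "",
) -> tuple[MetabolicRateSeries, QuotientSeries]:
    """Aggregate cycle-level gas rates to hourly means and attach quotients.

    RQ is computed from the hourly means (not per cycle); AQ pairs each
    bi-hourly AE value with the mean VO2 of its containing 2-h window. Hours
    whose cycles are all missing propagate as NaN.
    """
    cycle_times_h = np.asarray(cycle_times_h, dtype=float)
    vo2_cycles = np.asarray(vo2_cycles, dtype=float)
    vco2_cycles = np.asarray(vco2_cycles, dtype=float)
    if cycle_times_h.size == 0:
        raise ValueError("no cycles to aggregate")
    if n_hours is None:
        n_hours = int(np.floor(cycle_times_h.max())) + 1
    hour_idx = np.floor(cycle_times_h).astype(int)
    vo2_h = np.full(n_hours, np.nan)
    vco2_h = np.full(n_hours, np.nan)
    for h in range(n_hours):
        sel = hour_idx == h
        if not np.any(sel):
            continue
        with np.errstate(invalid="ignore"):
            vo2_h[h] = np.nanmean(vo2_cycles[sel]) if np.any(np.isfinite(vo2_cycles[sel])) else np.nan
            vco2_h[h] = np.nanmean(vco2_cycles[sel]) if np.any(np.isfinite(vco2_cycles[sel])) else np.nan
    hours = np.arange(n_hours) + 0.5
    rq = respiratory_quotient(vco2_h, vo2_h)

    if vn_times_h is None:
        vn_times_h = np.empty(0)
        vn = np.empty(0)
    vn_times_h = np.asarray(vn_times_h, dtype=float)
    vn = np.asarray(vn, dtype=float)
    aq = np.full(vn.shape, np.nan)
    for j, tm in enumerate(vn_times_h):
        h0 = int(np.floor(tm / 2.0)) * 2
        window = [h for h in (h0, h0 + 1) if 0 <= h < n_hours]
        vals = vo2_h[window]
        if len(vals) and np.any(np.isfinite(vals)):
            aq[j] = ammonia_quotient(vn[j], np.nanmean(vals))
    mseries = MetabolicRateSeries(hours, vo2_h, vco2_h, vn_times_h, vn, tank_id)
    qseries = QuotientSeries(hours, rq, vn_times_h.copy(), aq, tank_id)
    return mseries, qseries


# ---------------------------------------------------------------------------
# Whole-dataset pipeline helpers


def analyze_tank(ts, tank_id: str, n: int = 7) -> tuple[MetabolicRateSeries, QuotientSeries]:
    """Full rate pipeline for one tank of a trace set."""
    o2 = ts.series(tank_id, "O2")
    co2 = ts.series(tank_id, "CO2")
    nh3 = ts.series(tank_id, "NH3N")
    t_o2, vo2 = cycle_rate_series(o2, ts.chamber, ts.fish, n=n)
    t_co2, vco2 = cycle_rate_series(co2, ts.chamber, ts.fish, n=n)
    if not np.allclose(t_o2, t_co2):
        raise ValueError(f"O2 and CO2 cycle grids disagree for tank {tank_id!r}")
    vn_t, vn = ammonia_rate_series(nh3, ts.chamber, ts.fish)
    n_hours = ts.days * 24
    return hourly_aggregate(t_o2, vo2, vco2, vn_t, vn, n_hours=n_hours, tank_id=tank_id)


def analyze_traceset(ts, n: int = 7) -> dict[str, tuple[MetabolicRateSeries, QuotientSeries]]:
    """Run the rate pipeline for every tank; keyed by tank id."""
    results = {tid: analyze_tank(ts, tid, n=n) for tid in ts.tank_ids}
    logger.info("rate pipeline: %d tanks, %d hours", len(results), ts.days * 24)
    return results


#: Canonical parameter order used throughout reporting.
PARAMETERS = ("OR", "CR", "AE", "RQ", "AQ")


def parameter_matrices(
    results: Mapping[str, tuple[MetabolicRateSeries, QuotientSeries]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Stack per-tank series into (times, tanks x T) matrices per parameter."""
    tank_ids = sorted(results)
    first_m, first_q = results[tank_ids[0]]
    grids = {
        "OR": first_m.times, "CR": first_m.times, "RQ": first_q.times,
        "AE": first_m.vn_times, "AQ": first_q.aq_times,
    }
    pick = {
        "OR": lambda m, q: m.vo2, "CR": lambda m, q: m.vco2,
        "AE": lambda m, q: m.vn, "RQ": lambda m, q: q.rq, "AQ": lambda m, q: q.aq,
    }
    out = {}
    for name in PARAMETERS:
        rows = np.vstack([pick[name](*results[tid]) for tid in tank_ids])
        out[name] = (grids[name], rows)
    return out


def group_mean_series(
    results: Mapping[str, tuple[MetabolicRateSeries, QuotientSeries]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Tank-mean time series per parameter (NaN-aware mean across tanks)."""
    mats = parameter_matrices(results)
    out = {}
    for name, (times, rows) in mats.items():
        with np.errstate(invalid="ignore"):
            out[name] = (times, np.nanmean(rows, axis=0))
    return out


def seven_day_means(
    results: Mapping[str, tuple[MetabolicRateSeries, QuotientSeries]]
) -> dict[str, float]:
    """Whole-experiment mean of each parameter across tanks and time."""
    mats = parameter_matrices(results)
    return {name: float(np.nanmean(rows)) for name, (_, rows) in mats.items()}
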