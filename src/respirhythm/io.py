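"""Text formats and run configuration.

One long-format trace dialect keeps tanks and channels joinable:

    time_s,tank_id,channel,conc_mg_per_L

with a YAML metadata sidecar (group profile, geometry, photoperiod, seed,
start clock) next to it. Rate tables are written long as

    time_h,tank_id,vo2,vco2,vn,rq,aq

with empty fields marking missing values — hourly rows carry the gas rates
and RQ, bi-hourly rows carry AE and AQ. Malformed trace rows are reported
with their file line numbers; nothing is silently coerced.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .rates import CHANNELS, ConcentrationSeries, MetabolicRateSeries, QuotientSeries
from .sim import (
    START_CLOCK_H,
    ChamberSpec,
    FishLot,
    PhotoperiodSchedule,
    TraceSet,
    TreatmentProfile,
)

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["time_s", "tank_id", "channel", "conc_mg_per_L"]
RATE_COLUMNS = ["time_h", "tank_id", "vo2", "vco2", "vn", "rq", "aq"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def write_traces(ts: TraceSet, path, meta_path=None) -> Path:
    """Write a trace set as delimiter-separated text plus a YAML sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _meta_path(path)
    frames = []
    for (tank_id, channel) in sorted(ts.traces):
        s = ts.traces[(tank_id, channel)]
        frames.append(pd.DataFrame({
            "time_s": s.times, "tank_id": tank_id, "channel": channel,
            "conc_mg_per_L": s.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta = {
        "profile": dataclasses.asdict(ts.profile),
        "fish": dataclasses.asdict(ts.fish),
        "chamber": dataclasses.asdict(ts.chamber),
        "schedule": dataclasses.asdict(ts.schedule),
        "days": ts.days,
        "seed": ts.seed,
        "start_clock": ts.start_clock,
        "tank_effects": {k: float(v) for k, v in ts.tank_effects.items()},
    }
    meta["profile"]["ae_surge"] = list(ts.profile.ae_surge)
    meta["profile"]["cr_suppression"] = list(ts.profile.cr_suppression)
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    logger.info("wrote %d trace rows to %s (+ %s)",
                sum(s.n for s in ts.traces.values()), path, meta_path.name)
    return path


def read_traces(path, meta_path=None) -> TraceSet:
    """Load and validate a trace file written by :func:`write_traces`.

    Raises ``ValueError`` naming the offending file line for unknown channels
    or non-monotone timestamps; raises ``FileNotFoundError`` when the metadata
    sidecar is absent.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _meta_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar {meta_path} is missing")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["channel"].isin(CHANNELS)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(
            f"{path}, line {line}: unknown channel {df.loc[df.index[bad][0], 'channel']!r}"
        )
    meta = yaml.safe_load(meta_path.read_text())
    profile_meta = dict(meta["profile"])
    profile_meta["ae_surge"] = tuple(profile_meta["ae_surge"])
    profile_meta["cr_suppression"] = tuple(profile_meta["cr_suppression"])
    traces: dict[tuple[str, str], ConcentrationSeries] = {}
    for (tank_id, channel), sub in df.groupby(["tank_id", "channel"], sort=True):
        t = sub["time_s"].to_numpy(dtype=float)
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            row = sub.index[int(np.argmax(diffs <= 0)) + 1]
            raise ValueError(
                f"{path}, line {int(row) + 2}: non-monotone time for "
                f"tank {tank_id!r} channel {channel}"
            )
        traces[(str(tank_id), str(channel))] = ConcentrationSeries(
            t, sub["conc_mg_per_L"].to_numpy(dtype=float), str(channel), str(tank_id)
        )
    ts = TraceSet(
        traces=traces,
        profile=TreatmentProfile(**profile_meta),
        fish=FishLot(**meta["fish"]),
        chamber=ChamberSpec(**meta["chamber"]),
        schedule=PhotoperiodSchedule(**meta["schedule"]),
        days=int(meta["days"]),
        seed=int(meta["seed"]),
        start_clock=float(meta.get("start_clock", START_CLOCK_H)),
        tank_effects={str(k): float(v) for k, v in meta.get("tank_effects", {}).items()},
    )
    logger.info("read %d trace rows (%d tanks) from %s", len(df), len(ts.tank_ids), path)
    return ts


def write_rates(results: Mapping[str, tuple[MetabolicRateSeries, QuotientSeries]],
                path) -> Path:
    """Write per-tank rate/quotient tables in the long rate dialect."""
    path = Path(path)
    frames = []
    for tank_id in sorted(results):
        m, q = results[tank_id]
        hourly = pd.DataFrame({
            "time_h": m.times, "tank_id": tank_id,
            "vo2": m.vo2, "vco2": m.vco2, "vn": np.nan, "rq": q.rq, "aq": np.nan,
        })
        bihourly = pd.DataFrame({
            "time_h": m.vn_times, "tank_id": tank_id,
            "vo2": np.nan, "vco2": np.nan, "vn": m.vn, "rq": np.nan, "aq": q.aq,
        })
        frames.append(pd.concat([hourly, bihourly], ignore_index=True)
                      .sort_values("time_h", kind="stable"))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    logger.info("wrote rate table %s", path)
    return path


def read_rates(path) -> dict[str, tuple[MetabolicRateSeries, QuotientSeries]]:
    """Load a rate table back into per-tank series containers."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for tank_id, sub in df.groupby("tank_id", sort=True):
        hourly = sub[sub["vo2"].notna() | sub["vco2"].notna() | sub["rq"].notna()]
        bih = sub[sub["vn"].notna() | sub["aq"].notna()]
        m = MetabolicRateSeries(
            hourly["time_h"].to_numpy(float), hourly["vo2"].to_numpy(float),
            hourly["vco2"].to_numpy(float), bih["time_h"].to_numpy(float),
            bih["vn"].to_numpy(float), str(tank_id))
        q = QuotientSeries(
            hourly["time_h"].to_numpy(float), hourly["rq"].to_numpy(float),
            bih["time_h"].to_numpy(float), bih["aq"].to_numpy(float), str(tank_id))
        out[str(tank_id)] = (m, q)
    return out


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run; YAML round-trippable."""

    preset: str = "control"
    days: int = 7
    tanks: int = 3
    seed: int = 0
    slope_n: int = 7
    som_grid: tuple[int, int] = (8, 6)
    som_epochs: int = 1000
    k_clusters: int = 6
    acf_max_lag: int = 72
    acf_detrend: str = "baseline"
    period_band: tuple[float, float] = (18.0, 30.0)
    out_dir: str = "."

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["som_grid"] = list(self.som_grid)
        d["period_band"] = list(self.period_band)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "som_grid" in d:
            d["som_grid"] = tuple(d["som_grid"])
        if "period_band" in d:
            d["period_band"] = tuple(d["period_band"])
        return cls(**d)
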