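"""Group- and phase-level hypothesis tests and the summary table.

One-way ANOVA (via scipy) and the Mann-Whitney U test back two comparison
families: each treatment group against control, and photophase against
scotophase within a group. The Mann-Whitney p value is exact — the full
permutation distribution of U over all C(n+m, n) label assignments, computed
on midranks so ties are handled exactly — whenever the smaller sample has at
most 8 observations, and a tie-corrected normal approximation with continuity
correction otherwise. No multiple-testing correction is applied; each test is
read at its own alpha.

Significance stars follow the usual convention: ``***`` p < 0.001, ``**``
p < 0.01, ``*`` p < 0.05.

``summary_table`` reports, per group and parameter, the mean +- SD across
tank means (tanks are the biological replicates) with treatment-vs-control
and light-vs-dark tests. Because only three tanks per group exist, the
comparison tests default to time-resolved observations (``granularity=
"hourly"``) — a tank-mean Mann-Whitney with n = 3 cannot go below p = 0.1 —
but tank-mean granularity is available via a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Largest "smaller sample" size for which the exact Mann-Whitney tail is used.
EXACT_LIMIT = 8

#: Enumeration budget: fall back to the normal approximation when the number
#: of label assignments C(n+m, min(n, m)) exceeds this.
_MAX_ENUMERATIONS = 100_000


def star_annotation(p: float) -> str:
    """Significance stars as a pure threshold function of p."""
    if not 0 <= p <= 1:
        raise ValueError("p value outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group (or k-group) comparison."""

    parameter: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        return star_annotation(self.p_value)


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    Raises when every observation is identical (zero between- and
    within-group variance leaves F undefined).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical; F is undefined")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of the first sample (ties count one half)."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact tail probability by enumerating all label assignments.

    Uses midranks of the pooled sample, so the permutation distribution is
    exact in the presence of ties. Two-sided: total probability of U values
    at least as far from nm/2 as observed.
    """
    n, m = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    offset = n * (n + 1) / 2.0
    centre = n * m / 2.0
    dev = abs(u_obs - centre) - 1e-9  # tolerance for float midrank sums
    hits = total = 0
    for comb in combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - centre) >= dev:
            hits += 1
    return hits / total


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 two_sided: bool = True) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of the first sample, p value).

    Exact enumeration when ``min(n, m) <= 8``; tie-corrected normal
    approximation with continuity correction otherwise. With
    ``two_sided=False`` the p value is the smaller one-sided tail.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    u = _u_statistic(a, b)
    if (min(n, m) <= EXACT_LIMIT
            and math.comb(n + m, min(n, m)) <= _MAX_ENUMERATIONS):
        p = _exact_two_sided_p(a, b, u)
    else:
        pooled = np.concatenate([a, b])
        _, counts = np.unique(pooled, return_counts=True)
        nm = n + m
        tie_term = np.sum(counts ** 3 - counts) / (nm * (nm - 1))
        var_u = n * m / 12.0 * (nm + 1 - tie_term)
        if var_u <= 0:
            return u, 1.0
        z = (abs(u - n * m / 2.0) - 0.5) / math.sqrt(var_u)
        z = max(z, 0.0)
        p = 2.0 * sps.norm.sf(z)
        p = min(p, 1.0)
    if not two_sided:
        p = p / 2.0
    return u, p


# --- summary table ---------------------------------------------------------


def _observations(rows: np.ndarray, granularity: str) -> np.ndarray:
    """Flatten a (tanks, T) matrix into the unit-of-analysis vector."""
    if granularity == "hourly":
        flat = rows.ravel()
        return flat[np.isfinite(flat)]
    if granularity == "tank":
        with np.errstate(invalid="ignore"):
            means = np.nanmean(rows, axis=1)
        return means[np.isfinite(means)]
    raise ValueError("granularity must be 'hourly' or 'tank'")


def summary_table(
    data: Mapping[str, Mapping[str, np.ndarray]],
    phase_flags: Mapping[str, np.ndarray],
    control: str = "control",
    granularity: str = "hourly",
    parameters: tuple[str, ...] = ("OR", "CR", "AE", "RQ", "AQ"),
) -> pd.DataFrame:
    """Group x parameter summary with significance annotation.

    ``data[group][param]`` is a (tanks, T) observation matrix (NaN = missing);
    ``phase_flags[param]`` is the boolean photophase flag for that parameter's
    time grid. Each row carries the mean +- SD across tank means, the
    treatment-vs-control Mann-Whitney (headline, starred) and ANOVA p values,
    and the within-group light-vs-dark Mann-Whitney on time-resolved
    observations. Control rows carry no treatment stars.
    """
    if control not in data:
        raise ValueError(f"control group {control!r} missing from data")
    rows = []
    for group in data:
        for param in parameters:
            if param not in data[group]:
                raise ValueError(f"group {group!r} lacks parameter {param!r}")
            mat = np.asarray(data[group][param], dtype=float)
            if mat.ndim != 2 or mat.shape[0] < 2:
                raise ValueError("need a (tanks, T) matrix with >= 2 tanks")
            with np.errstate(invalid="ignore"):
                tank_means = np.nanmean(mat, axis=1)
            mean = float(np.mean(tank_means))
            sd = float(np.std(tank_means, ddof=1))
            rec = {
                "group": group, "parameter": param,
                "mean": mean, "sd": sd, "n_tanks": mat.shape[0],
            }
            if group != control:
                obs_t = _observations(mat, granularity)
                obs_c = _observations(np.asarray(data[control][param], float),
                                      granularity)
                _, p_mw = mann_whitney(obs_t, obs_c)
                _, p_anova = anova_oneway(obs_t, obs_c)
                rec.update(p_vs_control=p_mw, p_vs_control_anova=p_anova,
                           stars=star_annotation(p_mw))
            else:
                rec.update(p_vs_control=np.nan, p_vs_control_anova=np.nan, stars="")
            flags = np.asarray(phase_flags[param], dtype=bool)
            if flags.size != mat.shape[1]:
                raise ValueError(f"phase flags for {param!r} do not match its grid")
            light = mat[:, flags].ravel()
            dark = mat[:, ~flags].ravel()
            _, p_ld = mann_whitney(light[np.isfinite(light)],
                                   dark[np.isfinite(dark)])
            rec.update(p_light_dark=p_ld, light_dark_stars=star_annotation(p_ld))
            rows.append(rec)
    table = pd.DataFrame(rows)
    logger.info("summary table: %d groups x %d parameters (%s granularity)",
                len(data), len(parameters), granularity)
    return table


def render_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of the summary table, one group per block."""
    lines = []
    for group, sub in table.groupby("group", sort=False):
        lines.append(f"[{group}]")
        for _, row in sub.iterrows():
            entry = f"  {row['parameter']:>3}: {row['mean']:10.2f} +- {row['sd']:8.2f}"
            if row["stars"]:
                entry += f" {row['stars']}"
            entry += (f"   light-vs-dark p={row['p_light_dark']:.2e}"
                      f"{row['light_dark_stars']}")
            lines.append(entry)
    return "\n".join(lines)
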