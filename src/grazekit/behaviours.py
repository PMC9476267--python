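"""The eleven daily grazing-personality behaviours, day filters, per-cow profiles.

Metrics are computed per cow per civil day (configurable timezone, default
UTC) from cleaned, DEM-annotated trajectories:

==================  ======  =====================================================
behaviour           units   definition
==================  ======  =====================================================
ho_dist             m/d     sum of planar distances between consecutive fixes
ve_dist             m/d     sum of |elevation change| between consecutive fixes
three_d_dist        m/d     sum of 3-D distances (hypotenuse of step and dz)
ele_range           m       daily max elevation - min elevation
ele_gain            m/d     sum of positive elevation changes
rel_ele             0-1     (cow mean elev - herd min) / herd elevation range
rel_ele85           0-1     (cow 85th elev quantile - herd min) / herd range
rel_ele_range       0-1     cow elevation range / herd elevation range
slope85             %       85th quantile of per-fix slope (degrees also kept)
hr_mcp              ha/d    area of the 100% minimum convex polygon of fixes
sp_tortuosity       m/ha    ho_dist / hr_mcp (undefined on zero-area days)
==================  ======  =====================================================

"Herd" for the relative metrics is the mob sharing a paddock that day.
Quantiles use linear interpolation between order statistics.

Filters mirror the field protocol: a day is valid when at least 75% of the
expected fixes were recorded (216 of 288 at 5-min cadence); analysis windows
keep, per mob, the first up to 28 days on which the herd-level median per-fix
slope exceeds 8 degrees; cows with fewer than 7 retained valid days are
excluded entirely.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .config import Thresholds

log = logging.getLogger(__name__)

BEHAVIOURS = (
    "ho_dist", "ve_dist", "three_d_dist", "ele_range", "ele_gain",
    "rel_ele", "rel_ele85", "rel_ele_range", "slope85", "hr_mcp",
    "sp_tortuosity",
)


def expected_fixes_per_day(fix_interval: int) -> int:
    return 86400 // fix_interval


def min_fixes_per_day(fix_interval: int, rate: float = 0.75) -> int:
    """Minimum fix count for a valid day (216 at 5-min cadence, 75% rate)."""
    return int(np.ceil(rate * expected_fixes_per_day(fix_interval)))


# ---------------------------------------------------------------------------
# per-day metrics
# ---------------------------------------------------------------------------

def daily_distances(x, y, elev):
    """(ho_dist, ve_dist, three_d_dist, ele_gain, ele_range) for one cow-day.

    Elevation terms are NaN-tolerant: steps with a missing elevation on
    either end contribute horizontal distance only.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    elev = np.asarray(elev, float)
    if len(x) < 2:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    step = np.hypot(np.diff(x), np.diff(y))
    dz = np.diff(elev)
    dz_ok = np.nan_to_num(dz)
    ho = float(step.sum())
    ve = float(np.abs(dz_ok).sum())
    d3 = float(np.hypot(step, dz_ok).sum())
    gain = float(np.clip(dz_ok, 0.0, None).sum())
    finite = elev[np.isfinite(elev)]
    rng = float(finite.max() - finite.min()) if len(finite) else np.nan
    return ho, ve, d3, gain, rng


def mcp_area(x, y) -> float:
    """Area of the convex hull of the day's fixes, in hectares.

    Fewer than 3 distinct non-collinear points give area 0.
    """
    pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    if len(pts) < 3:
        return 0.0
    return float(MultiPoint(pts).convex_hull.area) / 1e4


def tortuosity(ho_dist: float, hr_mcp: float) -> float:
    """ho_dist / hr_mcp in m/ha; NaN when the day's polygon has zero area."""
    if hr_mcp > 0:
        return ho_dist / hr_mcp
    return np.nan


def slope_q85(slope_values) -> float:
    v = np.asarray(slope_values, float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan
    return float(np.quantile(v, 0.85))  # linear-interpolation quantile


def compute_daily_records(annotated: pd.DataFrame, tz: str = "UTC") -> pd.DataFrame:
    """One row per cow-day with all per-cow behaviours (relative metrics later).

    ``annotated`` is a cleaned fix table with ``elevation``, ``slope_pct`` and
    ``slope_deg`` columns.  The civil date in ``tz`` defines the day boundary.
    """
    df = annotated.copy()
    ts = df["timestamp"]
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    df["date"] = ts.dt.tz_convert(tz).dt.date
    rows = []
    for (cow_id, date), sub in df.groupby(["cow_id", "date"], sort=True):
        x = sub["x"].to_numpy(float)
        y = sub["y"].to_numpy(float)
        elev = sub["elevation"].to_numpy(float)
        ho, ve, d3, gain, erange = daily_distances(x, y, elev)
        hr = mcp_area(x, y)
        finite = elev[np.isfinite(elev)]
        rows.append({
            "cow_id": cow_id,
            "date": date,
            "fix_count": len(sub),
            "ho_dist": ho,
            "ve_dist": ve,
            "three_d_dist": d3,
            "ele_gain": gain,
            "ele_range": erange,
            "ele_mean": float(finite.mean()) if len(finite) else np.nan,
            "ele_q85": float(np.quantile(finite, 0.85)) if len(finite) else np.nan,
            "slope85": slope_q85(sub["slope_pct"]),
            "slope85_deg": slope_q85(sub["slope_deg"]),
            "hr_mcp": hr,
            "sp_tortuosity": tortuosity(ho, hr),
        })
    return pd.DataFrame(rows)


def herd_relative(daily: pd.DataFrame, annotated: pd.DataFrame,
                  mob_of: pd.Series, tz: str = "UTC") -> pd.DataFrame:
    """Add rel_ele, rel_ele85 and rel_ele_range columns to ``daily``.

    Herd statistics (min, max elevation) are taken over all fixes of all cows
    of the same mob on the same day.  Days whose herd elevation range is zero
    get NaN relative metrics.
    """
    df = annotated.copy()
    ts = df["timestamp"]
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    df["date"] = ts.dt.tz_convert(tz).dt.date
    df["mob"] = df["cow_id"].map(mob_of)
    herd = df.groupby(["mob", "date"])["elevation"].agg(["min", "max"])
    herd["range"] = herd["max"] - herd["min"]
    out = daily.copy()
    out["mob"] = out["cow_id"].map(mob_of)
    key = pd.MultiIndex.from_arrays([out["mob"], out["date"]])
    hmin = herd["min"].reindex(key).to_numpy()
    hrange = herd["range"].reindex(key).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_ele = (out["ele_mean"].to_numpy() - hmin) / hrange
        rel_ele85 = (out["ele_q85"].to_numpy() - hmin) / hrange
        rel_range = out["ele_range"].to_numpy() / hrange
    bad = ~(hrange > 0)
    for arr in (rel_ele, rel_ele85, rel_range):
        arr[bad] = np.nan
    out["rel_ele"] = rel_ele
    out["rel_ele85"] = rel_ele85
    out["rel_ele_range"] = rel_range
    if bad.any():
        log.warning("%d cow-days with zero herd elevation range flagged", int(bad.sum()))
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_days(daily: pd.DataFrame, fix_interval: int, rate: float = 0.75) -> pd.DataFrame:
    """Set the ``valid`` flag from the recording-rate rule."""
    threshold = min_fixes_per_day(fix_interval, rate)
    out = daily.copy()
    out["valid"] = out["fix_count"] >= threshold
    log.info("day filter: >= %d fixes required; %d/%d cow-days valid",
             threshold, int(out["valid"].sum()), len(out))
    return out


def select_window(daily: pd.DataFrame, annotated: pd.DataFrame,
                  mob_of: pd.Series, thresholds: Thresholds) -> pd.DataFrame:
    """Apply the terrain gate and the 7-28 day analysis window.

    Per mob, keep the first up to ``max_days`` days (chronologically from
    deployment start) whose herd-level median per-fix slope exceeds
    ``slope_gate_deg``; then drop cows with fewer than ``min_days`` retained
    valid days.  Returns the retained valid cow-day records.
    """
    df = annotated.copy()
    ts = df["timestamp"]
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    df["date"] = ts.dt.tz_convert(thresholds.timezone).dt.date
    df["mob"] = df["cow_id"].map(mob_of)
    med = df.groupby(["mob", "date"])["slope_deg"].median()
    keep_dates: dict = {}
    for mob, sub in med.groupby(level="mob"):
        passing = [d for (_, d), v in sub.items() if v > thresholds.slope_gate_deg]
        if not passing:
            log.warning("mob %s never passes the %g-degree slope gate; excluded",
                        mob, thresholds.slope_gate_deg)
            continue
        keep_dates[mob] = set(sorted(passing)[: thresholds.max_days])
    out = daily.copy()
    if "mob" not in out.columns:
        out["mob"] = out["cow_id"].map(mob_of)
    gate = [
        (m in keep_dates) and (d in keep_dates[m])
        for m, d in zip(out["mob"], out["date"])
    ]
    out = out.loc[np.asarray(gate) & out["valid"].to_numpy()]
    n_days = out.groupby("cow_id").size()
    keep_cows = n_days[n_days >= thresholds.min_days].index
    dropped = sorted(set(out["cow_id"]) - set(keep_cows))
    if dropped:
        log.info("excluded %d cows with < %d retained valid days",
                 len(dropped), thresholds.min_days)
    return out[out["cow_id"].isin(keep_cows)].reset_index(drop=True)


def aggregate_profiles(retained: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-cow arithmetic means across retained valid days, joined to metadata.

    Days with undefined tortuosity (zero-area polygons) are excluded pairwise
    from that behaviour's mean only.  Cows without metadata are dropped with
    a warning.
    """
    cols = [c for c in list(BEHAVIOURS) + ["slope85_deg"] if c in retained.columns]
    prof = retained.groupby("cow_id")[cols].mean()  # skipna by default
    prof["n_valid_days"] = retained.groupby("cow_id").size()
    prof = prof.reset_index()
    merged = prof.merge(metadata, on="cow_id", how="left", validate="one_to_one")
    missing = merged["genotype"].isna()
    if missing.any():
        log.warning("dropping %d cows with no metadata", int(missing.sum()))
        merged = merged[~missing]
    return merged.reset_index(drop=True)


def compute_behaviours(annotated: pd.DataFrame, metadata: pd.DataFrame,
                       thresholds: Thresholds | None = None):
    """Full metric stage: daily records, filters, per-cow profiles.

    Returns ``(daily, retained, profiles)`` where ``daily`` holds every
    cow-day, ``retained`` the cow-days surviving all filters and ``profiles``
    the per-cow means joined to metadata.
    """
    thresholds = thresholds or Thresholds()
    mob_of = metadata.set_index("cow_id")["mob"]
    daily = compute_daily_records(annotated, thresholds.timezone)
    daily = herd_relative(daily, annotated, mob_of, thresholds.timezone)
    daily = filter_days(daily, thresholds.fix_interval, thresholds.day_rate_min)
    retained = select_window(daily, annotated, mob_of, thresholds)
    profiles = aggregate_profiles(retained, metadata)
    return daily, retained, profiles
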