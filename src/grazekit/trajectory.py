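"""Fix tables and per-cow trajectories: reading, step statistics, outlier removal.

A fix table is a tidy DataFrame with columns ``cow_id``, ``timestamp`` (UTC),
``x``, ``y`` (metres in a planar projection).  A trajectory is the per-cow
time-ordered fix table augmented with per-step statistics: ``dt`` (s),
``step`` (m), ``speed`` (m/s), ``heading`` (rad, counterclockwise from +x) and
``turn`` (rad in (-pi, pi]); all of these describe the *incoming* step of each
fix, so the first row carries NaN.  Turning angles across recording gaps
longer than ``gap_tolerance`` are flagged undefined (``turn_valid`` False)
while distances still accumulate across the gap.

GPS outliers are detected with the classic speed/turn signature: a fix is
flagged when its incoming speed alone is impossibly high, or when both the
incoming and outgoing speeds are elevated *and* the path doubles back sharply
(the teleport-and-return "spike").
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cow_id", "timestamp", "x", "y")

# default thresholds; exposed through PipelineConfig and logged into outputs
SPEED_MAX = 2.5         # m/s, sustained speed no grazing cow reaches
SPIKE_SPEED = 1.5       # m/s, elevated speed on both sides of a spike
TURN_MIN = np.radians(150.0)  # doubling back


class SchemaError(ValueError):
    """A required column is missing or a row cannot be parsed."""


def read_fixes(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a fix table from CSV (default) or GPX.

    Duplicate (cow_id, timestamp) rows are dropped (first kept, count logged)
    and rows are sorted by cow then time.
    """
    if fmt is None:
        fmt = "gpx" if str(path).lower().endswith(".gpx") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"fix table {path} is missing column(s) {missing}")
        try:
            df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
        except (ValueError, TypeError):
            # fall back to row-level parsing so the offending line can be named
            parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
            bad = np.flatnonzero(parsed.isna() & df["timestamp"].notna())
            if len(bad):
                raise SchemaError(
                    f"unparseable timestamp at data row {bad[0] + 1} of {path}: "
                    f"{df['timestamp'].iloc[bad[0]]!r}"
                ) from None
            df["timestamp"] = parsed
    elif fmt == "gpx":
        df = _read_gpx(path)
    else:
        raise ValueError(f"unknown fix format {fmt!r}")
    if not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
        raise SchemaError(f"non-finite coordinates in {path}")
    n0 = len(df)
    df = df.drop_duplicates(subset=["cow_id", "timestamp"], keep="first")
    if len(df) < n0:
        log.warning("dropped %d duplicate (cow_id, timestamp) rows", n0 - len(df))
    return df.sort_values(["cow_id", "timestamp"], kind="mergesort").reset_index(drop=True)


_GPX_NS = "http://www.topografix.com/GPX/1/1"


def _read_gpx(path) -> pd.DataFrame:
    """GPX trackpoints; one <trk> per cow (name = cow_id).

    Coordinates are taken verbatim (lat -> y, lon -> x): this package works in
    planar metric coordinates throughout, and GPX is accepted only as a
    container under that documented assumption.
    """
    root = ET.parse(path).getroot()
    ns = {"g": _GPX_NS}
    rows = []
    for trk in root.findall("g:trk", ns):
        name_el = trk.find("g:name", ns)
        cow_id = name_el.text if name_el is not None else "track"
        for pt in trk.iter(f"{{{_GPX_NS}}}trkpt"):
            time_el = pt.find("g:time", ns)
            rows.append(
                (cow_id, time_el.text if time_el is not None else None,
                 float(pt.get("lon")), float(pt.get("lat")))
            )
    if not rows:
        raise SchemaError(f"no trackpoints found in {path}")
    df = pd.DataFrame(rows, columns=["cow_id", "timestamp", "x", "y"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_gpx(fixes: pd.DataFrame, path) -> None:
    """Write a fix table as GPX (one track per cow; x -> lon, y -> lat)."""
    gpx = ET.Element("gpx", attrib={"version": "1.1", "creator": "grazekit", "xmlns": _GPX_NS})
    for cow_id, sub in fixes.groupby("cow_id", sort=True):
        trk = ET.SubElement(gpx, "trk")
        ET.SubElement(trk, "name").text = str(cow_id)
        seg = ET.SubElement(trk, "trkseg")
        for row in sub.itertuples():
            pt = ET.SubElement(seg, "trkpt", attrib={"lat": repr(float(row.y)), "lon": repr(float(row.x))})
            ET.SubElement(pt, "time").text = row.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ")
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# step statistics
# ---------------------------------------------------------------------------

def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out


def build_trajectory(fixes: pd.DataFrame, gap_tolerance: float | None = None,
                     fix_interval: float = 300.0) -> pd.DataFrame:
    """Compute per-step statistics for a single cow's ordered fixes.

    ``gap_tolerance`` defaults to twice ``fix_interval``; turning angles whose
    incoming or previous step spans a longer gap are flagged undefined.
    Returns a copy with columns dt, step, speed, heading, turn, turn_valid.
    """
    if gap_tolerance is None:
        gap_tolerance = 2.0 * fix_interval
    traj = fixes.sort_values("timestamp", kind="mergesort").reset_index(drop=True).copy()
    n = len(traj)
    if n < 2:
        for c in ("dt", "step", "speed", "heading", "turn"):
            traj[c] = np.nan
        traj["turn_valid"] = False
        traj.attrs["empty"] = True
        return traj
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    t = traj["timestamp"].to_numpy("datetime64[ns]").astype("int64") / 1e9
    dt = np.full(n, np.nan)
    dt[1:] = np.diff(t)
    if np.any(dt[1:] <= 0):
        raise ValueError("timestamps must be strictly increasing within a cow")
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.full(n, np.nan)
    step[1:] = np.hypot(dx, dy)
    heading = np.full(n, np.nan)
    heading[1:] = np.arctan2(dy, dx)
    turn = np.full(n, np.nan)
    turn[2:] = wrap_angle(heading[2:] - heading[1:-1])
    turn_valid = np.isfinite(turn)
    # undefined across gaps: either the incoming or the previous step too long
    gap = dt > gap_tolerance
    turn_valid[2:] &= ~(gap[2:] | gap[1:-1])
    turn = np.where(turn_valid, turn, np.nan)
    traj["dt"] = dt
    traj["step"] = step
    traj["speed"] = step / dt
    traj["heading"] = heading
    traj["turn"] = turn
    traj["turn_valid"] = turn_valid
    traj.attrs["empty"] = False
    return traj


def detect_outliers(traj: pd.DataFrame, speed_max: float = SPEED_MAX,
                    spike_speed: float = SPIKE_SPEED,
                    turn_min: float = TURN_MIN) -> np.ndarray:
    """Flag GPS outlier fixes; returns a boolean vector aligned with rows.

    A fix is flagged when both its incoming and outgoing speeds exceed
    ``speed_max`` (a position no grazing animal can hold on either side), or
    when both exceed the lower ``spike_speed`` while the turning angle at the
    fix exceeds ``turn_min`` in magnitude (the teleport-and-return spike).
    Requiring the speed excess on *both* sides keeps the legitimate fix after
    a teleport -- whose incoming speed is inflated only because its
    predecessor was bad -- from being flagged along with the bad one.
    The input is not modified.
    """
    if speed_max <= 0 or spike_speed <= 0 or turn_min <= 0:
        raise ValueError("outlier thresholds must be positive")
    n = len(traj)
    if n == 0:
        return np.zeros(0, dtype=bool)
    speed_in = traj["speed"].to_numpy(float)          # incoming step of fix i
    speed_out = np.full(n, np.nan)
    speed_out[:-1] = speed_in[1:]                      # outgoing step of fix i
    heading = traj["heading"].to_numpy(float)
    # turn *at* fix i = change of direction between incoming and outgoing step
    turn_at = np.full(n, np.nan)
    turn_at[1:-1] = np.abs(wrap_angle(heading[2:] - heading[1:-1]))
    with np.errstate(invalid="ignore"):
        flags = ((speed_in > speed_max) & (speed_out > speed_max)) | (
            (speed_in > spike_speed) & (speed_out > spike_speed) & (turn_at > turn_min)
        )
    return flags  # NaN comparisons are False, so endpoints default to kept


def remove_and_rebuild(traj: pd.DataFrame, flags: np.ndarray, **build_kw) -> pd.DataFrame:
    """Drop flagged fixes and recompute all step statistics on the remainder."""
    if len(flags) != len(traj):
        raise ValueError("flags do not align with fixes")
    kept = traj.loc[~np.asarray(flags, dtype=bool), list(REQUIRED_COLUMNS) +
                    [c for c in traj.columns if c not in REQUIRED_COLUMNS and
                     c not in ("dt", "step", "speed", "heading", "turn", "turn_valid")]]
    return build_trajectory(kept.reset_index(drop=True), **build_kw)


def clean_fixes(fixes: pd.DataFrame, speed_max: float = SPEED_MAX,
                spike_speed: float = SPIKE_SPEED, turn_min: float = TURN_MIN,
                fix_interval: float = 300.0) -> tuple[pd.DataFrame, int]:
    """Detect-and-remove outliers for every cow; returns (trajectories, n_removed).

    The result concatenates per-cow rebuilt trajectories.  Cows with fewer
    than 2 fixes after cleaning are dropped (flagged in the log).
    """
    out = []
    n_removed = 0
    for cow_id, sub in fixes.groupby("cow_id", sort=True):
        traj = build_trajectory(sub, fix_interval=fix_interval)
        if traj.attrs.get("empty"):
            log.warning("cow %s has <2 fixes; excluded", cow_id)
            continue
        flags = detect_outliers(traj, speed_max, spike_speed, turn_min)
        n_removed += int(flags.sum())
        if flags.any():
            traj = remove_and_rebuild(traj, flags, fix_interval=fix_interval)
        if traj.attrs.get("empty"):
            log.warning("cow %s empty after outlier removal; excluded", cow_id)
            continue
        out.append(traj)
    if not out:
        return fixes.iloc[0:0].copy(), n_removed
    res = pd.concat(out, ignore_index=True)
    log.info("outlier filter removed %d of %d fixes", n_removed, len(fixes))
    return res, n_removed
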