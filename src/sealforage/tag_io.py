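"""Tag-archive and GPS CSV I/O plus location quality control.

File formats
------------
Tag archive CSV (one row per 10-s sample):
    ``seal_id,timestamp,depth_m,temp_c,ll,wet``
GPS fix CSV (one row per Fastloc fix):
    ``seal_id,timestamp,lon,lat,nsats,residual``

Timestamps are ISO-8601 in UTC.  Light level (``ll``) is the tag's
log-scaled three-digit value in [25, 225]; ``wet`` is 0/1.

Quality control removes fixes derived from fewer than 5 satellites or
with residual error above 30, then applies a 10 m/s speed filter that
greedily removes the fix implicated in the worst great-circle speed
violation until no consecutive pair exceeds the threshold.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAG_COLUMNS = ["seal_id", "timestamp", "depth_m", "temp_c", "ll", "wet"]
GPS_COLUMNS = ["seal_id", "timestamp", "lon", "lat", "nsats", "residual"]

LL_MIN, LL_MAX = 25.0, 225.0
#: shallowest admissible raw depth (m); small negative readings are
#: transducer drift and are handled by zero-offset correction downstream
DEPTH_FLOOR = -2.0

EARTH_RADIUS_KM = 6371.0088


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def read_tag_archive(path) -> tuple[dict[str, pd.DataFrame], int]:
    """Read a tag archive CSV into per-seal, time-sorted sample tables.

    Malformed rows (unparseable fields, light level outside the sensor
    range, physically impossible depths) are dropped and counted rather
    than raised.  Returns ``(records_by_seal, n_skipped)``.
    """
    df = pd.read_csv(path, dtype={"seal_id": str})
    _require_columns(df, TAG_COLUMNS, path)
    n_in = len(df)

    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    for col in ("depth_m", "temp_c", "ll"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["wet"] = pd.to_numeric(df["wet"], errors="coerce")

    ok = (
        df["timestamp"].notna()
        & df["depth_m"].notna()
        & df["temp_c"].notna()
        & df["ll"].between(LL_MIN, LL_MAX)
        & (df["depth_m"] >= DEPTH_FLOOR)
        & df["wet"].isin([0, 1])
    )
    n_skipped = int(n_in - ok.sum())
    if n_skipped:
        logger.warning("read_tag_archive: skipped %d malformed row(s)", n_skipped)
    df = df.loc[ok].copy()
    df["wet"] = df["wet"].astype(bool)

    out: dict[str, pd.DataFrame] = {}
    for seal_id, grp in df.groupby("seal_id", sort=True):
        if not grp["timestamp"].is_monotonic_increasing:
            warnings.warn(f"seal {seal_id}: out-of-order timestamps re-sorted")
            grp = grp.sort_values("timestamp", kind="stable")
        out[seal_id] = grp.reset_index(drop=True)
    return out, n_skipped


def write_tag_archive(records: pd.DataFrame, path) -> None:
    """Write tag samples (columns as in :data:`TAG_COLUMNS`) to CSV."""
    df = records[TAG_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    df["wet"] = df["wet"].astype(int)
    df.to_csv(path, index=False)


def read_gps(path) -> pd.DataFrame:
    """Read a GPS fix CSV, parse timestamps, and sort within seal."""
    df = pd.read_csv(path, dtype={"seal_id": str})
    _require_columns(df, GPS_COLUMNS, path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    df = df.dropna(subset=["timestamp", "lon", "lat"])
    df = df.sort_values(["seal_id", "timestamp"], kind="stable")
    return df.reset_index(drop=True)


def write_gps(fixes: pd.DataFrame, path) -> None:
    df = fixes[GPS_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    df.to_csv(path, index=False)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (km) between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _pair_speeds(fixes: pd.DataFrame) -> np.ndarray:
    """Speeds (m/s) between consecutive fixes; length len(fixes)-1."""
    lon = fixes["lon"].to_numpy(float)
    lat = fixes["lat"].to_numpy(float)
    t = fixes["timestamp"].to_numpy("datetime64[ns]").astype("int64") / 1e9
    dist_m = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) * 1000.0
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt > 0, dist_m / dt, np.inf)
    return v


def _speed_filter_one(fixes: pd.DataFrame, max_speed: float) -> pd.DataFrame:
    """Greedy single-fix removal until all consecutive speeds <= max_speed.

    At each pass, the fix participating in the fastest violating segment
    is removed — of its two endpoints, the one whose removal lowers the
    local maximum speed the most (ties break toward the later fix).
    """
    fixes = fixes.reset_index(drop=True)
    while len(fixes) >= 2:
        v = _pair_speeds(fixes)
        worst = int(np.argmax(v))
        if v[worst] <= max_speed:
            break

        def local_max_without(idx: int) -> float:
            sub = fixes.drop(index=idx).reset_index(drop=True)
            if len(sub) < 2:
                return 0.0
            lo = max(0, idx - 2)
            hi = min(len(sub) - 1, idx + 1)
            return float(np.max(_pair_speeds(sub.iloc[lo : hi + 1])))

        drop = worst if local_max_without(worst) < local_max_without(worst + 1) else worst + 1
        fixes = fixes.drop(index=drop).reset_index(drop=True)
    return fixes


def filter_gps(fixes: pd.DataFrame, max_speed: float = 10.0) -> pd.DataFrame:
    """Apply satellite/residual quality control and the speed filter.

    Fixes from < 5 satellites or with residual error > 30 are removed;
    remaining fixes then pass through the greedy 10 m/s speed filter,
    per seal.  Input must be time-sorted within seal.
    """
    good = (fixes["nsats"] >= 5) & (fixes["residual"] <= 30)
    kept = fixes.loc[good]
    out = []
    for seal_id, grp in kept.groupby("seal_id", sort=True):
        if len(grp) < 2:
            warnings.warn(f"seal {seal_id}: fewer than 2 fixes after quality filter")
            out.append(grp)
            continue
        out.append(_speed_filter_one(grp, max_speed))
    if not out:
        return kept.reset_index(drop=True)
    return pd.concat(out, ignore_index=True)
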