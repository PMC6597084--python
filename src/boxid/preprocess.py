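"""Raw sensor streams -> deduplicated, normalized 7-D records.

The seven features are hour of day, latitude, longitude, accelerometer-norm
mean, accelerometer-norm standard deviation, battery status and WiFi router
count, each scaled to [0, 1].  Streams are first aggregated to the duty-cycle
level (at most one row per participant per cycle), merged, geographically
filtered, cleaned of gross accelerometer outliers, and min-max normalized
with dataset-wide bounds; exact duplicate 7-tuples are dropped last because
coincident points confuse the box-counting decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RawSensorLog

logger = logging.getLogger(__name__)

FEATURES = ["hour01", "lat01", "lon01", "acc01", "sd01", "bat01", "wifi01"]

#: Default geographic filter bounds (lon_min, lon_max, lat_min, lat_max) —
#: the urban extent the pipeline was designed around.
DEFAULT_GEO_BOUNDS = (-106.7649138128, -106.52225318, 52.058367, 52.214608)

BATTERY_ENCODING = {
    "not charging": 0.0,
    "charging ac": 0.25,
    "charging usb": 0.5,
    "charging wireless": 1.0,
}


@dataclass
class NormalizedDataset:
    """Finalized records plus per-stage provenance counts."""

    records: pd.DataFrame
    d: int = 7
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.records)

    def to_points(self) -> np.ndarray:
        return self.records[FEATURES].to_numpy(dtype=float)


def encode_battery(status: str) -> float:
    """Map a charging-status string to its code on the [0, 1] scale.

    Not Charging -> 0, Charging AC -> 0.25, Charging USB -> 0.5,
    Charging Wireless -> 1 (note the deliberate gap at 0.75).  Matching is
    case-insensitive; anything else is an error.
    """
    key = str(status).strip().lower()
    if key not in BATTERY_ENCODING:
        raise ValueError(f"unrecognized battery status: {status!r}")
    return BATTERY_ENCODING[key]


def _last_per_cycle(df: pd.DataFrame, period: int, cols: list[str]) -> pd.DataFrame:
    """Most recent row per (participant, cycle); ties broken by input order."""
    out = df.copy()
    out["cycle"] = (out["timestamp"] // period).astype(np.int64)
    out = out.sort_values(["participant", "cycle", "timestamp"], kind="stable")
    dup = out.duplicated(subset=["participant", "cycle", "timestamp"], keep="last")
    if dup.any():
        logger.warning(
            "%d duplicate timestamps within a stream; keeping last", int(dup.sum())
        )
    out = out.groupby(["participant", "cycle"], as_index=False).last()
    return out[["participant", "cycle", "timestamp"] + cols]


def aggregate_to_duty_cycle(raw: RawSensorLog, period: int | None = None) -> pd.DataFrame:
    """Aggregate the four streams to one row per participant per duty cycle.

    GPS, battery (and the timestamp used for the hour feature) take the most
    recent in-cycle value; accelerometer samples reduce to the mean and
    population standard deviation of their L2 norms over the cycle; WiFi
    reduces to the count of distinct router MACs.  A cycle with no GPS fix is
    dropped entirely (indoors: the whole record is ignored), as is any cycle
    missing one of the other streams, since all seven features are required.
    """
    p = period if period is not None else raw.duty_period_s

    gps = _last_per_cycle(raw.gps, p, ["lat", "lon"])

    acc = raw.accel.copy()
    acc["norm"] = np.sqrt(acc["x"] ** 2 + acc["y"] ** 2 + acc["z"] ** 2)
    acc["cycle"] = (acc["timestamp"] // p).astype(np.int64)
    acc_g = acc.groupby(["participant", "cycle"])["norm"].agg(
        acc_mean="mean", acc_sd=lambda v: float(np.std(v, ddof=0))
    ).reset_index()

    bat = _last_per_cycle(raw.battery, p, ["status"])

    wifi = raw.wifi.copy()
    wifi["cycle"] = (wifi["timestamp"] // p).astype(np.int64)
    wifi_g = (
        wifi.groupby(["participant", "cycle"])["mac"]
        .nunique()
        .rename("wifi_count")
        .reset_index()
    )

    merged = gps.merge(acc_g, on=["participant", "cycle"], how="inner")
    merged = merged.merge(
        bat.drop(columns=["timestamp"]), on=["participant", "cycle"], how="inner"
    )
    merged = merged.merge(wifi_g, on=["participant", "cycle"], how="left")
    merged["wifi_count"] = merged["wifi_count"].fillna(0).astype(int)
    merged["hour"] = (merged["timestamp"].astype(np.int64) % 86400) // 3600
    return merged


def filter_geo(
    table: pd.DataFrame,
    lon_min: float = DEFAULT_GEO_BOUNDS[0],
    lon_max: float = DEFAULT_GEO_BOUNDS[1],
    lat_min: float = DEFAULT_GEO_BOUNDS[2],
    lat_max: float = DEFAULT_GEO_BOUNDS[3],
) -> pd.DataFrame:
    """Keep rows inside the bounding box, boundary values included."""
    for lo, hi, name in ((lon_min, lon_max, "lon"), (lat_min, lat_max, "lat")):
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid {name} bounds: [{lo}, {hi}]")
    keep = (
        table["lon"].between(lon_min, lon_max)
        & table["lat"].between(lat_min, lat_max)
    )
    return table[keep].reset_index(drop=True)


def remove_outliers_3sd(values) -> np.ndarray:
    """Boolean keep-mask: drop values more than 3 SDs from the mean.

    Mean and SD are computed once over the whole input (single pass, not
    iterative).  Zero spread keeps everything.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mu, sd = v.mean(), v.std(ddof=0)
    if sd == 0:
        return np.ones(v.size, dtype=bool)
    return np.abs(v - mu) <= 3.0 * sd


def _minmax(col: pd.Series, name: str) -> pd.Series:
    lo, hi = col.min(), col.max()
    if hi == lo:
        logger.warning("feature %s is degenerate (min == max); set to 0", name)
        return pd.Series(np.zeros(len(col)), index=col.index)
    return (col - lo) / (hi - lo)


def normalize_features(table: pd.DataFrame) -> NormalizedDataset:
    """Scale the merged per-cycle table into final [0,1] 7-tuples.

    Hour is divided by 23 (so both 0 and 1 are attainable), battery uses the
    fixed categorical codes, and latitude, longitude, both accelerometer
    features and the WiFi count are min-max scaled with bounds taken over the
    whole dataset (across participants).  Zero-WiFi rows are removed before
    scaling; exact duplicates on all seven fields are dropped (keep first).
    """
    prov: dict[str, int] = {"normalize_in": len(table)}
    t = table[table["wifi_count"] > 0].copy()
    prov["after_wifi_nonzero"] = len(t)
    out = pd.DataFrame(
        {
            "hour01": t["hour"].astype(float) / 23.0,
            "lat01": _minmax(t["lat"], "lat"),
            "lon01": _minmax(t["lon"], "lon"),
            "acc01": _minmax(t["acc_mean"], "acc_mean"),
            "sd01": _minmax(t["acc_sd"], "acc_sd"),
            "bat01": t["status"].map(encode_battery),
            "wifi01": _minmax(t["wifi_count"].astype(float), "wifi_count"),
        }
    )
    out = out.drop_duplicates(keep="first").reset_index(drop=True)
    prov["after_dedup"] = len(out)
    return NormalizedDataset(records=out, d=7, provenance=prov)


def preprocess(
    raw: RawSensorLog,
    period: int | None = None,
    geo_bounds: tuple[float, float, float, float] = DEFAULT_GEO_BOUNDS,
) -> NormalizedDataset:
    """Full pipeline: aggregate -> geo filter -> 3-SD outlier removal ->
    normalize/dedup, with provenance counts at every stage."""
    agg = aggregate_to_duty_cycle(raw, period)
    prov = {"aggregated": len(agg)}
    geo = filter_geo(agg, *geo_bounds)
    prov["after_geo_filter"] = len(geo)
    if len(geo) >= 2:
        keep = remove_outliers_3sd(geo["acc_mean"]) & remove_outliers_3sd(
            geo["acc_sd"]
        )
        geo = geo[keep].reset_index(drop=True)
    prov["after_outlier_removal"] = len(geo)
    ds = normalize_features(geo)
    ds.provenance = {**prov, **ds.provenance}
    return ds
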