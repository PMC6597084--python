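"""Synthetic inputs with known ground truth.

Two families of generators:

* geometric point sets (Sierpinski gasket via the chaos game, uniform
  k-dimensional planes embedded in ``[0,1]^d``) whose intrinsic dimension is
  known in closed form, used to validate the box-counting estimator; and

* duty-cycled smartphone sensor logs that emulate the structure of
  multi-participant behavioral studies — GPS fixes around a few anchor
  locations inside an urban bounding box, accelerometer bursts whose mean and
  spread both track an activity level, diurnal battery charging, and
  location-dependent WiFi router visibility — used to exercise the full
  preprocessing + estimation pipeline end to end.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Urban bounding box used by default for synthetic GPS: a prairie-city
#: rectangle roughly 17 x 17 km (lon_min, lon_max, lat_min, lat_max).
DEFAULT_BBOX = (-106.7649138128, -106.52225318, 52.058367, 52.214608)

BATTERY_STATUSES = (
    "Not Charging",
    "Charging AC",
    "Charging USB",
    "Charging Wireless",
)

#: Chaos-game iterations discarded before points are emitted.
SIERPINSKI_BURN_IN = 100


@dataclass(frozen=True)
class SyntheticSpec:
    """Reproducible description of a synthetic point-set draw."""

    kind: str
    n_points: int
    embed_dim: int
    intrinsic_dim: float | str
    seed: int
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate(spec: SyntheticSpec) -> np.ndarray:
    """Dispatch a :class:`SyntheticSpec` to the matching generator."""
    if spec.kind == "sierpinski":
        return gen_sierpinski(spec.n_points, spec.seed, spec.embed_dim)
    if spec.kind == "kplane":
        k = int(spec.intrinsic_dim)
        return gen_kplane(k, spec.embed_dim, spec.n_points, spec.seed, spec.noise_sd)
    raise ValueError(f"unknown generator kind: {spec.kind!r}")


def gen_sierpinski(n_points: int, seed: int, embed_dim: int = 2) -> np.ndarray:
    """Sample the Sierpinski gasket by the chaos game.

    Starting from an interior point, repeatedly jump halfway toward a
    uniformly chosen vertex of the unit-base equilateral triangle; after a
    burn-in the iterates are (approximately) uniform on the gasket, whose
    similarity dimension is ``log 3 / log 2`` — strictly between 1 and 2.
    Coordinates beyond the first two are held at 0.5.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if embed_dim < 2:
        raise ValueError("embed_dim must be >= 2 for the Sierpinski gasket")
    rng = np.random.default_rng(seed)
    vertices = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3.0) / 2.0]])
    total = SIERPINSKI_BURN_IN + n_points
    choices = rng.integers(0, 3, size=total)
    pts = np.empty((total, 2))
    x = np.array([0.25, 0.25])
    for i, c in enumerate(choices):
        x = 0.5 * (x + vertices[c])
        pts[i] = x
    out = pts[SIERPINSKI_BURN_IN:]
    if embed_dim > 2:
        full = np.full((n_points, embed_dim), 0.5)
        full[:, :2] = out
        return full
    return out


def gen_kplane(
    k: int, d: int, n_points: int, seed: int, noise_sd: float = 0.0
) -> np.ndarray:
    """Uniform sample of a k-dimensional axis-aligned slice of ``[0,1]^d``.

    The first ``k`` axes are uniform on [0, 1]; the remaining ``d - k`` axes
    are fixed at 0.5 (interior, so the half-open box convention is never
    stressed).  Optional isotropic Gaussian jitter is clipped back to [0, 1].
    """
    if not (1 <= k <= d):
        raise ValueError(f"need 1 <= k <= d, got k={k}, d={d}")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    pts = np.full((n_points, d), 0.5)
    pts[:, :k] = rng.uniform(0.0, 1.0, size=(n_points, k))
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
        np.clip(pts, 0.0, 1.0, out=pts)
    return pts


# ---------------------------------------------------------------------------
# Duty-cycled sensor-log simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShedConfig:
    """Parameters of the sensor-log simulator.

    Defaults emulate a duty cycle of one active minute every five, 2-3
    anchor locations (home / work / a third place) per participant inside
    the urban bounding box, GPS noise of about 10 m (1e-4 degrees), an
    indoor fraction of cycles with no GPS fix, overnight AC charging, and
    accelerometer noise whose scale follows a per-cycle activity level so
    that the per-cycle mean and standard deviation of the norm co-vary.
    """

    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    duty_period_s: int = 300
    active_window_s: int = 60
    gps_noise_sd_deg: float = 1e-4
    p_gps_missing: float = 0.2
    p_transit: float = 0.05
    accel_samples_per_cycle: int = 12
    gravity: float = 9.81
    accel_noise_base: float = 0.02
    accel_noise_scale: float = 0.8
    accel_motion_scale: float = 2.0
    routers_per_anchor: tuple[int, int, int] = (8, 15, 6)
    p_router_seen: float = 0.7
    n_street_routers: int = 40

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.bbox
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ValueError(f"empty bounding box: {self.bbox}")
        if self.active_window_s > self.duty_period_s:
            raise ValueError("active window cannot exceed duty period")


@dataclass
class RawSensorLog:
    """Four raw sensor tables keyed by participant id and epoch timestamp."""

    gps: pd.DataFrame
    accel: pd.DataFrame
    battery: pd.DataFrame
    wifi: pd.DataFrame
    duty_period_s: int = 300
    active_window_s: int = 60

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "gps": self.gps,
            "accel": self.accel,
            "battery": self.battery,
            "wifi": self.wifi,
        }

    def write_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False)


def _mac(i: int) -> str:
    return ":".join(f"{(i >> (8 * j)) & 0xFF:02X}" for j in range(5, -1, -1))


def gen_shed_like(
    n_participants: int,
    n_days: int,
    seed: int,
    config: ShedConfig | None = None,
) -> RawSensorLog:
    """Simulate duty-cycled raw sensor logs for a multi-participant study."""
    if n_participants < 1 or n_days < 1:
        raise ValueError("n_participants and n_days must be >= 1")
    cfg = config or ShedConfig()
    rng = np.random.default_rng(seed)
    lon_min, lon_max, lat_min, lat_max = cfg.bbox
    lon_span, lat_span = lon_max - lon_min, lat_max - lat_min
    n_cycles = (86400 * n_days) // cfg.duty_period_s

    gps_parts, accel_parts, bat_parts, wifi_parts = [], [], [], []
    street_pool = np.arange(cfg.n_street_routers)
    next_router = cfg.n_street_routers

    for pid in range(n_participants):
        # anchors in the interior 80% of the box: home, work, third place
        anchors = np.column_stack(
            [
                lon_min + lon_span * rng.uniform(0.1, 0.9, size=3),
                lat_min + lat_span * rng.uniform(0.1, 0.9, size=3),
            ]
        )
        anchor_routers = []
        for n_r in cfg.routers_per_anchor:
            anchor_routers.append(np.arange(next_router, next_router + n_r))
            next_router += n_r

        starts = np.arange(n_cycles, dtype=np.int64) * cfg.duty_period_s
        hours = (starts % 86400) // 3600

        # anchor schedule: overnight+evening home, working hours work,
        # some evenings at the third place
        state = np.zeros(n_cycles, dtype=int)  # 0 home, 1 work, 2 third
        state[(hours >= 9) & (hours <= 17)] = 1
        evening = (hours >= 18) & (hours <= 21)
        state[evening & (rng.random(n_cycles) < 0.3)] = 2
        transit = rng.random(n_cycles) < cfg.p_transit

        lon = anchors[state, 0] + rng.normal(0, cfg.gps_noise_sd_deg, n_cycles)
        lat = anchors[state, 1] + rng.normal(0, cfg.gps_noise_sd_deg, n_cycles)
        n_tr = int(transit.sum())
        lon[transit] = rng.uniform(lon_min, lon_max, n_tr)
        lat[transit] = rng.uniform(lat_min, lat_max, n_tr)

        # GPS: one fix per cycle, some cycles indoors with no fix at all
        gps_seen = rng.random(n_cycles) >= cfg.p_gps_missing
        gps_ts = starts + rng.uniform(0, cfg.active_window_s, n_cycles)
        gps_parts.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "timestamp": gps_ts[gps_seen],
                    "lat": lat[gps_seen],
                    "lon": lon[gps_seen],
                }
            )
        )

        # battery: overnight AC charging, mostly discharging otherwise
        night = (hours >= 23) | (hours <= 6)
        status = np.where(
            night & (rng.random(n_cycles) < 0.9),
            "Charging AC",
            rng.choice(
                BATTERY_STATUSES, size=n_cycles, p=[0.92, 0.02, 0.05, 0.01]
            ),
        )
        bat_ts = starts + rng.uniform(0, cfg.active_window_s, n_cycles)
        bat_parts.append(
            pd.DataFrame(
                {"participant": pid, "timestamp": bat_ts, "status": status}
            )
        )

        # accelerometer: noise scale and a sustained-motion offset both follow
        # a per-cycle activity level, so the per-cycle mean of the norm and
        # its SD are strongly correlated.  Overnight the phone rests (near-
        # zero activity), making night records nearly coincident — the source
        # of deep co-location in the decomposition.
        sedentary = rng.random(n_cycles) < 0.85  # sitting / phone at rest
        activity = np.where(
            night,
            rng.uniform(0.0, 0.01, n_cycles),
            np.where(
                sedentary,
                rng.uniform(0.0, 0.03, n_cycles),
                rng.uniform(0.1, 0.4, n_cycles),
            ),
        )
        activity[transit] = rng.uniform(0.4, 0.8, n_tr)
        sigma = cfg.accel_noise_base + cfg.accel_noise_scale * activity
        motion = cfg.accel_motion_scale * activity  # sustained-motion offset
        m = cfg.accel_samples_per_cycle
        noise = rng.normal(size=(n_cycles, m, 3)) * sigma[:, None, None]
        xyz = noise + np.array([0.0, 0.0, cfg.gravity])
        xyz[:, :, 2] += motion[:, None]
        offs = np.linspace(1.0, cfg.active_window_s - 1.0, m)
        acc_ts = (starts[:, None] + offs[None, :]).ravel()
        accel_parts.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "timestamp": acc_ts,
                    "x": xyz[:, :, 0].ravel(),
                    "y": xyz[:, :, 1].ravel(),
                    "z": xyz[:, :, 2].ravel(),
                }
            )
        )

        # WiFi: anchor-specific router sets; only a handful seen in transit
        wifi_ts = starts + rng.uniform(0, cfg.active_window_s, n_cycles)
        rows_ts, rows_mac = [], []
        for s in range(3):
            at_anchor = (state == s) & ~transit
            idx = np.nonzero(at_anchor)[0]
            routers = anchor_routers[s]
            seen = rng.random((idx.size, routers.size)) < cfg.p_router_seen
            ci, ri = np.nonzero(seen)
            rows_ts.append(wifi_ts[idx[ci]])
            rows_mac.append(routers[ri])
        tr_idx = np.nonzero(transit)[0]
        n_seen = rng.poisson(1.5, tr_idx.size).clip(0, 5)
        for i, cnt in zip(tr_idx, n_seen):
            if cnt:
                macs = rng.choice(street_pool, size=cnt, replace=False)
                rows_ts.append(np.full(cnt, wifi_ts[i]))
                rows_mac.append(macs)
        all_ts = np.concatenate(rows_ts) if rows_ts else np.array([])
        all_mac = np.concatenate(rows_mac) if rows_mac else np.array([], int)
        order = np.argsort(all_ts, kind="stable")
        wifi_parts.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "timestamp": all_ts[order],
                    "mac": [_mac(int(r)) for r in all_mac[order]],
                }
            )
        )

    return RawSensorLog(
        gps=pd.concat(gps_parts, ignore_index=True),
        accel=pd.concat(accel_parts, ignore_index=True),
        battery=pd.concat(bat_parts, ignore_index=True),
        wifi=pd.concat(wifi_parts, ignore_index=True),
        duty_period_s=cfg.duty_period_s,
        active_window_s=cfg.active_window_s,
    )
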