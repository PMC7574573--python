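"""Per-dive environmental covariates from tag sensor profiles.

The ascent phase of each dive is treated as an upper-water-column cast:
mean temperature over the top 50 m (T50), mixed-layer depth (MLD), and
the diffuse light attenuation coefficient (LA, per metre) from a linear
regression of the tag's log-scaled light level (LL) on depth.  LA is
inverted through a bio-optical model

    K_d = K_w + chi * chla**e

to estimate chlorophyll-a concentration (mg m^-3).  Chl-a estimates are
restricted to dives reaching >= 50 m whose midpoint falls within the
4-hour window around local noon (10:00-14:00 Atlantic Standard Time,
UTC-4) to limit solar-zenith effects.  Bottom-phase mean depth and
temperature describe conditions where a benthic forager actually feeds.

The tag's light sensor maps 10 decades of irradiance
(5e-12 .. 5e-2 W cm^-2) onto LL in [25, 225], i.e. 20 LL units per
decade, so an OLS slope b of LL on depth converts to attenuation as
LA = -b * ln(10) / 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .dives import Dive
from .tag_io import LL_MAX, LL_MIN

#: LL units per decade of irradiance (sensor range 25-225 over 10 decades)
LL_UNITS_PER_DECADE = 20.0

#: offset of Atlantic Standard Time from UTC (no DST)
AST_UTC_OFFSET = timedelta(hours=-4)
NOON_WINDOW = (10, 14)  # [10:00, 14:00) AST
CHLA_MIN_DEPTH = 50.0


@dataclass(frozen=True)
class BioOpticalModel:
    """Attenuation-chlorophyll relation K_d = K_w + chi * chla**e.

    Defaults are Morel-type open-ocean coefficients; users with a
    locally validated model supply their own.  ``K_w`` is pure-water
    attenuation (m^-1).
    """

    K_w: float = 0.04
    chi: float = 0.0518
    e: float = 0.428

    def __post_init__(self):
        if self.chi <= 0 or self.e <= 0:
            raise ValueError("bio-optical coefficients chi and e must be > 0")

    def forward(self, chla):
        """Diffuse attenuation K_d (m^-1) at chlorophyll ``chla``."""
        return self.K_w + self.chi * np.asarray(chla, float) ** self.e

    def invert(self, K_d):
        """Chlorophyll (mg m^-3) from attenuation; 0 at or below K_w."""
        K_d = np.asarray(K_d, float)
        excess = np.maximum(K_d - self.K_w, 0.0)
        return (excess / self.chi) ** (1.0 / self.e)


def upper_column_temperature(dive: Dive, max_depth: float = 50.0) -> float | None:
    """Mean ascent-phase temperature over the upper ``max_depth`` metres."""
    asc = dive.phase("ascent")
    sel = asc["depth_m"] <= max_depth
    if not sel.any():
        return None
    return float(asc.loc[sel, "temp_c"].mean())


def estimate_light_attenuation(
    dive: Dive,
    units_per_decade: float = LL_UNITS_PER_DECADE,
    max_depth: float = 50.0,
    min_samples: int = 5,
) -> float | None:
    """Light attenuation LA (m^-1) from OLS of LL on ascent depth.

    Samples pinned at the sensor limits (LL = 25 or 225, saturation or
    floor clipping) are excluded; at least ``min_samples`` unclipped
    upper-column samples and non-degenerate depth spread are required.
    Negative slopes of LL with height (i.e. positive with depth) clamp
    to LA = 0.
    """
    asc = dive.phase("ascent")
    sel = (
        (asc["depth_m"] <= max_depth)
        & (asc["ll"] > LL_MIN)
        & (asc["ll"] < LL_MAX)
    )
    z = asc.loc[sel, "depth_m"].to_numpy(float)
    ll = asc.loc[sel, "ll"].to_numpy(float)
    if z.size < min_samples or np.ptp(z) == 0:
        return None
    slope = np.polyfit(z, ll, 1)[0]
    return max(0.0, -slope * np.log(10.0) / units_per_decade)


def in_noon_window(dive: Dive) -> bool:
    """Whether the dive's temporal midpoint lies in 10:00-14:00 AST."""
    mid = dive.start + (dive.end - dive.start) / 2
    mid_ast = pd.Timestamp(mid).tz_convert("UTC") + AST_UTC_OFFSET
    return NOON_WINDOW[0] <= mid_ast.hour < NOON_WINDOW[1]


def estimate_chla(
    LA: float | None,
    dive: Dive,
    model: BioOpticalModel | None = None,
) -> float | None:
    """Chlorophyll-a (mg m^-3) by bio-optical inversion of LA.

    Defined only for dives reaching >= 50 m with midpoints inside the
    noon window; otherwise the estimate is unreliable and ``None`` is
    returned.
    """
    if LA is None:
        return None
    if dive.max_depth < CHLA_MIN_DEPTH or not in_noon_window(dive):
        return None
    model = model or BioOpticalModel()
    return float(model.invert(LA))


def mixed_layer_depth(
    dive: Dive,
    delta_T: float = 0.5,
    surface_ref_depth: float = 5.0,
) -> tuple[float, bool] | None:
    """MLD: shallowest ascent depth where temperature departs from the
    near-surface mean by >= ``delta_T`` degC.

    Returns ``(mld_m, bottom_limited)``; ``bottom_limited`` is True when
    no departure is found and the deepest sampled depth is reported.
    ``None`` when there are no near-surface samples or the profile spans
    less than 10 m.
    """
    asc = dive.phase("ascent")
    z = asc["depth_m"].to_numpy(float)
    T = asc["temp_c"].to_numpy(float)
    if z.size == 0 or np.ptp(z) < 10.0:
        return None
    surf = z <= surface_ref_depth
    if not surf.any():
        return None
    ref = float(T[surf].mean())
    order = np.argsort(z, kind="stable")
    dev = np.abs(T[order] - ref) >= delta_T
    if dev.any():
        return float(z[order][np.argmax(dev)]), False
    return float(z.max()), True


def bottom_conditions(dive: Dive) -> tuple[float, float]:
    """Mean depth (m) and temperature (degC) over the bottom phase."""
    bot = dive.phase("bottom")
    return float(bot["depth_m"].mean()), float(bot["temp_c"].mean())


def enviro_table(
    dives: list[Dive],
    stats: pd.DataFrame,
    model: BioOpticalModel | None = None,
) -> pd.DataFrame:
    """Per-dive environmental covariate table.

    Columns: ``seal_id, dive_start, dive_end, T50, mld_m, la_per_m,
    chla_mg_m3, bot_depth_m, bot_temp_c, bot_dur_s, noon``; undefined
    estimates are NaN.
    """
    bot_dur = dict(zip(zip(stats["start"], stats["end"]), stats["bottom_duration_s"]))
    rows = []
    for d in dives:
        la = estimate_light_attenuation(d)
        mld = mixed_layer_depth(d)
        bd, bt = bottom_conditions(d)
        rows.append(
            {
                "seal_id": d.seal_id,
                "dive_start": d.start,
                "dive_end": d.end,
                "T50": upper_column_temperature(d),
                "mld_m": mld[0] if mld is not None else np.nan,
                "la_per_m": la if la is not None else np.nan,
                "chla_mg_m3": (
                    c if (c := estimate_chla(la, d, model)) is not None else np.nan
                ),
                "bot_depth_m": bd,
                "bot_temp_c": bt,
                "bot_dur_s": bot_dur.get((d.start, d.end), np.nan),
                "noon": in_noon_window(d),
            }
        )
    return pd.DataFrame(rows)
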