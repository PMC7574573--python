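"""Dive detection, phase segmentation and dive-statistic filtering.

The depth series is first zero-offset corrected (ZOC) to remove pressure
transducer drift: within rolling windows, a low quantile of near-surface
readings estimates the surface baseline, which is interpolated in time
and subtracted.  Dives are maximal wet submergences bounded by the
surface; dives shallower than 5 m or longer than 30 min are discarded.
Each dive is split into descent / bottom / ascent, the bottom phase
being the contiguous envelope of samples at depths >= 80% of the dive's
maximum depth.  Implausible dives (descent or ascent rate >= 6 m/s or
exactly 0, duration <= 20 s) are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fraction of max depth defining the bottom phase
BOTTOM_FRACTION = 0.8
MAX_DIVE_DURATION_S = 30 * 60.0
MIN_DIVE_DEPTH_M = 5.0


@dataclass
class Dive:
    """One detected dive: its samples and descent/bottom/ascent bounds.

    ``i_bottom_start``/``i_bottom_end`` are inclusive sample indices into
    ``samples`` of the first and last sample at >= 80% of max depth.
    """

    seal_id: str
    samples: pd.DataFrame  # columns timestamp, depth_m, temp_c, ll, wet
    i_bottom_start: int = field(default=-1)
    i_bottom_end: int = field(default=-1)

    @property
    def start(self):
        return self.samples["timestamp"].iloc[0]

    @property
    def end(self):
        return self.samples["timestamp"].iloc[-1]

    @property
    def max_depth(self) -> float:
        return float(self.samples["depth_m"].max())

    def phase(self, name: str) -> pd.DataFrame:
        """Samples of one phase: 'descent', 'bottom' or 'ascent'."""
        i0, i1 = self.i_bottom_start, self.i_bottom_end
        if name == "descent":
            return self.samples.iloc[:i0]
        if name == "bottom":
            return self.samples.iloc[i0 : i1 + 1]
        if name == "ascent":
            return self.samples.iloc[i1 + 1 :]
        raise ValueError(f"unknown phase {name!r}")


def zero_offset_correct(
    records: pd.DataFrame,
    window_hours: float = 6.0,
    surface_quantile: float = 0.05,
    surface_max_depth: float = 10.0,
) -> pd.DataFrame:
    """Remove transducer drift by subtracting a rolling surface baseline.

    Within each ``window_hours`` window the baseline is the
    ``surface_quantile`` of readings shallower than ``surface_max_depth``
    (the seal surfaces between dives, so those readings should read 0).
    Baselines at window centres are linearly interpolated over time;
    windows with no near-surface readings carry the previous baseline.
    Corrected depths are clamped at 0.
    """
    records = records.sort_values("timestamp", kind="stable").reset_index(drop=True)
    t = records["timestamp"].to_numpy("datetime64[ns]").astype("int64") / 1e9
    depth = records["depth_m"].to_numpy(float)

    win = window_hours * 3600.0
    t0, t1 = t[0], t[-1]
    n_win = max(1, int(np.ceil((t1 - t0) / win)))
    knot_t, knot_v = [], []
    for k in range(n_win):
        lo, hi = t0 + k * win, t0 + (k + 1) * win
        sel = np.flatnonzero((t >= lo) & (t < hi) & (depth < surface_max_depth))
        if sel.size == 0:
            warnings.warn("ZOC window without surface readings; carrying baseline")
            continue
        q = float(np.quantile(depth[sel], surface_quantile))
        # anchor the knot where the quantile occurs, so a drifting offset
        # is tracked without the lag a window-centre anchor would add
        j = sel[np.argmin(np.abs(depth[sel] - q))]
        knot_t.append(t[j])
        knot_v.append(q)

    if not knot_t:
        baseline = np.zeros_like(depth)
    elif len(knot_t) == 1:
        baseline = np.full_like(depth, knot_v[0])
    else:
        from scipy.interpolate import interp1d

        f = interp1d(knot_t, knot_v, kind="linear", bounds_error=False,
                     fill_value="extrapolate", assume_sorted=True)
        baseline = f(t)
    out = records.copy()
    out["depth_m"] = np.maximum(depth - baseline, 0.0)
    return out


def detect_dives(
    records: pd.DataFrame,
    depth_threshold: float = MIN_DIVE_DEPTH_M,
    max_duration_s: float = MAX_DIVE_DURATION_S,
) -> list[Dive]:
    """Extract dives from ZOC-corrected records of one seal.

    A dive is a maximal run of wet samples at depth > 0 bounded by the
    surface.  Dives with max depth < ``depth_threshold`` (surface
    splashing, near-surface rolling) or duration > ``max_duration_s``
    (merged-dive artifacts) are discarded here.
    """
    seal_id = str(records["seal_id"].iloc[0]) if "seal_id" in records else ""
    depth = records["depth_m"].to_numpy(float)
    wet = records["wet"].to_numpy(bool)
    sub = (depth > 0) & wet

    # run boundaries of the submerged mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], sub.view(np.int8), [0]))))
    dives: list[Dive] = []
    for s, e in zip(edges[::2], edges[1::2]):  # [s, e) submerged run
        chunk = records.iloc[s:e]
        if chunk["depth_m"].max() < depth_threshold:
            continue
        dur = (
            chunk["timestamp"].iloc[-1] - chunk["timestamp"].iloc[0]
        ).total_seconds()
        if dur > max_duration_s:
            continue
        d = Dive(seal_id=seal_id, samples=chunk.reset_index(drop=True))
        d.i_bottom_start, d.i_bottom_end = split_phases(d)
        dives.append(d)
    return dives


def split_phases(dive: Dive) -> tuple[int, int]:
    """Bottom-phase bounds: the contiguous envelope of samples at
    depth >= 80% of max depth; descent precedes it, ascent follows.

    Wiggles above the 80% line inside the envelope remain part of the
    bottom phase.  A V-shaped dive yields a single-sample bottom.
    """
    depth = dive.samples["depth_m"].to_numpy(float)
    if depth.size < 3:
        raise ValueError("dive needs >= 3 samples to split phases")
    cutoff = BOTTOM_FRACTION * depth.max()
    idx = np.flatnonzero(depth >= cutoff)
    return int(idx[0]), int(idx[-1])


def dive_stats(dive: Dive) -> dict:
    """Summary statistics: duration, max depth, phase rates and bottom time.

    Phase durations are spans between boundary sample times, so they sum
    exactly to the dive duration.  Descent/ascent rate is max depth over
    the phase duration (vendor-summary convention).
    """
    t = dive.samples["timestamp"]
    i0, i1 = dive.i_bottom_start, dive.i_bottom_end
    duration = (t.iloc[-1] - t.iloc[0]).total_seconds()
    descent_dur = (t.iloc[i0] - t.iloc[0]).total_seconds()
    bottom_dur = (t.iloc[i1] - t.iloc[i0]).total_seconds()
    ascent_dur = (t.iloc[-1] - t.iloc[i1]).total_seconds()
    maxd = dive.max_depth
    return {
        "seal_id": dive.seal_id,
        "start": t.iloc[0],
        "end": t.iloc[-1],
        "duration_s": duration,
        "max_depth_m": maxd,
        "descent_rate": maxd / descent_dur if descent_dur > 0 else 0.0,
        "ascent_rate": maxd / ascent_dur if ascent_dur > 0 else 0.0,
        "bottom_duration_s": bottom_dur,
    }


def filter_dives(stats: pd.DataFrame) -> pd.DataFrame:
    """Drop biologically implausible dives.

    Removes dives with descent or ascent rate >= 6 m/s (faster than the
    animal can swim) or exactly 0 (phase-detection failure), and dives
    <= 20 s (misidentified surface behaviour).
    """
    ok = (
        (stats["descent_rate"] < 6.0)
        & (stats["descent_rate"] > 0.0)
        & (stats["ascent_rate"] < 6.0)
        & (stats["ascent_rate"] > 0.0)
        & (stats["duration_s"] > 20.0)
    )
    return stats.loc[ok].reset_index(drop=True)


def process_tag_records(
    records: pd.DataFrame,
    zoc_window_hours: float = 6.0,
    apply_zoc: bool = True,
) -> tuple[list[Dive], pd.DataFrame]:
    """Full dive pipeline for one seal: ZOC -> detect -> stats -> filter.

    Returns the dives surviving the statistic filters and their table.
    """
    rec = zero_offset_correct(records, zoc_window_hours) if apply_zoc else records
    dives = detect_dives(rec)
    if not dives:
        return [], pd.DataFrame(
            columns=[
                "seal_id", "start", "end", "duration_s", "max_depth_m",
                "descent_rate", "ascent_rate", "bottom_duration_s",
            ]
        )
    stats = pd.DataFrame([dive_stats(d) for d in dives])
    kept = filter_dives(stats)
    keep_ix = set(
        kept.set_index(["start", "end"]).index
    )
    dives_kept = [
        d for d in dives if (d.start, d.end) in keep_ix
    ]
    return dives_kept, kept
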