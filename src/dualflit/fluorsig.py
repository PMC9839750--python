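"""Fluorescence signal treatment.

Temporal homogenization of frame means (power-law trend for the stemness/GFP
channel with residual ambient autofluorescence, linear trend for the
commitment/mCherry channel), overexposed-frame rejection, per-cell mean
extraction within tracked masks, window-5 moving-average smoothing, per
sequence min/max normalization with an optional post-differentiation 99th
percentile reference, and quintile coding for lineage-tree heatmaps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import simulate as sim
from .tracking import CellTrack, TrackSet


@dataclass(frozen=True)
class FluorChannel:
    """Acquisition properties of one fluorescence channel."""

    name: str
    trend_form: str = "linear"            # "power_law" | "linear"
    saturation_value: float = 4095.0
    overexposure_fraction_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.trend_form not in ("power_law", "linear"):
            raise ValueError(f"unknown trend form {self.trend_form!r}")
        if not (0.0 < self.overexposure_fraction_threshold <= 1.0):
            raise ValueError("overexposure threshold must be in (0,1]")


def default_channels() -> dict[str, FluorChannel]:
    """Stemness channel fitted with a power law (ambient autofluorescence
    decays over the run), commitment channel with a linear trend."""
    return {
        sim.STEM_CHANNEL: FluorChannel(sim.STEM_CHANNEL, "power_law"),
        sim.COMMIT_CHANNEL: FluorChannel(sim.COMMIT_CHANNEL, "linear"),
    }


@dataclass
class HomogenizationFit:
    """Fitted temporal trend of per-frame mean intensities.

    power_law: g(t) = a * t**b + c with t 1-based; linear: g(t) = a*t + b.
    """

    form: str
    params: tuple[float, ...]
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def trend(self, frames: np.ndarray | Sequence[int]) -> np.ndarray:
        t = np.asarray(frames, dtype=np.float64) + 1.0
        if self.form == "power_law":
            a, b, c = self.params
            return a * t ** b + c
        a, b = self.params
        return a * t + b

    def to_dict(self) -> dict:
        return {"form": self.form, "params": list(self.params)}


@dataclass
class Trace:
    """Per-track, per-channel fluorescence signal on the 20-min frame grid.

    Arrays are aligned: index i corresponds to frame ``first_frame + i``.
    ``missing`` marks frames where the signal is undefined (overexposed frame
    or cell absent); normalized values live in [0, 1] on non-missing frames.
    """

    track_id: int
    channel: str
    first_frame: int
    raw: np.ndarray
    missing: np.ndarray
    interval_min: float = sim.FLUOR_INTERVAL_MIN
    smoothed: Optional[np.ndarray] = None
    normalized: Optional[np.ndarray] = None
    quintile: Optional[np.ndarray] = None
    norm_bounds: Optional[tuple[float, float, str]] = None  # (min, max, max_source)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.raw.shape != self.missing.shape:
            raise ValueError("raw and missing must have equal length")

    def __len__(self) -> int:
        return self.raw.size

    @property
    def frames(self) -> np.ndarray:
        return self.first_frame + np.arange(len(self))

    @property
    def times_h(self) -> np.ndarray:
        return self.frames * self.interval_min / 60.0

    @property
    def lifetime_h(self) -> float:
        return len(self) * self.interval_min / 60.0

    def valid(self, values: Optional[np.ndarray] = None) -> np.ndarray:
        v = self.raw if values is None else values
        return v[~self.missing]


# --------------------------------------------------------------------------- #
# temporal homogenization
# --------------------------------------------------------------------------- #

def _power(t, a, b, c):
    return a * np.power(t, b) + c


def fit_temporal_trend(frame_means: np.ndarray | Sequence[float],
                       form: str = "linear") -> HomogenizationFit:
    """Least-squares fit of the frame-mean series.

    The power law is fitted by nonlinear least squares initialized from a
    log-log linear fit of the min-subtracted series; if that fails to
    converge the fit falls back to a linear trend with a warning.
    """
    m = np.asarray(frame_means, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        raise ValueError("frame means must be finite")
    t = np.arange(1, m.size + 1, dtype=np.float64)
    if form == "linear":
        if m.size < 3:
            raise ValueError("linear trend needs >= 3 frames")
        a, b = np.polyfit(t, m, 1)
        fit = HomogenizationFit("linear", (float(a), float(b)))
    elif form == "power_law":
        if m.size < 4:
            raise ValueError("power-law trend needs >= 4 frames")
        eps = 1e-9
        shifted = m - m.min() + eps
        if np.ptp(m) < 1e-12:
            fit = HomogenizationFit("power_law", (0.0, 1.0, float(m.mean())))
        else:
            slope, intercept = np.polyfit(np.log(t), np.log(shifted), 1)
            p0 = (float(np.exp(intercept)), float(slope), float(m.min()))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    params, _ = curve_fit(_power, t, m, p0=p0, maxfev=20000)
                fit = HomogenizationFit("power_law", tuple(float(p) for p in params))
                if not np.all(np.isfinite(fit.trend(np.arange(m.size)))):
                    raise RuntimeError("non-finite trend")
            except (RuntimeError, ValueError):
                warnings.warn("power-law fit did not converge; falling back to "
                              "linear trend", stacklevel=2)
                a, b = np.polyfit(t, m, 1)
                fit = HomogenizationFit("linear", (float(a), float(b)))
    else:
        raise ValueError(f"unknown trend form {form!r}")
    fit.residuals = m - fit.trend(np.arange(m.size))
    return fit


def homogenize(frames: np.ndarray, fit: HomogenizationFit) -> np.ndarray:
    """Shift every frame so its mean lands on the fitted trend.

    F'_t = F_t + (g(t) - m_t).  The output is real-valued and unclipped (it
    may go negative); mean(F'_t) equals g(t) exactly up to float error.
    """
    stack = np.asarray(frames, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, height, width) stack")
    means = stack.mean(axis=(1, 2))
    g = fit.trend(np.arange(stack.shape[0]))
    return stack + (g - means)[:, None, None]


def flag_overexposed(frames: np.ndarray, channel: FluorChannel) -> np.ndarray:
    """Flag frames whose saturated-pixel fraction reaches the threshold."""
    stack = np.asarray(frames)
    frac = (stack >= channel.saturation_value).mean(axis=(1, 2))
    return frac >= channel.overexposure_fraction_threshold


# --------------------------------------------------------------------------- #
# per-cell signal
# --------------------------------------------------------------------------- #

def extract_trace(track: CellTrack, corrected: np.ndarray, ts: TrackSet,
                  channel: str, flagged: Optional[np.ndarray] = None) -> Trace:
    """Mean corrected pixel value inside the track's mask per frame.

    Frames flagged as overexposed are marked missing; an empty mask on a live
    unflagged frame is an error naming the track and frame.
    """
    n = track.lifetime_frames
    raw = np.zeros(n)
    missing = np.zeros(n, dtype=bool)
    for i, f in enumerate(range(track.first_frame, track.last_frame + 1)):
        if flagged is not None and flagged[f]:
            missing[i] = True
            continue
        m = ts.mask(track.track_id, f)
        if not m.any():
            raise ValueError(f"track {track.track_id}: empty mask at frame {f}")
        raw[i] = corrected[f][m].mean()
    return Trace(track.track_id, channel, track.first_frame, raw, missing,
                 interval_min=ts.interval_min)


def smooth(trace: Trace, window: int = 5) -> Trace:
    """Centered moving average over non-missing frames.

    The window truncates at the track ends and skips missing frames: each
    output value is the mean of the available members of its window.  The
    window-5 default matches the acquisition pipeline this package models.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if trace.missing.all():
        raise ValueError(f"track {trace.track_id}: all frames missing")
    half = window // 2
    n = len(trace)
    out = np.full(n, np.nan)
    for i in range(n):
        if trace.missing[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = ~trace.missing[lo:hi]
        out[i] = trace.raw[lo:hi][sel].mean()
    trace.smoothed = out
    return trace


def normalize_traces(traces: Sequence[Trace],
                     differentiation_p99: Optional[float] = None) -> list[Trace]:
    """Min/max-normalize all traces of one sequence/channel jointly.

    The minimum is the smallest smoothed value over all tracks of the
    sequence; the maximum is the larger of the observed maximum and the 99th
    percentile of the post-differentiation validation image when provided.
    """
    if not traces:
        raise ValueError("no traces to normalize")
    if any(t.smoothed is None for t in traces):
        raise ValueError("smooth() must run before normalization")
    lo = min(float(np.nanmin(t.smoothed)) for t in traces)
    obs_hi = max(float(np.nanmax(t.smoothed)) for t in traces)
    if differentiation_p99 is not None and differentiation_p99 > obs_hi:
        hi, source = float(differentiation_p99), "differentiation_p99"
    else:
        hi, source = obs_hi, "observed"
    if hi <= lo:
        raise ValueError("degenerate dynamic range")
    for t in traces:
        t.normalized = np.clip((t.smoothed - lo) / (hi - lo), 0.0, 1.0)
        t.normalized[t.missing] = np.nan
        t.norm_bounds = (lo, hi, source)
    return list(traces)


def normalize(trace: Trace, differentiation_p99: Optional[float] = None) -> Trace:
    """Single-trace convenience wrapper around :func:`normalize_traces`."""
    return normalize_traces([trace], differentiation_p99)[0]


def to_quintiles(trace: Trace) -> Trace:
    """Code the normalized signal into five fixed-width bins of [0, 1].

    q = min(floor(5*s) + 1, 5); bins [0,.2) [.2,.4) [.4,.6) [.6,.8) [.8,1].
    """
    if trace.normalized is None:
        raise ValueError("normalize() must run before quintile coding")
    q = np.full(len(trace), 0, dtype=np.int64)
    ok = ~np.isnan(trace.normalized)
    q[ok] = np.minimum(np.floor(5.0 * trace.normalized[ok]).astype(np.int64) + 1, 5)
    trace.quintile = q
    return trace


def differentiation_reference(image: np.ndarray) -> float:
    """99th percentile of a post-differentiation validation image."""
    return float(np.percentile(np.asarray(image, dtype=np.float64), 99))


# --------------------------------------------------------------------------- #
# pipeline + export
# --------------------------------------------------------------------------- #

def process_sequence(ts: TrackSet, stacks: Mapping[str, np.ndarray],
                     channels: Optional[Mapping[str, FluorChannel]] = None,
                     window: int = 5,
                     differentiation_p99: Optional[Mapping[str, float]] = None,
                     ) -> tuple[dict[tuple[int, str], Trace], dict[str, HomogenizationFit]]:
    """Full signal treatment of one tracked sequence.

    Per channel: flag overexposed frames, fit the temporal trend on clean
    frames, homogenize, extract per-track raw traces, smooth, normalize
    jointly across the sequence, and quintile-code.
    """
    channels = channels or default_channels()
    traces: dict[tuple[int, str], Trace] = {}
    fits: dict[str, HomogenizationFit] = {}
    for name, stack in stacks.items():
        ch = channels[name]
        flagged = flag_overexposed(stack, ch)
        means = stack.mean(axis=(1, 2))
        # fit on clean frames only, evaluated on the full frame grid
        fit = _refit_on_grid(means, flagged, ch.trend_form)
        fits[name] = fit
        corrected = homogenize(stack, fit)
        ch_traces = []
        for tid in sorted(ts.tracks):
            tr = extract_trace(ts.tracks[tid], corrected, ts, name, flagged)
            if tr.missing.all():
                continue
            ch_traces.append(smooth(tr, window))
        ref = differentiation_p99.get(name) if differentiation_p99 else None
        for tr in normalize_traces(ch_traces, ref):
            traces[(tr.track_id, name)] = to_quintiles(tr)
    return traces, fits


def _refit_on_grid(means: np.ndarray, flagged: np.ndarray,
                   form: str) -> HomogenizationFit:
    """Fit the trend excluding flagged frames but evaluate on the full grid."""
    t_all = np.arange(1, means.size + 1, dtype=np.float64)
    t = t_all[~flagged]
    m = means[~flagged]
    if form == "linear":
        a, b = np.polyfit(t, m, 1)
        fit = HomogenizationFit("linear", (float(a), float(b)))
    else:
        eps = 1e-9
        slope, intercept = np.polyfit(np.log(t), np.log(m - m.min() + eps), 1)
        p0 = (float(np.exp(intercept)), float(slope), float(m.min()))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params, _ = curve_fit(_power, t, m, p0=p0, maxfev=20000)
            fit = HomogenizationFit("power_law", tuple(float(p) for p in params))
        except (RuntimeError, ValueError):
            a, b = np.polyfit(t, m, 1)
            fit = HomogenizationFit("linear", (float(a), float(b)))
    fit.residuals = means - fit.trend(np.arange(means.size))
    return fit


def traces_to_frame(traces: Mapping[tuple[int, str], Trace],
                    sequence_id: str = "") -> pd.DataFrame:
    """Tidy per-frame table of all traces (one row per track/channel/frame)."""
    rows = []
    for (tid, ch), tr in sorted(traces.items()):
        for i, f in enumerate(tr.frames):
            rows.append({
                "sequence": sequence_id, "track": tid, "channel": ch,
                "frame": int(f), "time_min": float(f * tr.interval_min),
                "raw": tr.raw[i],
                "smoothed": np.nan if tr.smoothed is None else tr.smoothed[i],
                "normalized": np.nan if tr.normalized is None else tr.normalized[i],
                "quintile": 0 if tr.quintile is None else int(tr.quintile[i]),
                "missing": bool(tr.missing[i]),
            })
    return pd.DataFrame(rows)


def frame_to_traces(df: pd.DataFrame) -> dict[tuple[int, str], Trace]:
    """Rebuild Trace objects from a tidy trace table (inverse of
    :func:`traces_to_frame` up to float formatting)."""
    out: dict[tuple[int, str], Trace] = {}
    for (tid, ch), grp in df.groupby(["track", "channel"], sort=True):
        grp = grp.sort_values("frame")
        interval = sim.FLUOR_INTERVAL_MIN
        if len(grp) > 1:
            interval = float(np.diff(grp["time_min"].to_numpy()).min())
        tr = Trace(int(tid), str(ch), int(grp["frame"].iloc[0]),
                   grp["raw"].to_numpy(dtype=float),
                   grp["missing"].to_numpy(dtype=bool), interval_min=interval)
        tr.smoothed = grp["smoothed"].to_numpy(dtype=float)
        tr.normalized = grp["normalized"].to_numpy(dtype=float)
        tr.quintile = grp["quintile"].to_numpy(dtype=np.int64)
        out[(int(tid), str(ch))] = tr
    return out


def write_fits(fits: Mapping[str, HomogenizationFit], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in fits.items()}, fh, indent=2)


__all__ = [
    "FluorChannel", "HomogenizationFit", "Trace", "default_channels",
    "fit_temporal_trend", "homogenize", "flag_overexposed", "extract_trace",
    "smooth", "normalize", "normalize_traces", "to_quintiles",
    "differentiation_reference", "process_sequence", "traces_to_frame",
    "write_fits",
]
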