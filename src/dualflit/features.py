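"""Division-event feature extraction.

Each parent -> two-daughter division is summarized by a 38-dimensional
feature vector: per-cell reporter statistics (min/max/mean/variance of the
stemness and commitment reporters for the parent and both daughters),
lifetimes and their difference, further-division flags, daughter contrasts,
terminal commitment values and slopes, generation and division time.  The
registry is data-driven so individual features can be renamed or replaced
while the count stays fixed at 38.

Daughters are canonically ordered by descending lifetime-mean commitment
signal before extraction, which makes asymmetric divisions well-posed and the
vector invariant to the raw daughter order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import simulate as sim
from .fluorsig import Trace

N_FEATURES = 38

_CELL_STATS = ("min", "max", "mean", "var")


def _cell_feature_names(prefix: str) -> list[str]:
    return [f"{prefix}_{ch}_{st}" for ch in ("stem", "commit") for st in _CELL_STATS]


#: Names of the 38 features, in vector order.
FEATURE_NAMES: list[str] = (
    _cell_feature_names("parent")            # f1-f8
    + _cell_feature_names("daughter_high")   # f9-f16
    + _cell_feature_names("daughter_low")    # f17-f24
    + ["parent_lifetime_h",                  # f25
       "daughter_high_lifetime_h",           # f26
       "daughter_low_lifetime_h",            # f27
       "lifetime_difference_h",              # f28
       "daughter_high_divides_again",        # f29
       "daughter_low_divides_again",         # f30
       "daughter_stem_mean_contrast",        # f31
       "daughter_commit_mean_contrast",      # f32
       "daughter_high_final_commit",         # f33
       "daughter_low_final_commit",          # f34
       "daughter_high_commit_slope_per_h",   # f35
       "daughter_low_commit_slope_per_h",    # f36
       "parent_generation",                  # f37
       "division_time_h"]                    # f38
)
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass(frozen=True)
class DivisionEvent:
    """A parent -> two-daughter division with canonically ordered daughters."""

    sequence_id: str
    parent: int
    daughter_high: int   # larger lifetime-mean commitment signal
    daughter_low: int
    division_time_h: float
    parent_generation: int


TraceMap = Mapping[tuple[int, str], Trace]


def _norm_values(traces: TraceMap, track: int, channel: str) -> np.ndarray:
    key = (track, channel)
    if key not in traces:
        raise ValueError(f"no {channel} trace for track {track}")
    tr = traces[key]
    if tr.normalized is None:
        raise ValueError(f"track {track}: trace not normalized")
    vals = tr.normalized[~tr.missing]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"track {track}: zero non-missing frames")
    return vals


def _mean_commit(traces: TraceMap, track: int) -> float:
    return float(_norm_values(traces, track, sim.COMMIT_CHANNEL).mean())


def make_division_event(sequence_id: str, parent: int, daughter_a: int,
                        daughter_b: int, division_time_h: float,
                        parent_generation: int, traces: TraceMap) -> DivisionEvent:
    """Build an event, ordering the daughters by lifetime-mean commitment.

    Ties fall back to the lower track id as daughter_high so the ordering is
    independent of the argument order.
    """
    ma, mb = _mean_commit(traces, daughter_a), _mean_commit(traces, daughter_b)
    if (ma, -daughter_a) >= (mb, -daughter_b):
        high, low = daughter_a, daughter_b
    else:
        high, low = daughter_b, daughter_a
    return DivisionEvent(sequence_id, parent, high, low, division_time_h,
                         parent_generation)


def _slope_per_h(traces: TraceMap, track: int) -> float:
    tr = traces[(track, sim.COMMIT_CHANNEL)]
    ok = ~tr.missing & ~np.isnan(tr.normalized)
    t, y = tr.times_h[ok], tr.normalized[ok]
    if t.size < 2 or np.ptp(t) == 0:
        return 0.0
    return float(np.polyfit(t, y, 1)[0])


def extract_features(event: DivisionEvent, traces: TraceMap,
                     divides_again: Mapping[int, bool]) -> np.ndarray:
    """Compute the 38-feature vector of one division event.

    Statistics run over each track's full lifetime on normalized traces,
    skipping missing frames; slopes over fewer than 2 frames are 0.
    """
    vec: list[float] = []
    for track in (event.parent, event.daughter_high, event.daughter_low):
        for channel in (sim.STEM_CHANNEL, sim.COMMIT_CHANNEL):
            v = _norm_values(traces, track, channel)
            vec.extend([float(v.min()), float(v.max()), float(v.mean()),
                        float(v.var())])
    life = {t: traces[(t, sim.COMMIT_CHANNEL)].lifetime_h
            for t in (event.parent, event.daughter_high, event.daughter_low)}
    vec.append(life[event.parent])
    vec.append(life[event.daughter_high])
    vec.append(life[event.daughter_low])
    vec.append(abs(life[event.daughter_high] - life[event.daughter_low]))
    vec.append(float(bool(divides_again.get(event.daughter_high, False))))
    vec.append(float(bool(divides_again.get(event.daughter_low, False))))
    mean_stem = {t: float(_norm_values(traces, t, sim.STEM_CHANNEL).mean())
                 for t in (event.daughter_high, event.daughter_low)}
    vec.append(abs(mean_stem[event.daughter_high] - mean_stem[event.daughter_low]))
    vec.append(abs(_mean_commit(traces, event.daughter_high)
                   - _mean_commit(traces, event.daughter_low)))
    for t in (event.daughter_high, event.daughter_low):
        vec.append(float(_norm_values(traces, t, sim.COMMIT_CHANNEL)[-1]))
    vec.append(_slope_per_h(traces, event.daughter_high))
    vec.append(_slope_per_h(traces, event.daughter_low))
    vec.append(float(event.parent_generation))
    vec.append(float(event.division_time_h))
    out = np.asarray(vec, dtype=np.float64)
    if out.size != N_FEATURES:
        raise AssertionError("feature registry out of sync")
    if not np.all(np.isfinite(out)):
        bad = [FEATURE_NAMES[i] for i in np.where(~np.isfinite(out))[0]]
        raise ValueError(f"non-finite features {bad} for parent {event.parent}")
    return out


# --------------------------------------------------------------------------- #
# standardization
# --------------------------------------------------------------------------- #

@dataclass
class FeatureScaling:
    """Frozen z-scoring parameters and per-feature weights.

    Population (n-denominator) standard deviation; zero-variance columns get
    sd 1 so they standardize to 0 rather than blowing up.
    """

    mean: np.ndarray
    sd: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.mean, self.sd, self.weights):
            if np.asarray(arr).shape != (N_FEATURES,):
                raise ValueError(f"scaling arrays must have length {N_FEATURES}")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist(),
                "weights": self.weights.tolist(), "features": FEATURE_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaling":
        return cls(np.asarray(d["mean"], dtype=np.float64),
                   np.asarray(d["sd"], dtype=np.float64),
                   np.asarray(d["weights"], dtype=np.float64))


def standardize(matrix: np.ndarray,
                weights: Optional[np.ndarray] = None
                ) -> tuple[np.ndarray, FeatureScaling]:
    """Column-wise z-score the training matrix, then apply feature weights."""
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected an (n, {N_FEATURES}) matrix")
    if X.shape[0] < 2:
        raise ValueError("standardization needs >= 2 rows")
    w = np.ones(N_FEATURES) if weights is None else np.asarray(weights, float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)          # population convention (ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    scaling = FeatureScaling(mean, sd, w)
    return apply_scaling(X, scaling), scaling


def apply_scaling(vectors: np.ndarray, scaling: FeatureScaling) -> np.ndarray:
    """Apply a previously fitted scaling; never refits."""
    X = np.asarray(vectors, dtype=np.float64)
    if X.shape[-1] != N_FEATURES:
        raise ValueError(f"expected feature dimension {N_FEATURES}")
    return (X - scaling.mean) / scaling.sd * scaling.weights


# --------------------------------------------------------------------------- #
# bridges and I/O
# --------------------------------------------------------------------------- #

def traces_from_clone(clone: sim.SimulatedClone) -> dict[tuple[int, str], Trace]:
    """Wrap a simulated clone's ground-truth traces as normalized Traces."""
    out: dict[tuple[int, str], Trace] = {}
    for (cid, ch), vals in clone.true_traces.items():
        if vals.size == 0:
            continue
        first, _ = clone.frames[cid]
        tr = Trace(cid, ch, first, raw=vals.copy(),
                   missing=np.zeros(vals.size, dtype=bool))
        tr.smoothed = vals.copy()
        tr.normalized = vals.copy()
        tr.norm_bounds = (0.0, 1.0, "observed")
        out[(cid, ch)] = tr
    return out


def events_from_clone(clone: sim.SimulatedClone, traces: TraceMap,
                      max_generation: Optional[int] = None
                      ) -> tuple[list[DivisionEvent], dict[int, bool], list[str]]:
    """All usable division events of a clone, plus divides-again flags.

    Returns (events, divides_again, true_labels) aligned with the ground
    truth.  Divisions whose daughters have no observable frames (division at
    the very end of the window) are skipped.  ``max_generation`` keeps only
    divisions producing generation <= max_generation.
    """
    divides_again = {cid: clone.cells[cid].fate == "divided" for cid in clone.cells}
    events, labels = [], []
    for cell in clone.divisions():
        gen_out = cell.generation + 1
        if max_generation is not None and gen_out > max_generation:
            continue
        d1, d2 = cell.children
        try:
            ev = make_division_event(clone.preset_name, cell.cell_id, d1, d2,
                                     cell.end_time, cell.generation, traces)
        except ValueError:
            continue  # daughter unobservable within the window
        events.append(ev)
        labels.append(cell.division_type)
    return events, divides_again, labels


def feature_matrix(events: Sequence[DivisionEvent], traces: TraceMap,
                   divides_again: Mapping[int, bool]) -> np.ndarray:
    return np.vstack([extract_features(e, traces, divides_again)
                      for e in events]) if events else np.empty((0, N_FEATURES))


def matrix_to_frame(matrix: np.ndarray,
                    events: Sequence[DivisionEvent]) -> pd.DataFrame:
    df = pd.DataFrame(matrix, columns=FEATURE_NAMES)
    df.insert(0, "sequence", [e.sequence_id for e in events])
    df.insert(1, "parent", [e.parent for e in events])
    return df


def write_scaling(scaling: FeatureScaling, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(scaling.to_dict(), fh, indent=2)


def read_scaling(path: str | Path) -> FeatureScaling:
    with open(path) as fh:
        return FeatureScaling.from_dict(json.load(fh))


__all__ = [
    "N_FEATURES", "FEATURE_NAMES", "DivisionEvent", "FeatureScaling",
    "make_division_event", "extract_features", "standardize", "apply_scaling",
    "traces_from_clone", "events_from_clone", "feature_matrix",
    "matrix_to_frame", "write_scaling", "read_scaling",
]
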