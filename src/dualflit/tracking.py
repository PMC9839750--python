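"""Cell masks and parent-linked tracks.

Provides a deliberately simple segment-and-link tracker (global threshold +
greedy nearest-centroid linking with topological division detection) plus a
lossless reader/writer for Cell-Tracking-Challenge-style track directories,
which is the supported route for importing externally produced or manually
corrected tracks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from skimage import filters, measure

from . import simulate as sim


@dataclass
class LabeledFrame:
    """Connected-component labeling of one frame."""

    frame_index: int
    label_image: np.ndarray
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    areas: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_labels(cls, frame_index: int, label_image: np.ndarray) -> "LabeledFrame":
        lf = cls(frame_index, label_image.astype(np.int32, copy=False))
        for rp in measure.regionprops(lf.label_image):
            lf.centroids[rp.label] = tuple(rp.centroid)
            lf.areas[rp.label] = int(rp.area)
        return lf

    @property
    def labels(self) -> list[int]:
        return sorted(self.centroids)


@dataclass
class CellTrack:
    """One cell's lifetime within a tracked sequence."""

    track_id: int
    parent_id: int            # 0 = founder
    first_frame: int
    last_frame: int
    centroids: list[tuple[float, float]] = field(default_factory=list)
    end_fate: str = "survived_to_end"  # divided | died | survived_to_end

    @property
    def lifetime_frames(self) -> int:
        return self.last_frame - self.first_frame + 1


@dataclass
class TrackSet:
    """A collection of parent-linked tracks plus per-frame label images."""

    tracks: dict[int, CellTrack]
    n_frames: int
    label_images: Optional[list[np.ndarray]] = None  # labels are track ids
    sequence_id: str = ""
    interval_min: float = sim.FLUOR_INTERVAL_MIN

    def children(self, track_id: int) -> list[int]:
        return sorted(t.track_id for t in self.tracks.values()
                      if t.parent_id == track_id)

    def founders(self) -> list[int]:
        return sorted(t.track_id for t in self.tracks.values() if t.parent_id == 0)

    def mask(self, track_id: int, frame: int) -> np.ndarray:
        if self.label_images is None:
            raise ValueError("track set carries no label images")
        return self.label_images[frame] == track_id

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on the first breach."""
        if not self.founders():
            raise ValueError("track set has no founders")
        for t in self.tracks.values():
            if t.first_frame > t.last_frame:
                raise ValueError(f"track {t.track_id}: empty frame range")
            if t.parent_id:
                if t.parent_id not in self.tracks:
                    raise ValueError(f"track {t.track_id}: unknown parent {t.parent_id}")
                p = self.tracks[t.parent_id]
                if t.first_frame != p.last_frame + 1:
                    raise ValueError(
                        f"track {t.track_id}: starts at {t.first_frame}, parent "
                        f"{t.parent_id} ends at {p.last_frame}")
            kids = self.children(t.track_id)
            if t.end_fate == "divided" and len(kids) != 2:
                raise ValueError(f"track {t.track_id}: divided but {len(kids)} children")
            if t.end_fate != "divided" and kids:
                raise ValueError(f"track {t.track_id}: fate {t.end_fate} with children")
        # acyclic parent references
        for t in self.tracks.values():
            seen, cur = set(), t.track_id
            while cur:
                if cur in seen:
                    raise ValueError(f"cyclic parent links at track {cur}")
                seen.add(cur)
                cur = self.tracks[cur].parent_id


# --------------------------------------------------------------------------- #
# segmentation
# --------------------------------------------------------------------------- #

def segment_frame(image: np.ndarray, min_area: int = 9,
                  threshold_method: str = "otsu",
                  frame_index: int = 0) -> LabeledFrame:
    """Connected components above a global threshold, filtered by area.

    The default threshold is Otsu on the (typically summed-channel) image; an
    all-background frame yields a frame with zero labels.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a 2-D image")
    if threshold_method == "otsu":
        thresh = filters.threshold_otsu(img) if img.min() < img.max() else np.inf
    elif threshold_method == "mean":
        thresh = img.mean()
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    binary = img > thresh
    labels = measure.label(binary, connectivity=2)
    out = np.zeros_like(labels)
    nxt = 1
    for rp in measure.regionprops(labels):
        if rp.area >= min_area:
            out[labels == rp.label] = nxt
            nxt += 1
    return LabeledFrame.from_labels(frame_index, out)


# --------------------------------------------------------------------------- #
# greedy linking
# --------------------------------------------------------------------------- #

def link(frames: Sequence[LabeledFrame], max_step: float = 15.0,
         interval_min: float = sim.FLUOR_INTERVAL_MIN) -> TrackSet:
    """Greedy nearest-centroid frame-to-frame linking.

    Each object in frame t+1 claims its nearest live track within ``max_step``
    pixels.  One claimant continues the track; exactly two claimants end it as
    a division with both objects as daughters; further claimants (or objects
    with no candidate) open new founder tracks.  Tracks with no claimant end
    as died, or survived_to_end on the final frame.
    """
    if not frames:
        raise ValueError("need at least one frame")
    n_frames = frames[-1].frame_index + 1
    shape = frames[0].label_image.shape
    label_images = [np.zeros(shape, dtype=np.uint16) for _ in range(n_frames)]
    tracks: dict[int, CellTrack] = {}
    next_id = 1
    live: dict[int, tuple[float, float]] = {}   # track id -> last centroid

    def open_track(parent: int, frame: int, centroid) -> int:
        nonlocal next_id
        tid = next_id
        next_id += 1
        tracks[tid] = CellTrack(tid, parent, frame, frame, [tuple(centroid)])
        return tid

    for lf in frames:
        f = lf.frame_index
        assignments: dict[int, int] = {}   # region label -> track id (continuation)
        claims: dict[int, list[tuple[float, int]]] = {}
        for lbl in lf.labels:
            c = np.array(lf.centroids[lbl])
            best, best_d = 0, np.inf
            for tid, prev in live.items():
                d = float(np.hypot(c[0] - prev[0], c[1] - prev[1]))
                if d < best_d:
                    best, best_d = tid, d
            if best and best_d <= max_step:
                claims.setdefault(best, []).append((best_d, lbl))
        for tid, claimants in claims.items():
            claimants.sort()
            track = tracks[tid]
            if len(claimants) == 1:
                _, lbl = claimants[0]
                track.last_frame = f
                track.centroids.append(lf.centroids[lbl])
                assignments[lbl] = tid
            else:
                # two (or more) objects claim one predecessor: division
                track.end_fate = "divided"
                for _, lbl in claimants[:2]:
                    kid = open_track(tid, f, lf.centroids[lbl])
                    assignments[lbl] = kid
                for _, lbl in claimants[2:]:
                    assignments[lbl] = open_track(0, f, lf.centroids[lbl])
        for lbl in lf.labels:
            if lbl not in assignments:
                assignments[lbl] = open_track(0, f, lf.centroids[lbl])
        # unmatched live tracks disappeared before this frame
        for tid in list(live):
            track = tracks[tid]
            if track.last_frame < f and track.end_fate != "divided":
                track.end_fate = "died"
        for lbl, tid in assignments.items():
            label_images[f][lf.label_image == lbl] = tid
        live = {tid: tracks[tid].centroids[-1] for tid in tracks
                if tracks[tid].last_frame == f and tracks[tid].end_fate != "divided"}
    for t in tracks.values():
        if t.last_frame == n_frames - 1 and t.end_fate != "divided":
            t.end_fate = "survived_to_end"
    return TrackSet(tracks, n_frames, label_images, interval_min=interval_min)


# --------------------------------------------------------------------------- #
# Cell-Tracking-Challenge I/O
# --------------------------------------------------------------------------- #

_TIF_RE = re.compile(r"(\d+)\.tiff?$")


def write_ctc(ts: TrackSet, directory: str | Path,
              table_name: str = "res_track.txt") -> None:
    """Write a track table plus per-frame 16-bit label TIFFs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / table_name, "w") as fh:
        for tid in sorted(ts.tracks):
            t = ts.tracks[tid]
            fh.write(f"{t.track_id} {t.first_frame} {t.last_frame} {t.parent_id}\n")
    if ts.label_images is not None:
        for f, img in enumerate(ts.label_images):
            tifffile.imwrite(d / f"mask{f:04d}.tif", img.astype(np.uint16))


def read_ctc(directory: str | Path,
             interval_min: float = sim.FLUOR_INTERVAL_MIN) -> TrackSet:
    """Read a Cell-Tracking-Challenge-style directory back into a TrackSet.

    Raises ValueError naming the offending frame/label on malformed rows or
    when a mask label is missing from the table.
    """
    d = Path(directory)
    tables = sorted(d.glob("*.txt"))
    if not tables:
        raise ValueError(f"no track table (*.txt) in {d}")
    tracks: dict[int, CellTrack] = {}
    with open(tables[0]) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{tables[0].name}:{lineno}: expected 4 columns")
            try:
                tid, first, last, parent = (int(p) for p in parts)
            except ValueError as exc:
                raise ValueError(f"{tables[0].name}:{lineno}: non-integer field") from exc
            if tid <= 0 or first > last or parent < 0:
                raise ValueError(f"{tables[0].name}:{lineno}: malformed row {parts}")
            tracks[tid] = CellTrack(tid, parent, first, last)
    tifs = sorted((p for p in d.iterdir() if _TIF_RE.search(p.name)),
                  key=lambda p: int(_TIF_RE.search(p.name).group(1)))
    label_images: Optional[list[np.ndarray]] = None
    if tifs:
        label_images = [tifffile.imread(p) for p in tifs]
        for f, img in enumerate(label_images):
            for lbl in np.unique(img):
                if lbl == 0:
                    continue
                if int(lbl) not in tracks:
                    raise ValueError(f"frame {f}: mask label {int(lbl)} absent from table")
                t = tracks[int(lbl)]
                if not (t.first_frame <= f <= t.last_frame):
                    raise ValueError(
                        f"frame {f}: label {int(lbl)} outside its table range")
        for t in tracks.values():
            for f in range(t.first_frame, t.last_frame + 1):
                rp = measure.regionprops((label_images[f] == t.track_id).astype(np.uint8))
                t.centroids.append(tuple(rp[0].centroid) if rp else (np.nan, np.nan))
    n_frames = (len(label_images) if label_images
                else (max(t.last_frame for t in tracks.values()) + 1 if tracks
                      else 0))
    ts = TrackSet(tracks, n_frames, label_images, sequence_id=d.name,
                  interval_min=interval_min)
    for t in tracks.values():
        kids = ts.children(t.track_id)
        if kids:
            t.end_fate = "divided"
        elif t.last_frame == n_frames - 1:
            t.end_fate = "survived_to_end"
        else:
            t.end_fate = "died"
    return ts


# --------------------------------------------------------------------------- #
# ground-truth bridge
# --------------------------------------------------------------------------- #

def trackset_from_clone(clone: sim.SimulatedClone) -> TrackSet:
    """Build the ground-truth TrackSet of a simulated clone."""
    tracks: dict[int, CellTrack] = {}
    fates = {"divided": "divided", "died": "died",
             "survived_to_end": "survived_to_end"}
    for cid in sorted(clone.cells):
        c = clone.cells[cid]
        first, last = clone.frames.get(cid, (0, -1))
        if first > last:
            continue
        cents = (list(map(tuple, clone.positions[cid]))
                 if cid in clone.positions and len(clone.positions[cid]) else [])
        fate = fates[c.fate]
        # a division landing after the last rendered frame of the daughters is
        # still a division in the lineage sense
        tracks[cid] = CellTrack(cid, c.parent_id, first, last, cents, fate)
    label_images = list(clone.masks) if clone.masks is not None else None
    ts = TrackSet(tracks, clone.n_frames(), label_images,
                  sequence_id=clone.preset_name)
    # drop 'divided' fate when daughters fell entirely outside the window
    for t in tracks.values():
        if t.end_fate == "divided" and len(ts.children(t.track_id)) != 2:
            t.end_fate = "survived_to_end"
    return ts


__all__ = ["LabeledFrame", "CellTrack", "TrackSet", "segment_frame", "link",
           "read_ctc", "write_ctc", "trackset_from_clone"]
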