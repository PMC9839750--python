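"""Synthetic clonal time-lapse generator.

Emulates dual-reporter (stemness/commitment) time-lapse sequences of clonal
stem-cell colonies confined in hydrogel microwells: a stochastic branching
lineage with per-generation division-type probabilities, two-channel reporter
traces on a 20-min fluorescence frame grid, and rendered image stacks with
ground-truth label masks.  Every downstream stage of the pipeline (tracking,
trace extraction, division classification, lineage statistics) can be tested
against the exported ground truth.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml

# Channel names used throughout the package.
STEM_CHANNEL = "pax7"   # stemness reporter (GFP)
COMMIT_CHANNEL = "myog"  # commitment reporter (mCherry)
CHANNELS = (STEM_CHANNEL, COMMIT_CHANNEL)

#: Division-type labels: symmetric self-renewing, asymmetric, symmetric committed.
DIVISION_TYPES = ("SR", "A", "SC")

FLUOR_INTERVAL_MIN = 20.0
DT_HOURS = FLUOR_INTERVAL_MIN / 60.0


# --------------------------------------------------------------------------- #
# configuration types
# --------------------------------------------------------------------------- #

Triple = tuple[float, float, float]


@dataclass(frozen=True)
class ConditionPreset:
    """Per-condition lineage parameters.

    ``p_division_type`` is either a single (p_SR, p_A, p_SC) triple applied at
    every generation or a sequence of triples indexed by division generation
    (entry 0 = divisions producing generation 1).  ``p_divide`` likewise is a
    scalar or per-generation sequence giving the probability that a stem cell
    divides again within the observation window.
    """

    name: str
    p_division_type: Triple | Sequence[Triple]
    p_death: float
    cycle_time: tuple[float, float]  # (mean hours, sd hours), log-normal
    p_divide: float | Sequence[float] = 1.0

    def __post_init__(self) -> None:
        for triple in self._triples():
            if len(triple) != 3:
                raise ValueError("division-type entry must be a triple")
            if any(not (0.0 <= p <= 1.0) for p in triple):
                raise ValueError(f"division-type probabilities outside [0,1]: {triple}")
            if abs(sum(triple) - 1.0) > 1e-9:
                raise ValueError(f"division-type triple must sum to 1: {triple}")
        if not (0.0 <= self.p_death <= 1.0):
            raise ValueError("p_death must be in [0,1]")
        mean, sd = self.cycle_time
        if mean <= 0 or sd < 0:
            raise ValueError("cycle-time mean must be > 0 and sd >= 0")
        for p in self._pdivides():
            if not (0.0 <= p <= 1.0):
                raise ValueError("p_divide must be in [0,1]")

    def _triples(self) -> list[Triple]:
        first = self.p_division_type[0]
        if isinstance(first, (int, float)):
            return [tuple(self.p_division_type)]  # type: ignore[list-item]
        return [tuple(t) for t in self.p_division_type]  # type: ignore[arg-type]

    def _pdivides(self) -> list[float]:
        if isinstance(self.p_divide, (int, float)):
            return [float(self.p_divide)]
        return [float(p) for p in self.p_divide]

    def division_triple(self, generation: int) -> Triple:
        """Triple for a division producing ``generation`` (>= 1); clamps to last."""
        triples = self._triples()
        return triples[min(max(generation - 1, 0), len(triples) - 1)]

    def divide_probability(self, generation: int) -> float:
        ps = self._pdivides()
        return ps[min(max(generation - 1, 0), len(ps) - 1)]


@dataclass(frozen=True)
class ReporterDynamics:
    """Two-state reporter kinetics.

    Stem cells hold the stemness reporter near ``stem_pax7_level`` with the
    commitment reporter at ``myog_baseline``.  Cells committed at birth follow
    a logistic commitment-reporter rise (delay hours, rate per hour, plateau)
    while the stemness reporter decays exponentially.  The logistic/exponential
    forms are modeling stand-ins, not measured kinetics.
    """

    stem_pax7_level: float = 0.80
    committed_myog_rise: tuple[float, float, float] = (4.0, 1.5, 0.90)  # delay, rate, plateau
    pax7_decay_rate: float = 0.30
    trace_noise_sd: float = 0.02
    myog_baseline: float = 0.05

    def __post_init__(self) -> None:
        delay, rate, plateau = self.committed_myog_rise
        if not (0.0 < plateau <= 1.0):
            raise ValueError("plateau must be in (0,1]")
        if rate < 0 or delay < 0 or self.pax7_decay_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.trace_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry, acquisition grid and camera noise model."""

    frame_size: tuple[int, int] = (260, 346)  # (height, width)
    fluor_interval_min: float = FLUOR_INTERVAL_MIN
    duration_h: float = 72.0
    cell_radius: int = 6
    # per-channel background trend: stemness channel has residual ambient
    # autofluorescence (power-law decay), commitment channel drifts linearly.
    background: dict = field(default_factory=lambda: {
        STEM_CHANNEL: {"form": "power_law", "a": 120.0, "b": -0.35, "c": 280.0},
        COMMIT_CHANNEL: {"form": "linear", "a": -0.15, "b": 240.0},
    })
    flicker_sd: float = 15.0
    pixel_noise_sd: float = 8.0
    saturation: float = 4095.0
    cell_brightness: float = 1500.0
    microwell_radius: float = 110.0
    brownian_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_radius < 1:
            raise ValueError("cell radius must be >= 1 px")
        n = self.duration_h * 60.0 / self.fluor_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fluorescence interval must divide the duration")
        bg0 = self.background_value(STEM_CHANNEL, 0)
        if self.saturation <= bg0:
            raise ValueError("saturation must exceed the background mean")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 60.0 / self.fluor_interval_min)) + 1

    def background_value(self, channel: str, frame: int) -> float:
        p = self.background[channel]
        t = frame + 1  # 1-based to keep t**b finite at the first frame
        if p["form"] == "power_law":
            return p["a"] * t ** p["b"] + p["c"]
        if p["form"] == "linear":
            return p["a"] * t + p["b"]
        raise ValueError(f"unknown trend form {p['form']!r}")


# --------------------------------------------------------------------------- #
# lineage
# --------------------------------------------------------------------------- #

@dataclass
class SimCell:
    """One simulated cell: a node of the clonal lineage tree."""

    cell_id: int
    parent_id: int           # 0 = founder
    generation: int
    state: str               # "stem" | "committed"
    birth_time: float        # hours
    end_time: float          # hours (division, death, or window end)
    fate: str                # "divided" | "died" | "survived_to_end"
    division_type: Optional[str] = None   # SR/A/SC when fate == divided
    children: tuple[int, int] | tuple = ()


@dataclass
class SimulatedClone:
    """A simulated clone: lineage, optional traces and rendered sequence."""

    preset_name: str
    duration_h: float
    seed: int
    cells: dict[int, SimCell]
    # (cell_id, channel) -> trace values on that cell's frame grid
    true_traces: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    # noiseless model traces (same keys/grids as true_traces)
    clean_traces: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    frames: dict[int, tuple[int, int]] = field(default_factory=dict)  # cell -> (first, last)
    images: dict[str, np.ndarray] = field(default_factory=dict)       # channel -> (T,H,W)
    masks: Optional[np.ndarray] = None                                # (T,H,W) uint16
    positions: dict[int, np.ndarray] = field(default_factory=dict)    # cell -> (n,2) row/col

    @property
    def founders(self) -> list[int]:
        return [c.cell_id for c in self.cells.values() if c.parent_id == 0]

    def divisions(self) -> list[SimCell]:
        return [c for c in sorted(self.cells.values(), key=lambda c: c.cell_id)
                if c.fate == "divided"]

    def n_frames(self, interval_min: float = FLUOR_INTERVAL_MIN) -> int:
        return int(round(self.duration_h * 60.0 / interval_min)) + 1


def simulate_lineage(preset: ConditionPreset, duration_h: float = 72.0,
                     seed: int = 0) -> SimulatedClone:
    """Simulate one clonal lineage under a condition preset.

    Stem cells progress through log-normal cell cycles; at each cycle a cell
    may die (before dividing), stop cycling, or divide, with the division type
    drawn from the preset's per-generation triple.  Committed daughters exit
    the cycle: they persist (or die) but never divide, so they can never
    produce stem descendants.  Deterministic for a fixed seed.
    """
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    mean, sd = preset.cycle_time
    # log-normal parameterized by its own mean/sd in hours
    if sd > 0:
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        sigma = math.sqrt(sigma2)
    else:
        mu, sigma = math.log(mean), 0.0

    cells: dict[int, SimCell] = {}
    next_id = 1
    # FIFO over (cell_id) keeps draw order deterministic
    root = SimCell(1, 0, 0, "stem", 0.0, duration_h, "survived_to_end")
    cells[1] = root
    next_id = 2
    queue = [1]
    while queue:
        cid = queue.pop(0)
        cell = cells[cid]
        cycle = float(np.exp(mu + sigma * rng.standard_normal())) if sigma > 0 else mean
        t_event = cell.birth_time + cycle
        if rng.random() < preset.p_death:
            # death strikes before the division would occur
            t_death = cell.birth_time + rng.random() * cycle
            if t_death <= cell.end_time:
                cell.end_time = min(t_death, duration_h)
                cell.fate = "died" if t_death <= duration_h else "survived_to_end"
                if cell.fate == "died":
                    continue
            continue
        if cell.state != "stem":
            continue  # committed cells do not cycle
        gen_out = cell.generation + 1
        if rng.random() >= preset.divide_probability(gen_out):
            continue
        if t_event > duration_h:
            continue
        p_sr, p_a, p_sc = preset.division_triple(gen_out)
        u = rng.random()
        dtype = "SR" if u < p_sr else ("A" if u < p_sr + p_a else "SC")
        states = {"SR": ("stem", "stem"), "A": ("stem", "committed"),
                  "SC": ("committed", "committed")}[dtype]
        cell.end_time = t_event
        cell.fate = "divided"
        cell.division_type = dtype
        kids = []
        for st in states:
            kid = SimCell(next_id, cid, gen_out, st, t_event, duration_h,
                          "survived_to_end")
            cells[next_id] = kid
            kids.append(next_id)
            next_id += 1
        cell.children = tuple(kids)
        queue.extend(kids)
    return SimulatedClone(preset.name, duration_h, seed, cells)


# --------------------------------------------------------------------------- #
# traces
# --------------------------------------------------------------------------- #

def _frame_span(cell: SimCell, dt_h: float, n_frames: int) -> tuple[int, int]:
    """Inclusive (first, last) frame of a cell on the fluorescence grid.

    A dividing parent keeps the frame its division falls on; daughters start
    on the following frame, so per-frame masks never overlap.
    """
    if cell.parent_id == 0:
        first = int(math.ceil(cell.birth_time / dt_h - 1e-9))
    else:
        first = int(math.floor(cell.birth_time / dt_h + 1e-9)) + 1
    if cell.fate == "divided":
        last = int(math.floor(cell.end_time / dt_h + 1e-9))
    elif cell.fate == "died":
        # a dying cell is observed at least on its first frame, then vanishes
        last = max(int(math.floor(cell.end_time / dt_h + 1e-9)), first)
    else:
        last = n_frames - 1
    return first, min(last, n_frames - 1)


def simulate_traces(clone: SimulatedClone, dyn: ReporterDynamics = ReporterDynamics(),
                    seed: int = 0,
                    interval_min: float = FLUOR_INTERVAL_MIN) -> SimulatedClone:
    """Attach noisy two-channel reporter traces to every cell of ``clone``.

    Values are on a normalized [0, 1] scale and clipped there after adding
    per-frame Gaussian noise.
    """
    if not clone.cells:
        raise ValueError("clone has no lineage")
    rng = np.random.default_rng(seed)
    dt_h = interval_min / 60.0
    n_frames = clone.n_frames(interval_min)
    delay, rate, plateau = dyn.committed_myog_rise
    clone.frames.clear()
    clone.true_traces.clear()
    clone.clean_traces.clear()
    for cid in sorted(clone.cells):
        cell = clone.cells[cid]
        first, last = _frame_span(cell, dt_h, n_frames)
        clone.frames[cid] = (first, last)
        if first > last:
            for ch in CHANNELS:
                clone.true_traces[(cid, ch)] = np.empty(0)
                clone.clean_traces[(cid, ch)] = np.empty(0)
            continue
        t = np.arange(first, last + 1) * dt_h
        t_rel = t - cell.birth_time
        if cell.state == "stem":
            pax7 = np.full(t.size, dyn.stem_pax7_level)
            myog = np.full(t.size, dyn.myog_baseline)
        else:
            pax7 = dyn.stem_pax7_level * np.exp(-dyn.pax7_decay_rate * t_rel)
            myog = dyn.myog_baseline + plateau / (1.0 + np.exp(-rate * (t_rel - delay)))
        for ch, tr in ((STEM_CHANNEL, pax7), (COMMIT_CHANNEL, myog)):
            clone.clean_traces[(cid, ch)] = np.clip(tr, 0.0, 1.0)
            noisy = tr + rng.normal(0.0, dyn.trace_noise_sd, size=tr.shape) \
                if dyn.trace_noise_sd > 0 else tr.copy()
            clone.true_traces[(cid, ch)] = np.clip(noisy, 0.0, 1.0)
    return clone


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #

def _simulate_positions(clone: SimulatedClone, cfg: RenderConfig,
                        rng: np.random.Generator) -> None:
    """Frame-by-frame random walk inside the microwell.

    Each cell takes a Brownian step from its previous (post-repulsion)
    position, so pairwise repulsion displacements persist instead of being
    recomputed against a fixed trajectory.  Daughters start on opposite sides
    of the parent's final position.  Deterministic for a fixed generator.
    """
    h, w = cfg.frame_size
    center = np.array([h / 2.0, w / 2.0])
    n_frames = clone.n_frames(cfg.fluor_interval_min)
    limit = cfg.microwell_radius - cfg.cell_radius - 1
    min_sep = 2 * cfg.cell_radius + 1.0
    pos: dict[int, np.ndarray] = {
        cid: np.zeros((max(last - first + 1, 0), 2))
        for cid, (first, last) in clone.frames.items()}
    split_theta: dict[int, float] = {}

    def reflect(p: np.ndarray) -> np.ndarray:
        d = p - center
        r = float(np.linalg.norm(d))
        return center + d * (limit / r) if r > limit else p

    by_frame: dict[int, list[int]] = {}
    for cid, (first, last) in clone.frames.items():
        for f in range(first, last + 1):
            by_frame.setdefault(f, []).append(cid)
    for f in range(n_frames):
        ids = sorted(by_frame.get(f, []))
        for cid in ids:
            cell = clone.cells[cid]
            first, _ = clone.frames[cid]
            if f > first:
                p = pos[cid][f - 1 - first] + rng.normal(0.0, cfg.brownian_sd,
                                                         size=2)
            elif cell.parent_id == 0:
                p = center + rng.normal(0.0, 8.0, size=2)
            else:
                parent = clone.cells[cell.parent_id]
                ppos = pos[cell.parent_id]
                anchor = ppos[-1] if ppos.size else center
                if cid == parent.children[0]:
                    theta = rng.random() * 2 * np.pi
                    split_theta[cell.parent_id] = theta
                else:
                    theta = split_theta.get(cell.parent_id, 0.0) + np.pi
                p = anchor + (cfg.cell_radius + 1.5) * np.array(
                    [np.cos(theta), np.sin(theta)])
            pos[cid][f - first] = reflect(p)
        # deterministic pairwise repulsion until masks are disjoint
        for _ in range(60):
            moved = False
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = ids[i], ids[j]
                    pa = pos[a][f - clone.frames[a][0]]
                    pb = pos[b][f - clone.frames[b][0]]
                    delta = pb - pa
                    dist = float(np.linalg.norm(delta))
                    if dist < min_sep:
                        axis = delta / dist if dist > 1e-9 else np.array([1.0, 0.0])
                        push = (min_sep - dist) / 2.0 + 0.25
                        pa[:] = reflect(pa - axis * push)
                        pb[:] = reflect(pb + axis * push)
                        moved = True
            if not moved:
                break
    clone.positions = pos


def render_sequence(clone: SimulatedClone, cfg: RenderConfig) -> SimulatedClone:
    """Render two-channel image stacks and 16-bit ground-truth label masks.

    Per channel and frame: pixel = background trend(t) + global flicker(t)
    + sum of cell disks scaled by the cell's true trace value + Gaussian pixel
    noise, clipped at the saturation value.  Mask labels are cell/track ids.
    """
    if not clone.true_traces:
        raise ValueError("simulate_traces must run before rendering")
    rng = np.random.default_rng(cfg.seed)
    _simulate_positions(clone, cfg, rng)
    h, w = cfg.frame_size
    n_frames = clone.n_frames(cfg.fluor_interval_min)
    yy, xx = np.mgrid[0:h, 0:w]
    masks = np.zeros((n_frames, h, w), dtype=np.uint16)
    images = {ch: np.zeros((n_frames, h, w), dtype=np.float64) for ch in CHANNELS}
    flicker = {ch: (rng.normal(0.0, cfg.flicker_sd, size=n_frames)
                    if cfg.flicker_sd > 0 else np.zeros(n_frames))
               for ch in CHANNELS}
    for f in range(n_frames):
        disks: list[tuple[int, np.ndarray]] = []
        for cid in sorted(clone.cells):
            first, last = clone.frames[cid]
            if not (first <= f <= last):
                continue
            cy, cx = clone.positions[cid][f - first]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.cell_radius ** 2
            masks[f][disk] = cid
            disks.append((cid, disk))
        for ch in CHANNELS:
            frame = np.full((h, w), cfg.background_value(ch, f) + flicker[ch][f])
            for cid, disk in disks:
                first, _ = clone.frames[cid]
                val = clone.true_traces[(cid, ch)][f - first]
                frame[disk] += cfg.cell_brightness * val
            if cfg.pixel_noise_sd > 0:
                frame += rng.normal(0.0, cfg.pixel_noise_sd, size=frame.shape)
            images[ch][f] = np.clip(frame, 0.0, cfg.saturation)
    clone.images = images
    clone.masks = masks
    return clone


# --------------------------------------------------------------------------- #
# ground-truth export
# --------------------------------------------------------------------------- #

def truth_table(clone: SimulatedClone) -> list[tuple[int, int, int, int]]:
    """Cell-Tracking-Challenge-style rows (label, first, last, parent)."""
    rows = []
    for cid in sorted(clone.cells):
        first, last = clone.frames[cid]
        if first > last:
            continue
        rows.append((cid, first, last, clone.cells[cid].parent_id))
    return rows


def write_clone(clone: SimulatedClone, directory: str | Path) -> None:
    """Write image stacks, masks, truth tables, traces and config to disk."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for ch, stack in clone.images.items():
        tifffile.imwrite(d / f"{ch}.tif", np.round(stack).astype(np.uint16))
    if clone.masks is not None:
        (d / "TRA").mkdir(exist_ok=True)
        for f in range(clone.masks.shape[0]):
            tifffile.imwrite(d / "TRA" / f"man_track{f:04d}.tif", clone.masks[f])
        with open(d / "TRA" / "man_track.txt", "w") as fh:
            for row in truth_table(clone):
                fh.write(" ".join(str(x) for x in row) + "\n")
    with open(d / "truth_divisions.csv", "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["cell_id", "parent_id", "generation", "state", "birth_h",
                      "end_h", "fate", "division_type"])
        for cid in sorted(clone.cells):
            c = clone.cells[cid]
            wtr.writerow([c.cell_id, c.parent_id, c.generation, c.state,
                          f"{c.birth_time:.6f}", f"{c.end_time:.6f}", c.fate,
                          c.division_type or ""])
    if clone.true_traces:
        with open(d / "truth_traces.csv", "w", newline="") as fh:
            wtr = csv.writer(fh)
            wtr.writerow(["cell_id", "channel", "frame", "value"])
            for (cid, ch), tr in sorted(clone.true_traces.items()):
                first, _ = clone.frames[cid]
                for i, v in enumerate(tr):
                    wtr.writerow([cid, ch, first + i, f"{v:.6f}"])
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump({"preset": clone.preset_name, "duration_h": clone.duration_h,
                        "seed": clone.seed}, fh)


# --------------------------------------------------------------------------- #
# condition presets
# --------------------------------------------------------------------------- #

def preset_library() -> dict[str, ConditionPreset]:
    """Built-in condition presets.

    The PGE2 division-type triple (60/15/25, constant over the first
    generations) is the only numerically reported breakdown; the control and
    OSM presets are qualitative defaults chosen here (not reported values):
    control with more committing divisions, OSM with control-like generation-1
    behavior but cycling probability halving each generation.
    """
    return {
        "pge2": ConditionPreset("pge2", (0.60, 0.15, 0.25), p_death=0.05,
                                cycle_time=(10.0, 2.0), p_divide=0.90),
        "control": ConditionPreset("control", (0.45, 0.20, 0.35), p_death=0.05,
                                   cycle_time=(10.0, 2.0), p_divide=0.80),
        "osm": ConditionPreset("osm", (0.45, 0.20, 0.35), p_death=0.05,
                               cycle_time=(11.0, 2.5),
                               p_divide=(0.80, 0.40, 0.20, 0.10)),
    }


def simulate_cohort(preset: ConditionPreset, n_clones: int, duration_h: float = 72.0,
                    seed: int = 0, dyn: Optional[ReporterDynamics] = None
                    ) -> list[SimulatedClone]:
    """Simulate ``n_clones`` independent clones with traces attached."""
    if n_clones < 1:
        raise ValueError("need at least one clone")
    dyn = dyn or ReporterDynamics()
    ss = np.random.SeedSequence(seed).spawn(2 * n_clones)
    clones = []
    for i in range(n_clones):
        s_lin = int(ss[2 * i].generate_state(1)[0] % (2 ** 31))
        s_tr = int(ss[2 * i + 1].generate_state(1)[0] % (2 ** 31))
        clone = simulate_lineage(preset, duration_h, seed=s_lin)
        simulate_traces(clone, dyn, seed=s_tr)
        clones.append(clone)
    return clones


__all__ = [
    "ConditionPreset", "ReporterDynamics", "RenderConfig", "SimCell",
    "SimulatedClone", "simulate_lineage", "simulate_traces", "render_sequence",
    "simulate_cohort", "preset_library", "truth_table", "write_clone",
    "STEM_CHANNEL", "COMMIT_CHANNEL", "CHANNELS", "DIVISION_TYPES",
    "FLUOR_INTERVAL_MIN", "DT_HOURS",
]
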