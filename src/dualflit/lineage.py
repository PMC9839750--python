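"""Lineage tree reconstruction and cohort statistics.

Builds one rooted tree per founder from a parent-linked TrackSet with
classified division labels, computes generation-resolved occupancy and death
curves, cumulative and per-generation division-type breakdowns rescaled to a
cohort of 100 starting clones, and the infection-rate summary statistic
R = n_infected_wells / n_live_wells (dead colonies excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import simulate as sim
from .classify import LABELS
from .tracking import TrackSet


@dataclass
class TreeNode:
    """One track within a lineage tree."""

    track_id: int
    parent: int                     # 0 at the root
    generation: int                 # root = 0
    first_frame: int
    last_frame: int
    fate: str                       # divided | died | survived_to_end
    division_label: Optional[str] = None   # SR/A/SC on internal nodes
    children: tuple[int, ...] = ()
    quintiles: Optional[list[int]] = None  # commitment-reporter codes per frame


@dataclass
class LineageTree:
    """Rooted, generation-indexed tree of one clone's tracks."""

    root: int
    nodes: dict[int, TreeNode]
    interval_min: float = sim.FLUOR_INTERVAL_MIN
    sequence_id: str = ""

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.fate == "divided"]

    def max_generation(self) -> int:
        return max(n.generation for n in self.nodes.values())

    def to_dict(self) -> dict:
        return {"root": self.root, "sequence_id": self.sequence_id,
                "interval_min": self.interval_min,
                "nodes": [{"track_id": n.track_id, "parent": n.parent,
                           "generation": n.generation,
                           "first_frame": n.first_frame,
                           "last_frame": n.last_frame, "fate": n.fate,
                           "division_label": n.division_label,
                           "children": list(n.children),
                           "quintiles": n.quintiles}
                          for n in sorted(self.nodes.values(),
                                          key=lambda n: n.track_id)]}

    @classmethod
    def from_dict(cls, d: dict) -> "LineageTree":
        nodes = {n["track_id"]: TreeNode(
            n["track_id"], n["parent"], n["generation"], n["first_frame"],
            n["last_frame"], n["fate"], n.get("division_label"),
            tuple(n.get("children", ())), n.get("quintiles"))
            for n in d["nodes"]}
        return cls(d["root"], nodes, d.get("interval_min", sim.FLUOR_INTERVAL_MIN),
                   d.get("sequence_id", ""))


@dataclass(frozen=True)
class CloneCohortSummary:
    """Well-level outcome counts for the infection-rate statistic."""

    n_infected_wells: int
    n_live_wells: int

    def __post_init__(self) -> None:
        if self.n_infected_wells < 0 or self.n_live_wells < 0:
            raise ValueError("well counts must be >= 0")
        if self.n_infected_wells > self.n_live_wells:
            raise ValueError("infected wells cannot exceed live wells")


# --------------------------------------------------------------------------- #
# tree construction
# --------------------------------------------------------------------------- #

def build_trees(ts: TrackSet, labels: Mapping[int, str],
                quintiles: Optional[Mapping[int, Sequence[int]]] = None,
                excluded_founders: Sequence[int] = ()) -> list[LineageTree]:
    """One lineage tree per founder; every divided track must carry a label.

    ``excluded_founders`` removes clones whose post-differentiation validation
    failed (no commitment-reporter expression) before any statistics.
    """
    ts.validate()
    trees: list[LineageTree] = []
    for root in ts.founders():
        if root in excluded_founders:
            continue
        nodes: dict[int, TreeNode] = {}
        stack = [(root, 0)]
        while stack:
            tid, gen = stack.pop()
            t = ts.tracks[tid]
            kids = tuple(ts.children(tid))
            label = None
            if t.end_fate == "divided":
                if tid not in labels:
                    raise ValueError(f"division of track {tid} has no label")
                label = labels[tid]
                if label not in LABELS:
                    raise ValueError(f"track {tid}: unknown label {label!r}")
            nodes[tid] = TreeNode(tid, t.parent_id if tid != root else 0, gen,
                                  t.first_frame, t.last_frame, t.end_fate,
                                  label, kids,
                                  list(quintiles[tid]) if quintiles and tid in
                                  quintiles else None)
            stack.extend((k, gen + 1) for k in kids)
        trees.append(LineageTree(root, nodes, ts.interval_min, ts.sequence_id))
    return trees


def tree_from_clone(clone: sim.SimulatedClone) -> list[LineageTree]:
    """Ground-truth lineage trees of a simulated clone (truth labels)."""
    from .tracking import trackset_from_clone
    ts = trackset_from_clone(clone)
    labels = {t: clone.cells[t].division_type for t in ts.tracks
              if ts.tracks[t].end_fate == "divided"}
    return build_trees(ts, labels)


# --------------------------------------------------------------------------- #
# cohort statistics
# --------------------------------------------------------------------------- #

@dataclass
class CohortStats:
    """Generation- and time-resolved cohort summaries, per 100 starting clones."""

    time_h: np.ndarray
    live_by_generation: dict[int, np.ndarray]      # scaled counts over time
    cumulative_deaths: np.ndarray                  # scaled, over time
    cumulative_divisions: dict[str, np.ndarray]    # per label, scaled
    per_generation_fractions: dict[int, dict[str, float]]
    per_generation_counts: dict[int, dict[str, int]]  # raw (unscaled) counts
    n_founders: int
    normalize_to: float

    @property
    def scale(self) -> float:
        return self.normalize_to / self.n_founders

    def total_live(self) -> np.ndarray:
        return sum(self.live_by_generation.values())

    def check_conservation(self, atol: float = 1e-9) -> None:
        """live(t) + deaths(t) must equal founders + divisions(t), scaled."""
        total_div = sum(self.cumulative_divisions.values())
        lhs = self.total_live() + self.cumulative_deaths
        rhs = self.normalize_to + total_div
        if not np.allclose(lhs, rhs, atol=atol):
            raise AssertionError("cell-count conservation violated")


def cohort_stats(trees: Sequence[LineageTree], normalize_to: float = 100.0,
                 n_frames: Optional[int] = None) -> CohortStats:
    """Cohort curves on the fluorescence frame grid.

    A division is registered on the first frame its daughters exist
    (parent last frame + 1); a death on the frame after the dying track's
    last frame.  Counts are rescaled so the cohort represents
    ``normalize_to`` starting clones; per-generation type fractions are
    computed over labeled divisions only (generation of a division = parent
    generation + 1).
    """
    if not trees:
        raise ValueError("empty cohort")
    interval = trees[0].interval_min
    if n_frames is None:
        n_frames = max(n.last_frame for t in trees for n in t.nodes.values()) + 1
    time_h = np.arange(n_frames) * interval / 60.0
    n_founders = len(trees)
    scale = normalize_to / n_founders
    max_gen = max(t.max_generation() for t in trees)
    live = {g: np.zeros(n_frames) for g in range(max_gen + 1)}
    deaths = np.zeros(n_frames)
    cum = {lab: np.zeros(n_frames) for lab in LABELS}
    gen_counts: dict[int, dict[str, int]] = {}
    for tree in trees:
        for node in tree.nodes.values():
            lo = min(node.first_frame, n_frames - 1)
            hi = min(node.last_frame, n_frames - 1)
            live[node.generation][lo:hi + 1] += 1
            if node.fate == "died" and node.last_frame + 1 < n_frames:
                deaths[node.last_frame + 1:] += 1
            if node.fate == "divided" and node.division_label:
                f = min(node.last_frame + 1, n_frames - 1)
                cum[node.division_label][f:] += 1
                g = node.generation + 1
                gen_counts.setdefault(g, {lab: 0 for lab in LABELS})
                gen_counts[g][node.division_label] += 1
    fractions = {}
    for g, counts in sorted(gen_counts.items()):
        total = sum(counts.values())
        fractions[g] = {lab: counts[lab] / total for lab in LABELS} if total else {}
    return CohortStats(time_h, {g: v * scale for g, v in live.items()},
                       deaths * scale, {k: v * scale for k, v in cum.items()},
                       fractions, gen_counts, n_founders, normalize_to)


def stats_to_frames(stats: CohortStats) -> dict[str, pd.DataFrame]:
    """CohortStats as tidy tables (curves + per-generation breakdown)."""
    curves = pd.DataFrame({"time_h": stats.time_h,
                           "cumulative_deaths": stats.cumulative_deaths})
    for g, v in sorted(stats.live_by_generation.items()):
        curves[f"live_gen{g}"] = v
    for lab, v in stats.cumulative_divisions.items():
        curves[f"cumulative_{lab}"] = v
    rows = []
    for g, fr in sorted(stats.per_generation_fractions.items()):
        for lab in LABELS:
            rows.append({"generation": g, "division_type": lab,
                         "fraction": fr.get(lab, np.nan),
                         "count": stats.per_generation_counts[g][lab]})
    return {"curves": curves, "per_generation": pd.DataFrame(rows)}


def infection_rate(summary: CloneCohortSummary) -> float:
    """Fraction of surviving wells whose clone expresses the commitment
    reporter after differentiation: n_infected_wells / n_live_wells."""
    if summary.n_live_wells == 0:
        raise ValueError("undefined rate: no live wells")
    return summary.n_infected_wells / summary.n_live_wells


# --------------------------------------------------------------------------- #
# serialization / rendering
# --------------------------------------------------------------------------- #

def write_trees(trees: Sequence[LineageTree], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in trees], fh, indent=1)


def read_trees(path: str | Path) -> list[LineageTree]:
    with open(path) as fh:
        return [LineageTree.from_dict(d) for d in json.load(fh)]


def render_text(tree: LineageTree) -> str:
    """Indented text rendering with per-node commitment quintile codes."""
    lines: list[str] = []

    def walk(tid: int, depth: int) -> None:
        n = tree.nodes[tid]
        tag = f"[{n.division_label}]" if n.division_label else f"({n.fate})"
        quint = ""
        if n.quintiles:
            quint = " q:" + "".join(str(q) for q in n.quintiles)
        lines.append("  " * depth +
                     f"track {tid} gen {n.generation} "
                     f"frames {n.first_frame}-{n.last_frame} {tag}{quint}")
        for k in n.children:
            walk(k, depth + 1)

    walk(tree.root, 0)
    return "\n".join(lines)


__all__ = ["TreeNode", "LineageTree", "CloneCohortSummary", "CohortStats",
           "build_trees", "tree_from_clone", "cohort_stats", "stats_to_frames",
           "infection_rate", "write_trees", "read_trees", "render_text"]
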