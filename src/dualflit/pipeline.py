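"""End-to-end cohort pipeline helpers.

Couples the simulator, feature extraction and the division-type classifier
into the standard benchmark run: simulate a cohort of clones under a
condition preset, extract 38-feature vectors for all divisions up to a
generation cutoff from the ground-truth tracks and traces, train the k=3
classifier from a small deterministic anchor set, and summarize the
classified division-type percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classify as clf_mod
from . import features as feat_mod
from . import simulate as sim


@dataclass
class CohortRun:
    """Everything produced by one cohort classification run."""

    matrix: np.ndarray            # (n_divisions, 38)
    true_labels: np.ndarray       # ground-truth SR/A/SC per division
    pred_labels: np.ndarray       # classifier assignments
    generations: np.ndarray       # generation produced by each division
    classifier: clf_mod.DivisionClassifier
    clones: list[sim.SimulatedClone]

    def percentages_in_generations(self, lo: int, hi: int) -> dict[str, float]:
        """Classified division-type percentages within a generation window."""
        sel = (self.generations >= lo) & (self.generations <= hi)
        if not sel.any():
            raise ValueError(f"no divisions in generations {lo}-{hi}")
        return {lab: 100.0 * float((self.pred_labels[sel] == lab).mean())
                for lab in clf_mod.LABELS}

    def per_generation_percentages(self) -> dict[int, dict[str, float]]:
        out: dict[int, dict[str, float]] = {}
        for g in sorted(set(self.generations.tolist())):
            sel = self.generations == g
            out[int(g)] = {lab: 100.0 * float((self.pred_labels[sel] == lab).mean())
                           for lab in clf_mod.LABELS}
        return out

    @property
    def accuracy(self) -> float:
        return float((self.pred_labels == self.true_labels).mean())


def cohort_features(clones: list[sim.SimulatedClone], max_generation: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix, truth labels and division generations for a cohort."""
    mats, labels, gens = [], [], []
    for clone in clones:
        traces = feat_mod.traces_from_clone(clone)
        events, divides_again, lab = feat_mod.events_from_clone(
            clone, traces, max_generation=max_generation)
        if not events:
            continue
        mats.append(feat_mod.feature_matrix(events, traces, divides_again))
        labels.extend(lab)
        gens.extend(e.parent_generation + 1 for e in events)
    if not mats:
        raise ValueError("cohort produced no usable divisions")
    return (np.vstack(mats), np.asarray(labels), np.asarray(gens, dtype=int))


def classify_cohort(preset: sim.ConditionPreset, n_clones: int = 200,
                    duration_h: float = 72.0, seed: int = 0,
                    max_generation: int | None = 4,
                    anchors_per_class: int = 4, restarts: int = 50,
                    dyn: sim.ReporterDynamics | None = None) -> CohortRun:
    """Simulate, featurize, train (12 anchors by default) and classify."""
    clones = sim.simulate_cohort(preset, n_clones, duration_h, seed=seed, dyn=dyn)
    X, labels, gens = cohort_features(clones, max_generation)
    anchors = clf_mod.select_anchors(labels, X, anchors_per_class)
    clf = clf_mod.train(X, anchors, restarts=restarts, seed=seed)
    pred = clf_mod.predict(clf, X)
    return CohortRun(X, labels, pred, gens, clf, clones)


__all__ = ["CohortRun", "cohort_features", "classify_cohort"]
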