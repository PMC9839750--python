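# dualflit

Dual fluorescent-reporter time-lapse analysis of clonal stem-cell colonies.

Muscle stem cells (MuSCs) decide between self-renewal and myogenic
commitment one division at a time. With a stemness reporter (Pax7, GFP) and
a commitment reporter (myogenin, mCherry) imaged every 20 minutes over a
72 h time lapse, each division of a tracked clone can be classified as

- **SR** — symmetric self-renewing: two stem daughters,
- **A**  — asymmetric: one stem and one committed daughter,
- **SC** — symmetric committed: two committed daughters,

which turns a pile of microscopy frames into generation-resolved fate
statistics. `dualflit` implements that analysis end to end for anyone
studying niche-factor regulation of stem-cell fate in clonal time-lapse
data:

1. **Signal treatment** (`dualflit.fluorsig`) — per-channel temporal
   homogenization of frame means (power-law trend `g(t) = a·t^b + c` for the
   GFP channel, linear for mCherry; each frame is shifted by
   `g(t) − mean(F_t)`), overexposed-frame rejection, per-cell mean extraction
   inside tracked masks, window-5 moving-average smoothing, per-sequence
   min/max normalization (optionally against the 99th percentile of a
   post-differentiation validation image) and quintile coding for tree
   heatmaps.
2. **Division features** (`dualflit.features`) — every parent → two-daughter
   event becomes a 38-feature vector: min/max/mean/variance of both
   reporters for parent and daughters, lifetimes and their difference,
   further-division flags, daughter contrasts, terminal commitment values
   and slopes, generation and division time.
3. **Classification** (`dualflit.classify`) — K-means (k = 3, Lloyd's with
   restarts) on weighted z-scored features; a small annotated anchor set
   (n = 12 by default) attaches SR/A/SC to the clusters; new divisions are
   assigned to the nearest centroid.
4. **Lineage statistics** (`dualflit.lineage`) — classified lineage trees,
   generation occupancy and death curves, cumulative and per-generation
   division-type breakdowns rescaled to 100 starting clones, and the
   infection-rate statistic `R = n_infected_wells / n_live_wells`.
5. **Tracking substrate** (`dualflit.tracking`) — a simple
   threshold-and-link tracker plus a lossless reader/writer for
   Cell-Tracking-Challenge-style track files, the supported route for
   importing manually corrected tracks.
6. **Synthetic benchmark** (`dualflit.simulate`) — a generative model of the
   whole experiment: stochastic lineages with per-generation division-type
   probabilities, two-state reporter kinetics, and rendered 346×260
   two-channel image stacks with illumination drift, flicker, pixel noise
   and ground-truth label masks, so every stage is testable without real
   data.

## Worked example

```python
import numpy as np
from dualflit import simulate as sim, classify as clf
from dualflit.pipeline import classify_cohort

preset = sim.preset_library()["pge2"]      # 60/15/25 SR/A/SC per generation
run = classify_cohort(preset, n_clones=200, seed=1)

print(f"divisions in generations 1-4: "
      f"{((run.generations >= 1) & (run.generations <= 4)).sum()}")
print({lab: round(p, 1)
       for lab, p in run.percentages_in_generations(1, 4).items()})
print(f"agreement with ground truth: {run.accuracy:.3f}")
```

prints

```
divisions in generations 1-4: 896
{'SR': 61.8, 'A': 14.6, 'SC': 23.5}
agreement with ground truth: 0.991
```

896 divisions were produced by 200 simulated clones in four generations;
the classifier — trained from only 12 anchor divisions — assigns 61.8% of
them the symmetric self-renewing label, 14.6% asymmetric and 23.5%
symmetric committed, recovering the generating 60/15/25 split, and agrees
with the hidden truth labels for 99.1% of divisions.

The same steps are available from the shell:

```bash
dualflit simulate --preset pge2 --clones 10 --seed 1 --render --out runs/pge2
dualflit extract  --tracks runs/pge2/clone_000/TRA --images runs/pge2/clone_000 --out traces.csv
dualflit features --tracks runs/pge2/clone_000/TRA --traces traces.csv --out features.csv
dualflit train    --features features.csv --anchors anchors.json --out clf.json
dualflit classify --features features.csv --classifier clf.json --out divisions.csv
dualflit tree     --tracks runs/pge2/clone_000/TRA --divisions divisions.csv --out trees.json
dualflit stats    --trees trees.json --out stats/
dualflit report   --trees trees.json --out report/
```

## Layout

```
src/dualflit/
  simulate.py    synthetic lineages, reporter traces, rendered sequences
  tracking.py    segmentation, greedy linking, CTC track I/O
  fluorsig.py    homogenization, trace extraction, smoothing, normalization
  features.py    38-feature division descriptors + standardization
  classify.py    k-means training, anchor labeling, nearest-centroid
  lineage.py     trees, cohort statistics, infection rate
  pipeline.py    cohort-level convenience wrappers
  cli.py         command-line interface
docs/methods.md  model assumptions, parameter choices, limitations
```
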