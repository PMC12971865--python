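# gazeskill

Gaze-based skill analytics for laparoscopic peg-transfer training.

`gazeskill` turns per-frame instance annotations (polygon masks of the six
task objects and two grasper tools, with detection confidences) plus a raw
eye-tracking trace into six per-session behavioral metrics, then runs the
downstream skill analyses:

1. **gaze filter** — an I-VT velocity-threshold fixation filter
   (70 deg/s default) with gap bridging and minimum-duration pruning;
2. **AOI engine** — confidence filtering, object hold states from
   polygon overlap with the tools, and a dilated-contour hit test (5 px)
   that assigns each fixation–frame pair to one of five categories
   (object held by one tool / by two tools / not moving, tool only, none);
3. **metrics** — five fixation rates in frames/second (distinct frames
   per category divided by completion time) plus summed left+right mean
   grasper speed in px/s, and frame-wise Cohen's kappa for annotation
   agreement;
4. **clustering** — k-means++ on the z-scored metrics, elbow selection
   on the WCSS curve, merging of clusters into ordered skill levels via
   Games-Howell comparisons of completion times, per-metric ANOVA/Tukey
   (or Welch/Games-Howell) group tests, and paired/Welch t-tests across
   trainer types;
5. **prediction** — RF / SVM / CART / ANN classification of behavior
   levels under leave-one-out cross-validation, with Gini feature
   importances;
6. **simulator** — a synthetic peg-transfer session generator with
   HIGH/MID/LOW skill archetypes (skill-conditioned gaze policies,
   speed-scaled grasper kinematics, drop events) so the whole pipeline is
   testable without real recordings.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the geometry
and I-VT filters against brute-force oracles, the metric partition and
kinematic invariants, statistical routines against independent
implementations (pingouin / scipy), and clustering/prediction recovery on
banks of simulated cohorts. The full run takes ~8 minutes on one CPU.

## CLI

```bash
# simulate a 24-session cohort and write annotation/gaze/metadata fixtures
gazeskill simulate --out-dir fixtures/ --preset fast --n-sessions 24 --seed 1

# extract the six per-session metrics
gazeskill extract --fixtures fixtures/ --out metrics.csv

# cluster sessions, pick k at the elbow, merge into skill levels
gazeskill cluster --metrics metrics.csv --out cluster.json

# LOOCV prediction + Gini importances
gazeskill predict --metrics metrics.csv --labels cluster.json --out predict.json --model all
```

File formats: annotations are a COCO-style JSON dialect (`images[]` with
`frame_index`/`t`, `categories` named `object`/`tool`, `annotations[]`
with polygon `segmentation` and `score`); gaze traces are CSV with
columns `t_s, x_px, y_px, valid`; metrics and metadata are plain CSV.

## Library example

```python
from gazeskill import sim, metrics, cluster, predict

cfg = sim.SimConfig.fast(n_sessions=24, seed=0)
sessions, truth = sim.simulate_cohort(cfg)
table = metrics.extract_cohort_metrics(sessions)

model = cluster.kmeans_pp(table, k=cluster.elbow_select(
    cluster.kmeans_pp(table, k=2).wcss_curve))
skills = cluster.assign_skill_levels(model, table["completion_time"].to_numpy())
report = predict.loocv_evaluate(table, model.assignments, predict.ModelSpec("RF"))
```

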