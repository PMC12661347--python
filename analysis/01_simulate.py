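"""Generate the simulated study: two imaging sessions, behavior, histology.

Writes the ground-truth tables to results/ and the (binary) movies and
stacks to scratch/ for inspection.  Everything downstream regenerates
the same data deterministically from analysis/common.py.
"""

import json

import numpy as np
import pandas as pd

import common
from catrack import io as cio
from catrack import synthetic as syn

results, scratch = common.ensure_dirs()

fa = common.field_a()
fb = common.field_b()
print(f"Field A: {fa.n_cells} cells on a {fa.shape_px} px plane; "
      f"field B keeps {sum(c.cell_id < common.N_CELLS for c in fb.cells)} "
      f"of them (~{int(common.TURNOVER*100)}% turnover) plus "
      f"{sum(c.cell_id >= common.N_CELLS for c in fb.cells)} new cells.")

rows = []
for name, f, drift in (("A", fa, (0, 0, 0)), ("B", fb, common.TRUE_DRIFT_UM)):
    for c in f.cells:
        rows.append({"session": name, "cell_id": c.cell_id,
                     "x_um": c.centroid_um[0], "y_um": c.centroid_um[1],
                     "z_um": c.centroid_um[2], "radius_um": c.radius_um,
                     "functional": c.brightness[0],
                     "structural": c.brightness[1],
                     "drift_x_um": drift[0], "drift_y_um": drift[1],
                     "drift_z_um": drift[2]})
pd.DataFrame(rows).to_csv(results / "ground_truth_cells.csv", index=False)

for day in ("a", "b"):
    f, truth, rendered, _ = common.session(day)
    cio.write_movie_tiff(rendered, scratch / f"session_{day}.tif")
    stack = syn.render_structural_stack(
        f, seed=common.STUDY_SEED + 40, frames_per_z=2,
        drift_um=(0, 0, 0) if day == "a" else common.TRUE_DRIFT_UM)
    cio.write_stack_tiff(stack, scratch / f"stack_{day}.tif")
    print(f"Session {day.upper()}: movie {rendered.movie.shape} at "
          f"{rendered.frame_rate_hz} vol/s, structural stack "
          f"{stack.images.shape} over {stack.z_offsets_um[0]:+.0f} to "
          f"{stack.z_offsets_um[-1]:+.0f} um.")

log = common.behavior()
cio.write_behavior_csv(log, results / "behavior_trials.csv",
                       velocity_path=scratch / "behavior_velocity.csv")
print(f"Behavior: {log.n_trials} trials, accuracy {log.accuracy():.2f}, "
      f"{sum(t.outcome == 'timeout' for t in log.trials)} timeouts, "
      f"{sum(t.trial_type == 'memory' for t in log.trials)} memory trials.")

roi = np.array([[10, 10], [10, 240], [240, 240], [240, 10]])
histo_meta = []
for section in range(4):
    truth = syn.HistologyGroundTruth(
        true_count=8 + section, roi_polygon=roi, per_cell_area_px2=20.0,
        seed=common.STUDY_SEED + 50 + section)
    img = syn.render_histology(truth)
    np.save(scratch / f"histology_section{section}.npy", img)
    histo_meta.append({"section": section, "true_count": truth.true_count,
                       "per_cell_area_px2": truth.per_cell_area_px2})
(results / "histology_ground_truth.json").write_text(
    json.dumps(histo_meta, indent=2))
print(f"Histology: 4 sections with true counts "
      f"{[m['true_count'] for m in histo_meta]}.")
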