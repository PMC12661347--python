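"""Match cells across the two sessions.

Piecewise-rigid mapping between the brightness-corrected mean
projections transfers session A's masks into B's frame; the linear sum
assignment on 1 − IoU costs (gated at 10 px, kept below cost 0.8)
pairs the cells.  Ground-truth identities grade the result.
"""

import numpy as np
import pandas as pd

import common
from catrack import detection as det
from catrack import matching as mt
from catrack import registration as reg

results, _ = common.ensure_dirs()

projections, mask_sets, fields = {}, {}, {}
for day in ("a", "b"):
    field, truth, rendered, _ = common.session(day)
    movie = rendered.movie[:, 0]
    proj = np.clip(movie.mean(axis=0), 0, None)
    corrected = reg.brightness_correct(proj)
    projections[day] = corrected
    mask_sets[day] = det.detect_masks(corrected)
    fields[day] = field

shift_field = reg.piecewise_rigid_map(projections["a"], projections["b"],
                                      patch_grid=(2, 2))
res = mt.match_cells(mask_sets["a"], mask_sets["b"], shift_field,
                     frame_shape=projections["a"].shape)
groups = mt.split_matched_unique(res, len(mask_sets["a"]),
                                 len(mask_sets["b"]))


def nearest_truth(mask, field, drift_um=(0.0, 0.0)):
    # detected masks live in the session's (drifted) frame
    cents = field.centroids_px()
    cents = cents + np.array([drift_um[1] / field.pixel_size_um[1],
                              drift_um[0] / field.pixel_size_um[0]])
    d = np.sqrt(((cents - np.array(mask.centroid_px)) ** 2).sum(axis=1))
    i = int(np.argmin(d))
    return field.cells[i].cell_id if d[i] <= 4 else -1


rows = []
for i, j, cost in res.pairs:
    rows.append({"mask_a": i, "mask_b": j, "cost": cost,
                 "iou": 1 - cost,
                 "truth_a": nearest_truth(mask_sets["a"][i], fields["a"]),
                 "truth_b": nearest_truth(mask_sets["b"][j], fields["b"],
                                          common.TRUE_DRIFT_UM[:2])})
table = pd.DataFrame(rows)
table.to_csv(results / "matches.csv", index=False)

ids_a = {c.cell_id for c in fields["a"].cells}
ids_b = {c.cell_id for c in fields["b"].cells}
persistent = ids_a & ids_b
correct = ((table.truth_a == table.truth_b) & (table.truth_a >= 0)).sum()
print(f"Sessions share {len(persistent)} of "
      f"{len(ids_a)}/{len(ids_b)} cells (ground truth).")
print(f"Matching kept {len(res.pairs)} pairs (cost < {res.threshold}); "
      f"{correct} agree with ground-truth identity "
      f"({100 * correct / max(len(res.pairs), 1):.0f}% precision).")
print(f"Session-unique: {len(groups['unique_a'])} in A, "
      f"{len(groups['unique_b'])} in B.")
print("Wrote pair table to results/matches.csv.")
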