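"""Glial immunostain quantification on the simulated sections.

Per section: a fixed-length line profile across the ROI, watershed
particle counts with the per-marker size minima (Iba1 5 px², GFAP
10 px²), and the expression index (count/area × 10,000); then the
four-section animal average, plus a per-cell co-expression correlation
matrix on z-scored intensities.
"""

import numpy as np
import pandas as pd

import common
from catrack import histology as hi
from catrack import synthetic as syn

results, _ = common.ensure_dirs()

roi = np.array([[10, 10], [10, 240], [240, 240], [240, 10]])
roi_area = 230.0 * 230.0

rows = []
for section in range(4):
    truth = syn.HistologyGroundTruth(
        true_count=8 + section, roi_polygon=roi, per_cell_area_px2=20.0,
        seed=common.STUDY_SEED + 50 + section)
    img = syn.render_histology(truth)
    profile = hi.line_profile(img, start_px=(128, 10), angle_deg=0.0,
                              length_px=230)
    res = hi.count_particles(img, min_size_px2=hi.MIN_SIZE_GFAP_PX2)
    idx = hi.expression_index(res.count, roi_area)
    rows.append({"section": section, "true_count": truth.true_count,
                 "counted": res.count, "threshold": res.threshold_used,
                 "expression_index": idx,
                 "mean_profile_intensity": float(profile.intensities.mean())})
table = pd.DataFrame(rows)
table.to_csv(results / "histology_counts.csv", index=False)

print(table.to_string(index=False,
                      float_format=lambda v: f"{v:.3f}"))
animal_idx = hi.animal_average(table.expression_index)
animal_int = hi.animal_average(table.mean_profile_intensity)
print(f"Animal average over 4 sections: expression index "
      f"{animal_idx:.3f} cells/px² × 10,000; line-profile intensity "
      f"{animal_int:.3f} a.u.")
print(f"Counts match ground truth in "
      f"{(table.counted == table.true_count).sum()}/4 sections.")

# per-cell multichannel co-expression (three reporters, 38 cells):
# two channels co-vary with a shared expression level, one independent
rng = np.random.default_rng(common.STUDY_SEED + 70)
level = rng.lognormal(0, 0.4, size=38)
intens = np.column_stack([
    level * rng.lognormal(0, 0.15, size=38),
    level * rng.lognormal(0, 0.15, size=38),
    rng.lognormal(0, 0.4, size=38),
])
corr = hi.coexpression_correlation(intens)
pd.DataFrame(corr, columns=["ch1", "ch2", "ch3"]).to_csv(
    results / "coexpression_correlation.csv", index=False)
print(f"Co-expression (n=38 cells, z-scored): r(ch1, ch2) = "
      f"{corr[0, 1]:.2f} (shared driver), r(ch1, ch3) = {corr[0, 2]:.2f} "
      f"(independent).")
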