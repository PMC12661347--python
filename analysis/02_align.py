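"""Closed-loop 3-D alignment of session B's field to session A's reference.

Reproduces the between-session alignment procedure: acquire a
structural stack, take XY from the best-correlated Z, take Z from the
linear-offset Gaussian fit of correlation vs Z, adjust, repeat until
all residuals are < 5 μm.
"""

import json

import pandas as pd

import common
from catrack import registration as reg
from catrack import synthetic as syn

results, _ = common.ensure_dirs()

field = common.field_a()
reference = syn.render_structural_stack(field, seed=common.STUDY_SEED + 40,
                                        frames_per_z=2)
acquire = syn.make_acquire(field, common.TRUE_DRIFT_UM,
                           seed=common.STUDY_SEED + 40, frames_per_z=2)
res = reg.align_iterative(acquire, reference)

rows = []
for k, it in enumerate(res.iterations, start=1):
    rows.append({"iteration": k, "dx_um": it["dx_um"], "dy_um": it["dy_um"],
                 "dz_um": it["dz_um"], "peak_corr": it["peak_corr"],
                 "z_fit_width_um": (it["zfit"].width_um
                                    if it["zfit"] else None)})
pd.DataFrame(rows).to_csv(results / "alignment_iterations.csv", index=False)

summary = {
    "true_drift_um": list(common.TRUE_DRIFT_UM),
    "recovered_position_um": [round(v, 3) for v in res.final_position_um],
    "converged": res.converged,
    "n_iterations": res.n_iter,
}
(results / "alignment_summary.json").write_text(json.dumps(summary, indent=2))

print(f"True drift {common.TRUE_DRIFT_UM} um; recovered "
      f"{tuple(round(float(v), 2) for v in res.final_position_um)} um in "
      f"{res.n_iter} iteration(s); converged={res.converged}.")
err = [abs(a - b) for a, b in zip(res.final_position_um,
                                  common.TRUE_DRIFT_UM)]
print(f"Residual error (x, y, z): "
      f"({err[0]:.2f}, {err[1]:.2f}, {err[2]:.2f}) um — the loop stops "
      f"once each per-iteration shift is below 5 um.")
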