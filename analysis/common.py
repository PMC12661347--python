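"""Shared study configuration for the numbered analysis scripts.

One simulated "animal": a field of cortical cells imaged in two
sessions ~4 weeks apart with 3-D drift and ~20% cell turnover, a
behavior session in the virtual T-maze, and four immunostained
histology sections per hemisphere.  Everything is deterministic from
STUDY_SEED; scripts regenerate what they need rather than passing
binary intermediates around.
"""

from pathlib import Path

import numpy as np

from catrack import synthetic as syn

STUDY_SEED = 2024
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

# Desk-scale imaging geometry: one 128x128 um plane at 1 um/px (the
# full acquisition is 512x796 px x 3 planes; a single small plane keeps
# every script interactive while exercising the identical code paths).
FIELD_KW = dict(fov_um=(128.0, 128.0), pixel_size_um=(1.0, 1.0),
                n_planes=1, min_separation_um=18.0,
                structural_fraction=0.6)
N_CELLS = 20
N_FRAMES = 900
TRUE_DRIFT_UM = (9.0, -6.0, 8.0)  # session B relative to session A
TURNOVER = 0.2
VOL_RATE = syn.DEFAULT_VOLUME_RATE_HZ


def field_a():
    return syn.generate_field(N_CELLS, seed=STUDY_SEED, **FIELD_KW)


def field_b():
    return syn.shifted_field(field_a(), TURNOVER, seed=STUDY_SEED + 1)


def session(day: str):
    """Rendered functional session + ground truth for day 'a' or 'b'."""
    f = field_a() if day == "a" else field_b()
    drift = (0.0, 0.0, 0.0) if day == "a" else TRUE_DRIFT_UM
    truth = syn.make_session_truth(f, N_FRAMES,
                                   seed=STUDY_SEED + (10 if day == "a" else 20),
                                   drift_um=drift, spike_rate_hz=0.12)
    rendered, true_traces = syn.render_session(f, truth, N_FRAMES)
    return f, truth, rendered, true_traces


def behavior():
    return syn.simulate_behavior(60, seed=STUDY_SEED + 30, p_correct=0.85)


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return RESULTS, SCRATCH
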