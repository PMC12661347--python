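"""Ground-truthed synthetic data for the imaging pipeline.

Emulates the statistical structure the analysis assumes: multi-plane
two-photon movies (3 planes spaced 30 μm, ~10.4 volumes/s), cells as
2-D Gaussian blobs with AR(1) calcium dynamics driven by sparse spikes,
a rank-1 global background, skewed shot-like noise, session-to-session
rigid 3-D drift, a nuclear structural channel, virtual-reality T-maze
trial event streams, and histology sections with countable labeled
cells.  Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask

# Acquisition geometry defaults mirror the study conditions:
# FOV 583 x 862 x 60 um imaged as 512 x 796 px x 3 planes, planes
# spaced 30 um, cycled at 31.25 Hz frame rate (10.4 volumes/s).
DEFAULT_FOV_UM = (862.0, 583.0)  # (x, y)
DEFAULT_PIXEL_SIZE_UM = (862.0 / 796.0, 583.0 / 512.0)  # (x, y) um/px
DEFAULT_PLANE_SPACING_UM = 30.0
DEFAULT_N_PLANES = 3
DEFAULT_VOLUME_RATE_HZ = 10.4


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """One simulated soma."""

    cell_id: int
    centroid_um: tuple[float, float, float]  # (x, y, z)
    radius_um: float
    brightness: tuple[float, ...]  # per channel (functional, structural)
    plane_index: int


@dataclass(frozen=True)
class FieldGroundTruth:
    """A fixed population of cells in an imaging volume."""

    cells: tuple[CellSpec, ...]
    fov_um: tuple[float, float]
    plane_spacing_um: float
    n_planes: int
    pixel_size_um: tuple[float, float]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def shape_px(self) -> tuple[int, int]:
        """(rows, cols) of one imaging plane."""
        return (
            int(round(self.fov_um[1] / self.pixel_size_um[1])),
            int(round(self.fov_um[0] / self.pixel_size_um[0])),
        )

    def centroids_px(self) -> np.ndarray:
        """(n_cells, 2) array of (row, col) centroid positions."""
        out = np.empty((self.n_cells, 2))
        for i, c in enumerate(self.cells):
            out[i] = (c.centroid_um[1] / self.pixel_size_um[1],
                      c.centroid_um[0] / self.pixel_size_um[0])
        return out


@dataclass(frozen=True)
class SessionGroundTruth:
    """Everything that varies between sessions of the same field."""

    drift_um: tuple[float, float, float]  # (dx, dy, dz) applied to field
    spikes: np.ndarray  # (n_cells, n_frames) nonnegative amplitudes
    ar_coeff: float  # gamma in (0, 1)
    background_trace: np.ndarray  # (n_frames,)
    background_map: np.ndarray | None  # (rows, cols) weights, or None
    noise_params: dict
    seed: int

    def __post_init__(self):
        if not 0.0 < self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in (0, 1)")
        if np.any(self.spikes < 0):
            raise ValueError("spike amplitudes must be nonnegative")


@dataclass
class ImagingSession:
    """Multi-plane fluorescence movie with acquisition metadata."""

    movie: np.ndarray  # (n_frames, n_planes, rows, cols) float32
    frame_rate_hz: float  # volume rate
    plane_spacing_um: float
    pixel_size_um: tuple[float, float]
    channel: str = "functional"
    metadata: dict = dc_field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.movie.shape[0]

    @property
    def n_planes(self) -> int:
        return self.movie.shape[1]


@dataclass
class StructuralStack:
    """Mean-projected structural (nuclear) images on a Z-offset grid."""

    images: np.ndarray  # (n_z, n_planes, rows, cols)
    z_offsets_um: np.ndarray  # (n_z,) objective offsets
    pixel_size_um: tuple[float, float]
    plane_spacing_um: float

    @property
    def n_z(self) -> int:
        return self.images.shape[0]


def default_z_grid() -> np.ndarray:
    """The +30 … −30 μm, 5 μm step objective grid (13 positions)."""
    return np.arange(30.0, -35.0, -5.0)


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

def generate_field(
    n_cells: int,
    seed: int,
    *,
    fov_um: tuple[float, float] = DEFAULT_FOV_UM,
    pixel_size_um: tuple[float, float] = DEFAULT_PIXEL_SIZE_UM,
    n_planes: int = DEFAULT_N_PLANES,
    plane_spacing_um: float = DEFAULT_PLANE_SPACING_UM,
    min_separation_um: float = 15.0,
    radius_um_range: tuple[float, float] = (4.0, 7.0),
    z_jitter_um: float = 5.0,
    structural_fraction: float = 0.3,
    margin_um: float = 10.0,
    max_tries_per_cell: int = 2000,
) -> FieldGroundTruth:
    """Place cells at random with a minimum pairwise XY separation.

    Cells are assigned round-robin to planes with axial jitter; a
    ``structural_fraction`` of them carry a second (nuclear) channel,
    standing in for the GABAergic nuclear label used as a registration
    landmark.  Deterministic per seed; raises if the requested density
    is infeasible at the requested separation after bounded retries.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if fov_um[0] <= 0 or fov_um[1] <= 0 or n_planes < 1:
        raise ValueError("FOV and plane count must be positive")
    if pixel_size_um[0] <= 0 or pixel_size_um[1] <= 0:
        raise ValueError("pixel_size_um must be positive")

    rng = np.random.default_rng(seed)
    placed_xy: list[tuple[float, float]] = []
    cells: list[CellSpec] = []
    lo = margin_um
    for i in range(n_cells):
        ok = False
        for _ in range(max_tries_per_cell):
            x = rng.uniform(lo, fov_um[0] - lo)
            y = rng.uniform(lo, fov_um[1] - lo)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_separation_um ** 2
                   for px, py in placed_xy):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place cell {i} at separation "
                f"{min_separation_um} um after {max_tries_per_cell} tries"
            )
        placed_xy.append((x, y))
        plane = i % n_planes
        z = plane * plane_spacing_um + rng.uniform(-z_jitter_um, z_jitter_um)
        radius = rng.uniform(*radius_um_range)
        b_func = rng.uniform(0.5, 1.5)
        b_struct = rng.uniform(0.5, 1.5) if rng.uniform() < structural_fraction else 0.0
        cells.append(CellSpec(
            cell_id=i,
            centroid_um=(x, y, z),
            radius_um=radius,
            brightness=(b_func, b_struct),
            plane_index=plane,
        ))
    return FieldGroundTruth(
        cells=tuple(cells),
        fov_um=tuple(fov_um),
        plane_spacing_um=plane_spacing_um,
        n_planes=n_planes,
        pixel_size_um=tuple(pixel_size_um),
    )


# ---------------------------------------------------------------------------
# calcium dynamics
# ---------------------------------------------------------------------------

def simulate_calcium(
    spikes: np.ndarray, gamma: float, baseline: float = 0.0
) -> np.ndarray:
    """AR(1) calcium trace: c(t) = γ·c(t−1) + s(t), plus a constant baseline.

    The impulse response of a unit spike at t=0 is exactly γ^t.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    spikes = np.asarray(spikes, dtype=float)
    c = np.empty_like(spikes)
    prev = 0.0
    for t in range(spikes.shape[-1]):
        prev = gamma * prev + spikes[..., t]
        c[..., t] = prev
    return c + baseline


def make_session_truth(
    field: FieldGroundTruth,
    n_frames: int,
    seed: int,
    *,
    drift_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ar_coeff: float = 0.85,
    spike_rate_hz: float = 0.15,
    spike_amplitude: float = 1.0,
    volume_rate_hz: float = DEFAULT_VOLUME_RATE_HZ,
    background_amplitude: float = 0.2,
    noise_gain: float = 0.03,
    gamma_shape: float = 2.0,
    read_noise_sd: float = 0.01,
) -> SessionGroundTruth:
    """Draw per-session ground truth: spikes, background, drift, noise.

    Spike trains are sparse Bernoulli events at ``spike_rate_hz`` with
    log-normal amplitudes around ``spike_amplitude`` (in units of the
    cell's resting fluorescence, so a unit spike is a 100% ΔF/F
    transient).  The global background is a smooth spatial map times a
    slowly varying positive temporal trace — the rank-1 structure the
    extraction stage assumes.
    """
    rng = np.random.default_rng(seed)
    p = spike_rate_hz / volume_rate_hz
    events = rng.uniform(size=(field.n_cells, n_frames)) < p
    amps = spike_amplitude * rng.lognormal(mean=0.0, sigma=0.3,
                                           size=events.shape)
    spikes = np.where(events, amps, 0.0)

    t = np.arange(n_frames) / volume_rate_hz
    phase = rng.uniform(0, 2 * np.pi)
    bg_trace = background_amplitude * (
        1.0 + 0.5 * np.sin(2 * np.pi * 0.02 * t + phase)
    )
    rows, cols = field.shape_px
    raw = rng.standard_normal((rows, cols))
    bg_map = gaussian_filter(raw, sigma=max(rows, cols) / 8.0)
    bg_map -= bg_map.min()
    if bg_map.max() > 0:
        bg_map /= bg_map.max()

    return SessionGroundTruth(
        drift_um=tuple(drift_um),
        spikes=spikes,
        ar_coeff=ar_coeff,
        background_trace=bg_trace,
        background_map=bg_map,
        noise_params={
            "gain": noise_gain,
            "gamma_shape": gamma_shape,
            "read_sd": read_noise_sd,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _stamp_gaussian(
    image: np.ndarray,
    row: float,
    col: float,
    sigma_px: tuple[float, float],
    amplitude: float,
    truncate: float = 2.5,
) -> None:
    """Add a truncated 2-D Gaussian blob to ``image`` in place."""
    rows, cols = image.shape
    sr, sc = sigma_px
    r0 = max(int(np.floor(row - truncate * sr)), 0)
    r1 = min(int(np.ceil(row + truncate * sr)) + 1, rows)
    c0 = max(int(np.floor(col - truncate * sc)), 0)
    c1 = min(int(np.ceil(col + truncate * sc)) + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    g = np.exp(-(rr ** 2 / (2 * sr ** 2) + cc ** 2 / (2 * sc ** 2)))
    g[g < np.exp(-truncate ** 2 / 2.0)] = 0.0
    image[r0:r1, c0:c1] += amplitude * g


def _cell_footprint_params(
    cell: CellSpec,
    field: FieldGroundTruth,
    plane: int,
    drift_um: tuple[float, float, float],
    channel: int,
    sigma_z_um: float,
    radius_scale: float = 1.0,
) -> tuple[float, float, tuple[float, float], float] | None:
    """Apparent (row, col, sigma_px, brightness) of a cell in one plane.

    Axial defocus dims the cell by exp(−(Δz/σz)²) and inflates its
    footprint by √(1+(Δz/σz)²).  Returns None when invisible.
    """
    bright = cell.brightness[channel] if channel < len(cell.brightness) else 0.0
    if bright <= 0:
        return None
    dx, dy, dz = drift_um
    x = cell.centroid_um[0] + dx
    y = cell.centroid_um[1] + dy
    z = cell.centroid_um[2] + dz
    plane_z = plane * field.plane_spacing_um
    delta_z = z - plane_z
    decay = np.exp(-((delta_z / sigma_z_um) ** 2))
    if decay < 1e-3:
        return None
    inflate = np.sqrt(1.0 + (delta_z / sigma_z_um) ** 2)
    sigma_um = cell.radius_um * radius_scale / 2.0 * inflate
    sigma_px = (sigma_um / field.pixel_size_um[1],
                sigma_um / field.pixel_size_um[0])
    row = y / field.pixel_size_um[1]
    col = x / field.pixel_size_um[0]
    return row, col, sigma_px, bright * decay


def render_frame(
    field: FieldGroundTruth,
    plane: int,
    cell_gain: np.ndarray | Sequence[float],
    *,
    drift_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    channel: int = 0,
    sigma_z_um: float = 12.0,
    radius_scale: float = 1.0,
) -> np.ndarray:
    """Noiseless single-plane frame: Σ_cells footprint × gain."""
    rows, cols = field.shape_px
    img = np.zeros((rows, cols))
    for i, cell in enumerate(field.cells):
        fp = _cell_footprint_params(cell, field, plane, drift_um, channel,
                                    sigma_z_um, radius_scale)
        if fp is None:
            continue
        row, col, sigma_px, bright = fp
        _stamp_gaussian(img, row, col, sigma_px, bright * float(cell_gain[i]))
    return img


def render_session(
    field: FieldGroundTruth,
    truth: SessionGroundTruth,
    n_frames: int,
    *,
    baseline: float = 1.0,
    sigma_z_um: float = 12.0,
    volume_rate_hz: float = DEFAULT_VOLUME_RATE_HZ,
) -> tuple[ImagingSession, np.ndarray]:
    """Render a functional movie and return it with true cell traces.

    Pixel model: Σ_cells footprint × (baseline + calcium(t)) +
    background_map × background_trace(t) + skewed shot-like noise
    (gamma) + Gaussian read noise.  Cells defocus (dim and blur) with
    axial distance from each plane.  Returns ``(session, true_traces)``
    where ``true_traces[i, t]`` is cell i's noiseless somatic
    fluorescence brightness·(baseline + c_i(t)).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    spikes = truth.spikes[:, :n_frames]
    calcium = np.stack([
        simulate_calcium(spikes[i], truth.ar_coeff) for i in range(field.n_cells)
    ]) if field.n_cells else np.zeros((0, n_frames))
    gains = baseline + calcium  # (n_cells, n_frames)
    true_traces = np.array([
        field.cells[i].brightness[0] * gains[i] for i in range(field.n_cells)
    ]) if field.n_cells else np.zeros((0, n_frames))

    rows, cols = field.shape_px
    rng = np.random.default_rng(truth.seed + 1)
    movie = np.zeros((n_frames, field.n_planes, rows, cols), dtype=np.float32)

    # precompute per-plane static footprint images per cell (drifted);
    # each cell is separable: frame = Σ_i F_i(plane) * gain_i(t)
    any_visible = False
    for plane in range(field.n_planes):
        footprints = []
        idx = []
        for i, cell in enumerate(field.cells):
            fp = _cell_footprint_params(cell, field, plane, truth.drift_um, 0,
                                        sigma_z_um)
            if fp is None:
                continue
            row, col, sigma_px, bright = fp
            img = np.zeros((rows, cols))
            _stamp_gaussian(img, row, col, sigma_px, bright)
            if img.max() > 0:
                footprints.append(img)
                idx.append(i)
        if footprints:
            any_visible = True
            fp_stack = np.stack(footprints).reshape(len(footprints), -1)
            plane_frames = gains[idx].T @ fp_stack  # (n_frames, px)
            movie[:, plane, :, :] += plane_frames.reshape(
                n_frames, rows, cols).astype(np.float32)

    if truth.background_map is not None:
        bg = truth.background_map[None, None, :, :] * \
            truth.background_trace[:n_frames, None, None, None]
        movie += bg.astype(np.float32)

    npar = truth.noise_params
    if npar.get("gain", 0) > 0:
        shot = rng.gamma(npar["gamma_shape"],
                         scale=npar["gain"] / npar["gamma_shape"],
                         size=movie.shape)
        movie += shot.astype(np.float32)
    if npar.get("read_sd", 0) > 0:
        movie += (npar["read_sd"] *
                  rng.standard_normal(movie.shape)).astype(np.float32)

    meta = {"seed": truth.seed, "drift_um": list(truth.drift_um)}
    if field.n_cells and not any_visible:
        meta["warning"] = "drift pushed all cells out of the field of view"
    session = ImagingSession(
        movie=movie,
        frame_rate_hz=volume_rate_hz,
        plane_spacing_um=field.plane_spacing_um,
        pixel_size_um=field.pixel_size_um,
        channel="functional",
        metadata=meta,
    )
    return session, true_traces


def render_structural_stack(
    field: FieldGroundTruth,
    seed: int,
    *,
    z_offsets_um: np.ndarray | None = None,
    frames_per_z: int = 15,
    drift_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    sigma_z_um: float = 12.0,
    noise_sd: float = 0.01,
    nuclear_radius_scale: float = 0.5,
) -> StructuralStack:
    """Mean-projected nuclear-channel stack over an objective Z grid.

    Default grid is +30 … −30 μm in 5 μm steps (13 positions).  Moving
    the objective by +o μm images tissue o μm deeper, so a cell appears
    in focus at o ≈ (cell z + drift z) − plane z.  Only cells with a
    nonzero structural brightness appear.
    """
    if z_offsets_um is None:
        z_offsets_um = default_z_grid()
    z_offsets_um = np.asarray(z_offsets_um, dtype=float)
    if z_offsets_um.size == 0:
        raise ValueError("z_offsets_um must be nonempty")
    if frames_per_z < 1:
        raise ValueError("frames_per_z must be >= 1")

    rng = np.random.default_rng(seed)
    rows, cols = field.shape_px
    images = np.zeros((z_offsets_um.size, field.n_planes, rows, cols))
    dx, dy, dz = drift_um
    ones = np.ones(field.n_cells)
    for zi, off in enumerate(z_offsets_um):
        # objective offset shifts the imaged plane within the tissue
        eff_drift = (dx, dy, dz - off)
        for plane in range(field.n_planes):
            clean = render_frame(field, plane, ones, drift_um=eff_drift,
                                 channel=1, sigma_z_um=sigma_z_um,
                                 radius_scale=nuclear_radius_scale)
            acc = np.zeros_like(clean)
            for _ in range(frames_per_z):
                acc += clean
                if noise_sd > 0:
                    acc += noise_sd * rng.standard_normal(clean.shape)
            images[zi, plane] = acc / frames_per_z
    return StructuralStack(
        images=images,
        z_offsets_um=z_offsets_um,
        pixel_size_um=field.pixel_size_um,
        plane_spacing_um=field.plane_spacing_um,
    )


def make_acquire(
    field: FieldGroundTruth,
    true_drift_um: tuple[float, float, float],
    seed: int,
    **stack_kwargs,
) -> Callable[[np.ndarray], StructuralStack]:
    """Closed-loop acquisition callback for iterative alignment tests.

    Returns ``acquire(position)`` rendering the drifted field as seen
    with the objective moved by ``position`` (x, y, z in μm).
    Deterministic given the position.
    """
    def acquire(position: np.ndarray) -> StructuralStack:
        px, py, pz = (float(v) for v in np.asarray(position, dtype=float))
        eff = (true_drift_um[0] - px,
               true_drift_um[1] - py,
               true_drift_um[2] - pz)
        return render_structural_stack(field, seed, drift_um=eff,
                                       **stack_kwargs)
    return acquire


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

STEM_LENGTH_CM = 219.0
ARM_LENGTH_CM = 37.0
MEMORY_CUE_RANGE_CM = (8.5, 153.8)
TIMEOUT_S = 120.0
ERROR_EXTRA_TIMEOUT_S = 8.0
INTER_TRIAL_RANGE_S = (1.0, 1.5)
BIAS_WINDOW_TRIALS = 40


@dataclass(frozen=True)
class Trial:
    trial_type: str  # "visual" | "memory"
    cue_side: str  # "L" | "R"
    cue_pos_cm: float
    t_start: float
    t_choice: float | None
    t_outcome: float
    outcome: str  # "correct" | "incorrect" | "timeout"
    chosen_side: str | None


@dataclass
class BehaviorLog:
    trials: list[Trial]
    velocity_cm_s: np.ndarray  # per-frame, piecewise constant
    frame_rate_hz: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def accuracy(self) -> float:
        done = [t for t in self.trials if t.outcome != "timeout"]
        if not done:
            return float("nan")
        return sum(t.outcome == "correct" for t in done) / len(done)


def _bias_adjusted_p_right(history: list[Trial], k: float) -> float:
    """P(right cue) from performance over the trailing 40-trial window.

    Stand-in rule: P(R) = clip(0.5 + k·(acc_L − acc_R), 0.2, 0.8) where
    acc_side is the correct rate on trials whose cue was on that side.
    Cues shift toward the side the animal performs worse on.
    """
    recent = history[-BIAS_WINDOW_TRIALS:]
    by_side = {"L": [], "R": []}
    for t in recent:
        if t.outcome != "timeout":
            by_side[t.cue_side].append(t.outcome == "correct")
    if not by_side["L"] or not by_side["R"]:
        return 0.5
    acc_l = np.mean(by_side["L"])
    acc_r = np.mean(by_side["R"])
    return float(np.clip(0.5 + k * (acc_l - acc_r), 0.2, 0.8))


def simulate_behavior(
    n_trials: int,
    seed: int,
    *,
    p_correct: float = 0.85,
    p_respond: float = 1.0,
    speed_cm_s: float = 20.0,
    speed_sd_cm_s: float = 4.0,
    memory_fraction: float = 0.85,
    bias_gain_k: float = 0.6,
    frame_rate_hz: float = DEFAULT_VOLUME_RATE_HZ,
) -> BehaviorLog:
    """Simulate a session of the two-alternative T-maze task.

    A parameterized agent runs 219 cm to the junction and 37 cm into an
    arm; the choice is committed at junction passage.  Non-responding
    trials time out at 120 s; errors and timeouts add an 8 s penalty on
    top of the random 1–1.5 s inter-trial delay.  Memory-trial cue
    positions are uniform in [8.5, 153.8] cm, and the cue side is drawn
    with the trailing-40-trial bias-correcting probability rule.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if speed_cm_s <= 0:
        raise ValueError("agent speed must be > 0")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    vel_segments: list[tuple[float, float]] = []  # (duration_s, cm/s)
    clock = 0.0
    for _ in range(n_trials):
        p_right = _bias_adjusted_p_right(trials, bias_gain_k)
        cue_side = "R" if rng.uniform() < p_right else "L"
        is_memory = rng.uniform() < memory_fraction
        cue_pos = (rng.uniform(*MEMORY_CUE_RANGE_CM) if is_memory
                   else STEM_LENGTH_CM)
        t_start = clock
        if rng.uniform() >= p_respond:
            # never initiates: full 120 s timeout
            t_choice = None
            chosen = None
            outcome = "timeout"
            t_outcome = t_start + TIMEOUT_S
            vel_segments.append((TIMEOUT_S, 0.0))
        else:
            v = max(rng.normal(speed_cm_s, speed_sd_cm_s), 2.0)
            stem_t = STEM_LENGTH_CM / v
            arm_t = ARM_LENGTH_CM / v
            if stem_t + arm_t > TIMEOUT_S:
                t_choice = None
                chosen = None
                outcome = "timeout"
                t_outcome = t_start + TIMEOUT_S
                vel_segments.append((TIMEOUT_S, v))
            else:
                correct = rng.uniform() < p_correct
                chosen = cue_side if correct else ("L" if cue_side == "R" else "R")
                t_choice = t_start + stem_t
                t_outcome = t_choice + arm_t
                outcome = "correct" if chosen == cue_side else "incorrect"
                vel_segments.append((stem_t + arm_t, v))
        trials.append(Trial(
            trial_type="memory" if is_memory else "visual",
            cue_side=cue_side, cue_pos_cm=cue_pos,
            t_start=t_start, t_choice=t_choice, t_outcome=t_outcome,
            outcome=outcome, chosen_side=chosen,
        ))
        delay = rng.uniform(*INTER_TRIAL_RANGE_S)
        if outcome != "correct":
            delay += ERROR_EXTRA_TIMEOUT_S
        vel_segments.append((delay, 0.0))
        clock = t_outcome + delay

    # piecewise-constant per-frame velocity at the volume rate
    total_frames = int(np.ceil(clock * frame_rate_hz)) + 1
    velocity = np.zeros(total_frames)
    t = 0.0
    for dur, v in vel_segments:
        f0 = int(t * frame_rate_hz)
        f1 = min(int((t + dur) * frame_rate_hz) + 1, total_frames)
        velocity[f0:f1] = v
        t += dur
    return BehaviorLog(trials=trials, velocity_cm_s=velocity,
                       frame_rate_hz=frame_rate_hz)


# ---------------------------------------------------------------------------
# histology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistologyGroundTruth:
    """Synthetic immunostained section: countable labeled cells in a ROI."""

    true_count: int
    roi_polygon: np.ndarray  # (n_vertices, 2) in (row, col) pixels
    per_cell_area_px2: float
    seed: int


def render_histology(
    truth: HistologyGroundTruth,
    *,
    shape: tuple[int, int] = (256, 256),
    cell_intensity: float = 1.0,
    background_level: float = 0.05,
    noise_sd: float = 0.02,
    min_separation_px: float | None = None,
    max_tries: int = 10000,
) -> np.ndarray:
    """Render cells as bright disks of the given area on a noisy background.

    Cell centers fall inside the ROI polygon with a minimum separation
    (default: two disk diameters, keeping objects disjoint so that the
    ground-truth count is recoverable by labeling).  Deterministic per
    ``truth.seed``.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("image dims must be positive")
    rng = np.random.default_rng(truth.seed)
    radius = float(np.sqrt(truth.per_cell_area_px2 / np.pi))
    if min_separation_px is None:
        min_separation_px = 4.0 * radius + 2.0
    roi_mask = polygon2mask(shape, truth.roi_polygon)
    cand = np.argwhere(roi_mask)
    if truth.true_count > 0 and cand.size == 0:
        raise ValueError("ROI polygon contains no pixels")
    centers: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(centers) == truth.true_count:
            break
        c = cand[rng.integers(len(cand))]
        if (c[0] < radius + 1 or c[0] > shape[0] - radius - 2 or
                c[1] < radius + 1 or c[1] > shape[1] - radius - 2):
            continue
        if all(np.hypot(*(c - p)) >= min_separation_px for p in centers):
            centers.append(c)
    if len(centers) < truth.true_count:
        raise RuntimeError("could not place all cells inside the ROI")

    img = np.full(shape, background_level)
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    for c in centers:
        disk = (rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= radius ** 2
        img[disk] = background_level + cell_intensity
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(shape)
    return np.clip(img, 0.0, None)


def true_dff_peak(
    field: FieldGroundTruth,
    truth: SessionGroundTruth,
    mask_pixels: np.ndarray,
    cell_index: int,
    n_frames: int,
    *,
    baseline: float = 1.0,
    sigma_z_um: float = 12.0,
    q: float = 8.0,
) -> float:
    """Ground-truth peak ΔF/F of one cell as seen through a given mask.

    Computed from the generator's own model, independently of the
    extraction pipeline: the mask-mean of the cell's footprint φ gives
    signal φ·max(c) over a resting level composed of φ·baseline, the
    q-th percentile of the background under the mask, and the mean of
    the shot-noise offset.
    """
    gains = np.zeros(field.n_cells)
    gains[cell_index] = 1.0
    plane = field.cells[cell_index].plane_index
    fp = render_frame(field, plane, gains, drift_um=truth.drift_um,
                      sigma_z_um=sigma_z_um)
    phi = float(fp[mask_pixels[:, 0], mask_pixels[:, 1]].mean())
    c = simulate_calcium(truth.spikes[cell_index, :n_frames], truth.ar_coeff)
    bg = 0.0
    if truth.background_map is not None:
        w = truth.background_map[mask_pixels[:, 0], mask_pixels[:, 1]].mean()
        bg = float(w * np.percentile(truth.background_trace[:n_frames], q))
    noise_offset = truth.noise_params.get("gain", 0.0)
    return phi * float(c.max()) / (phi * baseline + bg + noise_offset)


def shifted_field(field: FieldGroundTruth, turnover_fraction: float,
                  seed: int, n_new: int | None = None) -> FieldGroundTruth:
    """Second-session field: drop a fraction of cells, add fresh ones.

    Models between-session cell turnover for matching tests; surviving
    cells keep their identity (cell_id).  New cells get ids beyond the
    original range and keep the minimum separation from *every*
    original position (including dropped cells), so ground-truth
    correspondence stays unambiguous.
    """
    rng = np.random.default_rng(seed)
    keep = rng.uniform(size=field.n_cells) >= turnover_fraction
    kept = [c for c, k in zip(field.cells, keep) if k]
    lost = int(field.n_cells - len(kept))
    if n_new is None:
        n_new = lost
    new_cells: list[CellSpec] = []
    next_id = max((c.cell_id for c in field.cells), default=-1) + 1
    existing_xy = [(c.centroid_um[0], c.centroid_um[1])
                   for c in field.cells]
    for j in range(n_new):
        for _ in range(2000):
            x = rng.uniform(10.0, field.fov_um[0] - 10.0)
            y = rng.uniform(10.0, field.fov_um[1] - 10.0)
            if all((x - px) ** 2 + (y - py) ** 2 >= 15.0 ** 2
                   for px, py in existing_xy):
                break
        else:
            continue
        existing_xy.append((x, y))
        plane = int(rng.integers(field.n_planes))
        z = plane * field.plane_spacing_um + rng.uniform(-5, 5)
        new_cells.append(CellSpec(
            cell_id=next_id + j,
            centroid_um=(x, y, z),
            radius_um=rng.uniform(4.0, 7.0),
            brightness=(rng.uniform(0.5, 1.5), 0.0),
            plane_index=plane,
        ))
    return replace(field, cells=tuple(kept) + tuple(new_cells))
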