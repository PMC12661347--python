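"""Cross-day 3-D field alignment.

Two-step alignment of a freshly acquired structural stack to a
reference from a previous session: (1) the top plane at each objective
Z position is cross-correlated with the reference top plane and the
best X/Y shift taken from the Z with the highest correlation; (2) the
X/Y-shifted stack is correlated with the reference at each Z and a
linear-offset Gaussian is fit to correlation vs Z, whose center gives
the axial shift.  The loop repeats, adjusting the (virtual) objective,
until all three shifts fall below 5 μm.

Also provides the brightness correction used before mask extraction
and a simplified piecewise-rigid mapping used to transfer cell masks
between sessions.

Conventions: pixel coordinates are 0-based (row=y, col=x); XY shifts
are *corrections* — applying the returned shift to the moving image
best matches the reference; the Z estimate is the apparent axial
displacement of the tissue (the objective adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .masks import CellMask
from .synthetic import StructuralStack

DEFAULT_MAX_SHIFT_PX = 20
CONVERGENCE_TOL_UM = 5.0


# ---------------------------------------------------------------------------
# brightness correction
# ---------------------------------------------------------------------------

def brightness_correct(image: np.ndarray, kernel_px: int = 25,
                       eps: float = 1e-6) -> np.ndarray:
    """Divide by a brightness map: the 25×25 median filter of the image.

    Flattens slow illumination/expression gradients before adaptive
    thresholding; a constant image maps to all ones.  Edge handling is
    reflect padding; ``eps`` guards division by zero.
    """
    image = np.asarray(image, dtype=float)
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be odd and >= 3")
    if kernel_px > min(image.shape):
        raise ValueError("kernel larger than image")
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    bmap = ndimage.median_filter(image, size=kernel_px, mode="reflect")
    return image / np.maximum(bmap, eps)


# ---------------------------------------------------------------------------
# rigid XY shift by zero-normalized cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class ShiftXY:
    """Rigid XY correction with its correlation diagnostics."""

    dx_um: float
    dy_um: float
    dx_px: float
    dy_px: float
    peak_corr: float
    source_plane: int = 0
    flags: tuple[str, ...] = ()


def _zncc_surface(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Circular zero-normalized cross-correlation surface.

    ``surface[sy, sx]`` (wrapped indices) is the Pearson correlation
    between ``image`` translated by (sy, sx) with periodic padding and
    ``reference``; an integer roll is therefore recovered exactly.
    """
    a = image - image.mean()
    b = reference - reference.mean()
    sa = np.sqrt((a ** 2).sum())
    sb = np.sqrt((b ** 2).sum())
    if sa == 0 or sb == 0:
        raise ValueError("degenerate correlation: zero-variance input")
    corr = np.fft.irfft2(np.conj(np.fft.rfft2(a)) * np.fft.rfft2(b),
                         s=a.shape)
    return corr / (sa * sb)


def rigid_shift_xy(
    image: np.ndarray,
    reference: np.ndarray,
    *,
    max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
    pixel_size_um: tuple[float, float] = (1.0, 1.0),
    subpixel: bool = True,
    corr_floor: float = 0.2,
) -> ShiftXY:
    """Best rigid shift of ``image`` onto ``reference``.

    The search is restricted to ±``max_shift_px`` per axis; the integer
    peak is refined by parabolic interpolation.  A peak correlation
    below ``corr_floor`` is flagged ``low_correlation``.  Ties between
    equal correlation peaks break toward the smallest-magnitude shift.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError("image and reference must share dimensions")
    surface = _zncc_surface(image, reference)
    n_r, n_c = surface.shape
    m_r = min(max_shift_px, n_r // 2 - 1)
    m_c = min(max_shift_px, n_c // 2 - 1)
    sy_cand = np.r_[np.arange(0, m_r + 1), np.arange(-m_r, 0)]
    sx_cand = np.r_[np.arange(0, m_c + 1), np.arange(-m_c, 0)]
    window = surface[np.ix_(sy_cand % n_r, sx_cand % n_c)]
    peak = window.max()
    # smallest |shift| among ties
    ties = np.argwhere(window >= peak - 1e-12)
    mags = [abs(sy_cand[i]) + abs(sx_cand[j]) for i, j in ties]
    i, j = ties[int(np.argmin(mags))]
    sy, sx = int(sy_cand[i]), int(sx_cand[j])

    dy, dx = float(sy), float(sx)
    if subpixel:
        dy += _parabolic_offset(surface[(sy - 1) % n_r, sx % n_c],
                                surface[sy % n_r, sx % n_c],
                                surface[(sy + 1) % n_r, sx % n_c])
        dx += _parabolic_offset(surface[sy % n_r, (sx - 1) % n_c],
                                surface[sy % n_r, sx % n_c],
                                surface[sy % n_r, (sx + 1) % n_c])
    flags = ("low_correlation",) if peak < corr_floor else ()
    return ShiftXY(
        dx_um=dx * pixel_size_um[0], dy_um=dy * pixel_size_um[1],
        dx_px=dx, dy_px=dy, peak_corr=float(peak), flags=flags,
    )


def _parabolic_offset(c_m: float, c_0: float, c_p: float) -> float:
    denom = c_m - 2 * c_0 + c_p
    if denom >= 0 or abs(denom) < 1e-15:
        return 0.0
    off = float(np.clip(0.5 * (c_m - c_p) / denom, -0.5, 0.5))
    return off if abs(off) > 1e-9 else 0.0


def translate_image(image: np.ndarray, dy_px: float, dx_px: float,
                    order: int = 1) -> np.ndarray:
    """Translate content by (dy, dx) px; integer shifts use periodic roll."""
    if float(dy_px).is_integer() and float(dx_px).is_integer():
        return np.roll(image, (int(dy_px), int(dx_px)), axis=(0, 1))
    return ndimage.shift(image, (dy_px, dx_px), order=order, mode="reflect")


# ---------------------------------------------------------------------------
# XY over a structural stack, then the Gaussian Z fit
# ---------------------------------------------------------------------------

def _top_plane_at_z0(stack: StructuralStack) -> np.ndarray:
    zi = int(np.argmin(np.abs(stack.z_offsets_um)))
    return stack.images[zi, 0]


def best_xy_over_stack(
    stack: StructuralStack,
    reference: "StructuralStack | np.ndarray",
    **kwargs,
) -> ShiftXY:
    """XY shift from the Z position with the highest top-plane correlation.

    The top plane at each Z is cross-correlated with the reference top
    plane; the shift from the best-correlated Z wins.
    """
    if stack.n_z == 0:
        raise ValueError("empty stack")
    ref_img = (_top_plane_at_z0(reference)
               if isinstance(reference, StructuralStack) else np.asarray(reference))
    kwargs.setdefault("pixel_size_um", stack.pixel_size_um)
    best: ShiftXY | None = None
    for zi in range(stack.n_z):
        s = rigid_shift_xy(stack.images[zi, 0], ref_img, **kwargs)
        if best is None or s.peak_corr > best.peak_corr:
            s.source_plane = zi
            best = s
    return best


@dataclass
class ZFit:
    """Linear-offset Gaussian fit of correlation vs Z."""

    center_um: float
    width_um: float
    amplitude: float
    offset: float
    rss: float
    n_points: int


def _gauss_offset(z, a, b, mu, sigma):
    return a * np.exp(-((z - mu) ** 2) / (2 * sigma ** 2)) + b


def fit_linear_offset_gaussian(z_um: Sequence[float],
                               corr: Sequence[float]) -> ZFit:
    """Least-squares fit of c(z) = a·exp(−(z−μ)²/(2σ²)) + b.

    Initialization: b = min(corr), a = max − min, μ = argmax z,
    σ = 2 × z-step; σ bounded to [step/2, z-range] and μ to the sampled
    range ± one step.  Raises ``no axial peak`` when no positive-
    amplitude optimum exists.
    """
    z = np.asarray(z_um, dtype=float)
    c = np.asarray(corr, dtype=float)
    if z.size < 4:
        raise ValueError("need at least 4 points for a 4-parameter fit")
    dz = np.diff(z)
    if not (np.all(dz > 0) or np.all(dz < 0)):
        raise ValueError("z must be strictly monotone")
    step = float(np.abs(dz).mean())
    zrange = float(z.max() - z.min())
    a0 = float(c.max() - c.min())
    p0 = [max(a0, 1e-6), float(c.min()), float(z[np.argmax(c)]), 2.0 * step]
    lower = [0.0, -np.inf, z.min() - step, step / 2.0]
    upper = [np.inf, np.inf, z.max() + step, zrange]
    try:
        popt, _ = curve_fit(_gauss_offset, z, c, p0=p0,
                            bounds=(lower, upper), xtol=1e-10, ftol=1e-10,
                            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"no axial peak: {exc}") from exc
    a, b, mu, sigma = popt
    if a <= 1e-6:
        raise ValueError("no axial peak: amplitude vanished at optimum")
    rss = float(((c - _gauss_offset(z, *popt)) ** 2).sum())
    return ZFit(center_um=float(mu), width_um=float(sigma),
                amplitude=float(a), offset=float(b), rss=rss,
                n_points=int(z.size))


def estimate_z_shift(
    stack: StructuralStack,
    reference_image: np.ndarray,
    xy_shift: ShiftXY | None = None,
) -> tuple[float, ZFit]:
    """Axial displacement from the correlation-vs-Z Gaussian fit.

    The (already or herein) X/Y-shifted stack top plane at each
    objective Z offset is correlated with the reference top-plane image
    and a linear-offset Gaussian fit to the profile; its center is the
    apparent axial displacement of the tissue — the amount the
    objective must move to restore focus.  A center at the edge of the
    sampled grid raises ``no axial peak`` (out of capture range).
    """
    ref = np.asarray(reference_image, dtype=float)
    corrs = []
    for zi in range(stack.n_z):
        img = stack.images[zi, 0]
        if xy_shift is not None:
            img = translate_image(img, xy_shift.dy_px, xy_shift.dx_px)
        a = img - img.mean()
        b = ref - ref.mean()
        denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
        corrs.append(float((a * b).sum() / denom) if denom > 0 else 0.0)
    z = stack.z_offsets_um
    fit = fit_linear_offset_gaussian(z, corrs)
    edge = float(np.abs(np.diff(z)).mean())
    if fit.center_um <= z.min() + edge / 2 or fit.center_um >= z.max() - edge / 2:
        raise ValueError("no axial peak: center at grid boundary")
    return fit.center_um, fit


# ---------------------------------------------------------------------------
# iterative closed-loop alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Per-iteration shifts and convergence of the closed alignment loop."""

    iterations: list[dict] = dc_field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    final_position_um: tuple[float, float, float] = (0.0, 0.0, 0.0)


def align_iterative(
    acquire: Callable[[np.ndarray], StructuralStack],
    reference: StructuralStack,
    *,
    max_iter: int = 10,
    tol_um: float = CONVERGENCE_TOL_UM,
    max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
) -> AlignmentResult:
    """Iterate acquire → XY shift → Z fit → adjust until shifts < 5 μm.

    ``acquire(position)`` must return a structural stack as seen with
    the objective moved by ``position`` (x, y, z in μm) and be
    deterministic given the position.  Convergence requires each of
    |dx|, |dy|, |dz| below ``tol_um`` within ``max_iter`` iterations;
    on failure the partial result is returned with ``converged=False``.
    """
    ref_top = _top_plane_at_z0(reference)
    position = np.zeros(3)
    result = AlignmentResult()
    for it in range(max_iter):
        stack = acquire(position)
        sxy = best_xy_over_stack(stack, ref_top, max_shift_px=max_shift_px)
        try:
            dz, zfit = estimate_z_shift(stack, ref_top, sxy)
        except ValueError:
            dz, zfit = 0.0, None
        result.iterations.append({
            "dx_um": sxy.dx_um, "dy_um": sxy.dy_um, "dz_um": dz,
            "peak_corr": sxy.peak_corr, "zfit": zfit,
        })
        # XY shifts are corrections (apply-to-image); the tissue moved
        # by their negative.  Z is the tissue displacement directly.
        position[0] -= sxy.dx_um
        position[1] -= sxy.dy_um
        position[2] += dz
        result.n_iter = it + 1
        # converged only on a real correlation peak: a sub-threshold
        # residual on a low-correlation (spurious) match does not count
        if (abs(sxy.dx_um) < tol_um and abs(sxy.dy_um) < tol_um
                and abs(dz) < tol_um and "low_correlation" not in sxy.flags):
            result.converged = True
            break
    result.final_position_um = tuple(position)
    return result


# ---------------------------------------------------------------------------
# piecewise-rigid mapping and mask transfer
# ---------------------------------------------------------------------------

@dataclass
class ShiftField:
    """Piecewise-rigid shift field over a patch grid.

    ``shifts_px[r, c] = (dy, dx)`` is the correction shift of the patch
    centered at ``(row_centers[r], col_centers[c])``; the dense field is
    the bilinear interpolation over patch centers (clamped outside).
    A 1×1 grid is exactly the rigid estimate.
    """

    shifts_px: np.ndarray  # (rows, cols, 2) as (dy, dx)
    row_centers: np.ndarray
    col_centers: np.ndarray
    init_shift_px: tuple[float, float] = (0.0, 0.0)  # (dy, dx)
    shape: tuple[int, int] = (0, 0)

    def dense(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """(rows, cols, 2) per-pixel (dy, dx) shift."""
        shape = shape or self.shape
        rr = np.clip(np.arange(shape[0]), self.row_centers[0],
                     self.row_centers[-1])
        cc = np.clip(np.arange(shape[1]), self.col_centers[0],
                     self.col_centers[-1])
        out = np.empty(shape + (2,))
        for k in range(2):
            if len(self.row_centers) == 1 and len(self.col_centers) == 1:
                out[..., k] = self.shifts_px[0, 0, k]
                continue
            from scipy.interpolate import RegularGridInterpolator
            interp = RegularGridInterpolator(
                (self.row_centers, self.col_centers), self.shifts_px[..., k],
                method="linear", bounds_error=False, fill_value=None)
            grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
            out[..., k] = interp(np.stack([grid_r.ravel(), grid_c.ravel()],
                                          axis=1)).reshape(shape)
        return out


def piecewise_rigid_map(
    image: np.ndarray,
    reference: np.ndarray,
    *,
    patch_grid: tuple[int, int] = (4, 4),
    init_shift_px: tuple[float, float] = (0.0, 0.0),
    max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
    min_patch_px: int = 16,
    subpixel: bool = True,
) -> ShiftField:
    """Per-patch rigid shifts between two mean projections.

    The moving image is first translated by ``init_shift_px`` (allowing
    a smaller automatic search); each tile of the grid is then
    registered rigidly and the per-patch shifts (including the initial
    one) define the field used to map cell masks across sessions.
    """
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError("image and reference must share dimensions")
    g_r, g_c = patch_grid
    if g_r < 1 or g_c < 1:
        raise ValueError("patch grid must be at least 1x1")
    ph, pw = image.shape[0] // g_r, image.shape[1] // g_c
    if ph < min_patch_px or pw < min_patch_px:
        raise ValueError(
            f"patch {ph}x{pw} smaller than minimum {min_patch_px} px")
    moved = translate_image(image, *init_shift_px) \
        if any(init_shift_px) else image
    shifts = np.zeros((g_r, g_c, 2))
    row_centers = np.empty(g_r)
    col_centers = np.empty(g_c)
    for r in range(g_r):
        r0 = r * ph
        r1 = image.shape[0] if r == g_r - 1 else (r + 1) * ph
        row_centers[r] = (r0 + r1 - 1) / 2.0
        for c in range(g_c):
            c0 = c * pw
            c1 = image.shape[1] if c == g_c - 1 else (c + 1) * pw
            col_centers[c] = (c0 + c1 - 1) / 2.0
            try:
                s = rigid_shift_xy(moved[r0:r1, c0:c1],
                                   reference[r0:r1, c0:c1],
                                   subpixel=subpixel,
                                   max_shift_px=min(max_shift_px,
                                                    (r1 - r0) // 2 - 1,
                                                    (c1 - c0) // 2 - 1))
                shifts[r, c] = (s.dy_px, s.dx_px)
            except ValueError:
                shifts[r, c] = (0.0, 0.0)
    shifts[..., 0] += init_shift_px[0]
    shifts[..., 1] += init_shift_px[1]
    return ShiftField(shifts_px=shifts, row_centers=row_centers,
                      col_centers=col_centers,
                      init_shift_px=tuple(init_shift_px), shape=image.shape)


def apply_shift_field(
    obj: "np.ndarray | CellMask | Sequence[CellMask]",
    field: ShiftField,
    shape: tuple[int, int] | None = None,
):
    """Warp an image (bilinear) or masks (nearest, binary preserved).

    Masks are forward-mapped pixelwise and rounded; a mask warped fully
    outside the frame comes back empty with an ``out_of_frame`` flag.
    """
    if isinstance(obj, CellMask):
        return _warp_mask(obj, field, shape or field.shape)
    if isinstance(obj, np.ndarray) and obj.ndim == 2:
        dense = field.dense(obj.shape)
        rr, cc = np.meshgrid(np.arange(obj.shape[0]),
                             np.arange(obj.shape[1]), indexing="ij")
        coords = np.stack([rr - dense[..., 0], cc - dense[..., 1]])
        return ndimage.map_coordinates(obj.astype(float), coords, order=1,
                                       mode="reflect")
    return [_warp_mask(m, field, shape or field.shape) for m in obj]


def _warp_mask(mask: CellMask, field: ShiftField,
               shape: tuple[int, int]) -> CellMask:
    dense = field.dense(shape)
    px = mask.pixels
    src = np.clip(px, [0, 0], [shape[0] - 1, shape[1] - 1])
    s = dense[src[:, 0], src[:, 1]]
    moved = np.rint(px + s).astype(int)
    inside = ((moved[:, 0] >= 0) & (moved[:, 0] < shape[0]) &
              (moved[:, 1] >= 0) & (moved[:, 1] < shape[1]))
    moved = np.unique(moved[inside], axis=0)
    flags = mask.flags
    if len(moved) == 0:
        flags = flags + ("out_of_frame",)
    elif len(moved) < mask.area_px2:
        flags = flags + ("clipped",)
    return CellMask(pixels=moved, plane_index=mask.plane_index, flags=flags)
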