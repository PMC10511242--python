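"""Traction force microscopy: bead displacement recovery and inversion.

The measurement chain mirrors the standard substrate-deformation
workflow: rigid drift correction, iterative window cross-correlation
(PIV) with window halving, optional single-particle tracking (SPT) on
the final subimages, outlier filtering, interpolation to a regular grid,
and regularized Fourier-transform traction cytometry (FTTC) on the
elastic half-space, followed by substrate strain energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, ifft2, next_fast_len
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .boussinesq import SubstrateParams, greens_tensor_fourier
from .fields import PA_UM3_TO_J, VectorField2D

__all__ = [
    "PivConfig", "ScatteredField", "EnergyRecord", "correct_drift",
    "recover_displacement", "recover_displacement_stack", "filter_outliers",
    "interpolate_to_grid", "fttc", "select_regularization_gcv",
    "strain_energy", "relative_strain_energy",
]


@dataclass
class PivConfig:
    """PIV / SPT / filtering parameters.

    The defaults are the acquisition-matched values: a 13.8 µm first
    window halved twice, discard thresholds of 2.5 µm on the magnitude
    and 1 µm on the neighbour difference, and a 1.3 µm output grid.
    """

    initial_window_um: float = 13.8
    n_refinements: int = 2
    spt_enabled: bool = True
    max_magnitude_um: float = 2.5
    max_neighbor_diff_um: float = 1.0
    grid_spacing_um: float = 1.3
    overlap: float = 0.5
    min_window_std: float = 1e-6  # empty-window guard (intensity units)

    def __post_init__(self):
        if self.initial_window_um <= 0 or self.grid_spacing_um <= 0:
            raise ValueError("window and grid sizes must be > 0")
        if self.max_magnitude_um <= 0 or self.max_neighbor_diff_um <= 0:
            raise ValueError("outlier thresholds must be > 0")


@dataclass
class ScatteredField:
    """Scattered displacement measurements in µm (per bead or per window)."""

    x_um: np.ndarray
    y_um: np.ndarray
    u_um: np.ndarray
    v_um: np.ndarray

    def __len__(self):
        return len(self.x_um)


@dataclass
class EnergyRecord:
    """Substrate strain energy (J), total and split into left/right halves."""

    time_index: int
    strain_energy_J: float
    left_energy_J: float
    right_energy_J: float


# ---------------------------------------------------------------------------
# drift correction and cross-correlation primitives
# ---------------------------------------------------------------------------

def correct_drift(stack: np.ndarray, reference: np.ndarray | None = None,
                  upsample: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Remove global rigid translation from every frame (subpixel).

    Frames are registered against ``reference`` (default: the first
    frame).  Returns the corrected stack and the per-frame (dy, dx)
    shifts that were removed.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("need an image stack")
    ref = stack[0] if reference is None else np.asarray(reference, float)
    out = np.empty_like(stack)
    shifts = np.zeros((stack.shape[0], 2))
    for k, frame in enumerate(stack):
        shift, _, _ = phase_cross_correlation(ref, frame,
                                              upsample_factor=upsample,
                                              normalization=None)
        shifts[k] = shift
        out[k] = ndimage.shift(frame, shift, order=3, mode="nearest")
    return out, shifts


def _xcorr_shift(ref_w: np.ndarray, def_w: np.ndarray,
                 max_shift: float) -> tuple[float, float] | None:
    """Subpixel (dy, dx) displacement of ``def_w`` relative to ``ref_w``
    via FFT cross-correlation with a parabolic peak fit.

    Ties in the integer peak are broken toward zero shift; returns None
    when the correlation peak is not significant.
    """
    a = ref_w - ref_w.mean()
    b = def_w - def_w.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return None
    c = ifft2(fft2(b) * np.conj(fft2(a))).real
    ny, nx = c.shape
    fy = np.fft.fftfreq(ny, 1.0 / ny).astype(int)
    fx = np.fft.fftfreq(nx, 1.0 / nx).astype(int)
    allowed = (np.abs(fy)[:, None] <= max_shift) & (np.abs(fx)[None, :] <= max_shift)
    cm = np.where(allowed, c, -np.inf)
    # toward-zero tie-break: among equal maxima prefer the smallest |shift|
    flat = cm.ravel()
    best = flat.max()
    if not np.isfinite(best) or best / denom < 0.02:
        return None
    cand = np.flatnonzero(flat >= best * (1 - 1e-12))
    iy, ix = np.unravel_index(cand, c.shape)
    dist = fy[iy] ** 2 + fx[ix] ** 2
    j = np.argmin(dist)
    iy, ix = int(iy[j]), int(ix[j])

    def subpixel(cm1, c0, cp1):
        # Gaussian three-point fit (exact for Gaussian correlation peaks,
        # far less peak-locking than a parabola); parabolic fallback
        if cm1 > 0 and c0 > 0 and cp1 > 0:
            lm1, l0, lp1 = np.log(cm1), np.log(c0), np.log(cp1)
            d = lm1 - 2 * l0 + lp1
            if d < 0:
                off = 0.5 * (lm1 - lp1) / d
                if abs(off) <= 1:
                    return off
        d = cm1 - 2 * c0 + cp1
        return 0.0 if d >= 0 else 0.5 * (cm1 - cp1) / d

    dy = fy[iy] + subpixel(c[(iy - 1) % ny, ix], c[iy, ix], c[(iy + 1) % ny, ix])
    dx = fx[ix] + subpixel(c[iy, (ix - 1) % nx], c[iy, ix], c[iy, (ix + 1) % nx])
    return dy, dx


def _bead_positions(window: np.ndarray, min_distance: int = 2,
                    rel_threshold: float = 0.2) -> np.ndarray:
    """Bead centres in a subimage, (row, col), with sub-pixel refinement.

    Gaussian interpolation of the peak (log-parabolic per axis): exact
    for an isolated Gaussian spot, and robust enough at realistic noise;
    falls back to the integer peak when neighbours are non-positive.
    """
    if window.max() <= 0:
        return np.empty((0, 2))
    sm = ndimage.gaussian_filter(window, 1.0)
    peaks = peak_local_max(sm, min_distance=min_distance,
                           threshold_rel=rel_threshold, exclude_border=1)
    out = []
    ny, nx = window.shape
    for r, c in peaks:
        pos = [float(r), float(c)]
        for ax, (i, n) in enumerate(((r, ny), (c, nx))):
            if not 0 < i < n - 1:
                continue
            if ax == 0:
                tri = window[i - 1:i + 2, c]
            else:
                tri = window[r, i - 1:i + 2]
            if np.any(tri <= 0):
                continue
            l0, l1, l2 = np.log(tri)
            den = l0 - 2 * l1 + l2
            if den < 0:
                off = 0.5 * (l0 - l2) / den
                if abs(off) < 1:
                    pos[ax] = i + off
        out.append(tuple(pos))
    return np.asarray(out) if out else np.empty((0, 2))


# ---------------------------------------------------------------------------
# PIV + SPT
# ---------------------------------------------------------------------------

def recover_displacement(reference: np.ndarray, deformed: np.ndarray,
                         cfg: PivConfig | None = None,
                         pixel_size_um: float = 0.1,
                         origin_um: tuple[float, float] = (0.0, 0.0)
                         ) -> ScatteredField:
    """Recover the substrate displacement between a reference and a
    deformed bead image.

    Multi-pass window cross-correlation starting from
    ``cfg.initial_window_um``, halving the window ``cfg.n_refinements``
    times while shifting the deformed subimages by the current estimate;
    if ``cfg.spt_enabled``, bead-level displacements are measured on the
    final subimages by nearest-neighbour matching.  Output positions and
    displacements are in µm (y up).
    """
    cfg = cfg or PivConfig()
    ref = np.asarray(reference, float)
    dfm = np.asarray(deformed, float)
    if ref.shape != dfm.shape:
        raise ValueError("images must have the same shape")
    ny, nx = ref.shape
    px = pixel_size_um

    interp = None  # current displacement estimate (px units), (y, x) -> (dy, dx)
    w0 = int(round(cfg.initial_window_um / px))
    for level in range(cfg.n_refinements + 1):
        w = max(8, w0 // 2**level)
        step = max(4, int(round(w * (1 - cfg.overlap))))
        centers, vals = [], []
        for r0 in range(0, ny - w + 1, step):
            for c0 in range(0, nx - w + 1, step):
                cy, cx = r0 + w / 2, c0 + w / 2
                guess = np.array([0.0, 0.0]) if interp is None else interp(cy, cx)
                gy, gx = int(round(guess[0])), int(round(guess[1]))
                r0d, c0d = r0 + gy, c0 + gx
                if r0d < 0 or c0d < 0 or r0d + w > ny or c0d + w > nx:
                    continue
                ref_w = ref[r0:r0 + w, c0:c0 + w]
                def_w = dfm[r0d:r0d + w, c0d:c0d + w]
                if ref_w.std() < cfg.min_window_std or def_w.std() < cfg.min_window_std:
                    continue
                res = _xcorr_shift(ref_w, def_w, max_shift=w / 3)
                if res is None:
                    continue
                centers.append((cy, cx))
                vals.append((gy + res[0], gx + res[1]))
        if not centers:
            raise RuntimeError("PIV found no valid correlation windows")
        centers = np.asarray(centers)
        vals = np.asarray(vals)
        lin = LinearNDInterpolator(centers, vals) if len(centers) >= 3 else None
        near = NearestNDInterpolator(centers, vals)

        def interp(cy, cx, _lin=lin, _near=near):
            if _lin is not None:
                v = _lin(cy, cx)
                if not np.any(np.isnan(v)):
                    return np.asarray(v).ravel()
            return np.asarray(_near(cy, cx)).ravel()

    if not cfg.spt_enabled:
        x = origin_um[0] + centers[:, 1] * px
        y = origin_um[1] + centers[:, 0] * px
        return ScatteredField(x, y, vals[:, 1] * px, vals[:, 0] * px)

    # --- SPT on the final subimages -----------------------------------
    xs, ys, us, vs = [], [], [], []
    for (cy, cx), (dy, dx) in zip(centers, vals):
        r0, c0 = int(cy - w / 2), int(cx - w / 2)
        ref_w = ref[r0:r0 + w, c0:c0 + w]
        beads_ref = _bead_positions(ref_w)
        if len(beads_ref) == 0:
            continue
        gy, gx = int(round(dy)), int(round(dx))
        r0d, c0d = r0 + gy, c0 + gx
        if r0d < 0 or c0d < 0 or r0d + w > ny or c0d + w > nx:
            continue
        def_w = dfm[r0d:r0d + w, c0d:c0d + w]
        beads_def = _bead_positions(def_w)
        if len(beads_def) == 0:
            continue
        tree = cKDTree(beads_def)
        resid = np.array([dy - gy, dx - gx])
        pred = beads_ref + resid
        tree_ref = cKDTree(pred)
        for bi, br in enumerate(beads_ref):
            d, j = tree.query(pred[bi], k=1)
            if d > 2.0:  # px; no credible partner
                continue
            # mutual-nearest check rejects ambiguous pairings in dense spots
            d_back, i_back = tree_ref.query(beads_def[j], k=1)
            if i_back != bi:
                continue
            disp = beads_def[j] - br + np.array([gy, gx])
            xs.append(origin_um[0] + (c0 + br[1]) * px)
            ys.append(origin_um[1] + (r0 + br[0]) * px)
            us.append(disp[1] * px)
            vs.append(disp[0] * px)
    if not xs:
        raise RuntimeError("SPT matched no beads; density too low?")
    # beads in overlapping windows are measured twice; average duplicates
    pts = np.column_stack([xs, ys])
    uv = np.column_stack([us, vs])
    tree = cKDTree(pts)
    groups = tree.query_ball_tree(tree, r=0.5 * px)
    keep = np.ones(len(pts), bool)
    for i, g in enumerate(groups):
        g = sorted(g)
        if g[0] != i:
            keep[i] = False
        else:
            uv[i] = uv[g].mean(axis=0)
    pts, uv = pts[keep], uv[keep]
    return ScatteredField(pts[:, 0], pts[:, 1], uv[:, 0], uv[:, 1])


def recover_displacement_stack(reference: np.ndarray, stack: np.ndarray,
                               cfg: PivConfig | None = None,
                               pixel_size_um: float = 0.1,
                               origin_um: tuple[float, float] = (0.0, 0.0),
                               filter_cfg: bool = True
                               ) -> list[VectorField2D]:
    """Cumulative displacement fields for a movie.

    Only the first frame is compared to the unstressed reference; every
    later frame is compared to its predecessor and the incremental
    gridded fields are accumulated (smaller displacements correlate more
    precisely).
    """
    cfg = cfg or PivConfig()
    stack = np.asarray(stack, float)
    fields = []
    prev = np.asarray(reference, float)
    total = None
    for k, frame in enumerate(stack):
        sc = recover_displacement(prev, frame, cfg, pixel_size_um, origin_um)
        if filter_cfg:
            sc = filter_outliers(sc, cfg)
        extent = (origin_um[0], origin_um[0] + (stack.shape[2] - 1) * pixel_size_um,
                  origin_um[1], origin_um[1] + (stack.shape[1] - 1) * pixel_size_um)
        inc = interpolate_to_grid(sc, cfg.grid_spacing_um, extent=extent)
        total = inc if total is None else VectorField2D(
            total.vx + inc.vx, total.vy + inc.vy, inc.grid_spacing_um,
            inc.origin_um, "displacement")
        fields.append(total.copy())
        prev = frame
    return fields


# ---------------------------------------------------------------------------
# filtering and gridding
# ---------------------------------------------------------------------------

def filter_outliers(field: ScatteredField | VectorField2D,
                    cfg: PivConfig | None = None):
    """Discard-and-replace erroneous vectors.

    A vector is erroneous when its magnitude exceeds
    ``cfg.max_magnitude_um`` or when it differs from the mean of its
    neighbours by more than ``cfg.max_neighbor_diff_um``; it is replaced
    by the mean of the surviving neighbours (falling back to the median
    of a larger neighbourhood when all neighbours are flagged).
    """
    cfg = cfg or PivConfig()
    grid_input = isinstance(field, VectorField2D)
    if grid_input:
        ny, nx = field.shape
        X, Y = field.coords()
        x, y = X.ravel(), Y.ravel()
        u, v = field.vx.ravel().copy(), field.vy.ravel().copy()
    else:
        x, y = np.asarray(field.x_um), np.asarray(field.y_um)
        u, v = np.asarray(field.u_um).copy(), np.asarray(field.v_um).copy()

    n = len(x)
    if n < 4:
        return field
    tree = cKDTree(np.column_stack([x, y]))
    k = min(9, n)
    _, idx = tree.query(np.column_stack([x, y]), k=k)
    nbr = idx[:, 1:]  # drop self

    mag = np.hypot(u, v)
    nbr_mean_u = u[nbr].mean(axis=1)
    nbr_mean_v = v[nbr].mean(axis=1)
    diff = np.hypot(u - nbr_mean_u, v - nbr_mean_v)
    bad = (mag > cfg.max_magnitude_um) | (diff > cfg.max_neighbor_diff_um)

    if np.any(bad):
        good = ~bad
        for i in np.flatnonzero(bad):
            nb = nbr[i][good[nbr[i]]]
            if len(nb) > 0:
                u[i] = u[nb].mean()
                v[i] = v[nb].mean()
            else:  # all neighbours flagged: median of a larger neighbourhood
                kk = min(25, n)
                _, big = tree.query([x[i], y[i]], k=kk)
                big = np.atleast_1d(big)
                bigg = big[good[big]]
                if len(bigg) == 0:
                    u[i] = v[i] = 0.0
                else:
                    u[i] = np.median(u[bigg])
                    v[i] = np.median(v[bigg])
    if grid_input:
        return VectorField2D(u.reshape(ny, nx), v.reshape(ny, nx),
                             field.grid_spacing_um, field.origin_um, field.kind)
    return ScatteredField(x, y, u, v)


def interpolate_to_grid(scattered: ScatteredField,
                        spacing_um: float = 1.3,
                        extent: tuple[float, float, float, float] | None = None
                        ) -> VectorField2D:
    """Interpolate scattered measurements onto a regular grid.

    Piecewise-linear interpolation on the Delaunay triangulation (exact
    for affine fields); grid nodes outside the convex hull are
    zero-filled.
    """
    x, y = np.asarray(scattered.x_um), np.asarray(scattered.y_um)
    if len(x) < 3:
        raise ValueError("need at least three measurements")
    if extent is None:
        extent = (x.min(), x.max(), y.min(), y.max())
    gx = np.arange(extent[0], extent[1] + spacing_um / 2, spacing_um)
    gy = np.arange(extent[2], extent[3] + spacing_um / 2, spacing_um)
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([x, y])
    uv = np.column_stack([scattered.u_um, scattered.v_um])
    try:
        lin = LinearNDInterpolator(pts, uv)
    except Exception as exc:  # collinear points
        raise ValueError("measurements are collinear") from exc
    vals = lin(np.column_stack([GX.ravel(), GY.ravel()]))
    vals = np.nan_to_num(vals, nan=0.0)
    return VectorField2D(vals[:, 0].reshape(GX.shape),
                         vals[:, 1].reshape(GX.shape),
                         spacing_um, (gx[0], gy[0]), kind="displacement")


# ---------------------------------------------------------------------------
# FTTC
# ---------------------------------------------------------------------------

def fttc(displacement: VectorField2D, substrate: SubstrateParams,
         reg_lambda: float = 0.0, pad_factor: float = 2.0) -> VectorField2D:
    """Fourier-transform traction cytometry with zero-order regularization.

    Inverts the elastic half-space response on a zero-padded grid:
    per-wavevector Tikhonov solve T̃ = (G̃ᵀG̃ + λ²I)⁻¹ G̃ᵀ ũ with the
    analytic Boussinesq kernel.  The k = 0 mode (net force) is set to
    zero since tractions of an isolated cell must balance.
    """
    if displacement.kind != "displacement":
        raise ValueError("input must be a displacement field")
    if reg_lambda < 0:
        raise ValueError("regularization must be >= 0")
    h = displacement.grid_spacing_um
    ny, nx = displacement.shape
    Ly = next_fast_len(int(np.ceil(pad_factor * ny)))
    Lx = next_fast_len(int(np.ceil(pad_factor * nx)))
    if Ly < 4 or Lx < 4:
        raise ValueError("grid too small")
    # cosine-taper the field into the pad region: an abrupt zero-padding
    # step rings spurious traction along the field border
    taper_y = max(1, min(ny // 8, (Ly - ny) // 2))
    taper_x = max(1, min(nx // 8, (Lx - nx) // 2))

    def ramp(n_taper):
        return 0.5 * (1 + np.cos(np.pi * (np.arange(1, n_taper + 1) / n_taper)))

    ux = np.zeros((Ly, Lx))
    uy = np.zeros((Ly, Lx))
    ux[:ny, :nx] = displacement.vx
    uy[:ny, :nx] = displacement.vy
    ry, rx = ramp(taper_y), ramp(taper_x)
    for arr in (ux, uy):
        # high side, and the periodic seam onto the low side
        arr[ny:ny + taper_y, :nx] = ry[:, None] * arr[ny - 1, :nx]
        arr[Ly - taper_y:, :nx] = ry[::-1, None] * arr[0, :nx]
        full = arr.copy()
        arr[:, nx:nx + taper_x] = full[:, nx - 1, None] * rx[None, :]
        arr[:, Lx - taper_x:] = full[:, 0, None] * rx[None, ::-1]

    kx = 2 * np.pi * np.fft.fftfreq(Lx, d=h)
    ky = 2 * np.pi * np.fft.fftfreq(Ly, d=h)
    KX, KY = np.meshgrid(kx, ky)
    gxx, gyy, gxy = greens_tensor_fourier(KX, KY, substrate)

    Ux, Uy = fft2(ux), fft2(uy)
    # (GᵀG + λ²I)⁻¹ Gᵀ for symmetric 2×2 G, vectorized over k
    a = gxx * gxx + gxy * gxy + reg_lambda**2
    b = gxy * (gxx + gyy)
    c = gxy * gxy + gyy * gyy + reg_lambda**2
    det = a * c - b * b
    det[det == 0] = np.inf
    rx = gxx * Ux + gxy * Uy
    ry = gxy * Ux + gyy * Uy
    Tx = (c * rx - b * ry) / det
    Ty = (-b * rx + a * ry) / det
    Tx[0, 0] = 0.0
    Ty[0, 0] = 0.0
    tx = ifft2(Tx).real[:ny, :nx]
    ty = ifft2(Ty).real[:ny, :nx]
    return VectorField2D(tx, ty, h, displacement.origin_um, kind="traction")


def select_regularization_gcv(displacement: VectorField2D,
                              substrate: SubstrateParams,
                              lambdas: np.ndarray | None = None,
                              pad_factor: float = 2.0) -> float:
    """Generalized cross-validation choice of the Tikhonov parameter.

    Works in the Fourier eigenbasis of the (symmetric) per-mode kernel so
    the GCV function is evaluated in closed form per candidate λ.
    """
    h = displacement.grid_spacing_um
    ny, nx = displacement.shape
    Ly = next_fast_len(int(np.ceil(pad_factor * ny)))
    Lx = next_fast_len(int(np.ceil(pad_factor * nx)))
    ux = np.zeros((Ly, Lx)); ux[:ny, :nx] = displacement.vx
    uy = np.zeros((Ly, Lx)); uy[:ny, :nx] = displacement.vy
    kx = 2 * np.pi * np.fft.fftfreq(Lx, d=h)
    ky = 2 * np.pi * np.fft.fftfreq(Ly, d=h)
    KX, KY = np.meshgrid(kx, ky)
    gxx, gyy, gxy = greens_tensor_fourier(KX, KY, substrate)
    # eigen-decomposition of each symmetric 2×2 kernel block
    tr, dif = gxx + gyy, gxx - gyy
    disc = np.sqrt(dif**2 + 4 * gxy**2)
    g1, g2 = (tr + disc) / 2, (tr - disc) / 2
    theta = 0.5 * np.arctan2(2 * gxy, dif)
    Ux, Uy = fft2(ux), fft2(uy)
    P1 = np.cos(theta) * Ux + np.sin(theta) * Uy
    P2 = -np.sin(theta) * Ux + np.cos(theta) * Uy
    mode_pow = np.stack([np.abs(P1) ** 2, np.abs(P2) ** 2])
    gs = np.stack([g1, g2])
    if lambdas is None:
        scale = np.median(gs[gs > 0])
        lambdas = scale * np.logspace(-4, 2, 25)
    best, best_score = 0.0, np.inf
    N = 2 * Lx * Ly
    for lam in lambdas:
        filt = lam**2 / (gs**2 + lam**2)  # residual factor per eigenmode
        rss = np.sum(filt**2 * mode_pow)
        tr_im_a = np.sum(filt)
        score = N * rss / tr_im_a**2 if tr_im_a > 0 else np.inf
        if score < best_score:
            best, best_score = lam, score
    return float(best)


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------

def strain_energy(traction: VectorField2D, displacement: VectorField2D,
                  mask: np.ndarray | None = None,
                  time_index: int = 0,
                  split: str = "vertical") -> EnergyRecord:
    """Substrate strain energy Es = ½ ∫ T·u dA over the mask, in J.

    ``split`` ("vertical" or "horizontal") selects the mask bisection for
    the left/right (or bottom/top) half energies.
    """
    if traction.shape != displacement.shape or \
            not np.isclose(traction.grid_spacing_um, displacement.grid_spacing_um):
        raise ValueError("fields must be co-registered")
    dens = 0.5 * (traction.vx * displacement.vx + traction.vy * displacement.vy)
    dens = dens * traction.dA_um2 * PA_UM3_TO_J
    m = np.ones(traction.shape, bool) if mask is None else mask
    X, Y = traction.coords()
    if split == "vertical":
        axis, coords = X, X[m]
    else:
        axis, coords = Y, Y[m]
    mid = (coords.min() + coords.max()) / 2 if m.any() else 0.0
    left = m & (axis <= mid)
    right = m & (axis > mid)
    return EnergyRecord(time_index, float(dens[m].sum()),
                        float(dens[left].sum()), float(dens[right].sum()))


def relative_strain_energy(series: list[EnergyRecord] | np.ndarray,
                           baseline_frames: int = 20,
                           cohort_baselines: np.ndarray | None = None
                           ) -> np.ndarray:
    """Normalized strain-energy curve.

    Subtracts this cell's baseline (mean of the first ``baseline_frames``
    frames) and divides by the cohort-average baseline (default: this
    cell alone).
    """
    e = np.array([r.strain_energy_J if isinstance(r, EnergyRecord) else r
                  for r in series], dtype=float)
    if len(e) < baseline_frames:
        raise ValueError("series shorter than the baseline window")
    own_base = e[:baseline_frames].mean()
    denom = own_base if cohort_baselines is None else float(
        np.mean(cohort_baselines))
    if denom == 0:
        raise ValueError("zero baseline energy")
    return (e - own_base) / denom


def response_at(curve: np.ndarray, frame: int) -> float:
    """Readout helper: value of a normalized curve at a stated frame
    (e.g. 2 min after the activation window ends)."""
    return float(curve[frame])
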