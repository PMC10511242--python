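"""Free stress-fiber tracking and the anisotropic tension model (ATM).

A free peripheral stress fiber spanning a non-adhesive gap balances a
line tension λ along the fiber against surface tensions pulling it
toward the cell body.  With an anisotropic tension tensor
Σ = diag(σx, σy), the force balance d(λ t̂)/ds + Σ·n̂ = 0 is solved by
axis-aligned ellipses with

    σx · b² = σy · a²          (a, b = x-, y-semi-axes)

along which the line tension varies; at the midpoint of a free fiber
spanning a horizontal chord λ = σx·b.  The isotropic limit is a circular
arc with R = λ/σ.  σx is measured on the traction maps, σy (and λ)
follow from fitting the ellipse to the tracked fiber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.signal import medfilt

from .fields import PA_UM2_TO_N, ContourTrack, VectorField2D

__all__ = ["AtmFit", "CornerForce", "track_fiber", "filter_track",
           "fit_contour_ellipse", "measure_sigma_x", "corner_force",
           "line_tension_and_fa", "contour_strain", "ellipse_point_distance"]


@dataclass
class AtmFit:
    """Result of the anisotropic-tension ellipse fit.

    Tensions are in Pa·µm (1 nN/µm = 1000 Pa·µm); the line tension λ (at
    the fiber midpoint) is in N.
    """

    sigma_x: float
    sigma_y: float
    line_tension_N: float
    center_um: tuple[float, float]
    a_um: float
    b_um: float
    residual_um: float


@dataclass
class CornerForce:
    """Integrated traction around one adhesive corner."""

    peak_position_um: np.ndarray
    force_N: np.ndarray
    radius_um: float


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def track_fiber(actin_stack: np.ndarray, endpoints: np.ndarray,
                n_profiles: int = 30, pixel_size_um: float = 0.1,
                origin_um: tuple[float, float] = (0.0, 0.0),
                profile_halfwidth_um: float = 12.0,
                smooth_um: float = 0.3,
                contrast_rel: float = 0.05) -> ContourTrack:
    """Track one fiber through a movie by line-profile peak detection.

    Between the two operator-defined endpoints, ``n_profiles`` parallel
    profiles are drawn perpendicular to the chord at regular intervals;
    on each profile the fiber position is the sub-pixel peak of the
    smoothed intensity.  Profiles whose contrast (peak − median) falls
    below ``contrast_rel`` of the frame's dynamic range are flagged
    missing.
    """
    stack = np.asarray(actin_stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    ep = np.asarray(endpoints, float).reshape(2, 2)
    px = pixel_size_um
    chord = ep[1] - ep[0]
    L = np.hypot(*chord)
    t_hat = chord / L
    n_hat = np.array([-t_hat[1], t_hat[0]])
    s_base = np.linspace(0, L, n_profiles + 2)[1:-1]
    t_samples = np.linspace(-profile_halfwidth_um, profile_halfwidth_um,
                            max(16, int(4 * profile_halfwidth_um / px)))
    dt = t_samples[1] - t_samples[0]

    n_frames = stack.shape[0]
    points = np.zeros((n_frames, n_profiles, 2))
    valid = np.zeros((n_frames, n_profiles), bool)
    for k, frame in enumerate(stack):
        rng_int = frame.max() - frame.min()
        for i, s in enumerate(s_base):
            base = ep[0] + s * t_hat
            pos = base[None, :] + t_samples[:, None] * n_hat[None, :]
            rows = (pos[:, 1] - origin_um[1]) / px
            cols = (pos[:, 0] - origin_um[0]) / px
            prof = ndimage.map_coordinates(frame, [rows, cols], order=1,
                                           mode="nearest")
            prof = ndimage.gaussian_filter1d(prof, max(smooth_um / dt, 0.5))
            j = int(np.argmax(prof))
            contrast = prof[j] - np.median(prof)
            points[k, i] = base + t_samples[j] * n_hat
            if contrast <= contrast_rel * rng_int or rng_int == 0:
                continue
            if 0 < j < len(prof) - 1:  # parabolic sub-sample refinement
                d = prof[j - 1] - 2 * prof[j] + prof[j + 1]
                off = 0.0 if d >= 0 else 0.5 * (prof[j - 1] - prof[j + 1]) / d
                points[k, i] = base + (t_samples[j] + off * dt) * n_hat
            valid[k, i] = True
    return ContourTrack(points, valid, ep)


def filter_track(track: ContourTrack, angle_max_deg: float = 15.0,
                 median_window: int = 5, temporal_window: int = 10,
                 temporal_nsigma: float = 2.0, spatial_nsigma: float = 3.0
                 ) -> ContourTrack:
    """Consistency filtering of a tracked fiber, in the stated order:
    temporal median (5 frames) → temporal 2σ outlier removal (10-frame
    windows) → spatial 3σ removal → adjacent-segment angle check (15°).

    Temporal steps are skipped with a warning when the track is shorter
    than ``temporal_window`` frames.  The returned track carries a
    boolean ``usable`` attribute, False when more than half the points
    were invalidated.
    """
    pts = track.points.copy()
    val = track.valid.copy()
    n_f, n_p = val.shape

    if n_f >= temporal_window:
        for i in range(n_p):
            for d in range(2):
                pts[:, i, d] = medfilt(pts[:, i, d], median_window)
        # moving-window 2σ outlier removal per point index
        for i in range(n_p):
            for k in range(n_f):
                lo = max(0, k - temporal_window // 2)
                hi = min(n_f, lo + temporal_window)
                sel = val[lo:hi, i]
                if sel.sum() < 3:
                    continue
                w = pts[lo:hi, i][sel]
                mean = w.mean(axis=0)
                d_k = np.linalg.norm(pts[k, i] - mean)
                sigma = np.sqrt(np.mean(np.sum((w - mean) ** 2, axis=1)))
                if sigma > 0 and d_k > temporal_nsigma * sigma:
                    val[k, i] = False
    elif n_f > 1:
        import warnings
        warnings.warn("track too short for temporal filtering; skipped")

    for k in range(n_f):
        sel = val[k]
        if sel.sum() >= 3:
            w = pts[k][sel]
            mean = w.mean(axis=0)
            d = np.linalg.norm(pts[k] - mean, axis=1)
            sigma = np.sqrt(np.mean(np.sum((w - mean) ** 2, axis=1)))
            if sigma > 0:
                val[k] &= d <= spatial_nsigma * sigma

        # angle criterion: the turn between adjacent segments must stay
        # small — a smooth fiber bends a few degrees per point, a badly
        # tracked point creates a sharp kink
        changed = True
        while changed:
            changed = False
            idx = np.flatnonzero(val[k])
            if len(idx) == 0:
                break
            poly = np.vstack([track.endpoints[0], pts[k][idx],
                              track.endpoints[1]])
            seg = np.diff(poly, axis=0)
            lens = np.linalg.norm(seg, axis=1)
            lens[lens == 0] = 1e-12
            unit = seg / lens[:, None]
            cross = unit[:-1, 0] * unit[1:, 1] - unit[:-1, 1] * unit[1:, 0]
            dot = np.einsum("ij,ij->i", unit[:-1], unit[1:])
            turn = np.abs(np.rad2deg(np.arctan2(cross, dot)))
            # turn[m] is the kink at interior polyline vertex m+1 = point m
            worst, worst_ang = -1, angle_max_deg
            for m, p_idx in enumerate(idx):
                if turn[m] > worst_ang:
                    worst, worst_ang = p_idx, turn[m]
            if worst >= 0:
                val[k, worst] = False
                changed = True

    out = ContourTrack(pts, val, track.endpoints.copy())
    out.usable = val.sum() >= 0.5 * track.valid.sum() if track.valid.any() else False
    return out


# ---------------------------------------------------------------------------
# ATM ellipse geometry
# ---------------------------------------------------------------------------

def ellipse_point_distance(px_: np.ndarray, py_: np.ndarray,
                           a: float, b: float) -> np.ndarray:
    """Orthogonal distance from points (relative to the ellipse centre)
    to the ellipse with semi-axes a, b, by Newton projection."""
    px_ = np.atleast_1d(np.asarray(px_, float))
    py_ = np.atleast_1d(np.asarray(py_, float))
    u = np.arctan2(py_ / b, px_ / a)
    for _ in range(30):
        cu, su = np.cos(u), np.sin(u)
        dx = a * cu - px_
        dy = b * su - py_
        g = -dx * a * su + dy * b * cu
        gp = (-a * su) ** 2 + (b * cu) ** 2 - dx * a * cu - dy * b * su
        step = np.where(np.abs(gp) > 1e-14, g / np.where(gp == 0, 1, gp), 0.0)
        u = u - np.clip(step, -0.5, 0.5)
    return np.hypot(a * np.cos(u) - px_, b * np.sin(u) - py_)


def _chord_frame(adhesion_points: np.ndarray):
    """Return (points transform, inverse) mapping so the adhesion chord is
    horizontal; supports x- or y-aligned chords."""
    p = np.asarray(adhesion_points, float).reshape(2, 2)
    if np.isclose(p[0, 1], p[1, 1]):
        return False, p
    if np.isclose(p[0, 0], p[1, 0]):
        return True, p[:, ::-1].copy()
    raise ValueError("adhesion chord must be axis-aligned")


def fit_contour_ellipse(points: np.ndarray | ContourTrack, sigma_x: float,
                        adhesion_points: np.ndarray) -> AtmFit:
    """Fit the ATM ellipse through both adhesion points to tracked fiber
    points, returning σy and the (midpoint) line tension λ.

    The ellipse family is parametrized by the axis ratio (i.e. σy/σx via
    σx b² = σy a²) and the y-semi-axis; the centre follows from the
    through-the-adhesions constraint.  σy and λ minimize the orthogonal
    point-to-ellipse distance.
    """
    if sigma_x <= 0:
        raise ValueError("sigma_x must be > 0 (measured on the TFM maps)")
    if isinstance(points, ContourTrack):
        pts = points.frame(0)
    else:
        pts = np.asarray(points, float)
    if len(pts) < 5:
        raise ValueError("need at least five valid points")
    transposed, p = _chord_frame(adhesion_points)
    if transposed:
        pts = pts[:, ::-1]
    xc = p[:, 0].mean()
    y0 = p[0, 1]
    half_chord = abs(p[1, 0] - p[0, 0]) / 2.0
    sgn = 1.0 if np.mean(pts[:, 1]) < y0 else -1.0  # centre opposite the bulge

    # initial guess from the circular sagitta
    sag = max(np.max(np.abs(pts[:, 1] - y0)), 1e-3)
    R0 = (half_chord**2 + sag**2) / (2 * sag)

    def unpack(q):
        r = np.exp(q[0])
        b = np.exp(q[1])
        a = r * b
        return r, a, b

    def residuals(q):
        r, a, b = unpack(q)
        if a <= half_chord:  # ellipse cannot reach the adhesions
            return np.full(len(pts), 1e3 * (half_chord / a))
        yc = y0 + sgn * b * np.sqrt(1 - (half_chord / a) ** 2)
        return ellipse_point_distance(pts[:, 0] - xc, pts[:, 1] - yc, a, b)

    # the flat-arc limit has a long, shallow cost valley: bound the axis
    # ratio and restart from several anisotropies, keeping the best
    bounds = ([-2.0, np.log(half_chord * 0.2)],
              [2.0, np.log(half_chord * 200)])
    best = None
    for r0 in (-0.7, 0.0, 0.7):
        b0 = max(R0, half_chord * 1.05) / np.exp(r0 / 2)
        q0 = np.array([r0, np.clip(np.log(b0), *[b[1] for b in bounds])])
        sol = least_squares(residuals, q0, method="trf", bounds=bounds,
                            max_nfev=400)
        cost = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or cost < best[0]:
            best = (cost, sol)
    cost, sol = best
    if not np.isfinite(cost) or cost > max(1.0, 0.2 * half_chord):
        raise RuntimeError("ellipse fit did not converge")
    r, a, b = unpack(sol.x)
    yc = y0 + sgn * b * np.sqrt(1 - (half_chord / a) ** 2)
    resid = float(np.sqrt(np.mean(sol.fun**2)))

    if transposed:
        # in the working frame x↔y are swapped, so the known tension σx
        # plays the σy role there: σy_orig = σx·(a/b)², λ = σy_orig·b
        center = (yc, xc)
        a_out, b_out = b, a
        sigma_y = sigma_x * (a / b) ** 2
        lam = sigma_y * b
    else:
        center = (xc, yc)
        a_out, b_out = a, b
        sigma_y = sigma_x * (b / a) ** 2  # from σx b² = σy a²
        lam = sigma_x * b  # λ at the y-extreme midpoint
    return AtmFit(sigma_x, float(sigma_y), float(lam * PA_UM2_TO_N),
                  center, float(a_out), float(b_out), resid)


# ---------------------------------------------------------------------------
# traction-derived forces
# ---------------------------------------------------------------------------

def measure_sigma_x(traction: VectorField2D, fiber_center: tuple[float, float],
                    window_um: tuple[float, float] = (4.0, 10.0)) -> float:
    """Surface tension in x from the traction maps: |Σ Tx dA| in a window
    around the centre of the vertical adherent fiber, divided by the
    window height.  Returns Pa·µm (1 nN/µm = 1000 Pa·µm)."""
    X, Y = traction.coords()
    wx, wy = window_um
    sel = (np.abs(X - fiber_center[0]) <= wx / 2) & \
          (np.abs(Y - fiber_center[1]) <= wy / 2)
    if not sel.any():
        raise ValueError("window lies outside the field")
    fx = traction.vx[sel].sum() * traction.dA_um2  # Pa·µm²
    return float(abs(fx) / wy)


def corner_force(traction: VectorField2D,
                 approximate_corner: tuple[float, float],
                 radius_um: float = 12.0,
                 search_radius_um: float = 8.0,
                 peak_factor: float = 3.0) -> CornerForce:
    """Total force in one corner: locate the traction-magnitude peak near
    the corner, then sum traction × area over a disc of ``radius_um``.

    Raises when no peak above ``peak_factor`` × the field's median
    magnitude exists near the corner (ties broken toward the corner).
    """
    X, Y = traction.coords()
    mag = traction.magnitude()
    near = np.hypot(X - approximate_corner[0], Y - approximate_corner[1]) \
        <= search_radius_um
    if not near.any():
        raise ValueError("search region outside the field")
    background = np.median(mag)
    peak_val = mag[near].max()
    if peak_val <= peak_factor * max(background, 1e-300) or peak_val == 0:
        raise ValueError("no traction peak above background near the corner")
    cand = near & (mag >= peak_val * (1 - 1e-12))
    d2 = (X - approximate_corner[0]) ** 2 + (Y - approximate_corner[1]) ** 2
    d2m = np.where(cand, d2, np.inf)
    iy, ix = np.unravel_index(np.argmin(d2m), mag.shape)
    peak = np.array([X[iy, ix], Y[iy, ix]])

    disc = np.hypot(X - peak[0], Y - peak[1]) <= radius_um
    F = np.array([traction.vx[disc].sum(), traction.vy[disc].sum()]) \
        * traction.dA_um2 * PA_UM2_TO_N
    return CornerForce(peak, F, radius_um)


def line_tension_and_fa(cf: CornerForce, contour_tangent: np.ndarray,
                        sigma_x: float | None = None,
                        adherent_length_um: float | None = None,
                        inward: np.ndarray | None = None,
                        correction=None) -> tuple[float, float]:
    """Project the corner force onto the contour tangent (line tension λ)
    and onto the y-axis (adherent-fiber force Fa), both in N.

    When ``sigma_x`` (Pa·µm) and ``adherent_length_um`` are given, the
    surface-tension pull on the adherent fiber is first removed via the
    default strategy F → F − σx·L/2·(inward unit vector); pass
    ``correction`` to substitute another strategy
    ``correction(F_N, sigma_x, L_um, inward) -> F_N``.
    """
    t_hat = np.asarray(contour_tangent, float)
    norm = np.hypot(*t_hat)
    if norm == 0:
        raise ValueError("zero-length tangent")
    t_hat = t_hat / norm
    F = cf.force_N.copy()
    if sigma_x is not None and adherent_length_um is not None:
        if correction is None:
            def correction(F, sx, L, inw):
                inw = np.asarray(inw if inw is not None else (-1.0, 0.0), float)
                return F - sx * L / 2.0 * PA_UM2_TO_N * inw
        F = correction(F, sigma_x, adherent_length_um, inward)
    lam = float(F @ t_hat)
    fa = float(F @ np.array([0.0, 1.0]))
    return lam, fa


def contour_strain(before: tuple[ContourTrack, ContourTrack],
                   after: tuple[ContourTrack, ContourTrack],
                   n_x: int = 50) -> dict:
    """Contour strain profile along x: the inter-fiber distance after
    photoactivation divided by the distance before.

    Each epoch is a (top fiber, bottom fiber) pair; frames within an
    epoch are averaged.  Fibers are interpolated onto a common x-grid
    restricted to the overlap of all four tracks.
    """
    def mean_profile(track: ContourTrack):
        xs, ys = [], []
        for k in range(track.n_frames):
            p = track.frame(k)
            if len(p) >= 2:
                order = np.argsort(p[:, 0])
                xs.append(p[order, 0])
                ys.append(p[order, 1])
        if not xs:
            raise ValueError("track has no usable frames")
        grid = np.linspace(max(x[0] for x in xs), min(x[-1] for x in xs), 200)
        return grid, np.mean([np.interp(grid, x, y) for x, y in zip(xs, ys)],
                             axis=0)

    profs = [mean_profile(t) for t in (*before, *after)]
    lo = max(p[0][0] for p in profs)
    hi = min(p[0][-1] for p in profs)
    if lo >= hi:
        raise ValueError("tracks do not overlap in x")
    x = np.linspace(lo, hi, n_x)
    tb, bb, ta, ba = [np.interp(x, *p) for p in profs]
    d_before = tb - bb
    d_after = ta - ba
    if np.any(d_before == 0):
        raise ValueError("degenerate inter-fiber distance")
    return {"x_um": x, "strain": d_after / d_before,
            "d_before_um": d_before, "d_after_um": d_after}
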