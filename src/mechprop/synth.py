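"""Synthetic-data generators.

Everything the pipeline consumes can be manufactured here with known
ground truth: corner-concentrated traction patterns on H-shaped or
rectangular micropatterns, bead images advected by the elastic
half-space response, oriented actin-like textures, free-fiber contour
points sampled from the anisotropic-tension ellipse, and photoactivation
time series driven by the active FEM model with a known coupling degree.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .boussinesq import SubstrateParams
from .fields import PA_UM2_TO_N, ContourTrack, VectorField2D

__all__ = [
    "PatternGeometry", "BeadImagePair", "make_pattern_traction",
    "render_bead_images", "make_oriented_texture", "make_contour_points",
    "make_activation_dataset", "SubstrateParams",
]


@dataclass
class PatternGeometry:
    """Adhesive micropattern geometry (H or rectangle), centred at (0, 0).

    Defaults match the 45 µm × 45 µm H pattern on which doublets and
    singlets are grown; aspect-ratio variants keep the spreading area and
    change width/height.
    """

    shape: str = "H"  # or "rectangle"
    width_um: float = 45.0
    height_um: float = 45.0
    corner_patch_radius_um: float = 3.0
    pixel_size_um: float = 0.1

    def __post_init__(self):
        if self.shape not in ("H", "rectangle"):
            raise ValueError("shape must be 'H' or 'rectangle'")
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("pattern dimensions must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")

    def corners(self) -> np.ndarray:
        """Corner positions, order: bottom-left, bottom-right, top-left,
        top-right."""
        w, h = self.width_um / 2.0, self.height_um / 2.0
        return np.array([[-w, -h], [w, -h], [-w, h], [w, h]])

    def cell_mask(self, grid_spacing_um: float,
                  margin_um: float = 10.0) -> tuple[np.ndarray, tuple[float, float]]:
        """Boolean mask of the spread cell (its rectangular hull) and the
        origin of the enclosing grid."""
        X, Y, origin = _field_grid(self, grid_spacing_um, margin_um)
        mask = (np.abs(X) <= self.width_um / 2) & (np.abs(Y) <= self.height_um / 2)
        return mask, origin


@dataclass
class BeadImagePair:
    """Reference bead image plus deformed frames rendered from known
    displacement fields."""

    reference: np.ndarray
    deformed: np.ndarray  # shape (n_frames, ny, nx)
    pixel_size_um: float
    bead_density_per_um2: float
    noise_sigma: float
    bead_xy_um: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.deformed.ndim == 2:
            self.deformed = self.deformed[None]
        if self.deformed.shape[1:] != self.reference.shape:
            raise ValueError("reference and deformed frames differ in shape")
        if np.any(self.reference < 0) or np.any(self.deformed < 0):
            raise ValueError("intensities must be non-negative")


def _field_grid(geometry: PatternGeometry, spacing: float, margin_um: float):
    half_x = geometry.width_um / 2 + margin_um
    half_y = geometry.height_um / 2 + margin_um
    nx = int(round(2 * half_x / spacing)) + 1
    ny = int(round(2 * half_y / spacing)) + 1
    x = (np.arange(nx) - (nx - 1) / 2) * spacing
    y = (np.arange(ny) - (ny - 1) / 2) * spacing
    X, Y = np.meshgrid(x, y)
    return X, Y, (x[0], y[0])


def make_pattern_traction(geometry: PatternGeometry,
                          corner_forces: list | np.ndarray,
                          fiber_arcs: list | None = None,
                          auto_balance: bool = True,
                          grid_spacing_um: float | None = None,
                          margin_um: float = 16.0) -> VectorField2D:
    """Traction field (Pa) with Gaussian hotspots at the pattern corners.

    Parameters
    ----------
    corner_forces : array-like, shape (4, 2)
        Force vector per corner in N (order bottom-left, bottom-right,
        top-left, top-right).
    fiber_arcs : optional list of dicts
        Additional line-distributed traction, each
        ``{"p0": (x, y), "p1": (x, y), "force_per_length_N_per_um": (fx, fy),
        "width_um": w}``.
    auto_balance : bool
        Subtract the mean corner force so the total traction integrates to
        zero (force balance of an isolated cell).
    """
    if geometry.corner_patch_radius_um <= 0:
        raise ValueError("corner patch radius must be > 0")
    spacing = grid_spacing_um or geometry.pixel_size_um
    corner_forces = np.asarray(corner_forces, dtype=float).reshape(4, 2)
    if auto_balance:
        corner_forces = corner_forces - corner_forces.mean(axis=0)

    X, Y, origin = _field_grid(geometry, spacing, margin_um)
    if geometry.corner_patch_radius_um > margin_um + min(
            geometry.width_um, geometry.height_um) / 2:
        raise ValueError("corner patches extend outside the field of view")
    tx = np.zeros_like(X)
    ty = np.zeros_like(X)
    sig = geometry.corner_patch_radius_um / 2.0  # patch ~ 2σ radius
    for (cx, cy), (fx, fy) in zip(geometry.corners(), corner_forces):
        g = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sig**2))
        g /= g.sum() * spacing**2 * PA_UM2_TO_N  # integral = 1 N
        tx += fx * g
        ty += fy * g

    for arc in fiber_arcs or []:
        p0 = np.asarray(arc["p0"], float)
        p1 = np.asarray(arc["p1"], float)
        fpl = np.asarray(arc["force_per_length_N_per_um"], float)
        w = arc.get("width_um", 1.0)
        seg = p1 - p0
        L = np.hypot(*seg)
        t_hat = seg / L
        # signed distance along / across the segment
        relx, rely = X - p0[0], Y - p0[1]
        s = relx * t_hat[0] + rely * t_hat[1]
        d = -relx * t_hat[1] + rely * t_hat[0]
        prof = np.exp(-d**2 / (2 * w**2)) * ((s >= 0) & (s <= L))
        area = prof.sum() * spacing**2
        if area > 0:
            # total force = fpl * L; convert N → Pa over the painted strip
            tx += fpl[0] * L / (area * PA_UM2_TO_N) * prof
            ty += fpl[1] * L / (area * PA_UM2_TO_N) * prof

    return VectorField2D(tx, ty, spacing, origin, kind="traction")


def render_bead_images(displacement: VectorField2D | list,
                       density_per_um2: float = 0.06,
                       psf_sigma_um: float = 0.3,
                       noise_sigma: float = 0.0,
                       seed: int | None = 0,
                       pixel_size_um: float | None = None) -> BeadImagePair:
    """Render a reference bead image and frames advected by displacement.

    ``displacement`` may be a single field or a list of *cumulative*
    fields (one per frame).  Beads are unit-amplitude Gaussian spots of
    waist ``psf_sigma_um``; Gaussian read noise of s.d. ``noise_sigma``
    (in units of the bead peak amplitude) is added to every frame and to
    the reference.  Deterministic for a fixed seed.
    """
    fields_ = displacement if isinstance(displacement, (list, tuple)) else [displacement]
    f0 = fields_[0]
    px = pixel_size_um or f0.grid_spacing_um
    X, Y = f0.coords()
    x0, y0 = f0.origin_um
    extent_x = X[0, -1] - X[0, 0]
    extent_y = Y[-1, 0] - Y[0, 0]
    nx = int(np.floor(extent_x / px)) + 1
    ny = int(np.floor(extent_y / px)) + 1

    rng = np.random.default_rng(seed)
    n_beads = rng.poisson(density_per_um2 * extent_x * extent_y)
    if n_beads == 0 or density_per_um2 * (4 * psf_sigma_um) ** 2 > 50:
        import warnings
        warnings.warn("bead density leaves correlation windows empty or saturated")
    bx = x0 + rng.uniform(0, extent_x, n_beads)
    by = y0 + rng.uniform(0, extent_y, n_beads)

    def paint(px_pos, py_pos):
        img = np.zeros((ny, nx))
        s = psf_sigma_um / px
        half = int(np.ceil(4 * s))
        cols = (px_pos - x0) / px
        rows = (py_pos - y0) / px
        for c, r in zip(cols, rows):
            ic, ir = int(round(c)), int(round(r))
            c0, c1 = max(ic - half, 0), min(ic + half + 1, nx)
            r0, r1 = max(ir - half, 0), min(ir + half + 1, ny)
            if c0 >= c1 or r0 >= r1:
                continue
            cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
            img[r0:r1, c0:c1] += np.exp(-((cc - c) ** 2 + (rr - r) ** 2) / (2 * s**2))
        return img

    reference = paint(bx, by)
    frames = []
    from scipy.interpolate import RegularGridInterpolator
    for fld in fields_:
        gx = fld.origin_um[0] + fld.grid_spacing_um * np.arange(fld.shape[1])
        gy = fld.origin_um[1] + fld.grid_spacing_um * np.arange(fld.shape[0])
        iux = RegularGridInterpolator((gy, gx), fld.vx, bounds_error=False,
                                      fill_value=0.0)
        iuy = RegularGridInterpolator((gy, gx), fld.vy, bounds_error=False,
                                      fill_value=0.0)
        pts = np.column_stack([by, bx])
        frames.append(paint(bx + iux(pts), by + iuy(pts)))
    deformed = np.stack(frames)

    if noise_sigma > 0:
        reference = reference + rng.normal(0, noise_sigma, reference.shape)
        deformed = deformed + rng.normal(0, noise_sigma, deformed.shape)
        reference = np.clip(reference, 0, None)
        deformed = np.clip(deformed, 0, None)
    return BeadImagePair(reference, deformed, px, density_per_um2,
                         noise_sigma, np.column_stack([bx, by]))


def make_oriented_texture(angle_deg: float, coherency_target: float,
                          size: int = 256, seed: int | None = 0) -> np.ndarray:
    """Filtered-noise texture whose dominant structure orientation is
    ``angle_deg`` (CCW from +x, in degrees).

    ``coherency_target`` in [0, 1] sets the anisotropy of the smoothing
    kernel monotonically; 0 gives isotropic noise (no preferred axis).
    """
    if not 0 <= coherency_target <= 1:
        raise ValueError("coherency_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pad = size  # generate larger, rotate, crop centre
    noise = rng.normal(size=(size + pad, size + pad))
    s0 = 1.2
    s_par = s0 * (1.0 + 14.0 * coherency_target)
    # smooth along x → structures elongated along x (θ = 0)
    tex = ndimage.gaussian_filter(noise, sigma=(s0, s_par))
    if angle_deg % 180 != 0:
        # positive structure angle (CCW, y up) = positive ndimage angle on
        # arrays whose row index increases with y
        tex = ndimage.rotate(tex, angle_deg, reshape=False, order=3,
                             mode="reflect")
    lo = (size + pad - size) // 2
    tex = tex[lo:lo + size, lo:lo + size]
    tex = tex - tex.min()
    return tex


def make_contour_points(sigma_x: float, sigma_y: float, line_tension: float,
                        adhesion_points: np.ndarray,
                        n_points: int = 30, noise_um: float = 0.0,
                        seed: int | None = 0,
                        bulge_toward: tuple[float, float] = (0.0, 0.0)
                        ) -> ContourTrack:
    """Sample a free-fiber contour from the anisotropic-tension ellipse.

    The force balance d(λ t̂)/ds + Σ·n̂ = 0 with Σ = diag(σx, σy) is solved
    by an axis-aligned ellipse with σx·b² = σy·a² and position-dependent
    line tension; ``line_tension`` is λ at the midpoint of the free arc.
    For the isotropic case the arc is a circle of radius λ/σ.

    ``adhesion_points`` (2×2) must share their y (horizontal chord, the
    usual free fiber spanning the non-adhesive gap) or their x (vertical
    chord; handled by transposition).
    """
    if sigma_x <= 0 or sigma_y <= 0 or line_tension <= 0:
        raise ValueError("tensions must be > 0")
    p = np.asarray(adhesion_points, dtype=float).reshape(2, 2)
    if np.allclose(p[0], p[1]):
        raise ValueError("adhesion points must be distinct")
    rng = np.random.default_rng(seed)

    transposed = False
    bt = np.asarray(bulge_toward, float)
    if not np.isclose(p[0, 1], p[1, 1]):
        if np.isclose(p[0, 0], p[1, 0]):
            p = p[:, ::-1].copy()
            bt = bt[::-1].copy()
            sigma_x, sigma_y = sigma_y, sigma_x
            transposed = True
        else:
            raise ValueError("adhesion chord must be axis-aligned")

    # λ at the arc midpoint (y-extreme of a horizontal chord) equals σx·b
    b = line_tension / sigma_x
    a = b * np.sqrt(sigma_x / sigma_y)
    xc = p[:, 0].mean()
    y0 = p[0, 1]
    half_chord = abs(p[1, 0] - p[0, 0]) / 2.0
    if a < half_chord:
        raise ValueError("no ATM ellipse through the adhesion points for "
                         "these tensions (semi-axis smaller than half-chord)")
    dy = b * np.sqrt(1.0 - (half_chord / a) ** 2)
    # centre sits on the far side of the chord from the bulge
    sgn = 1.0 if bt[1] < y0 else -1.0
    yc = y0 + sgn * dy

    u = np.array([np.arctan2((p[i, 1] - yc) / b, (p[i, 0] - xc) / a)
                  for i in range(2)])
    # traverse the minor arc through the extreme point opposite the centre
    u_ext = -np.pi / 2 if sgn > 0 else np.pi / 2
    lo, hi = min(u), max(u)
    if not lo < u_ext < hi:  # wrap the branch cut
        lo, hi = hi, lo + 2 * np.pi
    uu = np.linspace(lo, hi, n_points + 2)[1:-1]
    pts = np.column_stack([xc + a * np.cos(uu), yc + b * np.sin(uu)])
    if transposed:
        pts = pts[:, ::-1]
    pts = pts + rng.normal(0, noise_um, pts.shape) if noise_um > 0 else pts
    valid = np.ones(len(pts), bool)
    endpoints = np.asarray(adhesion_points, dtype=float).reshape(2, 2)
    return ContourTrack(pts[None], valid[None], endpoints)


def make_activation_dataset(fem_params=None, coupling_true: float = 0.4,
                            schedule: tuple[int, int, int] = (20, 10, 30),
                            seed: int | None = 0,
                            geometry: PatternGeometry | None = None) -> dict:
    """Photoactivation dataset generated by the active FEM model with a
    known coupling degree.

    Returns a dict with cumulative ``traction`` / ``stress`` /
    ``displacement`` stacks (one entry per simulated minute), the contour
    inter-fiber distance stack, the activation ``schedule``
    (baseline, activation, post frames) and the ground-truth ε in
    ``meta``.
    """
    from .activesim import FemParams, simulate_contour, simulate_fem

    if not -1.0 <= coupling_true <= 1.0:
        raise ValueError("coupling_true must lie in [-1, 1]")
    geometry = geometry or PatternGeometry()
    params = fem_params or FemParams()
    n_total = sum(schedule)
    if params.activation_window != (schedule[0], schedule[0] + schedule[1]):
        params = params.replace(activation_window=(schedule[0],
                                                   schedule[0] + schedule[1]),
                                n_frames=n_total)
    fem = simulate_fem(params, geometry, coupling_true)
    contour = simulate_contour(epsilon=coupling_true,
                               n_frames=n_total,
                               activation_window=params.activation_window)
    return {
        "traction": fem["traction"],
        "stress": fem["stress"],
        "displacement": fem["displacement"],
        "contour_distance": contour["distance"],
        "contour_x": contour["x_um"],
        "schedule": schedule,
        "meta": {"epsilon_true": coupling_true, "seed": seed},
    }
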