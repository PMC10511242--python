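"""Monolayer stress microscopy.

The cell sheet is modelled as a thin elastic layer in mechanical
equilibrium with the measured substrate tractions: the traction field is
applied as a body force to a plane-stress FEM on the cell mask with
traction-free boundary, and the recovered sheet stress σ (in Pa·µm =
1e-6 N/m) satisfies ∇·σ = T inside the mask.  Because the load is
prescribed, the recovered stress is independent of the sheet's elastic
modulus (only weakly dependent on its Poisson ratio).
"""

from __future__ import annotations

import numpy as np

from . import fem
from .fields import StressMap, VectorField2D

__all__ = ["msm_solve", "mean_stresses", "y_averaged_profiles",
           "stress_difference_map"]


def _coarsen(arr: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a 2D array by an integer factor (trailing rows/cols
    dropped)."""
    ny, nx = arr.shape
    ny2, nx2 = ny // factor, nx // factor
    a = arr[:ny2 * factor, :nx2 * factor].astype(float)
    return a.reshape(ny2, factor, nx2, factor).mean(axis=(1, 3))


def msm_solve(traction: VectorField2D, mask: np.ndarray,
              sheet_modulus: float = 1000.0, sheet_poisson: float = 0.5,
              mesh_factor: int = 1,
              balance_tol: float = 0.2) -> StressMap:
    """Recover the intracellular 2D stress tensor from traction.

    Parameters
    ----------
    traction : VectorField2D (Pa)
    mask : boolean array on the traction grid (the cell footprint)
    sheet_modulus : 2D Young's modulus of the sheet in Pa·µm — the result
        does not depend on it (regression-tested); it only sets the scale
        of the intermediate displacement.
    mesh_factor : element size in traction-grid pixels.
    balance_tol : maximum tolerated |net force| / Σ|T|dA before the
        uniform correction is considered meaningless.
    """
    if traction.kind != "traction":
        raise ValueError("input must be a traction field")
    mask = np.asarray(mask, bool)
    if mask.shape != traction.shape:
        raise ValueError("mask must live on the traction grid")
    if not mask.any():
        raise ValueError("degenerate mask")

    spacing = traction.grid_spacing_um * mesh_factor
    elem_mask = _coarsen(mask, mesh_factor) >= 0.5
    tx = _coarsen(np.where(mask, traction.vx, 0.0), mesh_factor)
    ty = _coarsen(np.where(mask, traction.vy, 0.0), mesh_factor)
    if not elem_mask.any():
        raise ValueError("mask too small for the requested mesh size")

    mesh = fem.QuadMesh.from_element_mask(
        elem_mask, spacing,
        origin=(traction.origin_um[0] - traction.grid_spacing_um / 2,
                traction.origin_um[1] - traction.grid_spacing_um / 2))
    e_sel = elem_mask
    bx = tx[e_sel]
    by = ty[e_sel]

    # remove residual net force and torque so the Neumann problem is solvable
    dA = spacing**2
    total_abs = np.sum(np.hypot(bx, by)) * dA
    net = np.array([bx.sum(), by.sum()]) * dA
    if total_abs > 0 and np.hypot(*net) / total_abs > balance_tol:
        raise ValueError("traction net force exceeds balance tolerance "
                         f"({np.hypot(*net) / total_abs:.2f} of total)")
    n_el = len(bx)
    bx = bx - net[0] / (n_el * dA)
    by = by - net[1] / (n_el * dA)
    ctr = mesh.elem_centers()
    cx, cy = ctr.mean(axis=0)
    rx, ry = ctr[:, 0] - cx, ctr[:, 1] - cy
    torque = np.sum(rx * by - ry * bx) * dA
    r2 = np.sum(rx**2 + ry**2) * dA
    if r2 > 0:
        bx += torque / r2 * ry
        by += -torque / r2 * rx

    C = fem.plane_stress_C(sheet_modulus, sheet_poisson)
    K = fem.assemble_stiffness(mesh, C)
    # cell equilibrium: ∇·σ − T = 0 → weak form loads the sheet with −T
    f = fem.load_from_body_force(mesh, -bx, -by)
    u = fem.solve_neumann(K, f, mesh)
    strains = fem.element_strains(mesh, u)
    sig = strains @ C.T  # (n_elems, 3) Voigt

    ney, nex = elem_mask.shape
    sxx = np.zeros((ney, nex)); syy = np.zeros((ney, nex)); sxy = np.zeros((ney, nex))
    idx = mesh.elem_index
    sel = idx >= 0
    sxx[sel] = sig[idx[sel], 0]
    syy[sel] = sig[idx[sel], 1]
    sxy[sel] = sig[idx[sel], 2]
    origin = (traction.origin_um[0] + (mesh_factor - 1) / 2 * traction.grid_spacing_um,
              traction.origin_um[1] + (mesh_factor - 1) / 2 * traction.grid_spacing_um)
    return StressMap(sxx, syy, sxy, elem_mask, spacing, origin)


def mean_stresses(stress: StressMap) -> dict:
    """Area-weighted mean normal stresses over the mask, plus left/right
    half means (vertical midline split)."""
    m = stress.mask
    if not m.any():
        raise ValueError("empty mask")
    nx = stress.shape[1]
    x_idx = np.arange(nx)
    cols = x_idx[m.any(axis=0)]
    mid = (cols.min() + cols.max()) / 2.0
    left = m & (x_idx[None, :] <= mid)
    right = m & (x_idx[None, :] > mid)
    out = {
        "sxx_mean": float(stress.sxx[m].mean()),
        "syy_mean": float(stress.syy[m].mean()),
        "sxx_left": float(stress.sxx[left].mean()) if left.any() else np.nan,
        "sxx_right": float(stress.sxx[right].mean()) if right.any() else np.nan,
        "syy_left": float(stress.syy[left].mean()) if left.any() else np.nan,
        "syy_right": float(stress.syy[right].mean()) if right.any() else np.nan,
    }
    return out


def y_averaged_profiles(stress: StressMap) -> dict:
    """x-profiles of the stress components averaged over y (mask rows)."""
    m = stress.mask
    with np.errstate(invalid="ignore"):
        n = m.sum(axis=0).astype(float)
        n[n == 0] = np.nan
        prof_xx = np.where(m, stress.sxx, 0.0).sum(axis=0) / n
        prof_yy = np.where(m, stress.syy, 0.0).sum(axis=0) / n
    x = stress.origin_um[0] + stress.grid_spacing_um * np.arange(stress.shape[1])
    return {"x_um": x, "sxx": prof_xx, "syy": prof_yy}


def stress_difference_map(before: StressMap, after: StressMap) -> StressMap:
    """after − before, elementwise on the common mask."""
    if before.shape != after.shape or not np.isclose(
            before.grid_spacing_um, after.grid_spacing_um):
        raise ValueError("stress maps are not co-registered")
    mask = before.mask & after.mask
    return StressMap(after.sxx - before.sxx, after.syy - before.syy,
                     after.sxy - before.sxy, mask,
                     before.grid_spacing_um, before.origin_um)
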