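"""Elastic half-space (Boussinesq) surface response.

The substrate is a linear elastic half-space; only tangential surface
displacement and traction are considered.  Two independent routes are
provided:

* :func:`forward_displacement` — aperiodic FFT convolution of the traction
  field with the real-space surface Green's function (the singular
  self-cell is replaced by its analytic cell average).  This is the
  forward model used to manufacture synthetic data and serves as the
  oracle for the Fourier-space inversion in :mod:`mechprop.tfm`.
* :func:`direct_displacement` — brute-force real-space summation at
  arbitrary evaluation points, with subdivision of nearby cells; used in
  tests as a second, fully independent quadrature.

The tangential surface Green's function is

    G_ij(r) = (1+ν) / (π E) [ (1−ν) δ_ij / r + ν r_i r_j / r³ ]

with Young's modulus E and Poisson ratio ν.  ν defaults to 0.5
(incompressible polyacrylamide convention) throughout the package; the
expressions are regular at ν = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft2, ifft2, next_fast_len

from .fields import VectorField2D


@dataclass
class SubstrateParams:
    """Elastic substrate: Young's modulus in Pa, Poisson ratio."""

    youngs_modulus_Pa: float = 20e3
    poisson_ratio: float = 0.5

    def __post_init__(self):
        if self.youngs_modulus_Pa <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0 <= self.poisson_ratio <= 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5]")


def greens_tensor(dx: np.ndarray, dy: np.ndarray,
                  substrate: SubstrateParams) -> tuple[np.ndarray, ...]:
    """Real-space Green's tensor components (Gxx, Gyy, Gxy) at offsets (dx, dy).

    Units: µm displacement per (Pa · µm²) of point force.  The r=0 entry is
    left infinite; callers must treat the singular cell themselves.
    """
    E, nu = substrate.youngs_modulus_Pa, substrate.poisson_ratio
    r = np.hypot(dx, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = (1 + nu) / (np.pi * E)
        gxx = pref * ((1 - nu) / r + nu * dx * dx / r**3)
        gyy = pref * ((1 - nu) / r + nu * dy * dy / r**3)
        gxy = pref * (nu * dx * dy / r**3)
    return gxx, gyy, gxy


def _self_cell_average(h: float, substrate: SubstrateParams) -> float:
    """Average of the diagonal Green's entry over the singular h×h cell.

    ∫ dA / r over a centred square of side h is 4 h ln(1+√2); the
    anisotropic part contributes half of that per diagonal component and
    nothing off-diagonal.
    """
    E, nu = substrate.youngs_modulus_Pa, substrate.poisson_ratio
    I1 = 4.0 * h * np.log(1.0 + np.sqrt(2.0))
    return (1 + nu) / (np.pi * E) * ((1 - nu) + nu / 2.0) * I1 / h**2


def forward_displacement(traction: VectorField2D,
                         substrate: SubstrateParams,
                         pad_factor: float = 2.0) -> VectorField2D:
    """Surface displacement (µm) produced by a traction field (Pa).

    Linear aperiodic convolution with the real-space kernel, computed via
    zero-padded FFTs.  ``pad_factor`` ≥ 2 guarantees no periodic
    wrap-around of the kernel support.
    """
    if traction.kind != "traction":
        raise ValueError("input field must be a traction field")
    h = traction.grid_spacing_um
    ny, nx = traction.shape
    # kernel sampled on all offsets −(n−1)..(n−1); linear conv size ≥ 2n−1
    Ly = next_fast_len(int(np.ceil(pad_factor * ny)) + ny)
    Lx = next_fast_len(int(np.ceil(pad_factor * nx)) + nx)
    oy = np.fft.fftfreq(Ly, 1.0 / Ly)  # signed integer offsets
    ox = np.fft.fftfreq(Lx, 1.0 / Lx)
    DX, DY = np.meshgrid(ox * h, oy * h)
    gxx, gyy, gxy = greens_tensor(DX, DY, substrate)
    g0 = _self_cell_average(h, substrate)
    gxx[0, 0] = g0
    gyy[0, 0] = g0
    gxy[0, 0] = 0.0

    tx = np.zeros((Ly, Lx))
    ty = np.zeros((Ly, Lx))
    tx[:ny, :nx] = traction.vx
    ty[:ny, :nx] = traction.vy
    Ftx, Fty = fft2(tx), fft2(ty)
    Fgxx, Fgyy, Fgxy = fft2(gxx), fft2(gyy), fft2(gxy)
    ux = ifft2(Fgxx * Ftx + Fgxy * Fty).real[:ny, :nx] * h**2
    uy = ifft2(Fgxy * Ftx + Fgyy * Fty).real[:ny, :nx] * h**2
    return VectorField2D(ux, uy, h, traction.origin_um, kind="displacement")


def direct_displacement(traction: VectorField2D,
                        substrate: SubstrateParams,
                        points_um: np.ndarray,
                        refine_radius_cells: float = 4.0,
                        refine: int = 8) -> np.ndarray:
    """Brute-force displacement at arbitrary points (µm), shape (n, 2).

    Cells closer than ``refine_radius_cells`` grid cells to an evaluation
    point are subdivided ``refine × refine`` to resolve the near-singular
    kernel.  Independent of the FFT route; O(n_points × n_cells).
    """
    h = traction.grid_spacing_um
    X, Y = traction.coords()
    tx, ty = traction.vx.ravel(), traction.vy.ravel()
    xs, ys = X.ravel(), Y.ravel()
    live = (tx != 0) | (ty != 0)
    xs, ys, tx, ty = xs[live], ys[live], tx[live], ty[live]

    # subcell offsets for refinement (cell-centred midpoint rule)
    s = (np.arange(refine) + 0.5) / refine - 0.5
    SX, SY = np.meshgrid(s * h, s * h)
    out = np.zeros((len(points_um), 2))
    for i, (px, py) in enumerate(np.atleast_2d(points_um)):
        dx, dy = px - xs, py - ys
        r = np.hypot(dx, dy)
        near = r < refine_radius_cells * h
        gxx, gyy, gxy = greens_tensor(dx[~near], dy[~near], substrate)
        ux = np.sum((gxx * tx[~near] + gxy * ty[~near])) * h * h
        uy = np.sum((gxy * tx[~near] + gyy * ty[~near])) * h * h
        for x0, y0, tx0, ty0 in zip(xs[near], ys[near], tx[near], ty[near]):
            ddx = px - (x0 + SX)
            ddy = py - (y0 + SY)
            gxx, gyy, gxy = greens_tensor(ddx, ddy, substrate)
            w = (h / refine) ** 2
            ok = np.isfinite(gxx)
            ux += np.sum((gxx * tx0 + gxy * ty0)[ok]) * w
            uy += np.sum((gxy * tx0 + gyy * ty0)[ok]) * w
        out[i] = (ux, uy)
    return out


def greens_tensor_fourier(kx: np.ndarray, ky: np.ndarray,
                          substrate: SubstrateParams) -> tuple[np.ndarray, ...]:
    """Analytic Fourier-space Green's tensor (Gxx, Gyy, Gxy) on a k-grid.

    k in rad/µm; the k = 0 entry is returned as 0 (the net-force mode of
    the half-space solution is undetermined and handled by the caller).
    """
    E, nu = substrate.youngs_modulus_Pa, substrate.poisson_ratio
    k = np.hypot(kx, ky)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1 + nu) / (E * k**3)
        gxx = pref * ((1 - nu) * k**2 + nu * ky**2)
        gyy = pref * ((1 - nu) * k**2 + nu * kx**2)
        gxy = -pref * nu * kx * ky
    zero = k == 0
    for g in (gxx, gyy, gxy):
        g[zero] = 0.0
    return gxx, gyy, gxy
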