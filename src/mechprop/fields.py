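"""Grid-based field containers shared across the pipeline.

Conventions
-----------
Arrays are indexed ``[iy, ix]`` with the physical y-axis pointing *up*:
row 0 is the bottom of the field of view.  Images loaded from disk (row 0
at the top) are flipped on load by the I/O helpers.  All angles are
measured counterclockwise from +x in [0°, 180°).

Units: lengths in µm, traction in Pa, 2D sheet stress in Pa·µm
(1 Pa·µm = 1e-6 N/m), forces in N, energies in J.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: 1 Pa · µm² in N (converts traction × cell area to force)
PA_UM2_TO_N = 1e-12
#: 1 Pa · µm³ in J (converts traction × displacement × cell area to energy)
PA_UM3_TO_J = 1e-18


@dataclass
class VectorField2D:
    """A 2D vector map (displacement in µm or traction in Pa) on a regular grid.

    Parameters
    ----------
    vx, vy : ndarray, shape (ny, nx)
        Cartesian components; ``vx[iy, ix]`` lives at
        ``origin + spacing * (ix, iy)``.
    grid_spacing_um : float
        Grid pitch in µm (isotropic).
    origin_um : tuple of float
        Physical (x, y) position of element ``[0, 0]``.
    kind : {"displacement", "traction"}
    """

    vx: np.ndarray
    vy: np.ndarray
    grid_spacing_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    kind: str = "displacement"

    def __post_init__(self):
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape:
            raise ValueError("vx and vy must have the same shape")
        if self.grid_spacing_um <= 0:
            raise ValueError("grid_spacing_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vx.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical x and y coordinate arrays, each shape (ny, nx)."""
        ny, nx = self.vx.shape
        x = self.origin_um[0] + self.grid_spacing_um * np.arange(nx)
        y = self.origin_um[1] + self.grid_spacing_um * np.arange(ny)
        return np.meshgrid(x, y)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    @property
    def dA_um2(self) -> float:
        return self.grid_spacing_um**2

    def net_force_N(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Vector sum of traction × cell area over the (optional) mask, in N."""
        if self.kind != "traction":
            raise ValueError("net force only defined for traction fields")
        m = np.ones(self.shape, bool) if mask is None else mask
        fx = self.vx[m].sum() * self.dA_um2 * PA_UM2_TO_N
        fy = self.vy[m].sum() * self.dA_um2 * PA_UM2_TO_N
        return np.array([fx, fy])

    def copy(self) -> "VectorField2D":
        return VectorField2D(self.vx.copy(), self.vy.copy(),
                             self.grid_spacing_um, self.origin_um, self.kind)

    # ----- I/O ---------------------------------------------------------
    def to_hdf5(self, path, **metadata) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("vx", data=self.vx)
            f.create_dataset("vy", data=self.vy)
            f.attrs["grid_spacing_um"] = self.grid_spacing_um
            f.attrs["origin_um"] = list(self.origin_um)
            f.attrs["kind"] = self.kind
            for k, v in metadata.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "VectorField2D":
        with h5py.File(path, "r") as f:
            return cls(f["vx"][()], f["vy"][()],
                       float(f.attrs["grid_spacing_um"]),
                       tuple(f.attrs["origin_um"]), str(f.attrs["kind"]))

    def to_csv(self, path, sidecar: dict | None = None) -> None:
        """Write (x, y, vx, vy) rows plus a JSON sidecar with grid metadata."""
        X, Y = self.coords()
        pd.DataFrame({"x_um": X.ravel(), "y_um": Y.ravel(),
                      "vx": self.vx.ravel(), "vy": self.vy.ravel()}).to_csv(
            path, index=False)
        meta = {"grid_spacing_um": self.grid_spacing_um,
                "origin_um": list(self.origin_um), "kind": self.kind}
        meta.update(sidecar or {})
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


@dataclass
class StressMap:
    """Per-pixel 2D sheet stress tensor (σxx, σyy, σxy) on a mask.

    Components are in Pa·µm (force per unit length of a cut through the
    sheet); they are zero outside ``mask``.
    """

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    mask: np.ndarray
    grid_spacing_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.sxx = np.asarray(self.sxx, dtype=float)
        self.syy = np.asarray(self.syy, dtype=float)
        self.sxy = np.asarray(self.sxy, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shapes = {self.sxx.shape, self.syy.shape, self.sxy.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("stress components and mask must share a shape")
        for comp in (self.sxx, self.syy, self.sxy):
            comp[~self.mask] = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.sxx.shape

    def copy(self) -> "StressMap":
        return StressMap(self.sxx.copy(), self.syy.copy(), self.sxy.copy(),
                         self.mask.copy(), self.grid_spacing_um, self.origin_um)

    def to_hdf5(self, path, **metadata) -> None:
        with h5py.File(path, "w") as f:
            for name in ("sxx", "syy", "sxy"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("mask", data=self.mask.astype(np.uint8))
            f.attrs["grid_spacing_um"] = self.grid_spacing_um
            f.attrs["origin_um"] = list(self.origin_um)
            for k, v in metadata.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "StressMap":
        with h5py.File(path, "r") as f:
            return cls(f["sxx"][()], f["syy"][()], f["sxy"][()],
                       f["mask"][()].astype(bool),
                       float(f.attrs["grid_spacing_um"]),
                       tuple(f.attrs["origin_um"]))


@dataclass
class ContourTrack:
    """Ordered per-frame point lists for one free stress fiber.

    ``points`` has shape (n_frames, n_points, 2) in µm; ``valid`` flags
    points that survived detection/filtering.  The two adhesion endpoints
    are fixed over time.
    """

    points: np.ndarray
    valid: np.ndarray
    endpoints: np.ndarray  # shape (2, 2): the two fixed adhesion points

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.endpoints = np.asarray(self.endpoints, dtype=float)
        if self.points.ndim == 2:  # single frame convenience
            self.points = self.points[None]
            self.valid = self.valid[None]
        if self.points.shape[:2] != self.valid.shape:
            raise ValueError("points and valid flags disagree in shape")
        if self.endpoints.shape != (2, 2):
            raise ValueError("need exactly two adhesion endpoints")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    def frame(self, k: int) -> np.ndarray:
        """Valid points of frame k, shape (m, 2)."""
        return self.points[k][self.valid[k]]

    def to_csv(self, path) -> None:
        rows = []
        for k in range(self.n_frames):
            for i in range(self.n_points):
                rows.append((k, i, self.points[k, i, 0], self.points[k, i, 1],
                             int(self.valid[k, i])))
        pd.DataFrame(rows, columns=["frame", "index", "x_um", "y_um", "valid"]
                     ).to_csv(path, index=False)
        meta = {"endpoints": self.endpoints.tolist()}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def from_csv(cls, path) -> "ContourTrack":
        df = pd.read_csv(path)
        n_f = int(df["frame"].max()) + 1
        n_p = int(df["index"].max()) + 1
        pts = np.zeros((n_f, n_p, 2))
        val = np.zeros((n_f, n_p), bool)
        pts[df["frame"], df["index"], 0] = df["x_um"]
        pts[df["frame"], df["index"], 1] = df["y_um"]
        val[df["frame"], df["index"]] = df["valid"].astype(bool)
        with open(str(path) + ".json") as fh:
            endpoints = np.array(json.load(fh)["endpoints"])
        return cls(pts, val, endpoints)


@dataclass
class CouplingCurve:
    """Model map from active-coupling degree ε ∈ [−1, 1] to the normalized
    right-half response."""

    epsilon_grid: np.ndarray
    normalized_right_response: np.ndarray
    channel: str = "sigma_xx"  # or sigma_yy / contour_strain
    abs_response: np.ndarray | None = None  # absolute-area convention, logged

    def __post_init__(self):
        self.epsilon_grid = np.asarray(self.epsilon_grid, dtype=float)
        self.normalized_right_response = np.asarray(
            self.normalized_right_response, dtype=float)
        if self.epsilon_grid.shape != self.normalized_right_response.shape:
            raise ValueError("grid and response must match")

    def is_monotone(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.diff(self.normalized_right_response) >= -tol))


@dataclass
class OrientationField:
    """Per-pixel structure-tensor orientation and coherency."""

    theta_deg: np.ndarray     # in [0, 180)
    coherency: np.ndarray     # in [0, 1]
    valid: np.ndarray         # gradient energy > 0 and inside border margin
    energy: np.ndarray = field(default=None)  # J11 + J22 (trace)

    def __post_init__(self):
        if self.theta_deg.shape != self.coherency.shape:
            raise ValueError("theta and coherency must match")
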