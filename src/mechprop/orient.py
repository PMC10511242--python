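"""Structural and mechanical polarization.

Structure-tensor orientation analysis of the actin network: for each
pixel the tensor J is built from Gaussian-derivative gradients averaged
over a Gaussian neighbourhood (waist 3 px by default),

    J11 = <Ix²>, J22 = <Iy²>, J12 = <Ix Iy>,

the local orientation θ (of the *structures*, i.e. the direction of
least intensity variation) follows tan(2θ) = 2 J12 / (J22 − J11), and
the coherency √((J22−J11)² + 4 J12²) / (J11+J22) grades how oriented the
neighbourhood is.  Pixels with coherency below a cutoff (0.4 by default)
are excluded, θmean is the circular mean of the surviving angles and the
polarization degree is <cos 2(θ − θmean)>.

Mechanical polarization is the stress anisotropy
(σxx − σyy) / (σxx + σyy) of the monolayer stress maps: +1 for a purely
horizontal stress state, 0 unpolarized, −1 purely vertical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import OrientationField, StressMap

__all__ = ["structure_tensor", "measure_actin_polarization",
           "mechanical_polarization", "actin_intensity_halves",
           "PolarizationResult"]


@dataclass
class PolarizationResult:
    theta_mean_deg: float
    structural_polarization: float
    axis_referenced_polarization: float  # same average referenced to the x-axis
    n_valid: int


def structure_tensor(image: np.ndarray, waist_px: float = 3.0,
                     deriv_sigma_px: float = 1.0) -> OrientationField:
    """Per-pixel orientation angle (degrees in [0, 180)) and coherency.

    Gradients are Gaussian derivatives at ``deriv_sigma_px`` (kept below
    the averaging waist so that a structureless image decorrelates inside
    the window and its coherency stays low); a border of 2×waist pixels
    is marked invalid, as are pixels with zero gradient energy (e.g. a
    constant image).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 7:
        raise ValueError("need a grayscale image of at least 7×7")
    Ix = ndimage.gaussian_filter(img, deriv_sigma_px, order=(0, 1))
    Iy = ndimage.gaussian_filter(img, deriv_sigma_px, order=(1, 0))
    J11 = ndimage.gaussian_filter(Ix * Ix, waist_px)
    J22 = ndimage.gaussian_filter(Iy * Iy, waist_px)
    J12 = ndimage.gaussian_filter(Ix * Iy, waist_px)

    energy = J11 + J22
    # orientation of structures = eigenvector of the smallest eigenvalue
    theta = 0.5 * np.arctan2(2 * J12, J22 - J11)
    theta_deg = np.rad2deg(theta) % 180.0
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.sqrt((J22 - J11) ** 2 + 4 * J12**2) / energy
    coherency = np.nan_to_num(coherency, nan=0.0)

    valid = energy > 1e-12 * max(energy.max(), 1e-300)
    border = int(np.ceil(2 * waist_px))
    if border > 0:
        valid[:border, :] = valid[-border:, :] = False
        valid[:, :border] = valid[:, -border:] = False
    return OrientationField(theta_deg, np.clip(coherency, 0, 1), valid, energy)


def measure_actin_polarization(field: OrientationField,
                               coherency_cutoff: float = 0.4,
                               roi_mask: np.ndarray | None = None
                               ) -> PolarizationResult:
    """Circular-mean orientation and polarization degree over the ROI.

    Angles with coherency below ``coherency_cutoff`` are excluded before
    averaging.  The polarization <cos 2(θ − θmean)> lies in (0, 1] by
    construction; the axis-referenced variant replaces θmean by 0° so
    that values are signed with respect to the x-axis (+1 horizontal,
    −1 vertical).
    """
    sel = field.valid & (field.coherency >= coherency_cutoff)
    if roi_mask is not None:
        sel = sel & roi_mask
    if not sel.any():
        raise ValueError("no valid pixels above the coherency cutoff")
    th = np.deg2rad(field.theta_deg[sel])
    c2, s2 = np.cos(2 * th).mean(), np.sin(2 * th).mean()
    theta_mean = 0.5 * np.arctan2(s2, c2)
    pol = float(np.mean(np.cos(2 * (th - theta_mean))))
    pol_axis = float(np.mean(np.cos(2 * th)))
    return PolarizationResult(np.rad2deg(theta_mean) % 180.0, pol, pol_axis,
                              int(sel.sum()))


def mechanical_polarization(stress: StressMap,
                            roi_mask: np.ndarray | None = None) -> float:
    """(σxx − σyy) / (σxx + σyy) from the mask-averaged normal stresses."""
    m = stress.mask if roi_mask is None else (stress.mask & roi_mask)
    if not m.any():
        raise ValueError("empty mask")
    sxx = stress.sxx[m].mean()
    syy = stress.syy[m].mean()
    denom = sxx + syy
    if denom == 0:
        raise ZeroDivisionError("zero mean normal stress")
    return float((sxx - syy) / denom)


def actin_intensity_halves(actin_stack: np.ndarray,
                           mask_stack: np.ndarray,
                           baseline_frames: int = 20,
                           erosion_um: float = 1.0,
                           pixel_size_um: float = 0.1
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized actin intensity time series of the left and right half.

    Masks are eroded by ``erosion_um`` to exclude the peripheral fibers,
    the cell is split at the vertical midline of each frame's mask, the
    intensity is summed per half and each series is normalized by its
    mean over the first ``baseline_frames`` frames.
    """
    stack = np.asarray(actin_stack, float)
    masks = np.asarray(mask_stack, bool)
    if masks.ndim == 2:
        masks = np.broadcast_to(masks, stack.shape)
    if stack.shape != masks.shape:
        raise ValueError("stack and masks must align")
    it = max(1, int(round(erosion_um / pixel_size_um)))
    left_s, right_s = [], []
    for frame, m in zip(stack, masks):
        m = ndimage.binary_erosion(m, iterations=it)
        if not m.any():
            raise ValueError("empty half-mask after erosion")
        cols = np.flatnonzero(m.any(axis=0))
        mid = (cols.min() + cols.max()) / 2.0
        ci = np.arange(m.shape[1])[None, :]
        left_s.append(frame[m & (ci <= mid)].sum())
        right_s.append(frame[m & (ci > mid)].sum())
    left = np.asarray(left_s)
    right = np.asarray(right_s)
    nb = min(baseline_frames, len(left))
    return left / left[:nb].mean(), right / right[:nb].mean()
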