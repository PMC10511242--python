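"""Active viscoelastic cell-sheet simulation and coupling estimation.

The cell (doublet, singlet or small tissue) is a plane-stress sheet of
Kelvin–Voigt elements carrying an isotropic active stress, attached to
an elastic foundation that represents the deformable substrate
(traction = Y·u).  Optogenetic activation raises the active stress in
the sender (left) region by Δσ and in the receiver (right) region by
ε·Δσ, where ε ∈ [−1, 1] is the degree of active coupling: 1 = receiver
contracts like the sender, 0 = passive receiver, −1 = equal-magnitude
relaxation.  A Maxwell variant (cell body fluidizes from activation
onward) reproduces the non-recovering singlet behaviour.

Coupling curves map ε to the normalized right-half response (signed
right-half area of the y-averaged after−before difference profile over
its total area); placing an experimental response on the inverse curve
estimates ε.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from . import fem
from .fields import CouplingCurve, StressMap, VectorField2D

__all__ = ["FemParams", "CouplingEstimate", "simulate_fem",
           "simulate_contour", "coupling_curve", "estimate_coupling",
           "attenuation_distance", "AttenuationResult",
           "normalized_right_response"]


@dataclass
class FemParams:
    """Constitutive and protocol parameters of the active sheet model.

    2D-sheet units: moduli and stresses in Pa·µm (modulus × thickness),
    viscosity in Pa·µm·min, foundation stiffness in Pa/µm (traction per
    unit displacement).  The defaults give a localization length
    √(E_s/Y) ≈ 15 µm, edge tractions of order 1 kPa with micron-scale
    substrate displacements (the scales observed on 20 kPa gels), and a
    ~20 % relative strain-energy rise under global activation.
    """

    sheet_modulus: float = 1.1e5          # E_s = E·h, Pa·µm
    sheet_poisson: float = 0.5
    viscosity: float = 2.2e5              # Kelvin–Voigt dashpot, Pa·µm·min
    substrate_stiffness: float = 500.0    # Y, Pa/µm
    baseline_active_stress: float = 15000.0  # Pa·µm
    activation_increment: float = 1400.0     # Δσ, Pa·µm
    activation_window: tuple = (20, 30)     # [start, end) in frames
    n_frames: int = 60
    dt_min: float = 1.0
    body_rheology: str = "kelvin_voigt"   # or "maxwell_after_activation"
    maxwell_time_min: float = 10.0
    mesh_resolution_um: float = 1.5
    activation_edge_um: float = 2.0       # smoothing of the sender boundary
    activation_offset_um: float = 0.0     # sender edge offset left of midline

    def __post_init__(self):
        if min(self.sheet_modulus, self.viscosity,
               self.substrate_stiffness) <= 0:
            raise ValueError("all moduli must be > 0")
        if not (0 <= self.activation_window[0] < self.activation_window[1]
                <= self.n_frames):
            raise ValueError("activation window outside the simulated span")
        if self.body_rheology not in ("kelvin_voigt",
                                      "maxwell_after_activation"):
            raise ValueError("unknown body rheology")

    def replace(self, **kw) -> "FemParams":
        return dataclasses.replace(self, **kw)


@dataclass
class CouplingEstimate:
    epsilon_hat: float
    channel: str
    experimental_normalized_response: float
    curve_used: CouplingCurve
    extrapolated: bool = False


@dataclass
class AttenuationResult:
    d_um: float
    beyond_domain: bool = False


# ---------------------------------------------------------------------------
# FEM time stepping
# ---------------------------------------------------------------------------

def _activation_weights(x: np.ndarray, mid: float, edge: float,
                        offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth sender (left) and receiver (right) membership of element
    centres; the two profiles tile the domain."""
    s = max(edge, 1e-6)
    left = 0.5 * (1 - np.tanh((x - (mid - offset)) / s))
    right = 0.5 * (1 + np.tanh((x - (mid + offset)) / s))
    return left, right


def simulate_fem(params: FemParams, geometry=None, epsilon: float = 0.0,
                 width_um: float | None = None,
                 height_um: float | None = None) -> dict:
    """Time series of the activated sheet: traction, stress and
    displacement stacks (one frame per simulated minute).

    ``geometry`` may be a :class:`~mechprop.synth.PatternGeometry`;
    alternatively pass the rectangle dimensions directly.
    """
    if not -1.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [-1, 1]")
    if geometry is not None:
        width_um = geometry.width_um
        height_um = geometry.height_um
    w, h = float(width_um), float(height_um)
    res = params.mesh_resolution_um
    nex = max(4, int(round(w / res)))
    ney = max(4, int(round(h / res)))
    hx = w / nex  # snap the element size to the geometry
    if abs(w / nex - h / ney) > 1e-9:
        ney = max(4, int(round(h / hx)))
    mesh = fem.QuadMesh.from_element_mask(np.ones((ney, nex), bool), hx,
                                          origin=(-w / 2, -h / 2))
    C = fem.plane_stress_C(params.sheet_modulus, params.sheet_poisson)
    Cv = fem.plane_stress_C(params.viscosity, params.sheet_poisson)
    K = fem.assemble_stiffness(mesh, C)
    Kv = fem.assemble_stiffness(mesh, Cv)
    Mf = params.substrate_stiffness * fem.lumped_foundation(mesh)
    dt = params.dt_min

    ctr = mesh.elem_centers()
    fL, fR = _activation_weights(ctr[:, 0], 0.0, params.activation_edge_um,
                                 params.activation_offset_um)

    def sigma_a(frame: int) -> np.ndarray:
        s = np.full(mesh.n_elems, params.baseline_active_stress)
        a0, a1 = params.activation_window
        if a0 <= frame < a1:
            s = s + params.activation_increment * (fL + epsilon * fR)
        return s

    maxwell = params.body_rheology == "maxwell_after_activation"
    act_start = params.activation_window[0]
    beta = 1.0 / (1.0 + dt / params.maxwell_time_min)

    kv_solver = spla.factorized((K + Mf + Kv / dt).tocsc())
    mx_solver = spla.factorized((beta * K + Mf).tocsc()) if maxwell else None

    # start from the Kelvin–Voigt steady state of the baseline stress
    s0 = np.full(mesh.n_elems, params.baseline_active_stress)
    f0 = fem.load_from_prestress(mesh, np.column_stack([s0, s0, 0 * s0]))
    u = spla.factorized((K + Mf).tocsc())(f0)
    eps_n = fem.element_strains(mesh, u)
    # total stored stress (elastic + active); the Maxwell variant relaxes
    # this whole quantity — fluidization of the actin network lets even
    # the actively generated stress decay as the network turns over
    sig_tot = eps_n @ C.T + np.column_stack([s0, s0, 0 * s0])
    sa_prev = s0

    node_shape = (ney + 1, nex + 1)
    tractions, stresses, displacements = [], [], []
    for frame in range(params.n_frames):
        sa = sigma_a(frame)
        svo = np.column_stack([sa, sa, np.zeros_like(sa)])
        f = fem.load_from_prestress(mesh, svo)
        dsa = np.column_stack([sa - sa_prev, sa - sa_prev,
                               np.zeros_like(sa)])
        if maxwell and frame >= act_start:
            # implicit Maxwell update of the TOTAL stress,
            # σ_{n+1} = β(σ_n + CΔε + Δσa·I): history and the activation
            # increment enter the load as an effective pre-stress
            pre = beta * (sig_tot - eps_n @ C.T + dsa)
            u_new = mx_solver(fem.load_from_prestress(mesh, pre))
            eps_new = fem.element_strains(mesh, u_new)
            sig_tot = beta * (sig_tot + (eps_new - eps_n) @ C.T + dsa)
            tot = sig_tot.copy()
        else:
            u_new = kv_solver(f + Kv.dot(u) / dt)
            eps_new = fem.element_strains(mesh, u_new)
            sig_pass = eps_new @ C.T + ((eps_new - eps_n) / dt) @ Cv.T
            sig_tot = eps_new @ C.T + svo
            tot = sig_pass + svo
        eps_n = eps_new
        u = u_new
        sa_prev = sa

        ux = u[0::2].reshape(node_shape)
        uy = u[1::2].reshape(node_shape)
        displacements.append(VectorField2D(ux.copy(), uy.copy(), hx,
                                           (-w / 2, -h / 2), "displacement"))
        tractions.append(VectorField2D(
            params.substrate_stiffness * ux,
            params.substrate_stiffness * uy, hx, (-w / 2, -h / 2), "traction"))
        smap = np.zeros((ney, nex, 3))
        smap.reshape(-1, 3)[mesh.elem_index.ravel()] = tot
        stresses.append(StressMap(
            smap[:, :, 0], smap[:, :, 1], smap[:, :, 2],
            np.ones((ney, nex), bool), hx,
            (-w / 2 + hx / 2, -h / 2 + hx / 2)))
    return {"traction": tractions, "stress": stresses,
            "displacement": displacements, "mesh": mesh, "params": params,
            "epsilon": epsilon}


# ---------------------------------------------------------------------------
# active contour simulation
# ---------------------------------------------------------------------------

def simulate_contour(epsilon: float = 0.0,
                     sigma0: float = 1.0,
                     line_tension: float = 30.0,
                     delta_rel: float = 0.3,
                     n_frames: int = 60,
                     activation_window: tuple[int, int] = (20, 30),
                     endpoints_x: tuple[float, float] = (-22.5, 22.5),
                     y_top: float = 22.5,
                     edge_um: float = 2.0,
                     n_nodes: int = 61,
                     tol_um: float = 1e-7,
                     max_iter: int = 8000) -> dict:
    """Quasi-static relaxation of the free fibers under an isotropic,
    position-dependent surface tension.

    During the activation window the surface tension of the left half is
    raised by ``delta_rel``·σ0 and of the right half by ε·``delta_rel``·σ0.
    The top fiber is relaxed explicitly; the bottom fiber is its mirror
    image, so the inter-fiber distance is d(x) = 2·y_top(x).

    Units are arbitrary but consistent (λ/σ0 is a length in µm; the
    default gives a baseline radius of curvature of 30 µm).
    """
    if not -1.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [-1, 1]")
    x0, x1 = endpoints_x
    lam = line_tension
    # initial shape: circular arc through the endpoints with R = λ/σ0
    R = lam / sigma0
    half = (x1 - x0) / 2.0
    if R < half:
        raise ValueError("line tension too small for a contour through "
                         "the endpoints")
    xc = (x0 + x1) / 2.0
    yc = y_top + np.sqrt(R**2 - half**2)
    phi0 = np.arctan2(y_top - yc, x0 - xc)
    phi1 = np.arctan2(y_top - yc, x1 - xc)
    tt = np.linspace(phi0, phi1, n_nodes)
    xs = xc + R * np.cos(tt)
    ys = yc + R * np.sin(tt)
    pts = np.column_stack([xs, ys])

    def sigma_of_x(x, frame):
        a0, a1 = activation_window
        if a0 <= frame < a1:
            s = max(edge_um, 1e-6)
            left = 0.5 * (1 - np.tanh((x - xc) / s))
            right = 1.0 - left
            return sigma0 * (1 + delta_rel * (left + epsilon * right))
        return np.full_like(x, sigma0)

    from scipy.linalg import solve_banded

    def relax(pts, sig_fun):
        """Semi-implicit overdamped relaxation: the (stiff) tension term
        is treated implicitly via a tridiagonal solve, the surface-
        tension force explicitly, so steps far beyond the explicit
        diffusion limit remain stable."""
        ds = np.linalg.norm(np.diff(pts, axis=0), axis=1).mean()
        dt_r = 5.0 * ds**2 / lam
        m = len(pts) - 2
        a = dt_r * lam / ds**2
        ab = np.zeros((3, m))
        ab[0, 1:] = -a
        ab[1, :] = 1 + 2 * a
        ab[2, :-1] = -a
        for it in range(max_iter):
            tan = pts[2:] - pts[:-2]
            tan /= np.linalg.norm(tan, axis=1, keepdims=True)
            # inward normal: tangent rotated −90°, which for the
            # left-to-right, bulge-down parametrization points toward the
            # cell body everywhere (including near the adhesions)
            nrm = np.column_stack([tan[:, 1], -tan[:, 0]])
            sig = sig_fun(pts[1:-1, 0])
            rhs = pts[1:-1] + dt_r * sig[:, None] * nrm
            rhs[0] += a * pts[0]
            rhs[-1] += a * pts[-1]
            new = np.column_stack([solve_banded((1, 1), ab, rhs[:, 0]),
                                   solve_banded((1, 1), ab, rhs[:, 1])])
            delta = np.abs(new - pts[1:-1]).max()
            pts[1:-1] = new
            if delta < tol_um:
                break
        else:
            raise RuntimeError("contour relaxation did not converge")
        return pts

    frames = []
    for frame in range(n_frames):
        pts = relax(pts, lambda x, f=frame: sigma_of_x(x, f))
        frames.append(pts.copy())

    grid = np.linspace(x0 + 1.0, x1 - 1.0, 80)
    dist = np.stack([2 * np.interp(grid, f[:, 0], f[:, 1]) for f in frames])
    return {"x_um": grid, "distance": dist, "shapes": frames,
            "epsilon": epsilon, "activation_window": activation_window}


# ---------------------------------------------------------------------------
# coupling curves and inversion
# ---------------------------------------------------------------------------

def normalized_right_response(x: np.ndarray, profile: np.ndarray,
                              mid: float = 0.0,
                              degenerate_tol: float = 0.05
                              ) -> tuple[float, float]:
    """Signed and absolute right-half area fractions of a response
    profile (trapezoid quadrature, exact split at ``mid``)."""
    x = np.asarray(x, float)
    profile = np.asarray(profile, float)
    if not (x[0] <= mid <= x[-1]):
        raise ValueError("mid outside the profile support")
    if mid not in x:  # insert an interpolated sample at the split
        pm = np.interp(mid, x, profile)
        i = np.searchsorted(x, mid)
        x = np.insert(x, i, mid)
        profile = np.insert(profile, i, pm)
    right_sel = x >= mid
    total = np.trapezoid(profile, x)
    right = np.trapezoid(profile[right_sel], x[right_sel])
    total_abs = np.trapezoid(np.abs(profile), x)
    right_abs = np.trapezoid(np.abs(profile[right_sel]), x[right_sel])
    if total_abs == 0 or abs(total) < degenerate_tol * total_abs:
        raise ZeroDivisionError("degenerate response: total area ~ 0")
    return right / total, right_abs / total_abs


def response_from_diff_map(diff: StressMap, channel: str = "sigma_yy",
                           mid: float | None = None) -> float:
    """Normalized right-half response of a stress-change map: y-average
    the selected component and take the signed right-half area fraction."""
    from .msm import y_averaged_profiles
    prof = y_averaged_profiles(diff)
    comp = prof["sxx"] if channel == "sigma_xx" else prof["syy"]
    x = prof["x_um"]
    ok = np.isfinite(comp)
    if mid is None:
        mid = (x[ok].min() + x[ok].max()) / 2.0
    signed, _ = normalized_right_response(x[ok], comp[ok], mid)
    return signed


def response_from_stress_maps(before: StressMap, after: StressMap,
                              channel: str = "sigma_yy",
                              mid: float | None = None) -> float:
    """Normalized right-half response computed exactly as for the model
    curves: after−before difference map → y-average → area fractions."""
    from .msm import stress_difference_map
    return response_from_diff_map(stress_difference_map(before, after),
                                  channel, mid)


def coupling_curve(channel: str = "sigma_yy",
                   epsilon_grid: np.ndarray | None = None,
                   params: FemParams | None = None,
                   geometry=None,
                   before_frames: int = 3, after_frames: int = 3,
                   contour_kwargs: dict | None = None,
                   response_source: str = "msm",
                   imaging_kwargs: dict | None = None) -> CouplingCurve:
    """Model coupling curve: normalized right-half response vs ε.

    ``channel`` selects the σxx or σyy FEM stress response or the
    contour-strain response.  Per ε the after−before difference map is
    y-averaged and the signed right-half area fraction is taken (the
    absolute-area convention is stored alongside in ``abs_response``).

    ``response_source`` controls how the model's stress maps are
    obtained: ``"msm"`` (default) pushes the model's traction through the
    same monolayer-stress-microscopy solve used for experimental data, so
    that curve and measurement are strictly comparable;
    ``"model_stress"`` uses the simulation's internal (active + passive)
    stress directly; ``"imaging"`` additionally sends the model traction
    through the noise-free bead-imaging/PIV/FTTC chain (pass imaging
    options, e.g. substrate, via ``imaging_kwargs``) so the curve shares
    the measurement operator of imaged data.
    """
    if epsilon_grid is None:
        epsilon_grid = np.linspace(-1, 1, 9)
    epsilon_grid = np.asarray(epsilon_grid, float)
    signed = np.empty_like(epsilon_grid)
    unsig = np.empty_like(epsilon_grid)

    for i, eps in enumerate(epsilon_grid):
        if channel in ("sigma_xx", "sigma_yy"):
            p = params or FemParams()
            if geometry is None:
                out = simulate_fem(p, epsilon=eps, width_um=45, height_um=45)
            else:
                out = simulate_fem(p, geometry, eps)
            a0, a1 = p.activation_window
            from .msm import msm_solve, stress_difference_map
            w2 = abs(out["traction"][0].origin_um[0])
            h2 = abs(out["traction"][0].origin_um[1])

            def avg_traction(frames):
                stack = out["traction"]
                f0 = stack[frames[0]]
                vx = np.mean([stack[k].vx for k in frames], axis=0)
                vy = np.mean([stack[k].vy for k in frames], axis=0)
                return VectorField2D(vx, vy, f0.grid_spacing_um,
                                     f0.origin_um, "traction")

            if response_source == "msm":
                def stress_of(frames):
                    tr = avg_traction(frames)
                    return msm_solve(tr, np.ones(tr.shape, bool))
                diff = stress_difference_map(
                    stress_of(range(a0 - before_frames, a0)),
                    stress_of(range(a1 - after_frames, a1)))
            elif response_source == "imaging":
                from .pipeline import measure_stress_change
                kw = dict(imaging_kwargs or {})
                substrate = kw.pop("substrate", None)
                if substrate is None:
                    from .boussinesq import SubstrateParams
                    substrate = SubstrateParams()
                diff = measure_stress_change(
                    avg_traction(range(a0 - before_frames, a0)),
                    avg_traction(range(a1 - after_frames, a1)),
                    substrate, (w2, h2), **kw)
            else:
                def avg(stack, frames):
                    s = stack[frames[0]].copy()
                    arrs = [stack[k] for k in frames]
                    s.sxx = np.mean([m.sxx for m in arrs], axis=0)
                    s.syy = np.mean([m.syy for m in arrs], axis=0)
                    s.sxy = np.mean([m.sxy for m in arrs], axis=0)
                    return s
                diff = stress_difference_map(
                    avg(out["stress"], range(a0 - before_frames, a0)),
                    avg(out["stress"], range(a1 - after_frames, a1)))
            try:
                signed[i] = response_from_diff_map(diff, channel, 0.0)
                from .msm import y_averaged_profiles
                prof = y_averaged_profiles(diff)
                comp = prof["sxx"] if channel == "sigma_xx" else prof["syy"]
                ok = np.isfinite(comp)
                _, unsig[i] = normalized_right_response(prof["x_um"][ok],
                                                        comp[ok], 0.0)
            except ZeroDivisionError:  # antisymmetric response at ε = −1
                signed[i] = unsig[i] = np.nan
        elif channel == "contour_strain":
            kw = dict(contour_kwargs or {})
            kw.setdefault("n_frames", 31)
            kw.setdefault("activation_window", (15, 31))
            out = simulate_contour(epsilon=eps, **kw)
            a0, a1 = out["activation_window"]
            d_before = out["distance"][max(a0 - 3, 0):a0].mean(axis=0)
            d_after = out["distance"][a1 - 3:a1].mean(axis=0)
            strain = d_after / d_before - 1.0
            try:
                signed[i], unsig[i] = normalized_right_response(
                    out["x_um"], strain, 0.0)
            except ZeroDivisionError:
                signed[i] = unsig[i] = np.nan
        else:
            raise ValueError(f"unknown channel {channel!r}")
    ok = np.isfinite(signed)
    return CouplingCurve(epsilon_grid[ok], signed[ok], channel,
                         abs_response=unsig[ok])


def estimate_coupling(curve: CouplingCurve,
                      before: StressMap | None = None,
                      after: StressMap | None = None,
                      response: float | None = None) -> CouplingEstimate:
    """Invert the coupling curve at an experimental response.

    Either pass before/after stress maps (the response is then computed
    with the same y-average + area normalization as the model) or the
    precomputed normalized response itself.  The curve must be monotone;
    out-of-range responses are clamped and flagged extrapolated.
    """
    if response is None:
        if before is None or after is None:
            raise ValueError("need either stress maps or a response value")
        response = response_from_stress_maps(before, after, curve.channel)
    r = curve.normalized_right_response
    if not curve.is_monotone():
        raise ValueError("coupling curve is not monotone; refusing to invert")
    extrapolated = not (r.min() <= response <= r.max())
    eps_hat = float(np.interp(response, r, curve.epsilon_grid))
    eps_hat = float(np.clip(eps_hat, curve.epsilon_grid.min(),
                            curve.epsilon_grid.max()))
    return CouplingEstimate(eps_hat, curve.channel, float(response), curve,
                            extrapolated)


def attenuation_distance(profile: np.ndarray, x_um: np.ndarray | None = None,
                         fraction: float = 0.2,
                         direction: int = +1) -> AttenuationResult:
    """Distance from the profile's maximum to the first crossing of
    ``fraction``·max along the propagation direction (sub-grid by linear
    interpolation)."""
    p = np.asarray(profile, float)
    x = np.arange(len(p), dtype=float) if x_um is None else np.asarray(x_um, float)
    i_max = int(np.argmax(p))
    target = fraction * p[i_max]
    idx = range(i_max, len(p)) if direction > 0 else range(i_max, -1, -1)
    prev_i = i_max
    for i in idx:
        if p[i] < target:
            x0_, x1_ = x[prev_i], x[i]
            p0_, p1_ = p[prev_i], p[i]
            xc = x0_ + (target - p0_) * (x1_ - x0_) / (p1_ - p0_)
            return AttenuationResult(abs(xc - x[i_max]), False)
        prev_i = i
    return AttenuationResult(abs(x[-1 if direction > 0 else 0] - x[i_max]),
                             True)
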