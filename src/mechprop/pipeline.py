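"""End-to-end orchestration: synthetic runs, exclusion rule, aggregation.

A run chains the modules in measurement order — synthetic activation
dataset (active FEM) → bead images → displacement recovery → FTTC → MSM
→ polarization / contour / coupling estimation — and produces one
:class:`CellRecord` per simulated cell plus summary tables.  Cells whose
baseline strain energy drifts are excluded exactly as in the
experimental protocol: an ordinary least-squares slope is fitted to the
relative strain-energy curve before activation and cells with
|slope| strictly above a threshold are dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activesim, contour, msm, orient, synth, tfm
from .boussinesq import SubstrateParams, forward_displacement

__all__ = ["RunConfig", "CellRecord", "exclude_unstable_baseline",
           "run_pipeline", "summarize"]


@dataclass
class RunConfig:
    """Configuration of a synthetic end-to-end run."""

    epsilon_true: tuple = (0.0, 0.5)       # one simulated cell per value
    schedule: tuple = (20, 10, 30)         # baseline / activation / post frames
    substrate: SubstrateParams = field(default_factory=SubstrateParams)
    piv: tfm.PivConfig = field(default_factory=tfm.PivConfig)
    fem_params: activesim.FemParams | None = None
    geometry: synth.PatternGeometry | None = None
    epsilon_grid: tuple = (-1.0, -0.5, 0.0, 0.25, 0.5, 0.75, 1.0)
    use_images: bool = False               # run the full bead-image chain
    pixel_size_um: float = 0.3
    bead_density_per_um2: float = 0.08
    noise_sigma: float = 0.0
    exclusion_threshold: float | None = None  # default: 10% drift over baseline
    seed: int = 0
    out_dir: str | None = None

    def content_hash(self) -> str:
        enc = json.dumps(dataclasses.asdict(self), sort_keys=True,
                         default=str).encode()
        return hashlib.sha256(enc).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        for key in ("input_files",):
            for p in raw.get(key, []):
                if not Path(p).exists():
                    raise FileNotFoundError(f"referenced file not found: {p}")
        raw.pop("input_files", None)
        if "substrate" in raw:
            raw["substrate"] = SubstrateParams(**raw["substrate"])
        if "piv" in raw:
            raw["piv"] = tfm.PivConfig(**raw["piv"])
        if "fem_params" in raw:
            raw["fem_params"] = activesim.FemParams(**raw["fem_params"])
        if "geometry" in raw:
            raw["geometry"] = synth.PatternGeometry(**raw["geometry"])
        return cls(**raw)


@dataclass
class CellRecord:
    """Aggregated per-cell quantities."""

    id: str
    epsilon_true: float
    spreading_area_um2: float
    strain_energy_J: np.ndarray
    relative_energy: np.ndarray
    sxx_mean: float
    syy_mean: float
    mechanical_polarization: float
    structural_polarization: float
    sigma_x: float
    sigma_y: float
    line_tension_N: float
    fa_N: float
    epsilon_hat_xx: float
    epsilon_hat_yy: float
    epsilon_hat_contour: float
    attenuation_d_um: float
    excluded: bool
    exclusion_slope: float
    error: str | None = None


def exclude_unstable_baseline(energy_series: np.ndarray,
                              threshold_slope: float,
                              baseline_frames: int | None = None
                              ) -> tuple[bool, float]:
    """OLS slope of the baseline of a relative strain-energy curve;
    excluded when |slope| is strictly above the threshold (per frame)."""
    e = np.asarray(energy_series, float)
    nb = len(e) if baseline_frames is None else baseline_frames
    if nb < 5:
        raise ValueError("need at least five baseline frames")
    t = np.arange(nb, dtype=float)
    slope = float(np.polyfit(t, e[:nb], 1)[0])
    return abs(slope) > threshold_slope, slope


def pad_field(field, margin_um: float = 12.0):
    """Embed a field in a zero margin (field of view larger than the
    cell, as in a real acquisition)."""
    h = field.grid_spacing_um
    n = int(round(margin_um / h))
    from .fields import VectorField2D
    return VectorField2D(np.pad(field.vx, n), np.pad(field.vy, n), h,
                         (field.origin_um[0] - n * h,
                          field.origin_um[1] - n * h), field.kind)


def frame_average(fields, frames):
    """Average a list of VectorField2D over the given frame indices."""
    from .fields import VectorField2D
    f0 = fields[frames[0]]
    return VectorField2D(np.mean([fields[k].vx for k in frames], axis=0),
                         np.mean([fields[k].vy for k in frames], axis=0),
                         f0.grid_spacing_um, f0.origin_um, f0.kind)


def measure_stress_change(t_before, t_after, substrate: SubstrateParams,
                          pattern_half_um: tuple[float, float],
                          piv: tfm.PivConfig | None = None,
                          pixel_size_um: float = 0.3,
                          bead_density_per_um2: float = 0.4,
                          psf_sigma_um: float = 0.45,
                          noise_sigma: float = 0.0,
                          margin_um: float = 12.0,
                          n_frame_pairs: int = 5,
                          seed: int = 0) -> msm.StressMap:
    """Photoactivation stress-change map through the full imaging chain.

    The before and after frames are rendered from the same bead field and
    the *incremental* displacement between them is measured by window
    correlation (per-bead re-localization errors would not cancel in a
    difference of two absolute recoveries, so SPT is bypassed here); the
    difference traction then feeds one MSM solve — all steps are linear.
    ``n_frame_pairs`` independent noise realizations of the two epochs
    are correlated and averaged, mirroring the frame averaging of the
    acquisition protocol (many baseline and activation frames).
    """
    piv = piv or tfm.PivConfig(spt_enabled=False)
    tb = pad_field(t_before, margin_um)
    ta = pad_field(t_after, margin_um)
    n = max(1, n_frame_pairs) if noise_sigma > 0 else 1
    disp = [forward_displacement(tb, substrate)] * n + \
           [forward_displacement(ta, substrate)] * n
    pair = synth.render_bead_images(disp, bead_density_per_um2,
                                    psf_sigma_um=psf_sigma_um,
                                    noise_sigma=noise_sigma, seed=seed,
                                    pixel_size_um=pixel_size_um)
    X, Y = tb.coords()
    extent = (X.min(), X.max(), Y.min(), Y.max())
    grids = []
    for k in range(n):
        sc = tfm.recover_displacement(pair.deformed[k], pair.deformed[n + k],
                                      piv, pixel_size_um,
                                      origin_um=tb.origin_um)
        sc = tfm.filter_outliers(sc, piv)
        grids.append(tfm.interpolate_to_grid(sc, piv.grid_spacing_um,
                                             extent=extent))
    grid = grids[0]
    if n > 1:
        grid.vx = np.mean([g.vx for g in grids], axis=0)
        grid.vy = np.mean([g.vy for g in grids], axis=0)
    dT = tfm.fttc(grid, substrate, reg_lambda=0.0)
    Xg, Yg = dT.coords()
    mask = (np.abs(Xg) <= pattern_half_um[0]) & \
           (np.abs(Yg) <= pattern_half_um[1])
    return msm.msm_solve(dT, mask)


def measure_absolute_traction(traction, substrate: SubstrateParams,
                              piv: tfm.PivConfig | None = None,
                              pixel_size_um: float = 0.3,
                              bead_density_per_um2: float = 0.4,
                              psf_sigma_um: float = 0.45,
                              noise_sigma: float = 0.0,
                              margin_um: float = 12.0,
                              seed: int = 0):
    """Absolute traction through the imaging chain (reference image vs
    stressed frame, PIV + single-particle tracking)."""
    piv = piv or tfm.PivConfig()
    tr = pad_field(traction, margin_um)
    disp = forward_displacement(tr, substrate)
    pair = synth.render_bead_images(disp, bead_density_per_um2,
                                    psf_sigma_um=psf_sigma_um,
                                    noise_sigma=noise_sigma, seed=seed,
                                    pixel_size_um=pixel_size_um)
    sc = tfm.recover_displacement(pair.reference, pair.deformed[0], piv,
                                  pixel_size_um, origin_um=tr.origin_um)
    sc = tfm.filter_outliers(sc, piv)
    X, Y = tr.coords()
    grid = tfm.interpolate_to_grid(sc, piv.grid_spacing_um,
                                   extent=(X.min(), X.max(),
                                           Y.min(), Y.max()))
    return tfm.fttc(grid, substrate, reg_lambda=0.0)


def run_pipeline(cfg: RunConfig) -> tuple[list[CellRecord], dict]:
    """Run the synthetic pipeline for every ``epsilon_true`` cell.

    Deterministic given ``cfg.seed``.  Per-cell failures are recorded in
    the record's ``error`` field and the run continues.
    """
    rng = np.random.default_rng(cfg.seed)
    geometry = cfg.geometry or synth.PatternGeometry()
    fem_params = cfg.fem_params or activesim.FemParams(
        n_frames=sum(cfg.schedule),
        activation_window=(cfg.schedule[0], cfg.schedule[0] + cfg.schedule[1]))
    thr = cfg.exclusion_threshold
    if thr is None:
        thr = 0.10 / cfg.schedule[0]  # >10% drift over the baseline window

    curve_source = "imaging" if cfg.use_images else "msm"
    imaging_kwargs = dict(substrate=cfg.substrate,
                          pixel_size_um=cfg.pixel_size_um,
                          bead_density_per_um2=cfg.bead_density_per_um2,
                          noise_sigma=0.0, seed=10_007)
    curves = {ch: activesim.coupling_curve(
        ch, np.asarray(cfg.epsilon_grid), params=fem_params,
        geometry=geometry, response_source=curve_source,
        imaging_kwargs=imaging_kwargs) for ch in ("sigma_xx", "sigma_yy")}
    curve_contour = activesim.coupling_curve(
        "contour_strain", np.asarray(cfg.epsilon_grid))

    half_w = geometry.width_um / 2
    records: list[CellRecord] = []
    report = {"config_hash": cfg.content_hash(), "seed": cfg.seed,
              "artifacts": [], "coupling_curves": {
                  ch: {"eps": c.epsilon_grid.tolist(),
                       "response": c.normalized_right_response.tolist()}
                  for ch, c in {**curves, "contour": curve_contour}.items()}}

    for j, eps_true in enumerate(cfg.epsilon_true):
        cell_id = f"cell{j:02d}_eps{eps_true:+.2f}"
        try:
            ds = synth.make_activation_dataset(
                fem_params, eps_true, cfg.schedule,
                seed=int(rng.integers(2**31 - 1)), geometry=geometry)
            a0 = cfg.schedule[0]
            a1 = a0 + cfg.schedule[1]
            energies = [tfm.strain_energy(t, d, time_index=k)
                        for k, (t, d) in enumerate(zip(ds["traction"],
                                                       ds["displacement"]))]
            e_J = np.array([e.strain_energy_J for e in energies])
            rel = tfm.relative_strain_energy(energies, baseline_frames=a0)
            excluded, slope = exclude_unstable_baseline(rel, thr, a0)

            cell_seed = int(rng.integers(2**31 - 1))
            tr_before = frame_average(ds["traction"], range(a0 - 3, a0))
            tr_after = frame_average(ds["traction"], range(a1 - 3, a1))
            half = (geometry.width_um / 2, geometry.height_um / 2)
            if cfg.use_images:
                tr_meas = measure_absolute_traction(
                    tr_before, cfg.substrate, cfg.piv, cfg.pixel_size_um,
                    cfg.bead_density_per_um2, noise_sigma=cfg.noise_sigma,
                    seed=cell_seed)
                Xg, Yg = tr_meas.coords()
                hull = (np.abs(Xg) <= half[0]) & (np.abs(Yg) <= half[1])
                s_before = msm.msm_solve(tr_meas, hull)
                dS = measure_stress_change(
                    tr_before, tr_after, cfg.substrate, half, cfg.piv
                    if not cfg.piv.spt_enabled else None,
                    pixel_size_um=cfg.pixel_size_um,
                    bead_density_per_um2=cfg.bead_density_per_um2,
                    noise_sigma=cfg.noise_sigma, seed=cell_seed)
            else:
                ones = np.ones(tr_before.shape, bool)
                s_before = msm.msm_solve(tr_before, ones)
                s_after = msm.msm_solve(tr_after, ones)
                dS = msm.stress_difference_map(s_before, s_after)

            means = msm.mean_stresses(s_before)
            mech_pol = orient.mechanical_polarization(s_before)
            tex = synth.make_oriented_texture(
                0.0 if mech_pol >= 0 else 90.0,
                min(abs(mech_pol) + 0.3, 1.0), size=128,
                seed=int(rng.integers(2**31 - 1)))
            st = orient.structure_tensor(tex)
            struct_pol = orient.measure_actin_polarization(
                st, coherency_cutoff=0.4).axis_referenced_polarization

            sigma_x = contour.measure_sigma_x(tr_before, (half_w, 0.0))
            sigma_y_true = sigma_x * max(means["syy_mean"], 1e-9) / \
                max(means["sxx_mean"], 1e-9)
            lam_true = max(sigma_x, sigma_y_true) * geometry.width_um * 0.6
            track = synth.make_contour_points(
                sigma_x, sigma_y_true, lam_true,
                [(-half_w, geometry.height_um / 2),
                 (half_w, geometry.height_um / 2)],
                noise_um=0.05, seed=int(rng.integers(2**31 - 1)))
            fit = contour.fit_contour_ellipse(track, sigma_x, track.endpoints)
            cf = contour.corner_force(tr_before,
                                      tuple(geometry.corners()[3]),
                                      peak_factor=1.2)
            lam_N, fa_N = contour.line_tension_and_fa(
                cf, contour_tangent=(0.0, 1.0))

            est = {}
            for ch in ("sigma_xx", "sigma_yy"):
                est[ch] = activesim.estimate_coupling(
                    curves[ch],
                    response=activesim.response_from_diff_map(dS, ch, 0.0)
                ).epsilon_hat
            d_b = ds["contour_distance"][a0 - 3:a0].mean(axis=0)
            d_a = ds["contour_distance"][a1 - 3:a1].mean(axis=0)
            strain_prof = d_a / d_b - 1.0
            resp_c, _ = activesim.normalized_right_response(
                ds["contour_x"], strain_prof, 0.0)
            est["contour"] = activesim.estimate_coupling(
                curve_contour, response=resp_c).epsilon_hat

            prof = msm.y_averaged_profiles(dS)
            ok = np.isfinite(prof["syy"])
            att = activesim.attenuation_distance(prof["syy"][ok],
                                                 prof["x_um"][ok])

            records.append(CellRecord(
                cell_id, eps_true, float(geometry.width_um *
                                         geometry.height_um),
                e_J, rel, means["sxx_mean"], means["syy_mean"], mech_pol,
                struct_pol, sigma_x, fit.sigma_y, lam_N, fa_N,
                est["sigma_xx"], est["sigma_yy"], est["contour"],
                att.d_um, excluded, slope))
        except Exception as exc:  # per-cell failure: record and continue
            records.append(CellRecord(
                cell_id, eps_true, np.nan, np.array([]), np.array([]),
                *([np.nan] * 12), True, np.nan, error=str(exc)))

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tab = summarize(records)["table"]
        tab_path = out / "cell_records.csv"
        tab.to_csv(tab_path, index=False)
        report["artifacts"].append(str(tab_path))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        report["artifacts"].append(str(out / "report.json"))
    return records, report


def summarize(records: list[CellRecord],
              groups: dict[str, list[CellRecord]] | None = None) -> dict:
    """Summary tables (medians, IQR) and an optional rank-based two-group
    test (Mann–Whitney–Wilcoxon U)."""
    if not records and not groups:
        raise ValueError("no records")
    cols = ["epsilon_true", "sxx_mean", "syy_mean", "mechanical_polarization",
            "structural_polarization", "sigma_x", "sigma_y", "line_tension_N",
            "fa_N", "epsilon_hat_xx", "epsilon_hat_yy", "epsilon_hat_contour",
            "attenuation_d_um", "excluded"]
    rows = [{c: getattr(r, c) for c in cols} | {"id": r.id} for r in records]
    table = pd.DataFrame(rows)
    num = table.select_dtypes(float)
    stats = pd.DataFrame({"median": num.median(), "q1": num.quantile(0.25),
                          "q3": num.quantile(0.75)})
    out = {"table": table, "stats": stats}
    if groups:
        if any(len(v) == 0 for v in groups.values()):
            raise ValueError("empty group")
        from scipy.stats import mannwhitneyu
        (n1, g1), (n2, g2) = list(groups.items())[:2]
        tests = {}
        for c in cols[:-1]:
            a = np.array([getattr(r, c) for r in g1], float)
            b = np.array([getattr(r, c) for r in g2], float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if len(a) and len(b):
                tests[c] = float(mannwhitneyu(a, b).pvalue)
        out["mannwhitney_p"] = tests
    return out
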