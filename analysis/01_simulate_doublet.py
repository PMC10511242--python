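#!/usr/bin/env python
"""Generate the synthetic reference doublet: corner-patch tractions on
the 45×45 µm H pattern, the elastic half-space displacement they
produce on a 20 kPa gel, and a noisy bead-image pair.

Writes results/analysis/01/: bead images (TIFF), ground-truth traction
and displacement (HDF5 + CSV), and a summary of the scales involved.
"""

from pathlib import Path

import numpy as np
import tifffile

from mechprop import synth
from mechprop.boussinesq import SubstrateParams, forward_displacement

OUT = Path("results/analysis/01")
OUT.mkdir(parents=True, exist_ok=True)
BIG = Path("scratch/analysis/01")  # binary artifacts (images, HDF5)
BIG.mkdir(parents=True, exist_ok=True)
SEED = 1

geo = synth.PatternGeometry(pixel_size_um=0.3, corner_patch_radius_um=4.0)
F = 100e-9  # 100 nN per corner, pointing inward (contractile doublet)
forces = [-c / np.hypot(*c) * F for c in geo.corners()]
traction = synth.make_pattern_traction(geo, forces, grid_spacing_um=0.3)
substrate = SubstrateParams()
disp = forward_displacement(traction, substrate)
pair = synth.render_bead_images(disp, density_per_um2=0.4,
                                psf_sigma_um=0.45, noise_sigma=0.1,
                                seed=SEED, pixel_size_um=0.3)

traction.to_hdf5(BIG / "traction_truth.h5", seed=SEED,
                 corner_force_N=F)
disp.to_hdf5(BIG / "displacement_truth.h5", seed=SEED)
traction.to_csv(BIG / "traction_truth.csv", sidecar={"seed": SEED})
tifffile.imwrite(BIG / "beads_reference.tif",
                 pair.reference[::-1].astype(np.float32))
tifffile.imwrite(BIG / "beads_deformed.tif",
                 pair.deformed[0][::-1].astype(np.float32))

summary = {
    "peak_traction_Pa": float(traction.magnitude().max()),
    "peak_displacement_um": float(disp.magnitude().max()),
    "n_beads": int(len(pair.bead_xy_um)),
    "seed": SEED,
}
import json
(OUT / "summary.json").write_text(json.dumps(summary, indent=1))
print("synthetic doublet on the H pattern (45 x 45 um, 20 kPa substrate)")
print(f"  field of view          : {traction.shape[1]} x {traction.shape[0]} px "
      f"at {traction.grid_spacing_um} um/px")
print(f"  peak traction          : {traction.magnitude().max():8.1f} Pa")
print(f"  net force (balance)    : {np.abs(traction.net_force_N()).max():8.2e} N")
print(f"  peak bead displacement : {disp.magnitude().max():8.3f} um")
print(f"  beads rendered         : {len(pair.bead_xy_um)} "
      f"(~{0.4 * 3.45**2:.1f} per final PIV window)")
print(f"summary in {OUT}/, images and fields in {BIG}/")
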