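"""Contrast collective motion between the mobile and damped ensembles.

Generates mode-plus-noise Cα trajectories for the wild-type ambient
condition (one strong collective bending mode) and the high-pressure
condition (noise-dominated), then compares RMSF, the first PCA mode and
the mean off-diagonal DCCM magnitude.  Strong correlated motion shows up
as a dominant first eigenvalue and widespread DCCM structure; its loss
under pressure (or mutation) reads out as both collapsing.
"""

import numpy as np

from baroshift import dccm, gen_mode_trajectory, load_preset, pca_modes, rmsf

for name in ("WT_AP", "WT_HP"):
    preset = load_preset(name)
    traj = gen_mode_trajectory(preset.mode_model(), 2000, seed=3)
    modes = pca_modes(traj)
    fluct = rmsf(traj)
    c = dccm(traj).to_numpy()
    off = ~np.eye(len(c), dtype=bool)
    frac1 = modes.eigenvalues[0] / modes.eigenvalues.sum()
    print(
        f"{name:8s} mean RMSF {fluct.rmsf.mean():.2f} A | "
        f"PC1 variance fraction {frac1:.2f} | "
        f"mean off-diagonal |DCCM| {np.abs(c[off]).mean():.3f}"
    )

print(
    "\nThe ambient wild type concentrates variance in one collective mode"
    "\nand shows broad motional correlations; under high pressure both"
    "\ncollapse toward the isotropic-noise floor."
)
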