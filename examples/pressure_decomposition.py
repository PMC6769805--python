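"""Separate a pressure titration into compression and transition patterns.

Simulates the default wild-type series (82 traceable residues, 10
pressures from 5 to 225 MPa), stacks it into the 164 x 10 shift matrix,
and runs the SVD decomposition.  The scores place each pressure point in
the PC1-PC2 plane; the initial score step defines the mechanical-
compression direction (i) and its in-plane orthogonal the thermodynamic-
transition direction (ii).  Back-projection gives per-residue shift
patterns for each effect.
"""

import numpy as np

from baroshift import decompose_pressure_series, gen_pressure_series, load_preset

preset = load_preset("WT_AP")
series = gen_pressure_series(
    preset.shift_model(), preset.pressures, noise_sd=preset.noise_sd_h, seed=42
)
decomp = decompose_pressure_series(series)

print(f"shift matrix: {2 * len(series.traceable_residues)} x {len(series)}")
print(f"components above tolerance: {decomp.n_significant}")
print(
    "variance explained by PC1/PC2: "
    f"{decomp.variance_explained[0]:.1%} / {decomp.variance_explained[1]:.1%}"
)

pat = decomp.pattern_ii
top = np.argsort(pat.delta_app)[-5:][::-1]
print("\nlargest transition-component shifts (residues most affected by the")
print("pressure-driven population shift):")
for i in top:
    print(
        f"  residue {pat.residue_ids[i]:3d}: "
        f"d_app = {pat.delta_app[i]:.4f} ppm "
        f"(dH {pat.delta_h[i]:+.4f}, dN {pat.delta_n[i]:+.4f})"
    )

truth = preset.shift_model()
cos = np.abs(
    np.corrcoef(pat.delta_h, truth.amp_h)[0, 1]
)
print(f"\ncorrelation of the recovered pattern with the planted transition")
print(f"amplitudes: r = {cos:.3f} — the decomposition isolates the right residues.")
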