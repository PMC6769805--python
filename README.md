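# baroshift

Analysis toolkit for characterizing how a point mutation or hydrostatic
pressure reshapes a protein's conformational ensemble, built around the
β2-microglobulin D76N problem: the amyloidogenic variant is crystallo-
graphically indistinguishable from the wild type, so the interesting
signal lives in stability, hidden excited states and dynamics rather
than in the average structure. The package provides the NMR- and
trajectory-side analyses for that kind of study, together with a
synthetic-data module that generates every input with known ground truth
so each analysis can be validated end to end.

Intended users are structural-bioinformatics and biomolecular-NMR people
who want these analyses as a tested, scriptable library rather than as
one-off notebook code.

## What it computes

**Pressure-series decomposition.** Amide shifts respond to pressure
through two superimposed effects: mechanical compression (roughly linear
in *p*) and a thermodynamic transition (a population shift between
subensembles, following f_E(p) = 1 / (1 + exp((ΔG₀ + pΔV)/RT)) ).
Per-residue ¹H and ¹⁵N shifts at P pressures are stacked into a 2R×P
matrix **X** (¹⁵N rows scaled by 1/5 to match the weighted shift metric
Δδ_app = (Δδ_H² + (Δδ_N/5)²)^½). After centering on the lowest-pressure
column, an SVD places each pressure point in PC space; the unit secant of
the first score step defines the compression direction (i), its in-plane
orthogonal the transition direction (ii), and back-projection through the
left singular vectors yields per-residue Δδ patterns for each effect.

**Trajectory dynamics.** Backbone (φ, ψ) distributions on a fixed 10×10
grid of 36° bins, compared between conditions by
χ² = (1/n²) ΣΣ (f₁(φᵢ, ψⱼ) − f₂(φᵢ, ψⱼ))², n = 10; per-residue RMSF
about an iteratively superposed mean; essential-dynamics PCA modes
(porcupine vectors); the dynamic cross-correlation matrix
C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩⟨|Δr_j|²⟩)^½; kernel-density segmentation
of a side-chain distance (e.g. D76 Oδ2 – K41 Nζ) into subensembles; and
subensemble-conditioned χ², which flags residues whose backbone
distribution depends on the local state of a distant contact.

**Relaxation and exchange.** Mono-exponential fits I(t) = A·e^(−kt) for
R₂ series (7 delays, 17.6–228.8 ms) and H/D-exchange decays; an
aggregation correction (ratio or rate-difference mode) for samples that
aggregate during exchange; intrinsic rates from the standard additive
nearest-neighbor sequence model; protection factors P = k_int / k_ex.

**pH unfolding.** Base-10 logistic fits
S(pH) = S_f + (S_u − S_f)/(1 + 10^(m·(pH − pH_mid))) of fluorescence
titrations, reporting the unfolding midpoint.

Synthetic study conditions ship as plain-text presets — `WT_AP`
(heterogeneous wild-type ensemble: 3 local subensembles, mobile
periphery), `D76N_AP` and `WT_HP` (converged, damped ensembles) — and
are the single source of ground truth for the recovery tests.

## Worked example

```sh
python examples/ph_unfolding.py
```

```
WT_AP    midpoint pH = 4.114 +/- 0.007 (preset ground truth 4.11)
D76N_AP  midpoint pH = 4.537 +/- 0.007 (preset ground truth 4.54)
```

The fitted midpoints are the pH of half-unfolding: the D76N variant loses
its fold ~0.4 pH units before the wild type, i.e. the mutation
destabilizes the native state.

```sh
python examples/pressure_decomposition.py
```

```
shift matrix: 164 x 10
components above tolerance: 9
variance explained by PC1/PC2: 99.5% / 0.5%
...
correlation of the recovered pattern with the planted transition
amplitudes: r = 0.995 — the decomposition isolates the right residues.
```

The 82 traceable residues at 10 pressures give a 164×10 matrix whose
centered SVD has 9 informative components; the transition-direction
pattern recovers the planted excited-state amplitudes almost exactly.

The other examples (`ensemble_coupling.py`, `trajectory_dynamics.py`,
`exchange_and_relaxation.py`, `assignment_tracking.py`) walk through the
remaining capabilities the same way. A thin CLI wraps the library for
shell use:

```sh
baroshift run --preset WT_AP --seed 1 --out run/
```

writes every stage's TSV outputs plus a checksummed run manifest.

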