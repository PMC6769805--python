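# Methods

This note documents the models behind `baroshift`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical conventions. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Two-state pressure response of chemical shifts

Each residue's amide shifts respond to pressure as

    δ(p) = δ0 + slope · p + f_E(p) · amp,
    f_E(p) = 1 / (1 + exp((ΔG0 + p·ΔV) / (R·T))),

independently for the ¹H and ¹⁵N axes. `slope` (ppm/MPa) is the
within-state compression response; `amp` (ppm) is the shift difference
between the ground and excited conformations; ΔG0 (J/mol) is the
excited-minus-ground free energy at zero pressure and ΔV (mL/mol) the
partial-molar-volume difference. Units cohere because
1 MPa·mL/mol = 1 J/mol; R = 8.314 J/(mol·K). With ΔV < 0 the excited
state is favored under pressure and f_E rises monotonically.

Preset thermodynamics (ΔG0 = 12 kJ/mol, ΔV = −100 mL/mol, T = 298.15 K)
put the transition midpoint near 120 MPa with a ~25 MPa width, so the
first pressure step (5 → 25 MPa) is dominated by compression — the
situation the direction-identification step of the decomposition
assumes. Per-residue slopes and amplitudes are Gaussian draws from the
preset's recorded parameter seed (slope sd 0.001 ppm/MPa ¹H, 0.004
ppm/MPa ¹⁵N; amplitude sd 0.10 ppm ¹H, 0.40 ppm ¹⁵N — magnitudes typical
of amide pressure responses). The amplitude vector is orthogonalized
against the slope vector in the weighted (N/5) row space: the
decomposition models compression and transition as independent
directions, so a ground-truth preset consistent with that model should
plant them orthogonally. Measurement noise defaults to 0.002 ppm (¹H)
and 5× that on ¹⁵N, the usual precision ratio of HSQC peak positions.
No noise magnitudes are reported for the original measurements; these
are conventions.

## Shift-matrix decomposition

The 2R×P matrix stacks rows residue-major (¹H then ¹⁵N per residue),
¹⁵N rows multiplied by 1/5 so Euclidean row-space distance equals the
weighted apparent shift difference Δδ_app = (Δδ_H² + (Δδ_N/5)²)^½. The
scale is recorded in metadata and undone for ppm reports.

Centering subtracts the lowest-pressure column by default, making the
origin of PC space the first spectrum (the convention in which pressure
titrations are plotted); column-mean centering is available. Scores are
singular-value-weighted right singular vectors, so each pressure point
is a point in PC space; each PC is oriented so the final pressure point
scores non-negatively (a reproducible sign convention). Singular values
above 1e-10 × the largest are counted as significant — after first-column
centering the numerically forced rank is P − 1, so a 10-pressure series
has at most 9 informative components.

The compression direction v_i is the unit secant from the first to the
second score point (a least-squares fit over the first m points is
available when the low-pressure region is noisy); the transition
direction v_ii is v_i rotated +90°, signed so the net first-to-last
displacement projects non-negatively onto it. Patterns are
U[:, :2]·v scaled by the range of score projections along v — the
amplitude actually traversed along that direction. This normalization is
a convention; only the pattern's shape (which residues, what relative
size) is identification-relevant.

## Peak tracking

Assignments are propagated pressure-step by pressure-step by nearest
neighbor under the weighted shift metric, with a 0.05 ppm default step
ceiling. Two candidates within the ceiling whose distances differ by
less than 10%, or one candidate claimed by two residues, raise an
ambiguity error naming the residues — overlapping peaks are a fact of
crowded spectra and silent tie-breaking would corrupt every downstream
per-residue quantity. Residues lost at any pressure are excluded
everywhere so the series stays rectangular (the "traceable" set). How
signals were traced in the original experiments is not described;
nearest-neighbor chaining is this package's convention.

## Latent-state ensembles

A small Markov chain (3 states for the wild-type presets, 1 for the
converged mutant/high-pressure presets; stay probability 0.98) drives
both the side-chain distance and the backbone dihedrals:

* distances are state-conditioned Gaussians truncated at zero (means
  3/6/10 Å, sd 0.4 Å for the wild type — well-separated interaction
  modes; single means 4.0–4.5 Å otherwise);
* dihedrals are von Mises pairs per residue (concentration κ = 8,
  roughly a 23° circular sd). Coupled residues (41, 55, 76 — the contact
  partners and one remote reporter) shift their means by ±60° across
  states; all other residues are state-independent, and the single-state
  presets sit exactly at the wild type's first-subensemble parameters
  because base parameters derive from the shared parameter seed.

Every generator draws from substreams keyed on (seed, stream, residue),
so adding residues never perturbs existing draws and runs are exactly
reproducible.

Segmentation estimates the distance density with a Gaussian KDE
(Silverman bandwidth), takes local maxima above 5% of the global peak as
modes, and cuts at the minima between them. Modes closer than about one
bandwidth merge — two states 1 sd apart are reported as one; this
resolution limit is inherent to density-based boundaries (the original
analysis drew such borders by eye). Subensembles with fewer than 50
frames mark their χ² pairs low-confidence.

## Dihedral χ²

Histograms use 10 bins of 36° per axis from −180°, half-open with the
top edge closed (+180° falls in the last bin, −180° in the first).
Frequencies are fractions, not counts, which makes χ² independent of
frame count in expectation; whether the original statistic used counts
or fractions is not stated, and fractions are the choice here. The
statistic is accumulated with compensated summation so it is independent
of traversal order, and the test oracle recomputes it with an exact
rational double loop.

## Mode trajectories, RMSF, PCA, DCCM

Synthetic trajectories are frames = mean + Σ a_k(t)·mode_k + noise with
Gaussian mode amplitudes — latent-mode constructs sufficient for
fluctuation analyses, not physically realistic conformations (no bonded
geometry, no excluded volume; the mean structure is an arbitrary smooth
curve). Preset modes are smoothed seed-derived vectors projected onto
the complement of the rigid-body subspace of the mean structure, since
an internal collective motion carries no net translation or rotation.
The mobile wild-type preset uses one collective mode (amplitude sd
3.0 Å against a 0.25 Å isotropic noise floor); the damped presets shrink
the mode to 0.5 Å, which removes most inter-residue correlation —
the contrast the DCCM comparison is meant to detect.

Analyses select Cα atoms, unweighted. Superposition is batched Kabsch
onto an iteratively refined mean (two mean refinements), and covariance
uses 1/F normalization so the eigenvalue sum equals Σ RMSF² exactly (a
tested identity). Exactly static trajectories short-circuit to zero RMSF
to avoid mean round-off. An `align=False` path skips superposition for
pre-aligned frames; note that constructed motions containing rigid-body
content change their correlation structure under superposition, which is
physics, not error.

## Relaxation and H/D exchange

Decay fits are A·e^(−kt) with the baseline fixed at zero (single-
exponential assumption), log-linear initialization, nonlinear
refinement, k ≥ 0, errors from the fit covariance. Per-residue failures
are flagged without aborting a profile; residues exchanging too fast to
observe are represented as missing, not zero. Prolines and the
N-terminus carry no amide and are excluded.

For aggregating samples two corrections are provided and the choice is
recorded in the output: `ratio` (k_obs/k_agg, the printed form of the
correction) and `difference` (max(k_obs − k_agg, 0), the additive-
channels expectation). The ratio of two rates is dimensionless, so the
two modes differ in meaning as well as value; neither is asserted as
the "true" reading and the default is `ratio`. The synthetic exchange
curves compose channels additively (k_obs = k_ex + k_agg).

Intrinsic rates use the standard additive nearest-neighbor model: acid-,
base- and water-catalyzed channels from poly-alanine reference rates
(log₁₀ k_A = 1.62, k_B = 10.05, k_W = −1.5 per minute, pK_D = 15.05),
corrected by per-residue log-factors for the residue's own side chain
and its predecessor, with Arrhenius scaling (14/17/19 kcal/mol,
reference 293 K). The parameter table ships as plain text in package
data; ionization-state variants (Asp/Glu/His) are collapsed to single
rows (ionized Asp/Glu, neutral His), a simplification acceptable at the
mildly acidic conditions modeled. An externally supplied k_int table
overrides prediction. Protection factors are P = k_int/k_ex — the ratio
is stated ambiguously in places in the literature; the field-standard
orientation (large P = protected) is used. k_ex = 0 reports P = ∞
(above detection).

## pH unfolding

The base-10 logistic in pH is chosen because acid unfolding is a
proton-linked equilibrium; the exact parameterization of the original
sigmoid fits is unstated. The midpoint initializes at the
half-amplitude crossing; a fitted midpoint outside the sampled range is
flagged rather than rejected; a flat signal raises. Preset midpoints are
4.11 (wild type) and 4.54 (D76N) with slope 2 pH⁻¹, baselines 1 → 3
fluorescence units (unfolding raises tryptophan fluorescence here), and
1% amplitude noise.

## Problem sizes and runtime

Default analysis sizes were chosen so every check runs comfortably on a
single CPU: pressure series use the full 82-residue, 10-pressure design;
ensemble analyses (segmentation, conditional χ²) use 50 000 frames,
where the null χ² level is ~1e-6 and the planted couplings sit three
orders of magnitude above it; coordinate-trajectory analyses use
2 000–10 000 frames. The full pipeline (`baroshift run`) completes in a
few seconds per condition.

## Known limitations

* Trajectories and dihedral series are statistical emulations; passing
  tests demonstrate correctness of the analyses, not realism of protein
  mechanics. In particular dihedral distributions are unimodal von Mises
  per state, while real Ramachandran densities are multimodal.
* Tracking assumes continuous, slow peak movement; fast exchange-regime
  jumps or peak crossings surface as ambiguity errors rather than being
  resolved.
* The decomposition's direction identification inherits the assumption
  that compression dominates the first pressure step and that the two
  effects are orthogonal in the PC plane; systems violating either need
  the least-squares initial-direction option or manual direction input.
* No thermodynamic fitting of ΔG/ΔV to score trajectories is attempted;
  the analysis stops at patterns, as the underlying procedure does.
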