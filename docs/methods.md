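# Methods

This document states the models implemented by `bindentropy`, the
conventions and default parameters, and the known limitations. All gas
constants are R = 8.314 J mol⁻¹ K⁻¹; natural logarithms are used
throughout; energies are reported in kJ/mol.

## Isothermal titration calorimetry (`bindentropy.itc`)

**Binding model.** Single-site mass action with a binding-competent
protein fraction n. With total protein M, total ligand X, and
dissociation constant K_d, the complex concentration is the closed-form
quadratic root

    [MX] = (α − √(α² − 4 n M X)) / 2,   α = n M + X + K_d,

clipped to [0, min(nM, X)]. A bisection solver of the same mass-action
equations (`complex_concentration_bisect`) is kept as an independent
reference path and is cross-checked in the tests.

**Injection bookkeeping.** Perfusion (displaced-volume) model of
MicroCal-type instruments: each injection of volume V_i displaces V_i
of well-mixed cell contents, so cell-resident species dilute by
(1 − V_i/V₀) per injection while titrant accumulates. The measured heat
of injection i is the displaced-volume differential

    q_i = Q_i − Q_{i−1} + (V_i/V₀)(Q_i + Q_{i−1})/2 + Q_off,

with cumulative heat content Q_i = V₀·ΔH·[MX]_i and a per-replicate
heat-of-mixing offset Q_off.

**Titration direction.** The scheme supports either species in the
syringe (`titrant="protein"` or `"ligand"`). The synthetic default
titrates 1 mM ligand into 100 µM protein (250 µL cell, 20 × 2 µL,
301.1 K), which produces a sigmoidal isotherm reaching ~97% saturation —
the regime in which (n, K_d, ΔH) are jointly identifiable. Titrating
the dilute species into the concentrated one instead yields a nearly
constant per-injection heat from which K_d cannot be recovered; the
generator therefore defaults to the identifiable direction.

**Global fit.** (n, ln K_d, ΔH) are shared across replicates; each
replicate carries its own offset. Weighted least squares
(`scipy.optimize.least_squares`, trust-region reflective, Jacobian
x-scaling, tolerances 1e-14) with uncertainties from the SVD-based
covariance of the Jacobian scaled by reduced χ²; the K_d uncertainty is
mapped from ln K_d by the delta method. Derived quantities:
ΔG° = RT ln K_d, −TΔS° = ΔG° − ΔH°, with independent-error propagation.

## Relaxation observables (`bindentropy.observables`)

Monoexponential decays I(t) = I₀ e^(−Rt) are fit by weighted
least squares (inverse-variance weights when per-point noise is given).
Rate uncertainties come from leave-one-out jackknife,
SD = √((m−1)/m Σ(θ_i − θ̄)²), or from Monte-Carlo refits of
noise-resampled data. Duplicate delays are retained as independent
points. Chemical-shift perturbations are the weighted Euclidean
combination √(Δδ_H² + (w·Δδ_X)²) with w = 0.16 for ¹⁵N and 0.25 for
methyl ¹³C.

## Model-free analysis (`bindentropy.modelfree`)

**Spectral density.** J(ω) carries the 2/5 prefactor (a rigid isotropic
rotor has J(0) = (2/5)τ_c). Overall rotation uses the Woessner
five-exponential correlation function for a fully anisotropic diffusion
tensor, which collapses to three exponentials for axial symmetry and
one for isotropy; internal motion multiplies each component
(Lipari–Szabo, with the extended two-timescale form for methyls).
Tensor anisotropy and rhombicity are ζ = 2D_zz/(D_xx + D_yy) and
η = 1.5(D_yy − D_xx)/[D_zz − (D_xx + D_yy)/2]; τ_c = 1/(6 D_iso).

**Rates.** Standard ¹⁵N dipolar + CSA expressions with r_NH = 1.02 Å
and Δσ_N = −172 ppm; exchange broadening R_ex is parameterized at a
reference field (11.7 T) and scales as B₀² (fast-exchange limit).
²H methyl rates R1(D_z), R(3D_z²−2), R2(D_+), R(D_+D_z + D_zD_+) are
quadrupolar linear combinations of J(0), J(ω_D), J(2ω_D) with a
quadrupolar coupling constant of 167 kHz; the fast three-fold methyl
rotation scales the symmetry-axis amplitudes by
P₂(cos β)² = 1/9 for ideal tetrahedral geometry. All of these constants
live in `SpinSystemConstants` and can be overridden.

**Model sets and selection.** Backbone: m1 {O²}, m2 {O², τ_e},
m3 {O², R_ex}, m4 {O², τ_e, R_ex}. Methyl: s2 {O², τ_f},
s3 {O², τ_f, τ_s}, s4 {O_f², O_s², τ_f, τ_s}. A larger nested model is
promoted only when an F-test on the χ² drop is significant at
α = 0.05; AIC selection is available as an alternative. Parameter
uncertainties are SDs over Monte-Carlo refits of noise-resampled rates.
Fits use multi-start bounded least squares with Jacobian x-scaling and
a relative finite-difference step of 1e-4 (the default √ε-relative
step underflows the numerical sensitivity of τ parameters of order
10 ps).

**Diffusion-tensor fitting.** Candidate tensors are scored with the
rigid local model (per-site O² only), under which all R1/R2 are linear
in O² and the weighted least-squares O² has a closed form; the rigid
rates are evaluated vectorized over sites. NOEs enter only through
rigid-site preselection (NOE > 0.65 at the highest measured field),
never the tensor χ², because they are O²-independent under the rigid
model. Isotropic fits optimize τ_c; axial fits (D_iso, ζ, axis
orientation); rhombic fits add η and the third Euler angle, with
multi-start Nelder–Mead over axis orientations. τ_c is initialized from
the median R2/R1 ratio at the highest field by bisection.
`alternating_tensor_refinement` then alternates tensor and per-site
fits, re-fitting the tensor on sites whose selected model carries no
exchange term — this removes the upward τ_c bias that R_ex-carrying
sites would otherwise cause. Nearly parallel NH vectors cannot
constrain an anisotropic tensor; such geometry triggers a warning and
an isotropic fallback.

## Conformational entropy from order parameters (`bindentropy.conf_entropy`)

Per-site entropy uses the diffusion-in-a-cone relationship
S(O²) = R ln[π(3 − √(1 + 8·O))] with O = √O², so a state difference is
the log-ratio sum

    ΔS_bb = R Σ_k ln[(3 − √(1 + 8 O_Ak)) / (3 − √(1 + 8 O_Bk))].

Methyl-bearing side chains scale each site's log-ratio by an empirical
residue-type coefficient C_m (Val/Thr 1.32, Ile/Leu 3.1, Met 2.31) that
maps methyl-axis entropy to full side-chain torsional entropy; Ala uses
the unscaled form. Results are reported as −TΔS at T = 301 K. O² ≥ 1 is
clipped to 1 − 10⁻⁶ with a warning (the cone expression diverges at
O² = 1). Sites missing in any complex are dropped listwise before
comparison. The three-complex statistic is
ΔP(A) = P(A) − (P(B) + P(C))/2, which sums to zero over the three
complexes and equals 1.5× the deviation from the three-way mean. Errors
are SDs over Monte-Carlo resampling of O² from the stated per-site sds.

## Radial shells (`bindentropy.shells`)

Residues are assigned to concentric shells by the minimum atom–atom
distance to any ligand atom (computed with gemmi from a PDB file;
waters ignored; no hydrogens added). Default edges: 1 Å shells from 2
to 9 Å, then 2 Å shells to 27 Å; membership is half-open [lo, hi).
Distances below 2 Å warn and join the innermost shell; distances beyond
27 Å are excluded. Shell means are referenced so the lowest shell mean
is zero; the cumulative curve at shell j's midpoint is the raw running
mean over all residues in shells 0..j. Empty shells are reported as
missing (NaN), not zero.

## Trajectory entropies (`bindentropy.traj_entropy`)

**Dihedral histograms.** S = −R Σ p ln p over 5° bins (72 per angle,
72 × 72 for joint φ/ψ), normalized against a free rotor and reported as
−T(S − R·dim·ln 72)/1000 kJ/mol at 301 K: a uniform distribution scores
0, a single occupied bin scores RT ln 72 = 10.70 kJ/mol per dimension.
Block averaging cuts the series into 5 ns windows (500 snapshots at the
default 10 ps sampling) and reports the mean with the SEM over blocks.
The histogram estimator carries the usual finite-sample bias (entropy
underestimated, hence −TΔS overestimated, by roughly
(n_bins − 1)/(2N ln) per block); with 500 snapshots in 72 bins this is
a few tenths of kJ/mol and is visible as the gap between block means
and the analytic large-sample truth.

**iRED order parameters.** The matrix M_ij = ⟨P₂(v_i · v_j)⟩ over
common snapshots is eigendecomposed and
O²_i = 1 − Σ_m λ_m e²_{mi} over internal modes, excluding the five
largest (overall-rotation) modes. The result is invariant under a
global rigid rotation of every snapshot. For N independent sites the
five excluded modes absorb, on average, a 5/N share of the internal
amplitude, so the estimator's finite-N expectation is
1 − (1 − O²)(1 − 5/N): a ~0.015 upward bias at N = 116 for O² = 0.65
that vanishes as N grows. The cone-model generator provides the
analytic truth O² = [cos θ(1 + cos θ)/2]².

## Synthetic data (`bindentropy.synthetic_data`)

All generators take an explicit seed and return data plus ground truth.
Defaults mirror the study conditions: duplicate ITC titrations with 2%
heat noise; 116 backbone amides (O² ~ Beta(28, 5.4), mean ≈ 0.84; 60%
rigid m1, 30% m2 with τ_e 20–60 ps, 10% m3 with R_ex 1–4 s⁻¹) at
11.7/14.1/18.8 T with 1.5% rate noise and 0.015 NOE noise, τ_c = 7 ns;
73 methyls with ²H rates at two fields; von Mises dihedral mixtures
with the analytic binned entropy as truth; uniform-in-cone bond
vectors; toy PDB complexes whose residues sit at prescribed minimum
ligand distances exactly (axis-aligned placement, which requires
prescriptions with at most three decimals so the PDB coordinate
precision represents them exactly).

## Limitations

- The ITC model is strictly single-site; multi-site or competitive
  schemes are out of scope.
- Exchange broadening is modelled only in the fast-exchange B₀² limit.
- The cone entropy expression diverges as O² → 1; clipped sites carry
  a warning and their entropy is a lower bound.
- The C_m side-chain coefficients are empirical calibrations; applying
  them to residue types outside the calibrated set raises an error
  rather than guessing.
- Solvation entropies, ligand entropies from MD, RMSF profiles, and
  ensemble-refinement statistics require original simulation or
  crystallographic data and are deliberately not computed here.
- Histogram and iRED estimators carry the finite-sample and finite-N
  biases quantified above; tests compare them against their known
  expectations rather than pretending they are unbiased.
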