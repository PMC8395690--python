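# bindentropy

Thermodynamic decomposition of protein–ligand binding from calorimetry,
NMR relaxation, and trajectory-style time series.

High-affinity binding is set by the balance of enthalpy and entropy, and
the entropic term itself decomposes into contributions that different
experiments can see: overall binding thermodynamics from isothermal
titration calorimetry (ITC), and conformational entropy of the protein
from NMR order parameters or molecular-dynamics-style dihedral and
bond-vector series. `bindentropy` implements that full chain for a
three-complex comparison study:

- **`itc`** — single-site Wiseman isotherm with perfusion (displaced
  volume) injection bookkeeping, global fitting of replicate
  thermograms with shared (n, K_d, ΔH°) and per-replicate heat offsets,
  and derivation of ΔG° = RT ln K_d and −TΔS° = ΔG° − ΔH°.
- **`observables`** — monoexponential relaxation-decay fitting with
  jackknife or Monte-Carlo errors, chemical-shift perturbations, and
  rate-table IO.
- **`modelfree`** — Lipari–Szabo spectral densities for isotropic,
  axially symmetric, and fully anisotropic rotational diffusion
  (Woessner multi-exponential), ¹⁵N R1/R2/NOE and ²H methyl quadrupolar
  rate expressions, nested model selection by F-test with Monte-Carlo
  errors, and global diffusion-tensor fitting from many sites' rates
  plus NH bond orientations.
- **`conf_entropy`** — conformational entropy from order parameters via
  the diffusion-in-a-cone relationship, residue-type coefficients that
  scale methyl-axis entropy to full side-chain entropy, and the
  three-complex comparison statistic ΔP(A) = P(A) − (P(B)+P(C))/2.
- **`shells`** — radial profiles of per-residue entropy in concentric
  shells around the bound ligand, with distances computed from a PDB
  structure.
- **`traj_entropy`** — dihedral-histogram entropies normalized to a
  free rotor, block averaging, and iRED (isotropic reorientational
  eigenmode dynamics) order parameters from bond-vector series.
- **`synthetic_data`** — seeded generators with known ground truth for
  every input the pipeline consumes, used by the test and acceptance
  suites.

## Worked example

Fit duplicate synthetic ITC titrations (2 µL injections of 1 mM ligand
into 100 µM protein, 2% heat noise) and derive the thermodynamics:

```python
import numpy as np
from bindentropy import itc, conf_entropy, synthetic_data as syn

replicates, truth = syn.gen_itc(seed=7)
result = itc.fit_global(replicates)
s = result.summary
print(f"n    = {result.params.n:.3f} +/- {result.sd_n:.3f}")
print(f"Kd   = {result.params.Kd * 1e6:.2f} +/- {result.sd_Kd * 1e6:.2f} uM")
print(f"dG   = {s.dG:.1f} +/- {s.sd_dG:.1f} kJ/mol")
print(f"dH   = {s.dH:.1f} +/- {s.sd_dH:.1f} kJ/mol")
print(f"-TdS = {s.mTdS:.1f} +/- {s.sd_mTdS:.1f} kJ/mol")
```

```
n    = 0.948 +/- 0.003
Kd   = 2.00 +/- 0.08 uM
dG   = -32.9 +/- 0.1 kJ/mol
dH   = -50.4 +/- 0.4 kJ/mol
-TdS = 17.5 +/- 0.4 kJ/mol
```

Compare the conformational entropy of three complexes from their
order-parameter tables (here generated with known per-complex offsets;
`bb` is backbone, `sc` is methyl-bearing side chains, values are
−TΔΔS in kJ/mol with Monte-Carlo errors):

```python
tables = syn.gen_order_parameter_tables(
    seed=11, shift={"M": 0.0, "P": 0.01, "O": -0.03})
report = conf_entropy.entropy_report(
    tables, n_mc=200, rng=np.random.default_rng(0))
print(report.to_frame().round(1))
```

```
     bb  bb_sd    sc  sc_sd  bb_plus_sc  bb_plus_sc_sd
M  17.7    3.7  16.3    7.7        34.0            8.6
P  52.0    5.7  44.8    9.4        96.8           11.0
O -69.8    3.4 -61.1    7.2      -130.9            8.0
```

The deltas sum to zero by construction; the complex whose order
parameters were shifted down (`O`, more flexible) carries the negative
−TΔΔS, i.e. a favourable conformational-entropy contribution.

Per-site model-free analysis of a synthetic 116-residue protein
(¹⁵N R1/R2/NOE at 11.7/14.1/18.8 T, τ_c = 7 ns):

```python
from bindentropy import modelfree as mf

records, truths, tensor, orientations = syn.gen_relaxation(seed=42)
site = "res17"
fit = mf.fit_site(records[site], tensor, orientations[site],
                  n_mc=200, rng=np.random.default_rng(0))
print(f"site {site}: model {fit.params.model_id}, "
      f"O2 = {fit.params.order_parameter:.3f} +/- {fit.sds['O2']:.3f} "
      f"(truth {truths[site].order_parameter:.3f}, {truths[site].model_id})")
```

```
site res17: model m1, O2 = 0.849 +/- 0.005 (truth 0.843, m1)
```

A `bindentropy` command-line interface wraps the same operations
(`fit-decays`, `itc-fit`, `modelfree`, `entropy`, `shells`,
`traj-entropy`, `synth`); run `bindentropy --help` for usage.

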