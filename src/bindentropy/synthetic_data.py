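"""Seeded generators for every input the pipeline consumes.

Each generator takes an explicit seed (or Generator), draws from its own
pseudo-random stream, and returns the generated data together with the
ground truth used to produce it, so recovery tests and the acceptance
study can compare fitted against true parameters without external data.

Defaults mirror the study conditions of the galectin-3C work: duplicate
ITC titrations reaching ~97% saturation with ~2% heat noise; 116
backbone amides at 11.7/14.1/18.8 T with 1-2% rate noise and a ~7 ns
rotational correlation time; 73 methyl groups with 2H rates at two
fields; 100 ns of 10 ps-sampled trajectory data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import vonmises

from . import itc as itc_mod
from . import modelfree as mf
from .conf_entropy import OrderParameterRecord, OrderParameterTable
from .observables import RateRecord
from .traj_entropy import (BondVectorSeries, DihedralSeries, R_GAS,
                           cone_order_parameter)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# ITC

#: Default scheme reproducing a sigmoidal low-micromolar isotherm that
#: reaches ~97% saturation at the final injection: 1 mM ligand titrated
#: into 100 uM protein in a 250 uL cell, 20 x 2 uL injections at 301.1 K.
DEFAULT_ITC_SCHEME = itc_mod.TitrationScheme(
    V0=250e-6,
    injection_volumes=(2e-6,) * 20,
    syringe_conc=1000e-6,
    cell_conc=100e-6,
    temperature=301.1,
    titrant="ligand",
)

DEFAULT_ITC_TRUTH = itc_mod.BindingParams(
    n=0.95, Kd=2.0e-6, dH=-50.4e3, Q_off=-2e-6)


def gen_itc(
    seed,
    truth: itc_mod.BindingParams = DEFAULT_ITC_TRUTH,
    scheme: itc_mod.TitrationScheme = DEFAULT_ITC_SCHEME,
    noise_frac: float = 0.02,
    n_replicates: int = 2,
) -> tuple[list[itc_mod.Thermogram], itc_mod.BindingParams]:
    """Replicate thermograms with Gaussian heat noise plus the truth.

    ``noise_frac`` scales the per-injection noise SD to the mean absolute
    model heat (2% by default, matching typical integrated-peak errors).
    """
    rng = _rng(seed)
    model = itc_mod.predicted_heats(scheme, truth)
    sd = noise_frac * float(np.mean(np.abs(model - truth.Q_off)))
    reps = []
    for _ in range(n_replicates):
        q = model + (rng.normal(0.0, sd, model.size) if sd > 0 else 0.0)
        reps.append(itc_mod.Thermogram(
            heats=q, scheme=scheme,
            sd=np.full(model.size, sd) if sd > 0 else None))
    return reps, truth


# ---------------------------------------------------------------------------
# relaxation

DEFAULT_FIELDS_15N = (11.7, 14.1, 18.8)  # T
DEFAULT_FIELDS_2H = (11.7, 14.1)  # T


def sample_backbone_truth(
    rng: np.random.Generator,
    n_sites: int = 116,
    frac_m1: float = 0.6,
    frac_m2: float = 0.3,
) -> dict[str, mf.ModelFreeParams]:
    """Per-site model-free truths with a Beta-shaped O2 distribution
    centred near the observed <O2> ~ 0.84; the remaining fraction of
    sites carries exchange broadening (m3)."""
    truths = {}
    for i in range(n_sites):
        o2 = float(np.clip(rng.beta(28.0, 5.4), 0.02, 0.98))
        u = rng.random()
        if u < frac_m1:
            p = mf.ModelFreeParams(model_id="m1", O2=o2)
        elif u < frac_m1 + frac_m2:
            p = mf.ModelFreeParams(model_id="m2", O2=o2,
                                   tau_e=float(rng.uniform(20e-12, 60e-12)))
        else:
            p = mf.ModelFreeParams(model_id="m3", O2=o2,
                                   Rex=float(rng.uniform(1.0, 4.0)))
        truths[f"res{i + 1}"] = p
    return truths


def gen_relaxation(
    seed,
    truths: Mapping[str, mf.ModelFreeParams] | None = None,
    tensor: mf.DiffusionTensor | None = None,
    orientations: Mapping[str, np.ndarray] | None = None,
    fields: Sequence[float] = DEFAULT_FIELDS_15N,
    noise_frac: float = 0.015,
    noe_sd: float = 0.015,
    constants: mf.SpinSystemConstants = mf.DEFAULT_CONSTANTS,
) -> tuple[dict[str, list[RateRecord]], dict[str, mf.ModelFreeParams],
           mf.DiffusionTensor, dict[str, np.ndarray]]:
    """15N R1/R2/NOE tables from known model-free parameters plus noise.

    Returns (records_by_site, truths, tensor, NH orientations). Rates get
    relative Gaussian noise of ``noise_frac``; NOEs get absolute noise of
    ``noe_sd`` (ratios have roughly constant error).
    """
    rng = _rng(seed)
    if tensor is None:
        tensor = mf.DiffusionTensor.isotropic(7.0e-9)
    if truths is None:
        truths = sample_backbone_truth(rng)
    if orientations is None:
        orientations = {s: random_unit_vector(rng) for s in truths}
    records: dict[str, list[RateRecord]] = {}
    for site, p in truths.items():
        v = orientations[site]
        recs = []
        for b0 in fields:
            r1, r2, noe = mf.rates_15N(p, tensor, v, b0, constants)
            for rtype, val in (("R1", r1), ("R2", r2), ("NOE", noe)):
                sd = noe_sd if rtype == "NOE" else noise_frac * abs(val)
                obs = val + rng.normal(0.0, sd) if sd > 0 else val
                recs.append(RateRecord(site, b0, rtype, obs, max(sd, 1e-12)))
        records[site] = recs
    return records, dict(truths), tensor, dict(orientations)


def sample_methyl_truth(
    rng: np.random.Generator, n_sites: int = 73,
) -> dict[str, mf.ModelFreeParams]:
    truths = {}
    for i in range(n_sites):
        o2 = float(np.clip(rng.beta(6.0, 2.8), 0.02, 0.98))
        truths[f"met{i + 1}"] = mf.ModelFreeParams(
            model_id="s2", O2=o2, tau_f=float(rng.uniform(10e-12, 60e-12)))
    return truths


def gen_methyl_relaxation(
    seed,
    truths: Mapping[str, mf.ModelFreeParams] | None = None,
    tensor: mf.DiffusionTensor | None = None,
    fields: Sequence[float] = DEFAULT_FIELDS_2H,
    noise_frac: float = 0.02,
    constants: mf.SpinSystemConstants = mf.DEFAULT_CONSTANTS,
) -> tuple[dict[str, list[RateRecord]], dict[str, mf.ModelFreeParams],
           mf.DiffusionTensor]:
    """2H methyl rate tables (four rates per field) with relative noise."""
    rng = _rng(seed)
    if tensor is None:
        tensor = mf.DiffusionTensor.isotropic(7.0e-9)
    if truths is None:
        truths = sample_methyl_truth(rng)
    names = ("R1Dz", "R3Dz2", "R2Dplus", "RDplusDz")
    records: dict[str, list[RateRecord]] = {}
    for site, p in truths.items():
        recs = []
        for b0 in fields:
            rates = mf.rates_2H_methyl(p, tensor, b0, constants)
            for rtype, val in zip(names, rates):
                sd = noise_frac * abs(val)
                obs = val + rng.normal(0.0, sd) if sd > 0 else val
                recs.append(RateRecord(site, b0, rtype, obs, max(sd, 1e-12)))
        records[site] = recs
    return records, dict(truths), tensor


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# order-parameter tables

def gen_order_parameter_tables(
    seed,
    labels: Sequence[str] = ("M", "P", "O"),
    n_backbone: int = 116,
    n_methyl: int = 73,
    sd_backbone: float = 0.01,
    sd_methyl: float = 0.02,
    shift: Mapping[str, float] | None = None,
) -> dict[str, OrderParameterTable]:
    """Three-complex O2 tables with a known per-complex O2 offset.

    ``shift`` adds a constant to each complex's O2 values (clipped to
    [0.02, 0.995]) so intercomplex entropy differences have a known sign.
    """
    rng = _rng(seed)
    shift = shift or {lab: 0.0 for lab in labels}
    methyl_types = ["VAL", "THR", "ILE", "LEU", "MET", "ALA"]
    base_bb = np.clip(rng.beta(28.0, 5.4, n_backbone), 0.05, 0.97)
    base_me = np.clip(rng.beta(6.0, 2.8, n_methyl), 0.05, 0.95)
    me_types = [methyl_types[int(rng.integers(len(methyl_types)))]
                for _ in range(n_methyl)]
    out = {}
    for lab in labels:
        recs = []
        for i in range(n_backbone):
            o2 = float(np.clip(base_bb[i] + shift[lab], 0.02, 0.995))
            recs.append(OrderParameterRecord(i + 113, "ALA", "backbone",
                                             o2, sd_backbone))
        for i in range(n_methyl):
            o2 = float(np.clip(base_me[i] + shift[lab], 0.02, 0.995))
            recs.append(OrderParameterRecord(i + 301, me_types[i], "methyl",
                                             o2, sd_methyl))
        out[lab] = OrderParameterTable(recs)
    return out


# ---------------------------------------------------------------------------
# trajectory-style series

def gen_dihedral(
    seed,
    n_snapshots: int = 100_000,
    means_deg: Sequence[float] = (-60.0, 60.0),
    kappas: Sequence[float] = (8.0, 8.0),
    weights: Sequence[float] | None = None,
    timestep: float = 10.0,
    site_id: str = "chi1",
    bin_width: float = 5.0,
) -> tuple[DihedralSeries, float]:
    """1D von Mises mixture samples plus the analytic binned entropy truth.

    The truth integrates the mixture density over the same 5-degree bins
    and evaluates -R sum p ln p, i.e. exactly what the histogram
    estimator converges to.
    """
    rng = _rng(seed)
    if weights is None:
        weights = np.full(len(means_deg), 1.0 / len(means_deg))
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    comp = rng.choice(len(weights), size=n_snapshots, p=weights)
    angles = np.empty(n_snapshots)
    for j, (mu, kap) in enumerate(zip(means_deg, kappas)):
        m = comp == j
        if kap <= 0:
            angles[m] = rng.uniform(-180.0, 180.0, m.sum())
        else:
            angles[m] = np.rad2deg(
                vonmises.rvs(kap, loc=np.deg2rad(mu), size=m.sum(),
                             random_state=rng))
    angles = (angles + 180.0) % 360.0 - 180.0
    truth = analytic_binned_entropy(means_deg, kappas, weights, bin_width)
    return DihedralSeries(site_id, angles, timestep), truth


def analytic_binned_entropy(
    means_deg: Sequence[float], kappas: Sequence[float],
    weights: Sequence[float], bin_width: float = 5.0,
) -> float:
    """-R sum p ln p of a von Mises mixture integrated over the bins."""
    n_bins = int(round(360.0 / bin_width))
    edges = np.deg2rad(np.linspace(-180.0, 180.0, n_bins + 1))
    p = np.zeros(n_bins)
    for mu, kap, w in zip(np.deg2rad(means_deg), kappas, weights):
        if kap <= 0:
            p += w / n_bins
        else:
            cdf = vonmises.cdf(edges, kap, loc=mu)
            p += w * np.diff(cdf)
    p = p / p.sum()
    p = p[p > 0]
    return float(-R_GAS * np.sum(p * np.log(p)))


def gen_bond_vectors(
    seed,
    cone_semi_angles_deg: Mapping[str, float],
    n_snapshots: int = 2000,
    timestep: float = 10.0,
) -> tuple[list[BondVectorSeries], dict[str, float]]:
    """Per-site cone-model bond vectors plus analytic O2 truths.

    Vectors are drawn uniformly (in solid angle) within a cone of the
    given semi-angle about a random site-specific axis; the analytic
    order parameter of that motion is [cos(t)(1 + cos(t))/2]^2.
    """
    rng = _rng(seed)
    series = []
    truth = {}
    for site, theta in cone_semi_angles_deg.items():
        axis = random_unit_vector(rng)
        # orthonormal frame around the axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(axis @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(axis, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        cmin = np.cos(np.deg2rad(theta))
        c = rng.uniform(cmin, 1.0, n_snapshots)
        s = np.sqrt(1.0 - c**2)
        phi = rng.uniform(0.0, 2 * np.pi, n_snapshots)
        vecs = (c[:, None] * axis[None, :]
                + s[:, None] * (np.cos(phi)[:, None] * e1[None, :]
                                + np.sin(phi)[:, None] * e2[None, :]))
        series.append(BondVectorSeries(site, vecs, timestep))
        truth[site] = cone_order_parameter(theta)
    return series, truth


# ---------------------------------------------------------------------------
# toy complexes

_AXES = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                  [-1, 0, 0], [0, -1, 0], [0, 0, -1]], dtype=float)


def _pdb_line(record: str, serial: int, name: str, resname: str,
              chain: str, resnum: int, pos: np.ndarray,
              element: str) -> str:
    return (f"{record:<6}{serial:>5} {name:<4} {resname:>3} {chain:1}"
            f"{resnum:>4}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {element:>2}")


def gen_toy_complex(
    prescribed_distances: Mapping[int, float],
    chain_id: str = "A",
    ligand_name: str = "LIG",
) -> str:
    """PDB text: a one-atom ligand at the origin plus small residue clusters.

    Each residue is a three-atom cluster placed along a coordinate axis so
    its minimum ligand distance equals the prescription exactly at the
    PDB's 1e-3 A coordinate precision (prescribe distances with at most
    three decimals). Residues cycle through the six axis directions.
    """
    lines = ["HETATM" + _pdb_line("", 1, "CL1", ligand_name, "L", 1,
                                  np.zeros(3), "C")[6:]]
    serial = 2
    for i, resnum in enumerate(sorted(prescribed_distances)):
        d = prescribed_distances[resnum]
        if round(d, 3) != d:
            raise ValueError(
                f"residue {resnum}: distance {d} has more than 3 decimals "
                "and cannot be represented exactly in PDB coordinates")
        u = _AXES[i % 6]
        for name, extra, elem in (("N", 0.0, "N"), ("CA", 0.8, "C"),
                                  ("C", 1.6, "C")):
            lines.append(_pdb_line("ATOM", serial, name, "ALA", chain_id,
                                   resnum, u * (d + extra), elem))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
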