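"""Dihedral-histogram entropy and iRED order parameters from trajectories.

Entropies come from empirical probability distributions over 5-degree
dihedral bins (72 per angle; 72x72 for joint phi/psi distributions),
S = -R sum p ln p, normalized to a free rotor (the uniform distribution
over the same bins) and reported as -T*dS at 301 K, so a fully
disordered angle scores 0 and increasing order scores positive values.
Block averaging over 5 ns windows (500 snapshots at 10 ps sampling)
yields means with standard errors over blocks.

Order parameters from bond-vector series use isotropic reorientational
eigenmode dynamics (iRED): eigendecomposition of the second-rank
covariance matrix M_ij = <P2(v_i . v_j)> across sites, with the five
largest modes attributed to overall tumbling and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

R_GAS = 8.314  # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 301.0  # K
DEFAULT_BIN_WIDTH = 5.0  # degrees


class InvalidInputError(ValueError):
    pass


@dataclass
class DihedralSeries:
    """A 1D (chi-like) or 2D (phi,psi) dihedral time series in degrees."""

    site_id: str
    angles: np.ndarray  # (n,) or (n, 2), wrapped to [-180, 180)
    timestep: float = 10.0  # ps

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if a.ndim != 2 or a.shape[1] not in (1, 2):
            raise InvalidInputError("angles must be (n,) or (n, 2)")
        if a.shape[0] < 1:
            raise InvalidInputError("need at least one snapshot")
        if np.any(a < -180.0) or np.any(a >= 180.0):
            warnings.warn("angles outside [-180, 180) wrapped automatically")
            a = wrap_angles(a)
        self.angles = a

    @property
    def dimensionality(self) -> int:
        return self.angles.shape[1]

    @property
    def n_snapshots(self) -> int:
        return self.angles.shape[0]


@dataclass(frozen=True)
class EntropyEstimate:
    """-T*dS (kJ/mol) relative to a free rotor, with a block-based SEM."""

    value: float
    sem: float = 0.0
    n_blocks: int = 1

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise InvalidInputError("sem must be >= 0")


@dataclass
class BondVectorSeries:
    """Unit bond vectors (e.g. NH) over snapshots for one site."""

    site_id: str
    vectors: np.ndarray  # (n, 3)
    timestep: float = 10.0  # ps

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidInputError("vectors must be (n, 3)")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidInputError("vectors must be unit-norm within 1e-6")
        self.vectors = v


def wrap_angles(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def _histogram_probs(angles: np.ndarray, bin_width: float) -> np.ndarray:
    if not np.isclose(360.0 / bin_width, round(360.0 / bin_width)):
        raise InvalidInputError("bin_width must divide 360")
    n_bins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    dims = angles.shape[1]
    # ties at bin edges go to the upper bin: np.histogramdd uses
    # half-open [lo, hi) bins except the last, which angles < 180 never hit
    hist, _ = np.histogramdd(angles, bins=[edges] * dims)
    return hist.ravel() / angles.shape[0]


def histogram_entropy(series: DihedralSeries,
                      bin_width: float = DEFAULT_BIN_WIDTH) -> float:
    """Raw histogram entropy S = -R sum p ln p (J mol^-1 K^-1).

    Empty bins contribute zero; the maximum R ln(n_bins) is attained only
    by the uniform distribution.
    """
    p = _histogram_probs(series.angles, bin_width)
    p = p[p > 0]
    return float(-R_GAS * np.sum(p * np.log(p)))


def normalize_free_rotor(
    raw_entropy: float,
    dimensionality: int,
    T: float = DEFAULT_TEMPERATURE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> float:
    """-T*(S - S_free) in kJ/mol; S_free = R ln(n_bins^dim).

    Zero for a uniform distribution, positive for anything more ordered
    (a single occupied bin gives R*T*ln 72 = 10.70 kJ/mol per dimension
    at 301 K and 5-degree bins).
    """
    if dimensionality not in (1, 2):
        raise InvalidInputError("dimensionality must be 1 or 2")
    n_bins = int(round(360.0 / bin_width))
    s_free = R_GAS * dimensionality * np.log(n_bins)
    return float(-T * (raw_entropy - s_free) / 1e3)


def block_average(
    series: DihedralSeries,
    window: float = 5000.0,  # ps
    T: float = DEFAULT_TEMPERATURE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> EntropyEstimate:
    """Normalized entropy as mean +/- SEM over fixed-length blocks.

    The series is cut into consecutive windows of ``window`` ps
    (500 snapshots at the default 10 ps sampling); a non-multiple tail is
    truncated with a warning. With fewer than 2 blocks the SEM is
    undefined and flagged as 0 with a warning.
    """
    per_block = int(round(window / series.timestep))
    if per_block < 1:
        raise InvalidInputError("window shorter than one timestep")
    n = series.n_snapshots
    n_blocks = n // per_block
    if n_blocks == 0:
        raise InvalidInputError("series shorter than one block")
    if n % per_block:
        warnings.warn(f"truncating {n % per_block} trailing snapshots")
    vals = []
    for b in range(n_blocks):
        chunk = DihedralSeries(
            series.site_id, series.angles[b * per_block:(b + 1) * per_block],
            series.timestep)
        vals.append(normalize_free_rotor(
            histogram_entropy(chunk, bin_width), series.dimensionality, T,
            bin_width))
    vals = np.asarray(vals)
    if n_blocks < 2:
        warnings.warn("fewer than 2 blocks; SEM undefined")
        return EntropyEstimate(float(vals[0]), 0.0, 1)
    sem = float(np.std(vals, ddof=1) / np.sqrt(n_blocks))
    return EntropyEstimate(float(np.mean(vals)), sem, n_blocks)


def ired_order_parameters(
    series: Sequence[BondVectorSeries],
    n_overall_modes: int = 5,
) -> dict[str, float]:
    """Per-site O2 by isotropic reorientational eigenmode analysis.

    Builds M_ij = <P2(v_i . v_j)> over common snapshots, eigendecomposes,
    and computes O2_i = 1 - sum over internal modes of lambda_m e_mi^2,
    excluding the ``n_overall_modes`` largest (overall rotation) modes.
    """
    if len(series) < 6:
        raise InvalidInputError("iRED needs >= 6 bond-vector series")
    n_snap = {s.vectors.shape[0] for s in series}
    if len(n_snap) != 1:
        raise InvalidInputError("all series must share the snapshot grid")
    V = np.stack([s.vectors for s in series])  # (sites, snaps, 3)
    dots = np.einsum("itk,jtk->ijt", V, V)
    M = (1.5 * dots**2 - 0.5).mean(axis=2)
    lam, vec = np.linalg.eigh(M)  # ascending
    if np.sum(lam > 1e-10) < 1:
        raise InvalidInputError("rank-deficient covariance matrix")
    internal = slice(0, max(len(series) - n_overall_modes, 0))
    contrib = (vec[:, internal]**2 * lam[None, internal]).sum(axis=1)
    o2 = np.clip(1.0 - contrib, 0.0, 1.0)
    return {s.site_id: float(v) for s, v in zip(series, o2)}


def cone_order_parameter(semi_angle_deg: float) -> float:
    """Analytic O2 of diffusion in a cone: [cos(t)(1 + cos(t))/2]^2."""
    c = np.cos(np.deg2rad(semi_angle_deg))
    return float((c * (1.0 + c) / 2.0) ** 2)


def read_angle_table(path) -> list[DihedralSeries]:
    """CSV `site,time_ps,angle_deg[,angle2_deg]` -> DihedralSeries list."""
    df = pd.read_csv(path)
    out = []
    for site, grp in df.groupby("site", sort=False):
        grp = grp.sort_values("time_ps")
        cols = ["angle_deg"]
        if "angle2_deg" in grp.columns and grp["angle2_deg"].notna().all():
            cols.append("angle2_deg")
        t = grp["time_ps"].to_numpy()
        dt = float(t[1] - t[0]) if t.size > 1 else 10.0
        out.append(DihedralSeries(str(site), grp[cols].to_numpy(), dt))
    return out


def read_vector_table(path) -> list[BondVectorSeries]:
    """CSV `site,time_ps,x,y,z` -> BondVectorSeries list."""
    df = pd.read_csv(path)
    out = []
    for site, grp in df.groupby("site", sort=False):
        grp = grp.sort_values("time_ps")
        t = grp["time_ps"].to_numpy()
        dt = float(t[1] - t[0]) if t.size > 1 else 10.0
        out.append(BondVectorSeries(
            str(site), grp[["x", "y", "z"]].to_numpy(), dt))
    return out
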