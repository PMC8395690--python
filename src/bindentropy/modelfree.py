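"""Lipari-Szabo model-free analysis of 15N and 2H methyl relaxation.

Spectral densities for isotropic, axially symmetric and fully anisotropic
(rhombic) rotational diffusion, the standard dipolar/CSA 15N rate
expressions and quadrupolar 2H methyl rate expressions, per-site nested
model fitting with F-test selection and Monte-Carlo errors, and global
diffusion-tensor optimisation from many sites' rates plus NH bond
orientations.

Conventions
-----------
* ``J(omega)`` carries the 2/5 prefactor: a rigid isotropic rotor has
  J(0) = (2/5) tau_c.
* The anisotropic correlation function is the five-exponential Woessner
  form; for an axially symmetric tensor it collapses to three
  exponentials, and for an isotropic tensor to a single one.
* Exchange broadening Rex is parameterised at a reference field and
  scales with B0^2 (fast-exchange limit).
* Tensor anisotropy zeta = 2 Dzz/(Dxx + Dyy) and rhombicity
  eta = 1.5 (Dyy - Dxx)/[Dzz - (Dxx + Dyy)/2]; an isotropic tensor has
  (zeta, eta) = (1, 0) by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import f as f_dist

from .observables import RateRecord

# physical constants (SI)
MU0 = 4e-7 * np.pi
HBAR = 1.054571817e-34
GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
GAMMA_N15 = -2.71261804e7
GAMMA_D = 4.106962898e7


class InvalidInputError(ValueError):
    pass


class UnderDeterminedError(ValueError):
    """Raised when a site has fewer data than the smallest model needs."""


@dataclass(frozen=True)
class SpinSystemConstants:
    """Interaction constants of the relaxation-active spin systems."""

    r_NH: float = 1.02e-10  # m
    csa_N: float = -172e-6  # dimensionless (ppm * 1e-6)
    quadrupolar_coupling: float = 167e3  # e^2 q Q / h, Hz
    #: squared P2(cos beta) for the C-D vector on the 3-fold methyl axis;
    #: 1/9 for ideal tetrahedral geometry
    methyl_axis_factor: float = 1.0 / 9.0
    rex_reference_field: float = 11.7  # T

    @property
    def dipolar_NH(self) -> float:
        """NH dipolar coupling constant d (rad/s)."""
        return MU0 / (4 * np.pi) * GAMMA_H * GAMMA_N15 * HBAR / self.r_NH**3


DEFAULT_CONSTANTS = SpinSystemConstants()

BACKBONE_MODELS = ("m1", "m2", "m3", "m4")
METHYL_MODELS = ("s2", "s3", "s4")
_MODEL_PARAMS = {
    "m1": ("O2",),
    "m2": ("O2", "tau_e"),
    "m3": ("O2", "Rex"),
    "m4": ("O2", "tau_e", "Rex"),
    "s2": ("O2", "tau_f"),
    "s3": ("O2", "tau_f", "tau_s"),
    "s4": ("Of2", "Os2", "tau_f", "tau_s"),
}


@dataclass(frozen=True)
class ModelFreeParams:
    """Parameters of one internal-motion model. Absent parameters are None."""

    model_id: str = "m1"
    O2: float | None = None
    tau_e: float | None = None  # s, fast internal (backbone naming)
    Rex: float | None = None  # s^-1 at the reference field
    Of2: float | None = None
    Os2: float | None = None
    tau_f: float | None = None  # s
    tau_s: float | None = None  # s

    def __post_init__(self) -> None:
        for name in ("tau_e", "tau_f", "tau_s"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        for name in ("O2", "Of2", "Os2"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise InvalidInputError(f"{name} must lie in [0, 1]")

    @property
    def order_parameter(self) -> float:
        """Total O2; the product Of2*Os2 for the extended model."""
        if self.O2 is not None:
            return self.O2
        if self.Of2 is not None and self.Os2 is not None:
            return self.Of2 * self.Os2
        raise InvalidInputError("no order parameter set")

    def tau_eff(self, tau_c: float) -> float | None:
        """(1/tau_c + 1/tau_s)^-1 when a slow internal time is present."""
        if self.tau_s is None:
            return None
        return 1.0 / (1.0 / tau_c + 1.0 / self.tau_s)


@dataclass(frozen=True)
class DiffusionTensor:
    """Rotational diffusion tensor in its principal axis system.

    ``euler`` (z-y-z convention, radians) rotates molecule-frame vectors
    into the tensor frame.
    """

    Dxx: float
    Dyy: float
    Dzz: float
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0 < self.Dxx <= self.Dyy <= self.Dzz):
            raise InvalidInputError("require 0 < Dxx <= Dyy <= Dzz")

    @property
    def D_iso(self) -> float:
        return (self.Dxx + self.Dyy + self.Dzz) / 3.0

    @property
    def tau_c(self) -> float:
        return 1.0 / (6.0 * self.D_iso)

    @property
    def zeta(self) -> float:
        return anisotropy_rhombicity(self.Dxx, self.Dyy, self.Dzz)[0]

    @property
    def eta(self) -> float:
        return anisotropy_rhombicity(self.Dxx, self.Dyy, self.Dzz)[1]

    @property
    def is_isotropic(self) -> bool:
        return (self.Dzz - self.Dxx) <= 1e-12 * self.D_iso

    @classmethod
    def isotropic(cls, tau_c: float) -> "DiffusionTensor":
        d = 1.0 / (6.0 * tau_c)
        return cls(d, d, d)

    @classmethod
    def from_zeta_eta(cls, D_iso: float, zeta: float, eta: float = 0.0,
                      euler: tuple[float, float, float] = (0.0, 0.0, 0.0),
                      ) -> "DiffusionTensor":
        """Build the tensor from (D_iso, zeta, eta); prolate for zeta > 1."""
        s = 3.0 * D_iso / (1.0 + zeta / 2.0)  # Dxx + Dyy
        dzz = zeta * s / 2.0
        diff = eta * s * (zeta - 1.0) / 3.0  # Dyy - Dxx
        dxx, dyy = (s - diff) / 2.0, (s + diff) / 2.0
        return cls(dxx, dyy, dzz, euler)

    def rotation(self) -> np.ndarray:
        a, b, g = self.euler
        return _rot_z(g) @ _rot_y(b) @ _rot_z(a)

    def correlation_components(
        self, bond_orientation: np.ndarray | None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Amplitudes c_i and decay rates lambda_i of the tumbling
        correlation function C_O(t) = sum_i c_i exp(-lambda_i t)."""
        if self.is_isotropic:
            return np.array([1.0]), np.array([6.0 * self.D_iso])
        if bond_orientation is None:
            raise InvalidInputError(
                "anisotropic tensor requires a bond orientation")
        v = np.asarray(bond_orientation, dtype=float)
        v = v / np.linalg.norm(v)
        dx, dy, dz = self.rotation() @ v  # direction cosines in the PAS
        Dx, Dy, Dz = self.Dxx, self.Dyy, self.Dzz
        Diso = self.D_iso
        L2 = (Dx * Dy + Dx * Dz + Dy * Dz) / 3.0
        delta = np.sqrt(max(Diso**2 - L2, 0.0))
        rates = np.array([
            4 * Dx + Dy + Dz,
            Dx + 4 * Dy + Dz,
            Dx + Dy + 4 * Dz,
            6 * Diso + 6 * delta,
            6 * Diso - 6 * delta,
        ])
        quart = dx**4 + dy**4 + dz**4
        f_amp = 0.25 * (3 * quart - 1)
        di = np.array([Dx - Diso, Dy - Diso, Dz - Diso])
        d4 = np.array([dx**4, dy**4, dz**4])
        cross = np.array([dy**2 * dz**2, dx**2 * dz**2, dx**2 * dy**2])
        if delta > 1e-12 * Diso:
            g_amp = np.sum(di * (3 * d4 + 6 * cross - 1)) / (12 * delta)
        else:  # numerically isotropic
            g_amp = 0.0
        amps = np.array([
            3 * dy**2 * dz**2,
            3 * dx**2 * dz**2,
            3 * dx**2 * dy**2,
            f_amp - g_amp,
            f_amp + g_amp,
        ])
        return amps, rates


def _rot_z(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(t: float) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def anisotropy_rhombicity(Dxx: float, Dyy: float,
                          Dzz: float) -> tuple[float, float]:
    """(zeta, eta) of a principal-values-sorted diffusion tensor."""
    if not Dxx <= Dyy <= Dzz:
        raise InvalidInputError("principal values must be sorted ascending")
    zeta = 2.0 * Dzz / (Dxx + Dyy)
    denom = Dzz - 0.5 * (Dxx + Dyy)
    if abs(denom) < 1e-15 * max(Dzz, 1e-300):
        return zeta, 0.0
    return zeta, 1.5 * (Dyy - Dxx) / denom


def _internal_components(params: ModelFreeParams,
                         axis_factor: float = 1.0) -> list[tuple[float, float]]:
    """Decompose the internal correlation function into (amplitude, rate)
    pairs; rate 0 marks the non-decaying plateau.

    ``axis_factor`` multiplies the slow/plateau amplitudes for methyl C-D
    vectors (fast 3-fold methyl rotation about the symmetry axis).
    """
    def rate(tau: float | None) -> float:
        # tau = 0 (or absent) means the component decays instantly and
        # contributes nothing to J; encode as an infinite rate
        return 1.0 / tau if tau else np.inf

    m = params.model_id
    comps: list[tuple[float, float]] = []
    if m in ("m1", "m2", "m3", "m4", "s2"):
        O2 = params.order_parameter
        tau = params.tau_e if m.startswith("m") else params.tau_f
        a0 = axis_factor * O2
        comps.append((a0, 0.0))
        comps.append((1.0 - a0, rate(tau)))
    elif m == "s3":
        if params.tau_s is None:
            raise InvalidInputError("s3 requires tau_s")
        a_slow = axis_factor * params.order_parameter
        comps.append((a_slow, rate(params.tau_s)))
        comps.append((1.0 - a_slow, rate(params.tau_f)))
    elif m == "s4":
        if params.Of2 is None or params.Os2 is None:
            raise InvalidInputError("s4 requires Of2 and Os2")
        a0 = axis_factor * params.Of2 * params.Os2
        a_slow = axis_factor * params.Of2 * (1.0 - params.Os2)
        comps.append((a0, 0.0))
        comps.append((a_slow, rate(params.tau_s)))
        comps.append((1.0 - a0 - a_slow, rate(params.tau_f)))
    else:
        raise InvalidInputError(f"unknown model {m!r}")
    return [(a, k) for a, k in comps if a != 0.0 and np.isfinite(a)]


def spectral_density(
    params: ModelFreeParams,
    tensor: DiffusionTensor,
    bond_orientation: np.ndarray | None,
    omega: float | np.ndarray,
    axis_factor: float = 1.0,
) -> np.ndarray | float:
    """Model-free spectral density J(omega) in s/rad (2/5 prefactor included).

    For anisotropic tensors the tumbling part is the Woessner
    multi-exponential weighted by the bond's direction cosines in the
    tensor frame; the internal motion multiplies each component.
    """
    scalar = np.isscalar(omega) or np.ndim(omega) == 0
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(w < 0):
        raise InvalidInputError("omega must be >= 0")
    c_amp, c_rate = tensor.correlation_components(bond_orientation)
    internal = _internal_components(params, axis_factor)
    J = np.zeros_like(w)
    for a_int, k_int in internal:
        taus = 1.0 / (c_rate + k_int)
        J += a_int * np.sum(
            c_amp[:, None] * taus[:, None]
            / (1.0 + (w[None, :] * taus[:, None]) ** 2),
            axis=0,
        )
    out = 0.4 * J
    return float(out[0]) if scalar else out


def rates_15N(
    params: ModelFreeParams,
    tensor: DiffusionTensor,
    bond_orientation: np.ndarray | None,
    B0: float,
    constants: SpinSystemConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, float]:
    """(R1, R2, NOE) for a backbone amide 15N at field B0 (Tesla).

    Standard dipolar + CSA expressions; Rex (if present) adds to R2
    scaled by (B0 / reference field)^2.
    """
    if B0 <= 0:
        raise InvalidInputError("B0 must be > 0")
    wH = GAMMA_H * B0
    wN = abs(GAMMA_N15) * B0
    freqs = np.array([0.0, wN, abs(wH - wN), wH, wH + wN])
    J0, JN, JHmN, JH, JHpN = spectral_density(
        params, tensor, bond_orientation, freqs)
    d2 = constants.dipolar_NH**2
    c2 = (wN * constants.csa_N)**2 / 3.0
    R1 = d2 / 4.0 * (JHmN + 3 * JN + 6 * JHpN) + c2 * JN
    R2 = d2 / 8.0 * (4 * J0 + JHmN + 3 * JN + 6 * JH + 6 * JHpN) \
        + c2 / 6.0 * (4 * J0 + 3 * JN)
    if params.Rex is not None:
        R2 += params.Rex * (B0 / constants.rex_reference_field)**2
    sigma = d2 / 4.0 * (6 * JHpN - JHmN)
    noe = 1.0 + (GAMMA_H / GAMMA_N15) * sigma / R1
    return float(R1), float(R2), float(noe)


def rates_2H_methyl(
    params: ModelFreeParams,
    tensor: DiffusionTensor,
    B0: float,
    constants: SpinSystemConstants = DEFAULT_CONSTANTS,
    bond_orientation: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """Quadrupolar 2H rates (R1Dz, R3Dz2, R2Dplus, RDplusDz) at field B0.

    The order parameter refers to the methyl symmetry axis; the fast
    3-fold rotation scales the axis amplitudes by ``methyl_axis_factor``.
    """
    if B0 <= 0:
        raise InvalidInputError("B0 must be > 0")
    wD = GAMMA_D * B0
    J0, JD, J2D = spectral_density(
        params, tensor, bond_orientation, np.array([0.0, wD, 2 * wD]),
        axis_factor=constants.methyl_axis_factor)
    xi2 = (2 * np.pi * constants.quadrupolar_coupling)**2
    r1dz = 3.0 / 16.0 * xi2 * (JD + 4 * J2D)
    r3dz2 = 9.0 / 16.0 * xi2 * JD
    r2dp = 1.0 / 32.0 * xi2 * (9 * J0 + 15 * JD + 6 * J2D)
    rdpdz = 1.0 / 32.0 * xi2 * (9 * J0 + 3 * JD + 6 * J2D)
    return float(r1dz), float(r3dz2), float(r2dp), float(rdpdz)


# ---------------------------------------------------------------------------
# per-site fitting

@dataclass
class ModelFreeFit:
    """Result of per-site model selection and fitting."""

    site_id: str
    params: ModelFreeParams
    sds: dict[str, float]
    chi2: float
    n_data: int
    candidates: dict[str, float] = field(default_factory=dict)  # model -> chi2


def _site_rates(params: ModelFreeParams, tensor: DiffusionTensor,
                orientation: np.ndarray | None,
                keys: Sequence[tuple[float, str]],
                constants: SpinSystemConstants) -> np.ndarray:
    """Predicted rates for the (field, type) keys of one site."""
    out = np.empty(len(keys))
    cache: dict[float, tuple] = {}
    for i, (b0, rtype) in enumerate(keys):
        if rtype in ("R1", "R2", "NOE"):
            if ("N", b0) not in cache:
                cache[("N", b0)] = rates_15N(params, tensor, orientation, b0,
                                             constants)
            r1, r2, noe = cache[("N", b0)]
            out[i] = {"R1": r1, "R2": r2, "NOE": noe}[rtype]
        else:
            if ("D", b0) not in cache:
                cache[("D", b0)] = rates_2H_methyl(params, tensor, b0,
                                                   constants, orientation)
            r1dz, r3dz2, r2dp, rdpdz = cache[("D", b0)]
            out[i] = {"R1Dz": r1dz, "R3Dz2": r3dz2, "R2Dplus": r2dp,
                      "RDplusDz": rdpdz}[rtype]
    return out


def _pack_bounds(model: str, tau_c: float):
    names = _MODEL_PARAMS[model]
    lo, hi, starts = [], [], []
    grid: dict[str, list[float]] = {
        "O2": [0.5, 0.85], "Of2": [0.8], "Os2": [0.6, 0.9],
        "tau_e": [5e-12, 50e-12, 500e-12],
        "tau_f": [5e-12, 50e-12],
        "tau_s": [1e-9, 3e-9],
        "Rex": [1.0],
    }
    bounds = {
        "O2": (0.0, 1.0), "Of2": (0.0, 1.0), "Os2": (0.0, 1.0),
        "tau_e": (0.0, tau_c), "tau_f": (0.0, tau_c), "tau_s": (0.0, 10 * tau_c),
        "Rex": (0.0, 100.0),
    }
    for n in names:
        lo.append(bounds[n][0])
        hi.append(bounds[n][1])
    start_sets = [[]]
    for n in names:
        start_sets = [s + [v] for s in start_sets for v in grid[n]]
    return names, np.array(lo), np.array(hi), [np.array(s) for s in start_sets]


def _to_params(model: str, names: Sequence[str], x: np.ndarray) -> ModelFreeParams:
    kw = dict(zip(names, (float(v) for v in x)))
    return ModelFreeParams(model_id=model, **kw)


def fit_site(
    records: Sequence[RateRecord],
    tensor: DiffusionTensor,
    bond_orientation: np.ndarray | None = None,
    model_set: str = "backbone",
    selection: str = "ftest",
    alpha: float = 0.05,
    n_mc: int = 500,
    constants: SpinSystemConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
) -> ModelFreeFit:
    """Fit nested model-free models to one site and select by F-test.

    A larger nested model is promoted only when the F-test p-value falls
    below ``alpha`` (0.05, i.e. the 95% level). With ``selection="aic"``
    the model with the lowest AIC wins instead. Parameter uncertainties
    are SDs over ``n_mc`` refits of noise-resampled data.
    """
    if not records:
        raise UnderDeterminedError("no records for site")
    records = sorted(records, key=lambda r: (r.field_strength, r.rate_type))
    site = records[0].site_id
    keys = [(r.field_strength, r.rate_type) for r in records]
    y = np.array([r.value for r in records])
    sd = np.array([r.sd for r in records])
    n_data = len(records)
    models = BACKBONE_MODELS if model_set == "backbone" else METHYL_MODELS
    max_k = max(len(_MODEL_PARAMS[m]) for m in models)
    fittable = [m for m in models if len(_MODEL_PARAMS[m]) <= n_data]
    if not fittable or n_data < 2:
        raise UnderDeterminedError(
            f"site {site!r}: {n_data} data cannot constrain any model "
            f"(largest model needs {max_k})")

    tau_c = tensor.tau_c

    def fit_model(model: str, y_obs: np.ndarray):
        names, lo, hi, starts = _pack_bounds(model, tau_c)

        def resid(x):
            try:
                p = _to_params(model, names, x)
            except InvalidInputError:
                return np.full(n_data, 1e6)
            return (_site_rates(p, tensor, bond_orientation, keys, constants)
                    - y_obs) / sd

        best = None
        for x0 in starts:
            x0c = np.clip(x0, lo + 1e-12, hi - 1e-12)
            # diff_step: default sqrt(eps)-relative steps underflow the
            # model's sensitivity for tau parameters of order 1e-11 s
            sol = least_squares(resid, x0c, bounds=(lo, hi), x_scale="jac",
                                diff_step=1e-4, xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, max_nfev=400)
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
        chi2 = float(2 * best.cost)
        return names, best.x, chi2

    fits = {m: fit_model(m, y) for m in fittable}
    chi2s = {m: fits[m][2] for m in fittable}

    if selection == "aic":
        chosen = min(fittable,
                     key=lambda m: chi2s[m] + 2 * len(_MODEL_PARAMS[m]))
    elif selection == "ftest":
        chosen = fittable[0]
        for m in fittable[1:]:
            k1 = len(_MODEL_PARAMS[chosen])
            k2 = len(_MODEL_PARAMS[m])
            if k2 <= k1:
                if chi2s[m] < chi2s[chosen] and _f_significant(
                        chi2s[fittable[0]], chi2s[m], len(
                            _MODEL_PARAMS[fittable[0]]), k2, n_data, alpha):
                    chosen = m
                continue
            if n_data <= k2:
                continue
            if _f_significant(chi2s[chosen], chi2s[m], k1, k2, n_data, alpha):
                chosen = m
    else:
        raise InvalidInputError(f"unknown selection {selection!r}")

    names, x, chi2 = fits[chosen]
    params = _to_params(chosen, names, x)

    rng = rng if rng is not None else np.random.default_rng()
    samples = {n: [] for n in names}
    for _ in range(n_mc):
        y_mc = y + rng.normal(0.0, sd)
        _, x_mc, _ = fit_model(chosen, y_mc)
        for n, v in zip(names, x_mc):
            samples[n].append(v)
    sds = {n: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
           for n, v in samples.items()}
    return ModelFreeFit(site_id=site, params=params, sds=sds, chi2=chi2,
                        n_data=n_data, candidates=chi2s)


def _f_significant(chi2_small: float, chi2_big: float, k1: int, k2: int,
                   n: int, alpha: float) -> bool:
    if chi2_big >= chi2_small or n <= k2:
        return False
    F = ((chi2_small - chi2_big) / (k2 - k1)) / (chi2_big / (n - k2))
    if chi2_big < 1e-12:  # essentially perfect fit
        return True
    return f_dist.sf(F, k2 - k1, n - k2) < alpha


# ---------------------------------------------------------------------------
# diffusion-tensor fitting

def select_rigid_sites(
    records_by_site: Mapping[str, Sequence[RateRecord]],
    noe_threshold: float = 0.65,
) -> list[str]:
    """Sites suitable for tensor fitting: NOE above threshold at the
    highest field where an NOE was measured."""
    out = []
    for site, recs in records_by_site.items():
        noes = [(r.field_strength, r.value) for r in recs if r.rate_type == "NOE"]
        if not noes:
            continue
        if max(noes)[1] > noe_threshold:
            out.append(site)
    return out


def _rigid_rates_allsites(
    tensor: DiffusionTensor,
    vecs: np.ndarray,
    fields: Sequence[float],
    constants: SpinSystemConstants,
) -> dict[tuple[float, str], np.ndarray]:
    """Rigid-model (O2 = 1) R1/R2 for all sites at once.

    Vectorizes the Woessner amplitudes over sites so the tensor-fit
    chi^2 avoids a per-site Python loop. Returns arrays indexed by
    (field, rate type), each of length n_sites.
    """
    n = vecs.shape[0]
    if tensor.is_isotropic:
        amps = np.ones((n, 1))
        rates = np.array([6.0 * tensor.D_iso])
    else:
        dc = vecs @ tensor.rotation().T  # (n, 3) direction cosines
        dx, dy, dz = dc[:, 0], dc[:, 1], dc[:, 2]
        Dx, Dy, Dz = tensor.Dxx, tensor.Dyy, tensor.Dzz
        Diso = tensor.D_iso
        L2 = (Dx * Dy + Dx * Dz + Dy * Dz) / 3.0
        delta = np.sqrt(max(Diso**2 - L2, 0.0))
        rates = np.array([4 * Dx + Dy + Dz, Dx + 4 * Dy + Dz,
                          Dx + Dy + 4 * Dz, 6 * Diso + 6 * delta,
                          6 * Diso - 6 * delta])
        quart = dx**4 + dy**4 + dz**4
        f_amp = 0.25 * (3 * quart - 1)
        cross = np.stack([dy**2 * dz**2, dx**2 * dz**2, dx**2 * dy**2])
        d4 = np.stack([dx**4, dy**4, dz**4])
        di = np.array([Dx - Diso, Dy - Diso, Dz - Diso])
        if delta > 1e-12 * Diso:
            g_amp = np.einsum("i,ij->j", di, 3 * d4 + 6 * cross - 1) \
                / (12 * delta)
        else:
            g_amp = np.zeros(n)
        amps = np.stack([3 * cross[0], 3 * cross[1], 3 * cross[2],
                         f_amp - g_amp, f_amp + g_amp], axis=1)
    taus = 1.0 / rates  # (k,)

    def J(w: float) -> np.ndarray:
        return 0.4 * np.sum(amps * taus / (1.0 + (w * taus) ** 2), axis=1)

    d2 = constants.dipolar_NH**2
    out: dict[tuple[float, str], np.ndarray] = {}
    for b0 in fields:
        wH = GAMMA_H * b0
        wN = abs(GAMMA_N15) * b0
        J0, JN, JHmN, JH, JHpN = (J(w) for w in
                                  (0.0, wN, abs(wH - wN), wH, wH + wN))
        c2 = (wN * constants.csa_N)**2 / 3.0
        out[(b0, "R1")] = d2 / 4.0 * (JHmN + 3 * JN + 6 * JHpN) + c2 * JN
        out[(b0, "R2")] = (d2 / 8.0 * (4 * J0 + JHmN + 3 * JN + 6 * JH
                                       + 6 * JHpN)
                           + c2 / 6.0 * (4 * J0 + 3 * JN))
    return out


def fit_diffusion_tensor(
    records_by_site: Mapping[str, Sequence[RateRecord]],
    nh_vectors: Mapping[str, np.ndarray],
    shape: str = "isotropic",
    constants: SpinSystemConstants = DEFAULT_CONSTANTS,
    preselect: bool = True,
    tau_c_init: float | None = None,
) -> DiffusionTensor:
    """Fit the global rotational diffusion tensor from many sites' R1/R2.

    Each candidate tensor is scored with the rigid local model (per-site
    O2 only), for which the weighted least-squares O2 is available in
    closed form because all rates are then linear in O2. NOEs are used
    only for rigid-site preselection, never in the tensor chi^2 (they are
    O2-independent under the rigid model).
    """
    if shape not in ("isotropic", "axial", "rhombic"):
        raise InvalidInputError(f"unknown tensor shape {shape!r}")
    sites = list(records_by_site)
    if preselect:
        rigid = select_rigid_sites(records_by_site)
        if len(rigid) >= 10:
            sites = rigid
    if len(sites) < 10:
        raise InvalidInputError("need >=10 rigid sites for a tensor fit")
    sites = [s for s in sites if s in nh_vectors]

    vecs = np.array([np.asarray(nh_vectors[s], float) for s in sites])
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    if shape != "isotropic":
        # degenerate geometry guard: vectors must span orientation space
        gram = vecs.T @ vecs / len(sites)
        if np.linalg.eigvalsh(gram)[0] < 1e-3:
            warnings.warn("NH vectors nearly parallel; falling back to an "
                          "isotropic tensor")
            shape = "isotropic"

    # flatten all R1/R2 records into (site index, field, type, y, weight)
    fields = sorted({r.field_strength for recs in records_by_site.values()
                     for r in recs if r.rate_type in ("R1", "R2")})
    idx_rows, key_rows, y_all, w_all = [], [], [], []
    site_slices = []
    pos = 0
    for i, s in enumerate(sites):
        recs = [r for r in records_by_site[s] if r.rate_type in ("R1", "R2")]
        for r in recs:
            idx_rows.append(i)
            key_rows.append((r.field_strength, r.rate_type))
            y_all.append(r.value)
            w_all.append(1.0 / r.sd**2)
        site_slices.append(slice(pos, pos + len(recs)))
        pos += len(recs)
    idx_rows = np.array(idx_rows)
    y_all = np.array(y_all)
    w_all = np.array(w_all)
    key_groups = {k: np.array([j for j, kk in enumerate(key_rows) if kk == k])
                  for k in set(key_rows)}

    def chi2_for(tensor: DiffusionTensor) -> float:
        table = _rigid_rates_allsites(tensor, vecs, fields, constants)
        base = np.empty(y_all.size)
        for k, rows in key_groups.items():
            base[rows] = table[k][idx_rows[rows]]
        total = 0.0
        for sl in site_slices:
            b, y, w = base[sl], y_all[sl], w_all[sl]
            o2 = np.sum(w * y * b) / np.sum(w * b**2)
            o2 = min(max(o2, 0.0), 1.0)
            total += float(np.sum(w * (o2 * b - y)**2))
        return total

    if tau_c_init is None:
        tau_c_init = _tau_c_from_r2_over_r1(records_by_site, constants)

    if shape == "isotropic":
        res = minimize(
            lambda x: chi2_for(DiffusionTensor.isotropic(abs(x[0]))),
            x0=[tau_c_init], method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-10})
        return DiffusionTensor.isotropic(abs(res.x[0]))

    d_iso0 = 1.0 / (6.0 * tau_c_init)

    def build(x) -> DiffusionTensor | None:
        if shape == "axial":
            d_iso, zeta, th, ph = x
            eta, euler = 0.0, (ph, th, 0.0)
        else:
            d_iso, zeta, eta, al, be, ga = x
            euler = (al, be, ga)
        try:
            return DiffusionTensor.from_zeta_eta(abs(d_iso), zeta, eta, euler)
        except InvalidInputError:
            return None

    def cost(x):
        t = build(x)
        return chi2_for(t) if t is not None else 1e12

    starts = []
    for th in (0.3, 1.0, 1.8):
        for ph in (0.0, 2.0, 4.0):
            if shape == "axial":
                starts.append([d_iso0, 1.10, th, ph])
            else:
                starts.append([d_iso0, 1.10, 0.5, ph, th, 0.0])
    best = None
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-9,
                                "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    tensor = build(best.x)
    if tensor is None:  # pragma: no cover
        raise InvalidInputError("tensor fit failed to produce a valid tensor")
    return tensor


def _tau_c_from_r2_over_r1(
    records_by_site: Mapping[str, Sequence[RateRecord]],
    constants: SpinSystemConstants,
) -> float:
    """Initial tau_c from the median R2/R1 ratio at the highest field."""
    by_field: dict[float, dict[str, dict[str, float]]] = {}
    for s, recs in records_by_site.items():
        for r in recs:
            if r.rate_type in ("R1", "R2"):
                by_field.setdefault(r.field_strength, {}).setdefault(
                    s, {})[r.rate_type] = r.value
    b0 = max(by_field)
    ratios = [v["R2"] / v["R1"] for v in by_field[b0].values()
              if "R1" in v and "R2" in v and v["R1"] > 0]
    target = float(np.median(ratios))

    def ratio(tau_c):
        p = ModelFreeParams(model_id="m1", O2=0.85)
        t = DiffusionTensor.isotropic(tau_c)
        r1, r2, _ = rates_15N(p, t, None, b0, constants)
        return r2 / r1

    lo, hi = 1e-9, 30e-9
    for _ in range(60):  # bisection; ratio is monotone in tau_c
        mid = 0.5 * (lo + hi)
        if ratio(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def alternating_tensor_refinement(
    records_by_site: Mapping[str, Sequence[RateRecord]],
    nh_vectors: Mapping[str, np.ndarray],
    shape: str = "isotropic",
    n_rounds: int = 2,
    constants: SpinSystemConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
    n_mc: int = 0,
) -> tuple[DiffusionTensor, dict[str, ModelFreeFit]]:
    """Alternate tensor fitting and per-site model-free fits to convergence.

    Round 1 fits the tensor on NOE-preselected rigid sites; subsequent
    rounds re-fit it on sites whose selected model carries no exchange
    term, then re-fit all sites at the final tensor.
    """
    tensor = fit_diffusion_tensor(records_by_site, nh_vectors, shape,
                                  constants)
    fits: dict[str, ModelFreeFit] = {}
    for rnd in range(n_rounds):
        fits = {
            s: fit_site(recs, tensor, nh_vectors.get(s), "backbone",
                        n_mc=0, constants=constants, rng=rng)
            for s, recs in records_by_site.items()
        }
        if rnd == n_rounds - 1:
            break
        calm = [s for s, f in fits.items()
                if f.params.model_id in ("m1", "m2")]
        subset = {s: records_by_site[s] for s in calm}
        if len(subset) >= 10:
            tensor = fit_diffusion_tensor(subset, nh_vectors, shape,
                                          constants, preselect=False,
                                          tau_c_init=tensor.tau_c)
    if n_mc > 0:
        fits = {
            s: fit_site(recs, tensor, nh_vectors.get(s), "backbone",
                        n_mc=n_mc, constants=constants, rng=rng)
            for s, recs in records_by_site.items()
        }
    return tensor, fits


def nh_vectors_from_structure(path: str) -> dict[str, np.ndarray]:
    """Per-residue N->H unit vectors from a PDB file (requires amide protons)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    out: dict[str, np.ndarray] = {}
    for model in st:
        for chain in model:
            for res in chain:
                n = res.find_atom("N", "*")
                h = res.find_atom("H", "*") or res.find_atom("HN", "*")
                if n is None or h is None:
                    continue
                v = np.array([h.pos.x - n.pos.x, h.pos.y - n.pos.y,
                              h.pos.z - n.pos.z])
                norm = np.linalg.norm(v)
                if norm > 0:
                    out[str(res.seqid.num)] = v / norm
        break
    return out
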