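"""Single-site ITC binding model and global replicate fitting.

The titration is modelled with the standard perfusion (displaced-volume)
bookkeeping of MicroCal-type instruments: each injection of volume V_i
displaces V_i of well-mixed cell contents, so for constant injection
volume v the cell-resident species dilutes as (1 - v/V0)^i while the
titrant accumulates as S*(1 - (1 - v/V0)^i).

The cumulative heat content after injection i is Q_i = V0 * dH * [MX]_i
with the single-site mass-action complex concentration

    [MX] = (alpha - sqrt(alpha^2 - 4 n M X)) / 2,   alpha = n M + X + Kd,

and the measured per-injection heat is the displaced-volume differential

    q_i = Q_i - Q_{i-1} + (V_i/V0) (Q_i + Q_{i-1}) / 2 + Q_off.

Free energy and entropy follow dG = R T ln Kd and -T dS = dG - dH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

R_GAS = 8.314  # J mol^-1 K^-1


class InvalidInputError(ValueError):
    pass


class FitFailureError(RuntimeError):
    pass


@dataclass(frozen=True)
class TitrationScheme:
    """Injection bookkeeping for one titration.

    ``titrant`` names which species sits in the syringe. The binding model
    distinguishes the protein M (carrying the binding-competent fraction n)
    from the ligand X; either may be titrated.
    """

    V0: float  # cell volume, L
    injection_volumes: tuple[float, ...]  # L per injection
    syringe_conc: float  # mol/L of the titrant
    cell_conc: float  # mol/L of the cell-resident species
    temperature: float = 301.1  # K
    titrant: str = "protein"  # "protein" or "ligand"

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_volumes",
                           tuple(float(v) for v in self.injection_volumes))
        if self.V0 <= 0:
            raise InvalidInputError("V0 must be > 0")
        if any(v <= 0 for v in self.injection_volumes):
            raise InvalidInputError("injection volumes must be > 0")
        if self.syringe_conc < 0 or self.cell_conc < 0:
            raise InvalidInputError("concentrations must be >= 0")
        if self.titrant not in ("protein", "ligand"):
            raise InvalidInputError("titrant must be 'protein' or 'ligand'")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass(frozen=True)
class BindingParams:
    """Single-site binding parameters shared across replicates."""

    n: float  # fraction of binding-competent protein
    Kd: float  # mol/L
    dH: float  # J/mol
    Q_off: float = 0.0  # J per injection, heat of mixing offset

    def __post_init__(self) -> None:
        if not self.Kd > 0:
            raise InvalidInputError("Kd must be > 0")
        if not (0 < self.n <= 2):
            raise InvalidInputError("n must lie in (0, 2]")


@dataclass
class Thermogram:
    """Per-injection heats (J) with optional uncertainties, plus the scheme."""

    heats: np.ndarray
    scheme: TitrationScheme
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.heats.size != self.scheme.n_injections:
            raise InvalidInputError(
                f"{self.heats.size} heats but scheme has "
                f"{self.scheme.n_injections} injections"
            )


@dataclass(frozen=True)
class ThermoSummary:
    """Derived overall thermodynamics, all energies in kJ/mol."""

    dG: float
    dH: float
    mTdS: float  # -T*dS = dG - dH
    Kd: float  # mol/L
    T: float  # K
    sd_dG: float = 0.0
    sd_dH: float = 0.0
    sd_mTdS: float = 0.0


def cell_concentrations(scheme: TitrationScheme,
                        injection_index: int) -> tuple[float, float]:
    """Total (protein, ligand) concentrations in the cell after injection i.

    ``injection_index`` counts completed injections; 0 means the initial
    cell contents. Perfusion model: each injection displaces its own
    volume of well-mixed cell contents.
    """
    if not 0 <= injection_index <= scheme.n_injections:
        raise InvalidInputError(
            f"injection_index {injection_index} outside 0..{scheme.n_injections}"
        )
    dil = 1.0
    titr = 0.0
    for v in scheme.injection_volumes[:injection_index]:
        f = 1.0 - v / scheme.V0
        dil *= f
        titr = titr * f + scheme.syringe_conc * (v / scheme.V0)
    resident = scheme.cell_conc * dil
    if scheme.titrant == "protein":
        return titr, resident
    return resident, titr


def complex_concentration(M_tot: float, X_tot: float,
                          params: BindingParams) -> float:
    """Mass-action single-site complex concentration [MX] (mol/L)."""
    if M_tot < 0 or X_tot < 0:
        raise InvalidInputError("total concentrations must be >= 0")
    nM = params.n * M_tot
    alpha = nM + X_tot + params.Kd
    disc = alpha * alpha - 4.0 * nM * X_tot
    root = (alpha - np.sqrt(max(disc, 0.0))) / 2.0
    return float(min(max(root, 0.0), min(nM, X_tot)))


def predicted_heats(scheme: TitrationScheme, params: BindingParams) -> np.ndarray:
    """Per-injection heats (J) for a scheme under single-site binding."""
    n_inj = scheme.n_injections
    q = np.empty(n_inj)
    Q_prev = scheme.V0 * params.dH * complex_concentration(
        *cell_concentrations(scheme, 0), params)
    for i in range(1, n_inj + 1):
        M_i, X_i = cell_concentrations(scheme, i)
        Q_i = scheme.V0 * params.dH * complex_concentration(M_i, X_i, params)
        v = scheme.injection_volumes[i - 1]
        q[i - 1] = Q_i - Q_prev + (v / scheme.V0) * (Q_i + Q_prev) / 2.0 \
            + params.Q_off
        Q_prev = Q_i
    return q


def saturation(M_tot: float, X_tot: float, params: BindingParams) -> float:
    """Fraction of the limiting species bound, [MX]/min(n*M, X), in [0, 1]."""
    if M_tot == 0 and X_tot == 0:
        raise InvalidInputError("both totals are zero; saturation undefined")
    limit = min(params.n * M_tot, X_tot)
    if limit == 0:
        return 0.0
    return complex_concentration(M_tot, X_tot, params) / limit


def derive_thermodynamics(
    Kd: float, dH: float, T: float,
    sd_Kd: float = 0.0, sd_dH: float = 0.0,
) -> ThermoSummary:
    """Overall thermodynamics from (Kd, dH): dG = RT ln Kd, -TdS = dG - dH.

    ``dH``/``sd_dH`` in J/mol; output energies in kJ/mol. Errors propagate
    assuming independence: sd(dG) = RT sd(Kd)/Kd,
    sd(-TdS) = sqrt(sd(dG)^2 + sd(dH)^2).
    """
    if Kd <= 0:
        raise InvalidInputError("Kd must be > 0")
    if T <= 0:
        raise InvalidInputError("T must be > 0")
    dG = R_GAS * T * np.log(Kd)
    mTdS = dG - dH
    sd_dG = R_GAS * T * sd_Kd / Kd
    sd_mTdS = float(np.hypot(sd_dG, sd_dH))
    return ThermoSummary(
        dG=dG / 1e3, dH=dH / 1e3, mTdS=mTdS / 1e3, Kd=Kd, T=T,
        sd_dG=sd_dG / 1e3, sd_dH=sd_dH / 1e3, sd_mTdS=sd_mTdS / 1e3,
    )


@dataclass
class GlobalFitResult:
    """Shared (n, Kd, dH) with per-replicate offsets and covariance-based sds."""

    params: BindingParams  # Q_off holds the first replicate's offset
    offsets: np.ndarray  # per replicate, J
    sd_n: float
    sd_Kd: float
    sd_dH: float
    sd_offsets: np.ndarray
    chi2: float
    n_points: int

    @property
    def summary(self) -> ThermoSummary:
        return derive_thermodynamics(
            self.params.Kd, self.params.dH, self.temperature,
            sd_Kd=self.sd_Kd, sd_dH=self.sd_dH)

    temperature: float = 301.1


def fit_global(
    thermograms: Sequence[Thermogram],
    init: BindingParams | None = None,
    exclude_first: bool = False,
) -> GlobalFitResult:
    """Weighted least-squares fit of one binding model to >=1 replicates.

    (n, Kd, dH) are shared across replicates; each replicate gets its own
    heat-of-mixing offset Q_off. Kd is optimised on a log scale. Parameter
    sds come from the Jacobian-based covariance scaled by reduced chi^2.

    ``exclude_first`` drops injection 1 of every replicate from the
    residuals (a common guard against diffusion across the syringe tip);
    it is off by default.
    """
    if not thermograms:
        raise InvalidInputError("need at least one thermogram")
    n_rep = len(thermograms)
    masks = []
    for tg in thermograms:
        m = np.ones(tg.heats.size, dtype=bool)
        if exclude_first:
            m[0] = False
        masks.append(m)
    n_points = int(sum(m.sum() for m in masks))
    if n_points < 5:
        raise InvalidInputError("need >=5 informative injections in total")

    if init is None:
        init = _initial_guess(thermograms[0])

    def unpack(x):
        n, lnKd, dH = x[0], x[1], x[2]
        offs = x[3:]
        return n, np.exp(lnKd), dH, offs

    def residuals(x):
        n, Kd, dH, offs = unpack(x)
        try:
            p = BindingParams(n=min(max(n, 1e-6), 2.0), Kd=Kd, dH=dH)
        except InvalidInputError:
            return np.full(n_points, 1e6)
        res = []
        for tg, off, m in zip(thermograms, offs, masks):
            model = predicted_heats(tg.scheme, replace(p, Q_off=off))
            r = model[m] - tg.heats[m]
            if tg.sd is not None:
                r = r / tg.sd[m]
            res.append(r)
        return np.concatenate(res)

    x0 = np.concatenate([[init.n, np.log(init.Kd), init.dH],
                         np.full(n_rep, init.Q_off)])
    lb = np.concatenate([[1e-6, np.log(1e-12), -1e7], np.full(n_rep, -np.inf)])
    ub = np.concatenate([[2.0, np.log(1.0), 1e7], np.full(n_rep, np.inf)])
    sol = least_squares(residuals, x0, bounds=(lb, ub), x_scale="jac",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000)
    if not sol.success:
        raise FitFailureError(
            f"global ITC fit did not converge: {sol.message}; "
            f"final residual norm {np.linalg.norm(sol.fun):.3g}")
    n, Kd, dH, offs = unpack(sol.x)
    chi2 = float(np.sum(sol.fun**2))
    dof = max(n_points - sol.x.size, 1)
    # covariance via J^T J pseudo-inverse, scaled by reduced chi2
    _, s, VT = np.linalg.svd(sol.jac, full_matrices=False)
    s = np.where(s > s[0] * 1e-12, s, np.inf)
    cov = (VT.T / s**2) @ VT * (chi2 / dof)
    sds = np.sqrt(np.diag(cov))
    return GlobalFitResult(
        params=BindingParams(n=n, Kd=Kd, dH=dH, Q_off=offs[0]),
        offsets=np.asarray(offs),
        sd_n=float(sds[0]),
        sd_Kd=float(sds[1] * Kd),  # delta method for lnKd -> Kd
        sd_dH=float(sds[2]),
        sd_offsets=sds[3:],
        chi2=chi2,
        n_points=n_points,
        temperature=thermograms[0].scheme.temperature,
    )


def _initial_guess(tg: Thermogram) -> BindingParams:
    """Crude starting point: offset from the last heats, dH from the total."""
    q = tg.heats
    off = float(np.median(q[-max(3, q.size // 5):]))
    sch = tg.scheme
    M_f, X_f = cell_concentrations(sch, sch.n_injections)
    limit = max(min(M_f, X_f), 1e-12)
    dH = float(np.sum(q - off) / (sch.V0 * limit))
    if dH == 0:
        dH = -4e4
    Kd0 = max(min(M_f, X_f) / 10.0, 1e-9)
    return BindingParams(n=1.0, Kd=Kd0, dH=dH, Q_off=off)


def complex_concentration_bisect(M_tot: float, X_tot: float,
                                 params: BindingParams) -> float:
    """Numeric root-solve of the mass-action equations (reference path).

    Solves (nM - c)(X - c) = Kd c by bisection; independent of the
    closed-form quadratic used by :func:`complex_concentration`.
    """
    nM = params.n * M_tot
    hi = min(nM, X_tot)
    if hi == 0:
        return 0.0

    def f(c):
        return (nM - c) * (X_tot - c) - params.Kd * c

    return float(brentq(f, 0.0, hi, xtol=1e-18, rtol=1e-15))
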