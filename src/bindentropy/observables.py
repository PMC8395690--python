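"""Shared measurement layer for relaxation observables.

Monoexponential decay fitting with jackknife or Monte-Carlo error
estimates, chemical-shift-perturbation arithmetic, and round-trip IO for
per-residue rate tables (R1/R2/NOE and the four quadrupolar methyl rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

RATE_TYPES = ("R1", "R2", "NOE", "R1Dz", "R3Dz2", "R2Dplus", "RDplusDz")

#: CSP weights for the heteronuclear axis: 0.16 for 15N amides, 0.25 for
#: 13C methyls.
CSP_WEIGHT_15N = 0.16
CSP_WEIGHT_13C = 0.25


class InvalidInputError(ValueError):
    """Raised when an operation receives data it cannot meaningfully use."""


class FitFailureError(RuntimeError):
    """Raised when a least-squares fit does not converge; carries diagnostics."""


@dataclass
class DecaySeries:
    """A relaxation decay: peak intensity as a function of relaxation delay.

    Duplicate delays (e.g. ``8 (x2)`` in an interleaved experiment) are kept
    as separate points; they carry real information about the noise level
    and contribute degrees of freedom to the fit.
    """

    site_id: str
    delays: np.ndarray  # s
    intensities: np.ndarray  # arbitrary units
    noise_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.noise_sd is not None:
            self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if self.delays.shape != self.intensities.shape:
            raise InvalidInputError("delays and intensities must have equal length")
        if np.any(self.delays < 0):
            raise InvalidInputError("delays must be non-negative")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidInputError("intensities must be finite")
        if np.unique(self.delays).size < 3:
            raise InvalidInputError(
                f"site {self.site_id!r}: need >=3 distinct delays for a decay fit"
            )


@dataclass(frozen=True)
class RateRecord:
    """One relaxation rate (or NOE) for one site at one static field."""

    site_id: str
    field_strength: float  # Tesla
    rate_type: str
    value: float  # s^-1 (NOE dimensionless)
    sd: float

    def __post_init__(self) -> None:
        if self.rate_type not in RATE_TYPES:
            raise InvalidInputError(
                f"unknown rate_type {self.rate_type!r}; expected one of {RATE_TYPES}"
            )
        if not self.sd > 0:
            raise InvalidInputError(f"sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class ShiftPerturbation:
    """Weighted Euclidean chemical-shift perturbation for one site."""

    site_id: str
    delta_H: float  # ppm
    delta_X: float  # ppm (15N or 13C)
    weight: float = CSP_WEIGHT_15N

    @property
    def csp(self) -> float:
        return chemical_shift_perturbation(self.delta_H, self.delta_X, self.weight)


def chemical_shift_perturbation(
    delta_H: float, delta_X: float, weight: float = CSP_WEIGHT_15N
) -> float:
    """Combined 1H/heteronuclear shift change, sqrt(dH^2 + (w*dX)^2) in ppm.

    ``weight`` scales the heteronuclear axis onto the 1H scale: 0.16 for
    backbone 15N, 0.25 for methyl 13C.
    """
    return float(np.hypot(delta_H, weight * delta_X))


def _fit_rate(delays: np.ndarray, intensities: np.ndarray,
              sigma: np.ndarray | None) -> tuple[float, float]:
    """Core I(t) = I0 exp(-R t) least-squares fit; returns (R, I0)."""
    i0_guess = intensities[np.argmin(delays)]
    if i0_guess == 0:
        i0_guess = np.max(np.abs(intensities)) or 1.0
    span = np.ptp(delays) or 1.0
    # crude log-linear start where intensities allow it
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = intensities / i0_guess > 1e-12
        if pos.sum() >= 2:
            slope = np.polyfit(delays[pos], np.log(intensities[pos] / i0_guess), 1)[0]
            r_guess = max(-slope, 1e-6)
        else:
            r_guess = 1.0 / span
    try:
        popt, _ = curve_fit(
            lambda t, i0, r: i0 * np.exp(-r * t),
            delays, intensities, p0=[i0_guess, r_guess],
            sigma=sigma, absolute_sigma=sigma is not None, maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitFailureError(
            f"monoexponential fit did not converge (start R={r_guess:.3g})"
        ) from exc
    return float(popt[1]), float(popt[0])


def fit_monoexponential(
    series: DecaySeries,
    error_method: str = "jackknife",
    n_mc: int = 200,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Fit I(t) = I0 exp(-R t) to a decay and estimate the rate uncertainty.

    Parameters
    ----------
    series:
        The decay to fit. If ``series.noise_sd`` is present the fit is
        inverse-variance weighted, otherwise unweighted.
    error_method:
        ``"jackknife"`` (leave-one-out) or ``"montecarlo"`` (``n_mc``
        refits of noise-resampled data; requires ``noise_sd`` or uses the
        residual RMS).
    rng:
        Random generator for the Monte-Carlo resampling (seeded by caller).

    Returns
    -------
    (rate, amplitude, rate_sd)
    """
    t, y = series.delays, series.intensities
    if np.ptp(y) == 0:
        raise FitFailureError(
            f"site {series.site_id!r}: constant intensities, decay rate degenerate"
        )
    rate, amp = _fit_rate(t, y, series.noise_sd)

    if error_method == "jackknife":
        n = t.size
        rates = []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if np.unique(t[mask]).size < 3:
                continue
            sig = series.noise_sd[mask] if series.noise_sd is not None else None
            rates.append(_fit_rate(t[mask], y[mask], sig)[0])
        rates = np.asarray(rates)
        m = rates.size
        rate_sd = float(np.sqrt((m - 1) / m * np.sum((rates - rates.mean()) ** 2)))
    elif error_method == "montecarlo":
        rng = rng if rng is not None else np.random.default_rng()
        if series.noise_sd is not None:
            sd = series.noise_sd
        else:
            resid = y - amp * np.exp(-rate * t)
            dof = max(t.size - 2, 1)
            sd = np.full_like(y, np.sqrt(np.sum(resid**2) / dof))
        rates = np.empty(n_mc)
        for k in range(n_mc):
            rates[k] = _fit_rate(t, y + rng.normal(0.0, sd), series.noise_sd)[0]
        rate_sd = float(np.std(rates, ddof=1))
    else:
        raise InvalidInputError(f"unknown error_method {error_method!r}")
    return rate, amp, rate_sd


# ---------------------------------------------------------------------------
# table IO

_RATE_COLUMNS = ["site", "field_T", "rate_type", "value", "sd"]


def write_rate_table(records: Iterable[RateRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.site_id, r.field_strength, r.rate_type, r.value, r.sd) for r in records],
        columns=_RATE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_rate_table(path: str | Path) -> list[RateRecord]:
    """Read a `site,field_T,rate_type,value,sd` CSV/TSV into RateRecords.

    Rejects unknown rate types and duplicated (site, field, type) keys,
    naming the offending rows.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(_RATE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~df["rate_type"].isin(RATE_TYPES)]
    if not bad.empty:
        lines = (bad.index + 2).tolist()  # +1 header +1 zero-base
        raise InvalidInputError(
            f"{path}: unknown rate_type at line(s) {lines}: "
            f"{sorted(bad['rate_type'].unique())}"
        )
    key = df[["site", "field_T", "rate_type"]]
    dup = key[key.duplicated(keep=False)]
    if not dup.empty:
        pairs = sorted({tuple(r) for r in dup.itertuples(index=False)})
        raise InvalidInputError(f"{path}: duplicated (site, field, type) rows: {pairs}")
    return [
        RateRecord(str(r.site), float(r.field_T), str(r.rate_type),
                   float(r.value), float(r.sd))
        for r in df.itertuples(index=False)
    ]


def write_decay_table(series_list: Sequence[DecaySeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for i in range(s.delays.size):
            row = {"site": s.site_id, "delay_s": s.delays[i],
                   "intensity": s.intensities[i]}
            if s.noise_sd is not None:
                row["sd"] = s.noise_sd[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decay_table(path: str | Path) -> list[DecaySeries]:
    df = pd.read_csv(path)
    out = []
    for site, grp in df.groupby("site", sort=False):
        sd = grp["sd"].to_numpy() if "sd" in grp.columns else None
        out.append(DecaySeries(str(site), grp["delay_s"].to_numpy(),
                               grp["intensity"].to_numpy(), sd))
    return out
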