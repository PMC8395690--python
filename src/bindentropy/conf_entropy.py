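"""Conformational entropy from NMR order parameters.

Per-residue entropies use the diffusion-in-a-cone relationship between a
bond-vector generalized order parameter and its orientational entropy,

    S(O2) = R ln[ pi (3 - sqrt(1 + 8 O)) ],    O = sqrt(O2),

so a backbone entropy difference between two states A and B is the
log-ratio sum

    dS_bb = R sum_k ln[ (3 - sqrt(1 + 8 O_Ak)) / (3 - sqrt(1 + 8 O_Bk)) ].

Methyl-bearing side chains additionally carry an empirical residue-type
coefficient C_m (1.32 for Val/Thr, 3.1 for Ile/Leu, 2.31 for Met) that
scales the methyl-axis term up to the full side-chain torsional entropy;
Ala side chains use the unscaled backbone form. Entropies are reported
as -T*dS at 301 K.

The intercomplex comparison statistic for three complexes A, B, C is
dP(A) = P(A) - (P(B) + P(C))/2; the three deltas sum to zero and equal
1.5x the deviation from the three-complex mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

R_GAS = 8.314  # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 301.0  # K

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Residue-type coefficients scaling methyl-axis entropy to full
#: side-chain entropy. Ala is handled through the backbone-form equation.
CM_COEFFICIENTS: dict[str, float] = {
    "VAL": 1.32, "THR": 1.32, "ILE": 3.1, "LEU": 3.1, "MET": 2.31,
}

_O2_CLIP = 1.0 - 1e-6


class InvalidInputError(ValueError):
    pass


@dataclass(frozen=True)
class OrderParameterRecord:
    residue: int
    restype: str  # three-letter amino-acid code
    site_class: str  # "backbone" or "methyl"
    O2: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.restype.upper() not in AMINO_ACIDS:
            raise InvalidInputError(f"unknown residue type {self.restype!r}")
        if self.site_class not in ("backbone", "methyl"):
            raise InvalidInputError("site_class must be 'backbone' or 'methyl'")
        if not 0 <= self.O2:
            raise InvalidInputError("O2 must be >= 0")
        if self.sd < 0:
            raise InvalidInputError("sd must be >= 0")


class OrderParameterTable:
    """Per-site O2 values with uncertainties for one complex."""

    def __init__(self, records: Sequence[OrderParameterRecord]):
        keys = [(r.residue, r.site_class) for r in records]
        if len(set(keys)) != len(keys):
            raise InvalidInputError("duplicate (residue, site_class) entries")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, site_class: str) -> "OrderParameterTable":
        return OrderParameterTable(
            [r for r in self.records if r.site_class == site_class])

    def keyed(self) -> dict[tuple[int, str], OrderParameterRecord]:
        return {(r.residue, r.site_class): r for r in self.records}

    @classmethod
    def from_csv(cls, path: str | Path) -> "OrderParameterTable":
        df = pd.read_csv(path)
        need = {"residue", "restype", "site_class", "O2"}
        if not need <= set(df.columns):
            raise InvalidInputError(
                f"{path}: need columns {sorted(need)} (optional sd)")
        return cls([
            OrderParameterRecord(
                int(r.residue), str(r.restype).upper(), str(r.site_class),
                float(r.O2), float(getattr(r, "sd", 0.0)))
            for r in df.itertuples(index=False)
        ])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(r.residue, r.restype, r.site_class, r.O2, r.sd)
             for r in self.records],
            columns=["residue", "restype", "site_class", "O2", "sd"],
        ).to_csv(path, index=False)


def _cone_log_term(O2: float | np.ndarray, site: str = "") -> np.ndarray:
    """ln(3 - sqrt(1 + 8*sqrt(O2))), the per-site entropy kernel (in R units,
    up to the additive ln(pi) constant that cancels in all differences)."""
    O2 = np.asarray(O2, dtype=float)
    if np.any(O2 < 0):
        raise InvalidInputError(f"O2 must be >= 0 {site}")
    if np.any(O2 >= 1.0):
        over = np.asarray(O2 >= 1.0).nonzero()
        warnings.warn(
            f"O2 >= 1 clipped to {_O2_CLIP} at positions {over[0].tolist()} "
            f"{site}".strip())
        O2 = np.minimum(O2, _O2_CLIP)
    return np.log(3.0 - np.sqrt(1.0 + 8.0 * np.sqrt(O2)))


def _aligned(table_a: OrderParameterTable, table_b: OrderParameterTable,
             site_class: str) -> tuple[np.ndarray, np.ndarray, list]:
    a = {k: r for k, r in table_a.keyed().items() if k[1] == site_class}
    b = {k: r for k, r in table_b.keyed().items() if k[1] == site_class}
    if set(a) != set(b):
        missing = sorted(set(a) ^ set(b))
        raise InvalidInputError(
            f"site sets differ between tables; unmatched sites: {missing}")
    keys = sorted(a)
    return (np.array([a[k].O2 for k in keys]),
            np.array([b[k].O2 for k in keys]),
            [a[k] for k in keys])


def backbone_entropy_diff(
    table_a: OrderParameterTable, table_b: OrderParameterTable,
    T: float = DEFAULT_TEMPERATURE,
) -> float:
    """-T*dS (kJ/mol) of backbone conformational entropy, state A minus B.

    Antisymmetric under swapping A and B; zero for identical tables.
    """
    o2a, o2b, _ = _aligned(table_a, table_b, "backbone")
    ds = R_GAS * float(np.sum(_cone_log_term(o2a, "(table A)")
                              - _cone_log_term(o2b, "(table B)")))
    return -T * ds / 1e3


def sidechain_entropy_diff(
    table_a: OrderParameterTable, table_b: OrderParameterTable,
    coeffs: Mapping[str, float] | None = None,
    T: float = DEFAULT_TEMPERATURE,
) -> float:
    """-T*dS (kJ/mol) of methyl side-chain entropy, A minus B.

    Each methyl-axis site contributes its cone log-ratio scaled by the
    residue-type coefficient C_m; Ala contributes unscaled (backbone form).
    """
    coeffs = CM_COEFFICIENTS if coeffs is None else coeffs
    o2a, o2b, recs = _aligned(table_a, table_b, "methyl")
    ds = 0.0
    for xa, xb, rec in zip(o2a, o2b, recs):
        rt = rec.restype.upper()
        if rt == "ALA":
            cm = 1.0
        elif rt in coeffs:
            cm = coeffs[rt]
        else:
            raise InvalidInputError(
                f"no side-chain coefficient for residue type {rt!r}")
        ds += cm * float(_cone_log_term(xa, f"(res {rec.residue} A)")
                         - _cone_log_term(xb, f"(res {rec.residue} B)"))
    return -T * R_GAS * ds / 1e3


def per_residue_entropy(
    table: OrderParameterTable, T: float = DEFAULT_TEMPERATURE,
) -> dict[int, float]:
    """Per-residue T*S (kJ/mol) on a common relative scale.

    The additive constant is immaterial: downstream shell profiles
    re-reference to their minimum. Higher O2 maps strictly to lower
    entropy.
    """
    out = {}
    for r in table.records:
        s = R_GAS * (float(_cone_log_term(r.O2, f"(res {r.residue})"))
                     + np.log(np.pi))
        out[r.residue] = T * s / 1e3
    return out


def intercomplex_delta(values: Mapping[str, float]) -> dict[str, float]:
    """dP(A) = P(A) - (P(B)+P(C))/2 for exactly three labeled values.

    The three deltas sum to zero, and each equals 1.5x the deviation of
    its complex from the three-way mean.
    """
    if len(values) != 3:
        raise InvalidInputError("intercomplex comparison needs exactly 3 values")
    labels = list(values)
    out = {}
    for lab in labels:
        others = [values[o] for o in labels if o != lab]
        out[lab] = values[lab] - 0.5 * sum(others)
    return out


@dataclass
class EntropyReport:
    """Intercomplex -T*ddS terms (kJ/mol) for three complexes."""

    T: float
    bb: dict[str, float]
    sc: dict[str, float]
    bb_sd: dict[str, float]
    sc_sd: dict[str, float]

    @property
    def total(self) -> dict[str, float]:
        return {k: self.bb[k] + self.sc[k] for k in self.bb}

    @property
    def total_sd(self) -> dict[str, float]:
        return {k: float(np.hypot(self.bb_sd[k], self.sc_sd[k]))
                for k in self.bb_sd}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bb": self.bb, "bb_sd": self.bb_sd,
            "sc": self.sc, "sc_sd": self.sc_sd,
            "bb_plus_sc": self.total, "bb_plus_sc_sd": self.total_sd,
        })


def _common_subset(tables: Mapping[str, OrderParameterTable],
                   site_class: str) -> dict[str, OrderParameterTable]:
    """Listwise drop of sites missing in any complex."""
    key_sets = [set(k for k in t.keyed() if k[1] == site_class)
                for t in tables.values()]
    common = set.intersection(*key_sets)
    return {
        lab: OrderParameterTable(
            [r for r in t.records
             if (r.residue, r.site_class) in common])
        for lab, t in tables.items()
    }


def _complex_sums(tables: Mapping[str, OrderParameterTable],
                  site_class: str, T: float,
                  coeffs: Mapping[str, float]) -> dict[str, float]:
    """Per-complex -T*S sums (relative scale) for the given site class."""
    out = {}
    for lab, t in tables.items():
        ds = 0.0
        for r in t.records:
            if r.site_class != site_class:
                continue
            cm = 1.0
            if site_class == "methyl" and r.restype.upper() != "ALA":
                if r.restype.upper() not in coeffs:
                    raise InvalidInputError(
                        f"no side-chain coefficient for {r.restype!r}")
                cm = coeffs[r.restype.upper()]
            ds += cm * float(_cone_log_term(r.O2, f"(res {r.residue})"))
        out[lab] = -T * R_GAS * ds / 1e3
    return out


def entropy_report(
    tables: Mapping[str, OrderParameterTable],
    T: float = DEFAULT_TEMPERATURE,
    coeffs: Mapping[str, float] | None = None,
    n_mc: int = 500,
    rng: np.random.Generator | None = None,
) -> EntropyReport:
    """Full three-complex intercomplex entropy comparison with MC errors.

    Sites missing in any complex are dropped listwise before comparison.
    """
    if len(tables) != 3:
        raise InvalidInputError("need exactly three complexes")
    coeffs = CM_COEFFICIENTS if coeffs is None else coeffs
    rng = rng if rng is not None else np.random.default_rng()

    result: dict[str, dict[str, float]] = {}
    sds: dict[str, dict[str, float]] = {}
    for site_class, key in (("backbone", "bb"), ("methyl", "sc")):
        sub = _common_subset(tables, site_class)
        sums = _complex_sums(sub, site_class, T, coeffs)
        result[key] = intercomplex_delta(sums)
        sds[key] = entropy_mc_errors(sub, site_class, T, coeffs, n_mc, rng)
    return EntropyReport(T=T, bb=result["bb"], sc=result["sc"],
                         bb_sd=sds["bb"], sc_sd=sds["sc"])


def entropy_mc_errors(
    tables: Mapping[str, OrderParameterTable],
    site_class: str,
    T: float = DEFAULT_TEMPERATURE,
    coeffs: Mapping[str, float] | None = None,
    n_mc: int = 500,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """SD of each intercomplex delta from O2 resampling.

    O2 values are resampled from normal distributions with the stated
    per-site sds (clipped to [0, 1)), the entropy sums recomputed, and
    the SD over ``n_mc`` resamples reported.
    """
    coeffs = CM_COEFFICIENTS if coeffs is None else coeffs
    rng = rng if rng is not None else np.random.default_rng()
    labels = list(tables)
    draws: dict[str, list[float]] = {lab: [] for lab in labels}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipping warnings inside resamples
        for _ in range(n_mc):
            perturbed = {}
            for lab, t in tables.items():
                recs = []
                for r in t.records:
                    o2 = float(np.clip(rng.normal(r.O2, r.sd) if r.sd > 0
                                       else r.O2, 0.0, _O2_CLIP))
                    recs.append(OrderParameterRecord(
                        r.residue, r.restype, r.site_class, o2, r.sd))
                perturbed[lab] = OrderParameterTable(recs)
            sums = _complex_sums(perturbed, site_class, T, coeffs)
            deltas = intercomplex_delta(sums)
            for lab in labels:
                draws[lab].append(deltas[lab])
    return {lab: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            for lab, v in draws.items()}
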