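"""Radial distribution of per-residue entropy around a bound ligand.

Residues are binned into concentric shells by the shortest distance
between any of their atoms and any ligand atom: 1 Angstrom-wide shells
from 2 to 9 A, then 2 A-wide shells out to 27 A. Shell means are
referenced so the lowest shell mean is zero; the cumulative curve at a
shell's midpoint is the running mean over all residues up to and
including that shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_EDGES = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0,
                 11.0, 13.0, 15.0, 17.0, 19.0, 21.0, 23.0, 25.0, 27.0)


class InvalidInputError(ValueError):
    pass


@dataclass(frozen=True)
class ShellScheme:
    """Concentric-shell edges (A). Membership is half-open [lower, upper)."""

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise InvalidInputError("edges must be strictly increasing, >=2")

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def n_shells(self) -> int:
        return len(self.edges) - 1

    def assign(self, distance: float) -> int | None:
        """Shell index for a distance; None beyond the outermost edge.

        Distances below the innermost edge (physically unexpected) go to
        the innermost shell with a warning.
        """
        e = self.edges
        if distance < e[0]:
            warnings.warn(
                f"distance {distance:.2f} A below the innermost edge "
                f"{e[0]} A; assigned to the innermost shell")
            return 0
        if distance >= e[-1]:
            return None
        return int(np.searchsorted(np.asarray(e), distance, side="right") - 1)


@dataclass
class ShellProfile:
    """Referenced per-shell means and the cumulative per-residue curve."""

    scheme: ShellScheme
    mean_entropy: np.ndarray  # per shell, min shell = 0; NaN for empty shells
    counts: np.ndarray
    cumulative: np.ndarray  # at shell midpoints; NaN until first occupied shell
    reference: float  # subtracted raw minimum shell mean

    def to_frame(self) -> pd.DataFrame:
        e = np.asarray(self.scheme.edges)
        return pd.DataFrame({
            "shell_lo": e[:-1],
            "shell_hi": e[1:],
            "midpoint": self.scheme.midpoints,
            "n_residues": self.counts,
            "mean_mTdS": self.mean_entropy,
            "cumulative": self.cumulative,
        })


def residue_ligand_distances(
    structure,  # path or gemmi.Structure
    ligand_selector: str = "LIG",
) -> dict[int, float]:
    """Minimum atom-atom distance (A) from each protein residue to the ligand.

    ``ligand_selector`` is the ligand residue name. Distances use every
    atom present in the model (heavy atoms plus any modelled hydrogens);
    no hydrogens are added. Waters are ignored.
    """
    import gemmi

    if not isinstance(structure, gemmi.Structure):
        structure = gemmi.read_structure(str(structure))
    model = structure[0]
    lig_xyz = []
    res_atoms: dict[int, list] = {}
    for chain in model:
        for res in chain:
            if res.name == ligand_selector:
                lig_xyz.extend([[a.pos.x, a.pos.y, a.pos.z] for a in res])
            elif res.name in ("HOH", "WAT", "DOD"):
                continue
            else:
                res_atoms.setdefault(res.seqid.num, []).extend(
                    [[a.pos.x, a.pos.y, a.pos.z] for a in res])
    if not lig_xyz:
        raise InvalidInputError(
            f"no ligand atoms matched residue name {ligand_selector!r}")
    lig = np.asarray(lig_xyz)
    out = {}
    for resnum, atoms in res_atoms.items():
        xyz = np.asarray(atoms)
        d = np.linalg.norm(xyz[:, None, :] - lig[None, :, :], axis=2)
        out[resnum] = float(d.min())
    return out


def build_profile(
    entropy: Mapping[int, float],
    distances: Mapping[int, float],
    scheme: ShellScheme | None = None,
) -> ShellProfile:
    """Bin per-residue entropies into shells and build the radial profile.

    Shell means are referenced to the minimum occupied shell; empty
    shells are recorded as NaN (missing), not zero. Residues beyond the
    outermost edge are excluded. The cumulative value at shell j's
    midpoint is the raw mean over residues of shells 0..j.
    """
    scheme = scheme if scheme is not None else ShellScheme()
    missing = set(entropy) ^ set(distances)
    if missing:
        raise InvalidInputError(
            f"entropy and distances must share residues; unmatched: "
            f"{sorted(missing)}")
    members: list[list[float]] = [[] for _ in range(scheme.n_shells)]
    for resnum in sorted(entropy):
        idx = scheme.assign(distances[resnum])
        if idx is None:
            continue
        members[idx].append(entropy[resnum])
    means = np.array([np.mean(m) if m else np.nan for m in members])
    counts = np.array([len(m) for m in members])
    if np.all(np.isnan(means)):
        raise InvalidInputError("no residues fall inside the shell scheme")
    ref = float(np.nanmin(means))
    cum = np.full(scheme.n_shells, np.nan)
    acc: list[float] = []
    for j in range(scheme.n_shells):
        acc.extend(members[j])
        if acc:
            cum[j] = float(np.mean(acc))
    return ShellProfile(scheme=scheme, mean_entropy=means - ref,
                        counts=counts, cumulative=cum, reference=ref)
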