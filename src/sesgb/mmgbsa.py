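"""Single-trajectory MM-GBSA end-point binding free energies.

Per snapshot, the effective binding energy is decomposed as

    ΔG_effective = ΔE_el + ΔE_LJ + ΔΔG_pol + ΔΔG_np

where ΔE_el / ΔE_LJ are the gas-phase receptor–ligand Coulomb and
Lennard-Jones interactions, and the ΔΔ solvation terms are the change upon
binding (complex minus receptor minus ligand, all conformations taken from
the same complex snapshot — the single-trajectory protocol, under which
intramolecular gas-phase terms cancel).  Averaging over snapshots and adding
the externally supplied configurational-entropy term −TΔS_conf, minus a
1.92 kcal/mol translational-entropy standard-state offset, yields ΔG_bind⁰.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .boundary import compute_sasa
from .constants import COULOMB_K
from .gb_energy import SolventParams, polar_solvation
from .model_io import RadiiSet, Solute, TrajectorySnapshot, assign_radii

__all__ = [
    "LJParams",
    "NonpolarParams",
    "Partition",
    "BindingComponents",
    "load_lj_sidecar",
    "gas_phase_interaction",
    "nonpolar_energy",
    "snapshot_components",
    "mmgbsa_average",
]

#: Default translational-entropy offset (kcal/mol) subtracted from −TΔS_conf
#: to move the gas-phase standard state to the 1 M solution standard state.
ENTROPY_OFFSET = 1.92


@dataclass(frozen=True)
class LJParams:
    """Per-atom Lennard-Jones σ (Å) and ε (kcal/mol); Lorentz–Berthelot mixing."""

    sigma: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self):
        if len(self.sigma) != len(self.epsilon):
            raise ValueError("sigma/epsilon length mismatch")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be nonnegative")


@dataclass(frozen=True)
class NonpolarParams:
    """ΔG_np = γ·SASA + offset; γ defaults to 0.005 kcal/mol/Ų, offset 0."""

    gamma: float = 0.005
    offset: float = 0.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("surface tension gamma must be nonnegative")


@dataclass(frozen=True)
class Partition:
    """Disjoint receptor/ligand atom-index sets covering the complex."""

    receptor: np.ndarray
    ligand: np.ndarray

    def __post_init__(self):
        r = set(int(i) for i in self.receptor)
        l = set(int(i) for i in self.ligand)
        if not r or not l:
            raise ValueError("receptor and ligand selections must be nonempty")
        if r & l:
            raise ValueError("receptor and ligand selections overlap")

    def validate_cover(self, n_atoms: int) -> None:
        union = set(int(i) for i in self.receptor) | set(int(i) for i in self.ligand)
        if union != set(range(n_atoms)):
            raise ValueError("partition does not cover the complex exactly")


@dataclass(frozen=True)
class BindingComponents:
    """Binding free-energy decomposition (kcal/mol).

    Per-snapshot instances leave the entropy fields at None; aggregates fill
    them and carry per-component standard errors of the mean.
    """

    dE_el: float
    dE_LJ: float
    ddG_pol: float
    ddG_np: float
    dG_effective: float
    minus_TdS_conf: float | None = None
    entropy_offset: float | None = None
    dG_bind0: float | None = None
    n_snapshots: int = 1
    stderr: dict | None = None

    def as_dict(self) -> dict:
        d = {
            "dE_el": self.dE_el,
            "dE_LJ": self.dE_LJ,
            "ddG_pol": self.ddG_pol,
            "ddG_np": self.ddG_np,
            "dG_effective": self.dG_effective,
            "minus_TdS_conf": self.minus_TdS_conf,
            "entropy_offset": self.entropy_offset,
            "dG_bind0": self.dG_bind0,
            "n_snapshots": self.n_snapshots,
        }
        if self.stderr is not None:
            d["stderr"] = self.stderr
        return d


def load_lj_sidecar(path: str | Path, solute: Solute) -> LJParams:
    """Read a JSON sidecar mapping atom serial → {sigma, epsilon}."""
    with open(path) as fh:
        table = json.load(fh)
    sigma = np.empty(solute.n_atoms)
    eps = np.empty(solute.n_atoms)
    for i, serial in enumerate(solute.serials):
        key = str(int(serial))
        if key not in table:
            raise KeyError(f"LJ sidecar missing entry for atom serial {serial}")
        sigma[i] = float(table[key]["sigma"])
        eps[i] = float(table[key]["epsilon"])
    return LJParams(sigma=sigma, epsilon=eps)


def gas_phase_interaction(
    complex_: Solute, part: Partition, lj: LJParams
) -> tuple[float, float]:
    """Vacuum receptor–ligand Coulomb and LJ interaction energies (no cutoff)."""
    if len(lj.sigma) != complex_.n_atoms:
        raise ValueError("LJ parameters must cover every atom of the complex")
    ri = np.asarray(part.receptor, dtype=int)
    li = np.asarray(part.ligand, dtype=int)
    dr = complex_.positions[ri][:, None, :] - complex_.positions[li][None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", dr, dr))
    if np.any(r == 0.0):
        raise ValueError("coincident receptor/ligand atom pair (zero distance)")
    qq = np.outer(complex_.charges[ri], complex_.charges[li])
    de_el = COULOMB_K * float(np.sum(qq / r))
    sig = 0.5 * (lj.sigma[ri][:, None] + lj.sigma[li][None, :])
    eps = np.sqrt(np.outer(lj.epsilon[ri], lj.epsilon[li]))
    sr6 = (sig / r) ** 6
    de_lj = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    return de_el, de_lj


def nonpolar_energy(sasa: float, np_params: NonpolarParams = NonpolarParams()) -> float:
    """Nonpolar solvation energy γ·SASA + offset, kcal/mol."""
    if sasa < 0:
        raise ValueError("SASA must be nonnegative")
    return np_params.gamma * sasa + np_params.offset


def snapshot_components(
    complex_: Solute,
    snap: TrajectorySnapshot,
    part: Partition,
    radii: RadiiSet,
    sp: SolventParams = SolventParams(),
    lj: LJParams | None = None,
    np_params: NonpolarParams = NonpolarParams(),
    h: float = 0.5,
    sasa_points: int = 960,
) -> BindingComponents:
    """All binding components for one snapshot (entropy fields unset)."""
    part.validate_cover(complex_.n_atoms)
    comp = assign_radii(complex_.with_positions(snap.positions), radii)
    if lj is None:
        lj = LJParams(
            sigma=np.full(comp.n_atoms, 3.0), epsilon=np.zeros(comp.n_atoms)
        )
    de_el, de_lj = gas_phase_interaction(comp, part, lj)

    rec = comp.subset(part.receptor, label=comp.label + "/receptor")
    lig = comp.subset(part.ligand, label=comp.label + "/ligand")

    probe = radii.rho_w
    anchor = comp.positions.mean(axis=0)  # shared grid alignment for the deltas
    ddg_pol = (
        polar_solvation(comp, sp=sp, h=h, probe=probe, anchor=anchor).dg_pol
        - polar_solvation(rec, sp=sp, h=h, probe=probe, anchor=anchor).dg_pol
        - polar_solvation(lig, sp=sp, h=h, probe=probe, anchor=anchor).dg_pol
    )
    sasa_c = compute_sasa(comp, probe=probe, n_points=sasa_points).total_area
    sasa_r = compute_sasa(rec, probe=probe, n_points=sasa_points).total_area
    sasa_l = compute_sasa(lig, probe=probe, n_points=sasa_points).total_area
    ddg_np = (
        nonpolar_energy(sasa_c, np_params)
        - nonpolar_energy(sasa_r, np_params)
        - nonpolar_energy(sasa_l, np_params)
    )
    return BindingComponents(
        dE_el=de_el,
        dE_LJ=de_lj,
        ddG_pol=ddg_pol,
        ddG_np=ddg_np,
        dG_effective=de_el + de_lj + ddg_pol + ddg_np,
    )


def mmgbsa_average(
    components: Sequence[BindingComponents],
    minus_TdS_conf: float | Sequence[float] = 0.0,
    entropy_offset: float = ENTROPY_OFFSET,
) -> BindingComponents:
    """Average per-snapshot components and apply the entropy term.

    ΔG_bind⁰ = ⟨ΔG_effective⟩ + (−TΔS_conf − offset).  The entropy term may
    be a scalar or a per-snapshot series (then its mean is used); it is
    computed externally (e.g. by normal-mode analysis) and accepted as input.
    """
    if len(components) == 0:
        raise ValueError("need at least one snapshot")
    fields = ("dE_el", "dE_LJ", "ddG_pol", "ddG_np", "dG_effective")
    arrays = {f: np.array([getattr(c, f) for c in components]) for f in fields}
    means = {f: float(a.mean()) for f, a in arrays.items()}
    n = len(components)
    stderr = {
        f: float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        for f, a in arrays.items()
    }
    tds = np.atleast_1d(np.asarray(minus_TdS_conf, dtype=float))
    tds_mean = float(tds.mean())
    return BindingComponents(
        dE_el=means["dE_el"],
        dE_LJ=means["dE_LJ"],
        ddG_pol=means["ddG_pol"],
        ddG_np=means["ddG_np"],
        dG_effective=means["dG_effective"],
        minus_TdS_conf=tds_mean,
        entropy_offset=entropy_offset,
        dG_bind0=means["dG_effective"] + tds_mean - entropy_offset,
        n_snapshots=n,
        stderr=stderr,
    )
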