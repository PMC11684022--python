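"""Effective Born radii from the SES boundary and ALPB polar solvation energy.

The effective Born radius of atom i is computed from the boundary patch set
by the R6 surface prescription,

    R_i^(-3) = (1/4π) Σ_p [(c_p − x_i)·n̂_p / |c_p − x_i|^6] · area_p,

which by the divergence theorem equals the volume integral
(3/4π) ∫_solvent |r − x_i|^(-6) dV and is exact for a spherical boundary
(R equals the sphere radius for the central atom).  Pairs then interact
through the canonical Still f_GB, and the total polar solvation energy uses
the ALPB correction, which restores the proper dependence on both dielectric
constants via the solute electrostatic size A.  Monovalent salt enters as
Debye–Hückel screening of the solvent term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .boundary import DielectricGrid, SurfacePatchSet, build_dielectric_grid, extract_surface_patches
from .constants import ALPB_ALPHA, COULOMB_K, DEBYE_KAPPA_COEFF
from .model_io import RadiiSet, Solute, assign_radii

__all__ = [
    "SolventParams",
    "ALPBParams",
    "BornRadiiResult",
    "PolarEnergyResult",
    "effective_born_radii",
    "gb_pair_function",
    "electrostatic_size",
    "alpb_polar_energy",
    "polar_solvation",
]


@dataclass(frozen=True)
class SolventParams:
    """Continuum solvent description.

    Defaults mirror aqueous MM-GBSA practice: solute dielectric 1, solvent
    dielectric 80, physiological 0.154 M monovalent salt.
    """

    eps_in: float = 1.0
    eps_out: float = 80.0
    salt_molar: float = 0.154
    temperature: float = 298.15

    def __post_init__(self):
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("require eps_out > eps_in >= 1")
        if self.salt_molar < 0:
            raise ValueError("salt concentration must be nonnegative")

    @property
    def kappa(self) -> float:
        """Debye screening constant, Å⁻¹."""
        return math.sqrt(DEBYE_KAPPA_COEFF * self.salt_molar)


@dataclass(frozen=True)
class ALPBParams:
    """ALPB constants: α, β = ε_in/ε_out, and electrostatic size A (Å)."""

    beta: float
    A: float
    alpha: float = ALPB_ALPHA

    def __post_init__(self):
        if self.A <= 0:
            raise ValueError("electrostatic size A must be positive")
        if not (0 < self.beta < 1):
            raise ValueError("beta = eps_in/eps_out must lie in (0, 1)")


@dataclass(frozen=True)
class BornRadiiResult:
    radii: np.ndarray  # (n,) Å
    h: float  # grid spacing used, Å
    clamped: tuple = ()  # indices whose raw R6 integral was nonpositive


@dataclass(frozen=True)
class PolarEnergyResult:
    dg_pol: float  # kcal/mol
    born: BornRadiiResult | None = None
    electrostatic_size_A: float | None = None
    pairwise: np.ndarray | None = None  # (n, n) kcal/mol, on request


def effective_born_radii(
    solute: Solute, patches: SurfacePatchSet, h: float | None = None
) -> BornRadiiResult:
    """R6 patch-sum effective Born radii for every atom.

    Atoms whose raw integral is nonpositive (possible near staircase
    artifacts) are clamped to their intrinsic radius and reported in
    ``clamped`` rather than aborting the calculation.
    """
    if patches.n_patches == 0:
        raise ValueError("patch set is empty")
    centers = patches.centers
    normals = patches.normals
    area = patches.area
    n = solute.n_atoms
    out = np.empty(n)
    clamped = []
    for i in range(n):
        d = centers - solute.positions[i]
        r2 = np.einsum("ij,ij->i", d, d)
        proj = np.einsum("ij,ij->i", d, normals)
        integral = (area / (4.0 * math.pi)) * np.sum(proj / r2**3)
        if integral <= 0.0 or not np.isfinite(integral):
            out[i] = solute.radii[i]
            clamped.append(i)
        else:
            out[i] = integral ** (-1.0 / 3.0)
    return BornRadiiResult(
        radii=out, h=h if h is not None else area**0.5, clamped=tuple(clamped)
    )


def gb_pair_function(r, Ri, Rj):
    """Still's interpolating distance f_GB = sqrt(r² + RiRj·exp(−r²/4RiRj))."""
    r2 = np.asarray(r, dtype=float) ** 2
    rr = np.multiply(Ri, Rj)
    return np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))


def electrostatic_size(solute: Solute, grid: DielectricGrid) -> float:
    """Electrostatic size A (Å) from the SES volume: A = (3V/4π)^(1/3).

    Exact for a spherical solute; used in the ALPB energy expression.
    """
    vol = grid.solute_volume
    if vol <= 0:
        raise ValueError("grid has no solute voxels; electrostatic size undefined")
    return (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)


def alpb_polar_energy(
    solute: Solute,
    born: BornRadiiResult,
    sp: SolventParams,
    alpb: ALPBParams | None,
    want_pairwise: bool = False,
) -> PolarEnergyResult:
    """Polar solvation free energy, kcal/mol.

    With ``alpb`` set, the ALPB-corrected GB expression is used; with
    ``alpb=None`` the canonical Still GB (conductor-like 1/f dependence on
    the dielectrics) is recovered, which is useful for testing.
    """
    if len(born.radii) != solute.n_atoms:
        raise ValueError("Born radii count does not match atom count")
    q = solute.charges
    R = born.radii
    pos = solute.positions
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    f = gb_pair_function(r, R[:, None], R[None, :])
    kappa = sp.kappa
    # per-pair dielectric factor with Debye–Hückel screening of the solvent
    dielec = 1.0 / sp.eps_in - np.exp(-kappa * f) / sp.eps_out
    if alpb is None:
        kernel = 1.0 / f
        scale = 1.0
    else:
        ab = alpb.alpha * alpb.beta
        kernel = 1.0 / f + ab / alpb.A
        scale = 1.0 / (1.0 + ab)
    qq = np.outer(q, q)
    terms = -(COULOMB_K / 2.0) * scale * dielec * qq * kernel
    dg = float(terms.sum())
    return PolarEnergyResult(
        dg_pol=dg,
        born=born,
        electrostatic_size_A=None if alpb is None else alpb.A,
        pairwise=terms if want_pairwise else None,
    )


def polar_solvation(
    solute: Solute,
    radii: RadiiSet | None = None,
    sp: SolventParams = SolventParams(),
    h: float = 0.5,
    use_alpb: bool = True,
    probe: float | None = None,
    anchor: np.ndarray | None = None,
) -> PolarEnergyResult:
    """Convenience chain: radii → SES grid → patches → Born radii → ΔG_pol.

    If ``radii`` is given, intrinsic radii are (re)assigned from it and its
    water-probe radius is used; otherwise the solute's current radii are used
    with an explicit ``probe`` (default 1.4 Å).  ``anchor`` pins the grid
    alignment (see :func:`sesgb.boundary.build_dielectric_grid`).
    """
    if radii is not None:
        solute = assign_radii(solute, radii)
        probe_r = radii.rho_w
    else:
        probe_r = 1.4 if probe is None else probe
    grid = build_dielectric_grid(solute, probe=probe_r, h=h, anchor=anchor)
    patches = extract_surface_patches(grid)
    born = effective_born_radii(solute, patches, h=h)
    alpb = None
    if use_alpb:
        A = electrostatic_size(solute, grid)
        alpb = ALPBParams(beta=sp.eps_in / sp.eps_out, A=A)
    res = alpb_polar_energy(solute, born, sp, alpb)
    return PolarEnergyResult(
        dg_pol=res.dg_pol,
        born=born,
        electrostatic_size_A=alpb.A if alpb else None,
    )
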