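"""Effective Born radii and ALPB polar energies against closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sesgb.boundary import build_dielectric_grid, extract_surface_patches
from sesgb.constants import COULOMB_K
from sesgb.fixtures import born_polar_energy, make_born_ion, make_two_sphere
from sesgb.gb_energy import (
    ALPBParams,
    BornRadiiResult,
    SolventParams,
    alpb_polar_energy,
    effective_born_radii,
    electrostatic_size,
    gb_pair_function,
    polar_solvation,
)
from sesgb.model_io import Atom, Solute, element_mass


def _patches(solute, probe, h):
    return extract_surface_patches(build_dielectric_grid(solute, probe, h))


# ---- f_GB ---------------------------------------------------------------


def test_gb_pair_function_self_term():
    assert gb_pair_function(0.0, 2.0, 2.0) == pytest.approx(2.0)


def test_gb_pair_function_asymptotic():
    r = 20.0 * math.sqrt(1.5 * 2.5)
    assert gb_pair_function(r, 1.5, 2.5) == pytest.approx(r, rel=1e-6)


@settings(deadline=None, derandomize=True)
@given(
    r=st.floats(0.0, 30.0),
    a=st.floats(0.5, 4.0),
    b=st.floats(0.5, 4.0),
)
def test_gb_pair_function_symmetric_and_bounded(r, a, b):
    fab = gb_pair_function(r, a, b)
    fba = gb_pair_function(r, b, a)
    assert fab == pytest.approx(fba, rel=1e-12)
    assert fab >= r  # f_GB interpolates above the bare distance


# ---- Born radii ---------------------------------------------------------


def test_born_radius_of_lone_sphere():
    ion = make_born_ion(1.0, 2.0)
    res = effective_born_radii(ion, _patches(ion, 1.4, 0.25), h=0.25)
    assert res.radii[0] == pytest.approx(2.0, rel=0.05)
    assert not res.clamped


def test_born_radius_off_center_matches_volume_integral():
    """Patch-sum radii for atoms inside a spherical solute vs direct voxel
    quadrature of (3/4π)∫_solvent |r−x|⁻⁶ dV (plus the analytic far tail)."""
    L, h = 3.0, 0.25
    big = Atom(1, "C", "C1", np.zeros(3), 0.0, L, 12.011)
    probes = [
        Atom(2 + k, "H", f"H{k}", np.array([0.0, 0.0, d]), 0.0, 0.1, 1.008)
        for k, d in enumerate((0.0, 1.0, 2.0))
    ]
    solute = Solute.from_atoms([big] + probes)
    grid = build_dielectric_grid(solute, probe=0.0, h=h)
    res = effective_born_radii(solute, extract_surface_patches(grid), h=h)
    # oracle: voxel quadrature over solvent within a ball of radius B around
    # each atom (B = distance to the nearest grid face), analytic beyond
    axes = [grid.voxel_centers_1d(a) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    solvent = ~grid.solute_mask
    pts = np.column_stack([X[solvent], Y[solvent], Z[solvent]])
    lo = np.array([ax[0] for ax in axes])
    hi = np.array([ax[-1] for ax in axes])
    for atom_idx, atom in enumerate(solute.atoms):
        x = atom.position
        B = float(min(np.min(x - lo), np.min(hi - x)))
        d2 = np.einsum("ij,ij->i", pts - x, pts - x)
        inside = d2 <= B * B
        integral = float(np.sum(d2[inside] ** -3)) * h**3 + (4 * math.pi) / (
            3 * B**3
        )
        oracle = (3.0 / (4.0 * math.pi) * integral) ** (-1.0 / 3.0)
        assert res.radii[atom_idx] == pytest.approx(oracle, rel=0.05)


def test_buried_atom_has_larger_born_radius():
    # clustered shell of atoms around a central one: burial inflates R
    rng = np.random.default_rng(1)
    shell = []
    for k in range(14):
        v = rng.normal(size=3)
        v *= 2.6 / np.linalg.norm(v)
        shell.append(Atom(2 + k, "C", f"C{k}", v, 0.0, 1.7, 12.011))
    center = Atom(1, "C", "C0", np.zeros(3), 0.0, 1.7, 12.011)
    solute = Solute.from_atoms([center] + shell)
    res = effective_born_radii(solute, _patches(solute, 1.4, 0.5), h=0.5)
    assert res.radii[0] > 1.7 * 1.5  # well above intrinsic
    assert res.radii[0] > np.mean(res.radii[1:])


def test_born_radius_grid_refinement_converges():
    ion = make_born_ion(1.0, 2.0)
    errors = []
    for h in (1.0, 0.5, 0.25):
        res = effective_born_radii(ion, _patches(ion, 1.4, h), h=h)
        errors.append(abs(res.radii[0] - 2.0))
    assert errors[0] >= errors[1] >= errors[2]


# ---- electrostatic size -------------------------------------------------


def test_electrostatic_size_sphere_and_scaling():
    ion = make_born_ion(1.0, 2.0)
    grid = build_dielectric_grid(ion, 1.4, 0.25)
    A = electrostatic_size(ion, grid)
    assert A == pytest.approx(2.0, rel=0.05)
    doubled = make_born_ion(1.0, 4.0)
    A2 = electrostatic_size(doubled, build_dielectric_grid(doubled, 1.4, 0.25))
    assert A2 == pytest.approx(2 * A, rel=0.05)


def test_electrostatic_size_two_disjoint_spheres():
    pair = make_two_sphere(1.5, 1.5, 12.0)
    A = electrostatic_size(pair, build_dielectric_grid(pair, 1.4, 0.25))
    assert A == pytest.approx((2 * 1.5**3) ** (1 / 3), rel=0.05)


# ---- ALPB energy --------------------------------------------------------


def test_alpb_reduces_to_born_when_A_equals_R(born_ion, saltless):
    born = BornRadiiResult(radii=np.array([2.0]), h=0.0)
    alpb = ALPBParams(beta=1.0 / 80.0, A=2.0)
    res = alpb_polar_energy(born_ion, born, saltless, alpb)
    assert res.dg_pol == pytest.approx(-81.98, abs=0.01)
    assert res.dg_pol == pytest.approx(born_polar_energy(1.0, 2.0), rel=1e-6)


def test_polar_energy_zero_for_neutral(saltless):
    ion = make_born_ion(0.0, 2.0)
    born = BornRadiiResult(radii=np.array([2.0]), h=0.0)
    res = alpb_polar_energy(ion, born, saltless, ALPBParams(beta=1 / 80, A=2.0))
    assert res.dg_pol == 0.0


def test_distant_charges_superpose(saltless):
    """Far-apart ions: f_GB → r, so the energy is two Born terms plus the
    exactly screened cross interaction, vanishing as r grows."""
    born = BornRadiiResult(radii=np.array([2.0, 2.0]), h=0.0)
    for r, tol in ((50.0, None), (500.0, 0.005)):
        pair = make_two_sphere(2.0, 2.0, r, q1=1.0, q2=1.0)
        res = alpb_polar_energy(pair, born, saltless, alpb=None)
        closed = 2 * born_polar_energy(1.0, 2.0) - COULOMB_K * (1 - 1 / 80.0) / r
        assert res.dg_pol == pytest.approx(closed, rel=1e-6)
        if tol is not None:
            assert res.dg_pol == pytest.approx(
                2 * born_polar_energy(1.0, 2.0), rel=tol
            )


def test_full_chain_born_ion_and_grid_convergence(born_ion, saltless):
    errors = []
    for h in (1.0, 0.5, 0.25):
        dg = polar_solvation(born_ion, sp=saltless, h=h, probe=1.4).dg_pol
        errors.append(abs(dg - born_polar_energy(1.0, 2.0)))
    assert errors[0] >= errors[1] >= errors[2]
    assert errors[2] / 81.98 < 0.05


def test_translation_invariance(saltless, toy_solute):
    from sesgb.model_io import assign_radii, get_radii_set

    s = assign_radii(toy_solute, get_radii_set("BONDI"))
    base = polar_solvation(s, sp=saltless, h=0.5, probe=1.4).dg_pol
    shifted = s.with_positions(s.positions + np.array([3.7, -2.1, 0.4]))
    moved = polar_solvation(shifted, sp=saltless, h=0.5, probe=1.4).dg_pol
    assert moved == pytest.approx(base, abs=1e-3)


def test_atom_reordering_invariance(saltless):
    pair = make_two_sphere(2.0, 1.5, 3.0, q1=0.6, q2=-0.6)
    rev = pair.subset([1, 0])
    a = polar_solvation(pair, sp=saltless, h=0.5, probe=1.4).dg_pol
    b = polar_solvation(rev, sp=saltless, h=0.5, probe=1.4).dg_pol
    assert a == pytest.approx(b, abs=1e-9)


def test_solvent_dielectric_monotonicity(born_ion):
    dg80 = polar_solvation(
        born_ion, sp=SolventParams(eps_out=80.0, salt_molar=0.0), h=0.5
    ).dg_pol
    dg1000 = polar_solvation(
        born_ion, sp=SolventParams(eps_out=1000.0, salt_molar=0.0), h=0.5
    ).dg_pol
    assert dg1000 < dg80 < 0
    # conductor bound: finite eps_out can never beat the conductor limit
    cond = dg1000 * (1.0) / (1.0 - 1.0 / 1000.0)
    assert abs(dg80) <= abs(cond) + 1e-9


def test_salt_screening_favors_charged_solute(born_ion):
    fresh = polar_solvation(born_ion, sp=SolventParams(salt_molar=0.0), h=0.5).dg_pol
    salty = polar_solvation(born_ion, sp=SolventParams(salt_molar=0.154), h=0.5).dg_pol
    saltier = polar_solvation(born_ion, sp=SolventParams(salt_molar=1.0), h=0.5).dg_pol
    assert saltier <= salty <= fresh


def test_polar_energy_nonpositive_for_charged(saltless, toy_complex):
    solute, _, _ = toy_complex
    from sesgb.model_io import assign_radii, get_radii_set

    s = assign_radii(solute, get_radii_set("OPT_BIND5D"))
    res = polar_solvation(s, sp=saltless, h=0.5, probe=1.35)
    assert res.dg_pol < 0
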