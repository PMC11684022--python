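"""MM-GBSA decomposition: closed forms, identities, and physical limits."""

import numpy as np
import pytest

from sesgb.fixtures import make_toy_complex
from sesgb.gb_energy import SolventParams
from sesgb.mmgbsa import (
    BindingComponents,
    LJParams,
    NonpolarParams,
    Partition,
    gas_phase_interaction,
    load_lj_sidecar,
    mmgbsa_average,
    nonpolar_energy,
    snapshot_components,
)
from sesgb.model_io import TrajectorySnapshot, get_radii_set
from sesgb.fixtures import make_two_sphere


RADII = get_radii_set("OPT_BIND5D")


def _uniform_lj(n, sigma=3.0, eps=0.0):
    return LJParams(sigma=np.full(n, sigma), epsilon=np.full(n, eps))


# ---- gas phase ----------------------------------------------------------


def test_coulomb_closed_form():
    pair = make_two_sphere(2.0, 2.0, 10.0, q1=1.0, q2=1.0)
    part = Partition(receptor=np.array([0]), ligand=np.array([1]))
    de_el, de_lj = gas_phase_interaction(pair, part, _uniform_lj(2))
    assert de_el == pytest.approx(33.20636, abs=1e-4)
    assert de_lj == 0.0


def test_lj_root_and_minimum():
    part = Partition(receptor=np.array([0]), ligand=np.array([1]))
    sigma = 3.0
    at_sigma = make_two_sphere(1.5, 1.5, sigma)
    _, lj0 = gas_phase_interaction(at_sigma, part, _uniform_lj(2, sigma, 0.1))
    assert lj0 == pytest.approx(0.0, abs=1e-12)
    at_min = make_two_sphere(1.5, 1.5, sigma * 2 ** (1 / 6))
    _, ljm = gas_phase_interaction(at_min, part, _uniform_lj(2, sigma, 0.1))
    assert ljm == pytest.approx(-0.1, rel=1e-9)  # well depth ε


def test_zero_charges_zero_epsilon():
    pair = make_two_sphere(1.5, 1.5, 4.0)
    part = Partition(receptor=np.array([0]), ligand=np.array([1]))
    assert gas_phase_interaction(pair, part, _uniform_lj(2)) == (0.0, 0.0)


def test_coincident_cross_atoms_rejected():
    pair = make_two_sphere(1.5, 1.5, 0.0)
    part = Partition(receptor=np.array([0]), ligand=np.array([1]))
    with pytest.raises(ValueError, match="coincident"):
        gas_phase_interaction(pair, part, _uniform_lj(2))


def test_partition_validation():
    with pytest.raises(ValueError):
        Partition(receptor=np.array([0, 1]), ligand=np.array([1, 2]))
    with pytest.raises(ValueError):
        Partition(receptor=np.array([], dtype=int), ligand=np.array([0]))
    part = Partition(receptor=np.array([0]), ligand=np.array([1]))
    with pytest.raises(ValueError):
        part.validate_cover(3)


# ---- nonpolar -----------------------------------------------------------


@pytest.mark.parametrize(
    "sasa,gamma,offset,expected",
    [(100.0, 0.005, 0.0, 0.5), (0.0, 0.005, 0.0, 0.0), (100.0, 0.0072, 0.0, 0.72)],
)
def test_nonpolar_energy_arithmetic(sasa, gamma, offset, expected):
    assert nonpolar_energy(sasa, NonpolarParams(gamma, offset)) == pytest.approx(expected)


# ---- snapshot components ------------------------------------------------


def test_eq3_identity_and_component_oracle(toy_complex, saltless):
    solute, part, lj = toy_complex
    snap = TrajectorySnapshot(0, solute.positions)
    comps = snapshot_components(solute, snap, part, RADII, sp=saltless, lj=lj)
    assert comps.dG_effective == pytest.approx(
        comps.dE_el + comps.dE_LJ + comps.ddG_pol + comps.ddG_np, abs=1e-9
    )
    # oracle: recompute each term with the underlying modules directly
    from sesgb.boundary import compute_sasa
    from sesgb.gb_energy import polar_solvation
    from sesgb.model_io import assign_radii

    s = assign_radii(solute, RADII)
    de_el, de_lj = gas_phase_interaction(s, part, lj)
    assert comps.dE_el == pytest.approx(de_el, abs=1e-9)
    assert comps.dE_LJ == pytest.approx(de_lj, abs=1e-9)
    probe = RADII.rho_w
    anchor = s.positions.mean(axis=0)
    ddg_pol = (
        polar_solvation(s, sp=saltless, h=0.5, probe=probe, anchor=anchor).dg_pol
        - polar_solvation(
            s.subset(part.receptor), sp=saltless, h=0.5, probe=probe, anchor=anchor
        ).dg_pol
        - polar_solvation(
            s.subset(part.ligand), sp=saltless, h=0.5, probe=probe, anchor=anchor
        ).dg_pol
    )
    assert comps.ddG_pol == pytest.approx(ddg_pol, abs=1e-9)
    gamma = NonpolarParams().gamma
    ddg_np = gamma * (
        compute_sasa(s, probe=probe).total_area
        - compute_sasa(s.subset(part.receptor), probe=probe).total_area
        - compute_sasa(s.subset(part.ligand), probe=probe).total_area
    )
    assert comps.ddG_np == pytest.approx(ddg_np, abs=1e-9)


def test_noninteracting_limit(toy_complex, saltless):
    solute, part, lj = toy_complex
    for separation in (100.0, 500.0):
        pos = solute.positions.copy()
        pos[part.ligand] += np.array([0.0, 0.0, separation])
        snap = TrajectorySnapshot(0, pos)
        comps = snapshot_components(solute, snap, part, RADII, sp=saltless, lj=lj)
        for name in ("dE_el", "dE_LJ", "ddG_pol", "ddG_np", "dG_effective"):
            assert abs(getattr(comps, name)) < 0.05, (separation, name)


def test_salt_screens_polar_binding_term(toy_complex):
    """For a charged–charged complex the salt screens ΔΔG_pol (Debye–Hückel)."""
    solute, part, lj = toy_complex
    # give host and guest opposite net charges
    charges = solute.charges.copy()
    charges[part.receptor] += 1.0 / len(part.receptor)
    charges[part.ligand] -= 1.0 / len(part.ligand)
    from dataclasses import replace

    charged = replace(solute, charges=charges)
    snap = TrajectorySnapshot(0, charged.positions)
    fresh = snapshot_components(
        charged, snap, part, RADII, sp=SolventParams(salt_molar=0.0), lj=lj
    )
    salty = snapshot_components(
        charged, snap, part, RADII, sp=SolventParams(salt_molar=0.154), lj=lj
    )
    assert fresh.ddG_pol != pytest.approx(salty.ddG_pol, abs=1e-6)
    # salt stabilizes the separated ± ions more than the neutral complex,
    # raising the desolvation penalty and disfavoring charge–charge binding
    assert salty.ddG_pol > fresh.ddG_pol > 0


# ---- averaging ----------------------------------------------------------


def _components(dg):
    return BindingComponents(
        dE_el=dg / 2, dE_LJ=dg / 2, ddG_pol=0.0, ddG_np=0.0, dG_effective=dg
    )


def test_single_snapshot_no_entropy():
    agg = mmgbsa_average([_components(-10.0)], minus_TdS_conf=0.0, entropy_offset=0.0)
    assert agg.dG_bind0 == pytest.approx(-10.0)


def test_entropy_offset_arithmetic():
    agg = mmgbsa_average(
        [_components(-10.0), _components(-12.0)], minus_TdS_conf=5.0
    )
    assert agg.dG_bind0 == pytest.approx(-11.0 + 5.0 - 1.92)
    assert agg.n_snapshots == 2


def test_component_means_linear():
    rng = np.random.default_rng(8)
    rows = []
    for _ in range(20):
        vals = rng.normal(size=4)
        rows.append(
            BindingComponents(
                dE_el=vals[0],
                dE_LJ=vals[1],
                ddG_pol=vals[2],
                ddG_np=vals[3],
                dG_effective=float(vals.sum()),
            )
        )
    agg = mmgbsa_average(rows, minus_TdS_conf=0.0, entropy_offset=0.0)
    assert agg.dE_el == pytest.approx(np.mean([r.dE_el for r in rows]))
    assert agg.dG_effective == pytest.approx(
        agg.dE_el + agg.dE_LJ + agg.ddG_pol + agg.ddG_np, abs=1e-12
    )
    assert agg.stderr["dE_el"] > 0


def test_average_requires_snapshots():
    with pytest.raises(ValueError):
        mmgbsa_average([])


def test_lj_sidecar_round_trip(tmp_path, toy_complex):
    import json

    solute, _, lj = toy_complex
    sidecar = {
        str(int(s)): {"sigma": float(sg), "epsilon": float(ep)}
        for s, sg, ep in zip(solute.serials, lj.sigma, lj.epsilon)
    }
    p = tmp_path / "lj.json"
    p.write_text(json.dumps(sidecar))
    back = load_lj_sidecar(p, solute)
    np.testing.assert_allclose(back.sigma, lj.sigma)
    np.testing.assert_allclose(back.epsilon, lj.epsilon)
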