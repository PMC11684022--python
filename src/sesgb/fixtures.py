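"""Deterministic synthetic inputs for every stage of the pipeline.

These generators are first-class package code, not test helpers: they
produce analytically solvable solutes (Born ions, sphere pairs), toy
host–guest complexes with valid geometry and LJ sidecars, two-state
host–guest distance series with a controllable bound fraction, and
planted-radii training sets whose references are computed by this package's
own energy pipeline (so radii recovery has a known ground truth).  Every
generator is a pure function of its arguments: the same seed gives
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binding_kinetics import DistanceSeries
from .direct_optimizer import ObjectiveSpec, binding_polar_energy
from .gb_energy import SolventParams, polar_solvation
from .mmgbsa import LJParams, Partition
from .model_io import Atom, RadiiSet, Solute, element_mass

__all__ = [
    "FixtureSpec",
    "make_born_ion",
    "make_two_sphere",
    "make_toy_solute",
    "make_toy_complex",
    "make_distance_series",
    "make_training_set",
    "born_polar_energy",
]

#: Construction-time radii (Å) used only to guarantee non-overlapping
#: geometry; downstream code reassigns radii from a RadiiSet.
_BUILD_RADII = {"C": 1.70, "H": 1.20, "N": 1.55, "O": 1.50, "S": 1.80}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind + seed + kind-specific parameters."""

    kind: str  # born_ion | two_sphere | toy_complex | distance_series | training_set
    seed: int = 0
    parameters: dict = field(default_factory=dict)


def born_polar_energy(
    q: float, r: float, eps_in: float = 1.0, eps_out: float = 80.0
) -> float:
    """Closed-form Born ion polar solvation energy, kcal/mol (κ = 0)."""
    from .constants import COULOMB_K

    return -(COULOMB_K / 2.0) * (1.0 / eps_in - 1.0 / eps_out) * q * q / r


def make_born_ion(q: float, r: float, element: str = "C") -> Solute:
    """A single charged sphere at the origin; ΔG_pol is known in closed form."""
    atom = Atom(
        serial=1,
        element=element,
        name=element,
        position=np.zeros(3),
        charge=q,
        radius=r,
        mass=element_mass(element),
    )
    return Solute.from_atoms([atom], label=f"born_ion_q{q}_r{r}")


def make_two_sphere(
    r1: float,
    r2: float,
    separation: float,
    q1: float = 0.0,
    q2: float = 0.0,
    label: str = "two_sphere",
) -> Solute:
    """Two spheres on the z axis; the workhorse for overlap/reentrant tests."""
    atoms = [
        Atom(1, "C", "C1", np.array([0.0, 0.0, 0.0]), q1, r1, element_mass("C")),
        Atom(2, "C", "C2", np.array([0.0, 0.0, separation]), q2, r2, element_mass("C")),
    ]
    return Solute.from_atoms(atoms, label=label)


def _zero_sum(values: np.ndarray) -> np.ndarray:
    return values - values.mean()


def make_toy_solute(
    n_atoms: int,
    seed: int,
    elements: tuple = ("C", "H", "N", "O"),
    charge_scale: float = 0.3,
    zero_sum: bool = True,
) -> Solute:
    """A small non-overlapping atom cluster with Gaussian charges.

    Atoms are grown one at a time at contact distance from a random parent
    and rejected if they crowd any other atom closer than 0.8·(r_i + r_j).
    With ``zero_sum`` the charge jitter is recentred to a neutral molecule.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be at least 1")
    rng = np.random.default_rng(seed)
    els = [str(elements[i % len(elements)]) for i in range(n_atoms)]
    rng.shuffle(els)
    radii = np.array([_BUILD_RADII[e] for e in els])
    pos = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        for _ in range(200):
            parent = int(rng.integers(0, i))
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = pos[parent] + d * 0.9 * (radii[parent] + radii[i])
            gaps = np.linalg.norm(pos[:i] - cand, axis=1)
            if np.all(gaps >= 0.8 * (radii[:i] + radii[i])):
                pos[i] = cand
                break
        else:
            raise RuntimeError("could not place atom without overlap")
    charges = rng.normal(0.0, charge_scale, n_atoms)
    if zero_sum:
        charges = _zero_sum(charges)
    atoms = [
        Atom(i + 1, els[i], f"{els[i]}{i + 1}", pos[i], charges[i], radii[i],
             element_mass(els[i]))
        for i in range(n_atoms)
    ]
    return Solute.from_atoms(atoms, label=f"toy_solute_{seed}")


def make_toy_complex(
    n_host: int,
    n_guest: int,
    seed: int,
    charge_scale: float = 0.25,
) -> tuple[Solute, Partition, LJParams]:
    """A pocket-like host ring with a guest stack threaded through its axis.

    Host heavy atoms sit on a ring in the z = 0 plane (radius grown with
    n_host so neighbors stay apart); guest atoms stack along +z starting
    just above the ring center.  Charges are zero-sum within host and guest
    separately; a valid LJ sidecar is generated.  Minimum interatomic
    distance ≥ 0.8·(r_i + r_j) holds by construction.
    """
    if n_host < 1 or n_guest < 1:
        raise ValueError("host and guest must each have at least one atom")
    rng = np.random.default_rng(seed)
    host_els = [str(e) for e in rng.choice(["C", "N", "O"], size=n_host)]
    guest_els = [str(e) for e in rng.choice(["C", "N", "O", "H"], size=n_guest)]
    ring_r = max(3.2, 1.8 / math.sin(math.pi / max(n_host, 2)))
    host_pos = np.array(
        [
            [ring_r * math.cos(2 * math.pi * k / n_host),
             ring_r * math.sin(2 * math.pi * k / n_host),
             0.0]
            for k in range(n_host)
        ]
    )
    guest_pos = np.array([[0.0, 0.0, 0.8 + 3.2 * k] for k in range(n_guest)])
    jitter = rng.uniform(-0.1, 0.1, size=(n_host + n_guest, 3))
    pos = np.vstack([host_pos, guest_pos]) + jitter
    els = host_els + guest_els
    radii = np.array([_BUILD_RADII[e] for e in els])
    n = n_host + n_guest
    # audit the non-overlap guarantee
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pos[i] - pos[j]) < 0.8 * (radii[i] + radii[j]):
                raise RuntimeError("toy complex construction produced an overlap")
    charges = np.concatenate(
        [
            _zero_sum(rng.normal(0.0, charge_scale, n_host)),
            _zero_sum(rng.normal(0.0, charge_scale, n_guest)),
        ]
    )
    atoms = [
        Atom(i + 1, els[i], f"{els[i]}{i + 1}", pos[i], charges[i], radii[i],
             element_mass(els[i]))
        for i in range(n)
    ]
    solute = Solute.from_atoms(atoms, label=f"toy_complex_{seed}")
    part = Partition(
        receptor=np.arange(n_host), ligand=np.arange(n_host, n)
    )
    lj = LJParams(
        sigma=rng.uniform(2.6, 3.4, n), epsilon=rng.uniform(0.05, 0.2, n)
    )
    return solute, part, lj


def make_distance_series(
    p_bound: float,
    n_frames: int,
    bound_mu: float = 5.0,
    unbound_mu: float = 15.0,
    noise: float = 1.0,
    seed: int = 0,
    switch_rate: float = 0.09,
) -> DistanceSeries:
    """Two-state Markov center-of-mass distance series.

    The chain's stationary bound fraction is ``p_bound``; ``switch_rate``
    sets how often states flip (the default reproduces a realistic ~25
    transitions per 1000 frames at p_bound ≈ 0.84; 1.0 gives an i.i.d.
    series).  Modes must be separated by at least 6·noise so threshold
    classification is unambiguous.
    """
    if not (0.0 <= p_bound <= 1.0):
        raise ValueError("p_bound must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    if unbound_mu - bound_mu < 6.0 * noise:
        raise ValueError("modes must be separated by at least 6·noise")
    if not (0.0 < switch_rate <= 1.0):
        raise ValueError("switch_rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p_ub = switch_rate * (1.0 - p_bound)  # bound → unbound
    p_bu = switch_rate * p_bound  # unbound → bound
    bound = np.empty(n_frames, dtype=bool)
    u = rng.random(n_frames)
    bound[0] = u[0] < p_bound
    for t in range(1, n_frames):
        if bound[t - 1]:
            bound[t] = u[t] >= p_ub
        else:
            bound[t] = u[t] < p_bu
    mu = np.where(bound, bound_mu, unbound_mu)
    d = np.clip(mu + rng.normal(0.0, noise, n_frames), 0.01, None)
    return DistanceSeries(distances=d, frame_indices=np.arange(n_frames))


def make_training_set(
    planted: RadiiSet,
    n_solv: int,
    n_bind: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
    w1: float = 0.1,
    w2: float = 1.0,
    h: float = 0.5,
    sp: SolventParams | None = None,
    n_val_solv: int | None = None,
    n_val_bind: int | None = None,
) -> ObjectiveSpec:
    """Planted-radii training data for optimizer-recovery experiments.

    Toy solutes and complexes are generated, their reference polar solvation
    and polar binding energies are computed *by this package's own pipeline*
    at the planted radii, Gaussian noise of width ``noise_sigma`` is added,
    and disjoint held-out validation lists are produced the same way.  With
    zero noise, the objective is exactly zero at the planted point.
    """
    if n_solv < 1 or n_bind < 1:
        raise ValueError("need at least one solute and one complex")
    if sp is None:
        sp = SolventParams(salt_molar=0.0)
    rng = np.random.default_rng(seed)
    n_val_solv = max(1, n_solv // 2) if n_val_solv is None else n_val_solv
    n_val_bind = max(1, n_bind // 2) if n_val_bind is None else n_val_bind

    def jitter(value: float) -> float:
        if noise_sigma > 0:
            return value + float(rng.normal(0.0, noise_sigma))
        return value

    def solv_entry(sub_seed: int):
        # Alternate two deliberately informative geometries:
        # (a) single-element clusters with net charge, so each atomic radius
        #     is constrained almost independently of the others;
        # (b) "caliper" pairs — two charged atoms whose surface gap spans the
        #     probe-diameter range, so reentrant sealing pins the water probe
        #     radius, which compact convex clusters barely feel.
        kind = sub_seed % 5
        rng_local = np.random.default_rng(1000 * seed + sub_seed)
        if kind == 4:
            separation = (5.4, 6.2, 7.0, 7.8)[(sub_seed // 5) % 4]
            q1, q2 = rng_local.normal(0.0, 0.4, 2)
            s = make_two_sphere(
                1.7, 1.7, separation, q1=q1, q2=q2, label=f"caliper_{sub_seed}"
            )
        else:
            element = ("C", "H", "N", "O")[kind]
            n_atoms = 3 + sub_seed % 2
            s = make_toy_solute(
                n_atoms,
                seed=1000 * seed + sub_seed,
                elements=(element,),
                zero_sum=False,
            )
        ref = polar_solvation(s, radii=planted, sp=sp, h=h).dg_pol
        return s, jitter(ref)

    def bind_entry(sub_seed: int):
        cp, part, _ = make_toy_complex(5, 2, seed=2000 * seed + sub_seed)
        ref = binding_polar_energy(cp, part, planted, sp, h)
        return (cp, part), jitter(ref)

    train_solv = [solv_entry(i) for i in range(n_solv)]
    train_bind = [bind_entry(i) for i in range(n_bind)]
    val_solv = [solv_entry(n_solv + i) for i in range(n_val_solv)]
    val_bind = [bind_entry(n_bind + i) for i in range(n_val_bind)]
    return ObjectiveSpec(
        w1=w1,
        w2=w2,
        train_solv=train_solv,
        train_bind=train_bind,
        val_solv=val_solv,
        val_bind=val_bind,
        sp=sp,
        h=h,
    )
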