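"""Structures, trajectories, and the registry of dielectric-boundary radii sets.

The central container is :class:`Solute`: an ordered set of atoms with
positions (Å), partial charges (e), and intrinsic radii (Å).  Intrinsic radii
together with a water-probe radius define the solvent-excluded dielectric
boundary, so swapping a named :class:`RadiiSet` changes every downstream
energy.  File formats are deliberately plain text: PQR for charges+radii,
multi-model PDB or XYZ for trajectory snapshots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Solute",
    "RadiiSet",
    "TrajectorySnapshot",
    "PQRFormatError",
    "TrajectoryFormatError",
    "UnknownRadiiSetError",
    "UnsupportedElementError",
    "read_pqr",
    "write_pqr",
    "read_trajectory",
    "write_xyz",
    "get_radii_set",
    "list_radii_sets",
    "registry_as_json",
    "assign_radii",
    "infer_element",
    "element_mass",
]


class PQRFormatError(ValueError):
    """A PQR record could not be parsed."""


class TrajectoryFormatError(ValueError):
    """A trajectory file is malformed or inconsistent with its solute."""


class UnknownRadiiSetError(KeyError):
    """Requested radii set is not in the registry."""


class UnsupportedElementError(ValueError):
    """Element has no radius in the requested radii set."""


# Standard atomic weights (amu); used for centers of mass and radii of
# gyration only.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
}

_TWO_LETTER = {k for k in ELEMENT_MASSES if len(k) == 2}


def element_mass(element: str) -> float:
    """Standard atomic weight for an element symbol (case-insensitive)."""
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise UnsupportedElementError(f"no mass tabulated for element {element!r}")


def infer_element(name: str) -> str:
    """Infer an element symbol from a PQR/PDB atom name.

    Digits are stripped; a two-letter symbol (e.g. CL) is preferred only when
    the single-letter prefix is not one of C/H/N/O/S/P, which resolves the
    classic CA-is-carbon ambiguity in organic solutes.
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        raise UnsupportedElementError(f"cannot infer element from atom name {name!r}")
    if stripped[0] in "CHNOSP":
        return stripped[0]
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    return stripped[0]


@dataclass(frozen=True)
class Atom:
    """One atom: index, chemistry, geometry, and electrostatic parameters."""

    serial: int
    element: str
    name: str
    position: np.ndarray  # (3,) Å
    charge: float  # e
    radius: float  # Å
    mass: float  # amu

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: radius must be >= 0")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be > 0")


@dataclass(frozen=True)
class Solute:
    """An ordered collection of atoms with vectorized field access.

    Arrays are the source of truth; :attr:`atoms` materializes per-atom views.
    Instances are treated as immutable — transformations return new solutes.
    """

    label: str
    serials: np.ndarray  # (n,) int
    elements: tuple
    names: tuple
    positions: np.ndarray  # (n, 3) Å
    charges: np.ndarray  # (n,) e
    radii: np.ndarray  # (n,) Å
    masses: np.ndarray  # (n,) amu

    def __post_init__(self):
        n = len(self.serials)
        if n < 1:
            raise ValueError("a solute needs at least one atom")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_atoms, 3)")
        if np.any(self.radii < 0):
            raise ValueError("radii must be nonnegative")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], label: str = "") -> "Solute":
        return cls(
            label=label,
            serials=np.array([a.serial for a in atoms], dtype=int),
            elements=tuple(a.element for a in atoms),
            names=tuple(a.name for a in atoms),
            positions=np.array([a.position for a in atoms], dtype=float).reshape(-1, 3),
            charges=np.array([a.charge for a in atoms], dtype=float),
            radii=np.array([a.radius for a in atoms], dtype=float),
            masses=np.array([a.mass for a in atoms], dtype=float),
        )

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                serial=int(self.serials[i]),
                element=self.elements[i],
                name=self.names[i],
                position=self.positions[i].copy(),
                charge=float(self.charges[i]),
                radius=float(self.radii[i]),
                mass=float(self.masses[i]),
            )

    def with_positions(self, positions: np.ndarray) -> "Solute":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != self.positions.shape:
            raise ValueError("position array shape mismatch")
        return replace(self, positions=positions)

    def with_radii(self, radii: np.ndarray) -> "Solute":
        radii = np.asarray(radii, dtype=float)
        if radii.shape != self.radii.shape:
            raise ValueError("radius array shape mismatch")
        return replace(self, radii=radii)

    def subset(self, indices: Sequence[int], label: str = "") -> "Solute":
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("subset must contain at least one atom")
        return Solute(
            label=label or self.label,
            serials=self.serials[idx],
            elements=tuple(self.elements[i] for i in idx),
            names=tuple(self.names[i] for i in idx),
            positions=self.positions[idx],
            charges=self.charges[idx],
            radii=self.radii[idx],
            masses=self.masses[idx],
        )


@dataclass(frozen=True)
class TrajectorySnapshot:
    """Per-frame coordinates (Å) for an existing solute, plus optional box."""

    frame_index: int
    positions: np.ndarray  # (n, 3) Å
    box: np.ndarray | None = None  # (3,) box edge lengths, Å

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be nonnegative")


# --------------------------------------------------------------------------
# Radii registry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiiSet:
    """Water-probe + per-element radii (Å) defining the dielectric boundary.

    ``rho_s`` may be None for sets published without a sulfur radius; assigning
    such a set to a sulfur-containing solute is an error.
    """

    name: str
    rho_w: float
    rho_c: float
    rho_h: float
    rho_n: float
    rho_o: float
    rho_s: float | None = None
    note: str = ""

    def __post_init__(self):
        for key in ("rho_w", "rho_c", "rho_h", "rho_n", "rho_o"):
            v = getattr(self, key)
            if not (0 < v <= 5):
                raise ValueError(f"{self.name}: {key}={v} outside (0, 5] Å")
        if self.rho_s is not None and not (0 < self.rho_s <= 5):
            raise ValueError(f"{self.name}: rho_s outside (0, 5] Å")

    def for_element(self, element: str) -> float:
        table = {"C": self.rho_c, "H": self.rho_h, "N": self.rho_n, "O": self.rho_o}
        el = element.upper()
        if el == "S":
            if self.rho_s is None:
                raise UnsupportedElementError(
                    f"radii set {self.name!r} defines no sulfur radius"
                )
            return self.rho_s
        try:
            return table[el]
        except KeyError:
            raise UnsupportedElementError(
                f"radii set {self.name!r} defines no radius for element {element!r}"
            )

    def as_dict(self) -> dict:
        d = {
            "name": self.name,
            "rho_w": self.rho_w,
            "rho_c": self.rho_c,
            "rho_h": self.rho_h,
            "rho_n": self.rho_n,
            "rho_o": self.rho_o,
            "rho_s": self.rho_s,
        }
        if self.note:
            d["note"] = self.note
        return d


#: Published dielectric-boundary radii sets.  OPT_* sets come from the
#: mixed hydration/binding optimization this package reimplements; BONDI,
#: PARSE, ZAP9 and mbondi are the common literature sets they are compared
#: against.  Sulfur was never optimized: optimized sets carry the Bondi value
#: 1.80 Å, and the hydration-only set defines no sulfur radius at all.
_REGISTRY: dict[str, RadiiSet] = {
    s.name: s
    for s in (
        RadiiSet("OPT_BIND5D", 1.35, 2.23, 1.47, 2.37, 1.09, 1.80,
                 note="mixed-objective optimum, weights 0.1:1"),
        RadiiSet("OPT_BIND_0_1", 1.37, 1.40, 1.55, 2.35, 1.28, 1.80,
                 note="binding-only optimum, weights 0:1"),
        RadiiSet("OPT_BIND_0_3_1", 1.35, 2.23, 1.47, 2.37, 1.09, 1.80,
                 note="weights 0.3:1; coincides with OPT_BIND5D"),
        RadiiSet("OPT_BIND_1_1", 1.35, 2.25, 1.48, 1.75, 1.11, 1.80,
                 note="weights 1:1"),
        RadiiSet("OPT_SOLV", 0.53, 1.92, 1.29, 1.72, 1.74, None,
                 note="hydration-only optimum, weights 1:0; no sulfur radius"),
        RadiiSet("BONDI", 1.40, 1.70, 1.20, 1.55, 1.50, 1.80),
        RadiiSet("PARSE", 1.40, 1.70, 1.00, 1.50, 1.40, 1.85),
        RadiiSet("ZAP9", 1.40, 1.87, 1.10, 1.55, 1.52, 2.15),
        RadiiSet("mbondi", 1.40, 1.70, 1.20, 1.55, 1.50, 1.80,
                 note="simplified mbondi: the bonded-context hydrogen rule "
                      "(1.3 Å for H on N) is not applied; all H use 1.20 Å"),
    )
}


def get_radii_set(name: str) -> RadiiSet:
    """Look up a named radii set; raises listing available names if unknown."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownRadiiSetError(
            f"unknown radii set {name!r}; available: {', '.join(sorted(_REGISTRY))}"
        )


def list_radii_sets() -> list[str]:
    return sorted(_REGISTRY)


def registry_as_json() -> str:
    """Export the full registry as a JSON document."""
    return json.dumps(
        {name: rs.as_dict() for name, rs in sorted(_REGISTRY.items())}, indent=2
    )


def assign_radii(solute: Solute, radii: RadiiSet) -> Solute:
    """Return a copy of ``solute`` with intrinsic radii taken from ``radii``.

    Positions and charges are untouched.  Idempotent by construction.
    """
    new = np.array([radii.for_element(el) for el in solute.elements])
    return solute.with_radii(new)


# --------------------------------------------------------------------------
# PQR
# --------------------------------------------------------------------------


def read_pqr(path: str | Path, label: str | None = None) -> Solute:
    """Read a whitespace-separated PQR file into a :class:`Solute`.

    Both ATOM and HETATM records are accepted; the chain-ID column is
    optional.  The last five numeric fields of each record are x, y, z,
    charge, radius; the element is inferred from the atom name.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            parts = line.split()
            # layout: rec serial name resname [chain] resid x y z q r
            if len(parts) not in (10, 11):
                raise PQRFormatError(
                    f"{path.name}:{lineno}: expected 10 or 11 fields "
                    f"(got {len(parts)}) in {line!r}"
                )
            try:
                x, y, z, q, r = (float(v) for v in parts[-5:])
            except ValueError:
                raise PQRFormatError(
                    f"{path.name}:{lineno}: cannot parse numeric fields from {line!r}"
                )
            try:
                serial = int(parts[1])
            except ValueError:
                raise PQRFormatError(f"{path.name}:{lineno}: bad serial {parts[1]!r}")
            name = parts[2]
            element = infer_element(name)
            atoms.append(
                Atom(
                    serial=serial,
                    element=element,
                    name=name,
                    position=np.array([x, y, z]),
                    charge=q,
                    radius=r,
                    mass=element_mass(element),
                )
            )
    if not atoms:
        raise PQRFormatError(f"{path.name}: no ATOM/HETATM records found")
    return Solute.from_atoms(atoms, label=label or path.stem)


def write_pqr(solute: Solute, path: str | Path, resname: str = "MOL") -> None:
    """Write a PQR file (3-decimal coordinates, 4-decimal charge/radius)."""
    with open(path, "w") as fh:
        for a in solute.atoms:
            fh.write(
                f"ATOM {a.serial:6d} {a.name:<4s} {resname:<4s} {1:4d} "
                f"{a.position[0]:10.3f} {a.position[1]:10.3f} {a.position[2]:10.3f} "
                f"{a.charge:9.4f} {a.radius:8.4f}\n"
            )
        fh.write("END\n")


# --------------------------------------------------------------------------
# Trajectories: multi-model PDB and XYZ
# --------------------------------------------------------------------------


def read_trajectory(path: str | Path, solute: Solute) -> list[TrajectorySnapshot]:
    """Read a multi-model PDB or XYZ trajectory for ``solute``.

    Frames are returned in file order with frame_index 0..n-1.  Every frame
    must carry exactly one position per solute atom.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        frames = _read_xyz_frames(path)
    elif suffix in (".pdb", ".ent"):
        frames = _read_pdb_frames(path)
    else:
        raise TrajectoryFormatError(f"unsupported trajectory format {suffix!r}")
    snapshots = []
    for i, (positions, box) in enumerate(frames):
        if len(positions) != solute.n_atoms:
            raise TrajectoryFormatError(
                f"{path.name}: model {i + 1} has {len(positions)} atoms, "
                f"solute has {solute.n_atoms}"
            )
        snapshots.append(
            TrajectorySnapshot(
                frame_index=i,
                positions=np.asarray(positions, dtype=float),
                box=box,
            )
        )
    if not snapshots:
        raise TrajectoryFormatError(f"{path.name}: no frames found")
    return snapshots


def _read_xyz_frames(path: Path):
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"{path.name}:{i + 1}: expected atom count, got {lines[i].strip()!r}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = _parse_box_comment(comment)
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise TrajectoryFormatError(
                f"{path.name}: truncated frame starting at line {i + 1}"
            )
        positions = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"{path.name}:{i + 3 + j}: bad XYZ record {ln.strip()!r}"
                )
            positions.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append((positions, box))
        i += 2 + count
    return frames


def _parse_box_comment(comment: str) -> np.ndarray | None:
    # convention: "box 36.0 36.0 36.0" anywhere in the XYZ comment line
    parts = comment.split()
    if "box" in parts:
        k = parts.index("box")
        try:
            return np.array([float(v) for v in parts[k + 1 : k + 4]])
        except (ValueError, IndexError):
            return None
    return None


def _read_pdb_frames(path: Path):
    frames: list = []
    current: list | None = None
    box = None
    seen_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                except ValueError:
                    box = None
            elif rec == "MODEL":
                seen_model = True
                current = []
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append((current, box))
                current = None
    if current:
        frames.append((current, box))
    if not frames and not seen_model:
        raise TrajectoryFormatError(f"{path.name}: no coordinates found")
    return frames


def write_xyz(
    solute: Solute,
    snapshots: Sequence[TrajectorySnapshot] | None,
    path: str | Path,
) -> None:
    """Write the solute (or a snapshot sequence over it) as an XYZ trajectory."""
    if snapshots is None:
        snapshots = [TrajectorySnapshot(0, solute.positions)]
    with open(path, "w") as fh:
        for snap in snapshots:
            comment = f"frame {snap.frame_index}"
            if snap.box is not None:
                comment += " box " + " ".join(f"{v:.3f}" for v in snap.box)
            fh.write(f"{solute.n_atoms}\n{comment}\n")
            for el, pos in zip(solute.elements, snap.positions):
                fh.write(f"{el:<2s} {pos[0]:12.3f} {pos[1]:12.3f} {pos[2]:12.3f}\n")
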