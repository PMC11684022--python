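"""Deterministic DIRECT global search and the weighted radii-fitting objective.

DIRECT (DIviding RECTangles) recursively trisects the unit hypercube,
sampling box centers and subdividing only "potentially optimal" boxes —
those on the lower-right convex hull of (box size, center value).  It needs
no gradients or Lipschitz constant and is frugal with evaluations, which
matters here because each objective evaluation runs the full SES/GB energy
pipeline over every training structure.

The fitting objective mixes two root-mean-square errors,

    RMSE_total = w1 · RMSE_solv + w2 · RMSE_bind,

where RMSE_solv compares computed polar solvation energies of small solutes
with reference values and RMSE_bind compares polar binding energies
(ΔG_bind^pol = ΔE_el + ΔΔG_pol) of complexes with theirs.  The search space
is the 5-vector (ρ_W, ρ_C, ρ_H, ρ_N, ρ_O); the sulfur radius is held at its
Bondi value 1.80 Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import COULOMB_K
from .gb_energy import SolventParams, polar_solvation
from .mmgbsa import Partition
from .model_io import RadiiSet, Solute, assign_radii

__all__ = [
    "SearchDomain",
    "OptimizationTrace",
    "ObjectiveSpec",
    "direct_minimize",
    "rmse",
    "radii_objective",
    "optimize_radii",
    "objective_report",
    "default_radii_domain",
    "RADII_LABELS",
]

RADII_LABELS = ("rho_w", "rho_c", "rho_h", "rho_n", "rho_o")

#: Sulfur is never a search dimension; Bondi value.
RHO_S_FIXED = 1.80


@dataclass(frozen=True)
class SearchDomain:
    """Axis-aligned search bounds with per-dimension labels."""

    lower: np.ndarray
    upper: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if lo.shape != up.shape or lo.ndim != 1:
            raise ValueError("lower/upper must be 1-D arrays of equal length")
        if np.any(lo >= up):
            raise ValueError("require lower < upper in every dimension")

    @property
    def dim(self) -> int:
        return len(self.lower)

    def denormalize(self, u: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(u) * (self.upper - self.lower)


def default_radii_domain(lo: float = 0.3, hi: float = 3.0) -> SearchDomain:
    """Default 5-D radii bounds, generously covering published sets."""
    return SearchDomain(np.full(5, lo), np.full(5, hi), labels=RADII_LABELS)


@dataclass
class OptimizationTrace:
    """Append-only evaluation log with the running best."""

    evaluations: list = field(default_factory=list)  # (x, f, iteration)
    best_x: np.ndarray | None = None
    best_f: float = math.inf

    @property
    def n_evals(self) -> int:
        return len(self.evaluations)

    def record(self, x: np.ndarray, f: float, iteration: int) -> None:
        self.evaluations.append((np.array(x), f, iteration))
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x)

    def best_separated(self, k: int, separation: float = 0.15) -> list:
        """The k best evaluated points pairwise ≥ `separation` apart (max-norm).

        Useful for inspecting distinct local minima of the radii landscape.
        """
        ranked = sorted(self.evaluations, key=lambda e: e[1])
        kept: list = []
        for x, f, _ in ranked:
            if all(np.max(np.abs(x - kx)) >= separation for kx, _ in kept):
                kept.append((x, f))
                if len(kept) == k:
                    break
        return kept

    def to_rows(self) -> list:
        return [
            [it, f] + list(map(float, x)) for x, f, it in self.evaluations
        ]


# --------------------------------------------------------------------------
# Canonical DIRECT
# --------------------------------------------------------------------------


def direct_minimize(
    objective: Callable[[np.ndarray], float],
    domain: SearchDomain,
    max_evals: int,
    epsilon: float = 1e-4,
) -> OptimizationTrace:
    """Minimize ``objective`` over ``domain`` with canonical DIRECT.

    Fully deterministic: identical inputs produce identical traces.  An
    objective that raises or returns a non-finite value at a point has that
    point recorded as +inf and the search continues.
    """
    if max_evals < 1:
        raise ValueError("max_evals must be at least 1")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    D = domain.dim
    trace = OptimizationTrace()

    def evaluate(u: np.ndarray, iteration: int) -> float:
        x = domain.denormalize(u)
        try:
            f = float(objective(x))
            if not math.isfinite(f):
                f = math.inf
        except Exception:
            f = math.inf
        trace.record(x, f, iteration)
        return f

    centers: list = [np.full(D, 0.5)]
    levels: list = [np.zeros(D, dtype=int)]
    fvals: list = [evaluate(centers[0], 0)]
    ages: list = [0]
    next_age = 1

    iteration = 0
    while trace.n_evals < max_evals:
        iteration += 1
        sizes = [0.5 * math.sqrt(float(np.sum(3.0 ** (-2.0 * k)))) for k in levels]
        selected = _potentially_optimal(sizes, fvals, ages, epsilon, trace.best_f)
        if not selected:
            break
        # larger boxes first; ties by creation order
        selected.sort(key=lambda j: (-sizes[j], ages[j]))
        progressed = False
        for j in selected:
            if trace.n_evals >= max_evals:
                break
            c = centers[j]
            k = levels[j]
            kmin = int(k.min())
            long_dims = [d for d in range(D) if k[d] == kmin]
            delta = 3.0 ** (-(kmin + 1))
            sampled = []
            for d in long_dims:
                if trace.n_evals >= max_evals:
                    break
                up = c.copy()
                up[d] += delta
                dn = c.copy()
                dn[d] -= delta
                f_up = evaluate(up, iteration)
                if trace.n_evals >= max_evals:
                    # budget exhausted mid-pair: the lone sample is in the
                    # trace but the box is not divided along this dimension
                    break
                f_dn = evaluate(dn, iteration)
                sampled.append((min(f_up, f_dn), d, up, f_up, dn, f_dn))
                progressed = True
            if not sampled:
                continue
            sampled.sort(key=lambda t: (t[0], t[1]))
            cur = k.copy()
            for _, d, up, f_up, dn, f_dn in sampled:
                cur = cur.copy()
                cur[d] += 1
                centers.append(up)
                levels.append(cur)
                fvals.append(f_up)
                ages.append(next_age)
                next_age += 1
                centers.append(dn)
                levels.append(cur)
                fvals.append(f_dn)
                ages.append(next_age)
                next_age += 1
            levels[j] = cur
        if not progressed:
            break
    return trace


def _potentially_optimal(sizes, fvals, ages, epsilon, fmin):
    """Indices of potentially optimal boxes (size–value lower-right hull)."""
    reps: dict = {}
    for j, (d, f) in enumerate(zip(sizes, fvals)):
        key = round(d, 12)
        cur = reps.get(key)
        if cur is None or (f, ages[j]) < (fvals[cur], ages[cur]):
            reps[key] = j
    pts = sorted(((sizes[j], fvals[j], j) for j in reps.values()))
    # keep only sizes >= the size of the best-f representative (largest on tie)
    best = min(pts, key=lambda p: (p[1], -p[0]))
    pts = [p for p in pts if p[0] >= best[0]]
    # lower convex hull over (size, f), sizes ascending
    hull: list = []
    for p in pts:
        while len(hull) >= 2 and _cross(hull[-2], hull[-1], p) <= 0:
            hull.pop()
        hull.append(p)
    # epsilon test: achievable improvement must beat fmin - eps|fmin|
    keep = []
    threshold = fmin - epsilon * abs(fmin)
    for i, (d, f, j) in enumerate(hull):
        if i == len(hull) - 1:
            keep.append(j)
            continue
        d2, f2, _ = hull[i + 1]
        slope = (f2 - f) / (d2 - d)
        if f - slope * d <= threshold + 1e-15:
            keep.append(j)
    return keep


def _cross(a, b, c):
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


# --------------------------------------------------------------------------
# Radii-fitting objective
# --------------------------------------------------------------------------


def rmse(pred: Sequence[float], ref: Sequence[float]) -> float:
    """Root-mean-square deviation between two equal-length vectors."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("pred and ref must be nonempty and of equal length")
    return float(np.sqrt(np.mean((p - r) ** 2)))


@dataclass
class ObjectiveSpec:
    """Weighted hydration/binding training data for radii optimization.

    ``train_solv``: list of (Solute, reference ΔG_pol kcal/mol).
    ``train_bind``: list of ((Solute, Partition), reference ΔG_bind^pol).
    Validation lists are reported but never influence the search.
    """

    w1: float
    w2: float
    train_solv: list = field(default_factory=list)
    train_bind: list = field(default_factory=list)
    val_solv: list = field(default_factory=list)
    val_bind: list = field(default_factory=list)
    sp: SolventParams = field(default_factory=lambda: SolventParams(salt_molar=0.0))
    h: float = 0.5

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0 or (self.w1 == 0 and self.w2 == 0):
            raise ValueError("weights must be nonnegative and not both zero")
        if self.w1 > 0 and not self.train_solv:
            raise ValueError("w1 > 0 requires a nonempty hydration training list")
        if self.w2 > 0 and not self.train_bind:
            raise ValueError("w2 > 0 requires a nonempty binding training list")


def point_to_radii_set(point: Sequence[float], name: str = "OPT_CANDIDATE") -> RadiiSet:
    w, c, h, n, o = (float(v) for v in point)
    return RadiiSet(name, w, c, h, n, o, RHO_S_FIXED)


def binding_polar_energy(
    complex_: Solute,
    part: Partition,
    radii: RadiiSet,
    sp: SolventParams,
    h: float,
) -> float:
    """Polar binding energy ΔG_bind^pol = ΔE_el + ΔΔG_pol for one structure."""
    comp = assign_radii(complex_, radii)
    ri = np.asarray(part.receptor, dtype=int)
    li = np.asarray(part.ligand, dtype=int)
    dr = comp.positions[ri][:, None, :] - comp.positions[li][None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", dr, dr))
    de_el = COULOMB_K * float(
        np.sum(np.outer(comp.charges[ri], comp.charges[li]) / r)
    )
    probe = radii.rho_w
    anchor = comp.positions.mean(axis=0)
    ddg_pol = (
        polar_solvation(comp, sp=sp, h=h, probe=probe, anchor=anchor).dg_pol
        - polar_solvation(comp.subset(ri), sp=sp, h=h, probe=probe, anchor=anchor).dg_pol
        - polar_solvation(comp.subset(li), sp=sp, h=h, probe=probe, anchor=anchor).dg_pol
    )
    return de_el + ddg_pol


def _component_rmses(point, spec: ObjectiveSpec, solv, bind):
    radii = point_to_radii_set(point)
    out = {}
    if solv:
        pred = [
            polar_solvation(s, radii=radii, sp=spec.sp, h=spec.h).dg_pol
            for s, _ in solv
        ]
        out["rmse_solv"] = rmse(pred, [ref for _, ref in solv])
    if bind:
        pred = [
            binding_polar_energy(cp, part, radii, spec.sp, spec.h)
            for (cp, part), _ in bind
        ]
        out["rmse_bind"] = rmse(pred, [ref for _, ref in bind])
    return out


def radii_objective(point: Sequence[float], spec: ObjectiveSpec) -> float:
    """RMSE_total = w1·RMSE_solv + w2·RMSE_bind at one radii 5-vector."""
    total = 0.0
    comp = _component_rmses(
        point,
        spec,
        spec.train_solv if spec.w1 > 0 else [],
        spec.train_bind if spec.w2 > 0 else [],
    )
    if spec.w1 > 0:
        total += spec.w1 * comp["rmse_solv"]
    if spec.w2 > 0:
        total += spec.w2 * comp["rmse_bind"]
    return total


def objective_report(point: Sequence[float], spec: ObjectiveSpec) -> dict:
    """Train and validation RMSE components at a point (reporting only)."""
    report = {"point": [float(v) for v in point]}
    train = _component_rmses(point, spec, spec.train_solv, spec.train_bind)
    report["train"] = train
    report["train"]["rmse_total"] = spec.w1 * train.get("rmse_solv", 0.0) + spec.w2 * train.get("rmse_bind", 0.0)
    if spec.val_solv or spec.val_bind:
        val = _component_rmses(point, spec, spec.val_solv, spec.val_bind)
        val["rmse_total"] = spec.w1 * val.get("rmse_solv", 0.0) + spec.w2 * val.get("rmse_bind", 0.0)
        report["validation"] = val
    return report


def optimize_radii(
    spec: ObjectiveSpec,
    domain: SearchDomain | None = None,
    budget: int = 1000,
    epsilon: float = 1e-4,
    name: str = "OPT_RADII",
) -> tuple[RadiiSet, OptimizationTrace]:
    """Run DIRECT on the radii objective and return the best named set."""
    if domain is None:
        domain = default_radii_domain()
    if domain.dim != 5:
        raise ValueError("radii optimization is a 5-D search")
    trace = direct_minimize(
        lambda x: radii_objective(x, spec), domain, max_evals=budget, epsilon=epsilon
    )
    return point_to_radii_set(trace.best_x, name=name), trace
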