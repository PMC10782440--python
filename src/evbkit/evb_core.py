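"""Two-state empirical valence bond (EVB) energetics.

An EVB model describes a chemical reaction by two *diabatic* states, each an
ordinary force-field description of one bonding pattern: state 1 carries the
reactant topology (e.g. an intact ether bond about to break), state 2 the
product topology (the newly formed carbon-carbon bond).  Both states share the
same atoms and coordinates; only the parameterization differs.  The reactive
ground-state surface is the lower eigenvalue of the 2x2 Hamiltonian

    H = [[eps1,  H12 ],
         [H12,   eps2 + delta_alpha]]

where ``delta_alpha`` is a constant gas-phase shift applied to the product
state and ``H12`` a constant off-diagonal coupling.  Both are calibration
parameters fitted so a reference reaction reproduces known activation and
reaction free energies (see :mod:`evbkit.calibration`).

Every diabatic evaluation returns a full :class:`EnergyBreakdown`: six force
field terms (Morse bond, angle, torsion, improper, electrostatic, van der
Waals), each partitioned into reacting-reacting (rr), reacting-surrounding
(rs) and surrounding-surrounding (ss) groups.  The rr/rs split is what the
activation-enthalpy decomposition (:mod:`evbkit.decomposition`) consumes.

Units: kcal/mol for energies, Angstrom for lengths, radians for angles
internally, elementary charges for partial charges, amu for masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Coulomb prefactor, kcal*A/(mol*e^2).  Standard MD convention.
COULOMB_CONSTANT = 332.0636
#: Boltzmann constant, kcal/(mol*K).
KB = 0.0019872041
#: Converts (kcal/mol/A)/amu to acceleration in A/fs^2.
ACC_CONVERSION = 4.184e-4

TERMS = ("bond", "angle", "torsion", "improper", "elec", "vdw")
GROUPS = ("rr", "rs", "ss")

_MIN_PAIR_DISTANCE = 1e-6


class EVBError(Exception):
    """Base class for errors raised by evbkit."""


class TopologyError(EVBError):
    """Inconsistent topology or mismatched coordinate dimensions."""


class SingularityError(EVBError):
    """Two atoms closer than the numerical singularity threshold."""


class GeometryError(EVBError):
    """Degenerate geometry (e.g. collinear atoms in a dihedral)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSpec:
    """One atom: integer id, mass in amu, and whether it belongs to the
    reacting fragment (``r``) or the surroundings (``s``)."""

    id: int
    mass: float
    reacting_flag: bool

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise TopologyError(f"atom {self.id}: mass must be positive")


@dataclass(frozen=True)
class MorseBond:
    """Morse bond V(r) = D * (1 - exp(-a*(r - r0)))**2."""

    atoms: tuple[int, int]
    D: float
    a: float
    r0: float

    def __post_init__(self) -> None:
        if self.atoms[0] == self.atoms[1]:
            raise TopologyError("Morse bond must join two distinct atoms")
        if self.D <= 0 or self.a <= 0 or self.r0 <= 0:
            raise TopologyError("Morse parameters D, a, r0 must be positive")


@dataclass(frozen=True)
class HarmonicAngle:
    """Harmonic valence angle V = 0.5 * k * (theta - theta0)**2, theta0 in rad."""

    atoms: tuple[int, int, int]
    k: float
    theta0: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise TopologyError("angle force constant must be >= 0")
        if not 0.0 <= self.theta0 <= np.pi:
            raise TopologyError("theta0 must lie in [0, pi]")


@dataclass(frozen=True)
class TorsionTerm:
    """Periodic torsion V = k * (1 + cos(n*phi - delta))."""

    atoms: tuple[int, int, int, int]
    k: float
    n: int
    delta: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise TopologyError("torsion force constant must be >= 0")
        if self.n < 1:
            raise TopologyError("torsion periodicity must be >= 1")


@dataclass(frozen=True)
class ImproperTerm:
    """Harmonic improper dihedral V = 0.5 * k * wrap(xi - xi0)**2."""

    atoms: tuple[int, int, int, int]
    k: float
    xi0: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise TopologyError("improper force constant must be >= 0")


@dataclass
class NonbondedParams:
    """Per-atom charges and Lennard-Jones parameters plus exclusions.

    ``exclusions`` are 1-2/1-3 pairs that do not interact at all;
    ``pairs14`` interact with both electrostatics and LJ scaled by the
    respective factors (OPLS convention: 0.5 for both).  Combination rule is
    the geometric mean for both sigma and epsilon.
    """

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    exclusions: frozenset[frozenset[int]] = frozenset()
    pairs14: frozenset[frozenset[int]] = frozenset()
    scale14_elec: float = 0.5
    scale14_vdw: float = 0.5

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if np.any(self.sigma <= 0):
            raise TopologyError("LJ sigma must be positive")
        if np.any(self.epsilon < 0):
            raise TopologyError("LJ epsilon must be >= 0")
        self.exclusions = frozenset(frozenset(p) for p in self.exclusions)
        self.pairs14 = frozenset(frozenset(p) for p in self.pairs14)


@dataclass
class DiabaticTopology:
    """Force-field description of one diabatic (fixed-bonding-pattern) state.

    Both states of an EVB system reference the identical atom set; only term
    lists and nonbonded parameters differ.  ``label`` is 1 (reactant-like) or
    2 (product-like).
    """

    atoms: list[AtomSpec]
    bonds: list[MorseBond]
    angles: list[HarmonicAngle]
    torsions: list[TorsionTerm]
    impropers: list[ImproperTerm]
    nonbonded: NonbondedParams
    label: int = 1

    def __post_init__(self) -> None:
        ids = [a.id for a in self.atoms]
        if ids != list(range(len(self.atoms))):
            raise TopologyError("atom ids must be unique and contiguous from 0")
        if not any(a.reacting_flag for a in self.atoms):
            raise TopologyError("at least one atom must be reacting")
        if self.label not in (1, 2):
            raise TopologyError("state label must be 1 or 2")
        n = len(self.atoms)
        for term in (*self.bonds, *self.angles, *self.torsions, *self.impropers):
            for i in term.atoms:
                if not 0 <= i < n:
                    raise TopologyError(f"term references invalid atom id {i}")
        for arr in (self.nonbonded.charge, self.nonbonded.sigma,
                    self.nonbonded.epsilon):
            if arr.shape != (n,):
                raise TopologyError("nonbonded parameter arrays must have one "
                                    "entry per atom")
        self._compiled: _CompiledTopology | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def reacting(self) -> np.ndarray:
        return np.array([a.reacting_flag for a in self.atoms], dtype=bool)

    def compiled(self) -> "_CompiledTopology":
        if self._compiled is None:
            self._compiled = _CompiledTopology(self)
        return self._compiled


@dataclass(frozen=True)
class EVBCoupling:
    """The two calibration parameters of the 2x2 EVB Hamiltonian.

    ``delta_alpha`` (kcal/mol) shifts the product diabat; ``h12`` (kcal/mol)
    is the constant off-diagonal element, stored nonnegative (only its square
    enters the ground-state energy).
    """

    delta_alpha: float
    h12: float

    def __post_init__(self) -> None:
        if self.h12 < 0:
            raise ValueError("H12 is stored nonnegative by convention")


def _group_of(reacting: np.ndarray, atom_ids: Iterable[int]) -> int:
    """rr if every atom is reacting, ss if none is, rs otherwise."""
    flags = [bool(reacting[i]) for i in atom_ids]
    if all(flags):
        return 0
    if not any(flags):
        return 2
    return 1


class EnergyBreakdown:
    """Six-term energy decomposition partitioned into rr/rs/ss groups.

    Stored as a (3, 6) matrix: rows are the interaction groups
    (reacting-reacting, reacting-surrounding, surrounding-surrounding) and
    columns the terms ``bond, angle, torsion, improper, elec, vdw``.
    ``total`` is the matrix sum, so per-term group additivity
    (rr + rs + ss = term) and term additivity (sum of terms = total) hold by
    construction.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray | None = None):
        if matrix is None:
            matrix = np.zeros((3, 6))
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 6):
            raise ValueError("EnergyBreakdown matrix must have shape (3, 6)")
        self.matrix = matrix

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def term(self, name: str) -> float:
        return float(self.matrix[:, TERMS.index(name)].sum())

    def group(self, name: str) -> float:
        return float(self.matrix[GROUPS.index(name), :].sum())

    def __getattr__(self, name: str) -> float:
        if name in TERMS:
            return self.term(name)
        if name in GROUPS:
            return self.group(name)
        raise AttributeError(name)

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {g: {t: float(self.matrix[gi, ti]) for ti, t in enumerate(TERMS)}
                for gi, g in enumerate(GROUPS)}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{t}={self.term(t):.4f}" for t in TERMS)
        return f"EnergyBreakdown(total={self.total:.4f}, {parts})"


@dataclass
class DiabatsResult:
    """Energies, forces and breakdowns of both diabatic states at one
    configuration.  ``e2`` is the raw state-2 energy (no delta_alpha)."""

    e1: float
    e2: float
    f1: np.ndarray
    f2: np.ndarray
    bd1: EnergyBreakdown | None = None
    bd2: EnergyBreakdown | None = None


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def morse_energy(r, bond: MorseBond):
    """Morse potential V(r) = D * (1 - exp(-a*(r - r0)))**2.

    V(r0) = 0 and V -> D as r -> infinity.  Accepts scalars or arrays;
    raises on nonpositive distances.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Morse bond distance must be positive")
    x = 1.0 - np.exp(-bond.a * (r - bond.r0))
    out = bond.D * x * x
    return float(out) if out.ndim == 0 else out


def morse_energy_derivative(r, bond: MorseBond):
    """dV/dr of the Morse potential."""
    r = np.asarray(r, dtype=float)
    e = np.exp(-bond.a * (r - bond.r0))
    out = 2.0 * bond.D * bond.a * e * (1.0 - e)
    return float(out) if out.ndim == 0 else out


def ground_state_energy(eps1, eps2_shifted, coupling: EVBCoupling):
    """Ground-state eigenvalue and eigenvector weights of the 2x2 EVB matrix.

    Returns ``(Eg, w1, w2)`` where ``Eg = 0.5*(e1 + e2') -
    0.5*sqrt((e1 - e2')**2 + 4*H12**2)`` and ``w1, w2`` are the squared
    components of the ground eigenvector (w1 + w2 = 1).  ``eps2_shifted``
    must already include delta_alpha.  Vectorized over array inputs.
    """
    e1 = np.asarray(eps1, dtype=float)
    e2 = np.asarray(eps2_shifted, dtype=float)
    if not (np.all(np.isfinite(e1)) and np.all(np.isfinite(e2))):
        raise ValueError("diabatic energies must be finite")
    h = coupling.h12
    d = e1 - e2
    s = np.sqrt(d * d + 4.0 * h * h)
    eg = 0.5 * (e1 + e2) - 0.5 * s
    # Squared ground-eigenvector components in closed form:
    # w1 = (1 - d/s)/2, well-conditioned for any H12 >= 0.
    with np.errstate(invalid="ignore"):
        w1 = np.where(s > 0, 0.5 * (1.0 - d / np.where(s > 0, s, 1.0)), 0.5)
    w1 = np.clip(w1, 0.0, 1.0)
    w2 = 1.0 - w1
    if eg.ndim == 0:
        return float(eg), float(w1), float(w2)
    return eg, w1, w2


def mapping_energy(eps1, eps2_shifted, lam: float):
    """Linear mapping potential eps_m = (1 - lam)*eps1 + lam*eps2'."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    e1 = np.asarray(eps1, dtype=float)
    e2 = np.asarray(eps2_shifted, dtype=float)
    out = (1.0 - lam) * e1 + lam * e2
    return float(out) if out.ndim == 0 else out


def energy_gap(eps1, eps2_shifted):
    """Energy-gap reaction coordinate: delta_eps = eps1 - eps2'."""
    out = np.asarray(eps1, dtype=float) - np.asarray(eps2_shifted, dtype=float)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# geometry primitives (shared with decomposition.measure_geometry)
# ---------------------------------------------------------------------------

def distance(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[j] - coords[i]))


def angle_value(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Valence angle at j, in radians."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral_value(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Dihedral angle in radians in (-pi, pi]; raises on collinear triples."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b2n = np.linalg.norm(b2)
    if n1n < 1e-10 or n2n < 1e-10 or b2n < 1e-10:
        raise GeometryError("dihedral undefined: collinear atoms")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    phi = np.arctan2(y, x)
    if phi <= -np.pi:  # pragma: no cover - arctan2 already yields (-pi, pi]
        phi += 2 * np.pi
    return float(phi)


def _wrap_angle(x):
    """Wrap angle difference into (-pi, pi]."""
    return np.pi - np.mod(np.pi - x, 2.0 * np.pi)


# ---------------------------------------------------------------------------
# compiled topology + vectorized evaluation
# ---------------------------------------------------------------------------

class _CompiledTopology:
    """Array views over the term lists of a DiabaticTopology, built once."""

    def __init__(self, topo: DiabaticTopology):
        reacting = topo.reacting
        n = topo.n_atoms

        def _pack(terms, n_idx, names):
            idx = np.array([t.atoms for t in terms], dtype=int).reshape(-1, n_idx)
            params = {nm: np.array([getattr(t, nm) for t in terms], dtype=float)
                      for nm in names}
            grp = np.array([_group_of(reacting, t.atoms) for t in terms],
                           dtype=int)
            return idx, params, grp

        self.bond_idx, self.bond_p, self.bond_grp = _pack(
            topo.bonds, 2, ("D", "a", "r0"))
        self.angle_idx, self.angle_p, self.angle_grp = _pack(
            topo.angles, 3, ("k", "theta0"))
        self.torsion_idx, self.torsion_p, self.torsion_grp = _pack(
            topo.torsions, 4, ("k", "n", "delta"))
        self.improper_idx, self.improper_p, self.improper_grp = _pack(
            topo.impropers, 4, ("k", "xi0"))

        nb = topo.nonbonded
        ii, jj = np.triu_indices(n, k=1)
        keep = np.ones(ii.shape, dtype=bool)
        scale = np.ones(ii.shape)
        for m, (a, b) in enumerate(zip(ii, jj)):
            pair = frozenset((int(a), int(b)))
            if pair in nb.exclusions:
                keep[m] = False
            elif pair in nb.pairs14:
                scale[m] = -1.0  # marker, resolved below
        ii, jj, scale = ii[keep], jj[keep], scale[keep]
        is14 = scale < 0
        self.pair_i = ii
        self.pair_j = jj
        self.pair_qq = nb.charge[ii] * nb.charge[jj] * np.where(
            is14, nb.scale14_elec, 1.0)
        eps_ij = np.sqrt(nb.epsilon[ii] * nb.epsilon[jj]) * np.where(
            is14, nb.scale14_vdw, 1.0)
        sig_ij = np.sqrt(nb.sigma[ii] * nb.sigma[jj])
        self.pair_eps = eps_ij
        self.pair_sig = sig_ij
        both = reacting[ii] & reacting[jj]
        neither = ~reacting[ii] & ~reacting[jj]
        self.pair_grp = np.where(both, 0, np.where(neither, 2, 1))


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-handling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _row_norms(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", a, a))


def _eval_bonds(ct: _CompiledTopology, coords, matrix, forces):
    if ct.bond_idx.shape[0] == 0:
        return
    i, j = ct.bond_idx[:, 0], ct.bond_idx[:, 1]
    d = coords[j] - coords[i]
    r = _row_norms(d)
    if np.any(r <= 0):
        raise SingularityError("bonded atoms coincide")
    e = np.exp(-ct.bond_p["a"] * (r - ct.bond_p["r0"]))
    v = ct.bond_p["D"] * (1.0 - e) ** 2
    np.add.at(matrix, (ct.bond_grp, 0), v)
    if forces is not None:
        dvdr = 2.0 * ct.bond_p["D"] * ct.bond_p["a"] * e * (1.0 - e)
        fpair = (dvdr / r)[:, None] * d  # force on i along +d
        np.add.at(forces, i, fpair)
        np.add.at(forces, j, -fpair)


def _eval_angles(ct: _CompiledTopology, coords, matrix, forces):
    if ct.angle_idx.shape[0] == 0:
        return
    i, j, k = (ct.angle_idx[:, c] for c in range(3))
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    un = _row_norms(u)
    vn = _row_norms(v)
    uh = u / un[:, None]
    vh = v / vn[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    dtheta = theta - ct.angle_p["theta0"]
    np.add.at(matrix, (ct.angle_grp, 1), 0.5 * ct.angle_p["k"] * dtheta ** 2)
    if forces is not None:
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
        dedtheta = ct.angle_p["k"] * dtheta
        # dtheta/dxi = (c*uh - vh)/(|u| s); analogous for xk
        gi = (c[:, None] * uh - vh) / (un * s)[:, None]
        gk = (c[:, None] * vh - uh) / (vn * s)[:, None]
        fi = -dedtheta[:, None] * gi
        fk = -dedtheta[:, None] * gk
        np.add.at(forces, i, fi)
        np.add.at(forces, k, fk)
        np.add.at(forces, j, -(fi + fk))


def _dihedral_angles_grads(coords, idx, want_grads=True):
    i, j, k, l = (idx[:, c] for c in range(4))
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = _cross_rows(b1, b2)
    n2 = _cross_rows(b2, b3)
    b2n = _row_norms(b2)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", _cross_rows(n1, n2), b2) / b2n
    phi = np.arctan2(y, x)
    if not want_grads:
        return phi, None
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    if np.any(n1sq < 1e-18) or np.any(n2sq < 1e-18):
        raise GeometryError("torsion undefined: collinear atoms")
    dphi_di = -(b2n / n1sq)[:, None] * n1
    dphi_dl = (b2n / n2sq)[:, None] * n2
    c12 = np.einsum("ij,ij->i", b1, b2) / (b2n * b2n)
    c32 = np.einsum("ij,ij->i", b3, b2) / (b2n * b2n)
    dphi_dj = -(1.0 + c12[:, None]) * dphi_di + c32[:, None] * dphi_dl
    dphi_dk = c12[:, None] * dphi_di - (1.0 + c32[:, None]) * dphi_dl
    return phi, (dphi_di, dphi_dj, dphi_dk, dphi_dl)


def _eval_torsions(ct: _CompiledTopology, coords, matrix, forces):
    if ct.torsion_idx.shape[0] == 0:
        return
    phi, grads = _dihedral_angles_grads(coords, ct.torsion_idx,
                                        forces is not None)
    kk = ct.torsion_p["k"]
    nn = ct.torsion_p["n"]
    dd = ct.torsion_p["delta"]
    np.add.at(matrix, (ct.torsion_grp, 2), kk * (1.0 + np.cos(nn * phi - dd)))
    if forces is not None:
        dedphi = -kk * nn * np.sin(nn * phi - dd)
        for col, g in zip(range(4), grads):
            np.add.at(forces, ct.torsion_idx[:, col], -dedphi[:, None] * g)


def _eval_impropers(ct: _CompiledTopology, coords, matrix, forces):
    if ct.improper_idx.shape[0] == 0:
        return
    phi, grads = _dihedral_angles_grads(coords, ct.improper_idx,
                                        forces is not None)
    dxi = _wrap_angle(phi - ct.improper_p["xi0"])
    kk = ct.improper_p["k"]
    np.add.at(matrix, (ct.improper_grp, 3), 0.5 * kk * dxi ** 2)
    if forces is not None:
        dedphi = kk * dxi
        for col, g in zip(range(4), grads):
            np.add.at(forces, ct.improper_idx[:, col], -dedphi[:, None] * g)


def _eval_nonbonded(ct: _CompiledTopology, coords, matrix, forces):
    if ct.pair_i.shape[0] == 0:
        return
    d = coords[ct.pair_j] - coords[ct.pair_i]
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < _MIN_PAIR_DISTANCE ** 2):
        raise SingularityError("overlapping atoms in nonbonded evaluation")
    r = np.sqrt(r2)
    e_el = COULOMB_CONSTANT * ct.pair_qq / r
    sr6 = (ct.pair_sig ** 2 / r2) ** 3
    e_lj = 4.0 * ct.pair_eps * (sr6 * sr6 - sr6)
    np.add.at(matrix, (ct.pair_grp, 4), e_el)
    np.add.at(matrix, (ct.pair_grp, 5), e_lj)
    if forces is not None:
        # dE/dr terms; force on i is +(dE/dr) * dhat
        dvdr = -e_el / r + (-24.0 * ct.pair_eps * (2.0 * sr6 * sr6 - sr6) / r)
        fpair = (dvdr / r)[:, None] * d
        np.add.at(forces, ct.pair_i, fpair)
        np.add.at(forces, ct.pair_j, -fpair)


def diabatic_energy(coords: np.ndarray, topo: DiabaticTopology) -> EnergyBreakdown:
    """Evaluate one diabatic state, returning the full term/group breakdown.

    No cutoff is applied to any nonbonded pair (toy systems are small, and
    reacting atoms must interact with the entire system)."""
    bd, _ = diabatic_energy_forces(coords, topo, want_forces=False)
    return bd


def diabatic_energy_forces(
    coords: np.ndarray, topo: DiabaticTopology, want_forces: bool = True
) -> tuple[EnergyBreakdown, np.ndarray | None]:
    """Breakdown plus (optionally) analytic forces, shape (n_atoms, dim)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] != topo.n_atoms:
        raise TopologyError(
            f"coordinate array must have shape ({topo.n_atoms}, dim)")
    if coords.shape[1] == 1:
        # lift 1D systems into 3D for the geometry kernels
        coords3 = np.zeros((coords.shape[0], 3))
        coords3[:, 0] = coords[:, 0]
        bd, f3 = diabatic_energy_forces(coords3, topo, want_forces)
        return bd, (f3[:, :1] if f3 is not None else None)
    ct = topo.compiled()
    matrix = np.zeros((3, 6))
    forces = np.zeros_like(coords) if want_forces else None
    _eval_bonds(ct, coords, matrix, forces)
    _eval_angles(ct, coords, matrix, forces)
    _eval_torsions(ct, coords, matrix, forces)
    _eval_impropers(ct, coords, matrix, forces)
    _eval_nonbonded(ct, coords, matrix, forces)
    return EnergyBreakdown(matrix), forces


class _MergedStatePair:
    """Both diabatic states' term arrays concatenated for one-pass evaluation.

    State-2 atom indices are offset by n_atoms (the coordinate array is
    duplicated), and state-2 group indices by 3, so a single sweep of the
    term kernels fills a (6, 6) matrix whose top/bottom halves are the two
    states' (3, 6) breakdowns and a (2n, 3) force array whose halves are the
    per-state forces.
    """

    def __init__(self, topo1: DiabaticTopology, topo2: DiabaticTopology):
        n = topo1.n_atoms
        self.n_atoms = n
        c1, c2 = topo1.compiled(), topo2.compiled()

        def _cat_idx(a, b, cols):
            if a.shape[0] == 0 and b.shape[0] == 0:
                return np.zeros((0, cols), dtype=int)
            return np.vstack([a.reshape(-1, cols), b.reshape(-1, cols) + n])

        def _cat(a, b):
            return np.concatenate([a, b])

        self.bond_idx = _cat_idx(c1.bond_idx, c2.bond_idx, 2)
        self.bond_p = {k: _cat(c1.bond_p[k], c2.bond_p[k]) for k in c1.bond_p}
        self.bond_grp = _cat(c1.bond_grp, c2.bond_grp + 3)
        self.angle_idx = _cat_idx(c1.angle_idx, c2.angle_idx, 3)
        self.angle_p = {k: _cat(c1.angle_p[k], c2.angle_p[k])
                        for k in c1.angle_p}
        self.angle_grp = _cat(c1.angle_grp, c2.angle_grp + 3)
        self.torsion_idx = _cat_idx(c1.torsion_idx, c2.torsion_idx, 4)
        self.torsion_p = {k: _cat(c1.torsion_p[k], c2.torsion_p[k])
                          for k in c1.torsion_p}
        self.torsion_grp = _cat(c1.torsion_grp, c2.torsion_grp + 3)
        self.improper_idx = _cat_idx(c1.improper_idx, c2.improper_idx, 4)
        self.improper_p = {k: _cat(c1.improper_p[k], c2.improper_p[k])
                           for k in c1.improper_p}
        self.improper_grp = _cat(c1.improper_grp, c2.improper_grp + 3)
        self.pair_i = _cat(c1.pair_i, c2.pair_i + n)
        self.pair_j = _cat(c1.pair_j, c2.pair_j + n)
        self.pair_qq = _cat(c1.pair_qq, c2.pair_qq)
        self.pair_eps = _cat(c1.pair_eps, c2.pair_eps)
        self.pair_sig = _cat(c1.pair_sig, c2.pair_sig)
        self.pair_grp = _cat(c1.pair_grp, c2.pair_grp + 3)


def diabatic_pair_energy_forces(
    coords: np.ndarray, merged: _MergedStatePair
) -> tuple[EnergyBreakdown, EnergyBreakdown, np.ndarray, np.ndarray]:
    """Evaluate both diabatic states in one kernel sweep."""
    n = merged.n_atoms
    coords2 = np.vstack([coords, coords])
    matrix = np.zeros((6, 6))
    forces = np.zeros((2 * n, coords.shape[1]))
    _eval_bonds(merged, coords2, matrix, forces)
    _eval_angles(merged, coords2, matrix, forces)
    _eval_torsions(merged, coords2, matrix, forces)
    _eval_impropers(merged, coords2, matrix, forces)
    _eval_nonbonded(merged, coords2, matrix, forces)
    return (EnergyBreakdown(matrix[:3]), EnergyBreakdown(matrix[3:]),
            forces[:n], forces[n:])


# ---------------------------------------------------------------------------
# exclusion construction and serialization
# ---------------------------------------------------------------------------

def build_exclusions(
    n_atoms: int, bond_pairs: Sequence[tuple[int, int]]
) -> tuple[frozenset[frozenset[int]], frozenset[frozenset[int]]]:
    """Derive 1-2/1-3 exclusions and 1-4 pairs from a bond list."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for a, b in bond_pairs:
        adj[a].add(b)
        adj[b].add(a)
    excl: set[frozenset[int]] = set()
    p14: set[frozenset[int]] = set()
    for a in range(n_atoms):
        for b in adj[a]:
            excl.add(frozenset((a, b)))
            for c in adj[b] - {a}:
                excl.add(frozenset((a, c)))
                for d in adj[c] - {a, b}:
                    if d != a:
                        p14.add(frozenset((a, d)))
    p14 -= excl
    p14 = {p for p in p14 if len(p) == 2}
    return frozenset(excl), frozenset(p14)


def system_to_dict(
    atoms: list[AtomSpec],
    state1: DiabaticTopology,
    state2: DiabaticTopology,
    coupling: EVBCoupling,
) -> dict:
    """Serialize a two-state EVB system (sections atoms/state1/state2/coupling)."""

    def _topo(t: DiabaticTopology) -> dict:
        nb = t.nonbonded
        return {
            "bonds": [{"atoms": list(b.atoms), "D": b.D, "a": b.a, "r0": b.r0}
                      for b in t.bonds],
            "angles": [{"atoms": list(a.atoms), "k": a.k, "theta0": a.theta0}
                       for a in t.angles],
            "torsions": [{"atoms": list(x.atoms), "k": x.k, "n": x.n,
                          "delta": x.delta} for x in t.torsions],
            "impropers": [{"atoms": list(x.atoms), "k": x.k, "xi0": x.xi0}
                          for x in t.impropers],
            "nonbonded": {
                "charge": nb.charge.tolist(),
                "sigma": nb.sigma.tolist(),
                "epsilon": nb.epsilon.tolist(),
                "exclusions": sorted(sorted(p) for p in nb.exclusions),
                "pairs14": sorted(sorted(p) for p in nb.pairs14),
                "scale14_elec": nb.scale14_elec,
                "scale14_vdw": nb.scale14_vdw,
            },
            "label": t.label,
        }

    return {
        "atoms": [{"id": a.id, "mass": a.mass, "reacting_flag": a.reacting_flag}
                  for a in atoms],
        "state1": _topo(state1),
        "state2": _topo(state2),
        "coupling": {"delta_alpha": coupling.delta_alpha, "h12": coupling.h12},
    }


def system_from_dict(doc: dict):
    """Inverse of :func:`system_to_dict`."""
    atoms = [AtomSpec(d["id"], d["mass"], d["reacting_flag"])
             for d in doc["atoms"]]

    def _topo(d: dict, label: int) -> DiabaticTopology:
        nb = d["nonbonded"]
        return DiabaticTopology(
            atoms=atoms,
            bonds=[MorseBond(tuple(b["atoms"]), b["D"], b["a"], b["r0"])
                   for b in d["bonds"]],
            angles=[HarmonicAngle(tuple(a["atoms"]), a["k"], a["theta0"])
                    for a in d["angles"]],
            torsions=[TorsionTerm(tuple(t["atoms"]), t["k"], int(t["n"]),
                                  t["delta"]) for t in d["torsions"]],
            impropers=[ImproperTerm(tuple(t["atoms"]), t["k"], t["xi0"])
                       for t in d["impropers"]],
            nonbonded=NonbondedParams(
                charge=np.array(nb["charge"]),
                sigma=np.array(nb["sigma"]),
                epsilon=np.array(nb["epsilon"]),
                exclusions=frozenset(frozenset(p) for p in nb["exclusions"]),
                pairs14=frozenset(frozenset(p) for p in nb["pairs14"]),
                scale14_elec=nb.get("scale14_elec", 0.5),
                scale14_vdw=nb.get("scale14_vdw", 0.5),
            ),
            label=d.get("label", label),
        )

    coupling = EVBCoupling(doc["coupling"]["delta_alpha"],
                           doc["coupling"]["h12"])
    return atoms, _topo(doc["state1"], 1), _topo(doc["state2"], 2), coupling
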