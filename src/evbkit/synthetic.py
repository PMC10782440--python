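"""Synthetic study systems: 1D oracle diabats, 3D toy reactions, Arrhenius fixtures.

Three generators provide every input the pipeline is exercised on:

* :func:`make_oracle_1d` - a single particle on two displaced harmonic
  diabats.  Because both wells share one force constant, the energy gap is
  linear in the coordinate, so the ground-state free-energy profile along
  the gap can be computed to quadrature accuracy
  (:func:`oracle_profile_quadrature`) and serves as the independent oracle
  for the sampled FEP/umbrella estimators.  The ``reference`` preset is the
  desk-scale stand-in for the uncatalyzed reaction used to calibrate the
  EVB coupling parameters.

* :func:`make_toy_reaction` - a 6-atom reacting fragment in 3D whose two
  diabatic topologies emulate a breaking ether-like bond and a forming
  carbon-carbon bond (the rearrangement geometry of the chorismate ->
  prephenate analog), optionally surrounded by a Lennard-Jones bath inside
  a restraining sphere.  The ``catalyst`` variant adds fixed charges placed
  near the transition-state arrangement of the fragment, providing
  electrostatic transition-state stabilization - the qualitative catalysis
  signal the decomposition pipeline must detect.

* :func:`make_arrhenius_fixture` - temperature series dG_act(T) = dH - T*dS
  with optional Gaussian replicate noise, for the Arrhenius regression.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from numpy.polynomial.legendre import leggauss

from .evb_core import (KB, AtomSpec, DiabaticTopology, DiabatsResult,
                       EVBCoupling, EVBError, HarmonicAngle, MorseBond,
                       NonbondedParams, TorsionTerm, _MergedStatePair,
                       build_exclusions, diabatic_pair_energy_forces,
                       ground_state_energy, system_from_dict, system_to_dict)
from .free_energy import FreeEnergyProfile, extract_barriers
from .sampler import CompositeRestraint, FlatBottomDistance, HarmonicSphere


class PresetError(EVBError):
    pass


# ---------------------------------------------------------------------------
# 1D oracle system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleSystem1D:
    """Single particle on two displaced harmonic diabats.

    eps1(x) = 0.5*k*(x - x1)^2, eps2(x) = 0.5*k*(x - x2)^2 + c2 (raw, before
    delta_alpha).  The shared force constant makes the gap linear in x:
    deps(x) = k*(x2 - x1)*x + const, so gap bins map to exact x intervals.
    """

    k: float
    x1: float
    x2: float
    c2: float
    coupling: EVBCoupling
    domain: tuple[float, float]
    mass: float
    name: str = "oracle1d"

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not (lo < self.x1 < hi and lo < self.x2 < hi):
            raise PresetError("both diabat minima must lie inside the domain")
        if self.x1 == self.x2:
            raise PresetError("diabats need distinct minima on the domain")
        if self.k <= 0 or self.mass <= 0:
            raise PresetError("force constant and mass must be positive")

    # --- system protocol -------------------------------------------------
    dim: int = 1
    restraint = None

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass])

    def initial_coords(self) -> np.ndarray:
        return np.array([[self.x1]])

    def eps1(self, x):
        return 0.5 * self.k * (np.asarray(x) - self.x1) ** 2

    def eps2(self, x):
        return 0.5 * self.k * (np.asarray(x) - self.x2) ** 2 + self.c2

    def evaluate(self, coords: np.ndarray) -> DiabatsResult:
        x = float(coords[0, 0])
        d1 = x - self.x1
        d2 = x - self.x2
        return DiabatsResult(
            e1=0.5 * self.k * d1 * d1,
            e2=0.5 * self.k * d2 * d2 + self.c2,
            f1=np.array([[-self.k * d1]]),
            f2=np.array([[-self.k * d2]]),
        )

    # --- gap geometry -----------------------------------------------------
    def gap_coefficients(self) -> tuple[float, float]:
        """deps(x) = slope*x + intercept (includes delta_alpha)."""
        slope = self.k * (self.x2 - self.x1)
        intercept = (0.5 * self.k * (self.x1**2 - self.x2**2) - self.c2
                     - self.coupling.delta_alpha)
        return slope, intercept

    def x_of_gap(self, deps):
        slope, intercept = self.gap_coefficients()
        return (np.asarray(deps, dtype=float) - intercept) / slope

    def gap_of_x(self, x):
        slope, intercept = self.gap_coefficients()
        return slope * np.asarray(x, dtype=float) + intercept

    def ground_energy(self, x):
        e2s = self.eps2(x) + self.coupling.delta_alpha
        eg, _, _ = ground_state_energy(self.eps1(x), e2s, self.coupling)
        return eg

    def with_coupling(self, coupling: EVBCoupling) -> "OracleSystem1D":
        return replace(self, coupling=coupling)

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "oracle1d", "name": self.name, "k": self.k,
            "x1": self.x1, "x2": self.x2, "c2": self.c2,
            "domain": list(self.domain), "mass": self.mass,
            "coupling": {"delta_alpha": self.coupling.delta_alpha,
                         "h12": self.coupling.h12},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OracleSystem1D":
        return cls(k=d["k"], x1=d["x1"], x2=d["x2"], c2=d["c2"],
                   coupling=EVBCoupling(d["coupling"]["delta_alpha"],
                                        d["coupling"]["h12"]),
                   domain=tuple(d["domain"]), mass=d["mass"],
                   name=d.get("name", "oracle1d"))


def _load_preset(name: str) -> dict:
    path = resources.files("evbkit.presets").joinpath(f"{name}.json")
    try:
        return json.loads(path.read_text())
    except FileNotFoundError as err:
        raise PresetError(f"unknown preset {name!r}") from err


def make_oracle_1d(preset: str | dict = "reference") -> OracleSystem1D:
    """Build a 1D oracle system from a preset name or a parameter dict.

    Shipped presets: ``reference`` (asymmetric wells sized so calibration to
    an activation free energy of 24.5 kcal/mol and a reaction free energy of
    -12.8 kcal/mol succeeds) and ``symmetric`` (mirrored diabats; dG0 = 0 by
    symmetry for delta_alpha = 0).
    """
    if isinstance(preset, str):
        preset = _load_preset(f"oracle_{preset}")
    return OracleSystem1D.from_dict(preset)


def oracle_profile_quadrature(system: OracleSystem1D, T: float,
                              bins: int | np.ndarray = 101,
                              n_nodes: int = 64) -> FreeEnergyProfile:
    """Quadrature-exact ground-state free-energy profile along the gap.

    For each gap bin the Boltzmann weight of the ground surface is
    integrated with Gauss-Legendre quadrature over the exact x interval the
    (linear) gap maps onto.  No sampling noise enters; doubling ``n_nodes``
    leaves the profile unchanged to well below 1e-8.
    """
    lo, hi = system.domain
    g_lo, g_hi = sorted((float(system.gap_of_x(lo)), float(system.gap_of_x(hi))))
    if isinstance(bins, (int, np.integer)):
        edges = np.linspace(g_lo, g_hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    beta = 1.0 / (KB * T)
    nodes, weights = leggauss(n_nodes)
    # reference energy to keep the exponentials in range
    xg = np.linspace(lo, hi, 2001)
    shift = float(np.min(system.ground_energy(xg)))
    nb = edges.size - 1
    dg = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        xa, xb = sorted((float(system.x_of_gap(edges[b])),
                         float(system.x_of_gap(edges[b + 1]))))
        xa, xb = max(xa, lo), min(xb, hi)
        if xb <= xa:
            continue
        xm = 0.5 * (xa + xb) + 0.5 * (xb - xa) * nodes
        f = np.exp(-beta * (system.ground_energy(xm) - shift))
        integral = 0.5 * (xb - xa) * float(np.dot(weights, f))
        if integral > 0:
            dg[b] = -np.log(integral) / beta
            counts[b] = 10**9  # exact bins are never count-masked
    dg -= np.nanmin(dg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyProfile(edges=edges, centers=centers, dg=dg,
                             counts=counts, T=T, replicate=None)


def oracle_barriers(system: OracleSystem1D, T: float,
                    bins: int | np.ndarray = 101) -> tuple[float, float]:
    """(dG_act, dG0) of the quadrature profile."""
    prof = oracle_profile_quadrature(system, T, bins=bins)
    return extract_barriers(prof)


# ---------------------------------------------------------------------------
# 3D toy reaction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyReactionSpec:
    """Construction parameters of the 3D toy reaction system.

    The reacting fragment is a fixed 6-atom chain; state 1 carries the
    breaking bond (atoms 2-3, the ether-bond analog), state 2 the forming
    bond (atoms 0-5, the C-C analog), so the reaction closes the chain into
    a ring the way the pericyclic rearrangement does.  ``n_solvent``
    uncharged LJ particles emulate a solvent droplet held by a flat-bottom
    restraining sphere.  ``catalyst=True`` adds a pair of fixed charges
    (+q near the charge-accumulating atom 3, -q diametrically opposite)
    that stabilize the product-like charge distribution at the transition
    state; the reacting-fragment topology itself is identical in both
    variants.
    """

    n_solvent: int = 10
    restraint_radius: float = 6.5
    restraint_k: float = 10.0
    catalyst: bool = False
    catalyst_charge: float = 0.9
    catalyst_distance: float = 2.8


BREAKING_BOND = (2, 3)   # analog of the breaking C5-O7 ether bond
FORMING_BOND = (0, 5)    # analog of the forming C1-C9 bond

#: Fig-4-style observables: the two reacting distances and three backbone
#: torsions of the fragment.
TOY_GEOMETRY_DEFINITIONS = {
    "breaking_bond": BREAKING_BOND,
    "forming_bond": FORMING_BOND,
    "torsion_0123": (0, 1, 2, 3),
    "torsion_1234": (1, 2, 3, 4),
    "torsion_2345": (2, 3, 4, 5),
}


def _fragment_coords() -> np.ndarray:
    """Planar open-chain reactant geometry: bond 1.5 A, backbone angle 130 deg."""
    pts = [np.zeros(3)]
    heading = 0.0
    for _ in range(5):
        step = 1.5 * np.array([np.cos(heading), np.sin(heading), 0.0])
        pts.append(pts[-1] + step)
        heading += np.deg2rad(40.0)
    return np.array(pts)


class ToyReactionSystem:
    """Two-state EVB system over the toy fragment (+ bath, + catalyst)."""

    dim = 3

    def __init__(self, spec: ToyReactionSpec, seed: int,
                 coupling: EVBCoupling = EVBCoupling(-14.0, 6.0)):
        self.spec = spec
        self.seed = seed
        self.coupling = coupling
        self._merged = None
        self._build()

    def _build(self) -> None:
        spec = self.spec
        frag = _fragment_coords()
        centroid = frag.mean(axis=0)
        n_cat = 2 if spec.catalyst else 0
        n = 6 + n_cat + spec.n_solvent
        atoms = [AtomSpec(i, 12.0, True) for i in range(6)]
        coords = [frag]
        if spec.catalyst:
            direction = frag[3] - centroid
            direction /= np.linalg.norm(direction)
            pos_plus = frag[3] + spec.catalyst_distance * direction
            pos_minus = centroid - 9.0 * direction
            atoms += [AtomSpec(6, 1e5, False), AtomSpec(7, 1e5, False)]
            coords.append(np.array([pos_plus, pos_minus]))
        rng = np.random.default_rng(self.seed)
        if spec.n_solvent:
            base = 6 + n_cat
            atoms += [AtomSpec(base + i, 18.0, False)
                      for i in range(spec.n_solvent)]
            # deterministic golden-spiral shell + small seeded jitter
            i = np.arange(spec.n_solvent)
            phi = np.arccos(1 - 2 * (i + 0.5) / spec.n_solvent)
            theta = np.pi * (1 + 5**0.5) * (i + 0.5)
            shell = 4.8 * np.stack([np.sin(phi) * np.cos(theta),
                                    np.sin(phi) * np.sin(theta),
                                    np.cos(phi)], axis=1)
            shell += centroid + 0.25 * rng.standard_normal(shell.shape)
            coords.append(shell)
        xyz = np.vstack(coords)
        d = np.linalg.norm(xyz[None, :, :] - xyz[:, None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1.2:
            raise PresetError(
                f"overlapping initial coordinates (min distance {d.min():.2f} A)")
        self.atoms = atoms
        self._coords0 = xyz
        self.masses = np.array([a.mass for a in atoms])
        # pocket tethers keep the open-chain ends from fully extending in
        # either end state, bounding the reactant/product basins along the
        # gap; identical in both states, they cancel in the gap coordinate
        self.restraint = CompositeRestraint((
            HarmonicSphere(tuple(centroid), spec.restraint_radius,
                           spec.restraint_k),
            FlatBottomDistance(FORMING_BOND, 4.2, 20.0),
            FlatBottomDistance(BREAKING_BOND, 4.2, 20.0),
        ))

        permanent = [MorseBond((0, 1), 120.0, 2.0, 1.5),
                     MorseBond((1, 2), 120.0, 2.0, 1.5),
                     MorseBond((3, 4), 120.0, 2.0, 1.5),
                     MorseBond((4, 5), 120.0, 2.0, 1.5)]
        # wide wells (a = 1.0) give partially formed bonds intermediate
        # energies, keeping the gap coordinate continuous across windows
        bonds1 = permanent + [MorseBond(BREAKING_BOND, 200.0, 0.6, 1.45)]
        bonds2 = permanent + [MorseBond(FORMING_BOND, 200.0, 0.6, 1.55)]
        th0 = np.deg2rad(140.0)
        angles1 = [HarmonicAngle((0, 1, 2), 150.0, th0),
                   HarmonicAngle((1, 2, 3), 150.0, th0),
                   HarmonicAngle((2, 3, 4), 150.0, th0),
                   HarmonicAngle((3, 4, 5), 150.0, th0)]
        angles2 = [HarmonicAngle((3, 4, 5), 150.0, th0),
                   HarmonicAngle((4, 5, 0), 150.0, th0),
                   HarmonicAngle((5, 0, 1), 150.0, th0),
                   HarmonicAngle((0, 1, 2), 150.0, th0)]
        torsions1 = [TorsionTerm((0, 1, 2, 3), 1.0, 3, 0.0),
                     TorsionTerm((1, 2, 3, 4), 1.0, 3, 0.0),
                     TorsionTerm((2, 3, 4, 5), 1.0, 3, 0.0)]
        torsions2 = [TorsionTerm((3, 4, 5, 0), 1.0, 3, 0.0),
                     TorsionTerm((4, 5, 0, 1), 1.0, 3, 0.0),
                     TorsionTerm((5, 0, 1, 2), 1.0, 3, 0.0)]

        q1 = np.zeros(n)
        q2 = np.zeros(n)
        q1[[2, 3, 4]] = [0.20, -0.40, 0.20]
        q2[[2, 3, 4]] = [0.35, -0.70, 0.35]
        if spec.catalyst:
            q1[6], q1[7] = spec.catalyst_charge, -spec.catalyst_charge
            q2[6], q2[7] = spec.catalyst_charge, -spec.catalyst_charge
        sigma = np.full(n, 3.2)
        eps = np.full(n, 0.08)
        sigma[3], eps[3] = 3.0, 0.12
        if spec.catalyst:
            sigma[6:8], eps[6:8] = 3.0, 0.10
        if spec.n_solvent:
            sigma[6 + n_cat:], eps[6 + n_cat:] = 3.1, 0.15

        # exclusions are unioned over both states so the breaking/forming
        # pairs never see a bare Coulomb contact in either topology
        ex1, p14_1 = build_exclusions(n, [b.atoms for b in bonds1])
        ex2, p14_2 = build_exclusions(n, [b.atoms for b in bonds2])
        excl = frozenset(ex1 | ex2)
        p14 = frozenset((p14_1 | p14_2) - excl)

        def _nb(q):
            return NonbondedParams(charge=q, sigma=sigma, epsilon=eps,
                                   exclusions=excl, pairs14=p14)

        self.state1 = DiabaticTopology(atoms, bonds1, angles1, torsions1, [],
                                       _nb(q1), label=1)
        self.state2 = DiabaticTopology(atoms, bonds2, angles2, torsions2, [],
                                       _nb(q2), label=2)
        if abs(q1.sum() - q2.sum()) > 1e-12:
            raise PresetError("net charge not conserved between states")

    # --- system protocol --------------------------------------------------
    def initial_coords(self) -> np.ndarray:
        return self._coords0.copy()

    def evaluate(self, coords: np.ndarray) -> DiabatsResult:
        if self._merged is None:
            self._merged = _MergedStatePair(self.state1, self.state2)
        bd1, bd2, f1, f2 = diabatic_pair_energy_forces(coords, self._merged)
        return DiabatsResult(e1=bd1.total, e2=bd2.total, f1=f1, f2=f2,
                             bd1=bd1, bd2=bd2)

    def with_coupling(self, coupling: EVBCoupling) -> "ToyReactionSystem":
        out = ToyReactionSystem.__new__(ToyReactionSystem)
        out.__dict__ = dict(self.__dict__)
        out.coupling = coupling
        out._merged = self._merged
        return out

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        doc = system_to_dict(self.atoms, self.state1, self.state2,
                             self.coupling)
        doc["type"] = "toy_reaction"
        doc["spec"] = {k: getattr(self.spec, k)
                       for k in self.spec.__dataclass_fields__}
        doc["seed"] = self.seed
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ToyReactionSystem":
        spec = ToyReactionSpec(**doc["spec"])
        _, _, _, coupling = system_from_dict(doc)
        return cls(spec, doc["seed"], coupling)


def make_toy_reaction(spec: ToyReactionSpec | str | dict = "reference",
                      seed: int | None = None,
                      coupling: EVBCoupling | None = None) -> ToyReactionSystem:
    """Deterministically build a toy reaction system.

    ``spec`` may be a :class:`ToyReactionSpec`, a preset name (``reference``
    or ``catalyst``) or a preset dict.  An explicit ``seed`` overrides the
    preset's.  The catalyst variant differs from the reference only by the
    added fixed charges.
    """
    if isinstance(spec, str):
        spec = _load_preset(f"toy_{spec}")
    if isinstance(spec, dict):
        coupling = coupling or EVBCoupling(spec["coupling"]["delta_alpha"],
                                           spec["coupling"]["h12"])
        if seed is None:
            seed = spec.get("seed", 0)
        spec = ToyReactionSpec(**spec["spec"])
    if seed is None:
        seed = 0
    if coupling is None:
        coupling = EVBCoupling(-14.0, 6.0)
    return ToyReactionSystem(spec, seed, coupling)


def toy_simulation_config(seed: int = 0, production: bool = True) -> "SimulationConfig":
    """Shared sampling protocol for the 3D toys.

    The stiff reacting bonds ask for a 0.5 fs step; production windows run
    1.3 ps with a 0.2 ps discarded re-equilibration (about 51 windows x
    1.5 ps per replicate).  ``production=False`` halves the window length
    for quick smoke runs and calibration iterates.
    """
    from .sampler import SimulationConfig
    n_prod = 2600 if production else 1200
    n_equil = 400 if production else 200
    return SimulationConfig(seed=seed, timestep_fs=0.5, n_prod_steps=n_prod,
                            n_window_equil_steps=n_equil, sample_stride=4,
                            n_equil_steps=(150, 150, 150, 150, 150, 600))


# ---------------------------------------------------------------------------
# Arrhenius fixtures
# ---------------------------------------------------------------------------

DEFAULT_TEMPERATURES = (288.0, 293.0, 298.0, 303.0, 308.0, 313.0)


@dataclass(frozen=True)
class ArrheniusFixture:
    """Generator of dG_act(T) = dH - T*dS + noise temperature series."""

    dH: float
    dS: float
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    noise_sigma: float = 0.0
    replicates: int = 1
    seed: int = 0


@dataclass
class TemperatureSeries:
    """Replicate activation free energies at each temperature."""

    entries: list[tuple[float, np.ndarray]]
    label: str = ""

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.entries]
        if len(set(temps)) < 3:
            raise ValueError("need at least 3 distinct temperatures")
        for t, vals in self.entries:
            if np.asarray(vals).size < 1:
                raise ValueError(f"temperature {t} has no replicates")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries])


def make_arrhenius_fixture(fixture: ArrheniusFixture,
                           label: str = "fixture") -> TemperatureSeries:
    """Materialize a fixture; noiseless (sigma = 0) points lie exactly on
    the generating line."""
    rng = np.random.default_rng(fixture.seed)
    entries = []
    for T in fixture.temperatures:
        base = fixture.dH - T * fixture.dS
        noise = (fixture.noise_sigma
                 * rng.standard_normal(fixture.replicates)
                 if fixture.noise_sigma > 0 else np.zeros(fixture.replicates))
        entries.append((float(T), base + noise))
    return TemperatureSeries(entries=entries, label=label)
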