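"""Canonical sampling of EVB mapping potentials with Langevin dynamics.

The free-energy machinery needs Boltzmann-distributed configurations on each
lambda-mapping potential eps_m = (1-lam)*eps1 + lam*(eps2 + delta_alpha).
Sampling uses the BAOAB discretization of Langevin dynamics, which samples
the canonical ensemble at the target temperature (a weak-coupling bath does
not, so it is used here only in spirit: the staged heat-up protocol maps the
per-stage bath relaxation times onto Langevin friction as gamma = 1/tau).

Protocol per replicate: a six-stage equilibration ramps the temperature from
1 K to the target, then windows are visited in lambda order, each with a
short discarded re-equilibration followed by production sampling; the final
configuration of one window seeds the next.  Seeds are derived from a master
seed by a fixed counter scheme (``master + 10000*replicate + window``), so a
full protocol is reproducible bit-for-bit from its configuration.

A *system* is any object exposing ``masses`` (n,), ``dim``, ``coupling``
(:class:`~evbkit.evb_core.EVBCoupling`), ``initial_coords()`` and
``evaluate(coords) -> DiabatsResult``; an optional ``restraint`` (a
:class:`HarmonicSphere`) is added to both diabats and therefore cancels in
the energy gap.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .evb_core import (ACC_CONVERSION, KB, DiabatsResult, EnergyBreakdown,
                       EVBError, ground_state_energy, mapping_energy)

logger = logging.getLogger("evbkit.sampler")

EQUILIBRATION_SEED_OFFSET = 9999  # window slot reserved for the heat-up stages


class IntegrationError(EVBError):
    """Non-finite forces or coordinates during dynamics."""


class EquilibrationWarning(UserWarning):
    """Trailing kinetic temperature missed the target window."""


@dataclass(frozen=True)
class HarmonicSphere:
    """Flat-bottom spherical restraint: V = 0.5*k*max(0, |r-c| - R)**2 per atom."""

    center: tuple[float, ...]
    radius: float
    k: float

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        c = np.asarray(self.center, dtype=float)[: coords.shape[1]]
        d = coords - c
        r = np.linalg.norm(d, axis=1)
        over = np.maximum(0.0, r - self.radius)
        e = 0.5 * self.k * np.sum(over**2)
        f = np.zeros_like(coords)
        m = over > 0
        if np.any(m):
            f[m] = -(self.k * over[m] / r[m])[:, None] * d[m]
        return float(e), f


@dataclass(frozen=True)
class FlatBottomDistance:
    """Pair tether: V = 0.5*k*max(0, d - d0)**2 between two atoms.

    Applied as a system restraint (identically in both diabatic states), it
    cancels in the energy gap; it emulates a binding pocket that keeps a
    floppy fragment from fully extending."""

    atoms: tuple[int, int]
    d0: float
    k: float

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        i, j = self.atoms
        d = coords[j] - coords[i]
        r = float(np.linalg.norm(d))
        over = r - self.d0
        f = np.zeros_like(coords)
        if over <= 0 or r == 0:
            return 0.0, f
        fpair = (self.k * over / r) * d  # pulls i toward j
        f[i] = fpair
        f[j] = -fpair
        return 0.5 * self.k * over * over, f


@dataclass(frozen=True)
class CompositeRestraint:
    """Sum of independent restraint terms."""

    parts: tuple

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        e_tot = 0.0
        f_tot = np.zeros_like(coords)
        for p in self.parts:
            e, f = p.energy_forces(coords)
            e_tot += e
            f_tot += f
        return e_tot, f_tot


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale sampling protocol parameters.

    ``n_equil_steps``/``equil_relax_fs`` give the six-stage heat-up (first
    five stages short with tight coupling, final stage longer with weaker
    coupling).  ``friction_ps`` is the Langevin friction used during window
    equilibration and production.  The seed recorded here is the master seed
    of the whole protocol.
    """

    timestep_fs: float = 1.0
    n_equil_steps: tuple[int, ...] = (200, 200, 200, 200, 200, 1000)
    equil_relax_fs: tuple[float, ...] = (10.0, 10.0, 10.0, 10.0, 10.0, 100.0)
    n_window_equil_steps: int = 300
    n_prod_steps: int = 3000
    sample_stride: int = 3
    temperature: float = 298.0
    friction_ps: float = 25.0
    seed: int = 0
    store_coords: bool = True
    store_breakdowns: bool = True

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.n_equil_steps) != len(self.equil_relax_fs):
            raise ValueError("one relaxation time per equilibration stage")

    def config_hash(self) -> str:
        """Hash of every field except the seed (replicates share it)."""
        payload = repr(tuple(
            (k, v) for k, v in sorted(self.__dict__.items()) if k != "seed"))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class MDState:
    coords: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    potential: float
    diabats: DiabatsResult | None = None


@dataclass
class Frame:
    """One recorded configuration of a window trajectory."""

    step: int
    coords: np.ndarray | None
    eps1: float
    eps2_shifted: float
    Eg: float
    eps_m: float
    w1: float
    w2: float
    kinetic_temperature: float
    breakdown1: EnergyBreakdown | None
    breakdown2: EnergyBreakdown | None


@dataclass
class WindowTrajectory:
    """Columnar storage of the production frames of one (lambda, T, replicate).

    Arrays are aligned: ``e1``, ``e2s`` (state-2 energy including
    delta_alpha), ``eg``, ``em``, ``w1``, ``kin_t`` all have one entry per
    frame; ``bd1``/``bd2`` hold the per-frame (3, 6) group-by-term energy
    matrices when breakdowns were stored.  The ``frames`` iterator provides
    the record view.
    """

    lam: float
    T: float
    replicate: int
    step: np.ndarray
    e1: np.ndarray
    e2s: np.ndarray
    eg: np.ndarray
    em: np.ndarray
    w1: np.ndarray
    kin_t: np.ndarray
    coords: np.ndarray | None = None
    bd1: np.ndarray | None = None
    bd2: np.ndarray | None = None
    config_hash: str = ""
    equilibration_discarded: bool = True

    def __post_init__(self) -> None:
        if self.e1.shape[0] < 1:
            raise ValueError("a window trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.e1.shape[0])

    @property
    def gap(self) -> np.ndarray:
        return self.e1 - self.e2s

    @property
    def frames(self) -> Iterator[Frame]:
        for m in range(self.n_frames):
            yield Frame(
                step=int(self.step[m]),
                coords=None if self.coords is None else self.coords[m],
                eps1=float(self.e1[m]),
                eps2_shifted=float(self.e2s[m]),
                Eg=float(self.eg[m]),
                eps_m=float(self.em[m]),
                w1=float(self.w1[m]),
                w2=float(1.0 - self.w1[m]),
                kinetic_temperature=float(self.kin_t[m]),
                breakdown1=(None if self.bd1 is None
                            else EnergyBreakdown(self.bd1[m])),
                breakdown2=(None if self.bd2 is None
                            else EnergyBreakdown(self.bd2[m])),
            )


@dataclass
class EquilibrationStage:
    stage: int
    target_T: float
    n_steps: int
    mean_kinetic_T: float


@dataclass
class EquilibrationReport:
    state: MDState
    stages: list[EquilibrationStage]
    reached_target: bool


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def maxwell_velocities(masses: np.ndarray, T: float, dim: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities in A/fs."""
    sigma = np.sqrt(ACC_CONVERSION * KB * T / masses)
    return rng.standard_normal((masses.shape[0], dim)) * sigma[:, None]


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2)) / ACC_CONVERSION
    ndof = velocities.size
    return 2.0 * ke / (ndof * KB)


def _mapping_potential(system, lam: float):
    """Closure evaluating the sampling potential eps_m (+ restraint) and forces."""
    coupling = system.coupling
    restraint = getattr(system, "restraint", None)

    def pot(coords: np.ndarray) -> tuple[float, np.ndarray, DiabatsResult]:
        ev = system.evaluate(coords)
        e2s = ev.e2 + coupling.delta_alpha
        em = (1.0 - lam) * ev.e1 + lam * e2s
        f = (1.0 - lam) * ev.f1 + lam * ev.f2
        if restraint is not None:
            er, fr = restraint.energy_forces(coords)
            em += er
            f = f + fr
        return em, f, ev

    return pot


def langevin_step(state: MDState, potential, dt: float, gamma_fs: float,
                  T: float, masses: np.ndarray,
                  rng: np.random.Generator) -> MDState:
    """One BAOAB Langevin update (B: half kick, A: half drift, O: full
    Ornstein-Uhlenbeck velocity refresh).  With gamma = 0 this reduces to
    velocity Verlet.  Deterministic given the generator state."""
    if not np.all(np.isfinite(state.forces)):
        raise IntegrationError("non-finite force entering integration step")
    m = masses[:, None]
    v = state.velocities + 0.5 * dt * ACC_CONVERSION * state.forces / m
    x = state.coords + 0.5 * dt * v
    if gamma_fs > 0:
        c1 = np.exp(-gamma_fs * dt)
        sigma = np.sqrt((1.0 - c1 * c1) * ACC_CONVERSION * KB * T / masses)
        v = c1 * v + sigma[:, None] * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    em, f, ev = potential(x)
    if not np.all(np.isfinite(f)) or not np.isfinite(em):
        raise IntegrationError("integration blow-up: non-finite energy/force "
                               "after position update")
    v = v + 0.5 * dt * ACC_CONVERSION * f / m
    return MDState(coords=x, velocities=v, forces=f, potential=em, diabats=ev)


def _init_state(system, potential, T: float, rng: np.random.Generator) -> MDState:
    coords = np.array(system.initial_coords(), dtype=float)
    em, f, ev = potential(coords)
    vel = maxwell_velocities(np.asarray(system.masses, dtype=float), T,
                             coords.shape[1], rng)
    return MDState(coords=coords, velocities=vel, forces=f, potential=em,
                   diabats=ev)


def equilibrate(system, config: SimulationConfig, lam: float = 0.0,
                rng: np.random.Generator | None = None) -> EquilibrationReport:
    """Six-stage heat-up from 1 K to the target temperature on eps_m(lam).

    Stage temperatures interpolate linearly from 1 K to the target; each
    stage re-draws Maxwell-Boltzmann velocities and runs with friction
    gamma = 1/tau_stage.  Warns (with a diagnostic) if the trailing-window
    kinetic temperature misses the target by more than 10%.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + EQUILIBRATION_SEED_OFFSET)
    masses = np.asarray(system.masses, dtype=float)
    potential = _mapping_potential(system, lam)
    n_stages = len(config.n_equil_steps)
    targets = [1.0 + (config.temperature - 1.0) * s / (n_stages - 1)
               for s in range(n_stages)]
    state = _init_state(system, potential, targets[0], rng)
    stages: list[EquilibrationStage] = []
    trailing: list[float] = []
    for s, (n_steps, tau, T_s) in enumerate(
            zip(config.n_equil_steps, config.equil_relax_fs, targets)):
        gamma = 1.0 / tau
        state = replace(state, velocities=maxwell_velocities(
            masses, T_s, state.coords.shape[1], rng))
        kin = []
        for _ in range(n_steps):
            state = langevin_step(state, potential, config.timestep_fs, gamma,
                                  T_s, masses, rng)
            kin.append(kinetic_temperature(state.velocities, masses))
        half = kin[len(kin) // 2:]
        stages.append(EquilibrationStage(s, T_s, n_steps,
                                         float(np.mean(half))))
        if s == n_stages - 1:
            trailing = half
    mean_trailing = float(np.mean(trailing))
    # tolerance: 10% of target, widened when the trailing average cannot
    # statistically resolve 10% (few effective samples for small systems)
    ndof = state.coords.size
    tau = config.equil_relax_fs[-1]
    n_eff = max(1.0, len(trailing) * ndof * config.timestep_fs / (2.0 * tau))
    sigma = np.sqrt(2.0 / n_eff) * config.temperature
    tol = max(0.1 * config.temperature, 3.0 * sigma)
    ok = abs(mean_trailing - config.temperature) <= tol
    if not ok:
        warnings.warn(
            f"equilibration missed target temperature: trailing kinetic T "
            f"{mean_trailing:.1f} K vs target {config.temperature:.1f} K "
            f"(stages: {[(st.target_T, round(st.mean_kinetic_T, 1)) for st in stages]})",
            EquilibrationWarning,
        )
    return EquilibrationReport(state=state, stages=stages, reached_target=ok)


def run_window(system, lam: float, T: float, config: SimulationConfig,
               state: MDState, rng: np.random.Generator,
               replicate: int = 0) -> tuple[WindowTrajectory, MDState]:
    """Sample one lambda window: discarded re-equilibration then production.

    Stores per-frame diabatic energies, the ground-state energy and mixing
    weights, the mapping energy, and (optionally) coordinates and both
    state breakdowns.
    """
    masses = np.asarray(system.masses, dtype=float)
    potential = _mapping_potential(system, lam)
    gamma = config.friction_ps * 1e-3
    em, f, ev = potential(state.coords)
    state = MDState(state.coords, state.velocities, f, em, ev)
    for _ in range(config.n_window_equil_steps):
        state = langevin_step(state, potential, config.timestep_fs, gamma, T,
                              masses, rng)
    rec: dict[str, list] = {k: [] for k in
                            ("step", "e1", "e2s", "eg", "em", "w1", "kin",
                             "coords", "bd1", "bd2")}
    da = system.coupling.delta_alpha
    for step in range(config.n_prod_steps):
        state = langevin_step(state, potential, config.timestep_fs, gamma, T,
                              masses, rng)
        if (step + 1) % config.sample_stride:
            continue
        ev = state.diabats
        e2s = ev.e2 + da
        eg_val, w1, _ = ground_state_energy(ev.e1, e2s, system.coupling)
        rec["step"].append(step + 1)
        rec["e1"].append(ev.e1)
        rec["e2s"].append(e2s)
        rec["eg"].append(eg_val)
        rec["em"].append(mapping_energy(ev.e1, e2s, lam))
        rec["w1"].append(w1)
        rec["kin"].append(kinetic_temperature(state.velocities, masses))
        if config.store_coords:
            rec["coords"].append(state.coords.copy())
        if config.store_breakdowns and ev.bd1 is not None:
            rec["bd1"].append(ev.bd1.matrix)
            rec["bd2"].append(ev.bd2.matrix)
    traj = WindowTrajectory(
        lam=lam, T=T, replicate=replicate,
        step=np.array(rec["step"], dtype=int),
        e1=np.array(rec["e1"]), e2s=np.array(rec["e2s"]),
        eg=np.array(rec["eg"]), em=np.array(rec["em"]),
        w1=np.array(rec["w1"]), kin_t=np.array(rec["kin"]),
        coords=np.array(rec["coords"]) if rec["coords"] else None,
        bd1=np.array(rec["bd1"]) if rec["bd1"] else None,
        bd2=np.array(rec["bd2"]) if rec["bd2"] else None,
        config_hash=config.config_hash(),
    )
    return traj, state


def window_lambdas(n_windows: int) -> np.ndarray:
    if n_windows < 3:
        raise ValueError("need at least 3 windows")
    return np.linspace(0.0, 1.0, n_windows)


def run_fep_protocol(system, T: float, n_windows: int, n_replicates: int,
                     config: SimulationConfig) -> list[WindowTrajectory]:
    """Full FEP protocol: evenly spaced windows on [0, 1], one trajectory per
    (window, replicate).

    Window seeds follow ``master + 10000*replicate + window_index``; the
    heat-up uses the reserved window slot 9999.  A window failure aborts that
    replicate (logged) and the remaining replicates continue.
    """
    lambdas = window_lambdas(n_windows)
    cfg = replace(config, temperature=T)
    out: list[WindowTrajectory] = []
    for rep in range(n_replicates):
        base = config.seed + 10000 * rep
        try:
            report = equilibrate(
                system, cfg, lam=float(lambdas[0]),
                rng=np.random.default_rng(base + EQUILIBRATION_SEED_OFFSET))
            state = report.state
            rep_trajs = []
            for w, lam in enumerate(lambdas):
                rng = np.random.default_rng(base + w)
                traj, state = run_window(system, float(lam), T, cfg, state,
                                         rng, replicate=rep)
                logger.info("window lam=%.3f T=%.1f rep=%d frames=%d "
                            "<kinT>=%.1f", lam, T, rep, traj.n_frames,
                            float(np.mean(traj.kin_t)))
                rep_trajs.append(traj)
        except IntegrationError as err:
            logger.error("replicate %d aborted: %s", rep, err)
            continue
        out.extend(rep_trajs)
    return out
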