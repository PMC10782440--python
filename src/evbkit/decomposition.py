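"""Decomposition of the activation enthalpy into reacting-fragment terms.

Neglecting the pressure-volume term, the activation enthalpy can be
approximated by the difference in average potential energy between the
transition-state and reactant-state ensembles.  Only the terms involving the
reacting fragment are evaluated: interactions *within* the fragment (rr) and
between fragment and surroundings (rs).  The surroundings-surroundings term
involves numerically very large energies (the whole bath self-energy) and is
deliberately never computed here - the result type has no field for it, so
it cannot be misused silently.

The fragment contribution splits further into bonded (Morse bond, angle,
torsion, improper) and nonbonded (electrostatic, van der Waals) parts:

    dU_tot_r = dU_rr + dU_rs = dU_bonded + dU_nonbond

Per-frame component energies of the two diabatic states are mixed with the
ground-state eigenvector weights (w1, w2) before averaging, since the ground
surface is the physical one.  Ensembles are selected by energy-gap bin:
frames within +/- 1 bin of the RS (resp. TS) landmark of the free-energy
profile, pooled across windows and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evb_core import TERMS, EVBError, GeometryError, dihedral_value
from .free_energy import FreeEnergyProfile
from .sampler import WindowTrajectory

MIN_ENSEMBLE_FRAMES = 20
BONDED_TERMS = slice(0, 4)
NONBOND_TERMS = slice(4, 6)


class EnsembleError(EVBError):
    """Too few frames fell into the requested ensemble window."""


@dataclass
class StateEnsemble:
    """Frames pooled from all windows whose gap lies in one landmark window.

    ``bd1``/``bd2`` hold the per-frame (3, 6) group-by-term matrices of the
    two diabatic states; ``w1`` the ground-state weight of state 1.
    """

    label: str
    gap: np.ndarray
    w1: np.ndarray
    bd1: np.ndarray
    bd2: np.ndarray
    coords: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return int(self.gap.size)

    @property
    def mixed(self) -> np.ndarray:
        """Ground-state-weighted component matrices, shape (n, 3, 6)."""
        w1 = self.w1[:, None, None]
        return w1 * self.bd1 + (1.0 - w1) * self.bd2


@dataclass
class ComponentAverages:
    """Ensemble-mean U_rr / U_rs per force-field term (ss never computed)."""

    label: str
    mean_rr: dict[str, float]
    mean_rs: dict[str, float]
    frame_count: int
    flagged_low_sampling: bool

    @classmethod
    def from_ensemble(cls, ens: StateEnsemble) -> "ComponentAverages":
        mean = ens.mixed.mean(axis=0)  # (3, 6)
        if not np.all(np.isfinite(mean)):
            raise EnsembleError(f"non-finite component means in {ens.label}")
        return cls(
            label=ens.label,
            mean_rr={t: float(mean[0, i]) for i, t in enumerate(TERMS)},
            mean_rs={t: float(mean[1, i]) for i, t in enumerate(TERMS)},
            frame_count=ens.n_frames,
            flagged_low_sampling=ens.n_frames < MIN_ENSEMBLE_FRAMES,
        )


@dataclass
class ActivationDecomposition:
    """TS - RS differences of the reacting-fragment energy components.

    ``dU_tot_r = dU_rr + dU_rs = dU_bonded + dU_nonbond`` holds to 1e-9 by
    construction; ``term_deltas`` carries the six per-term differences
    (rr + rs combined)."""

    dU_rr: float
    dU_rs: float
    dU_tot_r: float
    dU_bonded: float
    dU_nonbond: float
    term_deltas: dict[str, float]
    rs_averages: ComponentAverages | None = None
    ts_averages: ComponentAverages | None = None

    @classmethod
    def from_term_deltas(cls, rr: dict[str, float], rs: dict[str, float]
                         ) -> "ActivationDecomposition":
        """Assemble the aggregate quantities from per-term rr/rs deltas."""
        term = {t: rr.get(t, 0.0) + rs.get(t, 0.0) for t in TERMS}
        d_rr = sum(rr.get(t, 0.0) for t in TERMS)
        d_rs = sum(rs.get(t, 0.0) for t in TERMS)
        bonded = sum(term[t] for t in TERMS[:4])
        nonbond = sum(term[t] for t in TERMS[4:])
        return cls(dU_rr=d_rr, dU_rs=d_rs, dU_tot_r=d_rr + d_rs,
                   dU_bonded=bonded, dU_nonbond=nonbond, term_deltas=term)

    def as_dict(self) -> dict:
        return {
            "dU_rr": self.dU_rr, "dU_rs": self.dU_rs,
            "dU_tot_r": self.dU_tot_r, "dU_bonded": self.dU_bonded,
            "dU_nonbond": self.dU_nonbond,
            "term_deltas": dict(self.term_deltas),
            "rs_frames": None if self.rs_averages is None
            else self.rs_averages.frame_count,
            "ts_frames": None if self.ts_averages is None
            else self.ts_averages.frame_count,
        }


def _pool(windows: Sequence[WindowTrajectory], lo: float, hi: float,
          label: str) -> StateEnsemble:
    gaps, w1s, b1s, b2s, xyz = [], [], [], [], []
    have_coords = all(w.coords is not None for w in windows)
    for w in windows:
        if w.bd1 is None or w.bd2 is None:
            raise EnsembleError(
                "window trajectories lack per-frame breakdowns; rerun with "
                "store_breakdowns=True")
        sel = (w.gap >= lo) & (w.gap < hi)
        if not np.any(sel):
            continue
        gaps.append(w.gap[sel])
        w1s.append(w.w1[sel])
        b1s.append(w.bd1[sel])
        b2s.append(w.bd2[sel])
        if have_coords:
            xyz.append(w.coords[sel])
    if not gaps:
        raise EnsembleError(
            f"no frames in the {label} gap window [{lo:.2f}, {hi:.2f}); "
            "longer sampling is needed")
    ens = StateEnsemble(
        label=label, gap=np.concatenate(gaps), w1=np.concatenate(w1s),
        bd1=np.concatenate(b1s), bd2=np.concatenate(b2s),
        coords=np.concatenate(xyz) if xyz else None)
    if ens.n_frames < MIN_ENSEMBLE_FRAMES:
        raise EnsembleError(
            f"only {ens.n_frames} frames in the {label} ensemble "
            f"(< {MIN_ENSEMBLE_FRAMES}); longer sampling is needed")
    return ens


def select_state_frames(windows: Sequence[WindowTrajectory],
                        profile: FreeEnergyProfile, halfwidth: int = 1,
                        ) -> tuple[StateEnsemble, StateEnsemble]:
    """Pool RS and TS ensembles from all windows by energy-gap bin.

    The RS (TS) ensemble collects frames whose gap falls within
    ``halfwidth`` bins of the profile's RS (TS) landmark, pooled across
    windows and replicates.  Requires an extracted profile.
    """
    if profile.rs_index is None or profile.ts_index is None:
        raise ValueError("profile landmarks missing; run extract_barriers first")
    edges = profile.edges

    def _window(idx: int) -> tuple[float, float]:
        lo = edges[max(idx - halfwidth, 0)]
        hi = edges[min(idx + halfwidth + 1, edges.size - 1)]
        return float(lo), float(hi)

    rs = _pool(windows, *_window(profile.rs_index), label="RS")
    ts = _pool(windows, *_window(profile.ts_index), label="TS")
    return rs, ts


def decompose_activation(rs: StateEnsemble, ts: StateEnsemble
                         ) -> ActivationDecomposition:
    """TS - RS ensemble averages of the rr and rs components, per term."""
    avg_rs = ComponentAverages.from_ensemble(rs)
    avg_ts = ComponentAverages.from_ensemble(ts)
    rr = {t: avg_ts.mean_rr[t] - avg_rs.mean_rr[t] for t in TERMS}
    rsd = {t: avg_ts.mean_rs[t] - avg_rs.mean_rs[t] for t in TERMS}
    out = ActivationDecomposition.from_term_deltas(rr, rsd)
    out.rs_averages = avg_rs
    out.ts_averages = avg_ts
    return out


# ---------------------------------------------------------------------------
# geometric observables
# ---------------------------------------------------------------------------

@dataclass
class GeometryObservables:
    """Per-frame distances (A) and torsions (degrees) with ensemble stats."""

    series: dict[str, np.ndarray]
    mean: dict[str, float]
    sem: dict[str, float]


def measure_geometry(coords: np.ndarray,
                     definitions: dict[str, tuple[int, ...]]
                     ) -> GeometryObservables:
    """Evaluate named distances (atom pairs) and torsions (atom quadruples).

    ``coords`` has shape (n_frames, n_atoms, 3).  Torsions are reported in
    degrees in (-180, 180]; collinear quadruples raise
    :class:`~evbkit.evb_core.GeometryError`.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
    n_atoms = coords.shape[1]
    series: dict[str, np.ndarray] = {}
    for name, atoms in definitions.items():
        if any(not 0 <= a < n_atoms for a in atoms):
            raise ValueError(f"{name}: invalid atom id in {atoms}")
        if len(atoms) == 2:
            i, j = atoms
            series[name] = np.linalg.norm(coords[:, j] - coords[:, i], axis=1)
        elif len(atoms) == 4:
            vals = np.array([dihedral_value(frame, *atoms)
                             for frame in coords])
            series[name] = np.rad2deg(vals)
        else:
            raise ValueError(f"{name}: definitions need 2 (distance) or "
                             f"4 (torsion) atoms, got {len(atoms)}")
    n = coords.shape[0]
    mean = {k: float(v.mean()) for k, v in series.items()}
    sem = {k: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
           for k, v in series.items()}
    return GeometryObservables(series=series, mean=mean, sem=sem)
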