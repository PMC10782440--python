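"""Free-energy profiles along the energy-gap coordinate.

Two estimators combine into the reactive free-energy profile:

1. *FEP between adjacent mapping potentials.*  The free-energy change from
   window m to m+1 is the Zwanzig exponential average
   ``dG = -kT * ln < exp(-beta * (eps_{m+1} - eps_m)) >_m``; forward and
   backward estimates from the two windows are averaged, which cancels the
   leading-order bias on well-overlapped windows.

2. *Umbrella correction to the ground state.*  Within each window, frames
   are binned by the energy gap ``deps = eps1 - eps2'`` and reweighted from
   the mapping potential to the ground-state surface:

   ``dg(deps_n) = dG(lam_m) - kT * ln < delta(deps - deps_n) *
   exp(-beta*(Eg - eps_m)) >_m``

   Bins receiving frames from several windows are combined by the
   count-weighted average of the per-window estimates.

The profile's landmarks are the reactant-side minimum (RS), the highest
interior bin between the two basin minima (TS) and the product-side minimum
(PS); the activation and reaction free energies are ``dG_act = dg(TS) -
dg(RS)`` and ``dG0 = dg(PS) - dg(RS)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .evb_core import KB, EVBError
from .sampler import WindowTrajectory

DEFAULT_BINS = 101
MIN_FRAMES_PER_WINDOW = 10
MIN_FRAMES_PER_BIN = 10


class OverlapWarning(UserWarning):
    """Poor phase-space overlap between adjacent windows."""


class SamplingGapError(EVBError):
    """Unsampled bins between the reactant and product basins."""


class BarrierlessError(EVBError):
    """Profile has no interior maximum between two basins."""


@dataclass
class FEPResult:
    """Cumulative free energy along the mapping parameter at one temperature.

    ``dG[0] = 0`` by construction; ``dG_fwd``/``dG_bwd`` are the raw one-sided
    increments (backward stored as the m+1 -> m estimate)."""

    lambdas: np.ndarray
    dG: np.ndarray
    dG_fwd: np.ndarray
    dG_bwd: np.ndarray
    T: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.dG)):
            raise ValueError("non-finite FEP increments")


@dataclass
class FreeEnergyProfile:
    """Binned ground-state free energy along the energy gap.

    ``dg`` is NaN in masked (undersampled) bins.  Landmark indices and the
    derived barriers are filled in by :func:`extract_barriers`."""

    edges: np.ndarray
    centers: np.ndarray
    dg: np.ndarray
    counts: np.ndarray
    T: float
    replicate: int | None = None
    rs_index: int | None = None
    ts_index: int | None = None
    ps_index: int | None = None
    dG_act: float | None = None
    dG0: float | None = None


def _sorted_single_replicate(windows: Sequence[WindowTrajectory]):
    reps = {w.replicate for w in windows}
    if len(reps) != 1:
        raise ValueError("fep_cumulative expects windows of one replicate; "
                         "split by replicate first")
    temps = {w.T for w in windows}
    if len(temps) != 1:
        raise ValueError("windows must share one temperature")
    return sorted(windows, key=lambda w: w.lam)


def fep_cumulative(windows: Sequence[WindowTrajectory], T: float) -> FEPResult:
    """Averaged forward/backward Zwanzig estimate of dG(lambda_m).

    Refuses windows with fewer than 10 frames; warns when the effective
    sample size of the exponential weights drops below 5% of the frames.
    """
    ws = _sorted_single_replicate(windows)
    if len(ws) < 2:
        raise ValueError("need at least two windows")
    for w in ws:
        if w.n_frames < MIN_FRAMES_PER_WINDOW:
            raise ValueError(
                f"window lam={w.lam:.3f} has only {w.n_frames} frames "
                f"(< {MIN_FRAMES_PER_WINDOW})")
    beta = 1.0 / (KB * T)
    n = len(ws)
    fwd = np.zeros(n - 1)
    bwd = np.zeros(n - 1)
    for m in range(n - 1):
        dlam = ws[m + 1].lam - ws[m].lam
        # eps_{m+1} - eps_m on frames of window m: -dlam * gap
        du_f = -dlam * ws[m].gap
        fwd[m] = -(logsumexp(-beta * du_f) - np.log(du_f.size)) / beta
        du_b = dlam * ws[m + 1].gap
        bwd[m] = -(logsumexp(-beta * du_b) - np.log(du_b.size)) / beta
        for du, which in ((du_f, "forward"), (du_b, "backward")):
            lw = -beta * du
            ess = np.exp(2 * logsumexp(lw) - logsumexp(2 * lw))
            if ess < 0.05 * du.size:
                warnings.warn(
                    f"poor {which} overlap between lam={ws[m].lam:.3f} and "
                    f"lam={ws[m + 1].lam:.3f}: ESS {ess:.1f} of {du.size}",
                    OverlapWarning)
    inc = 0.5 * (fwd - bwd)
    dG = np.concatenate([[0.0], np.cumsum(inc)])
    return FEPResult(lambdas=np.array([w.lam for w in ws]), dG=dG,
                     dG_fwd=fwd, dG_bwd=bwd, T=T)


def umbrella_profile(windows: Sequence[WindowTrajectory], fep: FEPResult,
                     bins: int | np.ndarray = DEFAULT_BINS,
                     min_frames_per_bin: int = MIN_FRAMES_PER_BIN,
                     ) -> FreeEnergyProfile:
    """Combine window contributions into the ground-state gap profile.

    ``bins`` may be a bin count (edges span the sampled gap range) or an
    explicit edge array.  Bins with fewer than ``min_frames_per_bin`` total
    frames are masked; a masked bin strictly between the outermost sampled
    bins raises :class:`SamplingGapError`.
    """
    ws = _sorted_single_replicate(windows)
    beta = 1.0 / (KB * fep.T)
    gaps = [w.gap for w in ws]
    if isinstance(bins, (int, np.integer)):
        lo = min(g.min() for g in gaps)
        hi = max(g.max() for g in gaps)
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if edges.ndim != 1 or edges.size < 4 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    nb = edges.size - 1
    num = np.zeros(nb)
    den = np.zeros(nb, dtype=int)
    for w, dGm in zip(ws, fep.dG):
        gap = w.gap
        logw = -beta * (w.eg - w.em)  # >= -beta*0; reweighting to ground state
        idx = np.digitize(gap, edges) - 1
        idx[gap == edges[-1]] = nb - 1
        inside = (idx >= 0) & (idx < nb)
        for b in np.unique(idx[inside]):
            sel = idx == b
            cnt = int(sel.sum())
            # <delta * exp>_m over ALL frames of the window
            log_mean = logsumexp(logw[sel]) - np.log(gap.size)
            g_mb = dGm - log_mean / beta
            num[b] += cnt * g_mb
            den[b] += cnt
    dg = np.full(nb, np.nan)
    ok = den >= min_frames_per_bin
    dg[ok] = num[ok] / den[ok]
    if not np.any(ok):
        raise SamplingGapError("no bin reached the frame threshold")
    if max(len(s) for s in _finite_segments(dg)) < 3:
        raise SamplingGapError(
            "no contiguous sampled region of at least 3 bins; sampling gaps "
            "fragment the profile")
    dg -= np.nanmin(dg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyProfile(edges=edges, centers=centers, dg=dg, counts=den,
                             T=fep.T, replicate=ws[0].replicate)


def _finite_segments(dg: np.ndarray) -> list[np.ndarray]:
    """Index arrays of the contiguous finite runs of a masked profile."""
    finite = np.isfinite(dg)
    segs = []
    start = None
    for i, f in enumerate(finite):
        if f and start is None:
            start = i
        elif not f and start is not None:
            segs.append(np.arange(start, i))
            start = None
    if start is not None:
        segs.append(np.arange(start, dg.size))
    return segs


def extract_barriers(profile: FreeEnergyProfile) -> tuple[float, float]:
    """Locate RS/TS/PS and return (dG_act, dG0); normalizes dg(RS) to 0.

    Landmarks are searched on the main contiguous sampled segment (the one
    containing the global minimum): RS and PS are the two lowest basin
    minima (RS the one at lower gap), TS the highest bin strictly between
    them.  Ties break toward lower gap.  Raises :class:`BarrierlessError`
    when no interior maximum separates two basins, or
    :class:`SamplingGapError` when an unsampled region cuts the second
    basin off the main segment.
    """
    dg = profile.dg
    segs = _finite_segments(dg)
    if not segs or max(len(s) for s in segs) < 3:
        raise BarrierlessError("profile has fewer than 3 usable bins")
    i_min = int(np.nanargmin(dg))
    main = next(s for s in segs if s[0] <= i_min <= s[-1])
    if len(main) < 3:
        raise SamplingGapError(
            "sampling gaps isolate the global minimum from the rest of the "
            "profile")
    lo, hi = int(main[0]), int(main[-1])
    v = dg[lo:hi + 1]
    # dominant interior maximum: the local max with the largest barrier over
    # the lower of its flanking minima (robust to small noise dips)
    best, best_prom = None, 0.0
    for i in range(1, v.size - 1):
        if v[i] >= v[i - 1] and v[i] >= v[i + 1]:
            prom = v[i] - max(float(np.min(v[:i])), float(np.min(v[i + 1:])))
            if prom > best_prom:
                best, best_prom = i, prom
    if best is None or best_prom <= 0:
        # a lower bin in a detached segment means a sampling gap cut off the
        # second basin; otherwise the surface is genuinely barrierless
        for s in segs:
            if s is main:
                continue
            edge = dg[hi] if s[0] > hi else dg[lo]
            if np.nanmin(dg[s]) < edge:
                raise SamplingGapError(
                    "unsampled gap region separates the reactant and product "
                    "basins; longer sampling or wider windows are needed")
        raise BarrierlessError("barrierless profile: no interior maximum "
                               "between two basins")
    i_rs = int(np.argmin(v[:best]))          # lowest bin on the reactant side
    i_ps = best + 1 + int(np.argmin(v[best + 1:]))  # lowest on product side
    i_ts = i_rs + 1 + int(np.argmax(v[i_rs + 1:i_ps]))  # highest in between
    if not (v[i_ts] > v[i_rs] and v[i_ts] > v[i_ps]):
        raise BarrierlessError("barrierless profile: no interior maximum")
    profile.rs_index = int(lo + i_rs)
    profile.ts_index = int(lo + i_ts)
    profile.ps_index = int(lo + i_ps)
    profile.dg = dg - v[i_rs]
    profile.dG_act = float(v[i_ts] - v[i_rs])
    profile.dG0 = float(v[i_ps] - v[i_rs])
    return profile.dG_act, profile.dG0


def replicate_profiles(windows: Sequence[WindowTrajectory], T: float,
                       bins: int | np.ndarray = DEFAULT_BINS,
                       ) -> list[FreeEnergyProfile]:
    """One extracted profile per replicate present in ``windows``."""
    reps = sorted({w.replicate for w in windows})
    profiles = []
    for rep in reps:
        ws = [w for w in windows if w.replicate == rep]
        fep = fep_cumulative(ws, T)
        prof = umbrella_profile(ws, fep, bins=bins)
        extract_barriers(prof)
        profiles.append(prof)
    return profiles


def average_profile(profiles: Sequence[FreeEnergyProfile],
                    min_replicate_fraction: float = 0.5,
                    ) -> FreeEnergyProfile:
    """Count-weighted average of replicate profiles on shared bin edges.

    Bins sampled by fewer than ``min_replicate_fraction`` of the replicates
    (at least 2) are masked: a bin visited by a single replicate's tail
    carries no cross-replicate support.  The averaged profile is
    re-normalized to a zero minimum.
    """
    if len(profiles) == 1:
        return profiles[0]
    edges = profiles[0].edges
    for p in profiles[1:]:
        if p.edges.shape != edges.shape or not np.allclose(p.edges, edges):
            raise ValueError("average_profile needs profiles on shared edges")
    dgs = np.array([p.dg for p in profiles])
    w = np.array([p.counts for p in profiles], dtype=float)
    w[~np.isfinite(dgs)] = 0.0
    n_contrib = (w > 0).sum(axis=0)
    need = max(2, int(np.ceil(min_replicate_fraction * len(profiles))))
    tot = w.sum(axis=0)
    with np.errstate(invalid="ignore"):
        avg = np.where(n_contrib >= need,
                       np.nansum(np.where(w > 0, dgs * w, 0.0), axis=0)
                       / np.where(tot > 0, tot, 1.0),
                       np.nan)
    avg -= np.nanmin(avg)
    return FreeEnergyProfile(edges=edges,
                             centers=0.5 * (edges[:-1] + edges[1:]),
                             dg=avg, counts=tot.astype(int),
                             T=profiles[0].T, replicate=None)


def common_gap_edges(windows: Sequence[WindowTrajectory],
                     bins: int = DEFAULT_BINS) -> np.ndarray:
    """Bin edges spanning the pooled sampled gap range of all windows."""
    lo = min(float(w.gap.min()) for w in windows)
    hi = max(float(w.gap.max()) for w in windows)
    return np.linspace(lo, hi, int(bins) + 1)


def barrier_statistics(profiles: Sequence[FreeEnergyProfile]) -> dict:
    """Mean and SEM of dG_act / dG0 across replicate profiles."""
    acts = np.array([p.dG_act for p in profiles], dtype=float)
    d0s = np.array([p.dG0 for p in profiles], dtype=float)
    n = acts.size

    def _sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    return {
        "n_replicates": int(n),
        "dG_act_mean": float(acts.mean()),
        "dG_act_sem": _sem(acts),
        "dG0_mean": float(d0s.mean()),
        "dG0_sem": _sem(d0s),
    }
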