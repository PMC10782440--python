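"""FEP estimator, umbrella combination and barrier extraction."""

import numpy as np
import pytest

from evbkit.evb_core import KB, EVBCoupling, DiabatsResult
from evbkit.free_energy import (BarrierlessError, FreeEnergyProfile,
                                average_profile, barrier_statistics,
                                common_gap_edges, extract_barriers,
                                fep_cumulative, replicate_profiles,
                                umbrella_profile)
from evbkit.sampler import SimulationConfig, WindowTrajectory, run_fep_protocol
from evbkit.synthetic import make_oracle_1d, oracle_profile_quadrature

T = 298.0
BETA = 1.0 / (KB * T)


def _window(lam, e1, e2s, replicate=0):
    e1 = np.asarray(e1, dtype=float)
    e2s = np.asarray(e2s, dtype=float)
    em = (1 - lam) * e1 + lam * e2s
    eg = np.minimum(e1, e2s)
    n = e1.size
    return WindowTrajectory(lam=lam, T=T, replicate=replicate,
                            step=np.arange(n), e1=e1, e2s=e2s, eg=eg, em=em,
                            w1=np.full(n, 0.5), kin_t=np.full(n, T))


class TestFEP:
    def test_identical_potentials_zero_increments(self):
        e = np.linspace(0, 1, 50)
        ws = [_window(lam, e, e) for lam in (0.0, 0.5, 1.0)]
        fep = fep_cumulative(ws, T)
        np.testing.assert_allclose(fep.dG, 0.0, atol=1e-12)

    def test_too_few_frames_refused(self):
        ws = [_window(0.0, np.zeros(5), np.zeros(5)),
              _window(1.0, np.zeros(5), np.zeros(5))]
        with pytest.raises(ValueError, match="frames"):
            fep_cumulative(ws, T)

    def test_displaced_harmonic_free_energy(self):
        """Equal-width displaced wells: dG(0 -> 1) equals the diabat offset
        (equal force constants mean identical partition widths)."""
        offset = 3.7
        params = {"type": "oracle1d", "name": "t", "k": 300.0, "x1": 0.2,
                  "x2": 0.8, "c2": offset, "domain": [-0.4, 1.4],
                  "mass": 12.0,
                  "coupling": {"delta_alpha": 0.0, "h12": 0.0}}
        system = make_oracle_1d(params)
        cfg = SimulationConfig(seed=5, n_prod_steps=1500,
                               n_window_equil_steps=200)
        ends = []
        for rep in range(3):
            trajs = run_fep_protocol(system, T, 11, 1,
                                     SimulationConfig(seed=5 + 100 * rep,
                                                      n_prod_steps=1500,
                                                      n_window_equil_steps=200))
            ends.append(fep_cumulative(trajs, T).dG[-1])
        sem = np.std(ends, ddof=1) / np.sqrt(len(ends))
        assert abs(np.mean(ends) - offset) < max(3 * sem, 0.05)

    def test_forward_and_averaged_estimators_agree(
            self, reference_trajectories):
        ws = [w for w in reference_trajectories if w.replicate == 0]
        fep = fep_cumulative(ws, T)
        fwd_total = float(np.sum(fep.dG_fwd))
        avg_total = float(fep.dG[-1])
        assert abs(fwd_total - avg_total) < 0.2


class TestUmbrella:
    def test_combined_bins_are_count_weighted_means(self):
        """Bins fed by two windows combine as the count-weighted average
        of the per-window estimates (hence lie between them), up to the
        single global normalization constant."""
        from scipy.special import logsumexp
        rng = np.random.default_rng(0)
        e1a = rng.normal(0.0, 0.3, 200)
        e1b = rng.normal(-0.05, 0.3, 200)
        wa = _window(0.0, e1a, e1a + 1.0 + rng.normal(0, 0.3, 200))
        wb = _window(0.1, e1b, e1b + 1.0 + rng.normal(0, 0.3, 200))
        fep = fep_cumulative([wa, wb], T)
        edges = np.linspace(-1.6, -0.4, 7)
        prof = umbrella_profile([wa, wb], fep, bins=edges,
                                min_frames_per_bin=1)
        offsets = []
        for b in range(edges.size - 1):
            vals, counts = [], []
            for w, dg0 in ((wa, fep.dG[0]), (wb, fep.dG[1])):
                sel = (w.gap >= edges[b]) & (w.gap < edges[b + 1])
                if sel.sum() == 0:
                    continue
                lm = logsumexp(-BETA * (w.eg[sel] - w.em[sel])) \
                    - np.log(w.gap.size)
                vals.append(dg0 - lm / BETA)
                counts.append(sel.sum())
            if not vals or not np.isfinite(prof.dg[b]):
                continue
            expected = np.average(vals, weights=counts)
            assert min(vals) - 1e-9 <= expected <= max(vals) + 1e-9
            offsets.append(prof.dg[b] - expected)
        # normalization is one shared constant across all bins
        assert len(offsets) >= 4
        assert np.ptp(offsets) < 1e-9

    def test_profile_invariant_under_global_diabat_shift(
            self, calibrated_reference):
        """Adding a constant to both diabats leaves the profile unchanged."""
        system, _ = calibrated_reference

        class Shifted:
            dim = 1
            restraint = None
            masses = system.masses
            coupling = system.coupling

            def initial_coords(self):
                return system.initial_coords()

            def evaluate(self, coords):
                ev = system.evaluate(coords)
                return DiabatsResult(e1=ev.e1 + 55.5, e2=ev.e2 + 55.5,
                                     f1=ev.f1, f2=ev.f2)

        cfg = SimulationConfig(seed=8, n_prod_steps=600,
                               n_window_equil_steps=100)
        base = run_fep_protocol(system, T, 11, 1, cfg)
        shifted = run_fep_protocol(Shifted(), T, 11, 1, cfg)
        pb = replicate_profiles(base, T, bins=41)[0]
        ps = replicate_profiles(shifted, T, bins=41)[0]
        np.testing.assert_allclose(pb.dg, ps.dg, atol=1e-8)
        assert pb.dG_act == pytest.approx(ps.dG_act, abs=1e-8)

    def test_state_swap_reverses_profile(self):
        """Swapping diabat labels (delta_alpha folded) maps
        (dG_act, dG0) -> (dG_act - dG0, -dG0); checked on quadrature."""
        system = make_oracle_1d("reference")
        cal = system.with_coupling(EVBCoupling(-12.86, 7.22))
        prof = oracle_profile_quadrature(cal, T)
        act, d0 = extract_barriers(prof)
        # state1' = old state2', state2' = old state1 up to one global
        # constant: swap the minima and negate the folded offset
        # (c2' + delta_alpha' = -(c2 + delta_alpha))
        swapped_params = {"type": "oracle1d", "name": "sw", "k": cal.k,
                          "x1": cal.x2, "x2": cal.x1,
                          "c2": -cal.c2,
                          "domain": list(cal.domain), "mass": cal.mass,
                          "coupling": {"delta_alpha":
                                       -cal.coupling.delta_alpha,
                                       "h12": cal.coupling.h12}}
        sw = make_oracle_1d(swapped_params)
        prof_sw = oracle_profile_quadrature(sw, T)
        act_sw, d0_sw = extract_barriers(prof_sw)
        assert act_sw == pytest.approx(act - d0, abs=2e-2)
        assert d0_sw == pytest.approx(-d0, abs=2e-2)


class TestBarriers:
    def _profile(self, dg, counts=None):
        dg = np.asarray(dg, dtype=float)
        n = dg.size
        edges = np.arange(n + 1, dtype=float)
        return FreeEnergyProfile(edges=edges,
                                 centers=0.5 * (edges[:-1] + edges[1:]),
                                 dg=dg,
                                 counts=np.full(n, 100) if counts is None
                                 else np.asarray(counts),
                                 T=T)

    def test_piecewise_example(self):
        act, d0 = extract_barriers(self._profile([0.0, 10.0, -5.0]))
        assert act == 10.0 and d0 == -5.0

    def test_monotone_profile_is_barrierless(self):
        with pytest.raises(BarrierlessError):
            extract_barriers(self._profile([5.0, 3.0, 1.0]))

    def test_normalization_and_ordering(self):
        p = self._profile([2.0, 1.0, 6.0, -3.0, 4.0])
        act, d0 = extract_barriers(p)
        assert p.dg[p.rs_index] == 0.0
        assert p.rs_index < p.ts_index < p.ps_index
        assert act == pytest.approx(5.0) and d0 == pytest.approx(-4.0)
        assert act >= 0.0


class TestReplicateStatistics:
    def test_sem_scales_with_sampling_length(self):
        """Doubling window length shrinks the replicate SEM of dG_act by
        about sqrt(2) (Monte-Carlo scaling, checked loosely)."""
        system = make_oracle_1d("reference").with_coupling(
            EVBCoupling(-12.86, 7.22))
        sems = {}
        for steps in (300, 600):
            acts = []
            for rep in range(128):
                cfg = SimulationConfig(seed=1000 * steps + rep,
                                       n_prod_steps=steps,
                                       n_window_equil_steps=80,
                                       n_equil_steps=(40,) * 5 + (120,),
                                       sample_stride=2)
                trajs = run_fep_protocol(system, T, 11, 1, cfg)
                acts.append(replicate_profiles(trajs, T, bins=31)[0].dG_act)
            sems[steps] = np.std(acts, ddof=1)
        ratio = sems[300] / sems[600]
        assert 1.2 <= ratio <= 1.7

    def test_barrier_statistics_summary(self, reference_trajectories):
        profiles = replicate_profiles(reference_trajectories, T)
        stats = barrier_statistics(profiles)
        assert stats["n_replicates"] == 10
        assert stats["dG_act_sem"] > 0
        assert stats["dG_act_mean"] == pytest.approx(24.5, abs=0.5)

    def test_average_profile_requires_shared_edges(
            self, reference_trajectories):
        profiles = replicate_profiles(reference_trajectories, T)
        with pytest.raises(ValueError):
            average_profile(profiles)  # per-replicate spans differ
        edges = common_gap_edges(reference_trajectories)
        shared = replicate_profiles(reference_trajectories, T, bins=edges)
        avg = average_profile(shared)
        assert np.isfinite(avg.dg).sum() >= 80
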