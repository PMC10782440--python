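"""Unit and property tests for the two-state EVB energetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evbkit.evb_core import (COULOMB_CONSTANT, AtomSpec, DiabaticTopology,
                             EnergyBreakdown, EVBCoupling, GeometryError,
                             HarmonicAngle, ImproperTerm, MorseBond,
                             NonbondedParams, SingularityError, TopologyError,
                             TorsionTerm, build_exclusions, diabatic_energy,
                             diabatic_energy_forces, dihedral_value,
                             energy_gap, ground_state_energy, mapping_energy,
                             morse_energy, system_from_dict, system_to_dict)

finite = st.floats(min_value=-500, max_value=500)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

class TestMorse:
    BOND = MorseBond((0, 1), D=100.0, a=2.0, r0=1.5)

    def test_zero_at_equilibrium(self):
        assert morse_energy(1.5, self.BOND) == 0.0

    def test_dissociation_plateau(self):
        r = self.BOND.r0 + 50.0 / self.BOND.a
        assert morse_energy(r, self.BOND) == pytest.approx(100.0,
                                                           rel=1e-9)

    def test_stretched_value(self):
        # direct evaluation of D*(1 - exp(-a*(r-r0)))**2 at r = 1.6
        expected = 100.0 * (1.0 - np.exp(-0.2)) ** 2
        assert morse_energy(1.6, self.BOND) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            morse_energy(0.0, self.BOND)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(TopologyError):
            MorseBond((0, 0), 100.0, 2.0, 1.5)
        with pytest.raises(TopologyError):
            MorseBond((0, 1), -1.0, 2.0, 1.5)


class TestGroundState:
    def test_degenerate_states(self):
        eg, w1, w2 = ground_state_energy(0.0, 0.0, EVBCoupling(0.0, 86.8))
        assert eg == pytest.approx(-86.8)
        assert w1 == pytest.approx(0.5) and w2 == pytest.approx(0.5)

    def test_uncoupled_lower_diabat(self):
        eg, w1, w2 = ground_state_energy(5.0, 3.0, EVBCoupling(0.0, 0.0))
        assert eg == 3.0 and w2 == 1.0

    def test_closed_form(self):
        eg, _, _ = ground_state_energy(0.0, 10.0, EVBCoupling(0.0, 5.0))
        assert eg == pytest.approx(5.0 - np.sqrt(50.0), rel=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(e1=finite, e2=finite, h=st.floats(min_value=0, max_value=200))
    def test_exchange_symmetry_and_bound(self, e1, e2, h):
        c = EVBCoupling(0.0, h)
        eg, w1, w2 = ground_state_energy(e1, e2, c)
        eg_sw, w1_sw, w2_sw = ground_state_energy(e2, e1, c)
        assert eg == pytest.approx(eg_sw, abs=1e-9)
        assert eg <= min(e1, e2) + 1e-9
        assert w1 + w2 == pytest.approx(1.0)
        assert w1_sw == pytest.approx(w2, abs=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(e1=finite, e2=finite,
           h=st.floats(min_value=0.0, max_value=100),
           dh=st.floats(min_value=0.1, max_value=50))
    def test_coupling_only_lowers_ground_state(self, e1, e2, h, dh):
        lo, _, _ = ground_state_energy(e1, e2, EVBCoupling(0.0, h))
        hi, _, _ = ground_state_energy(e1, e2, EVBCoupling(0.0, h + dh))
        assert hi <= lo + 1e-12

    def test_negative_h12_rejected(self):
        with pytest.raises(ValueError):
            EVBCoupling(0.0, -1.0)


class TestMappingAndGap:
    def test_endpoints_and_midpoint(self):
        assert mapping_energy(2.0, 6.0, 0.0) == 2.0
        assert mapping_energy(2.0, 6.0, 1.0) == 6.0
        assert mapping_energy(2.0, 6.0, 0.5) == 4.0

    def test_lambda_range_enforced(self):
        with pytest.raises(ValueError):
            mapping_energy(0.0, 1.0, 1.5)

    def test_gap_antisymmetry(self):
        assert energy_gap(10.0, -5.0) == 15.0
        assert energy_gap(-5.0, 10.0) == -15.0
        assert energy_gap(3.0, 3.0) == 0.0


# ---------------------------------------------------------------------------
# topology evaluation
# ---------------------------------------------------------------------------

def _two_charge_topology(q=1.0, eps=0.0):
    atoms = [AtomSpec(0, 12.0, True), AtomSpec(1, 12.0, True)]
    nb = NonbondedParams(np.array([q, q]), np.array([3.0, 3.0]),
                         np.array([eps, eps]))
    return DiabaticTopology(atoms, [], [], [], [], nb, label=1)


def _random_topology(seed):
    """Four atoms carrying every term type, for gradient checks."""
    rng = np.random.default_rng(seed)
    atoms = [AtomSpec(0, 12.0, True), AtomSpec(1, 12.0, True),
             AtomSpec(2, 16.0, True), AtomSpec(3, 12.0, False)]
    nb = NonbondedParams(rng.uniform(-0.5, 0.5, 4), rng.uniform(2.8, 3.4, 4),
                         rng.uniform(0.05, 0.2, 4),
                         exclusions=frozenset({frozenset((0, 1)),
                                               frozenset((1, 2))}),
                         pairs14=frozenset({frozenset((0, 3))}))
    topo = DiabaticTopology(
        atoms,
        [MorseBond((0, 1), 100.0, 2.0, 1.45), MorseBond((1, 2), 90.0, 1.6, 1.5)],
        [HarmonicAngle((0, 1, 2), 60.0, 1.9)],
        [TorsionTerm((0, 1, 2, 3), 2.0, 3, 0.4)],
        [ImproperTerm((1, 0, 2, 3), 4.0, 0.2)],
        nb, label=1)
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.3, 0.2],
                       [1.8, 2.5, 1.0]], dtype=float)
    coords += 0.1 * rng.standard_normal(coords.shape)
    return topo, coords


class TestDiabaticEnergy:
    def test_single_morse_bond_at_equilibrium(self):
        atoms = [AtomSpec(0, 12.0, True), AtomSpec(1, 12.0, True)]
        nb = NonbondedParams(np.zeros(2), np.ones(2) * 3.0, np.zeros(2),
                             exclusions=frozenset({frozenset((0, 1))}))
        topo = DiabaticTopology(atoms, [MorseBond((0, 1), 100.0, 2.0, 1.5)],
                                [], [], [], nb, label=1)
        bd = diabatic_energy(np.array([[0.0, 0, 0], [1.5, 0, 0]]), topo)
        assert bd.total == pytest.approx(0.0, abs=1e-12)

    def test_unit_charges_at_one_angstrom(self):
        bd = diabatic_energy(np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                             _two_charge_topology())
        assert bd.elec == pytest.approx(COULOMB_CONSTANT, rel=1e-12)
        assert bd.total == pytest.approx(332.0636, abs=1e-3)

    def test_overlapping_atoms_raise(self):
        with pytest.raises(SingularityError):
            diabatic_energy(np.array([[0.0, 0, 0], [1e-9, 0, 0]]),
                            _two_charge_topology())

    def test_mismatched_dimensions_raise(self):
        with pytest.raises(TopologyError):
            diabatic_energy(np.zeros((3, 3)), _two_charge_topology())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_breakdown_additivity(self, seed):
        topo, coords = _random_topology(seed)
        bd = diabatic_energy(coords, topo)
        m = bd.matrix
        assert bd.total == pytest.approx(m.sum(), rel=1e-12)
        for ti, t in enumerate(("bond", "angle", "torsion", "improper",
                                "elec", "vdw")):
            assert bd.term(t) == pytest.approx(m[:, ti].sum(), rel=1e-9,
                                               abs=1e-12)
        assert bd.rr + bd.rs + bd.ss == pytest.approx(bd.total, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_forces_match_finite_differences(self, seed):
        topo, coords = _random_topology(seed)
        bd, f = diabatic_energy_forces(coords, topo)
        h = 1e-6
        num = np.zeros_like(f)
        for i in range(coords.shape[0]):
            for d in range(3):
                xp, xm = coords.copy(), coords.copy()
                xp[i, d] += h
                xm[i, d] -= h
                ep = diabatic_energy(xp, topo).total
                em = diabatic_energy(xm, topo).total
                num[i, d] = -(ep - em) / (2 * h)
        scale = max(1.0, np.abs(f).max())
        assert np.abs(f - num).max() / scale < 1e-5


class TestGeometryPrimitives:
    def test_square_planar_torsion_is_zero(self):
        square = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert dihedral_value(square, 0, 1, 2, 3) == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_collinear_raises(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        with pytest.raises(GeometryError):
            dihedral_value(line, 0, 1, 2, 3)


class TestExclusionsAndSerialization:
    def test_build_exclusions_chain(self):
        excl, p14 = build_exclusions(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert frozenset((0, 1)) in excl          # 1-2
        assert frozenset((0, 2)) in excl          # 1-3
        assert frozenset((0, 3)) in p14           # 1-4
        assert frozenset((0, 4)) not in excl | p14  # 1-5 fully interacting

    def test_system_document_roundtrip(self):
        from evbkit.synthetic import make_toy_reaction
        sys_ = make_toy_reaction("reference", seed=0)
        doc = system_to_dict(sys_.atoms, sys_.state1, sys_.state2,
                             sys_.coupling)
        atoms, s1, s2, coupling = system_from_dict(doc)
        assert coupling == sys_.coupling
        assert [a.id for a in atoms] == [a.id for a in sys_.atoms]
        coords = sys_.initial_coords()
        for orig, restored in ((sys_.state1, s1), (sys_.state2, s2)):
            assert diabatic_energy(coords, restored).total == pytest.approx(
                diabatic_energy(coords, orig).total, rel=1e-12)

    def test_breakdown_shape_validated(self):
        with pytest.raises(ValueError):
            EnergyBreakdown(np.zeros((2, 6)))
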