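"""State enumeration, tropomyosin energetics and free-energy consistency."""

import numpy as np
import pytest

from xbgroup.params import EnergyProfiles, TropomyosinModel
from xbgroup.states import (
    ADJACENCY,
    STATE_LABELS,
    GroupState,
    XBState,
    allowed_transitions,
    enumerate_group_states,
    group_free_energy,
    group_state_index,
    group_tm_energy,
    segment_energy,
    segment_energy_exact,
    state_energy,
    state_force,
    state_force_rt,
    transition_delta_G,
)


class TestXBState:
    def test_five_states_with_consistent_flags(self):
        states = [XBState(s) for s in STATE_LABELS]
        assert len(states) == 5
        assert {s.label for s in states if s.ca_bound} == {"W_Ca", "S1_Ca", "S2_Ca"}
        assert {s.label for s in states if s.force_bearing} == {
            "S1_Ca",
            "S2_Ca",
            "S2",
        }
        assert {s.label: s.tm_position for s in states} == {
            "T": "T",
            "W_Ca": "W",
            "S1_Ca": "S",
            "S2_Ca": "S",
            "S2": "S",
        }

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            XBState("S3")


class TestEnumeration:
    @pytest.mark.parametrize(
        "q,states,expected",
        [(1, STATE_LABELS, 5), (3, STATE_LABELS, 125), (3, ("T", "W", "S"), 27)],
    )
    def test_counts(self, q, states, expected):
        out = enumerate_group_states(q, states)
        assert len(out) == expected
        assert len(set(out)) == expected

    def test_stable_index(self):
        states = enumerate_group_states(3)
        for i in (0, 17, 63, 124):
            assert group_state_index(states[i]) == i

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            enumerate_group_states(0)


class TestTransitions:
    @pytest.mark.parametrize(
        "sites,expected_targets",
        [
            (("T",), {("W_Ca",), ("S2",)}),
            (("W_Ca",), {("T",), ("S1_Ca",), ("S2_Ca",)}),
        ],
    )
    def test_single_site_adjacency(self, sites, expected_targets):
        out = allowed_transitions(GroupState(sites))
        assert {b.sites for _, _, b in out} == expected_targets

    def test_all_unbound_q3_has_six_transitions(self):
        out = allowed_transitions(GroupState(("T", "T", "T")))
        assert len(out) == 6
        for j, beta, B in out:
            assert sum(a != b for a, b in zip(("T", "T", "T"), B.sites)) == 1
            assert beta in ADJACENCY["T"]


class TestSegmentEnergy:
    def test_diagonal_zero_and_symmetry(self):
        tm = TropomyosinModel()
        for a in ("T", "W", "S"):
            assert segment_energy(a, a, tm) == 0.0
            for b in ("T", "W", "S"):
                assert segment_energy(a, b, tm) == segment_energy(b, a, tm)

    def test_fitted_values(self):
        tm = TropomyosinModel(u_tw=0.1, u_ws=0.05)
        assert segment_energy("T", "W", tm) == pytest.approx(0.1)
        assert segment_energy("W", "S", tm) == pytest.approx(0.05)
        # fourth-root combination
        assert segment_energy("T", "S", tm) == pytest.approx(
            (0.1**0.25 + 0.05**0.25) ** 4, rel=1e-12
        )
        assert segment_energy("T", "S", tm) == pytest.approx(1.148, abs=5e-4)

    def test_approximation_matches_exact_geometry(self):
        # The approximation error grows like ~3*sqrt(U/U_tr); assert the
        # mathematically correct envelope over a grid of segment energies.
        for u_tw in (0.01, 0.05, 0.1, 0.5, 1.0):
            for u_ws in (0.01, 0.05, 0.1, 0.5, 1.0):
                tm = TropomyosinModel(u_tw=u_tw, u_ws=u_ws)
                approx = segment_energy("T", "S", tm)
                exact = segment_energy_exact("T", "S", tm)
                rel = abs(approx - exact) / exact
                bound = 4.0 * np.sqrt(max(u_tw, u_ws) / tm.u_tr) + 1e-3
                assert rel < bound
        tm = TropomyosinModel(u_tw=0.1, u_ws=0.05)
        rel = abs(segment_energy("T", "S", tm) - segment_energy_exact("T", "S", tm))
        assert rel / segment_energy_exact("T", "S", tm) < 0.02

    def test_invalid_position(self):
        with pytest.raises(ValueError):
            segment_energy("T", "X", TropomyosinModel())

    def test_relaxed_energy_magnitude(self):
        tm = TropomyosinModel()
        assert tm.u_tr > 1000.0
        assert tm.u_tr > 100 * max(tm.u_tw, tm.u_ws)


class TestGroupTmEnergy:
    def test_all_unbound_is_zero(self):
        assert group_tm_energy(GroupState(("T", "T", "T")), TropomyosinModel()) == 0.0

    def test_single_site_w(self):
        tm = TropomyosinModel(u_tw=0.1, u_ws=0.05)
        assert group_tm_energy(GroupState(("W_Ca",)), tm) == pytest.approx(0.2)

    def test_all_strong_q3_boundary_segments_only(self):
        tm = TropomyosinModel(u_tw=0.1, u_ws=0.05)
        val = group_tm_energy(GroupState(("S1_Ca", "S1_Ca", "S1_Ca")), tm)
        assert val == pytest.approx(2 * segment_energy("T", "S", tm), rel=1e-12)
        assert val == pytest.approx(2.297, abs=2e-3)

    def test_reversal_invariance(self, rng):
        tm = TropomyosinModel()
        labels = np.array(STATE_LABELS)
        for _ in range(50):
            sites = tuple(labels[rng.integers(0, 5, size=4)])
            a = group_tm_energy(GroupState(sites), tm)
            b = group_tm_energy(GroupState(sites[::-1]), tm)
            assert a == pytest.approx(b, rel=1e-12)


class TestFreeEnergiesAndForces:
    def test_group_energy_examples(self):
        tm = TropomyosinModel(u_tw=0.1, u_ws=0.05)
        prof = EnergyProfiles()
        assert group_free_energy(GroupState(("T", "T", "T")), 3.0, prof, tm) == 0.0
        g = group_free_energy(GroupState(("S2",)), 0.0, prof, tm)
        assert g == pytest.approx(prof.g_s2_min + 2 * segment_energy("T", "S", tm))
        gw = group_free_energy(GroupState(("W_Ca",)), -5.0, prof, tm)
        assert gw == pytest.approx(prof.g_w + 0.2)

    def test_delta_g_equals_full_difference(self, rng):
        """Locality: the transition free-energy difference from the changing
        site plus its fragments equals the full group difference, at all x."""
        tm = TropomyosinModel(u_tw=0.3, u_ws=0.2)
        prof = EnergyProfiles()
        x = np.linspace(-17.9, 17.9, 41)
        states = enumerate_group_states(3)
        for _ in range(40):
            A = states[rng.integers(0, 125)]
            trans = allowed_transitions(A)
            j, beta, B = trans[rng.integers(0, len(trans))]
            local = transition_delta_G(A, B, j, x, prof, tm)
            full = group_free_energy(B, x, prof, tm) - group_free_energy(
                A, x, prof, tm
            )
            np.testing.assert_allclose(local, full, atol=1e-12)

    def test_delta_g_neighbor_examples(self):
        tm = TropomyosinModel(u_tw=0.1, u_ws=0.05)
        prof = EnergyProfiles()
        A = GroupState(("T", "T", "T"))
        dg = transition_delta_G(A, GroupState(("T", "W_Ca", "T")), 1, 0.0, prof, tm)
        assert dg == pytest.approx(prof.g_w + 0.2)
        # facilitated central attachment between two Ca-bound neighbors
        A2 = GroupState(("W_Ca", "T", "W_Ca"))
        dg2 = transition_delta_G(A2, GroupState(("W_Ca", "W_Ca", "W_Ca")), 1, 0.0, prof, tm)
        assert dg2 == pytest.approx(prof.g_w - 0.2)

    def test_delta_g_unreachable_rejected(self):
        tm, prof = TropomyosinModel(), EnergyProfiles()
        with pytest.raises(ValueError):
            transition_delta_G(
                GroupState(("T",)), GroupState(("S1_Ca",)), 0, 0.0, prof, tm
            )

    def test_forces_zero_for_non_force_states(self):
        prof = EnergyProfiles()
        x = np.linspace(-17, 17, 11)
        assert np.all(state_force_rt("T", x, prof) == 0)
        assert np.all(state_force_rt("W_Ca", x, prof) == 0)

    def test_force_is_profile_derivative(self):
        prof = EnergyProfiles()
        x = np.linspace(-15, 15, 201)
        h = 1e-6
        for label in ("S1_Ca", "S2_Ca", "S2"):
            num = (state_energy(label, x + h, prof) - state_energy(label, x - h, prof)) / (
                2 * h
            )
            np.testing.assert_allclose(state_force_rt(label, x, prof), num, rtol=1e-6)

    def test_force_unit_conversion(self):
        prof = EnergyProfiles(k_s2=1.0)
        tm = TropomyosinModel(temperature=310.0)
        # 1 RT/nm at 310 K is ~4.28 pN
        f = state_force("S2", 2.0, prof, tm)
        assert f == pytest.approx(2.0 * 4.28, rel=1e-2)

    def test_position_range_enforced(self):
        tm, prof = TropomyosinModel(), EnergyProfiles()
        with pytest.raises(ValueError):
            group_free_energy(GroupState(("T",)), 19.0, prof, tm)


# hypothesis property checks of the energy algebra
from hypothesis import given, settings, strategies as st

_energy = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)
_labels = st.sampled_from(STATE_LABELS)


class TestEnergyProperties:
    @given(u_tw=_energy, u_ws=_energy)
    @settings(max_examples=50, deadline=None)
    def test_ts_energy_dominates_components(self, u_tw, u_ws):
        """U(T,S) >= max(U(T,W), U(W,S)) whenever both are positive, and the
        table stays symmetric with a zero diagonal."""
        tm = TropomyosinModel(u_tw=u_tw, u_ws=u_ws)
        uts = segment_energy("T", "S", tm)
        assert uts >= max(u_tw, u_ws) - 1e-12
        for a in ("T", "W", "S"):
            assert segment_energy(a, a, tm) == 0.0
            for b in ("T", "W", "S"):
                assert segment_energy(a, b, tm) == segment_energy(b, a, tm)

    @given(sites=st.lists(_labels, min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_group_tm_energy_reversal_and_bounds(self, sites):
        tm = TropomyosinModel(u_tw=0.4, u_ws=0.3)
        gs = GroupState(tuple(sites))
        rev = GroupState(tuple(sites[::-1]))
        e = group_tm_energy(gs, tm)
        assert e == pytest.approx(group_tm_energy(rev, tm), rel=1e-12)
        # bounded by (q+1) maximal fragment energies
        assert 0.0 <= e <= (len(sites) + 1) * segment_energy("T", "S", tm) + 1e-12
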