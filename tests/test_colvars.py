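"""Collective variables, walls, steered ramps, protocol export."""

import warnings
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nucbreathe as nb
from nucbreathe.colvars import (
    BiasProtocol,
    CoordinationSpec,
    DistanceInvSpec,
    HarmonicWallSpec,
    SteeredSpec,
    coordination_number,
    distance_inv,
    evaluate_protocol,
    export_bias_config,
    parse_bias_config,
    pou_hd_insertion_preset,
    steered_center,
    tail_release_preset,
    wall_energy,
)
from nucbreathe.geometry import min_group_distance

from conftest import make_point_frame

GOLDEN_DIR = Path(__file__).parent / "data"


def group_pair_frame(rng, n1=50, n2=50, spread=30.0):
    xyz = rng.uniform(-spread, spread, size=(n1 + n2, 3))
    frame = make_point_frame(xyz)
    a = np.zeros(n1 + n2, dtype=bool)
    a[:n1] = True
    return frame, a, ~a


class TestDistanceInv:
    @pytest.mark.parametrize("n", [2, 10, 100])
    def test_singletons_reduce_to_plain_distance(self, n):
        frame = make_point_frame([[0.0, 0, 0], [3.0, 0, 0]])
        a = np.array([True, False])
        assert distance_inv(frame, DistanceInvSpec(a, ~a, n=n)) == \
            pytest.approx(3.0, rel=1e-12)

    def test_two_atom_group_against_arbitrary_precision_value(self):
        # group1={origin}, group2={(3,0,0),(4,0,0)}, n=100:
        # d = [ (3^-100 + 4^-100)/2 ]^(-1/100); sympy evaluates the
        # closed form at 50 digits
        import sympy
        expr = ((sympy.Integer(3) ** -100 + sympy.Integer(4) ** -100)
                / 2) ** sympy.Rational(-1, 100)
        expected = float(expr.evalf(50))
        assert expected == pytest.approx(3.0 * 2 ** 0.01, rel=1e-6)
        frame = make_point_frame([[0.0, 0, 0], [3.0, 0, 0], [4.0, 0, 0]])
        a = np.array([True, False, False])
        got = distance_inv(frame, DistanceInvSpec(a, ~a, n=100))
        assert got == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_decreases_with_n_toward_the_true_minimum(self, seed):
        rng = np.random.default_rng(seed)
        frame, a, b = group_pair_frame(rng)
        true_min = min(
            np.linalg.norm(frame.coords[i] - frame.coords[j])
            for i in np.nonzero(a)[0] for j in np.nonzero(b)[0])
        values = [distance_inv(frame, DistanceInvSpec(a, b, n=n))
                  for n in (2, 10, 100)]
        assert values[0] >= values[1] >= values[2]
        assert all(v >= true_min for v in values)
        # the 1/(N1 N2) normalization puts an exact analytic ceiling on
        # how closely d^[n] can approach the minimum
        assert values[2] <= true_min * (50 * 50) ** (1 / 100) * (1 + 1e-12)

    def test_overflow_safe_at_tiny_distances(self):
        frame = make_point_frame([[0.0, 0, 0], [1e-3, 0, 0]])
        a = np.array([True, False])
        got = distance_inv(frame, DistanceInvSpec(a, ~a, n=100))
        assert got == pytest.approx(1e-3, rel=1e-9)

    def test_coincident_atoms_return_zero_with_warning(self):
        frame = make_point_frame([[1.0, 2, 3], [1.0, 2, 3]])
        a = np.array([True, False])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            got = distance_inv(frame, DistanceInvSpec(a, ~a))
        assert got == 0.0
        assert any("coincident" in str(w.message) for w in caught)

    def test_odd_exponent_rejected(self):
        with pytest.raises(ValueError):
            DistanceInvSpec("a", "b", n=3)


class TestCoordinationNumber:
    def test_single_pair_at_2A(self):
        # r = 0.5: (1 - 0.5^6)/(1 - 0.5^12) evaluated directly
        expected = (1 - 0.5 ** 6) / (1 - 0.5 ** 12)
        frame = make_point_frame([[0.0, 0, 0], [2.0, 0, 0]])
        a = np.array([True, False])
        got = coordination_number(frame, CoordinationSpec(a, ~a))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.98462, abs=5e-6)

    def test_exactly_at_threshold_distance_gives_half(self):
        frame = make_point_frame([[0.0, 0, 0], [4.0, 0, 0]])
        a = np.array([True, False])
        assert coordination_number(frame, CoordinationSpec(a, ~a)) == \
            pytest.approx(0.5, rel=1e-12)

    def test_factorized_form_matches_rational_form_pointwise(self):
        # with m = 2n the switching function is 1/(1 + r^n); both forms
        # must agree to 1e-12 away from the removable singularity
        for r in np.concatenate([np.linspace(0.05, 0.999, 40),
                                 np.linspace(1.001, 5.0, 40)]):
            direct = (1 - r ** 6) / (1 - r ** 12)
            factorized = 1.0 / (1 + r ** 6)
            assert factorized == pytest.approx(direct, abs=1e-12)

    def test_far_pair_contributes_nothing(self):
        frame = make_point_frame([[0.0, 0, 0], [500.0, 0, 0]])
        a = np.array([True, False])
        assert coordination_number(frame, CoordinationSpec(a, ~a)) < 1e-12

    def test_strictly_decreasing_in_distance_and_bounded(self):
        rng = np.random.default_rng(3)
        distances = np.sort(rng.uniform(0.5, 12.0, size=30))
        values = []
        for d in distances:
            frame = make_point_frame([[0.0, 0, 0], [d, 0, 0]])
            a = np.array([True, False])
            values.append(coordination_number(frame,
                                              CoordinationSpec(a, ~a)))
        assert all(x > y for x, y in zip(values, values[1:]))
        assert all(0 < v < 1 for v in values)

    def test_total_bounded_by_pair_count(self):
        rng = np.random.default_rng(4)
        frame, a, b = group_pair_frame(rng, n1=20, n2=30, spread=8.0)
        c = coordination_number(frame, CoordinationSpec(a, b))
        assert 0 < c <= 20 * 30

    def test_exponent_ordering_enforced(self):
        with pytest.raises(ValueError):
            CoordinationSpec("a", "b", n=12, m=6)


class TestWallsAndRamps:
    def test_inside_allowed_region_costs_nothing(self):
        wall = HarmonicWallSpec(DistanceInvSpec("a", "b"), lower=12.0)
        assert wall_energy(14.0, wall) == 0.0

    def test_violation_depth_squared_convention(self):
        wall = HarmonicWallSpec(DistanceInvSpec("a", "b"), lower=12.0,
                                k=10.0)
        # delta = 2 Å: E = (10/2) * 2² = 20 kcal/mol
        assert wall_energy(10.0, wall) == pytest.approx(20.0)

    def test_zero_coordination_wall_at_zero(self):
        wall = HarmonicWallSpec(CoordinationSpec("a", "b"), upper=0.0)
        assert wall_energy(0.0, wall) == 0.0
        assert wall_energy(1.0, wall) == pytest.approx(5.0)

    def test_wall_needs_a_bound(self):
        with pytest.raises(ValueError):
            HarmonicWallSpec(DistanceInvSpec("a", "b"))

    def test_continuity_at_the_bound(self):
        wall = HarmonicWallSpec(DistanceInvSpec("a", "b"), lower=12.0)
        eps = 1e-7
        assert wall_energy(12.0, wall) == 0.0
        assert wall_energy(12.0 - eps, wall) < 1e-12  # C1 at the bound

    @pytest.mark.parametrize("start,end,t,expected", [
        (5.0, 15.0, 0.0, 5.0),        # ramp start
        (5.0, 15.0, 125.0, 10.0),     # halfway
        (32.0, 12.0, 250.0, 12.0),    # ramp end
        (32.0, 12.0, 400.0, 12.0),    # clamped after the ramp
    ])
    def test_steered_center_linearity(self, start, end, t, expected):
        spec = SteeredSpec(DistanceInvSpec("a", "b"), start=start, end=end,
                           duration=250.0)
        assert steered_center(t, spec) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        spec = SteeredSpec(DistanceInvSpec("a", "b"), 5, 15, 250)
        with pytest.raises(ValueError):
            steered_center(-1.0, spec)

    @settings(derandomize=True, max_examples=200)
    @given(value=st.floats(-100, 100), lower=st.floats(-50, 50),
           k=st.floats(0.1, 100))
    def test_wall_energy_piecewise_quadratic_and_nonnegative(
            self, value, lower, k):
        wall = HarmonicWallSpec(DistanceInvSpec("a", "b"), lower=lower,
                                k=k)
        e = wall_energy(value, wall)
        assert e >= 0
        if value >= lower:
            assert e == 0
        else:
            assert e == pytest.approx(0.5 * k * (lower - value) ** 2)


class TestPresets:
    def test_tail_release_numbers(self):
        p = tail_release_preset()
        terms = dict(p.terms)
        assert terms["tails_outer_dmin_wall"].lower == 12.0
        assert terms["tails_outer_coord_wall"].upper == 0.0
        assert all(t.k == 10.0 for t in terms.values())

    def test_pou_hd_insertion_numbers(self):
        terms = dict(pou_hd_insertion_preset().terms)
        assert (terms["hd_inner_ramp"].start,
                terms["hd_inner_ramp"].end) == (5.0, 15.0)
        assert (terms["hd_outer_ramp"].start,
                terms["hd_outer_ramp"].end) == (32.0, 12.0)
        assert (terms["hd_ldna_ramp"].start,
                terms["hd_ldna_ramp"].end) == (58.0, 28.0)
        assert all(terms[k].duration == 250.0 for k in
                   ("hd_inner_ramp", "hd_outer_ramp", "hd_ldna_ramp"))
        assert terms["tails_outer_dmin_wall"].lower == 30.0
        assert terms["intergyre_dmin_wall"].lower == 20.0
        assert all(t.k == 10.0 for t in terms.values())

    def test_coordination_defaults_match_stated_parameters(self):
        spec = dict(tail_release_preset().terms)[
            "tails_outer_coord_wall"].variable
        assert (spec.d0, spec.n, spec.m) == (4.0, 6, 12)


class TestProtocolEvaluation:
    def test_released_tails_satisfy_tail_release_walls(self):
        params = nb.SyntheticParams(
            frames=3, seed=5,
            tail_modes={r: "released" for r in
                        ("H3-A", "H4-A", "H2A-A", "H2B-A")})
        ens = nb.generate_breathing_trajectory(params)
        table = evaluate_protocol(ens.trajectory, tail_release_preset(),
                                  ens.topology)
        # distance walls are exactly satisfied; the C = 0 wall carries the
        # vanishing tail of the switching function only
        assert (table.energy_kcal_mol < 1e-6).all()
        assert not table.active.any()

    def test_wrapped_tails_violate_walls_from_frame_zero(self):
        ens = nb.generate_breathing_trajectory(
            nb.SyntheticParams(frames=2, seed=5))
        table = evaluate_protocol(ens.trajectory, tail_release_preset(),
                                  ens.topology)
        frame0 = table[table.frame == 0]
        assert (frame0.energy_kcal_mol > 0).all()

    def test_row_count_is_frames_times_terms(self):
        ens = nb.generate_breathing_trajectory(
            nb.SyntheticParams(frames=4, seed=5))
        protocol = tail_release_preset()
        table = evaluate_protocol(ens.trajectory, protocol, ens.topology)
        assert len(table) == 4 * len(protocol)

    def test_distance_inv_wall_consistent_with_true_minimum(self):
        # on the synthetic structure the CV sits between the true minimal
        # distance and the analytic normalization ceiling min*(N1 N2)^(1/n)
        ens = nb.generate_breathing_trajectory(
            nb.SyntheticParams(frames=1, seed=5))
        from nucbreathe.selections import resolve_group
        ref = ens.trajectory[0]
        a = resolve_group(ref, ens.topology, "tails:H3-A+H2A-A:CA")
        b = resolve_group(ref, ens.topology, "dna:outer_gyre_3p:P")
        cv = distance_inv(ref, DistanceInvSpec(a, b))
        true = min_group_distance(ref, a, b)
        ceiling = true * (int(a.sum()) * int(b.sum())) ** (1 / 100)
        assert true <= cv <= ceiling * (1 + 1e-12)


class TestConfigExport:
    def test_tail_release_golden_file(self):
        got = export_bias_config(tail_release_preset())
        want = (GOLDEN_DIR / "tail_release.colvars").read_text()
        assert got == want

    def test_pou_hd_insertion_golden_file(self):
        got = export_bias_config(pou_hd_insertion_preset())
        want = (GOLDEN_DIR / "pou_hd_insertion.colvars").read_text()
        assert got == want

    def test_exported_text_contains_the_protocol_numbers(self):
        text = export_bias_config(pou_hd_insertion_preset())
        for token in ("centers 5", "targetCenters 15", "centers 32",
                      "targetCenters 12", "centers 58", "targetCenters 28",
                      "targetDuration 250 ns", "lowerWalls 30",
                      "lowerWalls 20", "forceConstant 10"):
            assert token in text, token
        text2 = export_bias_config(tail_release_preset())
        assert "lowerWalls 12" in text2
        assert "upperWalls 0" in text2

    def test_export_parse_export_fixpoint(self):
        for preset in (tail_release_preset(), pou_hd_insertion_preset()):
            text = export_bias_config(preset)
            reparsed = parse_bias_config(text)
            assert export_bias_config(reparsed) == text

    def test_empty_protocol_exports_header_only(self):
        text = export_bias_config(BiasProtocol(name="empty", terms=()))
        assert text.startswith("#")
        assert "colvar" not in text
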