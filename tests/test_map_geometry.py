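"""Complex-analytic map geometry: projection, inverse, OP field, delays."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesocortex import map_geometry as mg

finite_complex = st.complex_numbers(
    min_magnitude=1e-3, max_magnitude=1e3, allow_nan=False, allow_infinity=False
)


class TestLattice:
    def test_interior_neighbor_distances_equal_spacing(self):
        frame = mg.hex_patch_lattice(1.0, (0, 10, 0, 10))
        pc = frame.patch_centers
        interior = pc[
            (pc.real > 2) & (pc.real < 8) & (pc.imag > 2) & (pc.imag < 8)
        ]
        for c in interior[:20]:
            d = np.sort(np.abs(pc - c))[1:7]
            assert np.allclose(d, 1.0, atol=1e-9)

    def test_sixty_degree_rotation_maps_centers_to_centers(self):
        frame = mg.hex_patch_lattice(1.0, (0, 12, 0, 12))
        pc = frame.patch_centers
        center = pc[np.argmin(np.abs(pc - (6 + 6j)))]
        rot = center + (pc - center) * cmath.exp(1j * math.pi / 3)
        # rotated interior points must coincide with existing centers
        inner = rot[np.abs(rot - center) < 3]
        for z in inner:
            assert np.min(np.abs(pc - z)) < 1e-6

    def test_center_count_matches_area_density(self):
        X, L = 1.0, 20.0
        frame = mg.hex_patch_lattice(X, (0, L, 0, L))
        expected = L * L / (math.sqrt(3) / 2 * X**2)
        boundary_band = 4 * L / X  # one lattice row/column of slack
        assert abs(len(frame.patch_centers) - expected) < boundary_band

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            mg.hex_patch_lattice(0.0, (0, 10, 0, 10))
        with pytest.raises(ValueError):
            mg.hex_patch_lattice(1.0, (0, 2, 0, 2))


class TestProjection:
    def test_fixed_point_at_center(self, default_map):
        assert mg.global_to_local(default_map.p0, default_map) == default_map.p0

    def test_modulus_law(self, default_map):
        r = np.random.default_rng(0)
        P = r.normal(size=50) + 1j * r.normal(size=50)
        p = mg.global_to_local(P, default_map)
        np.testing.assert_allclose(
            np.abs(p - default_map.p0) / np.abs(P - default_map.p0),
            abs(default_map.p_prime),
            rtol=1e-12,
        )

    def test_reference_value(self):
        # p0=0, p'=i, n=2: the unit point at 45 degrees maps to -1
        spec = mg.LocalMapSpec(p0=0j, p_prime=1j, n=2)
        p = mg.global_to_local(cmath.exp(1j * math.pi / 4), spec)
        assert abs(p - (-1 + 0j)) < 1e-12

    @settings(deadline=None, derandomize=True)
    @given(P=finite_complex, sheet=st.integers(0, 1))
    def test_round_trip_identity(self, P, sheet):
        spec = mg.LocalMapSpec(p0=1 + 1j, p_prime=0.3 + 0.4j, n=2)
        p = mg.global_to_local(P + spec.p0, spec)
        P_back = mg.local_to_global(p, spec, sheet=sheet)
        assert abs(mg.global_to_local(P_back, spec) - p) < 1e-9 * max(1, abs(p))

    def test_two_sheets_are_antipodes(self, default_map):
        P = 1.3 + 0.7j
        p = mg.global_to_local(P, default_map)
        P0 = mg.local_to_global(p, default_map, sheet=0)
        P1 = mg.local_to_global(p, default_map, sheet=1)
        assert abs((P0 - default_map.p0) + (P1 - default_map.p0)) < 1e-12

    def test_conformal_angle_multiplication(self, default_map):
        # d(arg image)/d(arg source) = n everywhere off-center
        n = default_map.n
        h = 1e-7
        for theta in np.linspace(0.1, 2 * math.pi, 7):
            a1 = np.angle(
                mg.global_to_local(cmath.exp(1j * (theta + h)), default_map)
                - default_map.p0
            )
            a0 = np.angle(
                mg.global_to_local(cmath.exp(1j * theta), default_map) - default_map.p0
            )
            d = (a1 - a0 + math.pi) % (2 * math.pi) - math.pi
            assert abs(d / h - n) < 1e-5


class TestOrientationPreference:
    def test_full_circuit_covers_180_degrees(self, default_map):
        assert mg.op_circuit_coverage(default_map, n_samples=360) == pytest.approx(180.0)

    def test_winding_number_is_one(self, default_map):
        assert mg.op_circuit_winding(default_map) == 1

    def test_chirality_flip_reverses_progression(self):
        s_plus = mg.LocalMapSpec(p0=0j, p_prime=0.5j, n=2, chirality=1)
        s_minus = mg.LocalMapSpec(p0=0j, p_prime=0.5j, n=2, chirality=-1)
        alpha = np.linspace(0.1, 0.5, 5)
        p = np.exp(1j * alpha)
        op_p = mg.op_field(p, s_plus)
        op_m = mg.op_field(p, s_minus)
        assert np.all(np.diff(op_p) > 0)
        assert np.all(np.diff(op_m) < 0)

    def test_op_zero_at_p_prime_azimuth(self, default_map):
        psi = np.angle(default_map.p_prime)
        p = default_map.p0 + cmath.exp(1j * psi)
        assert mg.op_field(np.array([p]), default_map)[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_singularity_and_mirrored_border_continuity(self):
        # adjacent maps with opposite chirality and the same rotation
        # constant join with no OP discontinuity across the shared border
        d = 2.0
        s1 = mg.LocalMapSpec(p0=0j, p_prime=0.5j, n=2, chirality=1)
        s2 = mg.LocalMapSpec(p0=complex(d), p_prime=0.5j, n=2, chirality=-1)
        ys = np.linspace(-1, 1, 101)
        eps = 1e-3
        jumps = []
        for y in ys:
            a = mg.op_field(np.array([complex(d / 2 - eps, y)]), s1)[0]
            b = mg.op_field(np.array([complex(d / 2 + eps, y)]), s2)[0]
            dd = abs(a - b) % 180
            jumps.append(min(dd, 180 - dd))
        assert max(jumps) < 1e-6
        assert mg.op_circuit_winding(s1) == 1  # one singularity per map


class TestMoebius:
    def test_smallest_injective_even_exponent_is_two(self):
        assert mg.smallest_injective_exponent() == 2

    def test_two_sheets_required(self):
        assert mg.moebius_injectivity_check(2, n_sheets=2)
        assert not mg.moebius_injectivity_check(2, n_sheets=1)  # plain disc: 2-to-1

    def test_higher_exponent_needs_matching_sheets(self):
        assert not mg.moebius_injectivity_check(4, n_sheets=2)
        assert mg.moebius_injectivity_check(4, n_sheets=4)

    def test_odd_exponent_rejected(self):
        with pytest.raises(ValueError):
            mg.moebius_injectivity_check(3)


class TestArcGeometry:
    @pytest.mark.parametrize("direction", [0.0, 0.6, 2.4, -1.1])
    def test_connection_arc_rotates_projection_by_90_degrees(self, direction):
        assert mg.arc_tangent_rotation(1.0, direction) == pytest.approx(90.0, abs=1e-6)


class TestDelayedProjection:
    def test_arrival_times_forced_by_formula(self, default_map):
        stim = mg.StimulusField(
            positions=np.array([2 + 0j]), times=np.array([0.0]), amplitudes=np.array([1.0])
        )
        loc = mg.project_stimulus(stim, default_map)
        d = abs(stim.positions[0] - loc.positions[0])
        assert loc.times[0] == pytest.approx(d / default_map.nu)

    def test_infinite_velocity_limit(self):
        spec = mg.LocalMapSpec(p0=0j, p_prime=0.5j, n=2, nu=1e12)
        r = np.random.default_rng(1)
        P = r.normal(size=20) + 1j * r.normal(size=20)
        stim = mg.StimulusField(positions=P, times=np.arange(20.0), amplitudes=np.ones(20))
        loc = mg.project_stimulus(stim, spec)
        np.testing.assert_allclose(loc.times, stim.times, atol=1e-9)

    def test_motor_backprojection_round_trip(self, default_map):
        r = np.random.default_rng(2)
        for _ in range(50):
            n = r.integers(1, 30)
            stim = mg.StimulusField(
                positions=r.normal(size=n) + 1j * r.normal(size=n),
                times=np.sort(r.uniform(0, 10, n)),
                amplitudes=r.uniform(0.1, 2, n),
            )
            loc = mg.project_stimulus(stim, default_map)
            motor = mg.motor_backproject(loc, default_map)
            loc2 = mg.project_stimulus(motor, default_map)
            np.testing.assert_allclose(loc2.times, loc.times, atol=1e-9)
            np.testing.assert_allclose(loc2.positions, loc.positions, atol=1e-9)

    def test_single_event_backprojection_timing(self, default_map):
        spec = mg.LocalMapSpec(p0=0j, p_prime=0.5j, n=2, nu=2.0)
        loc = mg.LocalActivity(
            positions=np.array([1 + 0j]),
            times=np.array([4.0]),
            amplitudes=np.array([1.0]),
            sources=np.array([1 + 5j]),
        )
        d = abs(loc.sources[0] - loc.positions[0])
        motor = mg.motor_backproject(loc, spec)
        assert motor.times[0] == pytest.approx(4.0 - d / 2.0)


class TestSuperposition:
    def test_single_field_is_plain_projection(self, default_map):
        stim = mg.StimulusField(
            positions=np.array([1 + 1j, 2 + 0j]),
            times=np.array([0.0, 1.0]),
            amplitudes=np.array([1.0, 2.0]),
        )
        one = mg.superpose_areas([stim], default_map)
        direct = mg.project_stimulus(stim, default_map)
        np.testing.assert_allclose(np.sort(one.times), np.sort(direct.times))

    def test_coincident_events_sum_amplitudes(self, default_map):
        f = lambda a: mg.StimulusField(
            positions=np.array([1 + 1j]), times=np.array([0.5]), amplitudes=np.array([a])
        )
        out = mg.superpose_areas([f(1.0), f(2.0), f(0.25)], default_map)
        assert len(out) == 1
        assert out.amplitudes[0] == pytest.approx(3.25)

    def test_disjoint_fields_union(self, default_map):
        f1 = mg.StimulusField(
            positions=np.array([1 + 0j]), times=np.array([0.0]), amplitudes=np.array([1.0])
        )
        f2 = mg.StimulusField(
            positions=np.array([0 + 2j]), times=np.array([1.0]), amplitudes=np.array([1.0])
        )
        assert len(mg.superpose_areas([f1, f2], default_map)) == 2


class TestTemporalFrequencyContrast:
    def test_circumferential_beats_radial(self):
        spec = mg.LocalMapSpec(p0=0j, p_prime=0.1j, n=2, nu=1.0)
        f_c, f_r = mg.tfp_contrast(spec, speed=1.0, radius=3.0)
        assert f_c > f_r

    def test_zero_delay_limit_equalizes(self):
        spec = mg.LocalMapSpec(p0=0j, p_prime=0.1j, n=2, nu=1e12)
        f_c, f_r = mg.tfp_contrast(spec, speed=1.0, radius=3.0)
        assert f_c == pytest.approx(f_r, rel=1e-6)

    def test_faster_conduction_monotone_toward_limit(self):
        ratios = []
        for nu in (0.5, 1.0, 2.0, 4.0):
            spec = mg.LocalMapSpec(p0=0j, p_prime=0.1j, n=2, nu=nu)
            f_c, f_r = mg.tfp_contrast(spec, speed=1.0, radius=3.0)
            ratios.append(f_c / f_r)
        assert all(a > b for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] > 1.0
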