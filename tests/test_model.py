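"""Unit and property tests for the ODE model layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

from tamodel.model import (
    FULL_PARAM_NAMES,
    OriginalParams,
    SimulationError,
    SolverConfig,
    VARIANT_NAMES,
    VARIANTS,
    ZParams,
    apply_variant,
    original_rhs,
    rescale,
    simulate,
    simulate_original,
    z_rhs,
)


def make_zparams(**overrides) -> ZParams:
    base = dict(k1=1.0, k2=1.0, d1=1.0, d2=1.0, d3=1.0, s1=1.0, s2=1.0,
                bm=0.0, bc=0.0, c0=0.0)
    base.update(overrides)
    return ZParams(**base)


class TestZRhs:
    def test_origin_reduces_to_production_terms(self):
        # at (0,0,0) both repression factors are 1 and mass-action terms vanish
        d = z_rhs((0.0, 0.0, 0.0), make_zparams(k1=2.0))
        assert d == pytest.approx((2.0, 1.0, 0.0), abs=1e-15)

    def test_all_ones_state_hand_value(self):
        p = make_zparams(bm=1.0, bc=1.0)
        d = z_rhs((1.0, 1.0, 1.0), p)
        assert d == pytest.approx((-0.75, -0.25, 0.0), abs=1e-15)

    @pytest.mark.parametrize("z1,z2", [(0.5, 2.0), (3.0, 0.1), (1.0, 1.0)])
    def test_complex_equilibrium_manifold(self, z1, z2, example_params):
        # wherever z3 = k2 z1 z2, the complex is stationary
        z3 = example_params.k2 * z1 * z2
        assert z_rhs((z1, z2, z3), example_params)[2] == pytest.approx(0.0, abs=1e-14)

    @given(
        z=st.tuples(*[st.floats(0, 50) for _ in range(3)]),
        d3=st.floats(0.01, 20),
        k2=st.floats(0.01, 20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_complex_balance_identity(self, z, d3, k2):
        # the third equation is exactly dz3/dt + d3 z3 = d3 k2 z1 z2
        p = make_zparams(d3=d3, k2=k2)
        dz3 = z_rhs(z, p)[2]
        assert dz3 + d3 * z[2] == pytest.approx(d3 * k2 * z[0] * z[1], rel=1e-12)

    def test_rejects_non_finite_state(self, example_params):
        with pytest.raises(ValueError, match="non-finite"):
            z_rhs((np.nan, 0.0, 0.0), example_params)

    def test_huge_z3_does_not_overflow(self, example_params):
        d = z_rhs((1.0, 1.0, 1e300), example_params)
        assert all(np.isfinite(d))


class TestOriginalRhs:
    def test_origin_case(self):
        p = OriginalParams(k1p=3, k2p=5, k3=1, d1=1, d2=1, d3=1, s1p=1, s2p=1)
        assert original_rhs((0.0, 0.0, 0.0), p) == pytest.approx((3.0, 5.0, 0.0))

    def test_complex_equation_balance(self):
        p = OriginalParams(k1p=1, k2p=1, k3=1, d1=1, d2=1, d3=1, s1p=1, s2p=1)
        assert original_rhs((1.0, 1.0, 1.0), p)[2] == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_point(self):
        p = OriginalParams(k1p=2, k2p=1, k3=1, d1=1, d2=1, d3=1, s1p=1, s2p=1,
                           bmp=1, bcp=1)
        d = original_rhs((1.0, 2.0, 3.0), p)
        assert d == pytest.approx((1 / 6, 5 / 12, -1.0), rel=1e-12)


class TestRescale:
    def test_printed_relations(self):
        p = OriginalParams(k1p=4, k2p=2, k3=3, d1=1, d2=1, d3=5, s1p=2, s2p=1,
                           bmp=0.5, bcp=0.25)
        z = rescale(p)
        assert z == pytest.approx(
            {"k1": 2.0, "k2": 6.0, "d1": 1.0, "d2": 1.0, "d3": 5.0,
             "s1": 5.0, "s2": 2.5, "bm": 1.0, "bc": 0.5}
        )

    def test_identity_scaling(self):
        p = OriginalParams(k1p=1.7, k2p=1, k3=0.3, d1=1, d2=2, d3=1, s1p=0.4,
                           s2p=0.9, bmp=0.2, bcp=0.1)
        z = rescale(p)
        assert z["k1"] == p.k1p and z["s1"] == p.s1p and z["s2"] == p.s2p
        assert z["bm"] == p.bmp and z["bc"] == p.bcp and z["k2"] == p.k3

    def test_trajectory_equivalence_single_draw(self):
        # y1 = k2p z1, y2 = k2p z2, y3 = (k2p/d3) z3 pointwise
        p = OriginalParams(k1p=3, k2p=2, k3=0.5, d1=1.5, d2=0.4, d3=1.2,
                           s1p=0.3, s2p=1.0, bmp=0.5, bcp=0.8)
        c0 = 0.7
        times = np.linspace(0, 10, 25)
        zp = ZParams(**rescale(p), c0=c0)
        traj_z = simulate(zp, (0, 0, c0), times)
        traj_y = simulate_original(p, (0, 0, (p.k2p / p.d3) * c0), times)
        np.testing.assert_allclose(traj_y.z1, p.k2p * traj_z.z1, atol=1e-7)
        np.testing.assert_allclose(traj_y.z2, p.k2p * traj_z.z2, atol=1e-7)
        np.testing.assert_allclose(traj_y.z3, (p.k2p / p.d3) * traj_z.z3, atol=1e-7)


class TestVariants:
    def test_registry_free_parameter_counts(self):
        expected = {"full": 10, "s1=s2": 9, "s1=s2_no_bm": 8, "s1=s2_no_bc": 8,
                    "s1=s2_no_bm_bc": 7, "s1!=s2_no_bm": 9, "s1!=s2_no_bc": 9,
                    "no_s1_s2_bm_bc": 6}
        assert {n: VARIANTS[n].nv for n in VARIANT_NAMES} == expected

    def test_full_is_identity_mapping(self):
        vec = np.array([3, 1, 2, 0.3, 1, 0.1, 2, 1, 1, 1.0])
        params = apply_variant("full", vec)
        np.testing.assert_array_equal(params.as_vector(), vec)

    def test_tie_shares_one_value(self):
        params = apply_variant("s1=s2", [1, 1, 1, 1, 1, 0.37, 0, 0, 0.5])
        assert params.s1 == params.s2 == 0.37

    def test_combined_tie_and_fixings(self):
        params = apply_variant("s1=s2_no_bm_bc", [1, 1, 1, 1, 1, 0.2, 0.5])
        assert params.s1 == params.s2 == 0.2
        assert params.bm == 0.0 and params.bc == 0.0

    def test_simplest_variant_fixes_scales_to_one(self):
        params = apply_variant("no_s1_s2_bm_bc", [2, 1, 1, 1, 1, 0.5])
        assert (params.s1, params.s2, params.bm, params.bc) == (1.0, 1.0, 0.0, 0.0)

    def test_length_mismatch_names_variant(self):
        with pytest.raises(ValueError, match="'s1=s2'.*9"):
            apply_variant("s1=s2", [1.0] * 10)

    @pytest.mark.parametrize("name", VARIANT_NAMES)
    def test_variant_rhs_nests_in_full(self, name):
        # a variant's RHS is the full RHS at the constrained parameter point
        rng = np.random.default_rng(7)
        free = np.where(
            [n in ("bm", "bc", "c0") for n in VARIANTS[name].free_names],
            rng.uniform(0, 2, VARIANTS[name].nv),
            rng.uniform(0.1, 3, VARIANTS[name].nv),
        )
        params = apply_variant(name, free)
        full_vec = params.as_vector()
        state = (0.4, 1.1, 0.6)
        assert z_rhs(state, params) == pytest.approx(
            z_rhs(state, apply_variant("full", full_vec)), rel=1e-15
        )


class TestSimulate:
    def test_fixed_point_stays_fixed(self, example_params):
        # locate an equilibrium numerically, then verify trajectory constancy
        z_eq = fsolve(lambda z: z_rhs(np.abs(z), example_params), [1.0, 1.0, 1.0])
        z_eq = np.abs(z_eq)
        assert np.allclose(z_rhs(z_eq, example_params), 0, atol=1e-9)
        traj = simulate(example_params, z_eq, np.linspace(0, 20, 11))
        np.testing.assert_allclose(traj.states, np.tile(z_eq, (11, 1)), rtol=1e-5)

    def test_short_time_taylor_expansion(self, example_params):
        # from (0,0,c0): dz1(0) = k1 s1/(s1+c0) + c0, linear in t for t -> 0
        p = example_params
        t = 1e-6
        traj = simulate(p, (0, 0, p.c0), np.array([0.0, t]))
        slope = p.k1 * p.s1 / (p.s1 + p.c0) + p.c0
        assert traj.z1[1] == pytest.approx(slope * t, rel=1e-3)

    def test_matches_fixed_step_rk4(self, example_params):
        # independent brute-force integrator at tiny fixed step
        p = example_params
        times = np.linspace(0, 10, 11)
        traj = simulate(p, (0, 0, p.c0), times, SolverConfig(rtol=1e-8, atol=1e-10))
        h = 1e-4
        y = np.array([0.0, 0.0, p.c0])
        out = [y.copy()]
        t_targets = iter(times[1:])
        target = next(t_targets)
        t = 0.0
        while True:
            k1v = np.array(z_rhs(y, p))
            k2v = np.array(z_rhs(y + h / 2 * k1v, p))
            k3v = np.array(z_rhs(y + h / 2 * k2v, p))
            k4v = np.array(z_rhs(y + h * k3v, p))
            y = y + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
            t += h
            if t >= target - h / 2:
                out.append(y.copy())
                try:
                    target = next(t_targets)
                except StopIteration:
                    break
        assert np.max(np.abs(np.array(out) - traj.states)) < 1e-5

    def test_nonnegativity_across_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            params = ZParams(
                k1=10 ** rng.uniform(-1, 1), k2=10 ** rng.uniform(-1, 1),
                d1=10 ** rng.uniform(-1, 1), d2=10 ** rng.uniform(-1, 1),
                d3=10 ** rng.uniform(-1, 1), s1=10 ** rng.uniform(-1, 1),
                s2=10 ** rng.uniform(-1, 1), bm=rng.uniform(0, 2),
                bc=rng.uniform(0, 2), c0=rng.uniform(0, 2),
            )
            traj = simulate(params, (0, 0, params.c0), np.linspace(0, 100, 21))
            assert traj.states.min() >= -10 * 1e-10 * max(1.0, traj.states.max())

    def test_decreasing_times_rejected(self, example_params):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate(example_params, (0, 0, 1), np.array([0.0, 2.0, 1.0]))

    def test_invalid_params_rejected_at_construction(self):
        with pytest.raises(ValueError, match="strictly positive"):
            make_zparams(k1=-1.0)
        with pytest.raises(ValueError, match="non-negative"):
            make_zparams(bm=-0.5)


def test_param_roundtrip_dict():
    p = ZParams(k1=1, k2=2, d1=3, d2=4, d3=5, s1=6, s2=7, bm=8, bc=9, c0=10)
    assert ZParams.from_dict(p.to_dict()) == p
    assert list(p.to_dict()) == list(FULL_PARAM_NAMES)
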