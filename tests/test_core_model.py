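"""Forward-model checks: boundary coefficient, Green's function, Siegert,
disk-source averaging and the Einstein-Stokes relation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcskit import (
    CorrelationCurve,
    FlowModel,
    OpticalProperties,
    effective_reflection_coefficient,
    einstein_stokes,
    g1_disk,
    g1_point,
    g2_from_g1,
    model_g2,
)
from dcskit.core_model import SemiInfiniteGeometry


@pytest.mark.parametrize(
    "n, expected",
    [
        (1.0, 0.002),  # -1.44 + 0.71 + 0.668 + 0.064 by hand
        (1.33, 0.4729),
        (1.4, 0.5300),
    ],
)
def test_effective_reflection_coefficient_polynomial(n, expected):
    assert effective_reflection_coefficient(n) == pytest.approx(expected, abs=5e-5)


def test_effective_reflection_coefficient_rejects_nonpositive_n():
    with pytest.raises(ValueError):
        effective_reflection_coefficient(0.0)


class TestEinsteinStokes:
    def test_water_at_20C_50nm_particle(self):
        # hand evaluation in SI then x1e4: kB*293.15 / (6 pi 1.002e-3 5e-8)
        db = einstein_stokes(293.15, 1.002e-3, 50e-9)
        assert db == pytest.approx(4.2858e-8, rel=1e-4)

    def test_linear_in_temperature(self):
        ratio = einstein_stokes(308.15, 1e-3, 5e-8) / einstein_stokes(298.15, 1e-3, 5e-8)
        assert ratio == pytest.approx(308.15 / 298.15, rel=1e-12)

    def test_vanishes_with_large_viscosity(self):
        assert einstein_stokes(293.15, 1e6, 5e-8) < 1e-16

    @pytest.mark.parametrize("args", [(0, 1e-3, 5e-8), (293, -1, 5e-8), (293, 1e-3, 0)])
    def test_rejects_nonpositive_inputs(self, args):
        with pytest.raises(ValueError):
            einstein_stokes(*args)


class TestG1Point:
    def test_no_flow_means_no_decay(self, phantom_optics, log_tau):
        geom = SemiInfiniteGeometry.from_optics(20.0, phantom_optics)
        g1 = g1_point(geom, phantom_optics, FlowModel(DB=0.0), log_tau)
        np.testing.assert_allclose(g1, 1.0, atol=1e-14)

    def test_normalized_at_zero_lag(self, phantom_optics):
        geom = SemiInfiniteGeometry.from_optics(15.0, phantom_optics)
        g1 = g1_point(geom, phantom_optics, FlowModel(DB=3e-7), np.array([0.0]))
        assert g1[0] == pytest.approx(1.0, rel=1e-14)

    def test_matches_independent_evaluation(self, phantom_optics):
        # frozen values from a scalar re-evaluation of the closed form
        # (phantom optics, rho = 20 mm, DB = 2.8e-7 cm^2/s, alpha = 1)
        geom = SemiInfiniteGeometry.from_optics(20.0, phantom_optics)
        g1 = g1_point(
            geom, phantom_optics, FlowModel(DB=2.8e-7), np.array([1e-6, 1e-5, 1e-4])
        )
        np.testing.assert_allclose(
            g1, [0.33218157263540166, 0.0025433076384523646, 4.119074396837976e-11],
            rtol=1e-10,
        )

    def test_strictly_decreasing_and_separation_decay(self, phantom_optics, log_tau):
        flow = FlowModel(DB=2.8e-7)
        prev = None
        for rho in (10.0, 14.0, 20.0):
            geom = SemiInfiniteGeometry.from_optics(rho, phantom_optics)
            g1 = g1_point(geom, phantom_optics, flow, log_tau)
            assert np.all(np.diff(g1) < 0)
            if prev is not None:
                # larger separation decays further at fixed tau
                assert np.all(g1 <= prev + 1e-12)
            prev = g1

    def test_increasing_db_never_increases_g1(self, phantom_optics, log_tau):
        geom = SemiInfiniteGeometry.from_optics(15.0, phantom_optics)
        g_lo = g1_point(geom, phantom_optics, FlowModel(DB=1e-7), log_tau)
        g_hi = g1_point(geom, phantom_optics, FlowModel(DB=4e-7), log_tau)
        assert np.all(g_hi <= g_lo + 1e-14)


class TestG1Disk:
    def test_tiny_disk_matches_point(self, phantom_optics, log_tau):
        geom = SemiInfiniteGeometry.from_optics(10.0, phantom_optics)
        flow = FlowModel(DB=2.87e-7)
        gp = g1_point(geom, phantom_optics, flow, log_tau)
        gd = g1_disk(geom, phantom_optics, flow, log_tau, source_radius=1e-6)
        np.testing.assert_allclose(gd, gp, rtol=1e-6)

    def test_disk_decays_slower_than_point(self, phantom_optics, log_tau):
        geom = SemiInfiniteGeometry.from_optics(10.0, phantom_optics)
        flow = FlowModel(DB=2.87e-7)
        gp = g1_point(geom, phantom_optics, flow, log_tau)
        gd = g1_disk(geom, phantom_optics, flow, log_tau, source_radius=2.5)
        assert np.all(gd >= gp - 1e-12)

    def test_matches_cartesian_riemann_oracle(self, phantom_optics):
        # 400x400 Cartesian grid average over the disk, frozen from the
        # brute-force evaluation at (rho, tau) = (10 mm, 1e-5 s)
        geom = SemiInfiniteGeometry.from_optics(10.0, phantom_optics)
        gd = g1_disk(
            geom, phantom_optics, FlowModel(DB=2.87e-7), np.array([1e-5]), 2.5
        )
        assert gd[0] == pytest.approx(0.07940830533365575, rel=1e-4)

    def test_self_convergence_below_tolerance(self, phantom_optics):
        geom = SemiInfiniteGeometry.from_optics(10.0, phantom_optics)
        flow = FlowModel(DB=2.87e-7)
        tau = np.logspace(-7, -4, 10)
        loose = g1_disk(geom, phantom_optics, flow, tau, 2.5, quadrature_tol=1e-4)
        tight = g1_disk(geom, phantom_optics, flow, tau, 2.5, quadrature_tol=1e-8)
        np.testing.assert_allclose(loose, tight, rtol=2e-4)


class TestSiegert:
    @pytest.mark.parametrize(
        "g1, beta, expected", [(1.0, 0.5, 1.5), (0.0, 0.3, 1.0), (0.5, 0.5, 1.125)]
    )
    def test_direct_values(self, g1, beta, expected):
        assert g2_from_g1(np.array([g1]), beta)[0] == pytest.approx(expected)

    @pytest.mark.parametrize("beta", [0.0, -0.2, 1.5])
    def test_rejects_bad_beta(self, beta):
        with pytest.raises(ValueError):
            g2_from_g1(np.array([0.5]), beta)

    @given(
        db=st.floats(1e-9, 1e-5),
        beta=st.floats(0.01, 1.0),
        rho=st.floats(5.0, 30.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_model_g2_bounded_by_siegert(self, db, beta, rho):
        props = OpticalProperties(mu_a=0.0025, mu_s_prime=1.0)
        tau = np.logspace(-9, -2, 40)
        curve = model_g2(rho, props, FlowModel(DB=db), tau, beta)
        assert np.all(curve.g2 >= 1.0 - 1e-12)
        assert np.all(curve.g2 <= 1.0 + beta + 1e-12)


class TestCorrelationCurve:
    def test_rejects_non_increasing_tau(self):
        with pytest.raises(ValueError):
            CorrelationCurve(tau=np.array([1e-6, 1e-6]), g2=np.array([1.5, 1.4]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            CorrelationCurve(tau=np.array([1e-6]), g2=np.array([1.5, 1.4]))


def test_geometry_derived_quantities(phantom_optics):
    geom = SemiInfiniteGeometry.from_optics(20.0, phantom_optics)
    assert geom.z0 == pytest.approx(1.0 / 1.0025)
    assert geom.r2 > geom.r1 > 0
    assert 0 <= geom.Reff < 1
    assert geom.r1 == pytest.approx(math.hypot(20.0, geom.z0))
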