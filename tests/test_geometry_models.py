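"""Closed-form shell geometry: metrics, growth scaling, exponent limits."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquegeom.geometry_models import (
    GrowthHypothesis,
    InvalidParameterError,
    Model1Params,
    Model2Params,
    asymptotic_exponent,
    ln_ratio,
    metrics_for,
    model1_metrics,
    model2_metrics,
    scale_params,
    sv_ratio_trajectory,
)
from plaquegeom.mesh_synthesis import MeshResolution, mesh_from_model1, mesh_from_model2

SQ116 = math.sqrt(116.0)


class TestClosedForms:
    @pytest.mark.parametrize(
        ("params", "expected"),
        [
            # right annular cylinder: elementary closed forms
            (
                Model1Params(2, 1, 10),
                dict(V=30 * math.pi, S=66 * math.pi, sv=2.2, L_wall=10.0, L_cross=SQ116),
            ),
            # one slanted end plane
            (
                Model1Params(2, 1, 10, math.pi / 4, 0),
                dict(
                    sv=2 + 0.1 * (math.sqrt(2) + 1),
                    L_wall=12.0,
                    L_cross=math.sqrt(160.0),
                ),
            ),
        ],
    )
    def test_model1_examples(self, params, expected):
        m = model1_metrics(params)
        got = dict(V=m.V, S=m.S, sv=m.sv_ratio, L_wall=m.L_wall, L_cross=m.L_cross)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, rel=1e-12)

    def test_model2_half_ring(self):
        m = model2_metrics(Model2Params(2, 1, 10, math.pi))
        assert m.V == pytest.approx(15 * math.pi, rel=1e-12)
        assert m.S == pytest.approx(33 * math.pi + 20, rel=1e-12)
        assert m.sv_ratio == pytest.approx(m.S / m.V, rel=1e-12)
        assert m.L == pytest.approx(SQ116, rel=1e-12)

    def test_sv_identity_random_params(self):
        """S/V computed from S and V matches the closed-form ratio (both models)."""
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            r = rng.uniform(0.2, 4.0)
            R = r + rng.uniform(0.05, 3.0)
            h = rng.uniform(0.5, 30.0)
            th1, th2 = rng.uniform(0.0, 1.2, size=2)
            if h > R * (math.tan(th1) + math.tan(th2)):
                m1 = model1_metrics(Model1Params(R, r, h, th1, th2))
                assert m1.S / m1.V == pytest.approx(m1.sv_ratio, rel=1e-10)
            theta = rng.uniform(0.05, 2 * math.pi * 0.999)
            m2 = model2_metrics(Model2Params(R, r, h, theta))
            assert m2.S / m2.V == pytest.approx(m2.sv_ratio, rel=1e-10)

    def test_invariant_violations_are_named(self):
        with pytest.raises(InvalidParameterError, match="R > r"):
            Model1Params(1.0, 2.0, 5.0)
        with pytest.raises(InvalidParameterError, match="h > 0"):
            Model2Params(2.0, 1.0, -1.0, 1.0)
        with pytest.raises(InvalidParameterError, match="end planes intersect"):
            Model1Params(2.0, 1.0, 1.0, 1.2, 1.2)
        with pytest.raises(InvalidParameterError, match="theta"):
            Model2Params(2.0, 1.0, 5.0, 7.0)

    def test_full_ring_emits_degeneracy_warning(self):
        with pytest.warns(RuntimeWarning, match="theta = 2\\*pi"):
            model2_metrics(Model2Params(2.0, 1.0, 10.0, 2 * math.pi))


class TestLnRatio:
    def test_forced_by_construction(self):
        from plaquegeom.geometry_models import ClosedFormMetrics

        m = ClosedFormMetrics(V=math.e**3, S=math.e**2, sv_ratio=math.e**-1)
        assert ln_ratio(m, "S_V") == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_model1_against_factored_form(self):
        """Direct evaluation matches the factored ln decomposition."""
        R, r, h = 2.0, 1.0, 10.0
        m = model1_metrics(Model1Params(R, r, h))
        direct = ln_ratio(m, "S_V")
        factored = math.log(math.pi * (R + r) * (2 * h + (R - r) * 2.0)) / math.log(
            math.pi * h * (R + r) * (R - r)
        )
        assert direct == pytest.approx(factored, rel=1e-12)
        assert direct == pytest.approx(math.log(66 * math.pi) / math.log(30 * math.pi))

    def test_model2_against_grouped_numerator(self):
        """Matches the grouped surface decomposition 2h(R-r)+theta(R+r)(R-r+h)."""
        R, r, h, theta = 2.0, 1.0, 10.0, math.pi
        m = model2_metrics(Model2Params(R, r, h, theta))
        direct = ln_ratio(m, "S_V")
        grouped = math.log(
            2 * h * (R - r) + theta * (R + r) * (R - r + h)
        ) / math.log(theta * h * (R + r) * (R - r) / 2.0)
        assert direct == pytest.approx(grouped, rel=1e-12)
        assert direct == pytest.approx(
            math.log(33 * math.pi + 20) / math.log(15 * math.pi)
        )

    def test_domain_errors(self):
        from plaquegeom.geometry_models import ClosedFormMetrics

        with pytest.raises(ValueError):
            ln_ratio(ClosedFormMetrics(V=1.0, S=5.0, sv_ratio=5.0), "S_V")


class TestScaleParams:
    BASE = Model1Params(2.0, 1.0, 10.0, 0.3, 0.2)

    def test_identity(self):
        assert scale_params(GrowthHypothesis("H1_1", self.BASE), 1.0) == self.BASE

    def test_linear_scaling(self):
        p = scale_params(GrowthHypothesis("H1_1", self.BASE), 10.0)
        assert (p.R, p.r, p.h) == (20.0, 10.0, 100.0)
        assert (p.theta1, p.theta2) == (0.3, 0.2)

    def test_secant_scaling(self):
        g = GrowthHypothesis("H1_2", Model1Params(2, 1, 10), secant_base=2.0)
        p = scale_params(g, 2.0)
        assert p.theta1 == pytest.approx(math.acos(0.25), rel=1e-12)
        assert 1.0 / math.cos(p.theta1) == pytest.approx(4.0, rel=1e-12)

    def test_secant_below_one_rejected(self):
        g = GrowthHypothesis("H1_2", Model1Params(2, 1, 10), secant_base=1.0)
        with pytest.raises(ValueError, match="secant"):
            scale_params(g, 0.5)

    def test_hypothesis_model_mismatch(self):
        with pytest.raises(InvalidParameterError):
            GrowthHypothesis("H2_1", self.BASE)
        with pytest.raises(InvalidParameterError):
            GrowthHypothesis("H1_1", Model2Params(2, 1, 10, 1.0))


class TestAsymptoticExponents:
    H11 = GrowthHypothesis("H1_1", Model1Params(2.0, 1.0, 10.0, 0.3, 0.2))
    H12 = GrowthHypothesis("H1_2", Model1Params(2.0, 1.0, 10.0), secant_base=2.0)
    H21 = GrowthHypothesis("H2_1", Model2Params(2.0, 1.0, 10.0, 1.0))

    @pytest.mark.parametrize(
        ("hyp", "pair", "length", "k_max", "limit", "tol"),
        [
            ("H11", "S_V", "wall", 1e4, 2 / 3, 1e-9),
            ("H11", "L_V", "wall", 1e4, 1 / 3, 1e-9),
            ("H11", "L_V", "cross", 1e4, 1 / 3, 1e-6),
            ("H12", "S_V", "wall", 1e6, 1.0, 0.01),
            ("H12", "L_V", "wall", 1e6, 2 / 3, 0.01),
            ("H21", "S_V", "wall", 1e6, 2 / 3, 0.01),
            ("H21", "L_V", "chord", 1e6, 1 / 3, 0.01),
        ],
    )
    def test_limits(self, hyp, pair, length, k_max, limit, tol):
        g = getattr(self, hyp)
        est = asymptotic_exponent(g, pair, length, k_max=k_max)
        assert est == pytest.approx(limit, abs=tol)

    def test_isometric_slope_exact_at_every_scale(self):
        """Under isometric growth the log-log S-V slope is 2/3 on every interval."""
        from plaquegeom.geometry_models import _log_quantities

        ks = np.geomspace(1.0, 1e4, 30)
        ln_s, ln_v = _log_quantities(self.H11, ks, "S_V", "wall")
        slopes = np.diff(ln_s) / np.diff(ln_v)
        assert np.allclose(slopes, 2 / 3, atol=1e-12)

    def test_slant_growth_slope_bounded(self):
        """H1.2 finite-scale S-V slopes stay within (2/3, 1]."""
        from plaquegeom.geometry_models import _log_quantities

        ks = np.geomspace(1.0, 1e6, 40)
        ln_s, ln_v = _log_quantities(self.H12, ks, "S_V", "wall")
        slopes = np.diff(ln_s) / np.diff(ln_v)
        assert np.all(slopes > 2 / 3)
        assert np.all(slopes <= 1.0 + 1e-12)

    def test_length_slopes_bracketed(self):
        """Model-1 trajectories keep the L-V slope inside [1/3, 2/3]; the
        partial-ring chord converges to 1/3 (transiently lower while the
        circumferential angle is still opening)."""
        from plaquegeom.geometry_models import _log_quantities

        for g, choice in ((self.H11, "wall"), (self.H12, "wall")):
            ks = np.geomspace(1.0, 1e5, 30)
            ln_l, ln_v = _log_quantities(g, ks, "L_V", choice)
            slopes = np.diff(ln_l) / np.diff(ln_v)
            assert np.all(slopes >= 1 / 3 - 1e-9)
            assert np.all(slopes <= 2 / 3 + 1e-9)
        ks = np.geomspace(1.0, 1e5, 30)
        ln_l, ln_v = _log_quantities(self.H21, ks, "L_V", "chord")
        slopes = np.diff(ln_l) / np.diff(ln_v)
        assert slopes[-1] == pytest.approx(1 / 3, abs=1e-3)
        assert np.all(slopes <= 2 / 3 + 1e-9)

    @pytest.mark.parametrize("hyp", ["H11", "H12", "H21"])
    def test_sv_ratio_strictly_decreasing(self, hyp):
        ks, sv = sv_ratio_trajectory(getattr(self, hyp), k_max=1e4)
        assert np.all(np.diff(sv) < 0)

    @pytest.mark.parametrize("hyp", ["H11", "H21"])
    def test_sv_ratio_decays_to_zero(self, hyp):
        """S/V vanishes under isometric and circumferential growth.  Under
        slant growth (H1.2) it instead approaches the constant
        2*secant_base/h0, so that trajectory is excluded here."""
        ks, sv = sv_ratio_trajectory(getattr(self, hyp), k_max=1e4)
        assert sv[-1] < 1e-3

    def test_sv_ratio_slant_growth_limit(self):
        """H1.2 S/V decreases toward 2*secant_base/h0 (0.4 for this base)."""
        ks, sv = sv_ratio_trajectory(self.H12, k_max=1e6)
        assert np.all(np.diff(sv) < 0)
        assert sv[-1] == pytest.approx(0.4, rel=1e-4)

    def test_precondition_errors(self):
        with pytest.raises(ValueError):
            asymptotic_exponent(self.H11, k_max=100.0)
        with pytest.raises(ValueError):
            asymptotic_exponent(self.H11, n_points=5)


class TestMeshOracle:
    """Closed forms agree with discrete measurement of the realized solids."""

    @pytest.mark.parametrize(
        "params",
        [Model1Params(3.0, 2.5, 8.0, 0.3, 0.2), Model2Params(2.8, 2.2, 6.0, 2.0)],
        ids=["slanted-ring", "partial-ring"],
    )
    def test_volume_and_area_within_half_percent(self, params):
        res = MeshResolution(256, 64, 8)
        if isinstance(params, Model1Params):
            mesh = mesh_from_model1(params, res)
        else:
            mesh = mesh_from_model2(params, res)
        m = metrics_for(params)
        assert mesh.volume == pytest.approx(m.V, rel=5e-3)
        assert mesh.area == pytest.approx(m.S, rel=5e-3)


@settings(derandomize=True, max_examples=200)
@given(
    r=st.floats(0.2, 3.0),
    dr=st.floats(0.05, 2.0),
    h=st.floats(0.5, 20.0),
    theta=st.floats(0.05, 2 * math.pi),
)
def test_model2_sv_identity_property(r, dr, h, theta):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = model2_metrics(Model2Params(r + dr, r, h, theta))
    assert m.S / m.V == pytest.approx(m.sv_ratio, rel=1e-10)
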