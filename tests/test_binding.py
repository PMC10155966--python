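"""Forward-model unit and property tests: conversions, dilution, heats,
the two-site free-concentration solver and the scaling degeneracy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import itcbayes as ib
from itcbayes.binding import R_KCAL, solve_free_two_site_lm

from oracles import (injection_heats_oracle, one_site_heat_oracle,
                     stepwise_mixing_oracle, two_site_free_oracle)

T25 = 298.15
RT = R_KCAL * T25


# ------------------------------------------------------------- conversions
@pytest.mark.parametrize("dg, kd, tol", [
    (-6.9, 8.7e-6, 0.1e-6),    # printed to two significant figures
    (0.0, 1.0, 1e-12),
    (-6.5, 1.72e-5, 2e-8),
])
def test_kd_from_dg_reference_values(dg, kd, tol):
    assert ib.kd_from_dg(dg, T25) == pytest.approx(kd, abs=tol)


def test_kd_from_dg_monotone_and_roundtrip():
    dgs = np.linspace(-15, 0, 40)
    kds = ib.kd_from_dg(dgs, T25)
    assert np.all(np.diff(kds) > 0)
    assert ib.dg_from_kd(kds, T25) == pytest.approx(dgs)


def test_kd_from_dg_rejects_nonfinite():
    with pytest.raises(ValueError):
        ib.kd_from_dg(np.nan, T25)
    with pytest.raises(ValueError):
        ib.kd_from_dg(-7.0, -1.0)


# ---------------------------------------------------------------- dilution
def test_dilution_limits():
    proto = ib.standard_protocol(6.0)
    conc = ib.AnalyteConcentrations(17.0, 500.0)
    mt, xt = ib.dilution_series(proto, conc)
    assert mt[0] == pytest.approx(conc.cell_M, rel=2e-3)   # ~zero volume in
    assert xt[0] == pytest.approx(0.0, abs=conc.syringe_M * 2e-3)
    assert np.all(np.diff(mt) < 0) and np.all(np.diff(xt) > 0)
    # full-replacement limit
    big = ib.TitrationProtocol(1.42, T25, (5000.0,) * 4)
    with pytest.warns(UserWarning):
        _, xt_big = ib.dilution_series(big, conc)
    assert xt_big[-1] == pytest.approx(conc.syringe_M, rel=1e-4)


def test_dilution_matches_stepwise_mixing_oracle():
    proto = ib.standard_protocol(6.0)
    conc = ib.AnalyteConcentrations(17.0, 500.0)
    mt, xt = ib.dilution_series(proto, conc)
    mt_o, xt_o = stepwise_mixing_oracle(proto.volumes_l, proto.cell_volume_l,
                                        conc.cell_M, conc.syringe_M)
    assert np.max(np.abs(mt / mt_o - 1)) < 1e-3
    assert np.max(np.abs(xt[1:] / xt_o[1:] - 1)) < 1e-3


# ---------------------------------------------------------------- 1:1 heat
def test_heat_one_site_limits():
    th = ib.ThermoOneSite(-8.0, -12.0)
    v0 = 1.42e-3
    assert ib.heat_one_site(34e-6, 0.0, th, v0, T25) == 0.0
    # saturation with effectively infinite affinity
    tight = ib.ThermoOneSite(-25.0, -12.0)
    q = ib.heat_one_site(34e-6, 200e-6, tight, v0, T25)
    assert q == pytest.approx(v0 * 34e-6 * -12.0 * 1e3, rel=1e-6)
    assert q < 0  # sign follows dH


def test_heat_one_site_matches_mass_balance_oracle():
    th = ib.ThermoOneSite(-8.0, -12.0)
    v0 = 1.42e-3
    for xt in (1e-6, 3.4e-5, 1e-4, 5e-4):
        q = ib.heat_one_site(34e-6, xt, th, v0, T25)
        q_o = one_site_heat_oracle(34e-6, xt, th.kd(T25), th.dH, v0)
        assert q == pytest.approx(q_o, rel=1e-10)


# -------------------------------------------------------- two-site solver
def test_solve_free_trivial_and_errors():
    m, x = ib.solve_free_two_site(1.7e-5, 0.0, 1e-5, 1e-6)
    assert (m, x) == (1.7e-5, 0.0)
    with pytest.raises(ValueError):
        ib.solve_free_two_site(-1e-5, 1e-5, 1e-5, 1e-6)
    with pytest.raises(ValueError):
        ib.solve_free_two_site(1e-5, 1e-5, -1e-5, 1e-6)


def test_solve_free_mass_balance_random_draws():
    rng = np.random.default_rng(42)
    mt, xt, kd1, kd2 = 10 ** rng.uniform(-7, -3, size=(4, 1000))
    m, x = ib.solve_free_two_site(mt, xt, kd1, kd2)
    mt_back = m * (1 + 2 * x / kd1 + x ** 2 / (kd1 * kd2))
    xt_back = x + m * (2 * x / kd1 + 2 * x ** 2 / (kd1 * kd2))
    assert np.max(np.abs(mt_back / mt - 1)) < 1e-9
    assert np.max(np.abs(xt_back / xt - 1)) < 1e-9
    assert np.all(m >= 0) and np.all(x >= 0)


def test_solve_free_noncooperative_reduces_to_independent_sites():
    # with equal microscopic constants the two grooves are independent and
    # each is occupied with probability x/(x+K)
    K = 8e-6
    mt = 1.7e-5
    for xt in (5e-6, 2e-5, 6e-5):
        m, x = ib.solve_free_two_site(mt, xt, K, K)
        mx = 2 * x * m / K
        mx2 = x * x * m / (K * K)
        bound_sites = (mx + 2 * mx2) / (2 * mt)
        assert bound_sites == pytest.approx(x / (x + K), rel=1e-8)


def test_solve_free_alpha_scaling_exact():
    base = (1.7e-5, 6e-5, 8e-6, 2e-6)
    m0, x0 = ib.solve_free_two_site(*base)
    for alpha in (0.5, 2.0, 5.0):
        m, x = ib.solve_free_two_site(*(alpha * np.asarray(base)))
        assert m == pytest.approx(alpha * m0, rel=1e-10)
        assert x == pytest.approx(alpha * x0, rel=1e-10)


def test_solve_free_agrees_with_lm_route():
    rng = np.random.default_rng(7)
    for _ in range(50):
        mt, xt, kd1, kd2 = 10 ** rng.uniform(-7, -3, size=4)
        m1, x1 = ib.solve_free_two_site(mt, xt, kd1, kd2)
        m2, x2 = solve_free_two_site_lm(mt, xt, kd1, kd2)
        assert m1 == pytest.approx(m2, rel=1e-7)
        assert x1 == pytest.approx(x2, rel=1e-7)


# ---------------------------------------------------------- two-site heat
def test_heat_two_site_limits():
    th = ib.ThermoTwoSite(-7.0, -1.0, -10.0, -1.5)
    v0 = 1.42e-3
    assert ib.heat_two_site(1.7e-5, 0.0, th, v0, T25) == 0.0
    tight = ib.ThermoTwoSite(-20.0, -1.0, -10.0, -1.5)
    q = ib.heat_two_site(1.7e-5, 3e-4, tight, v0, T25)
    total_dh_cal = (2 * tight.dH + tight.ddH) * 1e3
    assert q == pytest.approx(v0 * 1.7e-5 * total_dh_cal, rel=1e-6)


def test_heat_two_site_matches_2d_bracketing_oracle():
    th = ib.ThermoTwoSite(-7.0, -1.0, -10.0, -1.5)
    proto = ib.standard_protocol(6.0)
    conc = ib.AnalyteConcentrations(17.0, 500.0)
    mt, xt = ib.dilution_series(proto, conc)
    v0 = proto.cell_volume_l
    q = ib.heat_two_site(mt, xt, th, v0, T25)
    kd1, kd2 = th.kd1(T25), th.kd2(T25)
    m_o, x_o = two_site_free_oracle(mt, xt, kd1, kd2)
    mx = 2 * x_o * m_o / kd1
    mx2 = x_o ** 2 * m_o / (kd1 * kd2)
    q_o = v0 * (th.dH * 1e3 * mx + (2 * th.dH + th.ddH) * 1e3 * mx2)
    assert np.max(np.abs(q / q_o - 1)) < 1e-6


def test_cumulative_heat_monotone_toward_saturation():
    th = ib.ThermoTwoSite(-7.0, -1.0, -10.0, -1.5)  # both steps exothermic
    xts = np.linspace(0, 4e-4, 60)
    q = ib.heat_two_site(np.full_like(xts, 1.7e-5), xts, th, 1.42e-3, T25)
    assert np.all(np.diff(np.abs(q)) >= -1e-15)


# --------------------------------------------------------- injection heats
def test_injection_heats_constant_series_and_offset():
    proto = ib.standard_protocol(6.0)
    q = np.full(proto.n_injections, -3e-4)
    dq = ib.injection_heats(q, proto, dH0_ucal=0.0)
    expected = (proto.volumes_l / proto.cell_volume_l) * -3e-4 * 1e6
    # identity holds once the cell heat is at steady state (Q_{i-1} = Q_i);
    # the first entry also carries the step from the Q0 = 0 initial state
    assert dq[1:] == pytest.approx(expected[1:])
    v1 = proto.volumes_l[0] / proto.cell_volume_l
    assert dq[0] == pytest.approx(-3e-4 * 1e6 * (1 + v1 / 2))
    assert ib.injection_heats(q, proto, 0.7) - dq == pytest.approx(0.7)
    with pytest.raises(ValueError):
        ib.injection_heats(q[:-1], proto)


def test_injection_heats_matches_loop_oracle():
    th = ib.ThermoTwoSite(-7.0, -1.0, -10.0, -1.5)
    proto = ib.standard_protocol(6.0)
    conc = ib.AnalyteConcentrations(17.0, 500.0)
    mt, xt = ib.dilution_series(proto, conc)
    q = ib.heat_two_site(mt, xt, th, proto.cell_volume_l, T25)
    dq = ib.injection_heats(q, proto, -0.3)
    dq_o = injection_heats_oracle(q, proto.volumes_l, proto.cell_volume_l, -0.3)
    assert dq == pytest.approx(dq_o, rel=1e-12)


# --------------------------------------------------------------- degeneracy
def test_degeneracy_transform_rules():
    th = ib.ThermoTwoSite(-7.0, -1.0, -10.0, -1.5)
    conc = ib.AnalyteConcentrations(17.0, 500.0)
    t1, c1 = ib.degeneracy_transform(th, conc, 1.0, T25)
    assert t1 == th and c1 == conc
    t2, c2 = ib.degeneracy_transform(th, conc, 2.0, T25)
    assert t2.dG == pytest.approx(-7.0 + 0.4107, abs=2e-4)
    assert t2.ddG == th.ddG
    assert t2.dH == pytest.approx(-5.0)
    assert t2.ddH == pytest.approx(-0.75)
    assert (c2.cell_uM, c2.syringe_uM) == (34.0, 1000.0)
    with pytest.raises(ValueError):
        ib.degeneracy_transform(th, conc, 0.0, T25)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    dG=st.floats(-10, -4), ddG=st.floats(-3, 3),
    dH=st.floats(-20, -2), ddH=st.floats(-5, 5),
    alpha=st.sampled_from([0.5, 0.9, 2.0, 5.0]),
)
def test_degeneracy_leaves_injection_heats_invariant(dG, ddG, dH, ddH, alpha):
    th = ib.ThermoTwoSite(dG, ddG, dH, ddH)
    proto = ib.standard_protocol(6.0)
    conc = ib.AnalyteConcentrations(17.0, 500.0)
    dq0 = ib.model_injection_heats(th, proto, conc)
    th2, conc2 = ib.degeneracy_transform(th, conc, alpha, T25)
    dq1 = ib.model_injection_heats(th2, proto, conc2)
    # series-scale relative error (individual heats can pass through zero)
    assert np.max(np.abs(dq1 - dq0)) < 1e-10 * np.max(np.abs(dq0))


def test_degeneracy_one_site_invariant():
    th = ib.ThermoOneSite(-8.0, -12.0)
    proto = ib.standard_protocol(6.0)
    conc = ib.AnalyteConcentrations(34.0, 500.0)
    dq0 = ib.model_injection_heats(th, proto, conc)
    for alpha in (0.5, 0.9, 2.0, 5.0):
        th2, conc2 = ib.degeneracy_transform(th, conc, alpha, T25)
        dq1 = ib.model_injection_heats(th2, proto, conc2)
        assert np.max(np.abs(dq1 / dq0 - 1)) < 1e-10


def test_two_site_without_cooperativity_matches_identical_sites_isotherm():
    # ddG = ddH = 0 must reproduce the independent-identical-sites heats,
    # built here from the per-site closed form
    th2 = ib.ThermoTwoSite(-7.0, 0.0, -10.0, 0.0)
    proto = ib.standard_protocol(6.0)
    conc = ib.AnalyteConcentrations(17.0, 500.0)
    mt, xt = ib.dilution_series(proto, conc)
    K = th2.kd1(T25)
    q2 = ib.heat_two_site(mt, xt, th2, proto.cell_volume_l, T25)
    q_ind = np.array([
        one_site_heat_oracle(2 * m, x, K, -10.0, proto.cell_volume_l)
        for m, x in zip(mt, xt)])  # two independent sites at 2*[M] total
    assert np.max(np.abs(q2 / q_ind - 1)) < 1e-8
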