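import numpy as np
import pytest

from virtualckd.model_core import (
    CardiorenalModel,
    ConvergenceError,
    DegenerateKidneyError,
    Interventions,
)
from virtualckd.params import ParameterSet

NF = np.array([2.4e6])
NA = np.array([2100.0])


# --------------------------------------------------------------------- #
# operating point


def test_nominal_anchor_is_exact_fixed_point(nominal_model, iv):
    out = nominal_model.algebraic(NA, NF, iv)
    assert out.map[0] == pytest.approx(94.0, rel=1e-6)
    assert out.gfr[0] == pytest.approx(129.0, rel=1e-6)
    assert out.pc[0] == pytest.approx(52.0, rel=1e-6)
    assert out.rbf[0] == pytest.approx(1100.0, rel=1e-6)
    assert out.tgf[0] == pytest.approx(1.0, rel=1e-6)
    assert out.ang2[0] == pytest.approx(12.0, rel=1e-6)
    assert out.aldosterone[0] == pytest.approx(11.0, rel=1e-6)
    assert out.anp[0] == pytest.approx(27.0, rel=1e-6)
    assert out.ecfv[0] == pytest.approx(15.0, rel=1e-12)
    assert out.una[0] * 1440.0 == pytest.approx(123.0, rel=1e-6)


def test_gfr_sngfr_unit_identity(nominal_model, iv):
    for na in (1900.0, 2100.0, 2300.0):
        out = nominal_model.algebraic(np.array([na]), NF, iv)
        assert out.gfr[0] == pytest.approx(out.sngfr[0] * NF[0] * 1e-6, rel=1e-9)


def test_table_unit_arithmetic_oracle():
    # printed values reconcile: 54 nL/min * 2.4e6 nephrons = 129.6 mL/min
    assert 54e-6 * 2.4e6 == pytest.approx(129.0, rel=0.005)
    # CKD column: 69 nL/min * 720,268 nephrons = 49.7 mL/min, within 5% of 48
    assert 69e-6 * 720_268 == pytest.approx(49.7, abs=0.05)
    assert 69e-6 * 720_268 == pytest.approx(48.0, rel=0.05)


def test_pc_between_arterial_and_venous(nominal_model, iv):
    for na in (1950.0, 2100.0, 2250.0):
        out = nominal_model.algebraic(np.array([na]), NF, iv)
        assert nominal_model.pv < out.pc[0] < out.map[0]


# --------------------------------------------------------------------- #
# renal hemodynamics


def test_renal_hemodynamics_monotonicity(nominal_model):
    m = nominal_model
    base = m.renal_hemodynamics(94.0, NF, ra=np.array([0.07]), re=np.array([0.0989]))
    up_ra = m.renal_hemodynamics(94.0, NF, ra=np.array([0.09]), re=np.array([0.0989]))
    up_re = m.renal_hemodynamics(94.0, NF, ra=np.array([0.07]), re=np.array([0.13]))
    assert up_ra.pc[0] < base.pc[0]   # afferent constriction lowers Pc
    assert up_re.pc[0] > base.pc[0]   # efferent constriction raises Pc
    assert up_ra.rbf[0] < base.rbf[0]


def test_renal_hemodynamics_degenerate_kidney(nominal_model):
    with pytest.raises(DegenerateKidneyError):
        nominal_model.renal_hemodynamics(
            94.0, np.array([0.0]), ra=np.array([0.07]), re=np.array([0.1])
        )


def test_sngfr_floor_at_zero(nominal_model):
    out = nominal_model.renal_hemodynamics(
        40.0, NF, ra=np.array([0.2]), re=np.array([0.001])
    )
    assert out.sngfr[0] == 0.0
    assert out.gfr[0] == 0.0


# --------------------------------------------------------------------- #
# TGF and hormones


def test_tgf_normal_operating_point(nominal_model):
    assert nominal_model.tgf_signal(1.806, 12.0) == pytest.approx(1.0, rel=1e-9)


def test_tgf_monotone_both_inputs(nominal_model):
    m = nominal_model
    assert m.tgf_signal(2.2, 12.0) > m.tgf_signal(1.806, 12.0)
    assert m.tgf_signal(1.806, 20.0) > m.tgf_signal(1.806, 12.0)
    assert m.tgf_signal(0.0, 0.0) > 0.0
    # zero inputs approach the curves' lower saturation bound from above
    lower = np.asarray(
        m.s_tgf_del.b / m.s_tgf_del.ref * m.s_tgf_ang.b / m.s_tgf_ang.ref
    ).reshape(-1)[0]
    at_zero = float(np.asarray(m.tgf_signal(0.0, 0.0)).reshape(-1)[0])
    assert lower < at_zero < 1.0
    assert at_zero < float(np.asarray(m.tgf_signal(0.9, 6.0)).reshape(-1)[0])


def test_tgf_ckd_within_printed_band(nominal_model, ckd_state):
    # population value 0.76 +/- 0.3; nominal CKD model must land inside
    assert 0.46 < float(ckd_state.outputs.tgf[0]) < 1.06


def test_hormonal_cascade_nominal(nominal_model):
    ang2, aldo, anp = nominal_model.hormones(1.806, 94.0, 15.0)
    assert ang2[0] == pytest.approx(12.0, rel=1e-9)
    assert aldo[0] == pytest.approx(11.0, rel=1e-9)
    assert anp[0] == pytest.approx(27.0, rel=1e-9)


def test_full_blockade_zeroes_effect_channels(nominal_model, iv):
    out = nominal_model.algebraic(
        NA, NF, Interventions(ras_fraction=1.0)
    )
    assert np.all(out.ang2_eff == 0.0)


def test_anp_monotone_in_ecfv(nominal_model):
    _, _, anp_lo = nominal_model.hormones(1.806, 94.0, 14.5)
    _, _, anp_hi = nominal_model.hormones(1.806, 94.0, 15.5)
    assert anp_hi[0] > anp_lo[0]


def test_renin_decreasing_in_md_delivery_and_pressure(nominal_model):
    m = nominal_model
    lo_md, _, _ = m.hormones(1.2, 94.0, 15.0)
    hi_md, _, _ = m.hormones(2.4, 94.0, 15.0)
    assert lo_md[0] > hi_md[0]
    lo_p, _, _ = m.hormones(1.806, 85.0, 15.0)
    hi_p, _, _ = m.hormones(1.806, 105.0, 15.0)
    assert lo_p[0] > hi_p[0]


def test_ang2_raises_efferent_more_than_afferent(nominal_model):
    m = nominal_model
    ratio_12 = m.s_ang_re(12.0) / m.s_ang_ra(12.0)
    ratio_hi = m.s_ang_re(25.0) / m.s_ang_ra(25.0)
    assert ratio_hi > ratio_12


# --------------------------------------------------------------------- #
# daily stepping


def test_advance_day_fixed_point(nominal_model, nominal_steady, iv):
    st = nominal_steady.copy()
    before = st.outputs
    st2 = nominal_model.advance_day(st, iv)
    for name in ("map", "gfr", "pc", "ang2", "ecfv"):
        a = getattr(before, name)[0]
        b = getattr(st2.outputs, name)[0]
        assert abs(b - a) / abs(a) < 1e-3  # < 0.1% per day


def test_advance_day_sodium_mass_balance(nominal_model, nominal_steady, iv):
    st = nominal_steady.copy()
    st.na_total = st.na_total + 30.0  # perturb off steady state
    st2 = nominal_model.advance_day(st, iv)
    delta = st2.na_total - st.na_total
    assert delta[0] == pytest.approx(
        st2.day_intake[0] - st2.day_excretion[0], rel=1e-6, abs=1e-9
    )


def test_salt_step_raises_map(nominal_model, nominal_steady):
    st = nominal_steady.copy()
    high = Interventions(salt_override=246.0)
    for _ in range(30):
        st = nominal_model.advance_day(st, high)
    assert st.outputs.map[0] > 94.5
    # monotone: doubling intake settles at a higher steady MAP
    ss = nominal_model.steady_state(high)
    assert ss.outputs.map[0] > 94.5


def test_lv_mass_first_order_relaxation(nominal_model, nominal_steady):
    st = nominal_steady.copy()
    st.lv_mass = st.lv_mass + 40.0
    gaps = []
    for _ in range(3):
        st = nominal_model.advance_day(st, Interventions())
        gaps.append(abs(st.lv_mass[0] - 223.0))
    # monotone approach with a constant daily shrink factor
    assert gaps[0] > gaps[1] > gaps[2]
    r1 = gaps[1] / gaps[0]
    r2 = gaps[2] / gaps[1]
    assert r1 == pytest.approx(r2, rel=1e-2)
    assert r1 == pytest.approx(np.exp(-1.0 / nominal_model.lv_tau), rel=1e-2)


# --------------------------------------------------------------------- #
# steady state


def test_steady_state_nominal_values(nominal_steady):
    out = nominal_steady.outputs
    assert out.map[0] == pytest.approx(94.0, rel=0.001)
    assert out.ecfv[0] == pytest.approx(15.0, rel=0.001)


def test_steady_state_idempotent(nominal_model, nominal_steady):
    again = nominal_model.steady_state()
    assert again.na_total[0] == pytest.approx(nominal_steady.na_total[0], rel=1e-9)
    assert again.outputs.map[0] == pytest.approx(
        nominal_steady.outputs.map[0], rel=1e-9
    )


def test_steady_state_deterministic(nominal_model):
    a = CardiorenalModel(ParameterSet.nominal(1)).steady_state()
    b = CardiorenalModel(ParameterSet.nominal(1)).steady_state()
    assert a.na_total[0] == b.na_total[0]
    assert a.outputs.map[0] == b.outputs.map[0]


def test_chronic_sodium_balance_within_half_percent(nominal_model, ckd_state):
    # at any steady state, excretion equals intake within 0.5%
    out = ckd_state.outputs
    assert out.una[0] * 1440.0 == pytest.approx(123.0, rel=0.005)


def test_strict_solve_raises_with_worst_variable(nominal_model):
    with pytest.raises(ConvergenceError, match="worst residual"):
        nominal_model.algebraic(
            NA * 1.4, NF, Interventions(), max_iter=2, strict=True
        )


def test_ckd_baseline_near_printed_column(ckd_state):
    out = ckd_state.outputs
    assert out.gfr[0] == pytest.approx(48.0, rel=0.10)
    assert out.pc[0] == pytest.approx(68.0, rel=0.05)
    assert out.map[0] == pytest.approx(108.0, rel=0.05)
    assert out.rbf[0] == pytest.approx(382.0, rel=0.10)
    assert out.ecfv[0] == pytest.approx(15.0, rel=0.05)
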