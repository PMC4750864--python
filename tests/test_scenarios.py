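"""Scenario multiplier schedules: values, continuity, composition, signs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apap_pbpk.scenarios import (
    PiecewiseLinear,
    alcohol_schedule,
    build_scenario,
    chronic_apap_schedule,
    combined_chronic_alcohol,
    evaluate_modifiers,
    fasting_modifiers,
    neutral_modifiers,
)


@pytest.mark.parametrize("t, co_g, co_s", [
    (0.0, 1.0, 1.0),
    (2160.0, 1.25, 0.75),      # mid-ramp, linear interpolation
    (4320.0, 1.5, 0.5),        # adaptation complete after 3 days
    (99999.0, 1.5, 0.5),       # holds thereafter
])
def test_chronic_schedule_1g(t, co_g, co_s):
    m = chronic_apap_schedule(1.0)
    cg, cs, cox, kg = evaluate_modifiers(m, t)
    assert cg == pytest.approx(co_g)
    assert cs == pytest.approx(co_s)
    assert cox == 1.0 and kg == 1.0
    assert m.initial_gsh_fraction == 1.0


@pytest.mark.parametrize("dose, maxima", [
    (1.0, (1.5, 0.5)),
    (2.0, (2.25, 0.3)),
    (5.0, (2.25, 0.3)),  # doses above 2 g reuse the 2 g adaptation
])
def test_chronic_dose_tiers(dose, maxima):
    m = chronic_apap_schedule(dose)
    assert (m.co_g(4320.0), m.co_s(4320.0)) == pytest.approx(maxima)


def test_chronic_requires_positive_dose():
    with pytest.raises(ValueError):
        chronic_apap_schedule(0.0)


@pytest.mark.parametrize("t, co_ox", [
    (0.0, 2.14),           # induced maximum the moment drinking stops
    (3600.0, 1.57),        # halfway down the 5-day decay
    (7200.0, 1.0),
    (10000.0, 1.0),
])
def test_alcohol_cyp_decay(t, co_ox):
    m = alcohol_schedule()
    assert m.co_ox(t) == pytest.approx(co_ox)


def test_alcohol_gsh_recovery():
    m = alcohol_schedule()
    assert m.initial_gsh_fraction == 0.5
    assert m.gsh_target_fraction == 1.0  # the pool returns to normal
    assert m.k_gen_mult(0.0) == pytest.approx(0.5)
    assert m.k_gen_mult(720.0) == pytest.approx(0.75)
    assert m.k_gen_mult(1440.0) == 1.0
    assert m.co_g(5000.0) == 1.0 and m.co_s(5000.0) == 1.0


def test_fasting_constants():
    m = fasting_modifiers()
    for t in (0.0, 1234.5, 1e5):
        assert evaluate_modifiers(m, t) == pytest.approx((0.6, 0.7, 1.5, 0.75))
    assert m.initial_gsh_fraction == 0.75
    assert m.gsh_target_fraction == 0.75  # malnourished steady state persists


def test_combined_composition():
    m = combined_chronic_alcohol(1.0)
    cg, cs, cox, kg = evaluate_modifiers(m, 0.0)
    assert (cg, cox) == pytest.approx((1.0, 2.14))
    # at the end of the chronic ramp the alcohol decay is 60 % through
    cg, cs, cox, kg = evaluate_modifiers(m, 4320.0)
    assert cg == pytest.approx(1.5)
    assert cox == pytest.approx(2.14 - 1.14 * 4320 / 7200)  # 1.456
    assert m.initial_gsh_fraction == 0.5


def test_neutral_composition_is_identity():
    n = neutral_modifiers()
    m = combined_chronic_alcohol(1.0)
    prod = n.co_ox.product(n.co_g)
    assert prod(123.0) == 1.0
    # composing chronic co_ox (constant 1) with alcohol leaves alcohol's ramp
    assert m.co_ox(3600.0) == pytest.approx(alcohol_schedule().co_ox(3600.0))


def test_evaluate_rejects_negative_time():
    with pytest.raises(ValueError):
        evaluate_modifiers(neutral_modifiers(), -1.0)


@pytest.mark.parametrize("scenario", [
    chronic_apap_schedule(1.0),
    chronic_apap_schedule(5.0),
    alcohol_schedule(),
    fasting_modifiers(),
    combined_chronic_alcohol(2.0),
])
def test_schedules_continuous_at_breakpoints(scenario):
    eps = 1e-7
    for f in (scenario.co_g, scenario.co_s, scenario.co_ox, scenario.k_gen_mult):
        for b in f.times:
            left = f(max(b - eps, 0.0))
            right = f(b + eps)
            assert abs(left - right) < 1e-5  # linear => jump bounded by slope*eps
            assert abs(f(b) - right) < 1e-5


def test_table_sign_matrix():
    """Direction of each scenario's effect on the four metabolic components:
    chronic use raises glucuronidation and lowers sulfation only; alcohol
    raises oxidation and lowers GSH availability only; fasting lowers both
    conjugations, raises oxidation and lowers GSH."""
    t = 2000.0  # inside every ramp
    ch = evaluate_modifiers(chronic_apap_schedule(1.0), t)
    assert ch[0] > 1 and ch[1] < 1 and ch[2] == 1 and ch[3] == 1

    al = alcohol_schedule()
    av = evaluate_modifiers(al, t)
    assert av[0] == 1 and av[1] == 1 and av[2] > 1
    assert al.initial_gsh_fraction < 1

    fa = fasting_modifiers()
    fv = evaluate_modifiers(fa, t)
    assert fv[0] < 1 and fv[1] < 1 and fv[2] > 1
    assert fa.initial_gsh_fraction < 1


def test_build_scenario_dispatch():
    assert build_scenario("normal").name == "normal"
    assert build_scenario("chronic", 2.0).co_g(1e6) == 2.25
    assert build_scenario("fasting").co_ox(0.0) == 1.5
    with pytest.raises(ValueError):
        build_scenario("chronic")  # needs a dose
    with pytest.raises(ValueError):
        build_scenario("teetotal")


@given(
    times=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=6,
                   unique=True),
    values=st.lists(st.floats(0.1, 3.0, allow_nan=False), min_size=6, max_size=6),
    t=st.floats(0, 2e4, allow_nan=False),
)
def test_piecewise_linear_bounds_and_product(times, values, t):
    times = tuple(sorted(times))
    values = tuple(values[: len(times)])
    f = PiecewiseLinear(times, values)
    assert min(values) <= f(t) <= max(values)  # interpolation stays in hull
    g = f.product(f.scaled(2.0))
    # product evaluated at a merged breakpoint is exact
    for b in g.times:
        assert g(b) == pytest.approx(2.0 * f(b) ** 2)
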