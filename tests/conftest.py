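"""Shared fixtures. Expensive simulations are session-scoped so the unit and
acceptance tests reuse them."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from apap_pbpk import (
    calibrate_baseline,
    default_kinetics,
    default_physiology,
    simulate,
)
from apap_pbpk.dosing import Regimen
from apap_pbpk.scenarios import (
    alcohol_schedule,
    chronic_apap_schedule,
    neutral_modifiers,
)

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def physiology():
    return default_physiology()


@pytest.fixture(scope="session")
def kinetics():
    return default_kinetics()


@pytest.fixture(scope="session")
def calibrated_gsh_normal():
    """Baseline [GSH]_N recomputed from scratch by the calibration routine."""
    return calibrate_baseline()


@pytest.fixture(scope="session")
def single_1g_oral():
    """A 1 g oral dose followed for 12 h; the workhorse small run."""
    return simulate(Regimen.single(1.0, route="oral"), 720.0)


@pytest.fixture(scope="session")
def chronic_runs():
    """Five-day 6-hourly regimens at 1, 2 and 5 g, with and without the
    dose-dependent induction schedule."""
    out = {}
    for dose in (1.0, 2.0, 5.0):
        regimen = Regimen.periodic(dose, 360.0, 20, route="oral")
        out[(dose, "flat")] = simulate(regimen, 7200.0, scenario=neutral_modifiers())
        out[(dose, "induced")] = simulate(regimen, 7200.0,
                                          scenario=chronic_apap_schedule(dose))
    return out


@pytest.fixture(scope="session")
def alcohol_cyp_only_run():
    """Therapeutic chronic dosing with only the post-binge CYP decay applied
    (GSH pool and regeneration left normal)."""
    scenario = dataclasses.replace(
        alcohol_schedule(), k_gen_mult=neutral_modifiers().k_gen_mult,
        initial_gsh_fraction=1.0, name="alcohol-cyp-only")
    regimen = Regimen.periodic(1.0, 360.0, 20, route="oral")
    return simulate(regimen, 7200.0, scenario=scenario)


@pytest.fixture(scope="session")
def brute_force_comparison():
    """Max relative deviation between the adaptive solver and an independent
    fixed-step RK4 integration of an independently assembled right-hand side
    (QSS NAPQI form), on a 6-hour 1 g oral problem.

    The oracle rebuilds the transport matrix from the physiological table by
    hand; only the dose bookkeeping is shared.
    """
    t_end = 360.0
    dose_mmol = 0.79 * 1000.0 / 151.16  # 1 g oral, bioavailability-scaled
    gsh_n = default_kinetics().gsh.gsh_normal

    # Compartment order: adipose bone brain gut heart kidney liver lung
    # muscle rest skin spleen arterial venous.
    V = np.array([8372, 5992, 1400, 1197, 329, 308, 1799, 532,
                  28000, 13895, 2597, 182, 1799, 3598], dtype=float)
    Q = np.array([325, 325, 780, 1105, 260, 1235, 1625, 6500,
                  1105, 520, 325, 130, 0, 0], dtype=float)
    Kp = np.array([0.312, 0.682, 1.05, 0.92, 0.852, 0.906, 0.93, 0.87,
                   0.88, 1.0, 0.853, 0.915, 1.0, 1.0])
    iGUT, iKID, iLIV, iLNG, iSPL, iART, iVEN = 3, 5, 6, 7, 11, 12, 13

    A = np.zeros((14, 14))
    for i in range(12):  # perfused tissues, arterial inflow
        A[i, iART] += Q[i] / V[i]
        A[i, i] -= Q[i] / V[i] / Kp[i]
    # lung is fed by the venous pool instead
    A[iLNG, iART] = 0.0
    A[iLNG, iVEN] = Q[iLNG] / V[iLNG]
    # liver inflow is the portal/arterial mix
    q_ha = Q[iLIV] - Q[iGUT] - Q[iSPL]
    A[iLIV, iART] = q_ha / V[iLIV]
    A[iLIV, iGUT] = Q[iGUT] / V[iLIV] / Kp[iGUT]
    A[iLIV, iSPL] = Q[iSPL] / V[iLIV] / Kp[iSPL]
    # blood pools
    A[iART, iLNG] = Q[iLNG] / V[iART] / Kp[iLNG]
    A[iART, iART] = -Q[iLNG] / V[iART]
    for i in list(range(12)):
        if i in (iGUT, iSPL, iLNG):
            continue
        A[iVEN, i] = Q[i] / V[iVEN] / Kp[i]
    A[iVEN, iVEN] = -Q[iLNG] / V[iVEN]
    # renal extraction of arterial drug inside the kidney
    E = 0.02
    A[iKID, iART] -= E * Q[iKID] / V[iKID]

    vmax = np.array([0.97, 0.011, 0.035]) * 70.0 / 60.0  # mmol/min
    km = np.array([6.89, 0.097, 0.28])
    v_liv_l = V[iLIV] / 1000.0
    k_gen = 0.0026

    def rhs(y):
        c = y[:14]
        d = np.empty_like(y)
        d[:14] = A @ c
        c_drv = max(c[iLIV] / Kp[iLIV], 0.0)
        rates = vmax * c_drv / (km + c_drv)
        d[iLIV] -= rates.sum() / v_liv_l
        v_ox = rates[2]
        d[14] = k_gen * (gsh_n - y[14]) - v_ox / v_liv_l  # GSH, QSS NAPQI
        renal = E * Q[iKID] / 1000.0 * max(c[iART], 0.0)
        d[15:19] = (rates[0], rates[1], v_ox, renal)
        d[19] = v_ox  # conjugation equals oxidation under QSS
        return d

    dt = 1e-3
    n_steps = int(round(t_end / dt))
    y = np.zeros(20)
    y[14] = gsh_n
    y[iGUT] = dose_mmol / (V[iGUT] / 1000.0)
    sample_every = int(round(10.0 / dt))  # store every 10 min
    ref_rows = [y.copy()]
    for step in range(1, n_steps + 1):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if step % sample_every == 0:
            ref_rows.append(y.copy())
    ref = np.array(ref_rows)
    t_ref = np.arange(0.0, t_end + 1.0, 10.0)

    res = simulate(Regimen.single(1.0, route="oral"), t_end, qss_napqi=True)
    idx = np.searchsorted(res.time, t_ref)
    assert np.allclose(res.time[idx], t_ref)
    got = np.column_stack([res.conc[idx], res.gsh[idx], res.cum[idx]])

    scale = np.maximum(np.abs(ref), 1e-3 * np.abs(ref).max(axis=0, keepdims=True))
    scale = np.maximum(scale, 1e-12)
    return float(np.max(np.abs(got - ref) / scale))
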