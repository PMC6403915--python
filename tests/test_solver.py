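"""Method-of-lines film solver: RHS consistency, conservation, convergence."""

import numpy as np
import pytest

from polyscission import (FieldState, GridSpec, ModelParams, assemble_rhs,
                          init_uniform, integrate, reaction_sources,
                          simulate_well_mixed, time_to_fraction)
from polyscission.solver import IntegrationFailureError, SECONDS_PER_DAY


def test_grid_geometry():
    g = GridSpec(half_thickness=27.5e-4, n_nodes=51)
    assert g.dx == pytest.approx(27.5e-4 / 50)
    assert g.x[0] == 0.0 and g.x[-1] == pytest.approx(27.5e-4)
    # half-width end cells make the volume sum the exact trapezoid rule
    assert g.cell_volumes.sum() == pytest.approx(27.5e-4)


@pytest.mark.parametrize("n_nodes", [0, 2])
def test_invalid_grid(n_nodes):
    with pytest.raises(ValueError):
        GridSpec(n_nodes=n_nodes)


def test_uniform_state_no_reaction_is_stationary(params):
    p = ModelParams(kd=0.0, Mn_ref=params.Mn_ref)
    grid = GridSpec(n_nodes=11)
    st = init_uniform(2e5, 1.5, p, n_nodes=11, water=0.02)
    rhs = assemble_rhs(st, p, grid, sealed=True)
    assert np.allclose(rhs.to_vector(), 0.0, atol=1e-30)


def test_dry_sealed_film_is_stationary(params):
    # hydrolysis needs water: CW = 0 everywhere, sealed boundaries
    grid = GridSpec(n_nodes=11)
    st = init_uniform(2e5, 1.5, params, n_nodes=11, water=0.0)
    rhs = assemble_rhs(st, params, grid, sealed=True)
    assert np.allclose(rhs.to_vector(), 0.0, atol=1e-30)


def test_single_node_rhs_equals_reaction_sources(params):
    st = init_uniform(1e5, 1.7, params, n_nodes=1, water=0.0555)
    rhs = assemble_rhs(st, params, GridSpec(n_nodes=1))
    src = reaction_sources(st, params)
    for a, b in [(rhs.CW, src.CW), (rhs.CM, src.CM), (rhs.Colig, src.Colig),
                 (rhs.mu0, src.mu0), (rhs.mu1, src.mu1), (rhs.mu2, src.mu2)]:
        np.testing.assert_array_equal(a, b)


def test_no_degradation_keeps_mn_constant():
    p = ModelParams(kd=0.0, Mn_ref=406_000.0)
    t_eval = np.linspace(0, 1e7, 6)
    traj = simulate_well_mixed(406_000.0, 1.6, p, t_eval)
    np.testing.assert_allclose(traj.device_Mn, 406_000.0, rtol=1e-9)


def test_well_mixed_matches_logistic_closed_form(params):
    # with water pinned, the chain balance is logistic:
    # mu0(t) = mu1 / (1 + (mu1/mu0(0) - 1) exp(-lambda t)),
    # lambda = kd * CW * mu1 — an independent closed-form oracle
    cw = 0.0555
    mu1 = params.rho_pol / params.Mmon
    mu00 = params.rho_pol / 406_000.0
    lam = params.kd * cw * mu1
    t_eval = np.linspace(0, 2.5e7, 9)
    traj = simulate_well_mixed(406_000.0, 1.6, params, t_eval, fixed_cw=cw)
    mu0_exact = mu1 / (1.0 + (mu1 / mu00 - 1.0) * np.exp(-lam * t_eval))
    mn_exact = mu1 / mu0_exact * params.Mmon
    np.testing.assert_allclose(traj.device_Mn, mn_exact, rtol=1e-6)


def test_sealed_film_conserves_repeating_units(params):
    # nonuniform water -> nonuniform degradation -> real fluxes; the
    # domain integral of mu1 must still be constant (no mu1 source)
    grid = GridSpec(n_nodes=31)
    init = init_uniform(406_000.0, 1.6, params, n_nodes=31)
    init.CW[:] = 0.0555 * (grid.x / grid.half_thickness) ** 2
    t_half = time_to_fraction(406_000.0, 1.6, params, 0.5, fixed_cw=0.0555)
    traj = integrate(init, params, grid, np.linspace(0, 3 * t_half, 7),
                     sealed=True)
    drift = np.max(np.abs(traj.mu1_integral - traj.mu1_integral[0]))
    assert drift / traj.mu1_integral[0] < 1e-3
    assert traj.device_Mn[-1] < 0.55 * traj.device_Mn[0]


def test_open_film_grid_convergence(params):
    # device Mn at 51 and 101 nodes agree within 1% at all output times
    t_half = time_to_fraction(406_000.0, 1.6, params, 0.5, fixed_cw=0.0555)
    t_eval = np.linspace(0, t_half, 6)
    curves = {}
    for n in (51, 101):
        init = init_uniform(406_000.0, 1.6, params, n_nodes=n)
        curves[n] = integrate(init, params, GridSpec(n_nodes=n),
                              t_eval).device_Mn
    assert np.max(np.abs(curves[51] - curves[101]) / curves[101]) < 0.01


def test_open_film_mn_monotone_and_pd_valid(params):
    t_half = time_to_fraction(406_000.0, 1.6, params, 0.5, fixed_cw=0.0555)
    init = init_uniform(406_000.0, 1.6, params, n_nodes=31)
    traj = integrate(init, params, GridSpec(n_nodes=31),
                     np.linspace(0, t_half, 8))
    assert np.all(np.diff(traj.device_Mn) <= 0)  # sink-type boundaries
    assert np.all(traj.device_PD >= 1 - 1e-6)
    for st in traj.states:  # nodewise polydispersity too
        ok = (st.mu0 > 0) & (st.mu1 > 0)
        pd_nodes = st.mu2[ok] * st.mu0[ok] / st.mu1[ok] ** 2
        assert np.all(pd_nodes >= 1 - 1e-6)


def test_trajectory_export_units(params, tmp_path):
    t_eval = np.array([0.0, SECONDS_PER_DAY, 2 * SECONDS_PER_DAY])
    traj = simulate_well_mixed(1e5, 1.6, params, t_eval, fixed_cw=0.0555)
    df = traj.to_dataframe()
    assert list(df.columns) == ["time_days", "Mn_g_mol", "Mw_g_mol", "PD"]
    np.testing.assert_allclose(df["time_days"], [0, 1, 2])
    out = tmp_path / "traj.csv"
    traj.to_csv(out)
    assert out.read_text().startswith("time_days,")


def test_bad_t_eval_rejected(params):
    st = init_uniform(1e5, 1.6, params, n_nodes=1)
    with pytest.raises(ValueError):
        integrate(st, params, GridSpec(n_nodes=1), [1.0, 2.0])
    with pytest.raises(ValueError):
        integrate(st, params, GridSpec(n_nodes=1), [0.0, 2.0, 1.0])


def test_time_to_fraction_brackets_the_half_life(params):
    t_half = time_to_fraction(406_000.0, 1.6, params, 0.5, fixed_cw=0.0555)
    traj = simulate_well_mixed(406_000.0, 1.6, params,
                               np.array([0.0, t_half]), fixed_cw=0.0555)
    assert traj.device_Mn[-1] == pytest.approx(203_000.0, rel=1e-4)
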