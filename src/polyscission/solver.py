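"""Spatial discretization and stiff time integration of the film model.

The film is modelled over its half-thickness with symmetry at the centre
(x = 0) and the bathing medium at the surface (x = L): Dirichlet water at
``CW_surface`` and a perfect sink (zero concentration) for monomer and
the mobile oligomers.  The moments need no independent boundary
conditions: their transport is by definition the j^0-, j^1- and
j^2-weighted sum of the mobile species' flux divergences.

Discretization is node-centred conservative finite volumes on a uniform
grid (equivalent to centred finite differences in flux form): face
diffusivity is the arithmetic mean of the adjacent nodal values, end
cells have half width, so the conserved discrete integral is exactly the
trapezoidal rule.  The resulting ODE system (method of lines) is stiff
and integrated with an implicit solver.

A single-node grid gives the "well-mixed" model (no transport), used for
parameter fitting and oracle comparisons; ``fixed_cw`` optionally pins
the water concentration there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .kinetics import (FieldState, ModelParams, MomentTriple,
                       N_OLIGOMERS, OLIGOMER_LENGTHS, averages,
                       effective_diffusivity, reaction_sources)
from .state import init_uniform

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0

__all__ = ["GridSpec", "Trajectory", "IntegrationFailureError",
           "assemble_rhs", "integrate", "simulate_well_mixed",
           "time_to_fraction", "SECONDS_PER_DAY"]


class IntegrationFailureError(RuntimeError):
    """Stiff integrator failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:.6g} s)")
        self.last_time = last_time


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid over the film half-thickness.

    ``half_thickness`` in cm (default 27.5e-4, half of a 55 um film);
    nodes run from the film centre (x = 0) to the surface (x = L).
    ``n_nodes = 1`` selects the well-mixed (transport-free) model;
    otherwise at least 3 nodes are required.
    """

    half_thickness: float = 27.5e-4
    n_nodes: int = 51

    def __post_init__(self) -> None:
        if self.half_thickness <= 0:
            raise ValueError(
                f"half_thickness must be > 0, got {self.half_thickness}")
        if self.n_nodes != 1 and self.n_nodes < 3:
            raise ValueError(
                f"n_nodes must be 1 (well-mixed) or >= 3, got {self.n_nodes}")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.half_thickness, self.n_nodes)

    @property
    def dx(self) -> float:
        if self.n_nodes == 1:
            return self.half_thickness
        return self.half_thickness / (self.n_nodes - 1)

    @property
    def cell_volumes(self) -> np.ndarray:
        """Per-node control-volume widths (trapezoidal weights), cm."""
        if self.n_nodes == 1:
            return np.array([self.half_thickness])
        v = np.full(self.n_nodes, self.dx)
        v[0] = v[-1] = self.dx / 2.0
        return v


@dataclass
class Trajectory:
    """Time course of the field state and the device-level averages.

    ``device_Mn``/``device_Mw``/``device_PD`` apply the moments-to-
    averages map to the trapezoidal domain integrals of the moments; for
    a thin film this is what a GPC measurement of the whole specimen
    sees.  ``mu1_integral`` (repeating units per unit area, mol cm^-2) is
    conserved by sealed runs, a primary correctness check.
    """

    times: np.ndarray
    states: list
    device_Mn: np.ndarray
    device_Mw: np.ndarray
    device_PD: np.ndarray
    mu1_integral: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def times_days(self) -> np.ndarray:
        return self.times / SECONDS_PER_DAY

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_days": self.times_days,
            "Mn_g_mol": self.device_Mn,
            "Mw_g_mol": self.device_Mw,
            "PD": self.device_PD,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _diffusivities(state: FieldState, params: ModelParams):
    """Nodewise effective diffusivities (water, monomer, oligomer)."""
    ok = (state.mu0 > 0) & (state.mu1 > 0)
    mu0s = np.where(ok, state.mu0, 1.0)
    # empty/degenerate nodes carry no enhancement information: use Mn_ref
    Mn_local = np.where(ok, state.mu1 / mu0s * params.Mmon, params.Mn_ref)
    DW = effective_diffusivity(params.DW0, Mn_local, params.Mn_ref)
    DM = effective_diffusivity(params.DM0, Mn_local, params.Mn_ref)
    Dolig = effective_diffusivity(params.Dolig0, Mn_local, params.Mn_ref)
    return np.atleast_1d(DW), np.atleast_1d(DM), np.atleast_1d(Dolig)


def _div_term(C: np.ndarray, D: np.ndarray, grid: GridSpec,
              surface_bc: float | None) -> np.ndarray:
    """Flux divergence div(D grad C) for one species, mol cm^-3 s^-1.

    Zero flux at the centre face; at the surface face either zero flux
    (``surface_bc is None``, sealed) or a Dirichlet value applied at the
    boundary over the half-cell distance dx/2.
    """
    dx = grid.dx
    flux = np.zeros(grid.n_nodes + 1)  # flux[i] at face left of node i
    flux[1:-1] = -0.5 * (D[:-1] + D[1:]) * np.diff(C) / dx
    if surface_bc is not None:
        flux[-1] = -D[-1] * (surface_bc - C[-1]) / (dx / 2.0)
    return -(flux[1:] - flux[:-1]) / grid.cell_volumes


def assemble_rhs(state: FieldState, params: ModelParams, grid: GridSpec,
                 sealed: bool = False,
                 fixed_cw: float | None = None) -> FieldState:
    """Time derivative of the full state: transport plus reaction.

    ``sealed`` imposes zero flux on every species at both faces (the
    default film setup has Dirichlet water/sink-oligomer surface
    conditions).  ``fixed_cw`` freezes the water field (its derivative is
    zero), for well-mixed fitting runs with abundant water.
    """
    src = reaction_sources(state, params)

    if grid.n_nodes == 1:
        dCW = np.zeros(1) if fixed_cw is not None else src.CW
        return FieldState(CW=dCW, CM=src.CM, Colig=src.Colig,
                          mu0=src.mu0, mu1=src.mu1, mu2=src.mu2)

    DW, DM, Dolig = _diffusivities(state, params)
    bc_w = None if sealed else params.CW_surface
    bc_sink = None if sealed else 0.0

    div_W = _div_term(state.CW, DW, grid, bc_w)
    div_M = _div_term(state.CM, DM, grid, bc_sink)
    div_olig = np.stack([
        _div_term(state.Colig[k], Dolig, grid, bc_sink)
        for k in range(N_OLIGOMERS)
    ])

    # moment transport: j^p-weighted sums of the mobile species' divergences
    j = OLIGOMER_LENGTHS.astype(float)
    tr_mu0 = div_M + div_olig.sum(axis=0)
    tr_mu1 = div_M + (j[:, None] * div_olig).sum(axis=0)
    tr_mu2 = div_M + (j[:, None] ** 2 * div_olig).sum(axis=0)

    dCW = np.zeros_like(div_W) if fixed_cw is not None else div_W + src.CW
    return FieldState(
        CW=dCW,
        CM=div_M + src.CM,
        Colig=div_olig + src.Colig,
        mu0=tr_mu0 + src.mu0,
        mu1=tr_mu1 + src.mu1,
        mu2=tr_mu2 + src.mu2,
    )


def _atol_vector(init: FieldState, params: ModelParams,
                 atol_scale: float) -> np.ndarray:
    """Per-field absolute tolerances scaled to the initial magnitudes."""
    mu1_scale = max(float(init.mu1.max()), 1e-30)
    mu2_scale = max(float(init.mu2.max()), mu1_scale)
    cw_scale = max(float(init.CW.max()), params.CW_surface)
    n = init.n_nodes
    scales = ([cw_scale] + [mu1_scale] * (1 + N_OLIGOMERS)
              + [mu1_scale, mu1_scale, mu2_scale])
    return np.repeat(np.array(scales) * atol_scale, n)


def _jac_sparsity(n_nodes: int) -> sparse.spmatrix:
    """Block-tridiagonal sparsity: all fields couple at adjacent nodes."""
    T = sparse.diags([np.ones(n_nodes - 1), np.ones(n_nodes),
                      np.ones(n_nodes - 1)], offsets=(-1, 0, 1))
    F = np.ones((FieldState.N_FIELDS, FieldState.N_FIELDS))
    return sparse.kron(F, T, format="csr")


def integrate(init: FieldState, params: ModelParams, grid: GridSpec,
              t_eval, sealed: bool = False, fixed_cw: float | None = None,
              method: str = "BDF", rtol: float = 1e-6,
              atol_scale: float = 1e-9) -> Trajectory:
    """Integrate the model and report device-level averages over time.

    ``t_eval`` are output times in seconds, starting at 0.  Negative
    concentrations below the absolute tolerance are clipped to zero and
    logged; integrator failure raises :class:`IntegrationFailureError`
    carrying the last good time.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size < 1 or t_eval[0] != 0.0:
        raise ValueError("t_eval must start at 0")
    if t_eval.size > 1 and np.any(np.diff(t_eval) <= 0):
        raise ValueError("t_eval must be strictly increasing")
    if init.n_nodes != grid.n_nodes:
        raise ValueError(
            f"state has {init.n_nodes} nodes but grid has {grid.n_nodes}")

    init = init.copy()
    if fixed_cw is not None:
        init.CW[:] = fixed_cw

    n = grid.n_nodes
    atol = _atol_vector(init, params, atol_scale)

    def rhs(t, y):
        st = FieldState.from_vector(y, n)
        return assemble_rhs(st, params, grid, sealed=sealed,
                            fixed_cw=fixed_cw).to_vector()

    kwargs = {}
    if n > 1 and method in ("BDF", "Radau"):
        kwargs["jac_sparsity"] = _jac_sparsity(n)

    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), init.to_vector(),
                    method=method, t_eval=t_eval, rtol=rtol, atol=atol,
                    **kwargs)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationFailureError(
            f"stiff integration failed: {sol.message}", last)

    states, Mn, Mw, PD, mu1_int = [], [], [], [], []
    vols = grid.cell_volumes
    n_clipped = 0
    for k in range(sol.t.size):
        st = FieldState.from_vector(sol.y[:, k], n)
        for arr in (st.CW, st.CM, st.Colig, st.mu0, st.mu1, st.mu2):
            neg = arr < 0
            if neg.any():
                n_clipped += int((arr < -atol.max()).sum())
                arr[neg] = 0.0
        I0 = float(np.sum(st.mu0 * vols))
        I1 = float(np.sum(st.mu1 * vols))
        I2 = float(np.sum(st.mu2 * vols))
        mn, mw, pd_ = averages(MomentTriple(I0, I1, I2), params.Mmon)
        states.append(st)
        Mn.append(mn)
        Mw.append(mw)
        PD.append(pd_)
        mu1_int.append(I1)
    if n_clipped:
        logger.warning("clipped %d negative concentrations below -atol",
                       n_clipped)

    return Trajectory(
        times=sol.t.copy(), states=states,
        device_Mn=np.array(Mn), device_Mw=np.array(Mw),
        device_PD=np.array(PD), mu1_integral=np.array(mu1_int),
        diagnostics={"success": True, "message": sol.message,
                     "n_clipped": n_clipped, "nfev": sol.nfev,
                     "sealed": sealed, "fixed_cw": fixed_cw,
                     "method": method, "rtol": rtol},
    )


def simulate_well_mixed(Mn0: float, PD0: float, params: ModelParams,
                        t_eval, fixed_cw: float | None = None,
                        rtol: float = 1e-8) -> Trajectory:
    """Forward well-mixed run from a (Mn0, PD0) uniform start.

    ``fixed_cw`` (typically ``params.CW_surface``) pins the water
    concentration, modelling a fully hydrated specimen; otherwise the
    state starts pre-saturated at ``CW_surface`` and water is consumed by
    hydrolysis.
    """
    grid = GridSpec(n_nodes=1)
    water = fixed_cw if fixed_cw is not None else params.CW_surface
    init = init_uniform(Mn0, PD0, params, n_nodes=1, water=water)
    return integrate(init, params, grid, t_eval, fixed_cw=fixed_cw,
                     method="LSODA", rtol=rtol)


def time_to_fraction(Mn0: float, PD0: float, params: ModelParams,
                     fraction: float, fixed_cw: float | None = None,
                     rtol: float = 1e-8) -> float:
    """Time (s) for well-mixed device Mn to fall to ``fraction * Mn0``.

    Uses an integrator event on the molecular weight; the search horizon
    comes from the early-time growth rate of the chain concentration,
    lambda ~ kd * CW * mu1.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if params.kd <= 0:
        raise ValueError("kd must be > 0 to reach a molecular-weight drop")
    cw = fixed_cw if fixed_cw is not None else params.CW_surface
    mu1 = params.rho_pol / params.Mmon
    lam = params.kd * cw * mu1
    t_max = 20.0 * np.log(1.0 / fraction) / lam

    water = fixed_cw if fixed_cw is not None else params.CW_surface
    init = init_uniform(Mn0, PD0, params, n_nodes=1, water=water)
    grid = GridSpec(n_nodes=1)
    target = fraction * Mn0

    def hit(t, y):
        st = FieldState.from_vector(y, 1)
        return float(st.mu1[0] / st.mu0[0] * params.Mmon - target)

    hit.terminal = True
    hit.direction = -1

    def rhs(t, y):
        st = FieldState.from_vector(y, 1)
        return assemble_rhs(st, params, grid,
                            fixed_cw=fixed_cw).to_vector()

    sol = solve_ivp(rhs, (0.0, t_max), init.to_vector(), method="LSODA",
                    rtol=rtol, atol=_atol_vector(init, params, 1e-9),
                    events=hit)
    if not sol.success or not sol.t_events[0].size:
        raise IntegrationFailureError(
            f"molecular weight did not reach {fraction:.3g} of Mn0 "
            f"within the search horizon", float(sol.t[-1]))
    return float(sol.t_events[0][0])
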