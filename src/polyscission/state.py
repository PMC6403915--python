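"""Construction of initial states from macroscopic polymer specifications.

A uniform film of a polymer with number-average molecular weight ``Mn0``,
polydispersity ``PD0`` and density ``rho_pol`` fixes the three moments at
every node by inverting the moments-to-averages map:

    mu1 = rho_pol / Mmon        (repeating-unit concentration)
    mu0 = rho_pol / Mn0         (chain concentration)
    mu2 = PD0 * mu1**2 / mu0

The film starts dry (zero interior water unless requested) with zero
monomer and oligomer content: for high-molecular-weight polymer the true
initial oligomer mass fraction is negligible against mu0 ~ 3e-6 mol cm^-3.
"""

from __future__ import annotations

import numpy as np

from .kinetics import FieldState, ModelParams, N_OLIGOMERS


class InvalidSpecificationError(ValueError):
    """The macroscopic polymer specification is physically inadmissible."""


def init_uniform(Mn0: float, PD0: float, params: ModelParams,
                 n_nodes: int = 1, water: float = 0.0) -> FieldState:
    """Uniform initial state for a film of the given polymer.

    Parameters
    ----------
    Mn0 : float
        Initial number-average molecular weight, g mol^-1; must be >= the
        repeating-unit molar mass.
    PD0 : float
        Initial polydispersity Mw/Mn; must be >= 1.
    params : ModelParams
        Supplies Mmon and rho_pol.
    n_nodes : int
        Number of grid nodes (1 for the well-mixed model).
    water : float
        Interior water concentration, mol cm^-3 (0 = dry polymer;
        set to params.CW_surface for a pre-saturated start).

    Round trip: ``averages(init_uniform(Mn0, PD0, p).moments, p.Mmon)``
    returns ``(Mn0, PD0*Mn0, PD0)`` to machine precision.
    """
    if not PD0 >= 1.0:
        raise InvalidSpecificationError(f"PD0 must be >= 1, got {PD0}")
    if not Mn0 >= params.Mmon:
        raise InvalidSpecificationError(
            f"Mn0 ({Mn0}) must be >= Mmon ({params.Mmon})")
    if water < 0:
        raise InvalidSpecificationError(f"water must be >= 0, got {water}")

    mu1 = params.rho_pol / params.Mmon
    mu0 = params.rho_pol / Mn0
    mu2 = PD0 * mu1 ** 2 / mu0
    ones = np.ones(n_nodes)
    return FieldState(
        CW=water * ones,
        CM=np.zeros(n_nodes),
        Colig=np.zeros((N_OLIGOMERS, n_nodes)),
        mu0=mu0 * ones,
        mu1=mu1 * ones,
        mu2=mu2 * ones,
    )
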