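"""Reaction kinetics of autocatalytic hydrolytic chain scission.

The polymer chain-length distribution is summarised by its first three
statistical moments

    mu_j = sum_n n^j * C_n      (j = 0, 1, 2),

where ``C_n`` is the molar concentration of chains with ``n`` repeating
units.  mu0 is the chain (carboxylic end-group) concentration, mu1 the
repeating-unit concentration and mu2 the squared-length-weighted
concentration.  Hydrolysis of an ester bond at a uniformly random position
is autocatalysed by chain ends, giving third-order kinetics: every rate
carries the factor ``kd * CW * mu0``.

This module holds the parameter/state containers and the *local* physics —
reaction source terms, the degradation-enhanced diffusivity law and the
moments-to-averages map.  Spatial transport lives in :mod:`.solver`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "MomentTriple",
    "FieldState",
    "SourceTerms",
    "N_OLIGOMERS",
    "OLIGOMER_LENGTHS",
    "effective_diffusivity",
    "reaction_sources",
    "averages",
]

#: Diffusible oligomer lengths tracked explicitly (dimer .. nonamer).
#: Chains longer than 9 units are assumed immobile in the polymer matrix.
OLIGOMER_LENGTHS = np.arange(2, 10)
N_OLIGOMERS = len(OLIGOMER_LENGTHS)  # 8


class InvalidParameterError(ValueError):
    """A physical parameter violates its admissible range."""


class UndefinedAveragesError(ZeroDivisionError):
    """Average molecular weights are undefined (no chains present)."""


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the degradation model.

    Parameters
    ----------
    kd : float
        Degradation kinetic constant, cm^6 mol^-2 s^-1.  Third order:
        rate = kd * CW * (...) * mu0.
    DM0, Dolig0, DW0 : float
        Pristine (undegraded-matrix) diffusivities of monomer, oligomers
        and water, cm^2 s^-1.
    Mmon : float
        Molar mass of the repeating unit, g mol^-1 (90.08 for lactic acid).
    rho_pol : float
        Polymer density, g cm^-3.
    CW_surface : float
        Water concentration imposed at the film surface, mol cm^-3.
        Default 0.0555 is the molar concentration of pure water.
    Mn_ref : float
        Number-average molecular weight before degradation onset,
        g mol^-1; the normalisation of the diffusivity enhancement law.
    """

    kd: float = 0.0
    DM0: float = 1e-10
    Dolig0: float = 1e-10
    DW0: float = 1e-8
    Mmon: float = 90.08
    rho_pol: float = 1.2
    CW_surface: float = 0.0555
    Mn_ref: float = 406_000.0

    def __post_init__(self) -> None:
        if self.kd < 0:
            raise InvalidParameterError(f"kd must be >= 0, got {self.kd}")
        for name in ("DM0", "Dolig0", "DW0", "Mmon", "rho_pol",
                     "CW_surface", "Mn_ref"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value}")
        if self.Mn_ref < self.Mmon:
            raise InvalidParameterError(
                f"Mn_ref ({self.Mn_ref}) must be >= Mmon ({self.Mmon})")


class MomentTriple(NamedTuple):
    """First three statistical moments of the chain-length distribution.

    All entries are concentrations in mol cm^-3; each may be a scalar or a
    per-node array.  Valid triples satisfy mu1 >= mu0 (chain length >= 1)
    and mu2*mu0 >= mu1^2 (Cauchy–Schwarz, i.e. polydispersity >= 1).
    """

    mu0: np.ndarray | float
    mu1: np.ndarray | float
    mu2: np.ndarray | float


@dataclass
class FieldState:
    """Concentration fields of the full model state.

    Every attribute is an array over grid nodes (length ``n_nodes``;
    scalars are fine for a single well-mixed node wrapped as 1-element
    arrays).  Units mol cm^-3.

    Attributes
    ----------
    CW : water concentration.
    CM : monomer concentration.  Monomer is counted inside the moments
        (mu0 includes n = 1), hence CM <= mu0 for valid states.
    Colig : shape ``(8, n_nodes)``; rows are dimer..nonamer (n = 2..9).
    mu0, mu1, mu2 : statistical moments of the chain-length distribution.
    """

    CW: np.ndarray
    CM: np.ndarray
    Colig: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray

    def __post_init__(self) -> None:
        self.CW = np.atleast_1d(np.asarray(self.CW, dtype=float))
        self.CM = np.atleast_1d(np.asarray(self.CM, dtype=float))
        self.Colig = np.atleast_2d(np.asarray(self.Colig, dtype=float))
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        self.mu1 = np.atleast_1d(np.asarray(self.mu1, dtype=float))
        self.mu2 = np.atleast_1d(np.asarray(self.mu2, dtype=float))
        if self.Colig.shape != (N_OLIGOMERS, self.CW.size):
            raise ValueError(
                f"Colig must have shape ({N_OLIGOMERS}, {self.CW.size}), "
                f"got {self.Colig.shape}")

    @property
    def n_nodes(self) -> int:
        return self.CW.size

    @property
    def moments(self) -> MomentTriple:
        return MomentTriple(self.mu0, self.mu1, self.mu2)

    # -- flat-vector packing used by the ODE integrator -----------------
    # Layout (field-major): CW | CM | C2..C9 | mu0 | mu1 | mu2,
    # each block of length n_nodes.  13 fields total.

    N_FIELDS = 3 + N_OLIGOMERS + 2  # CW, CM, 8 oligomers, mu0, mu1, mu2

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.CW, self.CM, self.Colig.reshape(-1),
            self.mu0, self.mu1, self.mu2,
        ])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_nodes: int) -> "FieldState":
        vec = np.asarray(vec, dtype=float)
        if vec.size != cls.N_FIELDS * n_nodes:
            raise ValueError(
                f"vector length {vec.size} != {cls.N_FIELDS} * {n_nodes}")
        blocks = vec.reshape(cls.N_FIELDS, n_nodes)
        return cls(
            CW=blocks[0].copy(),
            CM=blocks[1].copy(),
            Colig=blocks[2:2 + N_OLIGOMERS].copy(),
            mu0=blocks[2 + N_OLIGOMERS].copy(),
            mu1=blocks[3 + N_OLIGOMERS].copy(),
            mu2=blocks[4 + N_OLIGOMERS].copy(),
        )

    def copy(self) -> "FieldState":
        return FieldState(self.CW.copy(), self.CM.copy(), self.Colig.copy(),
                          self.mu0.copy(), self.mu1.copy(), self.mu2.copy())


@dataclass
class SourceTerms:
    """Reaction source terms, mol cm^-3 s^-1, same shapes as FieldState."""

    CW: np.ndarray
    CM: np.ndarray
    Colig: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray


def effective_diffusivity(D0, Mn_local, Mn_ref):
    """Degradation-enhanced diffusivity.

    Chain scission opens wider diffusive paths; the diffusivity of every
    mobile species grows from its pristine value ``D0`` as the local
    number-average molecular weight ``Mn_local`` falls below the initial
    value ``Mn_ref``::

        D = D0 * exp(2.5 * (1 - Mn_local/Mn_ref)**0.5)

    The ratio Mn_local/Mn_ref is clamped to [0, 1] (transient overshoots
    above the initial molecular weight carry no physical enhancement), so
    the result is bounded in [D0, D0*e^2.5].

    Accepts scalars or arrays; broadcasts.
    """
    D0 = np.asarray(D0, dtype=float)
    Mn_ref_arr = np.asarray(Mn_ref, dtype=float)
    if np.any(D0 <= 0):
        raise InvalidParameterError("pristine diffusivity D0 must be > 0")
    if np.any(Mn_ref_arr <= 0):
        raise InvalidParameterError("Mn_ref must be > 0")
    ratio = np.clip(np.asarray(Mn_local, dtype=float) / Mn_ref_arr, 0.0, 1.0)
    out = D0 * np.exp(2.5 * np.sqrt(1.0 - ratio))
    return out if out.ndim else float(out)


def reaction_sources(state: FieldState, params: ModelParams) -> SourceTerms:
    """Hydrolysis source terms at each node (no transport).

    Random scission of a chain with n units proceeds at rate
    ``(n-1) * kd * CW * Cn * mu0`` (one event per bond, autocatalysed by
    chain ends) and produces each shorter length with multiplicity 2.
    Summed over the distribution this gives, with r = kd*CW*mu0:

    ==========  =====================================================
    species     source
    ==========  =====================================================
    monomer     ``+2 r (mu0 - CM)``
    water       ``-r (mu1 - mu0)``           (one water per scission)
    n-mer       ``+2 r (mu0 - sum_{j<=n} Cj) - (n-1) r Cn``
    mu0         ``+r (mu1 - mu0)``           (one new chain per scission)
    mu1         ``0``                        (repeating units conserved)
    mu2         ``+(r/3) (mu1 - 2 mu2^2/mu1 + mu2 mu1/mu0)``
    ==========  =====================================================

    The mu2 balance is closed with mu3 ~ 2 mu2^2/mu1 - mu2*mu1/mu0, which
    is exact for monodisperse states.  Nodes with mu0 = 0 or mu1 = 0
    (empty or fully degraded) get a zero mu2 source rather than an error.
    All rates are exactly linear in both kd and CW.
    """
    r = params.kd * state.CW * state.mu0  # common autocatalytic factor
    src_M = 2.0 * r * (state.mu0 - state.CM)
    src_W = -r * (state.mu1 - state.mu0)
    src_mu0 = r * (state.mu1 - state.mu0)
    src_mu1 = np.zeros_like(state.mu1)

    # cumulative sum_{j<=n} Cj including the monomer
    cum = state.CM + np.cumsum(state.Colig, axis=0)
    n_arr = OLIGOMER_LENGTHS[:, None].astype(float)
    src_olig = 2.0 * r * (state.mu0 - cum) - (n_arr - 1.0) * r * state.Colig

    ok = (state.mu0 > 0) & (state.mu1 > 0)
    mu0s = np.where(ok, state.mu0, 1.0)
    mu1s = np.where(ok, state.mu1, 1.0)
    bracket = (state.mu1 - 2.0 * state.mu2 ** 2 / mu1s
               + state.mu2 * state.mu1 / mu0s)
    src_mu2 = np.where(ok, (r / 3.0) * bracket, 0.0)

    return SourceTerms(CW=src_W, CM=src_M, Colig=src_olig,
                       mu0=src_mu0, mu1=src_mu1, mu2=src_mu2)


def averages(m: MomentTriple, Mmon: float):
    """Average molecular weights and polydispersity from the moments.

    Mn = (mu1/mu0) * Mmon,  Mw = (mu2/mu1) * Mmon,  PD = mu2*mu0/mu1^2.

    The identity ``Mw = PD * Mn`` holds exactly.  Raises
    :class:`UndefinedAveragesError` on mu0 <= 0 or mu1 <= 0.
    """
    mu0 = np.asarray(m.mu0, dtype=float)
    mu1 = np.asarray(m.mu1, dtype=float)
    mu2 = np.asarray(m.mu2, dtype=float)
    if np.any(mu0 <= 0) or np.any(mu1 <= 0):
        raise UndefinedAveragesError(
            "average molecular weights undefined: mu0 and mu1 must be > 0")
    Mn = mu1 / mu0 * Mmon
    Mw = mu2 / mu1 * Mmon
    PD = mu2 * mu0 / mu1 ** 2
    if Mn.ndim == 0:
        return float(Mn), float(Mw), float(PD)
    return Mn, Mw, PD
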