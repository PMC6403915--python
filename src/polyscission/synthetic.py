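"""Synthetic degradation datasets with the structure the fitting assumes.

The literature decay curves the reference constants were fitted to are
not tabulated, so studies here run on synthetic stand-ins: the well-mixed
forward model evaluated at the published initial conditions, with
multiplicative lognormal measurement noise.  GPC molecular-weight
determinations carry a roughly constant *relative* error, hence
lognormal factors at a default 3% coefficient of variation.  Per-dose
time horizons are chosen so every curve shows a comparable fractional
decline (to ~40% of the initial Mn by default), mirroring how such
degradation studies are designed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datasets import DegradationDataset, write_dataset
from .kinetics import ModelParams
from .reference import DOSE_TABLE, DoseCondition, dose_label
from .solver import SECONDS_PER_DAY, simulate_well_mixed, time_to_fraction

__all__ = ["generate_dataset", "default_times", "make_fixture_suite",
           "FIXTURE_SEEDS"]

#: Documented per-dose seeds for the bundled fixture suite.
FIXTURE_SEEDS = {"0 Mrad": 180, "5 Mrad": 185, "10 Mrad": 1810,
                 "20 Mrad": 1820}


def default_times(kd: float, Mn0: float, PD0: float,
                  params: ModelParams | None = None, n_points: int = 12,
                  decline_to: float = 0.4) -> np.ndarray:
    """Observation times (days) spanning decline of Mn to ``decline_to``.

    ``n_points`` points from 0 to just past the time at which the
    well-mixed model (water pinned at the surface concentration) reaches
    ``decline_to * Mn0``.
    """
    base = params if params is not None else ModelParams()
    p = ModelParams(kd=kd, DM0=base.DM0, Dolig0=base.Dolig0, DW0=base.DW0,
                    Mmon=base.Mmon, rho_pol=base.rho_pol,
                    CW_surface=base.CW_surface, Mn_ref=Mn0)
    t_end = time_to_fraction(Mn0, PD0, p, decline_to,
                             fixed_cw=p.CW_surface) * 1.02
    return np.linspace(0.0, t_end / SECONDS_PER_DAY, n_points)


def generate_dataset(kd: float, Mn0: float, PD0: float,
                     times_days=None, noise_cv: float = 0.03,
                     seed: int | None = None,
                     params: ModelParams | None = None,
                     label: str = "") -> DegradationDataset:
    """Forward-model Mn decay plus multiplicative measurement noise.

    Runs the well-mixed model (fixed water at the surface concentration)
    from (Mn0, PD0), then multiplies each Mn by an independent lognormal
    factor with unit mean and coefficient of variation ``noise_cv``.
    ``noise_cv=0`` returns the forward model exactly; a fixed seed makes
    the dataset bit-reproducible.  True parameters are attached as
    metadata.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    base = params if params is not None else ModelParams()
    p = ModelParams(kd=kd, DM0=base.DM0, Dolig0=base.Dolig0, DW0=base.DW0,
                    Mmon=base.Mmon, rho_pol=base.rho_pol,
                    CW_surface=base.CW_surface, Mn_ref=Mn0)
    if times_days is None:
        times_days = default_times(kd, Mn0, PD0, params=base)
    times_days = np.asarray(times_days, dtype=float)

    traj = simulate_well_mixed(Mn0, PD0, p, times_days * SECONDS_PER_DAY,
                               fixed_cw=p.CW_surface)
    mn = traj.device_Mn.copy()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        # unit-mean lognormal factors
        mn = mn * rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                                size=mn.size)
    return DegradationDataset(
        times_days=times_days, Mn=mn, dose_label=label,
        Mn0=Mn0, PD0=PD0,
        metadata={"kd_true": kd, "seed": seed, "noise_cv": noise_cv},
    )


def generate_for_dose(dose: float, seed: int | None = None,
                      noise_cv: float = 0.03,
                      params: ModelParams | None = None
                      ) -> DegradationDataset:
    """Dataset for one of the bundled reference doses (0/5/10/20 Mrad)."""
    label = dose_label(dose)
    if label not in DOSE_TABLE:
        raise KeyError(f"unknown dose {dose!r}; have "
                       f"{sorted(c.dose_mrad for c in DOSE_TABLE.values())}")
    cond: DoseCondition = DOSE_TABLE[label]
    if seed is None:
        seed = FIXTURE_SEEDS[label]
    return generate_dataset(cond.kd, cond.Mn0, cond.PD0, seed=seed,
                            noise_cv=noise_cv, params=params, label=label)


def make_fixture_suite(outdir, noise_cv: float = 0.03,
                       params: ModelParams | None = None) -> dict:
    """Write one CSV per reference dose; returns ``{label: path}``.

    Files ``dose0.csv`` .. ``dose20.csv`` each hold 12 points spanning
    decline to ~40% of the initial Mn, generated with the documented
    per-dose seeds, so the suite regenerates byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, cond in DOSE_TABLE.items():
        ds = generate_for_dose(cond.dose_mrad, noise_cv=noise_cv,
                               params=params)
        path = outdir / f"dose{cond.dose_mrad:g}.csv"
        write_dataset(ds, path)
        paths[label] = path
    return paths
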