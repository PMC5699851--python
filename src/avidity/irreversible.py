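"""Irreversibly linked bivalent ligand binding a two-site target.

The target population splits into four states: fully unbound, singly bound,
doubly bound by two different bivalents, and the 1:1 state in which a single
bivalent bridges both sites.  Writing ``F`` for the bridged fraction of
singly bound pairs (a function only of tether length and monomer K_D, see
:mod:`avidity.tether`), the 1:1 fraction at total site occupancy ``R`` is

    F_21 = R F / (1 - R (1 - F)),

and the EC50 (R = 1/2) obeys

    EC50 = K_D (1 - F) / (2 (1 + F)) + T0 / 2.

Relative to the monovalent single-site reference ``EC50_mm = K_D + T0/2``
the fold improvement is 2 at F = 0 (a pure statistical factor) and grows as
``4 sqrt(L_eff / K_D)`` once the effective concentration dwarfs K_D — the
origin of the 3/2-power scaling of the effective 1:1 dissociation constant
K_2 with the monomer K_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .monovalent import ec50_single_site
from .tether import (
    SPHERE_PREFACTOR,
    TetherGeometry,
    fraction_bridged,
    gated_effective_concentration,
)
from .units import check_nonnegative, check_positive

__all__ = [
    "IrreversibleBivalentState",
    "FoldImprovement",
    "f21_from_bridging",
    "ec50_irreversible",
    "fold_asymptotic",
    "k2_effective",
    "k2_asymptotic",
    "best_attainable_affinity",
    "dimer_dg_prediction",
    "tether_for_squared_scaling",
    "occupancy_curve_irreversible",
    "state_fractions_irreversible",
    "fig2_grid",
]


@dataclass(frozen=True)
class IrreversibleBivalentState:
    """Population fractions of the two-site target / bivalent system.

    ``f_2u + f_1u + f_22 + f_21 == 1``; ``r = f_21 + (1 - f_21) * f_t`` is
    the total fraction of sites occupied.  ``f_l`` is the exact bound-ligand
    fraction (near zero whenever ``T0 << L0``).
    """

    f_2u: float
    f_1u: float
    f_22: float
    f_21: float
    f_t: float
    f_t_dim: float
    r: float
    f_l: float = 0.0


@dataclass(frozen=True)
class FoldImprovement:
    """An EC50 together with its monovalent single-site reference."""

    ec50_model: float
    ec50_reference: float
    f_t_dim: float

    @property
    def fold(self) -> float:
        return self.ec50_reference / self.ec50_model


def f21_from_bridging(r: float, f_t_dim: float) -> float:
    """1:1-state target fraction from occupancy *r* and bridged fraction.

    ``F_21 = r F / (1 - r (1 - F))``; ranges from 0 (no bridging) to ``r``
    (every bound site is part of a bridged complex).
    """
    r = check_nonnegative("r", r)
    f = check_nonnegative("f_t_dim", f_t_dim)
    if r > 1.0 or f > 1.0:
        raise ValueError("r and f_t_dim must lie in [0, 1]")
    denom = 1.0 - r * (1.0 - f)
    if denom == 0.0:  # r == 1, f == 0: no 1:1 state exists
        return 0.0
    return r * f / denom


def ec50_irreversible(
    kd: float, geom: TetherGeometry, T0: float = 0.0
) -> FoldImprovement:
    """EC50 and fold improvement of the bivalent on a two-site target.

    At half occupancy the governing relation is linear in the ligand
    concentration, giving the exact closed form
    ``EC50 = K_D (1-F)/(2 (1+F)) + T0/2`` at any target concentration; the
    reference is the monovalent single-site ``EC50 = K_D + T0/2``.
    """
    kd = check_positive("kd", kd)
    T0 = check_nonnegative("T0", T0)
    f = fraction_bridged(gated_effective_concentration(geom).value, kd)
    ec50 = kd * (1.0 - f) / (2.0 * (1.0 + f)) + T0 / 2.0
    return FoldImprovement(
        ec50_model=ec50, ec50_reference=ec50_single_site(T0, kd), f_t_dim=f
    )


def fold_asymptotic(kd: float, L_eff: float) -> float:
    """Large-effective-concentration fold improvement ``4 sqrt(L_eff / K_D)``.

    Accurate to a couple of percent once ``L_eff / K_D >~ 1e4``; explains why
    the fold grows only with the square root of monomer potency.
    """
    kd = check_positive("kd", kd)
    L_eff = check_positive("L_eff", L_eff)
    return 4.0 * math.sqrt(L_eff / kd)


def k2_effective(kd: float, geom: TetherGeometry) -> float:
    """Effective dissociation constant of the closed 1:1 complex.

    ``K_2 = K_D (1 - F**2) / (4 F)`` with ``F`` the bridged fraction.
    Undefined when the tether cannot span (no closed complex exists).
    """
    kd = check_positive("kd", kd)
    f = fraction_bridged(gated_effective_concentration(geom).value, kd)
    if f == 0.0:
        raise ValueError("no closed 1:1 complex: tether cannot span the sites")
    return kd * (1.0 - f * f) / (4.0 * f)


def k2_asymptotic(kd: float, L_eff: float) -> float:
    """Limit form ``K_2 ~ sqrt(K_D**3 / (4 L_eff))`` for ``L_eff >> K_D``.

    Makes the 3/2-power law explicit: at fixed tether length the closed-
    complex affinity scales as ``K_D**1.5``.
    """
    kd = check_positive("kd", kd)
    L_eff = check_positive("L_eff", L_eff)
    return math.sqrt(kd**3 / (4.0 * L_eff))


def best_attainable_affinity(kd: float) -> float:
    """Screening rule: best effective dimer affinity ``K_D**(3/2)`` (molar).

    A dimensional convention on the molar standard state, e.g. a 70 nM
    monomer predicts ~20 pM for the best homodimer.
    """
    kd = check_positive("kd", kd)
    return kd**1.5


def dimer_dg_prediction(dg_monomer_kcal: float) -> float:
    """Free-energy form of the 3/2 rule: dimer ΔG = 1.5 x monomer ΔG."""
    dg = float(dg_monomer_kcal)
    if not math.isfinite(dg):
        raise ValueError(f"dg_monomer_kcal must be finite, got {dg_monomer_kcal!r}")
    return 1.5 * dg


def tether_for_squared_scaling(kd: float) -> float:
    """Tether length at which K_2 would scale as K_D squared.

    Solves ``sphere_effective_concentration(rho_p) = 1/(4 K_D)``, i.e.
    ``rho_p = (4 k K_D)**(1/3)`` with ``k`` the sphere prefactor.  Sub-
    ångström for any realistic K_D, showing that square-law additivity of
    binding free energies is unattainable for tethered dimers.
    """
    kd = check_positive("kd", kd)
    return (4.0 * SPHERE_PREFACTOR * kd) ** (1.0 / 3.0)


def state_fractions_irreversible(
    r: float, f_t_dim: float, L0: float = 0.0, T0: float = 0.0
) -> IrreversibleBivalentState:
    """Resolve all target-state fractions at occupancy *r*.

    ``F_T = r (1 - F)`` is the occupancy excluding the 1:1 state; the
    non-1:1 population then distributes binomially over the two sites.
    ``f_l`` is exact: ``T0 (r - F_21) / (L0 - T0 F_21)`` when ``L0 > 0``.
    """
    f21 = f21_from_bridging(r, f_t_dim)
    f_t = r * (1.0 - f_t_dim)
    one = 1.0 - f21
    f_l = 0.0
    if L0 > 0.0:
        f_l = T0 * (r - f21) / (L0 - T0 * f21)
    return IrreversibleBivalentState(
        f_2u=(1.0 - f_t) ** 2 * one,
        f_1u=2.0 * f_t * (1.0 - f_t) * one,
        f_22=f_t * f_t * one,
        f_21=f21,
        f_t=f_t,
        f_t_dim=f_t_dim,
        r=r,
        f_l=f_l,
    )


def occupancy_curve_irreversible(
    kd: float,
    geom: TetherGeometry,
    T0: float,
    L0_grid: Sequence[float],
) -> np.ndarray:
    """Total site occupancy R over a ligand titration.

    For each total bivalent concentration ``L0`` solves

    ``K_D * F_T = 2 (1 - F_T) (L0 - T0 R)``, ``F_T = R (1 - F)``

    for ``R`` in [0, 1] by bracketed root-finding on the monotone residual.
    """
    kd = check_positive("kd", kd)
    T0 = check_nonnegative("T0", T0)
    grid = np.asarray(L0_grid, dtype=float)
    if grid.ndim != 1 or np.any(grid < 0.0) or np.any(np.diff(grid) <= 0.0):
        raise ValueError("L0_grid must be 1-D, nonnegative and strictly increasing")
    f = fraction_bridged(gated_effective_concentration(geom).value, kd)

    def residual(r: float, L0: float) -> float:
        f_t = r * (1.0 - f)
        return kd * f_t - 2.0 * (1.0 - f_t) * (L0 - T0 * r)

    out = np.empty_like(grid)
    for i, L0 in enumerate(grid):
        if L0 == 0.0:
            out[i] = 0.0
            continue
        hi = 1.0
        if residual(hi, L0) < 0.0:  # saturating: R -> 1 only as L0 -> inf
            out[i] = 1.0
            continue
        out[i] = brentq(residual, 0.0, hi, args=(L0,), xtol=1e-15, rtol=1e-14)
    return out


def fig2_grid(kd_list, rho_grid, rho_s: float = 0.0, T0: float = 0.0) -> pd.DataFrame:
    """Sweep the irreversible-bivalent model over (K_D, rho_p) grids.

    Long-format DataFrame with columns
    ``K_D, rho_p, L_eff, F_T_Dim, EC50, fold``; deterministic row order
    (K_D outer, then rho_p).
    """
    rows = []
    for kd in kd_list:
        for rho_p in rho_grid:
            geom = TetherGeometry(rho_p, rho_s)
            L_eff = gated_effective_concentration(geom).value
            res = ec50_irreversible(kd, geom, T0)
            rows.append((kd, rho_p, L_eff, res.f_t_dim, res.ec50_model, res.fold))
    return pd.DataFrame(
        rows, columns=["K_D", "rho_p", "L_eff", "F_T_Dim", "EC50", "fold"]
    )
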