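"""Reversibly dimerizing monomers binding a two-site target.

Monomers carry linker moieties that associate in solution with dissociation
constant ``K_Dim``, so the ligand pool is a monomer/dimer mixture whose
composition shifts with total monomer concentration ``L0``.  The 1:1 state
(one assembled dimer bridging both target sites) can form along two routes:

* the *monomeric* route — two free monomers bind the two sites and then
  dimerize on the target with probability ``F_L,Dim`` (set by the linker
  effective concentration and K_Dim), or
* the *dimeric* route — a pre-formed solution dimer binds one site and
  bridges with probability ``F_T,Dim`` exactly as an irreversible bivalent.

The 1:1 fraction is blended between the two route-limits with weights
proportional to the relative abundance of doubly-monomer-bound targets
versus singly-dimer-bound targets.  The EC50 is the self-consistent root of

    L0 = K_D * (1 - 2 F_21(L0))        (R = 1/2, T0 << L0),

solved numerically because the solution dimer fraction ``F_DL`` depends on
``L0``.  Fold improvement is quoted against the monovalent single-site
reference, i.e. ``fold = K_D / EC50``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .irreversible import ec50_irreversible, f21_from_bridging
from .tether import (
    TetherGeometry,
    fraction_bridged,
    fraction_dimerized_pair,
    gated_effective_concentration,
    sphere_effective_concentration,
    dimer_moiety_effective_concentration,
)
from .units import check_nonnegative, check_positive

__all__ = [
    "ReversibleDimerState",
    "ReversibleEC50Result",
    "solution_dimer_fraction",
    "f21_monomeric_limit",
    "blended_f21",
    "ec50_reversible",
    "monomer_fraction_at",
    "threshold_tether_for_fold",
    "fig4_grid",
    "state_fractions_reversible",
]


@dataclass(frozen=True)
class ReversibleDimerState:
    """Full state-fraction bookkeeping for the monomer/dimer/target system.

    Target side: ``f_u + f_1 + f_22 + f_21 == 1``.  Ligand side (monomer
    units): ``f_ml + f_dl + d_21 == 1`` with ``f_ml`` split into unbound/
    bound monomer (``l_u``, ``l_1``) and ``f_dl`` into dimer states
    (``d_u``, ``d_1``, ``d_22``) binomially in the common bound-ligand
    fraction ``f_l`` (monomer and dimer arms are indistinguishable to the
    target).
    """

    f_u: float
    f_1: float
    f_22: float
    f_21: float
    f_t: float
    f_ml: float
    f_dl: float
    d_21: float
    l_u: float
    l_1: float
    d_u: float
    d_1: float
    d_22: float
    f_l: float
    f_l_dim: float
    f_t_dim: float
    r: float

    @property
    def r_prime(self) -> float:
        """Fraction of all monomer units bound: ``f_l (1 - d_21) + d_21``."""
        return self.f_l * (1.0 - self.d_21) + self.d_21


@dataclass(frozen=True)
class ReversibleEC50Result:
    """Self-consistent EC50 of the dimerizing-monomer system.

    ``ec50`` is in monomer-equivalent molar; ``fold = K_D / ec50`` in the
    dilute-target limit.  ``components`` carries the route weights and the
    two route-limit 1:1 fractions at the root, for diagnosing whether
    solution dimer or on-target dimerization drives the improvement.
    """

    ec50: float
    fold: float
    f_ml_at_ec50: float
    components: dict[str, float]


def solution_dimer_fraction(L0: float, kdim: float, d21: float = 0.0) -> float:
    """Fraction of monomer units residing in (non-1:1) solution dimers.

    Closed form of the monomer/dimer mass action at total monomer *L0* with
    a fraction *d21* sequestered in the 1:1 state:

    ``F_DL = 1 - D21 - K_Dim/(4 L0) * (sqrt(1 + 8 L0 (1-D21)/K_Dim) - 1)``
    """
    L0 = check_positive("L0", L0)
    kdim = check_positive("kdim", kdim)
    d21 = check_nonnegative("d21", d21)
    if d21 >= 1.0:
        raise ValueError("d21 must lie in [0, 1)")
    x = 8.0 * L0 * (1.0 - d21) / kdim
    # stable: K/(4 L0) * (sqrt(1+x)-1) = 2 (1-d21) / (sqrt(1+x)+1)
    return (1.0 - d21) * (1.0 - 2.0 / (math.sqrt(1.0 + x) + 1.0))


def f21_monomeric_limit(r: float, f_l_dim: float) -> float:
    """1:1 fraction when the ligand pool is purely monomeric.

    Two monomers bound to one target dimerize with probability *f_l_dim*:

    ``F21 = r (1 - r (1-f²)/2 - sqrt(r² (1-f²)²/4 + (1-r)(1-f)))``

    with ``f = f_l_dim``.  Vanishes at ``f = 0`` and reaches ``r`` at
    ``f = 1``.
    """
    r = check_nonnegative("r", r)
    f = check_nonnegative("f_l_dim", f_l_dim)
    if r > 1.0 or f > 1.0:
        raise ValueError("r and f_l_dim must lie in [0, 1]")
    a = r * (1.0 - f * f) / 2.0
    inner = 1.0 - a - math.sqrt(a * a + (1.0 - r) * (1.0 - f))
    return r * max(inner, 0.0)


def blended_f21(
    r: float, f_ml: float, f_dl: float, f_l_dim: float, f_t_dim: float
) -> float:
    """Blend the monomeric and dimeric route limits of the 1:1 fraction.

    Weights follow the abundance ratio of doubly-monomer-bound targets
    (``~ r F_ML²``) to singly-dimer-bound targets (``~ 2 (1-r) F_DL``),
    evaluated with the 1:1 state excluded.
    """
    denom = r * f_ml * f_ml + 2.0 * (1.0 - r) * f_dl
    if denom == 0.0:
        warnings.warn("degenerate ligand pool (F_ML = F_DL = 0); F_21 set to 0")
        return 0.0
    w_mono = r * f_ml * f_ml / denom
    return w_mono * f21_monomeric_limit(r, f_l_dim) + (1.0 - w_mono) * f21_from_bridging(
        r, f_t_dim
    )


def _route_fractions(geom: TetherGeometry, kd: float, kdim: float) -> tuple[float, float]:
    """(F_T,Dim, F_L,Dim) for the two 1:1-formation routes, gated on span."""
    if not geom.spans:
        return 0.0, 0.0
    f_t_dim = fraction_bridged(sphere_effective_concentration(geom.rho_p), kd)
    f_l_dim = fraction_dimerized_pair(
        dimer_moiety_effective_concentration(geom.rho_p), kdim
    )
    return f_t_dim, f_l_dim


def _one_minus_2f21(L0: float, kd: float, kdim: float, f_t_dim: float, f_l_dim: float):
    """Evaluate 1 - 2 F_21 at R = 1/2 with route weights from D_21 = 0."""
    f_dl = solution_dimer_fraction(L0, kdim, 0.0)
    f_ml = 1.0 - f_dl
    w_mono = f_ml * f_ml / (1.0 + f_dl * f_dl)
    w_dim = 2.0 * f_dl / (1.0 + f_dl * f_dl)
    mono = 1.0 - 2.0 * f21_monomeric_limit(0.5, f_l_dim)
    dim = (1.0 - f_t_dim) / (1.0 + f_t_dim)
    return w_mono * mono + w_dim * dim, f_ml, w_mono, w_dim


def ec50_reversible(
    kd: float, kdim: float, geom: TetherGeometry
) -> ReversibleEC50Result:
    """Self-consistent EC50 of reversibly dimerizing monomers, two-site target.

    Solves ``g(L0) = K_D (1 - 2 F_21(L0)) - L0 = 0`` on ``(0, K_D]`` by
    bracketed root-finding in log concentration.  ``g`` is positive at
    vanishing ``L0`` and nonpositive at ``K_D``, and monotone decreasing on
    the bracket, so the root is unique.  Fold is quoted against the
    monovalent single-site EC50 (= K_D in the dilute-target limit).
    """
    kd = check_positive("kd", kd)
    kdim = check_positive("kdim", kdim)
    f_t_dim, f_l_dim = _route_fractions(geom, kd, kdim)

    def g_log(u: float) -> float:
        L0 = 10.0**u
        return kd * _one_minus_2f21(L0, kd, kdim, f_t_dim, f_l_dim)[0] - L0

    lo, hi = math.log10(kd) - 14.0, math.log10(kd)
    if g_log(hi) >= 0.0:  # no 1:1 formation at all: EC50 = K_D exactly
        ec50 = kd
    else:
        ec50 = 10.0 ** brentq(g_log, lo, hi, xtol=1e-13, rtol=8.9e-16)
    omf, f_ml, w_mono, w_dim = _one_minus_2f21(ec50, kd, kdim, f_t_dim, f_l_dim)
    return ReversibleEC50Result(
        ec50=ec50,
        fold=kd / ec50,
        f_ml_at_ec50=f_ml,
        components={
            "w_mono": w_mono,
            "w_dim": w_dim,
            "f21_mono": f21_monomeric_limit(0.5, f_l_dim),
            "f21_dim": f21_from_bridging(0.5, f_t_dim),
            "f_t_dim": f_t_dim,
            "f_l_dim": f_l_dim,
        },
    )


def monomer_fraction_at(L0: float, kdim: float) -> float:
    """Fraction of ligand present as free monomer at total concentration *L0*."""
    return 1.0 - solution_dimer_fraction(L0, kdim, 0.0)


def threshold_tether_for_fold(
    kd: float,
    kdim: float,
    fold_target: float,
    rho_s: float = 0.0,
    rho_max: float = 1000.0,
) -> float | None:
    """Largest tether length at which the fold improvement still meets a target.

    Fold is monotone nonincreasing in ``rho_p`` (for ``rho_p >= rho_s``), so
    bisection on ``[rho_s, rho_max]`` locates the threshold.  Returns None
    when even the shortest spanning tether falls below *fold_target*.
    """
    if fold_target <= 1.0:
        return rho_max
    lo = max(rho_s, 1e-3)

    def fold_at(rho_p: float) -> float:
        return ec50_reversible(kd, kdim, TetherGeometry(rho_p, rho_s)).fold

    if fold_at(lo) < fold_target:
        return None
    if fold_at(rho_max) >= fold_target:
        return rho_max
    return brentq(lambda r: fold_at(r) - fold_target, lo, rho_max, xtol=1e-9)


def fig4_grid(
    kd_list, kdim_grid, rho_grid, rho_s: float = 0.0
) -> pd.DataFrame:
    """Sweep the reversible-dimer EC50 over (K_D, K_Dim, rho_p) grids.

    Returns a long-format DataFrame with columns
    ``K_D, K_Dim, rho_p, EC50, fold, F_ML_at_ec50``; deterministic row
    order (K_D outer, then K_Dim, then rho_p).
    """
    rows = []
    for kd in kd_list:
        for kdim in kdim_grid:
            for rho_p in rho_grid:
                res = ec50_reversible(kd, kdim, TetherGeometry(rho_p, rho_s))
                rows.append((kd, kdim, rho_p, res.ec50, res.fold, res.f_ml_at_ec50))
    return pd.DataFrame(
        rows, columns=["K_D", "K_Dim", "rho_p", "EC50", "fold", "F_ML_at_ec50"]
    )


def state_fractions_reversible(
    L0: float, kd: float, kdim: float, geom: TetherGeometry, r: float = 0.5
) -> ReversibleDimerState:
    """Resolve every state fraction of the system at occupancy *r*.

    Uses the dilute-target conventions of the EC50 solution: bound-ligand
    fraction ``f_l ~ 0`` and route weights at ``D_21 = 0``.  The returned
    fractions satisfy the target- and ligand-side conservation identities
    exactly.
    """
    f_t_dim, f_l_dim = _route_fractions(geom, kd, kdim)
    f_dl = solution_dimer_fraction(L0, kdim, 0.0)
    f_ml = 1.0 - f_dl
    f21 = blended_f21(r, f_ml, f_dl, f_l_dim, f_t_dim)
    f_t = (r - f21) / (1.0 - f21) if f21 < 1.0 else 0.0
    one = 1.0 - f21
    f_l = 0.0  # dilute-target limit
    d_21 = 0.0
    return ReversibleDimerState(
        f_u=(1.0 - f_t) ** 2 * one,
        f_1=2.0 * f_t * (1.0 - f_t) * one,
        f_22=f_t * f_t * one,
        f_21=f21,
        f_t=f_t,
        f_ml=f_ml,
        f_dl=f_dl,
        d_21=d_21,
        l_u=(1.0 - f_l) * f_ml,
        l_1=f_l * f_ml,
        d_u=(1.0 - f_l) ** 2 * f_dl,
        d_1=2.0 * f_l * (1.0 - f_l) * f_dl,
        d_22=f_l * f_l * f_dl,
        f_l=f_l,
        f_l_dim=f_l_dim,
        f_t_dim=f_t_dim,
        r=r,
    )
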