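"""Baseline occupancy and EC50 models without tether effects.

Three reference systems anchor everything else in the package:

* a monovalent ligand on a single-site target (the textbook quadratic
  isotherm),
* a monovalent ligand on a target carrying two equivalent, independent
  sites, and
* a bivalent ligand on a single-site target, where the two arms act as two
  independent ligands at twice the molecular concentration.

``R`` denotes the fraction of all target sites occupied; for independent
sites it equals the per-site occupancy ``F_T`` regardless of the number of
sites per target.  The EC50 is the total ligand concentration at which
``R = 1/2`` for a given total target concentration ``T0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import check_nonnegative, check_positive

__all__ = [
    "MonovalentOccupancy",
    "solve_single_site_occupancy",
    "ec50_single_site",
    "ec50_two_site_monovalent",
    "ec50_single_site_bivalent",
]


@dataclass(frozen=True)
class MonovalentOccupancy:
    """Occupancy fractions for monovalent binding.

    Attributes
    ----------
    f_t : float
        Fraction of target sites bound.
    f_l : float
        Fraction of ligand bound.
    r : float
        Fraction of all target sites occupied (equals ``f_t`` for
        independent sites).
    f_t1, f_t2 : float
        For a two-site target: fractions of targets with exactly one and
        exactly two sites occupied, ``2 F_T (1-F_T)`` and ``F_T**2``.
    """

    f_t: float
    f_l: float

    @property
    def r(self) -> float:
        return self.f_t

    @property
    def f_t1(self) -> float:
        return 2.0 * self.f_t * (1.0 - self.f_t)

    @property
    def f_t2(self) -> float:
        return self.f_t * self.f_t


def solve_single_site_occupancy(L0: float, T0: float, kd: float) -> MonovalentOccupancy:
    """Solve the single-site mass-action isotherm for the bound fraction.

    Finds the unique root in [0, 1] of

    ``K_D * F_T = (1 - F_T) * (L0 - F_T * T0)``

    using the citardauq form of the quadratic, which stays accurate when
    ``T0 << L0`` (the physically common regime where the naive root
    difference cancels catastrophically).
    """
    L0 = check_nonnegative("L0", L0)
    T0 = check_nonnegative("T0", T0)
    kd = check_positive("kd", kd)

    if L0 == 0.0:
        return MonovalentOccupancy(f_t=0.0, f_l=0.0)
    if T0 == 0.0:
        f_t = L0 / (L0 + kd)
        return MonovalentOccupancy(f_t=f_t, f_l=0.0)

    # T0*F^2 - (L0 + T0 + kd)*F + L0 = 0; smaller root is the physical one.
    b = L0 + T0 + kd
    disc = b * b - 4.0 * T0 * L0
    # disc >= (L0 - T0)^2 + kd^2 > 0 always; clamp tiny negatives anyway.
    sqrt_disc = math.sqrt(max(disc, 0.0))
    f_t = 2.0 * L0 / (b + sqrt_disc)  # citardauq: stable smaller root
    f_t = min(max(f_t, 0.0), 1.0)
    f_l = f_t * T0 / L0
    return MonovalentOccupancy(f_t=f_t, f_l=min(f_l, 1.0))


def ec50_single_site(T0: float, kd: float) -> float:
    """EC50 of a monovalent ligand on a single-site target: ``K_D + T0/2``."""
    T0 = check_nonnegative("T0", T0)
    kd = check_positive("kd", kd)
    return kd + T0 / 2.0


def ec50_two_site_monovalent(T0: float, kd: float) -> float:
    """EC50 of a monovalent ligand on a two-site target: ``K_D + T0``.

    Exceeds the single-site EC50 by ``T0/2`` because the two-site target
    presents twice as many sites at the same molar target concentration.
    """
    T0 = check_nonnegative("T0", T0)
    kd = check_positive("kd", kd)
    return kd + T0


def ec50_single_site_bivalent(T0: float, kd: float) -> float:
    """EC50 (in bivalent molecules) of a bivalent ligand on a one-site target.

    The two arms are independent, so each bivalent counts as two ligands:
    ``EC50 = (K_D + T0/2) / 2``, i.e. half the monovalent EC50 at ``T0 = 0``.
    """
    T0 = check_nonnegative("T0", T0)
    kd = check_positive("kd", kd)
    return (kd + T0 / 2.0) / 2.0
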