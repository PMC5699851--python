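"""Independent brute-force equilibrium solvers for validating closed forms.

These solvers deliberately share no code with the production paths: every
one uses plain bisection on a monotone mass-action residual, or damped
fixed-point iteration, so agreement with the closed forms is evidence and
not tautology.  They are slow by design and intended for the test suite and
for spot checks, not for analysis work.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tether import (
    TetherGeometry,
    dimer_moiety_effective_concentration,
    fraction_bridged,
    fraction_dimerized_pair,
    sphere_effective_concentration,
)

__all__ = [
    "OracleReport",
    "mass_action_single_site",
    "mass_action_dimerization",
    "fixed_point_reversible_ec50",
]


@dataclass(frozen=True)
class OracleReport:
    """Side-by-side record of a closed form against its brute-force value."""

    closed_form_value: float
    oracle_value: float
    iterations: int

    @property
    def rel_gap(self) -> float:
        scale = max(abs(self.closed_form_value), abs(self.oracle_value), 1e-300)
        return abs(self.closed_form_value - self.oracle_value) / scale


def mass_action_single_site(
    L0: float, T0: float, kd: float, iterations: int = 200
) -> float:
    """Bound target fraction by bisection on the single-site residual.

    The residual ``K_D F - (1 - F)(L0 - F T0)`` is monotone increasing in
    ``F`` on [0, 1], so 200 bisections pin the root to ~1e-60 absolute.
    """
    if L0 == 0.0:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if kd * mid - (1.0 - mid) * (L0 - mid * T0) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def mass_action_dimerization(
    L_total: float, kdim: float, iterations: int = 200
) -> float:
    """Fraction of monomer units in dimers, 2M <-> D, by bisection.

    Solves ``K_Dim * F_D = 2 L (1 - F_D)**2`` for the dimerized monomer
    fraction ``F_D`` (monomer fraction ``F_M = 1 - F_D``; dimer molar
    concentration ``L F_D / 2``).
    """
    if L_total == 0.0:
        return 0.0
    lo, hi = 0.0, 1.0
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        f_m = 1.0 - mid
        if kdim * mid - 2.0 * L_total * f_m * f_m > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def fixed_point_reversible_ec50(
    kd: float,
    kdim: float,
    geom: TetherGeometry,
    damping: float = 0.5,
    max_iter: int = 10_000,
    rtol: float = 1e-12,
) -> float:
    """Reversible-dimer EC50 by damped fixed-point iteration.

    Iterates ``L0 <- (1-d) L0 + d K_D (1 - 2 F_21(L0))`` from ``L0 = K_D``.
    The update map is evaluated from the same published closed forms as the
    production solver but converged by iteration rather than bracketing,
    providing an independent check of the root.
    """
    if geom.spans:
        f_t_dim = fraction_bridged(sphere_effective_concentration(geom.rho_p), kd)
        f_l_dim = fraction_dimerized_pair(
            dimer_moiety_effective_concentration(geom.rho_p), kdim
        )
    else:
        f_t_dim = f_l_dim = 0.0
    dim_factor = (1.0 - f_t_dim) / (1.0 + f_t_dim)

    def target(L0: float) -> float:
        # solution dimer fraction at D21 = 0, by bisection (no closed form)
        f_dl = mass_action_dimerization(L0, kdim)
        f_ml = 1.0 - f_dl
        w_mono = f_ml * f_ml / (1.0 + f_dl * f_dl)
        a = 0.5 * (1.0 - f_l_dim * f_l_dim) / 2.0
        f21_mono = 0.5 * (1.0 - a - (a * a + 0.5 * (1.0 - f_l_dim)) ** 0.5)
        mono = 1.0 - 2.0 * f21_mono
        return kd * (w_mono * mono + (1.0 - w_mono) * dim_factor)

    L0 = kd
    for it in range(1, max_iter + 1):
        nxt = (1.0 - damping) * L0 + damping * target(L0)
        if abs(nxt - L0) <= rtol * abs(nxt):
            return nxt
        L0 = nxt
    raise RuntimeError(
        f"fixed-point EC50 oracle failed to converge in {max_iter} iterations "
        f"(last L0 = {L0:.6e})"
    )
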