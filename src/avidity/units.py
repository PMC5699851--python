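"""Units, physical constants, and thermodynamic conversions.

All concentrations in this package are molar (M), all lengths are in
ångströms (Å), and all free energies are in kcal/mol with the convention
that negative means favorable binding.  Dissociation constants live on the
molar standard state, so ``ΔG = RT ln K_D`` with ``K_D`` in M.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "R_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "ArgumentError",
    "UnitParseError",
    "BindingConstants",
    "kd_from_dg",
    "dg_from_kd",
    "parse_concentration",
    "check_nonnegative",
    "check_positive",
]

#: Avogadro constant (CODATA, exact since the 2019 SI redefinition), 1/mol.
AVOGADRO = 6.02214076e23

#: Molar gas constant in kcal/(mol K).
R_KCAL = 1.98720425e-3

#: Ambient temperature used when no temperature is given, K.
DEFAULT_TEMPERATURE_K = 298.15


class ArgumentError(ValueError):
    """An argument violated a physical contract (sign, finiteness, range)."""


class UnitParseError(ArgumentError):
    """A concentration string could not be parsed."""


def check_nonnegative(name: str, value: float) -> float:
    """Validate that *value* is a finite number ≥ 0 and return it as float."""
    v = float(value)
    if math.isnan(v) or math.isinf(v) or v < 0.0:
        raise ArgumentError(f"{name} must be finite and >= 0, got {value!r}")
    return v


def check_positive(name: str, value: float) -> float:
    """Validate that *value* is a finite number > 0 and return it as float."""
    v = float(value)
    if math.isnan(v) or math.isinf(v) or v <= 0.0:
        raise ArgumentError(f"{name} must be finite and > 0, got {value!r}")
    return v


@dataclass(frozen=True)
class BindingConstants:
    """Equilibrium constants of one monomer/target/linker system.

    Parameters
    ----------
    kd : float
        Monomer-site dissociation constant, M.
    kdim : float, optional
        Monomer-monomer dimerization dissociation constant, M.
    k2 : float, optional
        Effective dissociation constant of the closed 1:1 complex, M.

    The association constant is the reciprocal of ``kd`` (``ka * kd == 1``).
    """

    kd: float
    kdim: float | None = None
    k2: float | None = None

    def __post_init__(self) -> None:
        check_positive("kd", self.kd)
        if self.kdim is not None:
            check_positive("kdim", self.kdim)
        if self.k2 is not None:
            check_positive("k2", self.k2)

    @property
    def ka(self) -> float:
        """Association constant, 1/M."""
        return 1.0 / self.kd


def kd_from_dg(dg_kcal: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert a binding free energy (kcal/mol) into a dissociation constant (M).

    Uses ``K_D = exp(ΔG / RT)`` on the molar standard state, so a favorable
    (negative) ΔG yields K_D < 1 M.
    """
    dg = float(dg_kcal)
    if not math.isfinite(dg):
        raise ArgumentError(f"dg_kcal must be finite, got {dg_kcal!r}")
    t = check_positive("temperature_K", temperature_K)
    return math.exp(dg / (R_KCAL * t))


def dg_from_kd(kd: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Convert a dissociation constant (M) into a binding free energy (kcal/mol)."""
    k = check_positive("kd", kd)
    t = check_positive("temperature_K", temperature_K)
    return R_KCAL * t * math.log(k)


_CONC_SUFFIX = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

_CONC_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(M|mM|uM|µM|nM|pM)?\s*$"
)


def parse_concentration(text: str | float) -> float:
    """Parse a concentration with an optional unit suffix into molar.

    Accepts a bare number (already molar) or a number immediately followed by
    one of ``M, mM, uM, µM, nM, pM``.  Negative values are rejected.

    >>> parse_concentration("10uM")
    1e-05
    """
    if isinstance(text, (int, float)):
        return check_nonnegative("concentration", text)
    m = _CONC_RE.match(text)
    if not m:
        raise UnitParseError(f"cannot parse concentration {text!r}")
    value = float(m.group(1)) * _CONC_SUFFIX[m.group(2) or "M"]
    return check_nonnegative("concentration", value)
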