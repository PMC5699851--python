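"""Synthetic titration curves and a model-free EC50 estimator.

Useful for end-to-end checks: generate an occupancy curve R(L0) from one of
the equilibrium models, optionally corrupt it with multiplicative lognormal
noise (occupancies are positive and bounded, so additive Gaussian noise is
unphysical), then recover the EC50 by isotonic regression plus
interpolation and compare with the analytic value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .irreversible import ec50_irreversible, occupancy_curve_irreversible
from .monovalent import (
    ec50_single_site,
    ec50_two_site_monovalent,
    solve_single_site_occupancy,
)
from .tether import TetherGeometry
from .units import ArgumentError, check_nonnegative

__all__ = [
    "TitrationCurve",
    "EstimationError",
    "default_grid",
    "simulate_titration",
    "estimate_ec50",
    "write_curve_csv",
    "read_curve_csv",
]

MODELS = ("single_site", "two_site_monovalent", "irreversible_bivalent")


class EstimationError(RuntimeError):
    """The EC50 could not be estimated from the supplied curve."""


@dataclass(frozen=True)
class TitrationCurve:
    """A (possibly noisy) occupancy-vs-concentration curve.

    ``L0_grid`` ascending, molar; ``R_values`` in [0, 1].
    """

    L0_grid: np.ndarray
    R_values: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None
    model_id: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.L0_grid, dtype=float)
        r = np.asarray(self.R_values, dtype=float)
        if grid.shape != r.shape or grid.ndim != 1:
            raise ArgumentError("L0_grid and R_values must be matching 1-D arrays")
        if np.any(np.diff(grid) <= 0.0):
            raise ArgumentError("L0_grid must be strictly ascending")
        object.__setattr__(self, "L0_grid", grid)
        object.__setattr__(self, "R_values", r)


def default_grid(center: float, decades: float = 4.0, per_decade: int = 24) -> np.ndarray:
    """Log-spaced concentration grid centered on *center* (e.g. an analytic EC50)."""
    half = decades / 2.0
    n = int(round(decades * per_decade)) + 1
    return np.logspace(np.log10(center) - half, np.log10(center) + half, n)


def _model_curve(model_id: str, params: dict, grid: np.ndarray) -> np.ndarray:
    kd = params["kd"]
    T0 = params.get("T0", 0.0)
    if model_id == "single_site":
        return np.array([solve_single_site_occupancy(x, T0, kd).r for x in grid])
    if model_id == "two_site_monovalent":
        # independent sites: identical per-site isotherm at doubled site count
        return np.array(
            [solve_single_site_occupancy(x, 2.0 * T0, kd).r for x in grid]
        )
    if model_id == "irreversible_bivalent":
        geom = TetherGeometry(params["rho_p"], params.get("rho_s", 0.0))
        return occupancy_curve_irreversible(kd, geom, T0, grid)
    raise ArgumentError(f"unknown model_id {model_id!r}; expected one of {MODELS}")


def analytic_ec50(model_id: str, params: dict) -> float:
    """Closed-form EC50 of the named model, for grid centering and checks."""
    kd = params["kd"]
    T0 = params.get("T0", 0.0)
    if model_id == "single_site":
        return ec50_single_site(T0, kd)
    if model_id == "two_site_monovalent":
        return ec50_two_site_monovalent(T0, kd)
    if model_id == "irreversible_bivalent":
        geom = TetherGeometry(params["rho_p"], params.get("rho_s", 0.0))
        return ec50_irreversible(kd, geom, T0).ec50_model
    raise ArgumentError(f"unknown model_id {model_id!r}; expected one of {MODELS}")


def simulate_titration(
    model_id: str,
    params: dict,
    L0_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Generate an occupancy curve from a model, with lognormal noise.

    ``noise_sd`` is the standard deviation of the log-noise; the noisy curve
    is ``R * exp(noise_sd * z)`` clipped to [0, 1].  Bit-reproducible for a
    fixed seed.
    """
    noise_sd = check_nonnegative("noise_sd", noise_sd)
    if L0_grid is None:
        L0_grid = default_grid(analytic_ec50(model_id, params))
    grid = np.asarray(L0_grid, dtype=float)
    r = _model_curve(model_id, params, grid)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        r = np.clip(r * rng.lognormal(0.0, noise_sd, size=r.shape), 0.0, 1.0)
    return TitrationCurve(
        L0_grid=grid,
        R_values=r,
        noise_sd=noise_sd,
        seed=seed,
        model_id=model_id,
        params=dict(params),
    )


def estimate_ec50(curve: TitrationCurve) -> float:
    """Model-free EC50: isotonic regression of R on log10(L0), interpolated at 1/2.

    Raises :class:`EstimationError` when the monotone fit never crosses 0.5.
    """
    x = np.log10(curve.L0_grid)
    r = isotonic_regression(curve.R_values, increasing=True).x
    if r[0] > 0.5 or r[-1] < 0.5:
        raise EstimationError(
            f"curve does not bracket R = 0.5 (fit range [{r[0]:.3g}, {r[-1]:.3g}])"
        )
    # first index where the fit reaches 0.5
    j = int(np.searchsorted(r, 0.5))
    if r[j] == 0.5 or j == 0:
        return float(10.0 ** x[j])
    x0, x1, r0, r1 = x[j - 1], x[j], r[j - 1], r[j]
    if r1 == r0:
        return float(10.0 ** (0.5 * (x0 + x1)))
    return float(10.0 ** (x0 + (0.5 - r0) * (x1 - x0) / (r1 - r0)))


def write_curve_csv(curve: TitrationCurve, path) -> None:
    """Write a curve as CSV with columns ``L0_molar, R`` (no index)."""
    pd.DataFrame({"L0_molar": curve.L0_grid, "R": curve.R_values}).to_csv(
        path, index=False
    )


def read_curve_csv(path) -> TitrationCurve:
    """Read a curve written by :func:`write_curve_csv`."""
    df = pd.read_csv(path)
    return TitrationCurve(
        L0_grid=df["L0_molar"].to_numpy(), R_values=df["R"].to_numpy()
    )
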