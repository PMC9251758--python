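"""Charging integral and the two-exponential interaction model.

The excess solvation free energy per unit area of a surface charged to
density sigma is the charging integral of the excess interfacial
potential,

    f(sigma) = int_0^sigma phi_int(s) ds,

which for a linear phi_int(sigma) = phi0 + k sigma closes to
f = phi0 sigma + k sigma^2 / 2, with an extremum on the weakly charged
branch at sigma_max = -phi0 / k.  The interfacial contribution to the
interaction free energy of two surfaces at separation x is modelled as
a sum of two exponentials,

    dF(x) = A exp(-kappa_el x) + B exp(-kappa_int x),   A > 0,

whose long-range branch is attractive iff B < 0 (B tracks phi_int at
low charge); with kappa_int < kappa_el the sum has an interior minimum
at x* = ln(A kappa_el / (-B kappa_int)) / (kappa_el - kappa_int).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid


@dataclass
class FreeEnergyCurve:
    sigma_grid: np.ndarray       # e/nm^2
    phi_int_values: np.ndarray   # V
    f_values: np.ndarray         # e V / nm^2
    phi0: float                  # V, intercept of the linear fit
    k: float                     # V nm^2/e, slope of the linear fit
    k_stderr: float
    sigma_max: float             # e/nm^2; nan when the slope is ~0
    fit_window: float

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("sigma_grid", "phi_int_values", "f_values"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# phi0_V: {self.phi0}", f"# k_Vnm2_per_e: {self.k}",
                 f"# sigma_max_e_per_nm2: {self.sigma_max}",
                 "# sigma\tphi_int_V\tf_eV_per_nm2"]
        for s, p, f in zip(self.sigma_grid, self.phi_int_values, self.f_values):
            lines.append(f"{s:.6g}\t{p:.10g}\t{f:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def charging_integral(sigma_grid, phi_int_values,
                      fit_window: float = 0.3) -> FreeEnergyCurve:
    """f(sigma) by trapezoid from 0, plus a linear (phi0, k) fit.

    The grid must include sigma = 0 (the reference state, f(0) = 0) and
    may extend to both signs; the fit uses the weak-charging window
    |sigma| <= fit_window.  sigma_max = -phi0/k is reported only when
    the slope differs from zero by more than 2 standard errors.
    """
    sigma = np.asarray(sigma_grid, dtype=float)
    phi = np.asarray(phi_int_values, dtype=float)
    if sigma.shape != phi.shape or sigma.ndim != 1:
        raise ValueError("sigma_grid and phi_int_values must be 1-D and equal length")
    if len(sigma) < 2:
        raise ValueError("need at least two grid points")
    if not np.all(np.isfinite(sigma)) or not np.all(np.isfinite(phi)):
        raise ValueError("grid and values must be finite")
    order = np.argsort(sigma)
    sigma, phi = sigma[order], phi[order]
    i0 = np.nonzero(np.isclose(sigma, 0.0, atol=1e-12))[0]
    if len(i0) == 0:
        raise ValueError("sigma_grid must include 0 (the uncharged reference)")
    i0 = int(i0[0])

    F = cumulative_trapezoid(phi, sigma, initial=0.0)
    f = F - F[i0]                    # reference f(0) = 0

    win = np.abs(sigma) <= fit_window + 1e-12
    if np.sum(win) < 2:
        win = np.ones_like(sigma, dtype=bool)
    k, phi0 = np.polyfit(sigma[win], phi[win], 1)
    n = int(np.sum(win))
    resid = phi[win] - (phi0 + k * sigma[win])
    if n > 2:
        sxx = np.sum((sigma[win] - sigma[win].mean()) ** 2)
        k_se = float(np.sqrt(np.sum(resid ** 2) / (n - 2) / sxx))
    else:
        k_se = 0.0
    if k != 0 and abs(k) > 2 * k_se:
        sigma_max = -phi0 / k
    else:
        sigma_max = float("nan")

    return FreeEnergyCurve(sigma_grid=sigma, phi_int_values=phi, f_values=f,
                           phi0=float(phi0), k=float(k), k_stderr=k_se,
                           sigma_max=float(sigma_max), fit_window=fit_window)


@dataclass(frozen=True)
class InteractionModelParams:
    A: float            # energy amplitude of the electrostatic branch, > 0
    B: float            # energy amplitude of the interfacial branch
    kappa_el: float     # nm^-1
    kappa_int: float    # nm^-1, < kappa_el

    def __post_init__(self):
        if self.A <= 0:
            raise ValueError("A must be positive")
        if not self.kappa_int < self.kappa_el:
            raise ValueError("kappa_int must be smaller than kappa_el")


def interaction_free_energy(x, params: InteractionModelParams):
    """A exp(-kappa_el x) + B exp(-kappa_int x) at separation x > 0 (nm)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("separation must be positive")
    val = (params.A * np.exp(-params.kappa_el * x)
           + params.B * np.exp(-params.kappa_int * x))
    return val if val.ndim else float(val)


def interaction_minimum(params: InteractionModelParams) -> float:
    """Closed-form stationary point of the two-exponential model (nm).

    Exists only for B < 0 (attractive long-range branch); then
    x* = ln(A kappa_el / (-B kappa_int)) / (kappa_el - kappa_int).
    """
    if params.B >= 0:
        raise ValueError("no interior minimum: B must be negative")
    num = params.A * params.kappa_el / (-params.B * params.kappa_int)
    return float(np.log(num) / (params.kappa_el - params.kappa_int))
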