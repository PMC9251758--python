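"""Excess interfacial potential from polarization profiles.

The electrical potential at a wall due to solvent polarization,
referenced to the bulk liquid at the capacitor midplane, is

    phi_md = (1/eps0) * int_{z_mid}^{z_s} P1(z) dz        (signed in z),

integrating the dipole-moment density only; the traceless-quadrupole
term integrates to (approximately) zero across the interface and is
reported as a diagnostic, never added.  Subtracting the potential of a
continuum-dielectric capacitor over the same interval,

    phi_cont = (1/eps0) * [ P_mid (z_int - z_mid)
                            + sigma_eff (eps_int - 1)/eps_int (z_s - z_int) ],

gives the excess interfacial potential phi_int = phi_md - phi_cont.
P_mid is the midplane (bulk-plateau) polarization, which embeds the
midplane permittivity through P_mid = sigma_eff (eps_mid - 1)/eps_mid;
the interfacial zone (z_int, z_s) uses eps_int = 1 by default
(effectively nonpolarizable) so it contributes no continuum
polarization.  For an uncharged wall phi_cont = 0 and phi_md integrated
out to z_s is the zero-charge potential phi0.

Sign conventions are fixed by the physics of a uniformly polarized
slab: phi(wall) - phi(mid) = (1/eps0) * int P dz taken along z from the
midplane to the wall, so a layer of dipoles whose negative sites face
the wall produces phi0 < 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .config_io import SystemDescriptor
from .constants import EPS0
from .profiles import AxialProfile, trapezoid_between


class PlaneLocationError(RuntimeError):
    """No interfacial plane could be located for a wall."""


@dataclass
class InterfacialPlanes:
    """Midplane, interfacial plane and surface plane for one wall."""

    z_mid: float
    z_int: float
    z_s: float
    wall: str            # left | right
    rule: str            # flat | rough

    def __post_init__(self):
        s = 1.0 if self.wall == "right" else -1.0
        if s * (self.z_int - self.z_mid) < 0 or s * (self.z_s - self.z_int) < -1e-9:
            raise ValueError(
                "planes must be ordered z_mid -> z_int -> z_s toward the wall"
            )


@dataclass
class InterfacialPotentialResult:
    wall: str
    sigma: float            # e/nm^2, charge density on this wall
    phi_md: float           # V
    phi_cont: float         # V
    phi_int: float          # V
    epsilon_mid: float      # nan when sigma = 0
    epsilon_int: float
    planes: InterfacialPlanes
    phi_quadrupole: float = 0.0    # diagnostic: quadrupole term over the interval

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def estimate_epsilon_mid(P_mid: float, sigma: float) -> float:
    """Midplane permittivity from P_mid = sigma (eps - 1)/eps.

    Both arguments are taken along the outward (midplane-to-wall)
    direction; ``sigma`` is the effective continuum charge density
    driving the field (nonzero).
    """
    if sigma == 0:
        raise ValueError("sigma = 0: the uncharged pathway needs no epsilon")
    ratio = P_mid / sigma
    if ratio < 0:
        raise ValueError("polarization opposes the field; check sign conventions")
    if ratio >= 1:
        raise ValueError("super-saturated polarization: P_mid >= sigma")
    return sigma / (sigma - P_mid)


def _bulk_window(descriptor: SystemDescriptor, fraction: float = 0.25):
    lo, hi = descriptor.wall_positions
    mid = 0.5 * (lo + hi)
    half = 0.5 * fraction * (hi - lo)
    return mid - half, mid + half


def _window_mean(profile: AxialProfile, lo: float, hi: float) -> float:
    sel = (profile.z_centers >= lo) & (profile.z_centers <= hi)
    if not np.any(sel):
        raise ValueError("profile does not cover the bulk window")
    return float(np.mean(profile.values[sel]))


def _window_std(profile: AxialProfile, lo: float, hi: float) -> float:
    sel = (profile.z_centers >= lo) & (profile.z_centers <= hi)
    return float(np.std(profile.values[sel]))


def _last_crossing_edge(z, v, threshold, tol):
    """Bin edge of the last above-to-below crossing scanning along z.

    ``z``/``v`` are ordered from the midplane outward.  A bin is below
    only if v < threshold - tol; the crossing is placed at the shared
    edge of the last above bin and its below successor.
    """
    below = v < (threshold - tol)
    above = ~below
    cross = None
    for i in range(len(v) - 1):
        if above[i] and below[i + 1]:
            cross = 0.5 * (z[i] + z[i + 1])
    return cross


def locate_planes(profiles: dict, descriptor: SystemDescriptor,
                  wall: str, density_rtol: float = 0.02) -> InterfacialPlanes:
    """Locate z_mid, z_int and z_s for one wall.

    Flat rule: z_int is the last z, scanning from the midplane toward
    the wall, at which P1 crosses below the continuum (midplane) value;
    rough rule: the last z at which the density crosses below the bulk
    value (mean over the central 25% of the slab).  z_s is the first
    profile point at which the density vanishes (< 1e-4 x bulk).  The
    flat rule falls back to the density rule when no robust P1 crossing
    exists (e.g. sigma = 0, P1 = 0 in the bulk).
    """
    lo, hi = descriptor.wall_positions
    z_mid = 0.5 * (lo + hi)
    s = 1.0 if wall == "right" else -1.0
    mode = descriptor.wall_mode.get(wall, "flat")

    dens = profiles["density"]
    win = _bulk_window(descriptor)
    rho_bulk = _window_mean(dens, *win)
    if rho_bulk <= 0:
        raise PlaneLocationError(f"no bulk density plateau ({wall} wall)")

    # order bins from the midplane outward toward this wall
    zc, dv = dens.z_centers, dens.values
    out = (s * (zc - z_mid)) >= 0
    order = np.argsort(s * zc[out])
    z_out = zc[out][order]
    rho_out = dv[out][order]

    def density_z_int():
        cross = _last_crossing_edge(z_out, rho_out, rho_bulk,
                                    density_rtol * rho_bulk)
        return cross

    rule = mode
    z_int = None
    if mode == "flat":
        P1 = profiles["P1"]
        P_mid = _window_mean(P1, *win)
        p_out = P1.values[out][order]
        tol = max(abs(P_mid) * density_rtol, 3.0 * _window_std(P1, *win))
        # outward component: scan s*P1 against s*P_mid
        z_int = _last_crossing_edge(z_out, s * p_out, s * P_mid, tol)
        if z_int is None:
            rule = "rough"
    if z_int is None:
        z_int = density_z_int()
    if z_int is None:
        raise PlaneLocationError(
            f"no interfacial crossing found for the {wall} wall: the profile "
            "never departs from its bulk/continuum value"
        )

    beyond = s * (z_out - z_int) > 0
    zero = rho_out < 1e-4 * rho_bulk
    cand = np.nonzero(beyond & zero)[0]
    if len(cand) == 0:
        raise PlaneLocationError(
            f"density never reaches zero beyond z_int for the {wall} wall"
        )
    z_s = float(z_out[cand[0]])
    return InterfacialPlanes(z_mid=float(z_mid), z_int=float(z_int),
                             z_s=z_s, wall=wall, rule=rule)


def excess_interfacial_potential(profiles: dict, planes: InterfacialPlanes,
                                 sigma: float, epsilon_int: float = 1.0,
                                 ) -> InterfacialPotentialResult:
    """phi_md, phi_cont and phi_int = phi_md - phi_cont for one wall.

    ``sigma`` is the surface charge density of the analysed wall
    (e/nm^2).  The effective continuum charge density along the outward
    direction is -sigma for either wall (field lines of the capacitor
    run from the positive toward the negative plate).
    """
    P1 = profiles["P1"]
    z_lo_prof, z_hi_prof = P1.z_centers[0], P1.z_centers[-1]
    if not (z_lo_prof <= planes.z_mid <= z_hi_prof) or \
       not (z_lo_prof - P1.bin_width <= planes.z_s <= z_hi_prof + P1.bin_width):
        raise ValueError("planes lie outside the profile support")
    s = 1.0 if planes.wall == "right" else -1.0

    phi_md = trapezoid_between(P1, planes.z_mid, planes.z_s) / EPS0

    # diagnostic quadrupole term over the same interval
    phi_quad = 0.0
    if "Qzz" in profiles:
        Q = profiles["Qzz"]
        dQ = AxialProfile("P1", Q.z_centers, np.gradient(Q.values, Q.bin_width),
                          Q.bin_width, Q.n_frames, Q.area)
        phi_quad = -trapezoid_between(dQ, planes.z_mid, planes.z_s) / EPS0

    if sigma == 0:
        phi_cont = 0.0
        eps_mid = float("nan")
    else:
        # bulk-plateau estimate of the midplane polarization: central half
        # of the mid-to-surface span on both sides of the midplane
        half = 0.5 * abs(planes.z_s - planes.z_mid)
        P_mid = _window_mean(P1, planes.z_mid - half, planes.z_mid + half)
        sigma_eff_out = -sigma            # outward continuum drive
        eps_mid = estimate_epsilon_mid(s * P_mid, sigma_eff_out)
        P_int_zone = (-sigma * s) * (epsilon_int - 1.0) / epsilon_int  # z-component
        phi_cont = (P_mid * (planes.z_int - planes.z_mid)
                    + P_int_zone * (planes.z_s - planes.z_int)) / EPS0

    return InterfacialPotentialResult(
        wall=planes.wall, sigma=float(sigma),
        phi_md=float(phi_md), phi_cont=float(phi_cont),
        phi_int=float(phi_md - phi_cont),
        epsilon_mid=float(eps_mid), epsilon_int=float(epsilon_int),
        planes=planes, phi_quadrupole=float(phi_quad),
    )


def wall_potential(profiles: dict, descriptor: SystemDescriptor, wall: str,
                   epsilon_int: float = 1.0) -> InterfacialPotentialResult:
    """Convenience wrapper: locate planes, then evaluate the potential."""
    planes = locate_planes(profiles, descriptor, wall)
    return excess_interfacial_potential(profiles, planes,
                                        descriptor.sigma.get(wall, 0.0),
                                        epsilon_int=epsilon_int)


def phi0_sign_calibration(profiles: dict, descriptor: SystemDescriptor,
                          wall: str = "right") -> int:
    """Sign of phi0 for an uncharged wall with one anisotropic layer.

    A layer whose molecular dipoles point away from the wall (negative
    sites wallward, as for water at an O-atom surface) must yield a
    negative sign.
    """
    res = wall_potential(profiles, descriptor, wall)
    return int(np.sign(res.phi_int))


def full_liquid_quadrupole_potential(profiles: dict) -> float:
    """Integral of dQzz/dz across the full profile support, in volts.

    With Qzz vanishing in the empty regions at both ends of the slab,
    this boundary difference is approximately zero -- the quadrupole
    term contributes nothing to the integrated potential, which is why
    phi_md integrates P1 only.
    """
    Q = profiles["Qzz"]
    dQ = np.gradient(Q.values, Q.bin_width)
    return float(np.trapezoid(dQ, Q.z_centers) / EPS0)
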