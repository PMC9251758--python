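"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np

from slabpol.config_io import MolecularConfiguration
from slabpol.synthetic import _rotation_matrices, spc_water_template

TEMPLATE = spc_water_template()
MU_SPC = TEMPLATE.dipole_magnitude       # 0.047343 e nm, hand-verified


def water_config(centers, cos_t=None, phi=None, psi=None, box=(2.0, 2.0, 5.0),
                 frame_index=0) -> MolecularConfiguration:
    """Water molecules at given centers with given dipole orientations."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    m = len(centers)
    cos_t = np.ones(m) if cos_t is None else np.asarray(cos_t, dtype=float)
    phi = np.zeros(m) if phi is None else np.asarray(phi, dtype=float)
    psi = np.zeros(m) if psi is None else np.asarray(psi, dtype=float)
    R = _rotation_matrices(cos_t, phi, psi)
    pos = (R[:, None, :, :] @ TEMPLATE.positions[None, :, :, None])[..., 0]
    pos = (pos + centers[:, None, :]).reshape(m * 3, 3)
    return MolecularConfiguration(
        positions=pos,
        charges=np.tile(TEMPLATE.charges, m),
        molecule_id=np.repeat(np.arange(m), 3),
        species_label=np.full(m * 3, "SOL", dtype=object),
        atom_names=np.tile(np.array(TEMPLATE.atom_names, dtype=object), m),
        box=np.asarray(box, dtype=float),
        vdw_radius=np.tile(TEMPLATE.vdw_radii, m),
        frame_index=frame_index,
    )


def random_water_config(rng, n, box) -> MolecularConfiguration:
    """Uniformly placed waters with isotropic orientations."""
    box = np.asarray(box, dtype=float)
    centers = rng.random((n, 3)) * box
    cos_t = 2 * rng.random(n) - 1
    phi = 2 * np.pi * rng.random(n)
    psi = 2 * np.pi * rng.random(n)
    return water_config(centers, cos_t, phi, psi, box=box)


# ----------------------------------------------------------------------
# independent ITIM probe-descent oracles
# ----------------------------------------------------------------------

def _lateral_d2_images(gx, gy, x, y, Lx, Ly):
    """Minimum-image lateral distance^2 via explicit periodic images."""
    best = np.inf
    for sx in (-Lx, 0.0, Lx):
        for sy in (-Ly, 0.0, Ly):
            dx = gx - (x + sx)
            dy = gy - (y + sy)
            d2 = dx * dx + dy * dy
            best = min(best, d2)
    return best


def itim_oracle_bisect(config, species=None, probe_radius=0.15,
                       mesh_spacing=0.02, n_layers=4, side="upper"):
    """Exhaustive probe descent: per-streamline contact heights found by
    bisection on the sphere-overlap predicate, molecules collected layer
    by layer.  Independent of the analytic tangency formula."""
    if species is None:
        mask = np.ones(config.n_atoms, dtype=bool)
    else:
        mask = config.species_label == species
    mask &= config.vdw_radius > 0
    atom_idx = np.nonzero(mask)[0]
    Lx, Ly = config.box[0], config.box[1]
    nx = max(int(round(Lx / mesh_spacing)), 1)
    ny = max(int(round(Ly / mesh_spacing)), 1)
    xs = np.arange(nx) * (Lx / nx)
    ys = np.arange(ny) * (Ly / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel()[:, None], gy.ravel()[:, None]
    s = 1.0 if side == "upper" else -1.0

    layer = np.zeros(config.n_molecules, dtype=int)
    active = np.ones(len(atom_idx), dtype=bool)
    for li in range(1, n_layers + 1):
        if not np.any(active):
            break
        sub = atom_idx[active]
        px, py, pz = (config.positions[sub, k][None, :] for k in range(3))
        reach = (config.vdw_radius[sub] + probe_radius)[None, :]
        dx = np.abs(gx - px)
        dx = np.minimum(dx, Lx - dx)
        dy = np.abs(gy - py)
        dy = np.minimum(dy, Ly - dy)
        d2 = dx * dx + dy * dy
        within = d2 < reach ** 2
        # bisect g(z) = (z - z_a)^2 + d2 - reach^2 on [z_a, z_a + s*reach]
        lo = np.broadcast_to(pz, d2.shape).copy()
        hi = pz + s * reach
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            g = (mid - pz) ** 2 + d2 - reach ** 2
            grow = g < 0          # still overlapping: move outward
            lo = np.where(grow, mid, lo)
            hi = np.where(grow, hi, mid)
        contact = 0.5 * (lo + hi)
        ordered = np.where(within, s * contact, -np.inf)
        best = ordered.max(axis=1)
        hit = np.isfinite(best)
        touched = np.unique(np.nonzero(
            within & hit[:, None] & (ordered >= best[:, None] - 1e-9))[1])
        if len(touched) == 0:
            break
        mols = np.unique(config.molecule_id[sub[touched]])
        layer[mols] = li
        active &= ~np.isin(config.molecule_id[atom_idx], mols)
    return layer


def itim_oracle_march(config, species=None, probe_radius=0.15,
                      mesh_spacing=0.1, n_layers=3, side="upper",
                      step=0.002):
    """Scalar marching probe descent (slow; tiny fixtures only)."""
    if species is None:
        mask = np.ones(config.n_atoms, dtype=bool)
    else:
        mask = config.species_label == species
    mask &= config.vdw_radius > 0
    atom_idx = list(np.nonzero(mask)[0])
    Lx, Ly, Lz = config.box
    nx = max(int(round(Lx / mesh_spacing)), 1)
    ny = max(int(round(Ly / mesh_spacing)), 1)
    s = 1.0 if side == "upper" else -1.0
    layer = np.zeros(config.n_molecules, dtype=int)
    active = set(atom_idx)
    for li in range(1, n_layers + 1):
        if not active:
            break
        touched_mols = set()
        sub = sorted(active)
        for ix in range(nx):
            for iy in range(ny):
                x = ix * Lx / nx
                y = iy * Ly / ny
                zs = [config.positions[a, 2] for a in sub]
                reach = [config.vdw_radius[a] + probe_radius for a in sub]
                z = (max(z0 + r for z0, r in zip(zs, reach)) + 0.05 if s > 0
                     else min(z0 - r for z0, r in zip(zs, reach)) - 0.05)

                def overlapping(zp):
                    hits = []
                    for a, r in zip(sub, reach):
                        d2 = _lateral_d2_images(
                            x, y, config.positions[a, 0],
                            config.positions[a, 1], Lx, Ly)
                        dz = zp - config.positions[a, 2]
                        if d2 + dz * dz < r * r:
                            hits.append(a)
                    return hits

                prev = z
                found = None
                for _ in range(int(2 * Lz / step)):
                    z -= s * step
                    if overlapping(z):
                        found = (prev, z)
                        break
                    prev = z
                if found is None:
                    continue
                free, over = found
                for _ in range(50):
                    mid = 0.5 * (free + over)
                    if overlapping(mid):
                        over = mid
                    else:
                        free = mid
                contact = 0.5 * (free + over)
                for a, r in zip(sub, reach):
                    d2 = _lateral_d2_images(x, y, config.positions[a, 0],
                                            config.positions[a, 1], Lx, Ly)
                    dz = contact - config.positions[a, 2]
                    if d2 + dz * dz <= (r + 1e-7) ** 2:
                        touched_mols.add(int(config.molecule_id[a]))
        if not touched_mols:
            break
        for m in touched_mols:
            layer[m] = li
        active = {a for a in active
                  if int(config.molecule_id[a]) not in touched_mols}
    return layer
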