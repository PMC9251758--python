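"""Synthetic slab configurations with analytically known statistics.

The generator emulates the one-body structure that the analysis stages
consume: rigid polar molecules confined between two walls, with a
prescribed density profile rho(z) and a prescribed orientational bias of
the molecular dipole.  Orientations follow the tilted distribution

    p(cos theta) ∝ exp(a(z) * cos theta),        azimuth uniform,

whose mean is the Langevin function L(a) = coth(a) - 1/a, so every
planted profile has a closed form: P1(z) = rho(z) |mu| L(a(z)) and the
interfacial potential of each wall follows by quadrature.  The planted
truth is returned alongside the frames and is the oracle for the
pipeline tests.

Sampling is stratified rather than i.i.d.: z positions use one stratum
per molecule (inverse CDF of rho), and within each z stratum the three
orientation uniforms (cos theta, azimuth, spin) are Latin-hypercube
stratified across frames.  Marginals are exactly the planted law;
ensemble averages converge at the stratified rate, which is what makes
planted-truth recovery tests decisive at desk scale.  Frames are
deterministic functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .config_io import MolecularConfiguration, SystemDescriptor
from .constants import EPS0


# ----------------------------------------------------------------------
# molecule templates
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid molecule in its body frame: dipole along +z, center at origin."""

    species: str
    atom_names: tuple
    positions: np.ndarray      # (n, 3) nm, center atom at origin
    charges: tuple             # e
    vdw_radii: tuple           # nm
    center_atom: str

    @property
    def dipole_magnitude(self) -> float:
        mu = np.asarray(self.charges) @ self.positions
        return float(np.linalg.norm(mu))


def spc_water_template() -> MoleculeTemplate:
    """Three-site water: O (sole vdW site) at the origin, dipole +z.

    Geometry r(OH) = 0.1 nm, HOH angle 109.47 deg, charges
    q_O = -0.82 e, q_H = +0.41 e; |mu| = 0.047343 e nm.
    """
    half = math.radians(109.47 / 2.0)
    s, c = math.sin(half), math.cos(half)
    pos = np.array([[0.0, 0.0, 0.0],
                    [0.1 * s, 0.0, 0.1 * c],
                    [-0.1 * s, 0.0, 0.1 * c]])
    return MoleculeTemplate(
        species="SOL",
        atom_names=("OW", "HW1", "HW2"),
        positions=pos,
        charges=(-0.82, 0.41, 0.41),
        vdw_radii=(0.1583, 0.0, 0.0),
        center_atom="OW",
    )


def dmso_like_template() -> MoleculeTemplate:
    """Four-site polar molecule with the opposite charge-shape asymmetry.

    The negative site (O-like) sits on the -z side so the dipole points
    +z, letting scenarios with a positive zero-charge potential be
    planted.  Multi-site: the molecular center must be named explicitly
    when a single center is required.
    """
    pos = np.array([[0.0, 0.0, 0.0],        # S-like center
                    [0.0, 0.0, -0.153],     # O-like
                    [0.13, 0.0, 0.08],      # C-like
                    [-0.13, 0.0, 0.08]])
    return MoleculeTemplate(
        species="DMS",
        atom_names=("S1", "O1", "C1", "C2"),
        positions=pos,
        charges=(0.54, -0.54, 0.0, 0.0),
        vdw_radii=(0.178, 0.148, 0.197, 0.197),
        center_atom="S1",
    )


def template_topology(templates, molecules=None, box=None) -> dict:
    """Topology sidecar dict for configurations built from templates."""
    top = {"slabpol_topology": 1, "species": []}
    for t in templates:
        top["species"].append({
            "name": t.species,
            "atoms": [{"name": n, "charge": float(q), "vdw_radius": float(r)}
                      for n, q, r in zip(t.atom_names, t.charges, t.vdw_radii)],
            "center_atom": t.center_atom,
        })
    if molecules is not None:
        top["molecules"] = [{"species": s, "count": int(c)} for s, c in molecules]
    if box is not None:
        top["box"] = [float(b) for b in box]
    return top


# ----------------------------------------------------------------------
# bias profiles and the tilted-cosine law
# ----------------------------------------------------------------------

def langevin(a):
    """L(a) = coth(a) - 1/a, the mean of cos(theta) under exp(a cos)."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = np.abs(a) < 1e-6
    out[small] = a[small] / 3.0           # series: a/3 - a^3/45 + ...
    x = a[~small]
    out[~small] = 1.0 / np.tanh(x) - 1.0 / x
    return out if out.ndim else float(out)


def sample_tilted_cos(u, a):
    """Inverse CDF of p(c) ∝ exp(a c) on [-1, 1]; u uniform in (0, 1)."""
    u = np.asarray(u, dtype=float)
    a = np.broadcast_to(np.asarray(a, dtype=float), u.shape)
    out = np.empty_like(u)
    small = np.abs(a) < 1e-8
    out[small] = 2.0 * u[small] - 1.0
    x = a[~small]
    # c = ln(e^{-a} + u (e^{a} - e^{-a})) / a, computed stably
    out[~small] = np.log(np.exp(-x) + u[~small] * (np.exp(x) - np.exp(-x))) / x
    return np.clip(out, -1.0, 1.0)


@dataclass(frozen=True)
class BiasLayer:
    """Constant Langevin bias ``a`` on the z interval [z_min, z_max)."""

    z_min: float
    z_max: float
    a: float


def bias_value(z, layers) -> np.ndarray:
    """Evaluate a piecewise-constant bias profile (0 outside all layers)."""
    z = np.asarray(z, dtype=float)
    a = np.zeros_like(z)
    for layer in layers:
        a = np.where((z >= layer.z_min) & (z < layer.z_max), layer.a, a)
    return a


def wall_layer_bias(a: float, width: float, z_lo: float, z_hi: float,
                    wall: str = "right") -> list:
    """Bias layer of the given width adjacent to one wall of the liquid."""
    if wall == "right":
        return [BiasLayer(z_hi - width, z_hi, a)]
    return [BiasLayer(z_lo, z_lo + width, a)]


# ----------------------------------------------------------------------
# planted truth
# ----------------------------------------------------------------------

@dataclass
class PlantedTruth:
    """Analytic one-body fields of a generated system."""

    z: np.ndarray              # fine grid, nm
    rho: np.ndarray            # nm^-3
    a: np.ndarray              # Langevin bias on the grid
    P1: np.ndarray             # e nm^-2
    mu_magnitude: float        # e nm
    z_liquid: tuple            # (z_lo, z_hi)
    z_mid: float
    phi0: dict                 # {"left": V, "right": V}
    sigma: float = 0.0                   # capacitor charge (left wall), e/nm^2
    epsilon_target: float | None = None  # for linear-response capacitors
    phi_int: float | None = None         # 0 by construction when planted
    planes: dict = field(default_factory=dict)   # rough-surface planes, nm

    def to_dict(self) -> dict:
        return {
            "z": self.z.tolist(), "rho": self.rho.tolist(),
            "a": self.a.tolist(), "P1": self.P1.tolist(),
            "mu_magnitude": self.mu_magnitude,
            "z_liquid": list(self.z_liquid), "z_mid": self.z_mid,
            "phi0": self.phi0, "sigma": self.sigma,
            "epsilon_target": self.epsilon_target, "phi_int": self.phi_int,
            "planes": self.planes,
        }


def _truth_from_fields(zgrid, rho, a, mu_mag, z_lo, z_hi) -> PlantedTruth:
    P1 = rho * mu_mag * langevin(a)
    z_mid = 0.5 * (z_lo + z_hi)
    # signed integrals from the midplane toward each wall
    right = (zgrid >= z_mid)
    left = (zgrid <= z_mid)
    phi_right = np.trapezoid(P1[right], zgrid[right]) / EPS0
    phi_left = -np.trapezoid(P1[left], zgrid[left]) / EPS0
    return PlantedTruth(
        z=zgrid, rho=rho, a=a, P1=P1, mu_magnitude=mu_mag,
        z_liquid=(z_lo, z_hi), z_mid=z_mid,
        phi0={"left": float(phi_left), "right": float(phi_right)},
    )


# ----------------------------------------------------------------------
# slab specification and generation
# ----------------------------------------------------------------------

@dataclass
class SlabSpec:
    """Conditions for a synthetic slab of rigid polar molecules.

    ``density`` is the molecular number density (nm^-3); the liquid
    occupies [margin, margin + thickness] along z inside a box of height
    thickness + 2*margin.  ``bias_layers`` is a list of
    :class:`BiasLayer`; ``density_shape`` optionally modulates rho(z)
    (relative shape, normalised internally).  ``min_distance`` is the
    hard-overlap cutoff between molecular centers.
    """

    area: float = 4.0            # nm^2
    thickness: float = 4.0       # nm
    density: float = 33.0        # nm^-3
    n_frames: int = 200
    seed: int = 0
    template: MoleculeTemplate = field(default_factory=spc_water_template)
    bias_layers: list = field(default_factory=list)
    bias_func: object = None              # callable (x, y, z) -> a; overrides layers
    density_shape: object = None          # callable z -> relative rho
    margin: float = 0.5                    # nm of empty box beyond each wall
    min_distance: float = 0.22             # nm
    max_attempts: int = 100000

    @property
    def z_lo(self) -> float:
        return self.margin

    @property
    def z_hi(self) -> float:
        return self.margin + self.thickness

    @property
    def box(self) -> np.ndarray:
        L = math.sqrt(self.area)
        return np.array([L, L, self.thickness + 2 * self.margin])

    @property
    def n_molecules(self) -> int:
        return int(round(self.density * self.area * self.thickness))


@dataclass
class SlabResult:
    frames: list
    truth: PlantedTruth
    descriptor: SystemDescriptor
    topology: dict


def _rotation_matrices(cos_t, phi, psi):
    """R = Rz(phi) Ry(theta) Rz(psi), vectorised; maps +z to the dipole axis."""
    ct = cos_t
    st = np.sqrt(np.clip(1.0 - ct * ct, 0.0, None))
    cp, sp = np.cos(phi), np.sin(phi)
    ck, sk = np.cos(psi), np.sin(psi)
    R = np.empty(cos_t.shape + (3, 3))
    R[..., 0, 0] = cp * ct * ck - sp * sk
    R[..., 0, 1] = -cp * ct * sk - sp * ck
    R[..., 0, 2] = cp * st
    R[..., 1, 0] = sp * ct * ck + cp * sk
    R[..., 1, 1] = -sp * ct * sk + cp * ck
    R[..., 1, 2] = sp * st
    R[..., 2, 0] = -st * ck
    R[..., 2, 1] = st * sk
    R[..., 2, 2] = ct
    return R


def _stratified_uniforms(rng, n_strata, n_frames):
    """(n_strata, n_frames) uniforms, Latin-hypercube across frames per stratum."""
    out = np.empty((n_strata, n_frames))
    for s in range(n_strata):
        perm = rng.permutation(n_frames)
        out[s] = (perm + rng.random(n_frames)) / n_frames
    return out


def _inverse_density_cdf(spec: SlabSpec, ngrid: int = 4001):
    """Fine grid of rho(z) and the inverse CDF for stratified z sampling."""
    z = np.linspace(spec.z_lo, spec.z_hi, ngrid)
    if spec.density_shape is None:
        shape = np.ones_like(z)
    else:
        shape = np.asarray(spec.density_shape(z), dtype=float)
        if np.any(shape < 0):
            raise ValueError("density_shape must be nonnegative")
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (shape[1:] + shape[:-1])
                                           * np.diff(z))])
    total = cdf[-1]
    rho = shape * (spec.n_molecules / (spec.area * total))
    cdf /= total

    def inv(u):
        return np.interp(u, cdf, z)

    return z, rho, inv


def _place_frame(rng, zs, spec: SlabSpec, blockers=None, allow_drop=False):
    """Place molecules laterally with hard-overlap rejection.

    ``zs`` are the (sorted) z coordinates for this frame.  Returns
    (positions (m,3), kept stratum indices).  Rejection redraws x,y only,
    preserving the z marginal; ``blockers`` are frozen atom positions
    (rough surfaces) included in the overlap test.
    """
    L = math.sqrt(spec.area)
    d2 = spec.min_distance ** 2
    n = len(zs)
    placed = np.empty((n, 3))
    kept = []
    if blockers is not None and len(blockers):
        b_order = np.argsort(blockers[:, 2])
        b_sorted = blockers[b_order]
        bz = b_sorted[:, 2]
    else:
        b_sorted = None
    budget = spec.max_attempts
    m = 0
    for s in range(n):
        z = zs[s]
        # liquid neighbours in z reach (placed list is z-sorted)
        j0 = np.searchsorted(placed[:m, 2], z - spec.min_distance)
        near = placed[j0:m]
        if b_sorted is not None:
            k0 = np.searchsorted(bz, z - spec.min_distance)
            k1 = np.searchsorted(bz, z + spec.min_distance)
            bnear = b_sorted[k0:k1]
        else:
            bnear = None
        ok = False
        attempts = 0
        cap = 2000 if allow_drop else budget
        while attempts < cap:
            attempts += 1
            x = rng.random() * L
            y = rng.random() * L
            ok = True
            for arr in (near, bnear):
                if arr is None or not len(arr):
                    continue
                dx = np.abs(arr[:, 0] - x)
                dy = np.abs(arr[:, 1] - y)
                dx = np.minimum(dx, L - dx)
                dy = np.minimum(dy, L - dy)
                dz = arr[:, 2] - z
                if np.any(dx * dx + dy * dy + dz * dz < d2):
                    ok = False
                    break
            if ok:
                break
        if ok:
            placed[m] = (x, y, z)
            kept.append(s)
            m += 1
        elif not allow_drop:
            raise RuntimeError(
                f"density too high to place molecule without overlap in "
                f"{cap} attempts (z = {z:.3f} nm)"
            )
    return placed[:m], np.array(kept, dtype=int)


def generate_slab(spec: SlabSpec, *, _blockers=None, _surface_atoms=None,
                  _allow_drop=False) -> SlabResult:
    """Generate frames plus planted truth for a slab specification.

    The private hooks are used by the rough-surface generator to merge
    frozen surface atoms into each frame.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.template
    N = spec.n_molecules
    F = spec.n_frames
    if N < 1:
        raise ValueError("spec yields no molecules")

    zgrid, rho_grid, inv_cdf = _inverse_density_cdf(spec)
    a_grid = bias_value(zgrid, spec.bias_layers)
    truth = _truth_from_fields(zgrid, rho_grid, a_grid, t.dipole_magnitude,
                               spec.z_lo, spec.z_hi)

    # stratified z per (stratum, frame); strata are u in [s/N, (s+1)/N)
    w = rng.random((N, F))
    z_all = inv_cdf((np.arange(N)[:, None] + w) / N)
    # Latin-hypercube orientation uniforms per stratum across frames
    u_cos = _stratified_uniforms(rng, N, F)
    u_phi = _stratified_uniforms(rng, N, F)
    u_psi = _stratified_uniforms(rng, N, F)

    nat = len(t.atom_names)
    frames = []
    for f in range(F):
        centers, kept = _place_frame(rng, z_all[:, f], spec,
                                     blockers=_blockers, allow_drop=_allow_drop)
        if spec.bias_func is not None:
            # planted truth then lives in the function, not in the grids
            a_mol = spec.bias_func(centers[:, 0], centers[:, 1], centers[:, 2])
        else:
            a_mol = bias_value(centers[:, 2], spec.bias_layers)
        cos_t = sample_tilted_cos(u_cos[kept, f], a_mol)
        phi = 2.0 * np.pi * u_phi[kept, f]
        psi = 2.0 * np.pi * u_psi[kept, f]
        R = _rotation_matrices(cos_t, phi, psi)
        # atoms: center + R @ template
        pos = (R[:, None, :, :] @ t.positions[None, :, :, None])[..., 0]
        pos = pos + centers[:, None, :]
        m = len(kept)
        positions = pos.reshape(m * nat, 3)
        charges = np.tile(t.charges, m)
        radii = np.tile(t.vdw_radii, m)
        names = np.tile(np.array(t.atom_names, dtype=object), m)
        mol_id = np.repeat(np.arange(m), nat)
        species = np.full(m * nat, t.species, dtype=object)
        if _surface_atoms is not None:
            # frozen surface first: its atom indices are frame-invariant
            # even when liquid placement drops differ between frames
            sp, sq, sr, sn, sm, ss = _surface_atoms
            n_surf_mol = int(sm.max()) + 1 if len(sm) else 0
            positions = np.vstack([sp, positions])
            charges = np.concatenate([sq, charges])
            radii = np.concatenate([sr, radii])
            names = np.concatenate([sn, names])
            mol_id = np.concatenate([sm, mol_id + n_surf_mol])
            species = np.concatenate([ss, species])
        frames.append(MolecularConfiguration(
            positions=positions, charges=charges, molecule_id=mol_id,
            species_label=species, atom_names=names, box=spec.box.copy(),
            vdw_radius=radii, frame_index=f,
        ))

    descriptor = SystemDescriptor(
        normal_axis="z",
        wall_positions=(spec.z_lo, spec.z_hi),
        wall_mode={"left": "flat", "right": "flat"},
        sigma={"left": 0.0, "right": 0.0},
        liquid_species=[t.species],
    )
    topology = template_topology([t], molecules=[(t.species, N)],
                                 box=spec.box)
    return SlabResult(frames=frames, truth=truth, descriptor=descriptor,
                      topology=topology)


# ----------------------------------------------------------------------
# linear-response capacitor
# ----------------------------------------------------------------------

def generate_capacitor_linear_response(spec: SlabSpec, sigma: float,
                                       epsilon_target: float) -> SlabResult:
    """Slab mimicking a uniform dielectric between charged walls.

    A spatially uniform bias a* is root-found so that the planted
    polarization equals the continuum value sigma (eps-1)/eps of a
    capacitor whose left plate carries +sigma.  The excess interfacial
    potential of such a system is zero by construction.
    """
    if sigma == 0:
        raise ValueError("sigma must be nonzero; use generate_slab for sigma = 0")
    if epsilon_target < 1:
        raise ValueError("epsilon_target must be >= 1")
    t = spec.template
    rho = spec.n_molecules / (spec.area * spec.thickness)
    target = sigma * (epsilon_target - 1.0) / epsilon_target
    saturation = rho * t.dipole_magnitude
    if abs(target) >= saturation:
        raise ValueError(
            f"requested polarization {target:.4g} e/nm^2 exceeds the "
            f"saturation value {saturation:.4g} e/nm^2"
        )
    if epsilon_target == 1.0 or target == 0.0:
        a_star = 0.0
    else:
        def resid(a):
            return rho * t.dipole_magnitude * langevin(a) - target
        lim = 700.0
        a_star = brentq(resid, -lim, lim, xtol=1e-14)

    layers = [BiasLayer(spec.z_lo, spec.z_hi + 1e-9, a_star)]
    result = generate_slab(replace(spec, bias_layers=layers))
    result.descriptor.sigma = {"left": float(sigma), "right": float(-sigma)}
    result.truth.sigma = float(sigma)
    result.truth.epsilon_target = float(epsilon_target)
    result.truth.phi_int = 0.0
    return result


# ----------------------------------------------------------------------
# rough decorated surfaces
# ----------------------------------------------------------------------

@dataclass
class RoughSurfaceSpec:
    """Frozen rough wall at the top of the box, decorated with OH groups.

    The surface is a lattice of frozen base atoms at
    z = z_surface + height(x, y), with hydroxyl-bearing groups
    (silanol-like or carboxyl-like O-H) pointing down into the liquid at
    randomly chosen sites.  A ``deprotonated_fraction`` of the groups
    lose their H and carry a discrete -1 e charge, realising a surface
    charge density sigma = -(deprotonated count)/area.
    """

    slab: SlabSpec = field(default_factory=SlabSpec)
    z_surface: float = None            # mean base height; default: slab z_hi
    amplitude: float = 0.15            # nm
    wavelength: float = 2.0            # nm (sinusoid); ignored for flat
    height_kind: str = "sinusoid"      # sinusoid | flat | noise
    lattice_spacing: float = 0.3       # nm
    group_density: float = 0.0         # groups per nm^2
    group_kind: str = "silanol"        # silanol | carboxyl
    deprotonated_fraction: float = 0.0
    surface_bias: float = 0.0          # Langevin bias within the first band
    surface_bias_width: float = 0.3    # nm below the local accessible ceiling
    seed: int = 1

    def __post_init__(self):
        if self.z_surface is None:
            self.z_surface = self.slab.z_hi
        if self.amplitude >= self.slab.thickness / 4:
            raise ValueError("amplitude must be below slab thickness / 4")


@dataclass
class RoughSurfaceResult(SlabResult):
    sigma_realized: float = 0.0
    surface_heights: np.ndarray = None      # base atom z per lattice site
    surface_xy: np.ndarray = None


def _surface_height(sspec: RoughSurfaceSpec, x, y, rng):
    if sspec.height_kind == "flat" or sspec.amplitude == 0:
        return np.zeros_like(x)
    if sspec.height_kind == "sinusoid":
        return sspec.amplitude * np.sin(2 * np.pi * x / sspec.wavelength)
    if sspec.height_kind == "noise":
        # few-mode random Fourier surface, periodic in the box
        L = math.sqrt(sspec.slab.area)
        h = np.zeros_like(x)
        for _ in range(4):
            kx, ky = rng.integers(1, 4, size=2)
            ph = rng.random() * 2 * np.pi
            h += np.cos(2 * np.pi * (kx * x + ky * y) / L + ph)
        h *= sspec.amplitude / max(np.max(np.abs(h)), 1e-12)
        return h
    raise ValueError(f"unknown height_kind {sspec.height_kind!r}")


def generate_rough_decorated_surface(sspec: RoughSurfaceSpec) -> RoughSurfaceResult:
    """Frozen decorated surface at the top of the box plus solvent below."""
    rng = np.random.default_rng(sspec.seed)
    slab = sspec.slab
    L = math.sqrt(slab.area)
    nside = max(int(round(L / sspec.lattice_spacing)), 1)
    xs = (np.arange(nside) + 0.5) * (L / nside)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    heights = sspec.z_surface + _surface_height(sspec, gx, gy, rng)

    n_sites = len(gx)
    n_groups = int(round(sspec.group_density * slab.area))
    if n_groups > n_sites:
        raise ValueError("group density exceeds lattice site density")
    group_sites = rng.choice(n_sites, size=n_groups, replace=False)
    n_deprot = int(round(sspec.deprotonated_fraction * n_groups))
    deprot = set(group_sites[:n_deprot].tolist())
    group_set = set(group_sites.tolist())
    sigma_realized = -n_deprot / slab.area

    pos, q, r, names, mol, species = [], [], [], [], [], []
    m = 0
    for i in range(n_sites):
        base = [gx[i], gy[i], heights[i]]
        if i in group_set:
            o = [gx[i], gy[i], heights[i] - 0.15]
            if i in deprot:
                pos += [base, o]
                q += [0.0, -1.0]
                r += [0.17, 0.152]
                names += ["SI", "OD"]
                mol += [m, m]
                species += ["SOM", "SOM"]
            else:
                h = [gx[i], gy[i], heights[i] - 0.25]
                pos += [base, o, h]
                q += [0.0, -0.41, 0.41]
                r += [0.17, 0.152, 0.0]
                names += ["SI", "OH", "HO"]
                mol += [m, m, m]
                species += ["SOH", "SOH", "SOH"]
        else:
            pos += [base]
            q += [0.0]
            r += [0.17]
            names += ["SI"]
            mol += [m]
            species += ["WAL"]
        m += 1
    surf_pos = np.array(pos)
    surf_r = np.array(r)
    surface = (surf_pos, np.array(q), surf_r,
               np.array(names, dtype=object), np.array(mol, dtype=int),
               np.array(species, dtype=object))
    # only vdW-carrying surface atoms exclude solvent centers (H sites
    # are bondable, not excluding)
    block_pos = surf_pos[surf_r > 0]

    # accessible ceiling for liquid centers under the surface atoms
    ngrid = 80
    cx = (np.arange(ngrid) + 0.5) * (L / ngrid)
    cgx, cgy = np.meshgrid(cx, cx, indexing="ij")
    ceil = np.full(cgx.shape, slab.z_hi)
    d = slab.min_distance
    for p in block_pos:
        dx = np.abs(cgx - p[0]); dx = np.minimum(dx, L - dx)
        dy = np.abs(cgy - p[1]); dy = np.minimum(dy, L - dy)
        d2 = dx * dx + dy * dy
        reach = d2 < d * d
        ceil[reach] = np.minimum(ceil[reach],
                                 p[2] - np.sqrt(d * d - d2[reach]))
    z_s_true = float(np.max(ceil))
    z_int_true = float(np.min(ceil))

    # liquid occupies up to the highest accessible point; an optional
    # surface-relative orientational bias is planted within a band below
    # the local accessible ceiling (the rough analogue of a wall layer)
    bias_func = None
    if sspec.surface_bias != 0.0:
        cell = L / ngrid

        def bias_func(x, y, z, _ceil=ceil, _cell=cell, _n=ngrid,
                      _a=sspec.surface_bias, _w=sspec.surface_bias_width,
                      _layers=slab.bias_layers):
            i = np.mod((np.asarray(x) / _cell).astype(int), _n)
            j = np.mod((np.asarray(y) / _cell).astype(int), _n)
            local = _ceil[i, j]
            base = bias_value(z, _layers)
            return np.where(local - z < _w, _a, base)

    liquid_spec = replace(
        slab, thickness=z_s_true - slab.z_lo, seed=slab.seed,
        bias_func=bias_func,
    )
    result = generate_slab(liquid_spec, _blockers=block_pos,
                           _surface_atoms=surface, _allow_drop=True)
    result.truth.planes = {"z_int": z_int_true, "z_s": z_s_true,
                           "surface_min": float(np.min(heights)),
                           "surface_max": float(np.max(heights))}

    # surface-group atom inventory (indices into each frame's atom arrays;
    # surface atoms sit after the liquid block, whose size varies by frame)
    def group_indices(cfg):
        donors_H, donors_heavy, acceptors = [], [], []
        base = np.nonzero(np.isin(cfg.species_label, ("SOH", "SOM")))[0]
        for i in base:
            nm = cfg.atom_names[i]
            if nm == "HO":
                donors_H.append(int(i))
            elif nm == "OH":
                donors_heavy.append(int(i))
                acceptors.append(int(i))
            elif nm == "OD":
                acceptors.append(int(i))
        return {"donor_H": donors_H, "donor_heavy": donors_heavy,
                "acceptor_heavy": acceptors}

    descriptor = SystemDescriptor(
        normal_axis="z",
        wall_positions=(slab.z_lo, sspec.z_surface),
        wall_mode={"left": "flat", "right": "rough"},
        sigma={"left": -sigma_realized, "right": sigma_realized},
        surface_group_atoms={"right": group_indices(result.frames[0])},
        liquid_species=[slab.template.species],
    )
    result.descriptor = descriptor
    top = result.topology
    for sp_name, atoms in [
        ("WAL", [{"name": "SI", "charge": 0.0, "vdw_radius": 0.17}]),
        ("SOH", [{"name": "SI", "charge": 0.0, "vdw_radius": 0.17},
                 {"name": "OH", "charge": -0.41, "vdw_radius": 0.152},
                 {"name": "HO", "charge": 0.41, "vdw_radius": 0.0}]),
        ("SOM", [{"name": "SI", "charge": 0.0, "vdw_radius": 0.17},
                 {"name": "OD", "charge": -1.0, "vdw_radius": 0.152}]),
    ]:
        top["species"].append({"name": sp_name, "atoms": atoms})
    return RoughSurfaceResult(
        frames=result.frames, truth=result.truth, descriptor=descriptor,
        topology=top, sigma_realized=sigma_realized,
        surface_heights=heights, surface_xy=np.column_stack([gx, gy]),
    )


# ----------------------------------------------------------------------
# hydrogen-bond fixtures
# ----------------------------------------------------------------------

@dataclass
class HBondFixture:
    name: str
    config: MolecularConfiguration
    descriptor: SystemDescriptor | None
    expect_bond: bool
    expect_category: str | None      # water_water | type1 | type2 | None


def _geometry_points(distance: float, angle_deg: float):
    """Donor-heavy at origin, H on +x; acceptor at the prescribed
    donor-acceptor distance with the prescribed donor-H-acceptor angle."""
    r_dh = 0.1
    beta = math.radians(180.0 - angle_deg)
    cb, sb = math.cos(beta), math.sin(beta)
    # |D A|^2 = |DH + t v|^2 = d^2  with v = (cb, sb, 0)
    t = -r_dh * cb + math.sqrt(r_dh * r_dh * cb * cb - r_dh * r_dh
                               + distance * distance)
    D = np.zeros(3)
    H = np.array([r_dh, 0.0, 0.0])
    A = H + t * np.array([cb, sb, 0.0])
    return D, H, A


def _water_at(o_pos, h1_pos, box_center):
    """Water with O at o_pos, one H at h1_pos, second H placed arbitrarily."""
    d1 = h1_pos - o_pos
    d1 /= np.linalg.norm(d1)
    # any unit vector at the HOH angle from d1
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d1 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(d1, ref)
    perp /= np.linalg.norm(perp)
    ang = math.radians(109.47)
    d2 = math.cos(ang) * d1 + math.sin(ang) * perp
    return np.array([o_pos, o_pos + 0.1 * d1, o_pos + 0.1 * d2])


def _dimer_config(distance, angle_deg):
    D, H, A = _geometry_points(distance, angle_deg)
    shift = np.array([2.0, 2.0, 2.0])
    donor = _water_at(D + shift, H + shift, None)
    # acceptor water: H atoms pointing away from the donor
    away = (A - D) / np.linalg.norm(A - D)
    acc = _water_at(A + shift, A + shift + 0.1 * away, None)
    pos = np.vstack([donor, acc])
    return MolecularConfiguration(
        positions=pos,
        charges=np.tile([-0.82, 0.41, 0.41], 2),
        molecule_id=np.repeat([0, 1], 3),
        species_label=np.full(6, "SOL", dtype=object),
        atom_names=np.array(["OW", "HW1", "HW2"] * 2, dtype=object),
        box=np.array([6.0, 6.0, 6.0]),
        vdw_radius=np.tile([0.1583, 0.0, 0.0], 2),
    )


def _surface_fragment(kind: str):
    """Water + one surface hydroxyl group; kind selects who donates."""
    shift = np.array([2.0, 2.0, 2.0])
    if kind == "type1":
        # water donates to the surface O
        D, H, A = _geometry_points(0.28, 165.0)
        water = _water_at(D + shift, H + shift, None)
        o_surf = A + shift
        si = o_surf + np.array([0.0, 0.0, 0.16])
        h_surf = o_surf + np.array([0.0, 0.1, 0.0])   # points sideways
        pos = np.vstack([water, [si, o_surf, h_surf]])
        surf_names = ["SI", "OH", "HO"]
    else:
        # surface O-H donates to the water O
        D, H, A = _geometry_points(0.28, 165.0)
        o_surf = D + shift
        h_surf = H + shift
        si = o_surf + np.array([0.0, 0.0, 0.16])
        away = (A - D) / np.linalg.norm(A - D)
        water = _water_at(A + shift, A + shift + 0.1 * away, None)
        pos = np.vstack([water, [si, o_surf, h_surf]])
        surf_names = ["SI", "OH", "HO"]
    cfg = MolecularConfiguration(
        positions=pos,
        charges=np.array([-0.82, 0.41, 0.41, 0.0, -0.41, 0.41]),
        molecule_id=np.array([0, 0, 0, 1, 1, 1]),
        species_label=np.array(["SOL"] * 3 + ["SOH"] * 3, dtype=object),
        atom_names=np.array(["OW", "HW1", "HW2"] + surf_names, dtype=object),
        box=np.array([6.0, 6.0, 6.0]),
        vdw_radius=np.array([0.1583, 0.0, 0.0, 0.17, 0.152, 0.0]),
    )
    desc = SystemDescriptor(
        wall_positions=(0.0, 4.0),
        wall_mode={"left": "flat", "right": "rough"},
        surface_group_atoms={"right": {"donor_H": [5], "donor_heavy": [4],
                                       "acceptor_heavy": [4]}},
        liquid_species=["SOL"],
    )
    return cfg, desc


def hbond_fixtures() -> list:
    """Labelled dimers and surface fragments spanning both criteria
    boundaries, for exact classification tests."""
    fixtures = []
    cases = [
        (0.29, 160.0, True), (0.28, 170.0, True), (0.295, 151.0, True),
        (0.30, 160.0, False),    # distance at threshold: strict <
        (0.32, 170.0, False),
        (0.29, 150.0, False),    # angle at threshold: strict >
        (0.25, 140.0, False),
        (0.305, 149.0, False),
    ]
    for d, ang, expect in cases:
        fixtures.append(HBondFixture(
            name=f"dimer_d{d:.3f}_a{ang:.0f}",
            config=_dimer_config(d, ang),
            descriptor=None,
            expect_bond=expect,
            expect_category="water_water" if expect else None,
        ))
    for kind in ("type1", "type2"):
        cfg, desc = _surface_fragment(kind)
        fixtures.append(HBondFixture(
            name=f"surface_{kind}", config=cfg, descriptor=desc,
            expect_bond=True, expect_category=kind,
        ))
    return fixtures
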