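"""Identification of truly interfacial molecules (ITIM), from scratch.

Probe spheres of radius R descend along streamlines perpendicular to
the surface, one per node of a lateral grid.  A probe touches an atom
of vdW radius r when their centers are (r + R) apart; the first atom
touched on each streamline marks its molecule as interfacial.  All
molecules touched in a pass form layer 1; removing them and repeating
yields deeper layers.  Streamlines run from the empty side of the
analysed surface toward the liquid (``side="upper"``: descending -z
from above), so layer 1 is always the molecular layer closest to the
analysed wall or vapor gap.  Lateral periodic images are included via
the minimum-image convention; the algorithm contains no randomness.

The tangency heights of the layer-1 atoms define the instantaneous
molecular surface -- a height map over the same grid -- against which
intrinsic (roughness-free) profiles are measured.  The Gibbs dividing
surface (equimolar plane) of a density profile provides the absolute
reference for surface roughness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config_io import MolecularConfiguration
from .constants import ITIM_MESH_SPACING, ITIM_PROBE_RADIUS_WATER
from .profiles import AxialProfile

_TIE_TOL = 1e-9


@dataclass
class LayerAssignment:
    """Layer index per molecule: 1..n_layers, or 0 for not interfacial."""

    layer_index: np.ndarray       # (n_molecules,) int
    probe_radius: float
    mesh_spacing: float
    n_layers: int
    side: str
    species: str | None = None

    def molecules_in_layer(self, layer: int) -> np.ndarray:
        return np.nonzero(self.layer_index == layer)[0]


@dataclass
class SurfaceHeightMap:
    """Probe tangency height (probe-center z) over the lateral grid."""

    x_nodes: np.ndarray
    y_nodes: np.ndarray
    heights: np.ndarray           # (nx, ny), NaN marks a gap
    mesh_spacing: float
    probe_radius: float
    side: str
    reference: str = "absolute"   # absolute | gibbs_dividing
    box: np.ndarray = field(default=None)

    def filled(self) -> np.ndarray:
        """Heights with gaps filled by iterative neighbour averaging."""
        h = self.heights.copy()
        while np.any(np.isnan(h)):
            nanmask = np.isnan(h)
            acc = np.zeros_like(h)
            cnt = np.zeros_like(h)
            for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = np.roll(h, shift, axis=(0, 1))
                good = ~np.isnan(nb)
                acc[good] += nb[good]
                cnt[good] += 1
            fillable = nanmask & (cnt > 0)
            if not np.any(fillable):
                raise RuntimeError("height map is entirely empty")
            h[fillable] = acc[fillable] / cnt[fillable]
        return h

    def local_height(self, x, y) -> np.ndarray:
        """Height at the nearest grid node (gaps filled)."""
        h = self.filled()
        nx, ny = h.shape
        Lx = self.box[0]
        Ly = self.box[1]
        i = np.mod(np.rint(np.asarray(x) / self.mesh_spacing).astype(int), nx)
        j = np.mod(np.rint(np.asarray(y) / self.mesh_spacing).astype(int), ny)
        return h[i, j]

    def rereference(self, z_ref: float) -> "SurfaceHeightMap":
        return SurfaceHeightMap(
            x_nodes=self.x_nodes, y_nodes=self.y_nodes,
            heights=self.heights - z_ref, mesh_spacing=self.mesh_spacing,
            probe_radius=self.probe_radius, side=self.side,
            reference="gibbs_dividing", box=self.box,
        )

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.heights, delimiter="\t",
                   header=f"mesh_spacing={self.mesh_spacing} "
                          f"probe_radius={self.probe_radius} side={self.side}")

    def render(self, path) -> None:
        """Heat-map image of the height field."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(self.heights.T, origin="lower", cmap="viridis",
                       extent=[0, self.box[0], 0, self.box[1]])
        fig.colorbar(im, ax=ax, label="height / nm")
        ax.set_xlabel("x / nm")
        ax.set_ylabel("y / nm")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _grid_nodes(box, mesh_spacing):
    nx = max(int(round(box[0] / mesh_spacing)), 1)
    ny = max(int(round(box[1] / mesh_spacing)), 1)
    xs = (np.arange(nx)) * (box[0] / nx)
    ys = (np.arange(ny)) * (box[1] / ny)
    return xs, ys


def _touch_heights(xs, ys, pos, radii, probe, box, side, chunk=2048):
    """Per grid node: tangency height and first-touched atom index.

    Returns (heights (nx*ny,), atom_index (nx*ny,), tie_list) where
    heights are NaN when no atom is within lateral reach.  ``tie_list``
    holds extra atoms tying for first touch on some node.
    """
    s = 1.0 if side == "upper" else -1.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    n = len(gx)
    heights = np.full(n, np.nan)
    first = np.full(n, -1, dtype=int)
    reach = radii + probe
    ties = []
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        dx = np.abs(gx[sl, None] - pos[None, :, 0])
        dx = np.minimum(dx, box[0] - dx)
        dy = np.abs(gy[sl, None] - pos[None, :, 1])
        dy = np.minimum(dy, box[1] - dy)
        d2 = dx * dx + dy * dy
        within = d2 < reach[None, :] ** 2
        disc = np.where(within, reach[None, :] ** 2 - d2, np.nan)
        z_touch = pos[None, :, 2] + s * np.sqrt(disc)
        with np.errstate(invalid="ignore"):
            ordered = s * z_touch
            best = np.nanmax(np.where(within, ordered, -np.inf), axis=1)
        hit = np.isfinite(best)
        idx = np.argmax(np.where(within, ordered, -np.inf), axis=1)
        heights[sl] = np.where(hit, s * best, np.nan)
        first[sl] = np.where(hit, idx, -1)
        # ties within tolerance join the same layer
        tie_rows = np.nonzero(
            hit[:, None] & within
            & (ordered >= (best[:, None] - _TIE_TOL))
        )
        for r, a in zip(*tie_rows):
            if a != idx[r]:
                ties.append(a)
    return heights, first, ties


def _species_atoms(config, species):
    if species is None:
        mask = np.ones(config.n_atoms, dtype=bool)
    else:
        mask = config.species_label == species
    if not np.any(mask):
        raise ValueError(f"no atoms of species {species!r}")
    if config.vdw_radius is None:
        raise ValueError("vdW radii are required for ITIM")
    mask &= config.vdw_radius > 0
    if not np.any(mask):
        raise ValueError("no atoms with positive vdW radius")
    return np.nonzero(mask)[0]


def assign_itim_layers(config: MolecularConfiguration,
                       species: str | None = None,
                       probe_radius: float = ITIM_PROBE_RADIUS_WATER,
                       mesh_spacing: float = ITIM_MESH_SPACING,
                       n_layers: int = 4,
                       side: str = "upper") -> LayerAssignment:
    """Assign molecules of a species to interfacial layers 1..n_layers."""
    atom_idx = _species_atoms(config, species)
    xs, ys = _grid_nodes(config.box, mesh_spacing)
    layer = np.zeros(config.n_molecules, dtype=int)
    active = np.ones(len(atom_idx), dtype=bool)
    for li in range(1, n_layers + 1):
        if not np.any(active):
            break
        sub = atom_idx[active]
        heights, first, ties = _touch_heights(
            xs, ys, config.positions[sub], config.vdw_radius[sub],
            probe_radius, config.box, side)
        touched_atoms = set(first[first >= 0].tolist()) | set(ties)
        if not touched_atoms:
            break
        mols = np.unique(config.molecule_id[sub[list(touched_atoms)]])
        layer[mols] = li
        active &= ~np.isin(config.molecule_id[atom_idx], mols)
    return LayerAssignment(layer_index=layer, probe_radius=probe_radius,
                           mesh_spacing=mesh_spacing, n_layers=n_layers,
                           side=side, species=species)


def instantaneous_surface(config: MolecularConfiguration,
                          layers: LayerAssignment,
                          mesh_spacing: float | None = None,
                          ) -> SurfaceHeightMap:
    """Height map of probe tangency against the layer-1 molecules."""
    mesh = layers.mesh_spacing if mesh_spacing is None else mesh_spacing
    atom_idx = _species_atoms(config, layers.species)
    in_l1 = layers.layer_index[config.molecule_id[atom_idx]] == 1
    sub = atom_idx[in_l1]
    if len(sub) == 0:
        raise ValueError("no layer-1 molecules; assign layers first")
    xs, ys = _grid_nodes(config.box, mesh)
    heights, _, _ = _touch_heights(xs, ys, config.positions[sub],
                                   config.vdw_radius[sub],
                                   layers.probe_radius, config.box,
                                   layers.side)
    return SurfaceHeightMap(
        x_nodes=xs, y_nodes=ys,
        heights=heights.reshape(len(xs), len(ys)),
        mesh_spacing=config.box[0] / len(xs), probe_radius=layers.probe_radius,
        side=layers.side, box=config.box.copy(),
    )


def gibbs_dividing_surface(profile: AxialProfile, side: str = "upper") -> float:
    """Equimolar plane of a density profile that decays on ``side``.

    The bulk density is the mean over the central 25% of the occupied
    support; the equimolar plane z_G satisfies

        int_{z0}^{end} rho dz = rho_bulk * (z_G - z0)

    for a bulk point z0, balancing the missing density on the bulk side
    against the tail density on the vapor side.
    """
    z, rho = profile.z_centers, profile.values
    occ = np.nonzero(rho > 1e-4 * np.max(rho))[0]
    if len(occ) < 4:
        raise ValueError("no bulk plateau detectable")
    i_lo, i_hi = occ[0], occ[-1]
    span = i_hi - i_lo + 1
    c0 = i_lo + int(span * 0.375)
    c1 = i_lo + int(span * 0.625)
    plateau = rho[c0:c1 + 1]
    rho_b = float(np.mean(plateau))
    if rho_b <= 0 or np.std(plateau) > 0.25 * rho_b:
        raise ValueError("no bulk plateau detectable")
    mid = (c0 + c1) // 2
    w = profile.bin_width
    # bins as boxes of width w (midpoint rule, exact for linear decay)
    if side == "upper":
        edge = z[mid] - w / 2
        mass = float(np.sum(rho[mid:]) * w)
        return float(edge + mass / rho_b)
    edge = z[mid] + w / 2
    mass = float(np.sum(rho[:mid + 1]) * w)
    return float(edge - mass / rho_b)


def surface_roughness(height_map: SurfaceHeightMap, z_ref: float) -> float:
    """RMS deviation of the instantaneous surface from a reference plane."""
    h = height_map.heights
    valid = np.isfinite(h)
    if not np.any(valid):
        raise ValueError("height map is empty")
    return float(np.sqrt(np.mean((h[valid] - z_ref) ** 2)))


def intrinsic_profile(frames: list, surface_maps: list,
                      moments: list, quantity: str = "density",
                      layers_list: list | None = None,
                      layer: int | None = None,
                      bin_width: float = 0.05,
                      xi_range: tuple = (-3.0, 1.0)) -> AxialProfile:
    """Profile of density or mu_z against distance from the local surface.

    The intrinsic coordinate is xi = s (z_mol - h(x, y)), with s = +1
    for an upper surface: xi = 0 on the instantaneous surface and
    xi < 0 inside the liquid, effectively removing surface roughness.
    ``layer`` restricts to molecules of one ITIM layer (None = all of
    the analysed species).
    """
    if len(frames) != len(surface_maps) or len(frames) != len(moments):
        raise ValueError("frames, surface_maps and moments must align")
    lo = np.floor(xi_range[0] / bin_width) * bin_width
    hi = np.ceil(xi_range[1] / bin_width) * bin_width
    n_bins = int(round((hi - lo) / bin_width))
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    counts = np.zeros(n_bins)
    weights = np.zeros(n_bins)
    area = float(frames[0].box[0] * frames[0].box[1])
    for k, (cfg, smap, mom) in enumerate(zip(frames, surface_maps, moments)):
        s = 1.0 if smap.side == "upper" else -1.0
        sel = np.ones(len(mom), dtype=bool)
        if layers_list is not None:
            la = layers_list[k]
            if la.species is not None:
                sel &= (mom.species == la.species)
            if layer is not None:
                sel &= (la.layer_index == layer)
        idx = np.nonzero(sel)[0]
        c = mom.centers[idx]
        h = smap.local_height(c[:, 0], c[:, 1])
        xi = s * (c[:, 2] - h)
        inside = (xi >= lo) & (xi < hi)
        b = ((xi[inside] - lo) / bin_width).astype(int)
        counts += np.bincount(b, minlength=n_bins)
        if quantity == "mu_z":
            weights += np.bincount(b, weights=mom.mu[idx, 2][inside],
                                   minlength=n_bins)
    if quantity == "density":
        values = counts / (area * bin_width * len(frames))
        kind = "density"
    elif quantity == "mu_z":
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, weights / np.maximum(counts, 1), 0.0)
        kind = "mu_z"
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return AxialProfile(kind, centers, values, bin_width, len(frames), area)
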