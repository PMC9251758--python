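"""Geometric hydrogen-bond detection and interfacial orientation statistics.

A hydrogen bond is declared when the donor-heavy to acceptor-heavy
distance is below 0.3 nm (strict) and the donor-H...acceptor angle,
measured at the H atom, exceeds 150 degrees (strict).  Bonds involving
frozen surface groups carry the amphoteric taxonomy of hydroxylated
surfaces: *type 1* when the surface oxygen accepts (including weak
bridge-oxygen acceptors) and *type 2* when the surface group donates;
the two types bias interfacial solvent dipoles in opposite directions.

Orientation statistics per ITIM layer report the angle

    theta' = arccos(<mu_hat> . n_z)

between the raw (unrenormalised) mean unit dipole of the layer and the
surface normal pointing toward the analysed wall, optionally split by
hydrogen-bond role (donor / acceptor), together with the mean number of
hydrogen bonds per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config_io import MolecularConfiguration, Moments, SystemDescriptor
from .constants import HBOND_ANGLE_DEG, HBOND_DISTANCE_NM


@dataclass
class HydrogenBond:
    donor_heavy: int
    donor_H: int
    acceptor_heavy: int
    distance: float          # nm, heavy-heavy
    angle: float             # degrees at H
    donor_molecule: int
    acceptor_molecule: int
    category: str = "water_water"


@dataclass
class OrientationStats:
    layer: int
    theta_prime: float                    # degrees
    mean_unit_dipole: np.ndarray
    n_hb_per_molecule: float
    theta_prime_donor: float = float("nan")
    theta_prime_acceptor: float = float("nan")
    n_molecules: int = 0


def enumerate_donors_acceptors(config: MolecularConfiguration,
                               descriptor: SystemDescriptor | None = None,
                               species: str | None = None):
    """Donor (heavy, H) pairs and acceptor heavy atoms.

    Liquid molecules contribute every H (name starting with 'H') paired
    with the nearest heavy atom of the same molecule, and every
    negatively charged heavy atom as an acceptor.  Surface groups come
    from the descriptor's per-wall inventory.
    """
    donors = []
    acceptors = []
    liquid = None
    if descriptor is not None and descriptor.liquid_species:
        liquid = set(descriptor.liquid_species)
    for idx in config.molecule_slices():
        sp = config.species_label[idx[0]]
        if species is not None and sp != species:
            continue
        if liquid is not None and sp not in liquid:
            continue
        names = [str(n) for n in config.atom_names[idx]]
        heavy = [i for i, n in zip(idx, names) if not n.startswith("H")]
        if not heavy:
            continue
        hpos = config.positions[heavy]
        for i, n in zip(idx, names):
            if n.startswith("H"):
                d = np.linalg.norm(hpos - config.positions[i], axis=1)
                donors.append((heavy[int(np.argmin(d))], int(i)))
        for i in heavy:
            if config.charges[i] < 0:
                acceptors.append(int(i))
    if descriptor is not None:
        for wall_groups in descriptor.surface_group_atoms.values():
            for hh, h in zip(wall_groups.get("donor_heavy", []),
                             wall_groups.get("donor_H", [])):
                donors.append((int(hh), int(h)))
            acceptors.extend(int(a) for a in wall_groups.get("acceptor_heavy", []))
    return np.array(donors, dtype=int).reshape(-1, 2), np.array(acceptors, dtype=int)


def _min_image(d, box):
    return d - box * np.round(d / box)


def detect_hydrogen_bonds(config: MolecularConfiguration,
                          donors: np.ndarray, acceptors: np.ndarray,
                          distance_cut: float = HBOND_DISTANCE_NM,
                          angle_cut: float = HBOND_ANGLE_DEG) -> list:
    """All donor/acceptor pairs meeting both geometric criteria."""
    if len(donors):
        names = config.atom_names
        dh = config.positions[donors[:, 0]]
        hh = config.positions[donors[:, 1]]
        bond_len = np.linalg.norm(_min_image(hh - dh, config.box), axis=1)
        if np.any(bond_len > 0.15):
            i = int(np.argmax(bond_len))
            raise ValueError(
                f"donor H {donors[i, 1]} ({names[donors[i, 1]]}) is "
                f"{bond_len[i]:.2f} nm from its heavy atom -- not bonded"
            )
    bonds = []
    if not len(donors) or not len(acceptors):
        return bonds
    apos = config.positions[acceptors]
    box = config.box
    dmol = config.molecule_id[donors[:, 0]]
    amol = config.molecule_id[acceptors]
    for (heavy, hyd), dm in zip(donors, dmol):
        dvec = _min_image(apos - config.positions[heavy], box)
        dist = np.linalg.norm(dvec, axis=1)
        cand = np.nonzero((dist < distance_cut) & (amol != dm))[0]
        if not len(cand):
            continue
        hpos = config.positions[hyd]
        v1 = _min_image(config.positions[heavy] - hpos, box)
        v1 /= np.linalg.norm(v1)
        for c in cand:
            v2 = _min_image(apos[c] - hpos, box)
            v2 /= np.linalg.norm(v2)
            cosang = np.clip(v1 @ v2, -1.0, 1.0)
            ang = float(np.degrees(np.arccos(cosang)))
            if ang > angle_cut:
                bonds.append(HydrogenBond(
                    donor_heavy=int(heavy), donor_H=int(hyd),
                    acceptor_heavy=int(acceptors[c]),
                    distance=float(dist[c]), angle=ang,
                    donor_molecule=int(dm),
                    acceptor_molecule=int(amol[c]),
                ))
    return bonds


def classify_surface_bonds(bonds: list, descriptor: SystemDescriptor):
    """Label bonds water_water / type1 / type2 and count the types.

    Type 1: a surface heavy atom accepts (bridge acceptors included);
    type 2: a surface group donates.  Returns (bonds, counts dict).
    """
    surf_acceptors = set()
    surf_donor_heavy = set()
    known = set()
    for wall_groups in descriptor.surface_group_atoms.values():
        surf_acceptors.update(int(a) for a in wall_groups.get("acceptor_heavy", []))
        surf_donor_heavy.update(int(a) for a in wall_groups.get("donor_heavy", []))
        for key in ("donor_H", "donor_heavy", "acceptor_heavy"):
            known.update(int(a) for a in wall_groups.get(key, []))
    counts = {"type1": 0, "type2": 0, "water_water": 0}
    for b in bonds:
        donor_is_surface = b.donor_heavy in surf_donor_heavy
        acceptor_is_surface = b.acceptor_heavy in surf_acceptors
        if acceptor_is_surface and b.acceptor_heavy not in known:
            raise ValueError(f"bond references atom {b.acceptor_heavy} "
                             "absent from the surface inventory")
        if donor_is_surface and acceptor_is_surface:
            b.category = "surface_surface"
            continue
        if acceptor_is_surface:
            b.category = "type1"
        elif donor_is_surface:
            b.category = "type2"
        else:
            b.category = "water_water"
        counts[b.category] += 1
    return bonds, counts


def surface_bond_counts(bonds_per_frame: list, descriptor: SystemDescriptor):
    """Per-frame mean counts <N_H1>, <N_H2> of type-1/type-2 bonds."""
    n1, n2 = [], []
    for bonds in bonds_per_frame:
        _, c = classify_surface_bonds(bonds, descriptor)
        n1.append(c["type1"])
        n2.append(c["type2"])
    return float(np.mean(n1)), float(np.mean(n2))


def _roles_per_molecule(bonds, n_molecules):
    """Boolean (donor, acceptor) role flags and bond counts per molecule."""
    donor = np.zeros(n_molecules, dtype=bool)
    acceptor = np.zeros(n_molecules, dtype=bool)
    n_bonds = np.zeros(n_molecules)
    for b in bonds:
        donor[b.donor_molecule] = True
        acceptor[b.acceptor_molecule] = True
        n_bonds[b.donor_molecule] += 1
        n_bonds[b.acceptor_molecule] += 1
    return donor, acceptor, n_bonds


def _theta_prime(unit_dipoles: np.ndarray, n_z: np.ndarray) -> float:
    """Angle of the raw mean unit dipole against the normal, degrees."""
    if len(unit_dipoles) == 0:
        return float("nan")
    mean = unit_dipoles.mean(axis=0)
    return float(np.degrees(np.arccos(np.clip(mean @ n_z, -1.0, 1.0))))


def orientation_statistics(frames: list, layers_list: list,
                           bonds_per_frame: list, moments_list: list,
                           n_z=(0.0, 0.0, 1.0)) -> list:
    """Per-layer theta', donor/acceptor splits and <N_H> per molecule.

    ``n_z`` is the surface normal pointing toward the analysed wall.
    The mean unit dipole is the raw average (no renormalisation before
    the dot product).
    """
    n_z = np.asarray(n_z, dtype=float)
    n_layers = layers_list[0].n_layers
    per_layer = {li: {"mu": [], "mu_d": [], "mu_a": [], "nb": 0.0, "pop": 0}
                 for li in range(1, n_layers + 1)}
    for cfg, la, bonds, mom in zip(frames, layers_list, bonds_per_frame,
                                   moments_list):
        norm = np.linalg.norm(mom.mu, axis=1)
        unit = np.where(norm[:, None] > 0, mom.mu / np.maximum(norm, 1e-300)[:, None], 0.0)
        donor, acceptor, n_bonds = _roles_per_molecule(bonds, cfg.n_molecules)
        for li in range(1, n_layers + 1):
            mols = la.molecules_in_layer(li)
            if len(mols) == 0:
                continue
            acc = per_layer[li]
            acc["mu"].append(unit[mols])
            acc["mu_d"].append(unit[mols[donor[mols]]])
            acc["mu_a"].append(unit[mols[acceptor[mols]]])
            acc["nb"] += float(np.sum(n_bonds[mols]))
            acc["pop"] += len(mols)
    out = []
    for li in range(1, n_layers + 1):
        acc = per_layer[li]
        if acc["pop"] == 0:
            raise ValueError(f"layer {li} is empty across all frames")
        mu = np.vstack(acc["mu"])
        mu_d = np.vstack(acc["mu_d"]) if acc["mu_d"] else np.empty((0, 3))
        mu_a = np.vstack(acc["mu_a"]) if acc["mu_a"] else np.empty((0, 3))
        mean = mu.mean(axis=0)
        out.append(OrientationStats(
            layer=li,
            theta_prime=_theta_prime(mu, n_z),
            mean_unit_dipole=mean,
            n_hb_per_molecule=acc["nb"] / acc["pop"],
            theta_prime_donor=_theta_prime(mu_d, n_z),
            theta_prime_acceptor=_theta_prime(mu_a, n_z),
            n_molecules=acc["pop"],
        ))
    return out


def bulk_reference_nh(frames: list, bonds_per_frame: list,
                      moments_list: list, z_center: float,
                      width: float = 0.3) -> float:
    """<N_H> per molecule in a slab of the given width at the box centre."""
    tot, pop = 0.0, 0
    for cfg, bonds, mom in zip(frames, bonds_per_frame, moments_list):
        _, _, n_bonds = _roles_per_molecule(bonds, cfg.n_molecules)
        z = mom.centers[:, 2]
        mols = np.nonzero(np.abs(z - z_center) <= width / 2)[0]
        tot += float(np.sum(n_bonds[mols]))
        pop += len(mols)
    if pop == 0:
        raise ValueError("no molecules in the bulk reference slab")
    return tot / pop


def hbonded_dipole_distribution(frames: list, bonds_per_frame: list,
                                moments_list: list, category: str,
                                descriptor: SystemDescriptor | None = None,
                                bins: int = 40):
    """Histogram and mean of mu_z for solvent molecules in bonds of a category.

    For surface bonds the solvent partner is the non-surface molecule.
    Returns (bin_centers, counts, mean_mu_z).
    """
    values = []
    for cfg, bonds, mom in zip(frames, bonds_per_frame, moments_list):
        if descriptor is not None:
            bonds, _ = classify_surface_bonds(bonds, descriptor)
        n_mol = cfg.n_molecules
        involved = np.zeros(n_mol, dtype=bool)
        surf_mols = set()
        if descriptor is not None:
            for wall_groups in descriptor.surface_group_atoms.values():
                for key in ("donor_heavy", "acceptor_heavy"):
                    for a in wall_groups.get(key, []):
                        surf_mols.add(int(cfg.molecule_id[int(a)]))
        for b in bonds:
            if b.category != category:
                continue
            for m in (b.donor_molecule, b.acceptor_molecule):
                if m not in surf_mols:
                    involved[m] = True
        sel = np.nonzero(involved)[0]
        if len(sel):
            values.append(mom.mu[sel, 2])
    if not values:
        raise ValueError(f"no bonds of category {category!r}")
    mu_z = np.concatenate(values)
    counts, edges = np.histogram(mu_z, bins=bins)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, counts, float(np.mean(mu_z))
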