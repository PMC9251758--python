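"""Configuration and topology I/O.

Coordinate files (PDB, GRO, XYZ; multi-frame XYZ trajectories) are read
through MDAnalysis and paired with a *topology sidecar* -- a small YAML
(or JSON) document supplying what coordinate formats do not carry:
per-atom partial charges, van der Waals radii, molecule grouping and the
per-species molecular-center atom.  Everything is normalised to the
package units (nm, e) on load.

Sidecar schema (version 1)::

    slabpol_topology: 1
    species:
      - name: SOL            # residue name in the coordinate file
        atoms:
          - {name: OW, charge: -0.82, vdw_radius: 0.1583}
          - {name: HW1, charge: 0.41, vdw_radius: 0.0}
          - {name: HW2, charge: 0.41, vdw_radius: 0.0}
        center_atom: OW
    molecules:               # optional; required for XYZ (no residues)
      - {species: SOL, count: 216}

Molecules are resolved from residue records when the coordinate format
has them, otherwise from the ``molecules`` block in file order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

SIDECAR_KEY = "slabpol_topology"
SIDECAR_VERSION = 1

#: nm per Angstrom (MDAnalysis native length unit)
_NM_PER_ANGSTROM = 0.1


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topology sidecars."""


@dataclass
class MolecularConfiguration:
    """One frame of a slab system.

    Arrays are per-atom unless stated otherwise; lengths in nm, charges
    in e.  ``molecule_id`` groups atoms into molecules (contiguous,
    starting at 0); ``species_label`` names the species of each atom's
    molecule; ``atom_names`` are the per-atom names used by center and
    donor/acceptor rules.
    """

    positions: np.ndarray        # (n_atoms, 3) nm
    charges: np.ndarray          # (n_atoms,) e
    molecule_id: np.ndarray      # (n_atoms,) int
    species_label: np.ndarray    # (n_atoms,) str
    atom_names: np.ndarray       # (n_atoms,) str
    box: np.ndarray              # (3,) nm
    vdw_radius: np.ndarray | None = None   # (n_atoms,) nm
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.species_label = np.asarray(self.species_label, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.vdw_radius is not None:
            self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------

    def validate(self) -> None:
        n = len(self.positions)
        for name, arr in [("charges", self.charges),
                          ("molecule_id", self.molecule_id),
                          ("species_label", self.species_label),
                          ("atom_names", self.atom_names)]:
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")
        # per-molecule net charge must be an integer multiple of 1e
        net = self.molecule_charges()
        bad = np.abs(net - np.round(net)) > 1e-6
        if np.any(bad):
            mols = np.nonzero(bad)[0][:5]
            raise ValueError(
                f"non-integer molecular net charge for molecule(s) {mols.tolist()}"
            )

    # -- molecule bookkeeping ---------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_id.max()) + 1 if self.n_atoms else 0

    def molecule_slices(self) -> list[np.ndarray]:
        """Atom-index array per molecule (file order preserved)."""
        order = np.argsort(self.molecule_id, kind="stable")
        ids = self.molecule_id[order]
        bounds = np.searchsorted(ids, np.arange(self.n_molecules + 1))
        return [order[bounds[i]:bounds[i + 1]] for i in range(self.n_molecules)]

    def molecule_charges(self) -> np.ndarray:
        return np.bincount(self.molecule_id, weights=self.charges,
                           minlength=self.n_molecules)

    def molecule_species(self) -> np.ndarray:
        """Species label per molecule."""
        first = np.zeros(self.n_molecules, dtype=int)
        # first atom of each molecule in file order
        seen = {}
        for i, m in enumerate(self.molecule_id):
            if m not in seen:
                seen[m] = i
        for m, i in seen.items():
            first[m] = i
        return self.species_label[first]


@dataclass
class SystemDescriptor:
    """Wall geometry and surface chemistry of a slab/capacitor system.

    ``sigma`` is the surface charge density per wall in e/nm^2;
    ``surface_group_atoms`` maps each wall to atom-index lists for
    donor H atoms, donor heavy atoms and acceptor heavy atoms of the
    frozen surface groups.
    """

    normal_axis: str = "z"
    wall_positions: tuple[float, float] = (0.0, 1.0)   # nm, (left, right)
    wall_mode: dict = field(default_factory=lambda: {"left": "flat", "right": "flat"})
    sigma: dict = field(default_factory=lambda: {"left": 0.0, "right": 0.0})
    surface_group_atoms: dict = field(default_factory=dict)
    liquid_species: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.normal_axis not in ("x", "y", "z"):
            raise ValueError("normal_axis must be one of x, y, z")
        lo, hi = self.wall_positions
        if not lo < hi:
            raise ValueError("left wall position must be below right wall position")

    def check_electroneutral(self, config: MolecularConfiguration,
                             tol: float = 1e-6) -> None:
        """Assert wall charges + liquid net charge per area sum to zero."""
        ax = "xyz".index(self.normal_axis)
        lat = [i for i in range(3) if i != ax]
        area = config.box[lat[0]] * config.box[lat[1]]
        liquid = 0.0
        species = set(self.liquid_species)
        mol_sp = config.molecule_species()
        net = config.molecule_charges()
        for m in range(config.n_molecules):
            if not species or mol_sp[m] in species:
                liquid += net[m]
        total = self.sigma["left"] + self.sigma["right"] + liquid / area
        if abs(total) > tol:
            raise ValueError(f"cell is not electroneutral: residual {total:.3g} e/nm^2")


def descriptor_to_dict(d: SystemDescriptor) -> dict:
    return {
        "normal_axis": d.normal_axis,
        "wall_positions": [float(x) for x in d.wall_positions],
        "wall_mode": dict(d.wall_mode),
        "sigma": {k: float(v) for k, v in d.sigma.items()},
        "surface_group_atoms": d.surface_group_atoms,
        "liquid_species": list(d.liquid_species),
    }


def descriptor_from_dict(d: dict) -> SystemDescriptor:
    return SystemDescriptor(
        normal_axis=d.get("normal_axis", "z"),
        wall_positions=tuple(d["wall_positions"]),
        wall_mode=d.get("wall_mode", {"left": "flat", "right": "flat"}),
        sigma=d.get("sigma", {"left": 0.0, "right": 0.0}),
        surface_group_atoms=d.get("surface_group_atoms", {}),
        liquid_species=d.get("liquid_species", []),
    )


def save_descriptor(d: SystemDescriptor, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(descriptor_to_dict(d), sort_keys=False))


def load_descriptor(path: str | Path) -> SystemDescriptor:
    return descriptor_from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class MolecularMoments:
    """Dipole and traceless quadrupole of one molecule about its center."""

    center: np.ndarray     # (3,) nm
    mu: np.ndarray         # (3,) e nm
    theta_zz: float        # e nm^2


class Moments:
    """Per-molecule moments for one frame, stored as arrays.

    Indexing returns a :class:`MolecularMoments`; the arrays
    (``centers``, ``mu``, ``theta_zz``) are used directly by the
    profile machinery.
    """

    def __init__(self, centers: np.ndarray, mu: np.ndarray,
                 theta_zz: np.ndarray, species: np.ndarray):
        self.centers = centers
        self.mu = mu
        self.theta_zz = theta_zz
        self.species = species

    def __len__(self) -> int:
        return len(self.centers)

    def __getitem__(self, i: int) -> MolecularMoments:
        return MolecularMoments(self.centers[i], self.mu[i], float(self.theta_zz[i]))


# ----------------------------------------------------------------------
# topology sidecar
# ----------------------------------------------------------------------

def load_topology(path: str | Path) -> dict:
    """Load and validate a topology sidecar (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        top = json.loads(text)
    else:
        top = yaml.safe_load(text)
    if not isinstance(top, dict) or SIDECAR_KEY not in top:
        raise TopologyError(f"not a topology sidecar (missing '{SIDECAR_KEY}' key)")
    if top[SIDECAR_KEY] != SIDECAR_VERSION:
        raise TopologyError(f"unsupported sidecar version {top[SIDECAR_KEY]}")
    if "species" not in top or not top["species"]:
        raise TopologyError("sidecar defines no species")
    for sp in top["species"]:
        for key in ("name", "atoms"):
            if key not in sp:
                raise TopologyError(f"species entry missing '{key}'")
        names = [a["name"] for a in sp["atoms"]]
        center = sp.get("center_atom")
        if center is not None and names.count(center) != 1:
            raise TopologyError(
                f"center_atom {center!r} must name exactly one atom of species "
                f"{sp['name']!r}"
            )
    return top


def save_topology(top: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(top, sort_keys=False))


def _species_table(top: dict) -> dict:
    return {sp["name"]: sp for sp in top["species"]}


# ----------------------------------------------------------------------
# coordinate readers
# ----------------------------------------------------------------------

def _iter_universe_frames(coords_path: Path):
    """Yield (names, resnames_or_None, positions_nm, box_nm) per frame."""
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coords_path))
        names = np.array([a.name for a in u.atoms], dtype=object)
        has_res = hasattr(u.atoms, "resnames") and u.trajectory.ts.dimensions is not None
        try:
            resnames = np.array(
                [a.resname for a in u.atoms], dtype=object)
        except Exception:
            resnames = None
        for ts in u.trajectory:
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = np.asarray(ts.dimensions[:3], dtype=float) * _NM_PER_ANGSTROM
            else:
                box = None
            yield names, resnames, ts.positions * _NM_PER_ANGSTROM, box


def _assign_molecules(names, resnames, top: dict):
    """Map file atoms onto sidecar species; return per-atom arrays.

    When molecule grouping comes from the sidecar's ``molecules`` block
    (formats without residues, e.g. XYZ), the sidecar's atom names are
    authoritative and returned in place of the file's element symbols.
    """
    table = _species_table(top)
    n = len(names)
    mol_id = np.empty(n, dtype=int)
    species = np.empty(n, dtype=object)
    charges = np.empty(n, dtype=float)
    radii = np.empty(n, dtype=float)
    out_names = np.array(names, dtype=object)

    if "molecules" in top and top["molecules"]:
        blocks = [(b["species"], int(b["count"])) for b in top["molecules"]]
    elif resnames is not None:
        # contiguous runs of identical resname whose length matches a species
        blocks = None
    else:
        raise TopologyError(
            "coordinate format carries no residues; sidecar needs a 'molecules' block"
        )

    i = 0
    mol = 0
    if blocks is not None:
        expected = sum(len(table[s]["atoms"]) * c for s, c in blocks
                       if s in table)
        for sp_name, count in blocks:
            if sp_name not in table:
                raise TopologyError(f"molecules block names unknown species {sp_name!r}")
            sp = table[sp_name]
            natoms = len(sp["atoms"])
            for _ in range(count):
                if i + natoms > n:
                    raise TopologyError(
                        f"atom-count mismatch: coordinates have {n} atoms, "
                        f"topology describes {expected}"
                    )
                for k, atom in enumerate(sp["atoms"]):
                    mol_id[i + k] = mol
                    species[i + k] = sp_name
                    charges[i + k] = float(atom["charge"])
                    radii[i + k] = float(atom.get("vdw_radius", 0.0))
                    out_names[i + k] = atom["name"]
                i += natoms
                mol += 1
        if i != n:
            raise TopologyError(
                f"atom-count mismatch: coordinates have {n} atoms, "
                f"topology describes {i}"
            )
    else:
        while i < n:
            rn = resnames[i]
            if rn not in table:
                raise TopologyError(f"residue {rn!r} not described by the sidecar")
            sp = table[rn]
            natoms = len(sp["atoms"])
            if i + natoms > n or not all(resnames[i + k] == rn for k in range(natoms)):
                raise TopologyError(
                    f"atom-count mismatch within residue {rn!r} at atom {i}"
                )
            for k, atom in enumerate(sp["atoms"]):
                mol_id[i + k] = mol
                species[i + k] = rn
                charges[i + k] = float(atom["charge"])
                radii[i + k] = float(atom.get("vdw_radius", 0.0))
            i += natoms
            mol += 1
    return mol_id, species, charges, radii, out_names


def read_trajectory(coords_path: str | Path,
                    topology_path: str | Path) -> list[MolecularConfiguration]:
    """Read all frames of a coordinate file with its topology sidecar."""
    top = load_topology(topology_path)
    frames = []
    for fi, (names, resnames, pos, box) in enumerate(
            _iter_universe_frames(Path(coords_path))):
        mol_id, species, charges, radii, names = _assign_molecules(
            names, resnames, top)
        if box is None:
            box_key = top.get("box")
            if box_key is None:
                raise TopologyError(
                    "coordinate file carries no box; add a 'box: [lx, ly, lz]' "
                    "entry (nm) to the sidecar"
                )
            box = np.asarray(box_key, dtype=float)
        cfg = MolecularConfiguration(
            positions=pos, charges=charges, molecule_id=mol_id,
            species_label=species, atom_names=names, box=box,
            vdw_radius=radii, frame_index=fi,
        )
        frames.append(cfg)
    return frames


def read_configuration(coords_path: str | Path,
                       topology_path: str | Path) -> MolecularConfiguration:
    """Read a single-frame configuration (first frame of the file)."""
    frames = read_trajectory(coords_path, topology_path)
    return frames[0]


def write_gro(config: MolecularConfiguration, path: str | Path,
              append: bool = False) -> None:
    """Write one frame in GRO format (positions in nm, native GRO units)."""
    lines = [f"slabpol frame {config.frame_index}", f"{config.n_atoms:5d}"]
    for i in range(config.n_atoms):
        res = config.molecule_id[i] + 1
        lines.append(
            f"{res % 100000:5d}{str(config.species_label[i])[:5]:<5s}"
            f"{str(config.atom_names[i])[:5]:>5s}{(i + 1) % 100000:5d}"
            f"{config.positions[i, 0]:8.3f}{config.positions[i, 1]:8.3f}"
            f"{config.positions[i, 2]:8.3f}"
        )
    lines.append(f"{config.box[0]:10.5f}{config.box[1]:10.5f}{config.box[2]:10.5f}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def write_xyz_trajectory(frames: list[MolecularConfiguration],
                         path: str | Path) -> None:
    """Write frames as a multi-frame XYZ file (coordinates in Angstrom)."""
    with open(path, "w") as fh:
        for cfg in frames:
            fh.write(f"{cfg.n_atoms}\n")
            fh.write(f"slabpol frame {cfg.frame_index}\n")
            for i in range(cfg.n_atoms):
                x, y, z = cfg.positions[i] / _NM_PER_ANGSTROM
                # element guess: first alphabetic character of the atom name
                name = str(cfg.atom_names[i])
                elem = next((c for c in name if c.isalpha()), "X")
                fh.write(f"{elem} {x:.6f} {y:.6f} {z:.6f}\n")


# ----------------------------------------------------------------------
# molecular moments
# ----------------------------------------------------------------------

def molecular_moments(config: MolecularConfiguration,
                      center_rule: dict | None = None) -> Moments:
    """Dipole and traceless-quadrupole moments about per-species centers.

    ``center_rule`` maps species label to the center atom name; species
    missing from the map fall back to the sidecar-style convention of a
    unique heavy atom only when the molecule has exactly one atom with a
    nonzero vdW radius (the single-vdW-site rule).  Multi-site species
    must be named explicitly.

    For net-neutral molecules ``mu`` is independent of the center;
    ``theta_zz`` always depends on it.  Lateral periodic images are
    resolved by minimum image about the center so split molecules are
    handled; the slab axis (z) is never wrapped.
    """
    center_rule = dict(center_rule or {})
    slices = config.molecule_slices()
    n_mol = config.n_molecules
    centers = np.empty((n_mol, 3))
    mu = np.empty((n_mol, 3))
    theta = np.empty(n_mol)
    mol_species = config.molecule_species()

    for m, idx in enumerate(slices):
        sp = mol_species[m]
        names = config.atom_names[idx]
        if sp in center_rule:
            cname = center_rule[sp]
            hit = np.nonzero(names == cname)[0]
            if len(hit) != 1:
                raise ValueError(
                    f"center atom {cname!r} absent (or not unique) in molecule {m} "
                    f"of species {sp!r}"
                )
            ci = idx[hit[0]]
        else:
            if config.vdw_radius is None:
                raise ValueError(
                    f"no center rule for species {sp!r} and no vdW radii to "
                    "apply the single-site rule"
                )
            sites = np.nonzero(config.vdw_radius[idx] > 0)[0]
            if len(sites) != 1:
                raise ValueError(
                    f"species {sp!r} has {len(sites)} vdW sites; an explicit "
                    "center_atom is required"
                )
            ci = idx[sites[0]]
        c = config.positions[ci]
        rel = config.positions[idx] - c
        # minimum image in the two lateral directions only
        for ax in (0, 1):
            L = config.box[ax]
            rel[:, ax] -= L * np.round(rel[:, ax] / L)
        q = config.charges[idx]
        centers[m] = c
        mu[m] = q @ rel
        r2 = np.sum(rel * rel, axis=1)
        theta[m] = 0.5 * np.sum(q * (3.0 * rel[:, 2] ** 2 - r2))
    return Moments(centers, mu, theta, mol_species)
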