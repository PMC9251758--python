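"""Area-averaged axial profiles along the surface normal.

Per-molecule quantities are binned at the molecular center (M-scheme)
into uniform z bins spanning the full box height, averaged over frames
and divided by bin volume, giving densities in nm^-3 and polarization
densities in e nm^-2 (dipole) / e nm^-1 (quadrupole).  The axial
polarization is assembled as

    P(z) = P1(z) - dQzz/dz,

with P1 = rho <mu_z> the dipole-moment density and Qzz = rho <theta_zz>
the traceless quadrupole-moment density; the derivative uses order-2
central differences (one-sided at the endpoints).  No smoothing is
applied anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .config_io import MolecularConfiguration, molecular_moments
from .constants import DEFAULT_BIN_WIDTH

PROFILE_UNITS = {
    "density": "nm^-3",
    "mu_z": "e nm",
    "P1": "e nm^-2",
    "Qzz": "e nm^-1",
    "P": "e nm^-2",
}


@dataclass
class AxialProfile:
    """A binned quantity versus z."""

    kind: str
    z_centers: np.ndarray
    values: np.ndarray
    bin_width: float
    n_frames: int
    area: float

    def __post_init__(self):
        if self.kind not in PROFILE_UNITS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        self.z_centers = np.asarray(self.z_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        dz = np.diff(self.z_centers)
        if len(dz) and not np.allclose(dz, self.bin_width, rtol=1e-6):
            raise ValueError("z_centers must be uniform with spacing bin_width")

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([self.z_centers - self.bin_width / 2,
                               [self.z_centers[-1] + self.bin_width / 2]])

    # -- serialisation ----------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        header = (f"# kind: {self.kind}\n# units: {PROFILE_UNITS[self.kind]}\n"
                  f"# bin_width: {self.bin_width}\n# n_frames: {self.n_frames}\n"
                  f"# area: {self.area}\n# z_nm\tvalue\n")
        body = "\n".join(f"{z:.6f}\t{v:.10g}"
                         for z, v in zip(self.z_centers, self.values))
        Path(path).write_text(header + body + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AxialProfile":
        meta = {}
        zs, vs = [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                if ":" in line:
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                continue
            if line.strip():
                z, v = line.split("\t")
                zs.append(float(z))
                vs.append(float(v))
        return cls(kind=meta["kind"], z_centers=np.array(zs),
                   values=np.array(vs), bin_width=float(meta["bin_width"]),
                   n_frames=int(meta["n_frames"]), area=float(meta["area"]))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["z_centers"] = self.z_centers.tolist()
        d["values"] = self.values.tolist()
        Path(path).write_text(json.dumps(d))


def _bin_grid(box_z: float, bin_width: float):
    n_bins = int(round(box_z / bin_width))
    if n_bins < 1:
        raise ValueError("bin_width exceeds the box height")
    width = box_z / n_bins          # snap so bins tile the box exactly
    centers = (np.arange(n_bins) + 0.5) * width
    return centers, width, n_bins


def _lateral_area(config: MolecularConfiguration) -> float:
    return float(config.box[0] * config.box[1])


def _frames_moments(frames, center_rule):
    """Moments per frame, computed on demand."""
    return [molecular_moments(f, center_rule) for f in frames]


def density_profile(frames: list, species: str | None = None,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    center_rule: dict | None = None,
                    moments: list | None = None) -> AxialProfile:
    """Number density of molecular centers versus z, averaged over frames."""
    if not frames:
        raise ValueError("at least one frame is required")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    box_z = frames[0].box[2]
    centers, width, n_bins = _bin_grid(box_z, bin_width)
    area = _lateral_area(frames[0])
    if moments is None:
        moments = _frames_moments(frames, center_rule)
    counts = np.zeros(n_bins)
    any_sel = False
    for mom in moments:
        sel = slice(None) if species is None else (mom.species == species)
        z = mom.centers[sel, 2] if species is not None else mom.centers[:, 2]
        if len(z):
            any_sel = True
        idx = np.clip((z / width).astype(int), 0, n_bins - 1)
        counts += np.bincount(idx, minlength=n_bins)
    if not any_sel:
        raise ValueError(f"no molecules of species {species!r} in any frame")
    values = counts / (area * width * len(frames))
    return AxialProfile("density", centers, values, width, len(frames), area)


def polarization_profiles(frames: list, moments: list | None = None,
                          bin_width: float = DEFAULT_BIN_WIDTH,
                          species: str | None = None,
                          center_rule: dict | None = None) -> dict:
    """P1, Qzz and P = P1 - dQzz/dz profiles (plus density and <mu_z>).

    Returns a dict of :class:`AxialProfile` keyed by kind.  The
    derivative of Qzz uses central differences; with fewer than 3 bins
    it is undefined and an error is raised.
    """
    if not frames:
        raise ValueError("at least one frame is required")
    box_z = frames[0].box[2]
    centers, width, n_bins = _bin_grid(box_z, bin_width)
    if n_bins < 3:
        raise ValueError("need at least 3 bins to differentiate Qzz")
    area = _lateral_area(frames[0])
    if moments is None:
        moments = _frames_moments(frames, center_rule)

    counts = np.zeros(n_bins)
    sum_mu = np.zeros(n_bins)
    sum_th = np.zeros(n_bins)
    for mom in moments:
        if species is not None:
            sel = mom.species == species
            z = mom.centers[sel, 2]
            mu_z = mom.mu[sel, 2]
            th = mom.theta_zz[sel]
        else:
            z, mu_z, th = mom.centers[:, 2], mom.mu[:, 2], mom.theta_zz
        idx = np.clip((z / width).astype(int), 0, n_bins - 1)
        counts += np.bincount(idx, minlength=n_bins)
        sum_mu += np.bincount(idx, weights=mu_z, minlength=n_bins)
        sum_th += np.bincount(idx, weights=th, minlength=n_bins)

    norm = area * width * len(frames)
    rho = counts / norm
    P1 = sum_mu / norm
    Qzz = sum_th / norm
    with np.errstate(invalid="ignore"):
        mu_mean = np.where(counts > 0, sum_mu / np.maximum(counts, 1), 0.0)
    dQ = np.gradient(Qzz, width)     # central, one-sided at the ends
    P = P1 - dQ

    make = lambda kind, vals: AxialProfile(kind, centers, vals, width,
                                           len(frames), area)
    return {"density": make("density", rho),
            "mu_z": make("mu_z", mu_mean),
            "P1": make("P1", P1),
            "Qzz": make("Qzz", Qzz),
            "P": make("P", P)}


def trapezoid_between(profile: AxialProfile, a: float, b: float) -> float:
    """Signed trapezoid integral of a profile from z = a to z = b.

    The profile is treated as piecewise linear between bin centers and
    constant beyond the outermost centers.
    """
    z, v = profile.z_centers, profile.values
    lo, hi = (a, b) if a <= b else (b, a)
    pts = [lo] + [float(x) for x in z if lo < x < hi] + [hi]
    pts = np.array(pts)
    vals = np.interp(pts, z, v)
    integral = np.trapezoid(vals, pts)
    return float(integral if a <= b else -integral)
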