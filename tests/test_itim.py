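"""ITIM layer detection, instantaneous surface and intrinsic profiles."""

import numpy as np
import pytest
from scipy.special import erf

import slabpol as sp
from slabpol.profiles import AxialProfile
from testutil import (itim_oracle_bisect, itim_oracle_march,
                      random_water_config, water_config)


def test_single_molecule_layer_one():
    cfg = water_config([[0.5, 0.5, 0.6]], box=(1.0, 1.0, 1.5))
    la = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.05)
    assert la.layer_index.tolist() == [1]


def test_stacked_molecules_layer_order():
    """Two molecules exactly stacked along z: upper first, lower second."""
    cfg = water_config([[0.5, 0.5, 0.9], [0.5, 0.5, 0.5]],
                       box=(1.0, 1.0, 2.0))
    la = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.05,
                               side="upper")
    assert la.layer_index.tolist() == [1, 2]
    oracle = itim_oracle_bisect(cfg, species="SOL", mesh_spacing=0.05,
                                side="upper")
    assert oracle.tolist() == [1, 2]
    # approaching from below reverses the order
    la_low = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.05,
                                   side="lower")
    assert la_low.layer_index.tolist() == [2, 1]


def _monolayer(nx=4, z=0.6, box=(1.2, 1.2, 1.5)):
    xs = (np.arange(nx) + 0.5) * box[0] / nx
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(),
                               np.full(nx * nx, z)])
    return water_config(centers, box=box)


def test_flat_monolayer_all_layer_one():
    cfg = _monolayer()
    la = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.05,
                               n_layers=3)
    assert np.all(la.layer_index == 1)


def test_probe_radius_monotonicity():
    """A larger probe never pushes a monolayer molecule deeper."""
    cfg = _monolayer()
    for probe in (0.05, 0.15, 0.3, 0.5):
        la = sp.assign_itim_layers(cfg, species="SOL", probe_radius=probe,
                                   mesh_spacing=0.05)
        assert np.all(la.layer_index == 1)


def test_determinism():
    rng = np.random.default_rng(3)
    cfg = random_water_config(rng, 10, (1.0, 1.0, 1.2))
    a = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.04)
    b = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.04)
    assert np.array_equal(a.layer_index, b.layer_index)


def test_oracle_equivalence_sample():
    """Vectorised ITIM matches the exhaustive probe-descent oracle."""
    rng = np.random.default_rng(12)
    for _ in range(20):
        n = int(rng.integers(2, 13))
        cfg = random_water_config(rng, n, (0.8, 0.8, 1.2))
        la = sp.assign_itim_layers(cfg, species="SOL", probe_radius=0.15,
                                   mesh_spacing=0.02, n_layers=4)
        oracle = itim_oracle_bisect(cfg, species="SOL", probe_radius=0.15,
                                    mesh_spacing=0.02, n_layers=4)
        assert np.array_equal(la.layer_index, oracle)


def test_marching_oracle_agrees_on_tiny_configs():
    """The scalar marching probe oracle agrees with both implementations
    on coarse meshes (a second, fully independent descent route)."""
    rng = np.random.default_rng(7)
    for _ in range(4):
        cfg = random_water_config(rng, int(rng.integers(2, 6)),
                                  (0.6, 0.6, 1.0))
        la = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.1,
                                   n_layers=3)
        march = itim_oracle_march(cfg, species="SOL", mesh_spacing=0.1,
                                  n_layers=3)
        assert np.array_equal(la.layer_index, march)


def test_flat_surface_map_constant():
    """Nodes directly above a dense flat atom sheet sit at z0 + r + R."""
    nx = 24
    box = (1.2, 1.2, 1.5)
    xs = np.arange(nx) * box[0] / nx      # atoms exactly on the mesh nodes
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(),
                               np.full(nx * nx, 0.6)])
    cfg = water_config(centers, box=box)
    la = sp.assign_itim_layers(cfg, species="SOL", probe_radius=0.15,
                               mesh_spacing=box[0] / nx)
    smap = sp.instantaneous_surface(cfg, la)
    expected = 0.6 + 0.1583 + 0.15
    node_vals = smap.heights[::1, ::1]
    # every node lies directly above some atom: constant map
    assert np.nanmax(np.abs(node_vals - expected)) < 1e-9


def test_sinusoidal_sheet_amplitude_recovery():
    """A sinusoidal atom sheet is recovered by the height map within the
    probe-smoothing tolerance (15% on the amplitude)."""
    amp, wav = 0.3, 3.0
    box = (3.0, 3.0, 3.0)
    n = 60
    xs = (np.arange(n) + 0.5) * box[0] / n
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    z = 1.5 + amp * np.sin(2 * np.pi * gx / wav)
    cfg = water_config(np.column_stack([gx.ravel(), gy.ravel(), z.ravel()]),
                       box=box)
    la = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.05,
                               n_layers=1)
    smap = sp.instantaneous_surface(cfg, la)
    h = smap.filled()
    hx = h.mean(axis=1)
    rec_amp = 0.5 * (hx.max() - hx.min())
    assert rec_amp == pytest.approx(amp, rel=0.15)
    x_nodes = smap.x_nodes
    target = np.sin(2 * np.pi * x_nodes / wav)
    corr = np.corrcoef(hx - hx.mean(), target)[0, 1]
    assert corr > 0.98


def test_adatom_bump_height():
    """A single adatom protruding 0.5 nm shows as a local bump of that
    height above the flat map level."""
    nx = 24
    box = (1.2, 1.2, 2.5)
    xs = np.arange(nx) * box[0] / nx
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(),
                               np.full(nx * nx, 0.6)])
    centers = np.vstack([centers, [[0.6, 0.6, 1.1]]])
    cfg = water_config(centers, box=box)
    la = sp.assign_itim_layers(cfg, species="SOL", probe_radius=0.15,
                               mesh_spacing=box[0] / nx)
    smap = sp.instantaneous_surface(cfg, la)
    base = 0.6 + 0.1583 + 0.15
    assert np.nanmax(smap.heights) == pytest.approx(base + 0.5, abs=1e-9)
    far = smap.heights[0, 12]           # far from the adatom
    assert far == pytest.approx(base, abs=1e-9)


def _density(z, rho):
    return AxialProfile("density", z, rho, float(z[1] - z[0]), 1, 4.0)


def test_gibbs_dividing_surface_cases():
    z = np.arange(0.025, 6.0, 0.05)
    rho_b = 33.0
    step = np.where(z < 4.5, rho_b, 0.0)
    step[z < 0.5] = rho_b                 # plateau everywhere below the step
    assert sp.gibbs_dividing_surface(_density(z, step)) == pytest.approx(
        4.5, abs=0.051)
    ramp = np.where(z < 4.0, rho_b, np.clip(rho_b * (5.0 - z), 0, rho_b))
    assert sp.gibbs_dividing_surface(_density(z, ramp)) == pytest.approx(
        4.5, abs=0.051)
    erfp = rho_b * 0.5 * (1.0 - erf((z - 3.7) / 0.3))
    assert sp.gibbs_dividing_surface(_density(z, erfp)) == pytest.approx(
        3.7, abs=0.051)
    with pytest.raises(ValueError, match="plateau"):
        decay = rho_b * np.exp(-2.0 * z)      # no flat bulk region at all
        sp.gibbs_dividing_surface(_density(z, decay))


def test_surface_roughness_flat_is_zero():
    cfg = _monolayer()
    la = sp.assign_itim_layers(cfg, species="SOL", mesh_spacing=0.05)
    smap = sp.instantaneous_surface(cfg, la)
    h = smap.filled()
    assert sp.surface_roughness(smap, float(np.mean(h))) < 0.09


def test_intrinsic_profile_flat_surface_is_shifted_absolute():
    """Over a flat surface the intrinsic profile is the absolute profile
    rigidly shifted by the (constant) surface height."""
    spec = sp.SlabSpec(area=4.0, thickness=3.0, density=30.0, n_frames=5,
                       seed=71)
    res = sp.generate_slab(spec)
    frames = res.frames
    moms = [sp.molecular_moments(f, {"SOL": "OW"}) for f in frames]
    layers, maps = [], []
    h0 = None
    for f in frames:
        la = sp.assign_itim_layers(f, species="SOL", mesh_spacing=0.05,
                                   n_layers=2)
        smap = sp.instantaneous_surface(f, la)
        h = smap.filled()
        if h0 is None:
            # flatten at a common bin multiple so both grids align
            h0 = float(np.floor(np.mean(h) / 0.05) * 0.05)
        smap.heights = np.full_like(h, h0)
        layers.append(la)
        maps.append(smap)
    intr = sp.intrinsic_profile(frames, maps, moms, "density",
                                bin_width=0.05, xi_range=(-3.5, 0.5))
    absolute = sp.density_profile(frames, bin_width=0.05,
                                  center_rule={"SOL": "OW"})
    # map each intrinsic bin onto its absolute-z counterpart
    for xi, v in zip(intr.z_centers, intr.values):
        z = xi + h0
        j = np.argmin(np.abs(absolute.z_centers - z))
        if abs(absolute.z_centers[j] - z) < 1e-9:
            assert v == pytest.approx(absolute.values[j], abs=1e-9)


def test_per_layer_densities_partition_total():
    """Layer-resolved intrinsic densities sum to the all-molecule profile
    bin-for-bin when every molecule is assigned a layer."""
    spec = sp.SlabSpec(area=2.25, thickness=1.5, density=25.0, n_frames=3,
                       seed=83)
    res = sp.generate_slab(spec)
    frames = res.frames
    moms = [sp.molecular_moments(f, {"SOL": "OW"}) for f in frames]
    layers, maps = [], []
    for f in frames:
        la = sp.assign_itim_layers(f, species="SOL", mesh_spacing=0.05,
                                   n_layers=30)
        assert np.all(la.layer_index >= 1)        # everything assigned
        layers.append(la)
        maps.append(sp.instantaneous_surface(f, la))
    total = sp.intrinsic_profile(frames, maps, moms, "density",
                                 layers_list=layers, layer=None,
                                 bin_width=0.1, xi_range=(-2.0, 0.5))
    acc = np.zeros_like(total.values)
    for li in range(1, 31):
        part = sp.intrinsic_profile(frames, maps, moms, "density",
                                    layers_list=layers, layer=li,
                                    bin_width=0.1, xi_range=(-2.0, 0.5))
        acc += part.values
    assert np.allclose(acc, total.values, atol=1e-12)


def test_intrinsic_sharpens_planted_surface_bias():
    """A first-band dipole bias under a rough surface appears as a sharp
    near-surface feature in the intrinsic mu_z profile, matching the
    planted Langevin mean, while the lab-frame peak is diluted."""
    a_surf = -1.5
    slab = sp.SlabSpec(area=9.0, thickness=3.0, density=30.0, n_frames=12,
                       seed=19)
    sspec = sp.RoughSurfaceSpec(slab=slab, amplitude=0.45, wavelength=3.0,
                                surface_bias=a_surf, surface_bias_width=0.3,
                                seed=19)
    res = sp.generate_rough_decorated_surface(sspec)
    frames = res.frames
    moms = [sp.molecular_moments(f, {"SOL": "OW", "WAL": "SI"}) for f in frames]
    layers, maps = [], []
    for f in frames:
        la = sp.assign_itim_layers(f, species="SOL", mesh_spacing=0.05,
                                   n_layers=1, side="upper")
        layers.append(la)
        maps.append(sp.instantaneous_surface(f, la))
    intr = sp.intrinsic_profile(frames, maps, moms, "mu_z",
                                layers_list=layers, bin_width=0.1,
                                xi_range=(-1.5, 0.5))
    planted = res.truth.mu_magnitude * sp.langevin(a_surf)
    # the band just below the instantaneous surface carries the bias
    band = (intr.z_centers > -0.55) & (intr.z_centers < -0.3)
    n_samples = 30.0 * 9.0 * 0.1 * 12 * band.sum()
    se = res.truth.mu_magnitude / np.sqrt(3 * n_samples)
    assert np.mean(intr.values[band]) == pytest.approx(planted, abs=10 * se)
    # lab frame: roughness smears the 0.3 nm biased band over a z-range
    # of order amplitude + band, so the feature is broader than intrinsic
    lab = sp.polarization_profiles(frames, moments=moms, bin_width=0.1,
                                   species="SOL")
    occ = lab["density"].values > 1.0
    half = planted / 2            # negative threshold
    lab_extent = np.sum(lab["mu_z"].values[occ] < half) * 0.1
    intr_extent = np.sum(intr.values < half) * 0.1
    assert intr_extent <= 0.5                  # sharp: about the band width
    assert lab_extent > intr_extent            # lab frame is broader
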