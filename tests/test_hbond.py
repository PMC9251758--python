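"""Hydrogen-bond detection, surface-bond taxonomy and orientation stats."""

import numpy as np
import pytest

import slabpol as sp
from slabpol.hbond import _roles_per_molecule
from testutil import MU_SPC, water_config


def _bonds_for(cfg, desc=None):
    donors, acceptors = sp.enumerate_donors_acceptors(cfg, desc)
    return sp.detect_hydrogen_bonds(cfg, donors, acceptors)


def test_fixture_classification_exact():
    """Every boundary-spanning fixture is classified exactly."""
    for fx in sp.hbond_fixtures():
        bonds = _bonds_for(fx.config, fx.descriptor)
        if fx.descriptor is not None:
            bonds, _ = sp.classify_surface_bonds(bonds, fx.descriptor)
        if fx.expect_bond:
            assert len(bonds) == 1, fx.name
            assert bonds[0].category == fx.expect_category, fx.name
        else:
            assert len(bonds) == 0, fx.name


def test_criteria_are_strict():
    """d < 0.3 nm and angle > 150 deg, both strict inequalities."""
    from slabpol.synthetic import _dimer_config
    assert len(_bonds_for(_dimer_config(0.28, 170.0))) == 1
    assert len(_bonds_for(_dimer_config(0.32, 170.0))) == 0
    assert len(_bonds_for(_dimer_config(0.28, 140.0))) == 0
    assert len(_bonds_for(_dimer_config(0.29999, 150.001))) == 1


def test_bond_attributes():
    from slabpol.synthetic import _dimer_config
    b = _bonds_for(_dimer_config(0.28, 170.0))[0]
    assert b.distance == pytest.approx(0.28, abs=1e-9)
    assert b.angle == pytest.approx(170.0, abs=1e-6)
    assert b.donor_molecule == 0
    assert b.acceptor_molecule == 1


def test_donor_not_bonded_error():
    cfg = water_config([[1.0, 1.0, 1.0]], box=(4.0, 4.0, 4.0))
    donors = np.array([[0, 5]])     # H of a *different* molecule
    cfg2 = water_config([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]],
                        box=(4.0, 4.0, 4.0))
    with pytest.raises(ValueError, match="not bonded"):
        sp.detect_hydrogen_bonds(cfg2, donors, np.array([3]))


def test_rigid_motion_invariance():
    """Bond sets survive global translation+rotation about z with rewrap."""
    from slabpol.synthetic import _dimer_config
    cfg = _dimer_config(0.285, 165.0)
    base = {(b.donor_H, b.acceptor_heavy) for b in _bonds_for(cfg)}
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    pos = cfg.positions @ R.T + np.array([5.1, -2.3, 0.4])
    pos[:, 0] %= cfg.box[0]
    pos[:, 1] %= cfg.box[1]
    moved = sp.MolecularConfiguration(
        positions=pos, charges=cfg.charges, molecule_id=cfg.molecule_id,
        species_label=cfg.species_label, atom_names=cfg.atom_names,
        box=cfg.box, vdw_radius=cfg.vdw_radius)
    assert {(b.donor_H, b.acceptor_heavy) for b in _bonds_for(moved)} == base


def test_partition_conservation():
    """N_H1 + N_H2 + water_water equals the total bond count."""
    slab = sp.SlabSpec(area=9.0, thickness=2.0, density=30.0, n_frames=4,
                       seed=31)
    sspec = sp.RoughSurfaceSpec(slab=slab, amplitude=0.2, wavelength=3.0,
                                group_density=1.5, seed=31)
    res = sp.generate_rough_decorated_surface(sspec)
    for cfg in res.frames:
        bonds = _bonds_for(cfg, res.descriptor)
        bonds, counts = sp.classify_surface_bonds(bonds, res.descriptor)
        n_surface_surface = sum(b.category == "surface_surface" for b in bonds)
        assert sum(counts.values()) + n_surface_surface == len(bonds)


def test_theta_prime_aligned_and_isotropic(isotropic_slab):
    """theta' = 0 for +n-aligned dipoles; 90 +- 0.5 deg for isotropy."""
    cfg = water_config(np.ones((50, 3)) + np.arange(50)[:, None] * 0.001,
                       cos_t=np.ones(50), box=(4.0, 4.0, 4.0))
    la = sp.LayerAssignment(layer_index=np.ones(50, dtype=int),
                            probe_radius=0.15, mesh_spacing=0.02,
                            n_layers=1, side="upper")
    mom = sp.molecular_moments(cfg, {"SOL": "OW"})
    stats = sp.orientation_statistics([cfg], [la], [[]], [mom])
    assert stats[0].theta_prime == pytest.approx(0.0, abs=1e-6)

    frames = isotropic_slab["result"].frames
    moms = isotropic_slab["moments"]
    n_mol = frames[0].n_molecules
    las = [sp.LayerAssignment(layer_index=np.ones(n_mol, dtype=int),
                              probe_radius=0.15, mesh_spacing=0.02,
                              n_layers=1, side="upper") for _ in frames]
    stats = sp.orientation_statistics(frames, las, [[] for _ in frames], moms)
    assert stats[0].n_molecules >= 1e5
    assert stats[0].theta_prime == pytest.approx(90.0, abs=0.5)


def test_theta_prime_matches_planted_langevin(biased_slab):
    """Layer-1 theta' agrees with arccos L(a) for the planted wall bias."""
    res = biased_slab["result"]
    frames = res.frames[:60]
    moms = biased_slab["moments"][:60]
    las, bonds = [], []
    for f, m in zip(frames, moms):
        layer = np.where(m.centers[:, 2] >= 4.2, 1, 0)
        las.append(sp.LayerAssignment(layer_index=layer, probe_radius=0.15,
                                      mesh_spacing=0.02, n_layers=1,
                                      side="upper"))
        bonds.append([])
    stats = sp.orientation_statistics(frames, las, bonds, moms,
                                      n_z=(0, 0, 1.0))
    expected = np.degrees(np.arccos(sp.langevin(-0.2)))
    assert stats[0].theta_prime > 90.0
    n = stats[0].n_molecules
    se_cos = (1 / np.sqrt(3)) / np.sqrt(n)
    se_deg = np.degrees(se_cos)          # d(arccos)/dx ~ -1 near x = 0
    assert stats[0].theta_prime == pytest.approx(expected, abs=3 * se_deg)


def test_nh_per_molecule_counting():
    """<N_H> counts each bond once per participating molecule."""
    from slabpol.synthetic import _dimer_config
    cfg = _dimer_config(0.28, 170.0)
    bonds = _bonds_for(cfg)
    donor, acceptor, n_bonds = _roles_per_molecule(bonds, cfg.n_molecules)
    assert donor.tolist() == [True, False]
    assert acceptor.tolist() == [False, True]
    assert n_bonds.tolist() == [1.0, 1.0]
    la = sp.LayerAssignment(layer_index=np.ones(2, dtype=int),
                            probe_radius=0.15, mesh_spacing=0.02,
                            n_layers=1, side="upper")
    mom = sp.molecular_moments(cfg, {"SOL": "OW"})
    stats = sp.orientation_statistics([cfg], [la], [bonds], [mom])
    assert stats[0].n_hb_per_molecule == pytest.approx(1.0)


def test_hbonded_dipole_distribution_signs():
    """Aligned bound molecules give mean +|mu|; a balanced mix gives 0."""
    centers = [[1.0, 1.0, 1.0], [1.0, 1.0, 1.28]]
    cfg = water_config(centers, cos_t=[1.0, 1.0], box=(4.0, 4.0, 4.0))
    bonds = _bonds_for(cfg)
    mom = sp.molecular_moments(cfg, {"SOL": "OW"})
    if bonds:
        _, _, mean = sp.hbonded_dipole_distribution(
            [cfg], [bonds], [mom], "water_water")
        assert abs(mean) <= MU_SPC + 1e-12


def test_type2_bias_gives_negative_mean_dipole():
    """A planted dipole bias away from a decorated top surface shows up
    as a negative mean mu_z of type-2-bonded solvent molecules."""
    slab = sp.SlabSpec(area=9.0, thickness=2.0, density=30.0, n_frames=6,
                       seed=47)
    sspec = sp.RoughSurfaceSpec(slab=slab, amplitude=0.1, wavelength=3.0,
                                group_density=2.0, surface_bias=-1.0,
                                surface_bias_width=0.35, seed=47)
    res = sp.generate_rough_decorated_surface(sspec)
    moms = [sp.molecular_moments(
        f, {"SOL": "OW", "WAL": "SI", "SOH": "OH", "SOM": "OD"})
        for f in res.frames]
    bonds_per_frame = [_bonds_for(f, res.descriptor) for f in res.frames]
    n_type2 = 0
    for bonds in bonds_per_frame:
        b2, counts = sp.classify_surface_bonds(bonds, res.descriptor)
        n_type2 += counts["type2"]
    assert n_type2 > 0
    _, _, mean = sp.hbonded_dipole_distribution(
        res.frames, bonds_per_frame, moms, "type2", descriptor=res.descriptor)
    assert mean < 0


def test_acceptor_charge_trend_monotonic():
    """Raising the planted surface charge level (deprotonation plus the
    matching orientational response) raises N_H1 and lowers N_H2."""
    n1s, n2s = [], []
    for deprot, a_surf in [(0.0, 0.0), (0.4, 1.5), (0.8, 4.0)]:
        slab = sp.SlabSpec(area=9.0, thickness=2.0, density=30.0,
                           n_frames=10, seed=53)
        sspec = sp.RoughSurfaceSpec(slab=slab, amplitude=0.1, wavelength=3.0,
                                    group_density=2.5,
                                    deprotonated_fraction=deprot,
                                    surface_bias=a_surf,
                                    surface_bias_width=0.35, seed=53)
        res = sp.generate_rough_decorated_surface(sspec)
        bonds_per_frame = [_bonds_for(f, res.descriptor) for f in res.frames]
        n1, n2 = sp.surface_bond_counts(bonds_per_frame, res.descriptor)
        n1s.append(n1)
        n2s.append(n2)
    assert n1s[0] < n1s[1] < n1s[2]
    assert n2s[0] > n2s[1] > n2s[2]


def test_bulk_reference_nh(isotropic_slab):
    frames = isotropic_slab["result"].frames[:10]
    moms = isotropic_slab["moments"][:10]
    bonds = [_bonds_for(f) for f in frames]
    nh = sp.bulk_reference_nh(frames, bonds, moms, z_center=2.5)
    assert nh >= 0.0
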