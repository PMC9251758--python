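"""Session-scoped synthetic datasets shared across test modules."""

import numpy as np
import pytest

import slabpol as sp


@pytest.fixture(scope="session")
def biased_slab():
    """2x2x4 nm^3 slab, 200 frames, bias a = -0.2 in a 0.3 nm layer at
    the right wall: the planted-phi0 recovery dataset."""
    spec = sp.SlabSpec(
        area=4.0, thickness=4.0, density=33.0, n_frames=200, seed=11,
        bias_layers=sp.wall_layer_bias(-0.2, 0.3, 0.5, 4.5, wall="right"),
    )
    res = sp.generate_slab(spec)
    moms = [sp.molecular_moments(f, {"SOL": "OW"}) for f in res.frames]
    profs = sp.polarization_profiles(res.frames, moments=moms)
    return {"spec": spec, "result": res, "moments": moms, "profiles": profs}


@pytest.fixture(scope="session")
def isotropic_slab():
    """Unbiased 2x2x4 nm^3 slab, 200 frames (~1e5 orientation samples)."""
    spec = sp.SlabSpec(area=4.0, thickness=4.0, density=33.0,
                       n_frames=200, seed=23)
    res = sp.generate_slab(spec)
    moms = [sp.molecular_moments(f, {"SOL": "OW"}) for f in res.frames]
    profs = sp.polarization_profiles(res.frames, moments=moms)
    return {"spec": spec, "result": res, "moments": moms, "profiles": profs}


@pytest.fixture(scope="session")
def capacitor_slab():
    """Linear-response capacitor: sigma = 0.05 e/nm^2, eps = 80, 200
    frames in a 3x3x4 nm^3 box (continuum-null dataset)."""
    spec = sp.SlabSpec(area=9.0, thickness=4.0, density=33.0,
                       n_frames=200, seed=37)
    res = sp.generate_capacitor_linear_response(spec, sigma=0.05,
                                                epsilon_target=80.0)
    moms = [sp.molecular_moments(f, {"SOL": "OW"}) for f in res.frames]
    profs = sp.polarization_profiles(res.frames, moments=moms)
    return {"spec": spec, "result": res, "moments": moms, "profiles": profs}
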