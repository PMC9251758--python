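"""Physical constants and internal units.

All quantities in the package are expressed in a fixed internal unit
system: lengths in nm, charges in elementary charges (e), potentials in
volts.  In these units the vacuum permittivity is

    eps0 = 8.8541878128e-12 C V^-1 m^-1
         = 0.0552635 e V^-1 nm^-1

which is the single conversion constant between polarization densities
(e nm^-2) integrated over nm and electrical potentials (V).
"""

#: vacuum permittivity in e V^-1 nm^-1
EPS0 = 0.0552635

#: geometric hydrogen-bond criteria: donor-heavy to acceptor-heavy
#: distance (nm, strict <) and donor-H...acceptor angle (degrees, strict >)
HBOND_DISTANCE_NM = 0.30
HBOND_ANGLE_DEG = 150.0

#: ITIM defaults: probe radius for water-like solvents (nm) and lateral
#: mesh spacing (nm)
ITIM_PROBE_RADIUS_WATER = 0.15
ITIM_PROBE_RADIUS_DMSO = 0.20
ITIM_MESH_SPACING = 0.02

#: default axial bin width for profiles (nm)
DEFAULT_BIN_WIDTH = 0.05
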