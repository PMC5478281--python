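"""Unit conventions and conversion constants.

Internal units throughout the package:

==========  ==============  =======================================
quantity    internal unit   notes
==========  ==============  =======================================
length      micrometre      segment lengths, vertex coordinates
force       nanonewton      tensions and adhesion strengths;
                            1 nN is also 1 nJ/m of line energy
time        second
energy      nN * um         1 nN*um = 1e-15 J (femtojoule)
angle       radian          converted to degrees only at the API
                            boundary (reports, CLI)
==========  ==============  =======================================

Friction constants:

* elongation viscosity  ``eta_elong``  -- nN*s   (force per strain rate)
* vertex friction       ``eta_z``      -- nN*s/um (1 nN*s/um = 1e-3 N*s/m)
* substrate friction    ``eta_par``, ``eta_perp`` -- Pa*s
  (force per unit length per velocity; 1 Pa*s * um/s * um = 1e-3 nN)
"""

import math

# force
PN_PER_NN = 1000.0
NN_PER_PN = 1.0e-3

# energy: internal (nN*um) -> joule
J_PER_NN_UM = 1.0e-15

# vertex friction: nN*s/um -> N*s/m
NSM_PER_NNSUM = 1.0e-3

# substrate friction: Pa*s expressed in internal nN/(um/s * um)
NN_PER_PAS_UM2 = 1.0e-3

# time
S_PER_MIN = 60.0

DEG_PER_RAD = 180.0 / math.pi
RAD_PER_DEG = math.pi / 180.0


def deg2rad(deg: float) -> float:
    return deg * RAD_PER_DEG


def rad2deg(rad: float) -> float:
    return rad * DEG_PER_RAD
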