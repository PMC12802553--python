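"""Physical constants and unit conversions (CODATA 2018)."""

#: Boltzmann constant in Hartree per Kelvin.
K_B_HA_PER_K = 3.166811563e-6

#: Boltzmann constant in J/K.
K_B_J_PER_K = 1.380649e-23

#: Planck constant in J*s.
H_J_S = 6.62607015e-34

#: Hartree in Joule.
HARTREE_J = 4.3597447222071e-18

#: Hartree in milli-Hartree.
MHA_PER_HA = 1.0e3


def ha_to_mha(e_ha: float) -> float:
    return e_ha * MHA_PER_HA


def mha_to_ha(e_mha: float) -> float:
    return e_mha / MHA_PER_HA
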