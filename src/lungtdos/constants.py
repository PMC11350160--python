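"""Physical constants shared by every module.

All lengths are centimetres, times nanoseconds, optical coefficients 1/cm.
"""

#: Speed of light in vacuum, cm/ns.
C_VACUUM_CM_NS: float = 29.9792458

#: Default refractive index of soft tissue.
N_TISSUE_DEFAULT: float = 1.4

#: Default refractive index of the external medium (air).
N_EXTERNAL_DEFAULT: float = 1.0


def speed_in_medium(n_in: float) -> float:
    """Speed of light inside a medium of refractive index ``n_in``, cm/ns."""
    if n_in < 1.0:
        raise ValueError(f"refractive index must be >= 1, got {n_in}")
    return C_VACUUM_CM_NS / n_in
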