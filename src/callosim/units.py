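"""Unit conventions and physical constants, centralized.

Conventions used throughout the package:

* b-value          : s/mm^2
* pulse timings    : ms (gradient duration ``delta``, separation ``Delta``, TE, TR)
* gradient strength: mT/m
* diffusivity      : um^2/ms  (1 um^2/ms == 1e-3 mm^2/s)
* length/diameter  : um
* relaxation rate  : 1/s
* MTSat            : percent units (p.u.)
"""

# Proton gyromagnetic ratio, rad s^-1 T^-1.
GYROMAGNETIC_RATIO_SI = 267.513e6

# Same constant expressed in the package's working units:
# rad ms^-1 um^-1 per (mT/m).  Multiplying by G [mT/m] gives the spatial
# phase-winding rate in rad/(ms um).
GAMMA = GYROMAGNETIC_RATIO_SI * 1e-9 * 1e-3

# 1 ms/um^2 (the natural b unit when mixing ms and um) equals 1000 s/mm^2.
B_MS_UM2_TO_S_MM2 = 1000.0


def b_to_ms_um2(b_s_mm2):
    """Convert a b-value from s/mm^2 to ms/um^2."""
    return b_s_mm2 / B_MS_UM2_TO_S_MM2


def b_from_ms_um2(b_ms_um2):
    """Convert a b-value from ms/um^2 to s/mm^2."""
    return b_ms_um2 * B_MS_UM2_TO_S_MM2
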