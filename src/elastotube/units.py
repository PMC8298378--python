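"""Unit conversions.

All internal computation is in CGS (cm, g, s; pressure in dyn/cm^2).
Conversions happen only at I/O boundaries: configuration files carry
stiffnesses in kPa and angles in degrees, results are reported in mmHg,
cm^2 and m/s.
"""

MMHG = 1333.22  # dyn/cm^2 per mmHg
KPA = 1.0e4  # dyn/cm^2 per kPa
M_PER_S = 100.0  # cm/s per m/s


def mmhg_to_cgs(p):
    return p * MMHG


def cgs_to_mmhg(p):
    return p / MMHG


def kpa_to_cgs(p):
    return p * KPA


def cgs_to_kpa(p):
    return p / KPA


def cms_to_ms(v):
    """cm/s -> m/s."""
    return v / M_PER_S
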