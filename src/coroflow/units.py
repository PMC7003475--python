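"""Unit conventions and conversions.

Everything internal is CGS (cm, g, s, dyn/cm^2).  Pressures cross the I/O
boundary in mmHg and are converted exactly once, here.
"""

MMHG_TO_DYN: float = 1333.22
"""1 mmHg in dyn/cm^2."""

LMIN_TO_MLS: float = 1000.0 / 60.0
"""1 L/min in cm^3/s."""


def mmhg_to_cgs(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG_TO_DYN


def cgs_to_mmhg(p_dyn: float) -> float:
    """Convert a pressure from dyn/cm^2 to mmHg."""
    return p_dyn / MMHG_TO_DYN


def lmin_to_mls(q_lmin: float) -> float:
    """Convert a flow rate from L/min to cm^3/s."""
    return q_lmin * LMIN_TO_MLS


def mls_to_lmin(q_mls: float) -> float:
    """Convert a flow rate from cm^3/s to L/min."""
    return q_mls / LMIN_TO_MLS
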