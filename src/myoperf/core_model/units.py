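"""Unit conventions and conversions.

All internal computation is done in CGS units:

* length   cm
* pressure dyn/cm^2  (barye)
* flow     mL/s
* resistance dyn.s/cm^5, capacitance cm^5/dyn, inductance dyn.s^2/cm^5

Clinical-facing values (mmHg, mL/min, mL/min/100 mL) are converted exactly
once at interface boundaries using the helpers below.
"""

from __future__ import annotations

#: dyn/cm^2 per mmHg
MMHG = 1333.22

#: dyn/cm^2 per Pa (1 Pa = 10 barye)
PA = 10.0

_TO_BARYE = {
    "mmHg": MMHG,
    "dyn/cm2": 1.0,
    "dyn/cm^2": 1.0,
    "Pa": PA,
}


def convert_pressure(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between mmHg, dyn/cm^2 and Pa.

    Parameters
    ----------
    value
        Pressure in ``from_unit``.
    from_unit, to_unit
        One of ``"mmHg"``, ``"dyn/cm2"`` (or ``"dyn/cm^2"``), ``"Pa"``.

    Returns
    -------
    float
        ``value`` expressed in ``to_unit``; exact linear conversion.
    """
    try:
        f = _TO_BARYE[from_unit]
    except KeyError:
        raise ValueError(f"unknown pressure unit {from_unit!r}") from None
    try:
        t = _TO_BARYE[to_unit]
    except KeyError:
        raise ValueError(f"unknown pressure unit {to_unit!r}") from None
    return value * (f / t)


def mmhg_to_barye(value: float) -> float:
    """mmHg -> dyn/cm^2."""
    return value * MMHG


def barye_to_mmhg(value: float) -> float:
    """dyn/cm^2 -> mmHg."""
    return value / MMHG


def mbf_clinical_to_flow_density(mbf: float) -> float:
    """mL/min/100mL -> (mL/s)/mL of tissue (i.e. 1/s)."""
    return mbf / 100.0 / 60.0


def flow_density_to_mbf_clinical(q: float) -> float:
    """(mL/s)/mL of tissue -> mL/min/100mL."""
    return q * 6000.0
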