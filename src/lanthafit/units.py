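"""Small unit helpers: concentrations are molar internally, volumes µL.

I/O accepts explicitly tagged concentration strings or (value, unit) pairs in
nM/µM/mM/M and converts to molar once at the boundary.
"""

from __future__ import annotations

import re

from .errors import InputError

#: gas constant, J mol^-1 K^-1
R_GAS = 8.31446261815324

_CONC_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

_CONC_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([pnuµm]?M)\s*$")


def to_molar(value: float | str, unit: str | None = None) -> float:
    """Convert a tagged concentration to molar.

    Accepts either ``to_molar(10, "uM")`` or ``to_molar("10 uM")``.
    """
    if isinstance(value, str):
        m = _CONC_RE.match(value)
        if not m:
            raise InputError(f"cannot parse concentration {value!r}")
        value, unit = float(m.group(1)), m.group(2)
    if unit is None:
        raise InputError("concentration unit tag is required")
    try:
        factor = _CONC_FACTORS[unit]
    except KeyError:
        raise InputError(f"unknown concentration unit {unit!r}") from None
    return float(value) * factor


def molar_to(value_molar: float, unit: str) -> float:
    """Convert a molar concentration to the requested unit."""
    try:
        return value_molar / _CONC_FACTORS[unit]
    except KeyError:
        raise InputError(f"unknown concentration unit {unit!r}") from None
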