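"""Parsing of raw museum coordinate strings.

Museum databases mix plain decimal degrees with degree–minute–second (DMS)
strings in a zoo of notations (``26°05'24"S``, ``26 05 24 S``, ``-26.09``).
This module turns one coordinate string into decimal degrees and classifies
the notation, so the QC layer can filter by reporting format and the
georeferencing layer can standardize.
"""

from __future__ import annotations

import re

_DECIMAL_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?)\s*([NSEWnsew]?)\s*$")
_DMS_RE = re.compile(
    r"""^\s*([+-]?)\s*(\d{1,3})\s*[°dD:\s]\s*          # degrees
         (\d{1,2}(?:\.\d+)?)\s*                        # minutes
         (?:['′mM:\s]\s*(\d{1,2}(?:\.\d+)?)\s*["″sS]?)?  # optional seconds
         \s*([NSEWnsew]?)\s*$""",
    re.VERBOSE,
)

#: absolute fractional parts of quarter-degree-square cell centres
QDS_FRACTIONS = (0.125, 0.375, 0.625, 0.875)


def parse_angle(raw: str) -> float:
    """Parse one coordinate string (decimal or DMS) to signed decimal degrees.

    Hemisphere letters S and W negate; an explicit leading sign also negates.
    Raises ``ValueError`` for unparseable input.
    """
    m = _DECIMAL_RE.match(raw)
    if m:
        val = float(m.group(1))
        if m.group(2).upper() in ("S", "W"):
            val = -abs(val)
        return val
    m = _DMS_RE.match(raw)
    if m:
        sign, deg, mins, secs, hemi = m.groups()
        val = float(deg) + float(mins) / 60.0 + (float(secs) if secs else 0.0) / 3600.0
        if sign == "-" or hemi.upper() in ("S", "W"):
            val = -val
        return val
    raise ValueError(f"unparseable coordinate string: {raw!r}")


def detect_format(raw: str) -> str:
    """Classify a non-empty coordinate string as 'DECIMAL' or 'DMS'.

    Raises ``ValueError`` if neither grammar matches.
    """
    if _DECIMAL_RE.match(raw):
        return "DECIMAL"
    if _DMS_RE.match(raw):
        return "DMS"
    raise ValueError(f"unparseable coordinate string: {raw!r}")


def is_quarter_degree_value(value: float, tol: float = 1e-9) -> bool:
    """True when |value| has a fractional part at a quarter-degree cell centre."""
    frac = abs(value) - int(abs(value))
    return any(abs(frac - q) <= tol for q in QDS_FRACTIONS)


def format_dms(value: float, hemi_pos: str, hemi_neg: str) -> str:
    """Render decimal degrees as a D°M'S" string with a hemisphere letter."""
    hemi = hemi_neg if value < 0 else hemi_pos
    total = abs(value)
    deg = int(total)
    rem = (total - deg) * 60.0
    mins = int(rem)
    secs = (rem - mins) * 60.0
    # guard against 60.0 rollover from floating error
    if secs >= 59.9999999:
        secs = 0.0
        mins += 1
    if mins >= 60:
        mins = 0
        deg += 1
    return f"{deg}°{mins:02d}'{secs:09.6f}\"{hemi}"
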