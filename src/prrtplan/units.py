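"""Administered-activity unit conversion (GBq / MBq / mCi)."""

from __future__ import annotations

__all__ = ["convert_activity"]

#: defining constant: 1 mCi = 37 MBq exactly
_MBQ_PER_UNIT = {"MBq": 1.0, "GBq": 1000.0, "mCi": 37.0}


def convert_activity(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an activity between GBq, MBq and mCi (exact, no rounding)."""
    try:
        in_mbq = value * _MBQ_PER_UNIT[from_unit]
        return in_mbq / _MBQ_PER_UNIT[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown activity unit {exc.args[0]!r}; expected one of GBq, MBq, mCi"
        ) from None
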