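"""Code 128 subset B encoding of identifier strings.

Code set B covers ASCII 32-126.  A symbol sequence is

    [Start B = 104] [data values: ASCII - 32] [checksum] [Stop = 106]

with checksum = (104 + sum of position * value) mod 103, positions
1-based over the data values.  Besides the raw value list, a printable
"font string" is produced using the de-facto Code 128 barcode-font
mapping (values 0-94 -> ASCII 32-126, values 95-106 -> ASCII 195-206),
which is deterministic and invertible.
"""

from __future__ import annotations

import dataclasses

__all__ = [
    "Code128Sequence",
    "START_B",
    "STOP",
    "decode_font_string",
    "encode_128B",
    "from_font_string",
    "to_font_string",
]

START_B = 104
STOP = 106


@dataclasses.dataclass(frozen=True)
class Code128Sequence:
    """Symbol values of one encoded string: start, data, checksum, stop."""

    values: tuple[int, ...]
    text: str

    @property
    def data_values(self) -> tuple[int, ...]:
        return self.values[1:-2]

    @property
    def checksum(self) -> int:
        return self.values[-2]


def _checksum(data_values: tuple[int, ...]) -> int:
    return (START_B + sum(i * v for i, v in enumerate(data_values, start=1))) % 103


def encode_128B(text: str) -> Code128Sequence:
    """Encode a string as a Code 128B symbol sequence.

    Every character must lie in ASCII 32-126 (the code set B charset);
    the empty string is rejected.
    """
    if not text:
        raise ValueError("cannot encode an empty string")
    data = []
    for ch in text:
        o = ord(ch)
        if not (32 <= o <= 126):
            raise ValueError(f"character {ch!r} outside the Code 128B charset (ASCII 32-126)")
        data.append(o - 32)
    data = tuple(data)
    return Code128Sequence((START_B, *data, _checksum(data), STOP), text)


def _font_char(value: int) -> str:
    if 0 <= value <= 94:
        return chr(value + 32)
    if 95 <= value <= 106:
        return chr(value + 100)
    raise ValueError(f"symbol value {value} outside 0..106")


def _font_value(ch: str) -> int:
    o = ord(ch)
    if 32 <= o <= 126:
        return o - 32
    if 195 <= o <= 206:
        return o - 100
    raise ValueError(f"font character {ch!r} maps to no Code 128 symbol value")


def to_font_string(seq: Code128Sequence) -> str:
    """Map each symbol value to its barcode-font codepoint."""
    return "".join(_font_char(v) for v in seq.values)


def from_font_string(font: str) -> tuple[int, ...]:
    """Inverse of :func:`to_font_string`: recover the symbol values."""
    return tuple(_font_value(ch) for ch in font)


def decode_font_string(font: str) -> Code128Sequence:
    """Decode a font string back to a validated symbol sequence.

    Checks the start/stop codes and the mod-103 checksum, and rebuilds
    the source text from the data values.
    """
    values = from_font_string(font)
    if len(values) < 4:
        raise ValueError("sequence too short: need start, data, checksum, stop")
    if values[0] != START_B:
        raise ValueError(f"sequence does not begin with Start B ({START_B})")
    if values[-1] != STOP:
        raise ValueError(f"sequence does not end with Stop ({STOP})")
    data = values[1:-2]
    if values[-2] != _checksum(data):
        raise ValueError("checksum mismatch")
    text = "".join(chr(v + 32) for v in data)
    return Code128Sequence(values, text)
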