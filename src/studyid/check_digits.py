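"""Check-digit computation and verification for study identifiers.

Four schemes are supported, differing in which manual-entry error
classes they detect:

``PARITY``
    check = (sum of character values) mod 10.  Detects single-character
    substitutions whose value change is nonzero mod 10; detects no
    transpositions.
``WEIGHTED_PARITY``
    check = (sum of position * value) mod 10, positions 1-based from the
    left.  Additionally detects every adjacent transposition of distinct
    digits, but misses some non-adjacent transpositions (those whose
    digit difference is 5).
``GUMM_1986``
    a mod-11 scheme with weights 2^i (1-based position): the check digit
    c satisfies (sum 2^i * value_i + c) = 0 mod 11.  Detects all
    single-digit substitutions and all transpositions (adjacent or not)
    for payloads of up to 9 characters.  When c would be 10 there is no
    single-digit check; :data:`REDRAW` is returned and the caller must
    discard the candidate random number and draw another.
``DAMM_2004``
    an interim-digit walk through a totally anti-symmetric quasigroup of
    order 10.  Detects all single-digit substitutions and all adjacent
    transpositions, with the check digit always in 0-9.

Character values: a decimal digit contributes its numeric value; a
letter contributes its ASCII code (e.g. 'A' -> 65).  The table-based
schemes (Gumm, Damm) operate on digits only, so letters are reduced
modulo 10 before entering the table.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional, Union


class CheckAlgorithm(str, enum.Enum):
    """Check-digit scheme selector; ``NONE`` disables the check block."""

    NONE = "NONE"
    PARITY = "PARITY"
    WEIGHTED_PARITY = "WEIGHTED_PARITY"
    GUMM_1986 = "GUMM_1986"
    DAMM_2004 = "DAMM_2004"


class _Redraw:
    """Sentinel: the mod-11 scheme produced check value 10 (no single digit)."""

    _instance: Optional["_Redraw"] = None

    def __new__(cls) -> "_Redraw":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "REDRAW"


#: Returned by :func:`gumm` / :func:`compute_check` when the candidate
#: payload admits no single-digit check; the caller redraws the number.
REDRAW = _Redraw()

CheckResult = Union[int, _Redraw]


class RedrawRequired(Exception):
    """Raised when an identifier cannot carry a single-digit check."""


class CheckDigitError(ValueError):
    """Invalid payload or unknown algorithm."""


class IdParseError(ValueError):
    """An identifier string does not fit the expected block layout."""


# Totally anti-symmetric quasigroup of order 10 (Damm's construction);
# zero diagonal, so damm(p + damm(p)) == 0 for every payload p.
DAMM_TABLE: tuple[tuple[int, ...], ...] = (
    (0, 3, 1, 7, 5, 9, 8, 6, 4, 2),
    (7, 0, 9, 2, 1, 5, 4, 8, 6, 3),
    (4, 2, 0, 6, 8, 7, 1, 3, 5, 9),
    (1, 7, 5, 0, 9, 8, 3, 4, 2, 6),
    (6, 1, 2, 3, 0, 4, 5, 9, 7, 8),
    (3, 6, 7, 4, 2, 0, 9, 5, 8, 1),
    (5, 8, 6, 9, 7, 2, 0, 1, 3, 4),
    (8, 9, 4, 5, 3, 6, 2, 0, 1, 7),
    (9, 4, 3, 8, 6, 1, 7, 2, 0, 5),
    (2, 5, 8, 1, 4, 3, 6, 7, 9, 0),
)


def char_value(ch: str) -> int:
    """Numeric contribution of one identifier character.

    Digits map to their value, letters to their ASCII code ('A' -> 65).
    Anything else is rejected.
    """
    if len(ch) != 1:
        raise CheckDigitError(f"expected a single character, got {ch!r}")
    if ch.isdigit() and ch.isascii():
        return int(ch)
    if ch.isalpha() and ch.isascii():
        return ord(ch)
    raise CheckDigitError(f"character {ch!r} is not a digit or ASCII letter")


def _values(payload: str) -> Iterable[int]:
    if not payload:
        raise CheckDigitError("payload must be non-empty")
    return (char_value(c) for c in payload)


def parity(payload: str) -> int:
    """Sum of character values modulo 10."""
    return sum(_values(payload)) % 10


def weighted_parity(payload: str) -> int:
    """Position-weighted sum modulo 10; positions are 1-based, left to right."""
    return sum(i * v for i, v in enumerate(_values(payload), start=1)) % 10


def damm(payload: str) -> int:
    """Interim-digit walk through the anti-symmetric quasigroup.

    Letters are reduced modulo 10 before entering the table.
    """
    interim = 0
    for v in _values(payload):
        interim = DAMM_TABLE[interim][v % 10]
    return interim


def gumm(payload: str) -> CheckResult:
    """Mod-11 check digit with weights 2^i (1-based position).

    Returns the digit c in 0..9 with (sum 2^i * v_i + c) = 0 mod 11, or
    :data:`REDRAW` when c would be 10.  Letters are reduced mod 10.
    """
    total = sum(pow(2, i, 11) * (v % 10) for i, v in enumerate(_values(payload), start=1))
    c = (-total) % 11
    return REDRAW if c == 10 else c


_DISPATCH = {
    CheckAlgorithm.PARITY: parity,
    CheckAlgorithm.WEIGHTED_PARITY: weighted_parity,
    CheckAlgorithm.GUMM_1986: gumm,
    CheckAlgorithm.DAMM_2004: damm,
}


def compute_check(payload: str, algorithm: CheckAlgorithm) -> CheckResult:
    """Dispatch to the configured scheme.

    ``REDRAW`` is only possible for ``GUMM_1986``; the other schemes
    always return a digit in 0-9.
    """
    algorithm = CheckAlgorithm(algorithm)
    if algorithm is CheckAlgorithm.NONE:
        raise CheckDigitError("no check algorithm configured")
    return _DISPATCH[algorithm](payload)


def split_check(id_string: str, layout=None, widths=None) -> tuple[str, str]:
    """Split an identifier into (payload, check character).

    With no layout, the check digit is taken to be the last character.
    With a layout (any sequence of blocks with a ``kind`` attribute whose
    value is one of ``C/T/N/V/X``) and a width per block kind, the check
    character is located at its block position and the payload is every
    other character in rendered order.
    """
    if layout is None:
        if len(id_string) < 2:
            raise IdParseError(f"identifier {id_string!r} too short to carry a check digit")
        return id_string[:-1], id_string[-1]
    if widths is None:
        raise IdParseError("widths are required to parse a layout-structured identifier")
    pos = 0
    payload_parts: list[str] = []
    check = ""
    for block in layout:
        kind = getattr(block.kind, "value", block.kind)
        w = widths[kind]
        part = id_string[pos : pos + w]
        if len(part) != w:
            raise IdParseError(f"identifier {id_string!r} shorter than layout requires")
        if kind == "X":
            check = part
        else:
            payload_parts.append(part)
        pos += w
    if pos != len(id_string):
        raise IdParseError(
            f"identifier {id_string!r} has {len(id_string)} characters, layout requires {pos}"
        )
    if not check:
        raise IdParseError("layout has no check block")
    return "".join(payload_parts), check


def verify(id_string: str, algorithm: CheckAlgorithm, layout=None, widths=None) -> bool:
    """True iff the embedded check digit matches the recomputed one.

    Raises :class:`IdParseError` when the string cannot be parsed under
    the layout at all (distinct from a clean ``False``).
    """
    payload, check = split_check(id_string, layout, widths)
    if not (len(check) == 1 and check.isdigit()):
        return False
    result = compute_check(payload, algorithm)
    return result is not REDRAW and result == int(check)
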