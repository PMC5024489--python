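"""Domain model for block-structured study identifiers.

A study identifier is a fixed-width string assembled from ordered
blocks: a study-center code [C], a study-track code [T], a unique
random number [N], a visit code [V] and a check digit [X].  Only the
random number is mandatory; the other blocks are optional and may be
arranged in any order.  Identifiers come in layers — personal-data ID
(P), study-data ID (S), temporary linkage ID (T) and external-partner
ID (E) — that draw their numbers from disjoint pools so the layer of a
number is recoverable from its value alone.
"""

from __future__ import annotations

import dataclasses
import enum
import re
import string
from typing import Optional, Sequence

from .check_digits import (
    REDRAW,
    CheckAlgorithm,
    IdParseError,
    RedrawRequired,
    compute_check,
)

__all__ = [
    "Block",
    "BlockKind",
    "BlockLayout",
    "IdRecord",
    "Layer",
    "LayerInterval",
    "StudyConfig",
    "ValidationReport",
    "assemble_id",
    "block_widths",
    "is_valid_code",
    "is_valid_visit",
    "parse_id",
    "validate_config",
    "visit_code_for_layer",
]

# Codes rendered into IDs and used in file names: strictly alphanumeric,
# so the fixed-width parse and the filename templates stay unambiguous.
_CODE_RE = re.compile(r"^[A-Za-z0-9]+$")

# Visit alphabet: digits 1-9 or single ASCII letters; lowercase i, e, o
# are excluded (case sensitive, so I/E/O remain legal).
_VISIT_ALLOWED = set("123456789") | (set(string.ascii_letters) - set("ieo"))


class BlockKind(str, enum.Enum):
    CENTER = "C"
    TRACK = "T"
    NUMBER = "N"
    VISIT = "V"
    CHECK = "X"


class Layer(str, enum.Enum):
    """Identifier layer: personal, study, temporary-linkage or external."""

    P = "P"
    S = "S"
    T = "T"
    E = "E"


def is_valid_code(code: str) -> bool:
    """True for non-empty alphanumeric codes (no spaces, no specials)."""
    return bool(_CODE_RE.match(code))


def is_valid_visit(code: str) -> bool:
    """True for a single visit character from the allowed alphabet."""
    return len(code) == 1 and code in _VISIT_ALLOWED


@dataclasses.dataclass(frozen=True)
class Block:
    """One structural block of an identifier.

    ``code`` carries the literal text rendered into the ID for
    CENTER/TRACK/VISIT blocks and is empty for NUMBER/CHECK, whose
    content is generated.
    """

    kind: BlockKind
    code: str = ""

    def __post_init__(self) -> None:
        kind = BlockKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.code and not is_valid_code(self.code):
            raise ValueError(f"block code {self.code!r} contains illegal characters")
        if kind in (BlockKind.NUMBER, BlockKind.CHECK) and self.code:
            raise ValueError(f"{kind.name} blocks carry no literal code")


@dataclasses.dataclass(frozen=True)
class BlockLayout:
    """Ordered block structure of every identifier in a study.

    Exactly one NUMBER block; at most one each of CENTER, TRACK, VISIT
    and CHECK; the order is arbitrary and preserved.
    """

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        blocks = tuple(
            b if isinstance(b, Block) else Block(BlockKind(b)) for b in self.blocks
        )
        object.__setattr__(self, "blocks", blocks)
        counts = {kind: 0 for kind in BlockKind}
        for b in blocks:
            counts[b.kind] += 1
        if counts[BlockKind.NUMBER] != 1:
            raise ValueError("layout must contain exactly one NUMBER [N] block")
        for kind in (BlockKind.CENTER, BlockKind.TRACK, BlockKind.VISIT, BlockKind.CHECK):
            if counts[kind] > 1:
                raise ValueError(f"layout may contain at most one {kind.name} block")

    @classmethod
    def parse(cls, text: str) -> "BlockLayout":
        """Build a layout from a compact spec like ``"C,T,N,V,X"`` or ``"CTNVX"``."""
        letters = [p for p in re.split(r"[,\s]+", text.strip()) if p]
        if all(len(p) == 1 for p in letters):
            kinds = letters
        else:
            kinds = list("".join(letters))
        try:
            return cls(tuple(Block(BlockKind(ch.upper())) for ch in kinds))
        except ValueError as exc:
            raise ValueError(f"cannot parse layout {text!r}: {exc}") from None

    def kinds(self) -> tuple[BlockKind, ...]:
        return tuple(b.kind for b in self.blocks)

    def has(self, kind: BlockKind) -> bool:
        return kind in self.kinds()

    def __iter__(self):
        return iter(self.blocks)

    def __str__(self) -> str:
        return ",".join(b.kind.value for b in self.blocks)


@dataclasses.dataclass(frozen=True)
class LayerInterval:
    """Half-open range of random numbers owned by one identifier layer."""

    layer: Layer
    lower: int  # inclusive
    upper: int  # exclusive

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer", Layer(self.layer))
        if not self.lower < self.upper:
            raise ValueError(f"empty interval [{self.lower}; {self.upper})")

    @property
    def size(self) -> int:
        return self.upper - self.lower

    def __contains__(self, n: object) -> bool:
        return isinstance(n, int) and self.lower <= n < self.upper


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """Complete parameterization of one study's identifiers.

    ``tracks`` maps each track code to its requested sample size.  When
    the layout has no TRACK block the study has exactly one implicit
    track whose code is the empty string.
    """

    study_name: str
    layout: BlockLayout
    k: int
    tracks: tuple[tuple[str, int], ...]
    center: Optional[str] = None
    visit: str = "1"
    check_algorithm: CheckAlgorithm = CheckAlgorithm.NONE
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tracks", tuple((str(t), int(n)) for t, n in self.tracks))
        object.__setattr__(self, "check_algorithm", CheckAlgorithm(self.check_algorithm))

    @property
    def track_codes(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.tracks)

    @property
    def total_n(self) -> int:
        return sum(n for _, n in self.tracks)

    def with_tracks(self, tracks: Sequence[tuple[str, int]]) -> "StudyConfig":
        return dataclasses.replace(self, tracks=tuple(tracks))


@dataclasses.dataclass(frozen=True)
class IdRecord:
    """One assembled identifier: layer, raw number and rendered string."""

    layer: Layer
    number: int
    rendered: str
    visit_rendered: str


@dataclasses.dataclass
class ValidationReport:
    """Outcome of configuration plausibility checks."""

    issues: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, field: str, message: str) -> None:
        self.issues.append((field, message))

    def __str__(self) -> str:
        if self.ok:
            return "configuration OK"
        return "\n".join(f"{field}: {message}" for field, message in self.issues)


def block_widths(config: StudyConfig) -> dict[str, int]:
    """Fixed character width of each block kind, keyed by its letter.

    Center and track widths are the lengths of the configured codes (all
    tracks must share one width); the number block is ``k`` characters;
    visit and check are one character each.
    """
    track_codes = config.track_codes
    return {
        BlockKind.CENTER.value: len(config.center or ""),
        BlockKind.TRACK.value: len(track_codes[0]) if track_codes else 0,
        BlockKind.NUMBER.value: config.k,
        BlockKind.VISIT.value: 1,
        BlockKind.CHECK.value: 1,
    }


def validate_config(config: StudyConfig) -> ValidationReport:
    """Plausibility-check every user input; all violations are collected.

    Rules: names non-empty and alphanumeric; 2 <= k <= 9; track codes
    unique, equal width, with positive sample sizes; the requested total
    per layer strictly below the pool capacity 3*10^(k-1); visit drawn
    from the allowed alphabet; a CHECK block requires an algorithm.
    """
    report = ValidationReport()
    layout = config.layout

    if not is_valid_code(config.study_name):
        report.add("study_name", "study name must be non-empty and alphanumeric")

    if not (2 <= config.k <= 9):
        report.add("k", f"random-number length k={config.k} outside the supported range 2..9")

    if layout.has(BlockKind.CENTER):
        if not config.center or not is_valid_code(config.center):
            report.add("center", "a CENTER block requires a non-empty alphanumeric center code")
    if layout.has(BlockKind.TRACK):
        codes = config.track_codes
        if not codes:
            report.add("tracks", "a TRACK block requires at least one track")
        if len(set(codes)) != len(codes):
            report.add("tracks", "duplicate track code")
        for code in codes:
            if not is_valid_code(code):
                report.add("tracks", f"track code {code!r} must be non-empty and alphanumeric")
        widths = {len(c) for c in codes if c}
        if len(widths) > 1:
            report.add("tracks", "all track codes must share one width for fixed-width parsing")
    else:
        if len(config.tracks) != 1:
            report.add("tracks", "without a TRACK block the study has exactly one implicit track")
        elif config.tracks[0][0] != "":
            report.add("tracks", "the implicit track must have an empty code")

    for code, n in config.tracks:
        if n < 1:
            report.add("tracks", f"sample size for track {code!r} must be a positive integer")

    if 2 <= config.k <= 9:
        cap = 3 * 10 ** (config.k - 1)
        if config.total_n >= cap:
            report.add(
                "tracks",
                f"requested combinations exceed capacity: {config.total_n} requested, "
                f"pool holds {cap} numbers per layer (must be lower)",
            )

    if layout.has(BlockKind.VISIT) and not is_valid_visit(config.visit):
        report.add(
            "visit",
            f"visit code {config.visit!r} not allowed: use one digit 1-9 or one letter "
            "(lowercase i, e, o excluded; case sensitive)",
        )

    if layout.has(BlockKind.CHECK) and config.check_algorithm is CheckAlgorithm.NONE:
        report.add("check_algorithm", "a CHECK block requires a check-digit algorithm")
    if not layout.has(BlockKind.CHECK) and config.check_algorithm is not CheckAlgorithm.NONE:
        report.add("check_algorithm", "a check-digit algorithm requires a CHECK block")

    if config.seed is not None and config.seed < 0:
        report.add("seed", "seed must be a non-negative integer")

    return report


def visit_code_for_layer(layer: Layer, configured_visit: str) -> str:
    """Visit character actually rendered: always "0" for the personal layer."""
    return "0" if Layer(layer) is Layer.P else configured_visit


def assemble_id(
    layout: BlockLayout,
    center: str,
    track: str,
    number: int,
    visit: str,
    algorithm: CheckAlgorithm = CheckAlgorithm.NONE,
    *,
    k: Optional[int] = None,
) -> str:
    """Concatenate the blocks in layout order and fill in the check digit.

    The check digit is computed over all non-check characters in
    rendered order and substituted at the CHECK block's position, so a
    CHECK block may sit anywhere in the layout.  Deterministic.

    Raises :class:`RedrawRequired` when the mod-11 scheme yields check
    value 10 — the caller discards ``number`` and draws a new one.
    """
    num_str = str(number)
    if k is not None and len(num_str) != k:
        raise ValueError(f"number {number} has {len(num_str)} digits, expected k={k}")
    parts: list[str] = []
    check_index: Optional[int] = None
    for block in layout:
        if block.kind is BlockKind.CENTER:
            if not center:
                raise ValueError("layout has a CENTER block but no center code was given")
            parts.append(center)
        elif block.kind is BlockKind.TRACK:
            if not track:
                raise ValueError("layout has a TRACK block but no track code was given")
            parts.append(track)
        elif block.kind is BlockKind.NUMBER:
            parts.append(num_str)
        elif block.kind is BlockKind.VISIT:
            if not visit:
                raise ValueError("layout has a VISIT block but no visit code was given")
            parts.append(visit)
        else:  # CHECK
            check_index = len(parts)
            parts.append("?")
    if check_index is not None:
        algorithm = CheckAlgorithm(algorithm)
        if algorithm is CheckAlgorithm.NONE:
            raise ValueError("layout has a CHECK block but no algorithm is configured")
        payload = "".join(p for i, p in enumerate(parts) if i != check_index)
        digit = compute_check(payload, algorithm)
        if digit is REDRAW:
            raise RedrawRequired(f"number {number} admits no single-digit check; redraw")
        parts[check_index] = str(digit)
    return "".join(parts)


def parse_id(id_string: str, layout: BlockLayout, widths: dict[str, int]) -> dict[str, str]:
    """Slice an identifier back into its blocks by fixed widths.

    Returns a mapping from block letter (C/T/N/V/X) to the rendered
    substring; inverse of :func:`assemble_id` for valid inputs.
    """
    pos = 0
    out: dict[str, str] = {}
    for block in layout:
        w = widths[block.kind.value]
        part = id_string[pos : pos + w]
        if len(part) != w:
            raise IdParseError(f"identifier {id_string!r} shorter than the layout requires")
        out[block.kind.value] = part
        pos += w
    if pos != len(id_string):
        raise IdParseError(
            f"identifier {id_string!r} has {len(id_string)} characters, layout requires {pos}"
        )
    n = out.get(BlockKind.NUMBER.value, "")
    if not n.isdigit():
        raise IdParseError(f"number block {n!r} of {id_string!r} is not numeric")
    return out
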