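"""The five study-level identifier tasks and their key-pair files.

A study lives in a directory named after the study.  Its unit of output
is the two-column key-pair file linking two identifier layers:

* ``(ID-P, ID-T)`` — written in creation order; links personal data to
  the temporary ID.
* ``(ID-S, ID-T)`` — same ID-T values, rows shuffled so the file order
  cannot be used to re-associate ID-P with ID-S.
* ``(ID-S, ID-S')`` — visit extension: same participant, new visit code.
* ``(ID-S, ID-E)`` — external-partner IDs per project.

Tasks: :func:`create_ids` (baseline batch), :func:`add_ids` (extend a
study with new unique numbers), :func:`add_visit`, :func:`add_track`,
:func:`generate_external`.  :func:`load_study` reconstructs the full
per-layer used-number state from the files on disk, which is what makes
uniqueness guarantees hold across program runs.

Every file is also written as a ``_barcode`` companion holding Code
128B font strings for both columns.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
import re
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

from .barcode128 import encode_128B, to_font_string
from .check_digits import REDRAW, CheckAlgorithm, RedrawRequired, compute_check
from .id_model import (
    BlockKind,
    Layer,
    StudyConfig,
    ValidationReport,
    assemble_id,
    block_widths,
    is_valid_code,
    is_valid_visit,
    parse_id,
    validate_config,
    visit_code_for_layer,
)
from .io_config import CONFIG_FILENAME, load_config, save_config
from .unique_random import (
    NumberPool,
    RandomSource,
    draw_unique,
    external_pool,
    layer_interval,
)

__all__ = [
    "ConfigValidationError",
    "KeyPairFile",
    "PairKind",
    "StudyState",
    "StudyTaskError",
    "add_ids",
    "add_track",
    "add_visit",
    "create_ids",
    "generate_external",
    "load_study",
]

ProgressFn = Callable[[int, int], None]

AUDIT_FILENAME = "audit.log"


class StudyTaskError(RuntimeError):
    """A task precondition failed or the on-disk study is inconsistent."""


class ConfigValidationError(ValueError):
    """The configuration failed its plausibility checks."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(str(report))


class PairKind(str, enum.Enum):
    IDP_IDT = "IDP_IDT"
    IDS_IDT = "IDS_IDT"
    IDS_IDSVISIT = "IDS_IDSVISIT"
    IDS_IDE = "IDS_IDE"


def baseline_filename(study: str, kind: PairKind, track: str, n: int) -> str:
    return f"{study}_{kind.value}_T={track}_N={n}_Baseline.txt"


def visit_filename(study: str, track: str, n: int, visit: str) -> str:
    return f"{study}_IDS_IDS{visit}_T={track}_N={n}_V={visit}.txt"


def external_filename(study: str, track: str, n: int, project: str) -> str:
    return f"{study}_IDS_IDE_T={track}_N={n}_Prj={project}.txt"


_FILE_RE = re.compile(
    r"^(?P<study>[A-Za-z0-9]+)_"
    r"(?P<kind>IDP_IDT|IDS_IDT|IDS_IDE|IDS_IDS(?P<vnew>[0-9A-Za-z]))_"
    r"T=(?P<track>[A-Za-z0-9]*)_"
    r"N=(?P<n>\d+)_"
    r"(?:Baseline|V=(?P<v>[0-9A-Za-z])|Prj=(?P<prj>[A-Za-z0-9]+))"
    r"(?P<barcode>_barcode)?\.(?P<ext>txt|old\d*)$"
)


@dataclasses.dataclass
class KeyPairFile:
    """One two-column key-pair mapping plus its templated file name."""

    pair_kind: PairKind
    track: str
    rows: list[tuple[str, str]]
    filename: str
    visit: Optional[str] = None
    project: Optional[str] = None

    def __post_init__(self) -> None:
        lefts = [l for l, _ in self.rows]
        rights = [r for _, r in self.rows]
        if len(set(lefts)) != len(lefts):
            raise StudyTaskError(f"{self.filename}: left-column IDs are not unique")
        if len(set(rights)) != len(rights):
            raise StudyTaskError(f"{self.filename}: right-column IDs are not unique")

    @property
    def barcode_filename(self) -> str:
        stem, ext = self.filename.rsplit(".", 1)
        return f"{stem}_barcode.{ext}"

    def write(self, directory: Path) -> list[Path]:
        """Write the pair file and its Code 128B companion atomically."""
        directory = Path(directory)
        written = []
        for name, render in (
            (self.filename, lambda s: s),
            (self.barcode_filename, lambda s: to_font_string(encode_128B(s))),
        ):
            path = directory / name
            tmp = path.with_name(path.name + ".tmp")
            with open(tmp, "w", encoding="utf-8") as fh:
                for left, right in self.rows:
                    fh.write(f"{render(left)}\t{render(right)}\n")
            tmp.replace(path)
            written.append(path)
        return written

    @staticmethod
    def read_rows(path: Path) -> list[tuple[str, str]]:
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise StudyTaskError(
                        f"{path.name}:{lineno}: expected two tab-separated columns"
                    )
                rows.append((parts[0], parts[1]))
        return rows


@dataclasses.dataclass
class _DiscoveredFile:
    path: Path
    kind: PairKind
    track: str
    n: int
    visit: Optional[str]
    project: Optional[str]
    is_old: bool
    rows: list[tuple[str, str]]


@dataclasses.dataclass
class StudyState:
    """Everything reconstructable from a study directory.

    ``used`` maps "P"/"S"/"T" (and ``("E", project)``) to the sets of
    random numbers already issued, which is the uniqueness scope for
    all later batches.  ``current`` holds the live (non-``.old``)
    baseline file per (pair kind, track).
    """

    directory: Path
    config: Optional[StudyConfig] = None
    files: list[_DiscoveredFile] = dataclasses.field(default_factory=list)
    used: dict = dataclasses.field(
        default_factory=lambda: {"P": set(), "S": set(), "T": set()}
    )
    current: dict = dataclasses.field(default_factory=dict)
    visits_used: set = dataclasses.field(default_factory=set)
    projects_used: set = dataclasses.field(default_factory=set)

    @property
    def tracks_on_disk(self) -> set:
        return {f.track for f in self.files}

    def current_rows(self, kind: PairKind, track: str) -> list[tuple[str, str]]:
        f = self.current.get((kind, track))
        return list(f.rows) if f else []


def _audit(directory: Path, task: str, enabled: bool, **fields) -> None:
    if not enabled:
        return
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    detail = "\t".join(f"{k}={v}" for k, v in fields.items())
    with open(Path(directory) / AUDIT_FILENAME, "a", encoding="utf-8") as fh:
        fh.write(f"{stamp}\t{task}\t{detail}\n")


def _number_of(id_string: str, config: StudyConfig) -> int:
    parts = parse_id(id_string, config.layout, block_widths(config))
    return int(parts[BlockKind.NUMBER.value])


def _check_width(config: StudyConfig) -> int:
    return 1 if config.layout.has(BlockKind.CHECK) else 0


def load_study(directory: Union[str, Path]) -> StudyState:
    """Rebuild a study's state from its directory.

    Parses every key-pair file (including archived ``.old`` batches),
    reconstructs the per-layer used-number sets and validates internal
    consistency; corrupt or mutually inconsistent files raise
    :class:`StudyTaskError` naming the file.  An empty directory yields
    an empty state.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise StudyTaskError(f"study directory {directory} does not exist")
    state = StudyState(directory=directory)

    config_path = directory / CONFIG_FILENAME
    entries = sorted(p for p in directory.iterdir() if p.is_file())
    pair_paths = [p for p in entries if _FILE_RE.match(p.name)]
    if config_path.exists():
        state.config = load_config(config_path)
    elif pair_paths:
        raise StudyTaskError(f"{directory} holds key-pair files but no {CONFIG_FILENAME}")
    else:
        return state

    config = state.config
    state.visits_used.add(config.visit)
    check_w = _check_width(config)

    for path in pair_paths:
        m = _FILE_RE.match(path.name)
        if m.group("barcode"):
            continue
        vnew = m.group("vnew")
        kind = PairKind.IDS_IDSVISIT if vnew else PairKind(m.group("kind"))
        rows = KeyPairFile.read_rows(path)
        f = _DiscoveredFile(
            path=path,
            kind=kind,
            track=m.group("track"),
            n=int(m.group("n")),
            visit=vnew,
            project=m.group("prj"),
            is_old=m.group("ext") != "txt",
            rows=rows,
        )
        state.files.append(f)

        for col, ids in (("left", [l for l, _ in rows]), ("right", [r for _, r in rows])):
            if len(set(ids)) != len(ids):
                raise StudyTaskError(f"{path.name}: duplicate ID in {col} column")

        try:
            if kind is PairKind.IDP_IDT:
                for left, right in rows:
                    state.used["P"].add(_number_of(left, config))
                    state.used["T"].add(_number_of(right, config))
            elif kind is PairKind.IDS_IDT:
                for left, right in rows:
                    state.used["S"].add(_number_of(left, config))
                    state.used["T"].add(_number_of(right, config))
            elif kind is PairKind.IDS_IDSVISIT:
                state.visits_used.add(f.visit)
                for left, _ in rows:
                    state.used["S"].add(_number_of(left, config))
            else:  # IDS_IDE
                project = f.project
                state.projects_used.add(project)
                pool = state.used.setdefault(("E", project), set())
                num_w = config.k + 1
                for left, right in rows:
                    state.used["S"].add(_number_of(left, config))
                    body = right[len(project):]
                    num = body[: len(body) - check_w] if check_w else body
                    if len(num) != num_w or not num.isdigit():
                        raise StudyTaskError(
                            f"{path.name}: external ID {right!r} does not parse as "
                            f"project + {num_w}-digit number"
                        )
                    pool.add(int(num))
        except ValueError as exc:
            raise StudyTaskError(f"{path.name}: {exc}") from None

        if not f.is_old and kind in (PairKind.IDP_IDT, PairKind.IDS_IDT):
            key = (kind, f.track)
            if key in state.current:
                raise StudyTaskError(
                    f"ambiguous study: both {state.current[key].path.name} and "
                    f"{path.name} are live {kind.value} files for track {f.track!r}"
                )
            state.current[key] = f

    # cross-file checks on the live baseline files
    for layer, kinds_cols in (
        ("P", [(PairKind.IDP_IDT, 0)]),
        ("S", [(PairKind.IDS_IDT, 0)]),
        ("T", [(PairKind.IDP_IDT, 1), (PairKind.IDS_IDT, 1)]),
    ):
        seen: dict[int, str] = {}
        for (kind, track), f in state.current.items():
            for col_kind, col in kinds_cols:
                if kind is not col_kind:
                    continue
                for row in f.rows:
                    num = _number_of(row[col], config)
                    prev = seen.get(num)
                    if prev is not None and prev != f.path.name and layer != "T":
                        raise StudyTaskError(
                            f"number {num} of layer {layer} appears in both "
                            f"{prev} and {f.path.name}"
                        )
                    seen[num] = f.path.name

    for track in {t for (_, t) in state.current}:
        fp = state.current.get((PairKind.IDP_IDT, track))
        fs = state.current.get((PairKind.IDS_IDT, track))
        if fp and fs:
            t_left = {_number_of(r, config) for _, r in fp.rows}
            t_right = {_number_of(r, config) for _, r in fs.rows}
            if t_left != t_right:
                raise StudyTaskError(
                    f"track {track!r}: ID-T sets of {fp.path.name} and "
                    f"{fs.path.name} differ"
                )
    return state


def _pools(config: StudyConfig, state: Optional[StudyState] = None) -> dict[Layer, NumberPool]:
    used = state.used if state else {"P": set(), "S": set(), "T": set()}
    return {
        layer: NumberPool(layer_interval(config.k, layer), set(used[layer.value]))
        for layer in (Layer.P, Layer.S, Layer.T)
    }


def _draw_one(
    pool: NumberPool,
    stream: RandomSource,
    config: StudyConfig,
    track: str,
    layer: Layer,
) -> tuple[int, str]:
    """Draw a number and assemble its ID, redrawing when the mod-11
    check admits no single digit (the rejected number stays burned)."""
    while True:
        num = draw_unique(pool, 1, stream)[0]
        try:
            rendered = assemble_id(
                config.layout,
                config.center or "",
                track,
                num,
                visit_code_for_layer(layer, config.visit),
                config.check_algorithm,
                k=config.k,
            )
            return num, rendered
        except RedrawRequired:
            continue


def _draw_track_rows(
    config: StudyConfig,
    track: str,
    n: int,
    pools: dict[Layer, NumberPool],
    streams: dict[Layer, RandomSource],
    progress: Optional[ProgressFn],
    done: int,
    total: int,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], int]:
    rows_pt, rows_st = [], []
    for _ in range(n):
        ids = {}
        for layer in (Layer.P, Layer.S, Layer.T):
            _, ids[layer] = _draw_one(pools[layer], streams[layer], config, track, layer)
            done += 1
            if progress:
                progress(done, total)
        rows_pt.append((ids[Layer.P], ids[Layer.T]))
        rows_st.append((ids[Layer.S], ids[Layer.T]))
    return rows_pt, rows_st, done


def _require_remaining(pools: dict[Layer, NumberPool], n_total: int) -> None:
    for layer, pool in pools.items():
        if n_total > pool.remaining:
            raise StudyTaskError(
                f"capacity exhausted for layer {layer.value}: {n_total} requested, "
                f"{pool.remaining} remaining"
            )


def create_ids(
    config: StudyConfig,
    rng: Optional[RandomSource] = None,
    base_dir: Union[str, Path] = ".",
    progress: Optional[ProgressFn] = None,
    audit: bool = True,
) -> list[KeyPairFile]:
    """Create the baseline batch: two key-pair files per track.

    For every participant slot a triple of numbers (ID-P, ID-S, ID-T)
    is drawn from the three disjoint layer intervals, all unique within
    the study.  The (ID-P, ID-T) file keeps creation order; the
    (ID-S, ID-T) file is row-shuffled with an independent stream.  The
    configuration is persisted into the new study directory.
    """
    report = validate_config(config)
    if not report.ok:
        raise ConfigValidationError(report)
    directory = Path(base_dir) / config.study_name
    if directory.exists():
        existing = [p.name for p in directory.iterdir() if _FILE_RE.match(p.name)]
        if existing or (directory / CONFIG_FILENAME).exists():
            raise StudyTaskError(
                f"directory {directory} already holds a study; use add_ids to extend it"
            )
    rng = rng or RandomSource(config.seed)
    pools = _pools(config)
    streams = {layer: rng.stream(f"draw/{layer.value}") for layer in pools}
    shuffle_gen = rng.stream("shuffle").generator()

    total = 3 * config.total_n
    done = 0
    outputs: list[KeyPairFile] = []
    for track, n in config.tracks:
        rows_pt, rows_st, done = _draw_track_rows(
            config, track, n, pools, streams, progress, done, total
        )
        shuffle_gen.shuffle(rows_st)
        outputs.append(
            KeyPairFile(
                PairKind.IDP_IDT, track, rows_pt,
                baseline_filename(config.study_name, PairKind.IDP_IDT, track, n),
            )
        )
        outputs.append(
            KeyPairFile(
                PairKind.IDS_IDT, track, rows_st,
                baseline_filename(config.study_name, PairKind.IDS_IDT, track, n),
            )
        )

    directory.mkdir(parents=True, exist_ok=True)
    save_config(config, directory / CONFIG_FILENAME)
    for f in outputs:
        f.write(directory)
    _audit(
        directory, "create_ids", audit,
        study=config.study_name, tracks=";".join(config.track_codes),
        n=";".join(str(n) for _, n in config.tracks), k=config.k,
        algorithm=config.check_algorithm.value, seed=config.seed,
        files=";".join(f.filename for f in outputs),
    )
    return outputs


def _archive(path: Path) -> Path:
    """Rename ``.txt`` to ``.old`` (``.old1``, ``.old2``... on collision)."""
    target = path.with_suffix(".old")
    i = 0
    while target.exists():
        i += 1
        target = path.with_suffix(f".old{i}")
    path.rename(target)
    return target


def _normalize_counts(
    config: StudyConfig, n_new: Union[int, Mapping[str, int]]
) -> dict[str, int]:
    if isinstance(n_new, int):
        if len(config.tracks) != 1:
            raise StudyTaskError(
                "an integer batch size is ambiguous for a multi-track study; "
                "pass a mapping of track code to count"
            )
        return {config.tracks[0][0]: n_new}
    counts = {str(t): int(n) for t, n in n_new.items()}
    known = set(config.track_codes)
    unknown = set(counts) - known
    if unknown:
        raise StudyTaskError(f"unknown tracks {sorted(unknown)}; add_track them first")
    return counts


def add_ids(
    config: StudyConfig,
    state: StudyState,
    n_new: Union[int, Mapping[str, int]],
    rng: Optional[RandomSource] = None,
    progress: Optional[ProgressFn] = None,
    audit: bool = True,
) -> list[KeyPairFile]:
    """Extend a study with a new batch of IDs, disjoint from all prior ones.

    Prior baseline files are archived (``.txt`` -> ``.old``) and merged
    files holding old plus new rows are written with the new total in
    their name.  Fails before touching any file when the remaining pool
    is too small.
    """
    counts = _normalize_counts(config, n_new)
    if any(n < 1 for n in counts.values()):
        raise StudyTaskError("batch sizes must be positive")
    rng = rng or RandomSource(config.seed)
    pools = _pools(config, state)
    n_total = sum(counts.values())
    _require_remaining(pools, n_total)

    streams = {layer: rng.stream(f"draw/add/{layer.value}") for layer in pools}
    shuffle_gen = rng.stream("shuffle/add").generator()
    total = 3 * n_total
    done = 0
    outputs: list[KeyPairFile] = []
    plans = []
    for track, n_add in counts.items():
        old_pt = state.current_rows(PairKind.IDP_IDT, track)
        old_st = state.current_rows(PairKind.IDS_IDT, track)
        new_pt, new_st, done = _draw_track_rows(
            config, track, n_add, pools, streams, progress, done, total
        )
        merged_pt = old_pt + new_pt
        merged_st = old_st + new_st
        shuffle_gen.shuffle(merged_st)
        n_merged = len(merged_pt)
        f_pt = KeyPairFile(
            PairKind.IDP_IDT, track, merged_pt,
            baseline_filename(config.study_name, PairKind.IDP_IDT, track, n_merged),
        )
        f_st = KeyPairFile(
            PairKind.IDS_IDT, track, merged_st,
            baseline_filename(config.study_name, PairKind.IDS_IDT, track, n_merged),
        )
        plans.append((track, f_pt, f_st))

    for track, f_pt, f_st in plans:
        for kind in (PairKind.IDP_IDT, PairKind.IDS_IDT):
            prior = state.current.get((kind, track))
            if prior is not None:
                _archive(prior.path)
                companion = prior.path.with_name(
                    prior.path.stem + "_barcode" + prior.path.suffix
                )
                if companion.exists():
                    _archive(companion)
        for f in (f_pt, f_st):
            f.write(state.directory)
            outputs.append(f)
            state.current[(f.pair_kind, track)] = _DiscoveredFile(
                path=state.directory / f.filename, kind=f.pair_kind, track=track,
                n=len(f.rows), visit=None, project=None, is_old=False,
                rows=list(f.rows),
            )

    for layer in (Layer.P, Layer.S, Layer.T):
        state.used[layer.value] = pools[layer].used
    _audit(
        state.directory, "add_ids", audit,
        study=config.study_name,
        n=";".join(f"{t}:{n}" for t, n in counts.items()),
        files=";".join(f.filename for f in outputs),
    )
    return outputs


def add_visit(
    config: StudyConfig,
    state: StudyState,
    new_visit: str,
    audit: bool = True,
) -> list[KeyPairFile]:
    """Issue follow-up study IDs for a new visit.

    No new numbers are drawn: each baseline ID-S keeps its random
    number and only the visit character changes (the check digit is
    recomputed when present).  Output is one (ID-S, ID-S') file per
    track, in baseline file order.
    """
    if not config.layout.has(BlockKind.VISIT):
        raise StudyTaskError("the layout has no VISIT block; visits cannot be encoded")
    if not is_valid_visit(new_visit):
        raise StudyTaskError(f"visit code {new_visit!r} not allowed")
    if new_visit in state.visits_used:
        raise StudyTaskError(f"visit {new_visit!r} has already been used in this study")

    widths = block_widths(config)
    outputs = []
    failures = []
    for track, _ in config.tracks:
        rows = state.current_rows(PairKind.IDS_IDT, track)
        out_rows = []
        for ids, _idt in rows:
            parts = parse_id(ids, config.layout, widths)
            try:
                new_ids = assemble_id(
                    config.layout,
                    parts.get(BlockKind.CENTER.value, ""),
                    parts.get(BlockKind.TRACK.value, ""),
                    int(parts[BlockKind.NUMBER.value]),
                    new_visit,
                    config.check_algorithm,
                    k=config.k,
                )
            except RedrawRequired:
                failures.append(ids)
                continue
            out_rows.append((ids, new_ids))
        if rows:
            outputs.append(
                KeyPairFile(
                    PairKind.IDS_IDSVISIT, track, out_rows,
                    visit_filename(config.study_name, track, len(out_rows), new_visit),
                    visit=new_visit,
                )
            )
    if failures:
        raise StudyTaskError(
            f"visit {new_visit!r} admits no single-digit mod-11 check for IDs "
            f"{failures[:5]}{'...' if len(failures) > 5 else ''}; the number is fixed, "
            "so these IDs cannot carry this visit under GUMM_1986"
        )
    for f in outputs:
        f.write(state.directory)
    state.visits_used.add(new_visit)
    _audit(
        state.directory, "add_visit", audit,
        study=config.study_name, visit=new_visit,
        files=";".join(f.filename for f in outputs),
    )
    return outputs


def add_track(
    config: StudyConfig,
    state: StudyState,
    new_track: str,
    audit: bool = True,
) -> list[KeyPairFile]:
    """Register a new study track by creating its empty baseline files.

    The files carry ``N=0``; a subsequent :func:`add_ids` populates
    them with numbers disjoint from every existing track.  The study
    configuration on disk is updated with the new track.
    """
    if not config.layout.has(BlockKind.TRACK):
        raise StudyTaskError("the layout has no TRACK block; tracks cannot be encoded")
    if not is_valid_code(new_track):
        raise StudyTaskError(f"track code {new_track!r} must be non-empty and alphanumeric")
    existing = set(config.track_codes) | state.tracks_on_disk
    if new_track in existing:
        raise StudyTaskError(f"track {new_track!r} has already been used in this study")
    widths = {len(c) for c in config.track_codes if c}
    if widths and len(new_track) not in widths:
        raise StudyTaskError(
            f"track {new_track!r} has width {len(new_track)}, study uses width {widths.pop()}"
        )

    outputs = []
    for kind in (PairKind.IDP_IDT, PairKind.IDS_IDT):
        f = KeyPairFile(
            kind, new_track, [],
            baseline_filename(config.study_name, kind, new_track, 0),
        )
        f.write(state.directory)
        state.current[(kind, new_track)] = _DiscoveredFile(
            path=state.directory / f.filename, kind=kind, track=new_track,
            n=0, visit=None, project=None, is_old=False, rows=[],
        )
        outputs.append(f)

    new_config = config.with_tracks(list(config.tracks) + [(new_track, 0)])
    save_config(new_config, state.directory / CONFIG_FILENAME)
    state.config = new_config
    _audit(
        state.directory, "add_track", audit,
        study=config.study_name, track=new_track,
        files=";".join(f.filename for f in outputs),
    )
    return outputs


def generate_external(
    state: StudyState,
    project: str,
    rng: Optional[RandomSource] = None,
    audit: bool = True,
) -> list[KeyPairFile]:
    """Create (ID-S, ID-E) key files for an external project.

    Each ID-E is the project code, a unique random number one digit
    longer than the study's k, and — when the study IDs carry one — a
    check digit under the same algorithm.  Every project draws from its
    own independent pool, so two external partners cannot link records
    through their ID-Es.  Rows are written sorted by ID-S.
    """
    config = state.config
    if config is None:
        raise StudyTaskError("study has no configuration; create it first")
    if not is_valid_code(project):
        raise StudyTaskError(f"project code {project!r} must be non-empty and alphanumeric")
    if project in state.projects_used:
        raise StudyTaskError(f"project {project!r} already has external IDs in this study")
    has_any = any(kind is PairKind.IDS_IDT for (kind, _t) in state.current)
    if not has_any:
        raise StudyTaskError("no (ID-S, ID-T) files found; create IDs first")

    rng = rng or RandomSource(config.seed)
    stream = rng.stream(f"external/{project}")
    pool = NumberPool(external_pool(config.k), set(state.used.get(("E", project), set())))
    use_check = (
        config.layout.has(BlockKind.CHECK)
        and config.check_algorithm is not CheckAlgorithm.NONE
    )

    outputs = []
    for track, _ in config.tracks:
        rows = state.current_rows(PairKind.IDS_IDT, track)
        if not rows:
            continue
        out_rows = []
        for ids, _idt in rows:
            while True:
                num = draw_unique(pool, 1, stream)[0]
                body = f"{project}{num}"
                if not use_check:
                    out_rows.append((ids, body))
                    break
                digit = compute_check(body, config.check_algorithm)
                if digit is REDRAW:
                    continue
                out_rows.append((ids, f"{body}{digit}"))
                break
        out_rows.sort(key=lambda row: row[0])
        outputs.append(
            KeyPairFile(
                PairKind.IDS_IDE, track, out_rows,
                external_filename(config.study_name, track, len(out_rows), project),
                project=project,
            )
        )
    for f in outputs:
        f.write(state.directory)
    state.projects_used.add(project)
    state.used[("E", project)] = pool.used
    _audit(
        state.directory, "generate_external", audit,
        study=config.study_name, project=project,
        files=";".join(f.filename for f in outputs),
    )
    return outputs
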