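"""XML persistence of study configurations.

Every study directory carries a ``config.xml`` recording all parameters
used to generate its identifiers, so later batch extensions, new visits
and external-ID runs reuse exactly the same structure.  The schema is
versioned; unknown elements found in an existing file are preserved on
rewrite.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Union

from .check_digits import CheckAlgorithm
from .id_model import BlockLayout, StudyConfig

__all__ = ["CONFIG_FILENAME", "ConfigFileError", "load_config", "save_config"]

CONFIG_FILENAME = "config.xml"
_SCHEMA_VERSION = "1"

_KNOWN_TAGS = {
    "study-name",
    "layout",
    "k",
    "center",
    "visit",
    "check-algorithm",
    "seed",
    "tracks",
}


class ConfigFileError(ValueError):
    """A configuration file is missing, malformed or ill-typed."""


def save_config(config: StudyConfig, path: Union[str, Path]) -> Path:
    """Write a configuration file; lossless round trip with :func:`load_config`.

    When ``path`` already holds a parseable configuration, elements with
    tags outside the schema are carried over unchanged.
    """
    path = Path(path)
    extras: list[ET.Element] = []
    if path.exists():
        try:
            old_root = ET.parse(path).getroot()
            extras = [el for el in old_root if el.tag not in _KNOWN_TAGS]
        except ET.ParseError:
            pass  # unreadable predecessor is simply replaced

    root = ET.Element("study-config", {"schema-version": _SCHEMA_VERSION})
    ET.SubElement(root, "study-name").text = config.study_name
    ET.SubElement(root, "layout").text = str(config.layout)
    ET.SubElement(root, "k").text = str(config.k)
    if config.center is not None:
        ET.SubElement(root, "center").text = config.center
    ET.SubElement(root, "visit").text = config.visit
    ET.SubElement(root, "check-algorithm").text = config.check_algorithm.value
    if config.seed is not None:
        ET.SubElement(root, "seed").text = str(config.seed)
    tracks = ET.SubElement(root, "tracks")
    for code, n in config.tracks:
        ET.SubElement(tracks, "track", {"code": code, "n": str(n)})
    root.extend(extras)

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tree.write(tmp, encoding="unicode", xml_declaration=True)
    tmp.replace(path)
    return path


def _text(root: ET.Element, tag: str, required: bool = True) -> Optional[str]:
    el = root.find(tag)
    if el is None or el.text is None:
        if required:
            raise ConfigFileError(f"missing <{tag}> element")
        return None
    return el.text.strip()


def _int(text: str, tag: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ConfigFileError(f"<{tag}> must be an integer, got {text!r}") from None


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Read a configuration file back into a :class:`StudyConfig`."""
    path = Path(path)
    if not path.exists():
        raise ConfigFileError(f"no configuration file at {path}")
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ConfigFileError(f"malformed XML in {path}: {exc}") from None
    if root.tag != "study-config":
        raise ConfigFileError(f"{path} is not a study configuration (root <{root.tag}>)")

    try:
        layout = BlockLayout.parse(_text(root, "layout"))
    except ValueError as exc:
        raise ConfigFileError(str(exc)) from None
    algo_text = _text(root, "check-algorithm")
    try:
        algorithm = CheckAlgorithm(algo_text)
    except ValueError:
        raise ConfigFileError(f"unknown check algorithm {algo_text!r}") from None

    tracks_el = root.find("tracks")
    if tracks_el is None:
        raise ConfigFileError("missing <tracks> element")
    tracks = []
    for el in tracks_el.findall("track"):
        code = el.get("code")
        n = el.get("n")
        if code is None or n is None:
            raise ConfigFileError("each <track> needs 'code' and 'n' attributes")
        tracks.append((code, _int(n, "track n")))

    seed_text = _text(root, "seed", required=False)
    return StudyConfig(
        study_name=_text(root, "study-name"),
        layout=layout,
        k=_int(_text(root, "k"), "k"),
        tracks=tuple(tracks),
        center=_text(root, "center", required=False),
        visit=_text(root, "visit"),
        check_algorithm=algorithm,
        seed=None if seed_text is None else _int(seed_text, "seed"),
    )
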