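"""Deterministic demo / test study generators.

Two profiles:

``small``
    one implicit track, 3-digit numbers, 10 participants, parity check
    — a sub-second study for tests and documentation examples.
``augur_like``
    a prospective-cohort shape: three recruitment tracks (registry,
    clinic, volunteers) encoded in the ID, a visit block, a Damm check
    digit, 140 participant slots total.  Number length and sample size
    are scaled down from a real recruitment campaign so the fixture
    builds in well under a second.

The same seed always yields a byte-identical directory (audit logging
is disabled because audit lines carry wall-clock timestamps).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from .check_digits import CheckAlgorithm
from .id_model import BlockLayout, StudyConfig
from .study_tasks import create_ids
from .unique_random import RandomSource

__all__ = ["PROFILES", "make_fixture_study"]

PROFILES = ("small", "augur_like")


def _profile_config(profile: str, seed: int) -> StudyConfig:
    if profile == "small":
        return StudyConfig(
            study_name="SMALL",
            layout=BlockLayout.parse("N,V,X"),
            k=3,
            tracks=(("", 10),),
            visit="1",
            check_algorithm=CheckAlgorithm.PARITY,
            seed=seed,
        )
    if profile == "augur_like":
        return StudyConfig(
            study_name="COHORT",
            layout=BlockLayout.parse("T,N,V,X"),
            k=4,
            tracks=(("1", 70), ("2", 40), ("3", 30)),
            visit="1",
            check_algorithm=CheckAlgorithm.DAMM_2004,
            seed=seed,
        )
    raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")


def make_fixture_study(
    profile: str, seed: int = 0, base_dir: Union[str, Path] = "."
) -> Path:
    """Create a populated study directory and return its path."""
    config = _profile_config(profile, seed)
    create_ids(config, rng=RandomSource(seed), base_dir=base_dir, audit=False)
    return Path(base_dir) / config.study_name
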