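"""Behaviour–sound classification framework.

Fattening pigs emit sounds in behavioural contexts that an expert observer
can label in the barn.  The framework organises those labels on three
levels: a top-level split into true *vocalizations* (produced by the vocal
tract) versus *other* sounds (cough, sneeze, ear shaking, snoring), a
welfare *valence* for vocalizations (positive/neutral, negative, or the
stand-alone alert category), and the concrete *behavior* itself.

The table is shipped as package data (``data/taxonomy.csv``) so external
tools can consume it without importing Python.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping


class Level1(str, Enum):
    """Top-level split: vocal-tract sound or not."""

    VOCALIZATION = "vocalization"
    OTHER = "other"


class Valence(str, Enum):
    """Welfare-related sign of a behaviour–vocalization combination."""

    POSITIVE_NEUTRAL = "positive_neutral"
    NEGATIVE = "negative"
    ALERT = "alert"
    OTHER = "other"


@dataclass(frozen=True)
class SoundClass:
    """Position of a behaviour label in the classification hierarchy."""

    behavior: str
    level1: Level1
    valence: Valence


def _load_table() -> dict[str, SoundClass]:
    path = resources.files("pigvox.data").joinpath("taxonomy.csv")
    table: dict[str, SoundClass] = {}
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["behavior"]] = SoundClass(
                behavior=row["behavior"],
                level1=Level1(row["level1"]),
                valence=Valence(row["valence"]),
            )
    return table


_TABLE: dict[str, SoundClass] = _load_table()

#: All recognised behaviour labels, in table order.
BEHAVIORS: tuple[str, ...] = tuple(_TABLE)

#: Aliases used interchangeably in field notes for the canonical labels.
DEFAULT_ALIASES: dict[str, str] = {
    "physical contact": "aversive_physical_contact",
    "physical_contact": "aversive_physical_contact",
    "resource conflict": "conflict_over_resources",
    "resource_conflict": "conflict_over_resources",
    "conflict over resources": "conflict_over_resources",
    "fighting": "fight",
    "playing": "playing_behavior",
    "playing behavior": "playing_behavior",
    "play": "playing_behavior",
    "grunt": "grunting",
    "cough": "coughing",
    "sneeze": "sneezing",
    "ear shaking": "ear_shaking",
    "snore": "snoring",
}


class UnknownBehaviorError(KeyError):
    """Raised for a behaviour label outside the framework (strict mode)."""


class UnknownValenceError(KeyError):
    """Raised for a valence label outside the framework."""


def _normalize(label: str) -> str:
    return " ".join(label.strip().lower().split())


def classify_behavior(
    label: str,
    strict: bool = True,
    aliases: Mapping[str, str] | None = None,
) -> SoundClass:
    """Map a behaviour label to its unique :class:`SoundClass`.

    Parameters
    ----------
    label:
        Behaviour name; case and surrounding/repeated whitespace are
        ignored.
    strict:
        When ``True`` only canonical labels are accepted.  When ``False``
        the alias table (``DEFAULT_ALIASES`` merged with *aliases*) is
        consulted first.
    aliases:
        Extra alias → canonical-label entries, e.g. from a config file.

    Raises
    ------
    UnknownBehaviorError
        If the (normalised, de-aliased) label is not in the framework.
    """
    norm = _normalize(label)
    key = norm.replace(" ", "_")
    if key not in _TABLE and not strict:
        merged = dict(DEFAULT_ALIASES)
        if aliases:
            merged.update({_normalize(a): c for a, c in aliases.items()})
        for probe in (norm, key):
            if probe in merged:
                key = merged[probe]
                break
    if key not in _TABLE:
        raise UnknownBehaviorError(f"unrecognized behavior label: {label!r}")
    return _TABLE[key]


def members_of(valence: Valence | str) -> frozenset[str]:
    """Return the behaviour labels carrying the given valence.

    The four valence sets partition the behaviour set.
    """
    try:
        val = Valence(valence)
    except ValueError as exc:
        raise UnknownValenceError(f"unrecognized valence label: {valence!r}") from exc
    return frozenset(b for b, sc in _TABLE.items() if sc.valence is val)


def valence_of(behaviors: Iterable[str]) -> dict[str, Valence]:
    """Convenience: valence for each canonical behaviour label given."""
    return {b: _TABLE[b].valence for b in behaviors}
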