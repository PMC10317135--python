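"""Outcome class scheme of the CrystalMation scoring system.

Crystallization wells are scored into 13 classes (12 user-facing classes
plus ``rim``, a preprocessing-only class for droplet-edge chops that would
otherwise be mistaken for crystals).  Each class carries a two-digit score
number whose leading digit encodes the coarse outcome; for evaluation the
classes collapse into the four groups *crystal*, *precipitate*, *other*
and *clear*.  Classes are totally ordered by priority: when a well
contains evidence for several classes, the highest-priority one wins.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Literal

import yaml

Group = Literal["crystal", "precipitate", "other", "clear"]

#: (name, score_no, group) in priority order, highest first.  Rim is the
#: preprocessing-only edge class and shares score number 1 with clear.
_FULL_TABLE: tuple[tuple[str, int, str], ...] = (
    ("Crystals harvestable", 23, "crystal"),
    ("Crystals bad form", 22, "crystal"),
    ("Crystals overnucleated", 21, "crystal"),
    ("Precipitate", 13, "precipitate"),
    ("Precipitate bad", 12, "precipitate"),
    ("Precipitate good", 11, "precipitate"),
    ("Null experiment", 34, "other"),
    ("Other", 33, "other"),
    ("Spherolites", 32, "other"),
    ("Phase separation", 31, "other"),
    ("Clear", 1, "clear"),
    ("Clear with other features", 2, "clear"),
    ("Rim", 1, "clear"),
)

_MERGED_TABLE: tuple[tuple[str, int, str], ...] = (
    ("crystal", 23, "crystal"),
    ("precipitate", 13, "precipitate"),
    ("other", 34, "other"),
    ("clear", 1, "clear"),
    ("rim", 1, "clear"),
)

#: score_no -> group for the 12 scored classes (rim handled via its flag).
_GROUP_OF_SCORE: dict[int, Group] = {
    23: "crystal", 22: "crystal", 21: "crystal",
    13: "precipitate", 12: "precipitate", 11: "precipitate",
    34: "other", 33: "other", 32: "other", 31: "other",
    1: "clear", 2: "clear",
}


@dataclass(frozen=True)
class ClassDef:
    """One outcome class: label, score number, group and priority rank."""

    name: str
    score_no: int
    group: Group
    priority_rank: int  # 0 = highest priority
    is_rim: bool = False

    def __post_init__(self) -> None:
        if self.group != _GROUP_OF_SCORE.get(self.score_no):
            raise ValueError(
                f"score {self.score_no} does not belong to group {self.group!r}"
            )
        if self.is_rim and self.score_no != 1:
            raise ValueError("rim must carry score number 1 (same as clear)")


@dataclass(frozen=True)
class ClassScheme:
    """An ordered collection of classes, highest priority first."""

    classes: tuple[ClassDef, ...]
    mode: Literal["full13", "merged5"]

    def __post_init__(self) -> None:
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        ranks = [c.priority_rank for c in self.classes]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise ValueError("priority ranks must be strictly increasing")
        expected = {"full13": 13, "merged5": 5}[self.mode]
        if len(self.classes) != expected:
            raise ValueError(f"{self.mode} scheme needs {expected} classes")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    @property
    def scored_classes(self) -> tuple[ClassDef, ...]:
        """Classes excluding the preprocessing-only rim class."""
        return tuple(c for c in self.classes if not c.is_rim)

    def by_name(self, name: str) -> ClassDef:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)

    def by_score(self, score_no: int, is_rim: bool = False) -> ClassDef:
        """Look up a class by score number (and the rim flag for score 1)."""
        for c in self.classes:
            if c.score_no == score_no and c.is_rim == is_rim:
                return c
        raise KeyError((score_no, is_rim))

    def index_of(self, class_def: ClassDef) -> int:
        """Position of a class in the scheme; the classifier's label index."""
        return self.classes.index(class_def)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"mode": self.mode, "classes": [asdict(c) for c in self.classes]}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassScheme":
        return cls(
            classes=tuple(ClassDef(**c) for c in d["classes"]),
            mode=d["mode"],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ClassScheme":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ClassScheme":
        return cls.from_dict(json.loads(text))


def _build(table: Iterable[tuple[str, int, str]], mode: str) -> ClassScheme:
    classes = tuple(
        ClassDef(
            name=name,
            score_no=score,
            group=group,  # type: ignore[arg-type]
            priority_rank=rank,
            is_rim=name.lower() == "rim",
        )
        for rank, (name, score, group) in enumerate(table)
    )
    return ClassScheme(classes=classes, mode=mode)  # type: ignore[arg-type]


def full_scheme() -> ClassScheme:
    """The full 13-class scheme in priority order, rim appended at clear."""
    return _build(_FULL_TABLE, "full13")


def merged_scheme() -> ClassScheme:
    """The 5-class merge: crystal, precipitate, other, clear, rim."""
    return _build(_MERGED_TABLE, "merged5")


def group_of(score_no: int, is_rim: bool = False) -> Group:
    """Map a score number to its 4-group evaluation label.

    Rim maps to clear (it shares score number 1).  Unknown score numbers
    raise ``KeyError`` -- they indicate a scheme mismatch upstream.
    """
    if is_rim:
        if score_no != 1:
            raise KeyError(f"rim chops carry score 1, got {score_no}")
        return "clear"
    try:
        return _GROUP_OF_SCORE[score_no]
    except KeyError:
        raise KeyError(f"unknown score number {score_no}") from None


def rank_compare(a: ClassDef, b: ClassDef) -> int:
    """Three-way priority comparison: negative if ``a`` outranks ``b``.

    The order is the scheme's top-to-bottom priority ranking
    (23 > 22 > 21 > 13 > 12 > 11 > 34 > 33 > 32 > 31 > 1 > 2, rim
    last-equal with clear -- compared by rank, rim sits after plain clear
    but ties with it for reporting purposes since both carry score 1).
    """
    return (a.priority_rank > b.priority_rank) - (a.priority_rank < b.priority_rank)
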