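"""Three-level indicator hierarchies with a round-wise revision audit trail.

Indicators are identified by dotted codes ("2.2.1"); the code alone determines
the level and the parent, so renames never break references. Revisions
(add/delete/rename) are applied per consultation round and recorded in an
ordered log; deleted indicators keep their records with ``status="deleted"``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "HierarchyError",
    "Indicator",
    "IndicatorHierarchy",
    "RevisionAction",
    "load_hierarchy",
    "write_hierarchy",
    "load_final_framework",
    "load_initial_framework",
    "load_revision_plan",
    "replay_revisions",
]

_STATUSES = {"active", "deleted", "revised", "merged"}


class HierarchyError(ValueError):
    """Raised for any structural violation; messages name the offending id."""


def _level_of(indicator_id: str) -> int:
    return len(indicator_id.split("."))


def _parent_of(indicator_id: str) -> str | None:
    parts = indicator_id.split(".")
    return ".".join(parts[:-1]) if len(parts) > 1 else None


def _id_key(indicator_id: str) -> tuple[int, ...]:
    """Sort key treating dotted codes numerically ("1.10" after "1.2")."""
    try:
        return tuple(int(p) for p in indicator_id.split("."))
    except ValueError:
        raise HierarchyError(f"malformed indicator id {indicator_id!r}") from None


@dataclass
class Indicator:
    """One node of the hierarchy.

    The level and the parent id are derived from ``id`` and validated against
    any explicitly supplied values on load.
    """

    id: str
    name: str
    interpretation: str = ""
    status: str = "active"
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _id_key(self.id)
        if self.status not in _STATUSES:
            raise HierarchyError(
                f"indicator {self.id}: unknown status {self.status!r}"
            )
        if not (1 <= self.level <= 3):
            raise HierarchyError(
                f"indicator {self.id}: level {self.level} outside 1..3"
            )

    @property
    def level(self) -> int:
        return _level_of(self.id)

    @property
    def parent_id(self) -> str | None:
        return _parent_of(self.id)

    @property
    def is_active(self) -> bool:
        return self.status in ("active", "revised")


@dataclass(frozen=True)
class RevisionAction:
    """A single recorded change: kind in {"add", "delete", "rename"}."""

    kind: str
    indicator_id: str
    name: str | None = None
    interpretation: str = ""
    note: str = ""

    @classmethod
    def from_dict(cls, d: dict) -> "RevisionAction":
        kind = d.get("action") or d.get("kind")
        if kind not in ("add", "delete", "rename"):
            raise HierarchyError(f"unknown revision action {kind!r}")
        return cls(
            kind=kind,
            indicator_id=d["id"],
            name=d.get("name") or d.get("new_name"),
            interpretation=d.get("interpretation", ""),
            note=d.get("note", ""),
        )


@dataclass
class IndicatorHierarchy:
    """Validated collection of indicators plus the revision log.

    ``round_log`` entries are ``(round, action, indicator_id, note)`` tuples in
    application order.
    """

    indicators: dict[str, Indicator] = field(default_factory=dict)
    round_log: list[tuple[int, str, str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_indicators(
        cls, indicators: Iterable[Indicator], metadata: dict | None = None
    ) -> "IndicatorHierarchy":
        h = cls(metadata=dict(metadata or {}))
        for ind in indicators:
            if ind.id in h.indicators:
                raise HierarchyError(f"duplicate indicator id {ind.id}")
            h.indicators[ind.id] = ind
        h.validate()
        return h

    # -- structure queries ------------------------------------------------

    def __iter__(self) -> Iterator[Indicator]:
        return iter(self.indicators.values())

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self.indicators

    def get(self, indicator_id: str) -> Indicator:
        try:
            return self.indicators[indicator_id]
        except KeyError:
            raise HierarchyError(f"unknown indicator id {indicator_id}") from None

    def active(self) -> list[Indicator]:
        return sorted(
            (i for i in self if i.is_active), key=lambda i: _id_key(i.id)
        )

    def active_at_level(self, level: int) -> list[Indicator]:
        return [i for i in self.active() if i.level == level]

    def active_counts(self) -> tuple[int, int, int]:
        """Number of active indicators at levels (1, 2, 3)."""
        return tuple(len(self.active_at_level(lv)) for lv in (1, 2, 3))

    def children_of(self, indicator_id: str) -> list[Indicator]:
        """Active children of an active indicator, sorted by id."""
        ind = self.get(indicator_id)
        if not ind.is_active:
            raise HierarchyError(f"indicator {indicator_id} is not active")
        return [
            i
            for i in self.active()
            if i.parent_id == indicator_id
        ]

    def leaves(self) -> list[Indicator]:
        """Active indicators with no active children."""
        parents = {i.parent_id for i in self.active()}
        return [i for i in self.active() if i.id not in parents]

    def validate(self) -> None:
        for ind in self:
            if ind.level > 1:
                parent = self.indicators.get(ind.parent_id)
                if parent is None:
                    raise HierarchyError(
                        f"orphan child {ind.id}: parent {ind.parent_id} missing"
                    )
                if ind.is_active and not parent.is_active:
                    raise HierarchyError(
                        f"active indicator {ind.id} has inactive parent {ind.parent_id}"
                    )

    # -- revisions --------------------------------------------------------

    def apply_revision(
        self, round_no: int, actions: Iterable[RevisionAction | dict]
    ) -> "IndicatorHierarchy":
        """Return a new hierarchy with one round of revisions applied.

        An empty action list still records a round marker. Deletions cascade
        status only to the named id (children must be deleted explicitly or
        the result fails validation).
        """
        h = copy.deepcopy(self)
        h.round_log.append((round_no, "round", "", "round marker"))
        for raw in actions:
            action = (
                raw if isinstance(raw, RevisionAction) else RevisionAction.from_dict(raw)
            )
            aid = action.indicator_id
            if action.kind == "add":
                if aid in h.indicators and h.indicators[aid].is_active:
                    raise HierarchyError(f"id collision on add: {aid}")
                h.indicators[aid] = Indicator(
                    id=aid,
                    name=action.name or aid,
                    interpretation=action.interpretation,
                )
                h.indicators = dict(
                    sorted(h.indicators.items(), key=lambda kv: _id_key(kv[0]))
                )
            elif action.kind == "delete":
                ind = h.get(aid)
                if not ind.is_active:
                    raise HierarchyError(f"cannot delete inactive indicator {aid}")
                ind.status = "deleted"
            elif action.kind == "rename":
                ind = h.get(aid)
                if not ind.is_active:
                    raise HierarchyError(f"cannot rename inactive indicator {aid}")
                if not action.name:
                    raise HierarchyError(f"rename of {aid} lacks a new name")
                ind.aliases = tuple(dict.fromkeys(ind.aliases + (ind.name,)))
                ind.name = action.name
                ind.status = "revised"
            h.round_log.append((round_no, action.kind, aid, action.note))
        h.validate()
        return h


# -- serialization --------------------------------------------------------


def _hierarchy_from_records(records: list[dict], metadata: dict) -> IndicatorHierarchy:
    indicators = []
    seen: set[str] = set()
    for rec in records:
        iid = rec["id"]
        if iid in seen:
            raise HierarchyError(f"duplicate indicator id {iid}")
        seen.add(iid)
        if "level" in rec and rec["level"] != _level_of(iid):
            raise HierarchyError(
                f"indicator {iid}: declared level {rec['level']} does not match id"
            )
        declared_parent = rec.get("parent")
        if declared_parent is not None and declared_parent != _parent_of(iid):
            raise HierarchyError(
                f"indicator {iid}: declared parent {declared_parent!r} does not match id"
            )
        indicators.append(
            Indicator(
                id=iid,
                name=rec["name"],
                interpretation=rec.get("interpretation", ""),
                status=rec.get("status", "active"),
                aliases=tuple(rec.get("aliases", ())),
            )
        )
    return IndicatorHierarchy.from_indicators(indicators, metadata=metadata)


def load_hierarchy(path: str | Path) -> IndicatorHierarchy:
    """Load and validate a hierarchy from a JSON or YAML file.

    The file holds ``{"metadata": {...}, "indicators": [{id, name, level,
    parent, interpretation}, ...]}``; ``level`` and ``parent`` are optional but
    checked against the id when present. Violations raise
    :class:`HierarchyError` naming the offending id — never silently repaired.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if isinstance(doc, list):  # bare list of records is accepted
        doc = {"indicators": doc}
    return _hierarchy_from_records(doc["indicators"], doc.get("metadata", {}))


def write_hierarchy(h: IndicatorHierarchy, path: str | Path) -> None:
    """Write a hierarchy to JSON (round-trips through :func:`load_hierarchy`)."""
    doc = {
        "metadata": h.metadata,
        "indicators": [
            {
                "id": i.id,
                "name": i.name,
                "level": i.level,
                "parent": i.parent_id,
                "interpretation": i.interpretation,
                "status": i.status,
                "aliases": list(i.aliases),
            }
            for i in h
        ],
    }
    Path(path).write_text(
        json.dumps(doc, indent=1, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def _data_path(name: str):
    return resources.files("delphiahp.data").joinpath(name)


def load_final_framework() -> IndicatorHierarchy:
    """The bundled final 3/9/19 digital-health-competency framework."""
    with resources.as_file(_data_path("final_framework.json")) as p:
        return load_hierarchy(p)


def load_initial_framework() -> IndicatorHierarchy:
    """The bundled pre-consultation framework (3/9/23 active indicators)."""
    with resources.as_file(_data_path("initial_framework.json")) as p:
        return load_hierarchy(p)


def load_revision_plan() -> list[dict]:
    """Recorded per-round revision actions taking the initial framework to the
    final one: ``[{"round": 1, "actions": [...]}, {"round": 2, ...}]``."""
    with resources.as_file(_data_path("framework_revisions.json")) as p:
        return json.loads(Path(p).read_text(encoding="utf-8"))


def replay_revisions(
    h: IndicatorHierarchy, plan: list[dict]
) -> IndicatorHierarchy:
    """Apply a multi-round revision plan in order."""
    for stage in plan:
        h = h.apply_revision(stage["round"], stage["actions"])
    return h
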