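"""Typed catalogue of secretory-pathway components with TSV I/O.

The catalogue file dialect is UTF-8 tab-separated text with a header row,
one component per row, and ";"-separated multi-valued cells. Component ids
are case-preserved but compared case-insensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Controlled vocabulary of sub-pathway labels.
SUBSYSTEM_VOCABULARY = frozenset(
    {
        "translocation",
        "protein_folding",
        "protein_transport",
        "UPR",
        "ERAD",
        "autophagy",
        "apoptosis",
        "ER_stress",
        "other",
    }
)

#: Columns of the catalogue TSV dialect, in order.
CATALOGUE_COLUMNS = (
    "id",
    "species",
    "subsystems",
    "functional_groups",
    "complexes",
    "evidence",
    "core",
    "partial",
    "kind",
    "homolog_of",
    "notes",
)


class Evidence(str, Enum):
    """Annotation support level of a component."""

    VERIFIED = "verified"
    TENTATIVE = "tentative"


class CatalogueError(ValueError):
    """Raised when a catalogue file or object violates its invariants."""


@dataclass(frozen=True)
class Component:
    """One secretory-pathway component (gene/protein) with its annotation.

    Parameters
    ----------
    id
        Unique gene symbol within a catalogue (compared case-insensitively).
    species
        Free-text species label, e.g. ``"mouse"``.
    subsystems
        Sub-pathway labels, each from :data:`SUBSYSTEM_VOCABULARY` unless
        the catalogue was loaded with ``allow_extra_labels``.
    functional_groups
        Literature-defined functional group labels (may be several).
    complexes
        Protein-complex labels the component belongs to.
    evidence
        :class:`Evidence` support level.
    core
        Whether the component belongs to the core secretory machinery.
    partial
        Whether the annotation is flagged partial.
    kind
        Node kind used when the catalogue is turned into a network;
        ``"component"`` normally, ``"isoprotein"`` for declared isoproteins.
    homolog_of
        Reference component id if this entry was transferred by homology.
    notes
        Free text.
    """

    id: str
    species: str = ""
    subsystems: frozenset[str] = frozenset()
    functional_groups: frozenset[str] = frozenset()
    complexes: frozenset[str] = frozenset()
    evidence: Evidence = Evidence.VERIFIED
    core: bool = False
    partial: bool = False
    kind: str = "component"
    homolog_of: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise CatalogueError("component id must be nonempty")
        if self.kind not in ("component", "isoprotein"):
            raise CatalogueError(f"invalid component kind {self.kind!r}")


@dataclass
class Catalogue:
    """An ordered, id-indexed collection of :class:`Component` records."""

    components: list[Component] = field(default_factory=list)
    species: str = ""
    source: str = ""
    extra_subsystem_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self._index: dict[str, Component] = {}
        for comp in self.components:
            key = comp.id.casefold()
            if key in self._index:
                raise CatalogueError(f"duplicate component id: {comp.id!r}")
            self._index[key] = comp

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self) -> Iterator[Component]:
        return iter(self.components)

    def __contains__(self, component_id: str) -> bool:
        return component_id.casefold() in self._index

    def get(self, component_id: str) -> Component:
        try:
            return self._index[component_id.casefold()]
        except KeyError:
            raise KeyError(f"unknown component id: {component_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.components]

    def validate(self) -> None:
        """Re-check the controlled vocabulary on every component."""
        allowed = SUBSYSTEM_VOCABULARY | self.extra_subsystem_labels
        for comp in self.components:
            unknown = comp.subsystems - allowed
            if unknown:
                raise CatalogueError(
                    f"component {comp.id!r}: unknown subsystem label(s) "
                    f"{sorted(unknown)}"
                )


def _parse_set(cell: str) -> frozenset[str]:
    return frozenset(tok.strip() for tok in cell.split(";") if tok.strip())


def _parse_bool(cell: str, *, line_no: int, column: str) -> bool:
    token = cell.strip().lower()
    if token in ("1", "true", "yes", "y"):
        return True
    if token in ("", "0", "false", "no", "n"):
        return False
    raise CatalogueError(f"line {line_no}: cannot parse boolean {column}={cell!r}")


def load_catalogue(
    path: str | Path,
    *,
    allow_extra_labels: bool = False,
    extra_labels: Iterable[str] = (),
) -> Catalogue:
    """Load a catalogue TSV, validating ids and controlled vocabularies.

    The file must carry a header row naming at least an ``id`` column; the
    remaining :data:`CATALOGUE_COLUMNS` are optional and default to empty.
    Unknown subsystem labels are errors unless ``allow_extra_labels`` is set
    or the labels are listed in ``extra_labels``.

    Raises
    ------
    CatalogueError
        On duplicate ids (all offenders listed), unknown subsystem labels
        (label and line number named), or malformed cells.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CatalogueError(f"{path}: empty catalogue file (header row required)")
    header = lines[0].rstrip("\n").split("\t")
    if "id" not in header:
        raise CatalogueError(f"{path}: header row must contain an 'id' column")
    col = {name: i for i, name in enumerate(header)}

    extra = frozenset(extra_labels)
    allowed = SUBSYSTEM_VOCABULARY | extra

    components: list[Component] = []
    seen: dict[str, int] = {}
    duplicates: dict[str, list[int]] = {}
    rejected: list[tuple[int, str]] = []

    def cell(fields: list[str], name: str) -> str:
        i = col.get(name)
        if i is None or i >= len(fields):
            return ""
        return fields[i]

    for line_no, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        cid = cell(fields, "id").strip()
        if not cid:
            rejected.append((line_no, "empty id"))
            continue
        key = cid.casefold()
        if key in seen:
            duplicates.setdefault(cid, [seen[key]]).append(line_no)
            continue
        seen[key] = line_no

        subsystems = _parse_set(cell(fields, "subsystems"))
        if not allow_extra_labels:
            unknown = subsystems - allowed
            if unknown:
                raise CatalogueError(
                    f"{path}: line {line_no}: unknown subsystem label(s) "
                    f"{sorted(unknown)} for component {cid!r}"
                )

        evidence_cell = cell(fields, "evidence").strip().lower() or "verified"
        try:
            evidence = Evidence(evidence_cell)
        except ValueError:
            raise CatalogueError(
                f"{path}: line {line_no}: invalid evidence value "
                f"{evidence_cell!r} (expected verified|tentative)"
            ) from None

        components.append(
            Component(
                id=cid,
                species=cell(fields, "species").strip(),
                subsystems=subsystems,
                functional_groups=_parse_set(cell(fields, "functional_groups")),
                complexes=_parse_set(cell(fields, "complexes")),
                evidence=evidence,
                core=_parse_bool(cell(fields, "core"), line_no=line_no, column="core"),
                partial=_parse_bool(
                    cell(fields, "partial"), line_no=line_no, column="partial"
                ),
                kind=cell(fields, "kind").strip() or "component",
                homolog_of=cell(fields, "homolog_of").strip() or None,
                notes=cell(fields, "notes").strip(),
            )
        )

    if duplicates:
        detail = "; ".join(
            f"{cid!r} on lines {lines_}" for cid, lines_ in sorted(duplicates.items())
        )
        raise CatalogueError(f"{path}: duplicate component id(s): {detail}")

    logger.info(
        "loaded %d components from %s (%d rejected rows)",
        len(components),
        path,
        len(rejected),
    )
    for line_no, reason in rejected:
        logger.warning("%s: line %d rejected: %s", path, line_no, reason)

    species = components[0].species if components else ""
    extra_seen: frozenset[str] = frozenset()
    if allow_extra_labels:
        extra_seen = frozenset().union(*(c.subsystems for c in components)) - SUBSYSTEM_VOCABULARY if components else frozenset()
    return Catalogue(
        components=components,
        species=species,
        source=str(path),
        extra_subsystem_labels=extra | extra_seen,
    )


def save_catalogue(cat: Catalogue, path: str | Path) -> None:
    """Write a catalogue in the TSV dialect read by :func:`load_catalogue`."""
    path = Path(path)
    rows = ["\t".join(CATALOGUE_COLUMNS)]
    for c in cat.components:
        rows.append(
            "\t".join(
                (
                    c.id,
                    c.species,
                    ";".join(sorted(c.subsystems)),
                    ";".join(sorted(c.functional_groups)),
                    ";".join(sorted(c.complexes)),
                    c.evidence.value,
                    "1" if c.core else "0",
                    "1" if c.partial else "0",
                    c.kind,
                    c.homolog_of or "",
                    c.notes,
                )
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def subsystem_counts(cat: Catalogue) -> dict[str, int]:
    """Count components per subsystem label.

    A component belonging to several subsystems contributes one count to
    each of them. Labels with no members are absent from the result; use
    ``result.get(label, 0)``.
    """
    counts: dict[str, int] = {}
    for comp in cat.components:
        for label in comp.subsystems:
            counts[label] = counts.get(label, 0) + 1
    return counts


def new_component(base: Component, **changes) -> Component:
    """Return a copy of ``base`` with ``changes`` applied."""
    return replace(base, **changes)
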