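"""Catalogue transfer between species from pairwise alignment hit tables.

Consumes standard 12-column tabular alignment output (qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore), with
optional columns 13-14 carrying partial / pseudogene flags for the subject.
Each reference protein is assigned its best hit (lowest e-value) and placed
in a tier:

* ``high`` -- percent identity above the high-identity cutoff;
* ``moderate`` -- identity above a lower cutoff, with a significant
  e-value and a bitscore above a floor;
* ``unmapped`` -- everything else, including subjects flagged pseudogene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from secrepath.catalogue import Catalogue, CatalogueError, Component, new_component

logger = logging.getLogger(__name__)


class HomologyError(ValueError):
    """Raised on malformed hit tables or inconsistent assignments."""


@dataclass(frozen=True)
class HomologyHit:
    """One alignment hit between a reference query and a target subject."""

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    evalue: float
    bitscore: float
    subject_partial: bool = False
    subject_pseudogene: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise HomologyError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise HomologyError(f"negative evalue {self.evalue}")


@dataclass(frozen=True)
class TierThresholds:
    """Acceptance rules for homolog assignment (all configurable)."""

    high_pident: float = 80.0
    moderate_pident: float = 60.0
    moderate_bitscore: float = 50.0
    moderate_evalue: float = 1e-5


@dataclass(frozen=True)
class HomologyAssignment:
    """Outcome for one reference id: a target id and tier, or unmapped."""

    reference_id: str
    target_id: str | None
    tier: str
    reason: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if self.tier not in ("high", "moderate", "unmapped"):
            raise HomologyError(f"invalid tier {self.tier!r}")
        if (self.tier == "unmapped") != (self.target_id is None):
            raise HomologyError(
                f"{self.reference_id}: tier {self.tier!r} inconsistent with "
                f"target {self.target_id!r}"
            )


def parse_hits(path: str | Path) -> list[HomologyHit]:
    """Parse a tabular alignment file into :class:`HomologyHit` records.

    Lines starting with ``#`` and blank lines are skipped. Columns 13 and
    14, when present, are read as partial and pseudogene flags
    (``1/true/yes`` count as set).
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    truthy = ("1", "true", "yes")
    for line_no, raw in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise HomologyError(
                f"{path}: line {line_no}: expected >= 12 tab-separated "
                f"columns, found {len(fields)}"
            )
        try:
            hit = HomologyHit(
                query_id=fields[0],
                subject_id=fields[1],
                pident=float(fields[2]),
                aln_length=int(fields[3]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                subject_partial=len(fields) > 12
                and fields[12].strip().lower() in truthy,
                subject_pseudogene=len(fields) > 13
                and fields[13].strip().lower() in truthy,
            )
        except (ValueError, HomologyError) as exc:
            raise HomologyError(f"{path}: line {line_no}: {exc}") from None
        hits.append(hit)
    return hits


def _best_hit(hits: Sequence[HomologyHit]) -> HomologyHit:
    # lowest e-value; ties -> higher bitscore, higher pident, then subject id
    return min(
        hits, key=lambda h: (h.evalue, -h.bitscore, -h.pident, h.subject_id)
    )


def assign_homologs(
    hits: Sequence[HomologyHit],
    thresholds: TierThresholds = TierThresholds(),
) -> list[HomologyAssignment]:
    """Assign each reference query exactly one tiered homolog decision.

    Pseudogene subjects are excluded before the best hit is chosen; a query
    whose hits are all pseudogenes is unmapped with reason ``pseudogene``.
    The partial flag of the accepted subject propagates to the assignment.
    Assignments are returned sorted by reference id.
    """
    by_query: dict[str, list[HomologyHit]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)

    assignments: list[HomologyAssignment] = []
    for query_id in sorted(by_query):
        candidates = [h for h in by_query[query_id] if not h.subject_pseudogene]
        if not candidates:
            assignments.append(
                HomologyAssignment(query_id, None, "unmapped", reason="pseudogene")
            )
            continue
        best = _best_hit(candidates)
        if best.pident > thresholds.high_pident:
            tier, reason = "high", f"pident {best.pident:g} > {thresholds.high_pident:g}"
        elif (
            best.pident > thresholds.moderate_pident
            and best.bitscore > thresholds.moderate_bitscore
            and best.evalue <= thresholds.moderate_evalue
        ):
            tier, reason = (
                "moderate",
                f"pident {best.pident:g}, bitscore {best.bitscore:g}, "
                f"evalue {best.evalue:g}",
            )
        else:
            assignments.append(
                HomologyAssignment(
                    query_id,
                    None,
                    "unmapped",
                    reason=(
                        f"best hit below thresholds (pident {best.pident:g}, "
                        f"bitscore {best.bitscore:g}, evalue {best.evalue:g})"
                    ),
                )
            )
            continue
        assignments.append(
            HomologyAssignment(
                query_id, best.subject_id, tier, reason=reason,
                partial=best.subject_partial,
            )
        )
    return assignments


@dataclass
class TransferReport:
    """Summary of a catalogue transfer."""

    mapped: list[str] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)
    many_to_one: dict[str, list[str]] = field(default_factory=dict)


def transfer_catalogue(
    ref_cat: Catalogue,
    assignments: Sequence[HomologyAssignment],
    *,
    target_species: str = "",
) -> tuple[Catalogue, TransferReport]:
    """Project a reference catalogue onto a target species.

    Each mapped assignment yields one target component carrying the
    reference component's subsystem, functional-group, and complex
    memberships, with ``homolog_of`` set to the reference id and the
    partial flag carried over. Unmapped references are listed in the
    report, as are target genes serving several reference components.

    Raises
    ------
    HomologyError
        If an assignment references an id absent from ``ref_cat``.
    """
    report = TransferReport()
    components: list[Component] = []
    target_use: dict[str, list[str]] = {}
    for a in assignments:
        if a.reference_id not in ref_cat:
            raise HomologyError(
                f"assignment references unknown reference id {a.reference_id!r}"
            )
        if a.tier == "unmapped":
            report.unmapped.append(a.reference_id)
            continue
        ref = ref_cat.get(a.reference_id)
        components.append(
            new_component(
                ref,
                id=ref.id,
                species=target_species,
                homolog_of=ref.id,
                partial=ref.partial or a.partial,
                notes=f"target={a.target_id} tier={a.tier}",
            )
        )
        report.mapped.append(a.reference_id)
        target_use.setdefault(a.target_id, []).append(a.reference_id)

    report.many_to_one = {
        t: refs for t, refs in target_use.items() if len(refs) > 1
    }
    if report.many_to_one:
        logger.warning(
            "%d target gene(s) map to several reference components",
            len(report.many_to_one),
        )
    try:
        target = Catalogue(
            components=components,
            species=target_species,
            source=f"transfer:{ref_cat.source}",
            extra_subsystem_labels=ref_cat.extra_subsystem_labels,
        )
    except CatalogueError as exc:  # duplicate ref ids cannot occur by construction
        raise HomologyError(str(exc)) from exc
    return target, report
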