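"""Differential-expression overlay on the network and complex enrichment.

Component nodes are coloured on a continuous blue-white-red gradient of
log2 fold change (saturating at |log2FC| = 4, reference ticks at +/-2) and
given a thick border when FDR < 0.05. Complexes, functional groups, or
subsystems are scored for coordinated up/down regulation with a one-sided
Fisher exact test of membership against regulation direction, deliberately
without any fold-change cut: coordinated sub-twofold shifts of whole
complexes are exactly the signal of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from secrepath.catalogue import Catalogue
from secrepath.expression import benjamini_hochberg
from secrepath.network import COMPONENT_LIKE, ReconNetwork, export_network

logger = logging.getLogger(__name__)

#: log2FC magnitude at which the node colour gradient saturates.
COLOUR_SATURATION_FC = 4.0
#: reference tick marks on the gradient (twofold up/down).
COLOUR_REFERENCE_TICKS = (-2.0, 2.0)


class OverlayError(ValueError):
    """Raised on invalid overlay inputs."""


@dataclass(frozen=True)
class NodeAnnotation:
    """Per-node styling derived from differential expression."""

    node_id: str
    log2fc: float | None
    fdr: float | None
    colour_value: float  # signed gradient position in [-1, 1]; 0 = neutral
    border_width: str  # thin | thick


def _colour_value(log2fc: float | None) -> float:
    if log2fc is None or np.isnan(log2fc):
        return 0.0
    return float(np.clip(log2fc / COLOUR_SATURATION_FC, -1.0, 1.0))


def annotate_network(
    net: ReconNetwork,
    dge: pd.DataFrame,
    *,
    fdr_cut: float = 0.05,
) -> dict[str, NodeAnnotation]:
    """Map a DGE table onto component nodes (case-insensitive ids).

    Genes absent from the table, and complex/functional-group hub nodes,
    receive the neutral colour and a thin border. Unmapped DGE genes are
    logged, never fatal.
    """
    for column in ("gene", "log2FC"):
        if column not in dge.columns:
            raise OverlayError(f"DGE table missing column {column!r}")
    has_fdr = "FDR" in dge.columns

    by_gene: dict[str, tuple[float, float | None]] = {}
    unmapped = []
    for row in dge.itertuples(index=False):
        node = net.resolve(str(row.gene))
        if node is None or net.nodes[node] not in COMPONENT_LIKE:
            unmapped.append(row.gene)
            continue
        by_gene[node] = (
            float(row.log2FC),
            float(row.FDR) if has_fdr else None,
        )
    if unmapped:
        logger.info("%d DGE gene(s) not mapped to component nodes", len(unmapped))

    annotations: dict[str, NodeAnnotation] = {}
    for node_id, kind in net.nodes.items():
        if kind in COMPONENT_LIKE and node_id in by_gene:
            log2fc, fdr = by_gene[node_id]
            annotations[node_id] = NodeAnnotation(
                node_id=node_id,
                log2fc=log2fc,
                fdr=fdr,
                colour_value=_colour_value(log2fc),
                border_width="thick" if fdr is not None and fdr < fdr_cut else "thin",
            )
        else:
            annotations[node_id] = NodeAnnotation(node_id, None, None, 0.0, "thin")
    return annotations


def default_member_criterion(
    log2fc: float, fdr: float | None, direction: str, fdr_cut: float = 0.05
) -> bool:
    """A gene counts as regulated in a direction when the sign of its
    log2FC matches and FDR < cut; no fold-change magnitude condition."""
    if fdr is None or not fdr < fdr_cut:
        return False
    return log2fc > 0 if direction == "up" else log2fc < 0


def sign_only_criterion(
    log2fc: float, fdr: float | None, direction: str, fdr_cut: float = 0.05
) -> bool:
    """Direction by sign of log2FC alone (no significance condition)."""
    return log2fc > 0 if direction == "up" else log2fc < 0


def _groups_of_kind(
    net: ReconNetwork, cat: Catalogue, kind: str
) -> dict[str, set[str]]:
    groups: dict[str, set[str]] = {}
    for comp in cat.components:
        node = net.resolve(comp.id)
        if node is None:
            continue
        if kind == "complex":
            labels = comp.complexes
        elif kind == "functional_group":
            labels = comp.functional_groups
        elif kind == "subsystem":
            labels = comp.subsystems
        else:
            raise OverlayError(f"invalid group kind {kind!r}")
        for label in labels:
            groups.setdefault(label, set()).add(node)
    return groups


def complex_enrichment(
    net: ReconNetwork,
    cat: Catalogue,
    dge: pd.DataFrame,
    *,
    kind: str = "complex",
    directions: tuple[str, ...] = ("up", "down"),
    member_criterion: Callable[..., bool] = default_member_criterion,
    min_members: int = 2,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of coordinated regulation per group.

    The background is every component-kind node of the network with a DGE
    row. For each group of the requested kind and each direction, the 2x2
    table is {member, non-member} x {regulated-in-direction, not}; p is
    the one-sided (greater) Fisher exact probability, reported with its
    -log10 transform and a BH-adjusted q over all tested groups. Groups
    with fewer than ``min_members`` scored members are skipped (logged).
    """
    has_fdr = "FDR" in dge.columns
    scored: dict[str, tuple[float, float | None]] = {}
    for row in dge.itertuples(index=False):
        node = net.resolve(str(row.gene))
        if node is not None and net.nodes[node] in COMPONENT_LIKE:
            scored[node] = (
                float(row.log2FC),
                float(row.FDR) if has_fdr else None,
            )
    if not scored:
        raise OverlayError("no DGE genes map onto the network background")

    groups = _groups_of_kind(net, cat, kind)
    rows = []
    for direction in directions:
        regulated = {
            node
            for node, (log2fc, fdr) in scored.items()
            if member_criterion(log2fc, fdr, direction)
        }
        for label in sorted(groups):
            members = groups[label] & scored.keys()
            if len(members) < min_members:
                logger.info(
                    "skipping %s %r (%d scored members)", kind, label, len(members)
                )
                continue
            a = len(members & regulated)
            b = len(members) - a
            c = len(regulated) - a
            d = len(scored) - len(members) - c
            odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append(
                {
                    "group": label,
                    "kind": kind,
                    "direction": direction,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "p": p,
                    "neg_log10_p": -np.log10(p),
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "group",
            "kind",
            "direction",
            "a",
            "b",
            "c",
            "d",
            "odds_ratio",
            "p",
            "neg_log10_p",
        ],
    )
    if len(result):
        result["q"] = benjamini_hochberg(result["p"].to_numpy())
    else:
        result["q"] = pd.Series(dtype=float)
    return result


def style_and_export(
    net: ReconNetwork,
    annotations: dict[str, NodeAnnotation],
    enrichment: pd.DataFrame,
    out_dir: str | Path,
    *,
    basename: str = "overlay",
) -> dict[str, Path]:
    """Write styled SIF/attribute/GraphML files plus the enrichment TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation_columns = {
        node_id: {
            "log2FC": "" if a.log2fc is None else f"{a.log2fc:.6g}",
            "FDR": "" if a.fdr is None else f"{a.fdr:.6g}",
            "colour": f"{a.colour_value:.6g}",
            "border": a.border_width,
        }
        for node_id, a in annotations.items()
    }
    paths = export_network(
        net, out_dir, annotations=annotation_columns, basename=basename
    )
    enrichment_path = out_dir / f"{basename}.enrichment.tsv"
    enrichment.to_csv(enrichment_path, sep="\t", index=False)
    paths["enrichment"] = enrichment_path
    return paths
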