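"""Heterogeneous network representation of a component catalogue.

Nodes are components, protein complexes, functional groups, and declared
isoproteins; edges are curated interactions plus membership edges tying
components to their complex and functional-group nodes. Export targets
the plain-text formats understood by network-visualisation tools: SIF,
a node-attribute TSV, and GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from secrepath.catalogue import Catalogue

logger = logging.getLogger(__name__)

NODE_KINDS = ("component", "complex", "functional_group", "isoprotein")
INTERACTION_CLASSES = ("protein_protein", "protein_DNA", "DNA_DNA", "membership")

#: Node kinds that behave like catalogue components in analyses.
COMPONENT_LIKE = ("component", "isoprotein")


class NetworkError(ValueError):
    """Raised when a network or its inputs violate an invariant."""


@dataclass(frozen=True)
class Interaction:
    """A typed edge between two named nodes."""

    source: str
    target: str
    interaction_class: str = "protein_protein"
    directed: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.interaction_class not in INTERACTION_CLASSES:
            raise NetworkError(
                f"invalid interaction class {self.interaction_class!r}"
            )


@dataclass
class ReconNetwork:
    """Registry of typed nodes plus an edge list.

    ``nodes`` maps node id -> kind; ids are case-preserved but must be
    unique case-insensitively. Edge endpoints must be registered nodes.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: list[Interaction] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self._canon: dict[str, str] = {}
        for node_id, kind in self.nodes.items():
            if kind not in NODE_KINDS:
                raise NetworkError(f"node {node_id!r}: invalid kind {kind!r}")
            key = node_id.casefold()
            if key in self._canon:
                raise NetworkError(f"duplicate node id: {node_id!r}")
            self._canon[key] = node_id
        for i, edge in enumerate(self.edges):
            for endpoint in (edge.source, edge.target):
                if endpoint.casefold() not in self._canon:
                    raise NetworkError(
                        f"edge {i}: endpoint {endpoint!r} is not a registered node"
                    )

    def resolve(self, node_id: str) -> str | None:
        """Map a case-insensitive id to the registered spelling, or None."""
        return self._canon.get(node_id.casefold())

    def kind_counts(self) -> dict[str, int]:
        counts = {kind: 0 for kind in NODE_KINDS}
        for kind in self.nodes.values():
            counts[kind] += 1
        return counts

    def nodes_of_kind(self, *kinds: str) -> list[str]:
        return [n for n, k in self.nodes.items() if k in kinds]

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            src = self.resolve(e.source)
            tgt = self.resolve(e.target)
            deg[src] += 1
            if tgt != src:
                deg[tgt] += 1
        return deg

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for node_id, kind in self.nodes.items():
            g.add_node(node_id, kind=kind)
        for e in self.edges:
            g.add_edge(
                self.resolve(e.source),
                self.resolve(e.target),
                interaction_class=e.interaction_class,
                directed=e.directed,
                provenance=e.provenance,
            )
        return g

    def n_connected_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())


def load_interactions(path: str | Path) -> list[Interaction]:
    """Read an interaction TSV: source, class, target, directed, provenance.

    A header row is required; ``directed`` and ``provenance`` are optional
    columns.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    col = {name: i for i, name in enumerate(header)}
    for required in ("source", "class", "target"):
        if required not in col:
            raise NetworkError(f"{path}: missing column {required!r}")

    def cell(fields: list[str], name: str) -> str:
        i = col.get(name)
        return fields[i] if i is not None and i < len(fields) else ""

    interactions = []
    for line_no, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        try:
            interactions.append(
                Interaction(
                    source=cell(fields, "source").strip(),
                    target=cell(fields, "target").strip(),
                    interaction_class=cell(fields, "class").strip()
                    or "protein_protein",
                    directed=cell(fields, "directed").strip().lower()
                    in ("1", "true", "yes"),
                    provenance=cell(fields, "provenance").strip(),
                )
            )
        except NetworkError as exc:
            raise NetworkError(f"{path}: line {line_no}: {exc}") from None
    return interactions


def save_interactions(interactions: Sequence[Interaction], path: str | Path) -> None:
    rows = ["source\tclass\ttarget\tdirected\tprovenance"]
    for e in interactions:
        rows.append(
            f"{e.source}\t{e.interaction_class}\t{e.target}\t"
            f"{'1' if e.directed else '0'}\t{e.provenance}"
        )
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def build_network(
    cat: Catalogue,
    interactions: Sequence[Interaction] = (),
    *,
    drop_isolated: bool = False,
) -> ReconNetwork:
    """Materialise the heterogeneous network for a catalogue.

    Complex and functional-group nodes are created from catalogue
    memberships, and one membership edge is added per component-to-complex
    and component-to-group assignment. Interactions may reference
    components (case-insensitively) or the materialised complex/group
    labels. With ``drop_isolated``, component-kind nodes with no edge at
    all are removed, mirroring a representation that leaves out components
    with no described connectivity.

    Raises
    ------
    NetworkError
        If an interaction endpoint matches no known node (the edge index
        is reported).
    """
    nodes: dict[str, str] = {}
    for comp in cat.components:
        nodes[comp.id] = comp.kind
    complexes = sorted({cx for c in cat.components for cx in c.complexes})
    groups = sorted({g for c in cat.components for g in c.functional_groups})
    for label in complexes:
        if label.casefold() not in {n.casefold() for n in nodes}:
            nodes[label] = "complex"
    for label in groups:
        if label.casefold() not in {n.casefold() for n in nodes}:
            nodes[label] = "functional_group"

    canon = {n.casefold(): n for n in nodes}
    edges: list[Interaction] = []
    for comp in cat.components:
        for cx in sorted(comp.complexes):
            edges.append(
                Interaction(comp.id, canon[cx.casefold()], "membership")
            )
        for g in sorted(comp.functional_groups):
            edges.append(
                Interaction(comp.id, canon[g.casefold()], "membership")
            )

    for i, e in enumerate(interactions):
        for endpoint in (e.source, e.target):
            if endpoint.casefold() not in canon:
                raise NetworkError(
                    f"interaction {i}: endpoint {endpoint!r} matches no "
                    "component, complex, or functional-group node"
                )
        edges.append(
            Interaction(
                canon[e.source.casefold()],
                canon[e.target.casefold()],
                e.interaction_class,
                e.directed,
                e.provenance,
            )
        )

    net = ReconNetwork(nodes=nodes, edges=edges, provenance=cat.source)
    if drop_isolated:
        deg = net.degree()
        keep = {
            n
            for n, kind in net.nodes.items()
            if kind not in COMPONENT_LIKE or deg[n] > 0
        }
        net = ReconNetwork(
            nodes={n: k for n, k in net.nodes.items() if n in keep},
            edges=[e for e in net.edges if e.source in keep and e.target in keep],
            provenance=net.provenance,
        )
    return net


def extract_subnetwork(
    net: ReconNetwork,
    selector: Iterable[str],
    cat: Catalogue | None = None,
) -> ReconNetwork:
    """Induced subgraph on components matching any selector label.

    A component matches if one of its subsystems, functional groups, or
    complexes is in ``selector`` (requires ``cat``), or if the selector
    names a complex/functional-group node of the network directly. The
    matched components' complex and group nodes are retained. The input
    network is not modified. An empty or unmatched selector yields an
    empty network.
    """
    wanted = {s.casefold() for s in selector}
    if not wanted:
        return ReconNetwork(provenance=net.provenance)

    keep_components: set[str] = set()
    if cat is not None:
        for comp in cat.components:
            labels = {
                lab.casefold()
                for lab in comp.subsystems | comp.functional_groups | comp.complexes
            }
            if labels & wanted and net.resolve(comp.id):
                keep_components.add(net.resolve(comp.id))

    hub_nodes = {
        n
        for n, kind in net.nodes.items()
        if kind in ("complex", "functional_group") and n.casefold() in wanted
    }
    for e in net.edges:
        if e.interaction_class == "membership":
            if e.target in hub_nodes and net.nodes.get(e.source) in COMPONENT_LIKE:
                keep_components.add(e.source)
            if e.source in hub_nodes and net.nodes.get(e.target) in COMPONENT_LIKE:
                keep_components.add(e.target)

    # retain hub nodes attached to a kept component
    keep = set(keep_components) | hub_nodes
    for e in net.edges:
        if e.interaction_class != "membership":
            continue
        if e.source in keep_components and net.nodes.get(e.target) not in COMPONENT_LIKE:
            keep.add(e.target)
        if e.target in keep_components and net.nodes.get(e.source) not in COMPONENT_LIKE:
            keep.add(e.source)

    return ReconNetwork(
        nodes={n: k for n, k in net.nodes.items() if n in keep},
        edges=[e for e in net.edges if e.source in keep and e.target in keep],
        provenance=net.provenance,
    )


def export_network(
    net: ReconNetwork,
    out_dir: str | Path,
    *,
    annotations: Mapping[str, Mapping[str, object]] | None = None,
    basename: str = "network",
) -> dict[str, Path]:
    """Write SIF, node-attribute TSV, and GraphML files for a network.

    ``annotations`` maps node id -> column -> value; annotation columns are
    appended to the node-attribute table (union of columns across nodes,
    sorted). Returns the written paths keyed by format.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sif_path = out_dir / f"{basename}.sif"
    attr_path = out_dir / f"{basename}.nodes.tsv"
    graphml_path = out_dir / f"{basename}.graphml"

    sif_lines = [
        f"{e.source}\t{e.interaction_class}\t{e.target}" for e in net.edges
    ]
    sif_path.write_text("\n".join(sif_lines) + ("\n" if sif_lines else ""), "utf-8")

    ann = annotations or {}
    extra_cols = sorted({c for v in ann.values() for c in v})
    header = ["id", "kind"] + extra_cols
    rows = ["\t".join(header)]
    for node_id, kind in net.nodes.items():
        node_ann = ann.get(node_id, {})
        rows.append(
            "\t".join(
                [node_id, kind]
                + ["" if node_ann.get(c) is None else str(node_ann.get(c)) for c in extra_cols]
            )
        )
    attr_path.write_text("\n".join(rows) + "\n", "utf-8")

    g = net.to_networkx()
    for node_id in g.nodes:
        for col, value in ann.get(node_id, {}).items():
            if value is not None:
                g.nodes[node_id][col] = value
    nx.write_graphml(g, graphml_path)

    logger.info(
        "exported network (%d nodes, %d edges) to %s",
        len(net.nodes),
        len(net.edges),
        out_dir,
    )
    return {"sif": sif_path, "attributes": attr_path, "graphml": graphml_path}


def import_sif(
    sif_path: str | Path, attr_path: str | Path | None = None
) -> ReconNetwork:
    """Rebuild a network from a SIF file and optional node-attribute TSV.

    Without the attribute table all nodes default to kind ``component``.
    """
    sif_path = Path(sif_path)
    kinds: dict[str, str] = {}
    if attr_path is not None:
        lines = Path(attr_path).read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        id_i, kind_i = header.index("id"), header.index("kind")
        for raw in lines[1:]:
            if not raw.strip():
                continue
            fields = raw.split("\t")
            kinds[fields[id_i]] = fields[kind_i]

    nodes: dict[str, str] = dict(kinds)
    edges: list[Interaction] = []
    for raw in sif_path.read_text(encoding="utf-8").splitlines():
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 3:
            raise NetworkError(f"{sif_path}: malformed SIF line {raw!r}")
        source, iclass, target = fields
        for endpoint in (source, target):
            nodes.setdefault(endpoint, "component")
        edges.append(Interaction(source, target, iclass))
    return ReconNetwork(nodes=nodes, edges=edges, provenance=str(sif_path))
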