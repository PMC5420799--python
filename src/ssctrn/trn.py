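"""Transcriptional-regulatory-network assembly and export.

A TRN is a typed graph: TF nodes and group-annotated target nodes, directed
protein-DNA edges (TF -> target, from the TF-target collection) and
undirected protein-protein edges overlaid from an interactome edge list.
Networks are exported as SIF (relation tags "pd" / "pp"), GraphML with node
attributes, or a node-attribute TSV; node and edge orderings are canonical
(sorted) so exports are byte-stable and GraphML round-trips losslessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .enrich import GeneSetCollection, enrich_collection


@dataclass
class TRNGraph:
    """Typed regulatory network with protein-DNA and protein-protein edges."""

    nodes: dict[str, dict] = field(default_factory=dict)  # id -> attributes
    pd_edges: set[tuple[str, str]] = field(default_factory=set)  # directed TF->target
    pp_edges: set[tuple[str, str]] = field(default_factory=set)  # undirected, stored sorted

    def __post_init__(self) -> None:
        for a, b in self.pd_edges | self.pp_edges:
            for n in (a, b):
                if n not in self.nodes:
                    raise ValueError(f"edge endpoint {n!r} is not a node")
        for a, b in self.pd_edges:
            if self.nodes[a].get("role") != "TF":
                raise ValueError(f"protein-DNA edge from non-TF node {a!r}")
        self.pp_edges = {tuple(sorted(e)) for e in self.pp_edges}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.pd_edges) + len(self.pp_edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def autoregulatory(self) -> list[str]:
        return sorted(a for a, b in self.pd_edges if a == b)


def build_trn(
    selected_tfs: list[str],
    group_of_gene: dict[str, int],
    allowed_groups: set[int],
    process_genes: set[str] | None,
    tf_targets: GeneSetCollection,
    ppi_edges: list[tuple[str, str]] | None = None,
) -> TRNGraph:
    """Assemble the TRN for selected TFs over group/process-restricted targets.

    Targets are each selected TF's annotated targets intersected with the
    allowed temporal groups and (if given) the process gene set. Protein-DNA
    edges come from the TF-target collection restricted to included node
    pairs; PPI edges are restricted the same way.
    """
    process = set(process_genes) if process_genes is not None else None
    qualifying: dict[str, set[str]] = {}
    for tf in selected_tfs:
        targets = set(tf_targets.sets.get(tf, []))
        targets = {
            g for g in targets
            if group_of_gene.get(g, 0) in allowed_groups and (process is None or g in process)
        }
        qualifying[tf] = targets
    all_targets = set().union(*qualifying.values()) if qualifying else set()
    if not all_targets:
        warnings.warn("no TF has any qualifying target: the TRN is empty")
        return TRNGraph()
    nodes: dict[str, dict] = {}
    for tf in selected_tfs:
        nodes[tf] = {
            "role": "TF",
            "group": int(group_of_gene.get(tf, 0)),
            "autoregulatory": False,
        }
    for g in sorted(all_targets - set(selected_tfs)):
        nodes[g] = {"role": "target", "group": int(group_of_gene.get(g, 0)),
                    "autoregulatory": False}
    pd_edges = set()
    for tf, targets in qualifying.items():
        for g in sorted(targets):
            pd_edges.add((tf, g))
            if tf == g:
                nodes[tf]["autoregulatory"] = True
    pp = set()
    if ppi_edges:
        for a, b in ppi_edges:
            if a in nodes and b in nodes and a != b:
                pp.add(tuple(sorted((a, b))))
    return TRNGraph(nodes=nodes, pd_edges=pd_edges, pp_edges=pp)


def strongly_regulating_tfs(
    candidate_tfs: list[str],
    target_pool: set[str],
    tf_targets: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    min_count: int = 5,
) -> list[str]:
    """TFs passing the major-TF thresholds against a process-restricted pool.

    "Strongly regulating" a process means the TF's targets are enriched in
    the process-restricted gene pool at FDR < alpha with >= min_count
    qualifying targets.
    """
    pool = sorted(set(target_pool) & set(universe))
    if not pool:
        return []
    candidates = GeneSetCollection(
        {t: tf_targets.sets[t] for t in candidate_tfs if t in tf_targets.sets},
        tf_targets.provenance,
    )
    rows = enrich_collection(pool, candidates, universe, min_count=min_count,
                             alpha=alpha, mode="fdr")
    return sorted(rows.loc[rows["passed"], "set"])


def to_networkx(graph: TRNGraph) -> nx.DiGraph:
    """Canonical networkx view: pp edges stored once, sorted, tagged."""
    g = nx.DiGraph()
    for node in graph.sorted_nodes():
        attrs = graph.nodes[node]
        g.add_node(
            node,
            role=str(attrs.get("role", "target")),
            group=int(attrs.get("group", 0)),
            autoregulatory=bool(attrs.get("autoregulatory", False)),
        )
    for a, b in sorted(graph.pd_edges):
        g.add_edge(a, b, interaction="pd")
    for a, b in sorted(graph.pp_edges):
        g.add_edge(a, b, interaction="pp")
    return g


def from_networkx(g: nx.DiGraph) -> TRNGraph:
    nodes = {
        str(n): {
            "role": str(d.get("role", "target")),
            "group": int(d.get("group", 0)),
            "autoregulatory": bool(d.get("autoregulatory", False)),
        }
        for n, d in g.nodes(data=True)
    }
    pd_edges, pp_edges = set(), set()
    for a, b, d in g.edges(data=True):
        if d.get("interaction") == "pp":
            pp_edges.add(tuple(sorted((str(a), str(b)))))
        else:
            pd_edges.add((str(a), str(b)))
    return TRNGraph(nodes=nodes, pd_edges=pd_edges, pp_edges=pp_edges)


def export_network(graph: TRNGraph, fmt: str, path: str | Path) -> None:
    """Write the network as ``sif``, ``graphml`` or ``tsv`` node attributes."""
    path = Path(path)
    if fmt == "sif":
        lines = [f"{a}\tpd\t{b}" for a, b in sorted(graph.pd_edges)]
        lines += [f"{a}\tpp\t{b}" for a, b in sorted(graph.pp_edges)]
        path.write_text("".join(line + "\n" for line in lines))
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(graph), path)
    elif fmt == "tsv":
        lines = ["node\trole\tgroup\tautoregulatory"]
        for node in graph.sorted_nodes():
            attrs = graph.nodes[node]
            lines.append(
                f"{node}\t{attrs.get('role', 'target')}\t{attrs.get('group', 0)}"
                f"\t{int(bool(attrs.get('autoregulatory', False)))}"
            )
        path.write_text("".join(line + "\n" for line in lines))
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def import_graphml(path: str | Path) -> TRNGraph:
    return from_networkx(nx.read_graphml(path))
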