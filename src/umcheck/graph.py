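"""Bipartite metabolic graphs and unconnected-module decomposition.

A metabolic network maps onto a directed bipartite graph: one node per
metabolite and per reaction, an arc metabolite -> reaction when the
metabolite is consumed (negative coefficient) and reaction -> metabolite
when it is produced.  Restricting this graph to the gap metabolites and
blocked reactions and taking connected components (ignoring arc
direction) yields the *unconnected modules* — coherent chunks of the
network silenced by missing connectivity, usually matching a biochemical
subsystem.  Components are computed on the undirected view because a
module rooted in a non-consumed metabolite has all its arcs pointing one
way yet is still a single unit of broken metabolism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .gapfind import BlockedSet, GapClass, GapSet
from .model import Model

__all__ = [
    "UnconnectedModule",
    "build_graph",
    "um_subgraph",
    "find_ums",
    "um_table",
    "export_graph",
    "write_um_table_tsv",
]


@dataclass(frozen=True)
class UnconnectedModule:
    """One connected component of the gap/blocked subgraph."""

    index: int
    reaction_ids: frozenset[str]
    metabolite_ids: frozenset[str]
    rnp: tuple[str, ...]
    rnc: tuple[str, ...]
    subsystem: str

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def members(self) -> frozenset[str]:
        return self.reaction_ids | self.metabolite_ids


def build_graph(
    model: Model,
    blocked: BlockedSet | None = None,
    gaps: GapSet | None = None,
) -> nx.DiGraph:
    """Directed bipartite graph of the whole model.

    Node attributes: ``kind`` (metabolite|reaction), ``label``,
    ``gap_class``, ``blocked``, ``reversible``.  Arc count equals the
    number of nonzero stoichiometric coefficients; reversible reactions
    keep their forward-written arcs and carry ``reversible=True``.
    """
    graph = nx.DiGraph()
    blocked_ids = blocked.blocked if blocked is not None else frozenset()
    gap_classes = dict(gaps.classes) if gaps is not None else {}
    gap_ids = gaps.gaps if gaps is not None else frozenset()
    for met in model.metabolites:
        graph.add_node(
            met.id,
            kind="metabolite",
            label=met.name or met.id,
            gap_class=gap_classes.get(
                met.id, GapClass.UNCLASSIFIED if met.id in gap_ids else ""
            ),
            blocked=False,
            reversible=False,
        )
    for rxn in model.reactions:
        graph.add_node(
            rxn.id,
            kind="reaction",
            label=rxn.name or rxn.id,
            gap_class="",
            blocked=rxn.id in blocked_ids,
            reversible=rxn.reversible,
        )
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                graph.add_edge(met_id, rxn.id)
            else:
                graph.add_edge(rxn.id, met_id)
    return graph


def um_subgraph(graph: nx.DiGraph, gaps: GapSet, blocked: BlockedSet) -> nx.DiGraph:
    """Induced subgraph on gap metabolites and blocked reactions."""
    keep = (set(gaps.gaps) | set(blocked.blocked)) & set(graph.nodes)
    return graph.subgraph(keep).copy()


def find_ums(
    subgraph: nx.DiGraph,
    model: Model | None = None,
    gaps: GapSet | None = None,
) -> list[UnconnectedModule]:
    """Weakly-connected components of the gap/blocked subgraph, sorted by
    reaction count (descending; ties by smallest member id)."""
    raw: list[dict] = []
    for component in nx.weakly_connected_components(subgraph):
        rxns = {n for n in component if subgraph.nodes[n]["kind"] == "reaction"}
        mets = component - rxns
        classes = {}
        if gaps is not None:
            classes = {m: gaps.classes.get(m, "") for m in mets}
        else:
            classes = {m: subgraph.nodes[m].get("gap_class", "") for m in mets}
        rnp = tuple(sorted(m for m, c in classes.items() if c == GapClass.RNP))
        rnc = tuple(sorted(m for m, c in classes.items() if c == GapClass.RNC))
        subsystem = "-"
        if model is not None and rxns:
            counts = Counter(
                model.reaction(r).subsystem for r in rxns
                if model.has_reaction(r) and model.reaction(r).subsystem
            )
            if counts:
                best = max(counts.values())
                subsystem = sorted(s for s, c in counts.items() if c == best)[0]
        raw.append(
            {"rxns": frozenset(rxns), "mets": frozenset(mets), "rnp": rnp,
             "rnc": rnc, "subsystem": subsystem}
        )
    raw.sort(key=lambda d: (-len(d["rxns"]), min(d["rxns"] | d["mets"])))
    return [
        UnconnectedModule(index=i + 1, reaction_ids=d["rxns"],
                          metabolite_ids=d["mets"], rnp=d["rnp"], rnc=d["rnc"],
                          subsystem=d["subsystem"])
        for i, d in enumerate(raw)
    ]


def um_table(ums: list[UnconnectedModule]) -> pd.DataFrame:
    """Summary table: one row per module (index, dominant subsystem,
    reaction and metabolite counts, RNP and RNC members)."""
    rows = [
        {
            "um": um.index,
            "subsystem": um.subsystem,
            "n_reactions": um.n_reactions,
            "n_metabolites": um.n_metabolites,
            "rnp": ";".join(um.rnp) if um.rnp else "-",
            "rnc": ";".join(um.rnc) if um.rnc else "-",
        }
        for um in ums
    ]
    return pd.DataFrame(
        rows,
        columns=["um", "subsystem", "n_reactions", "n_metabolites", "rnp", "rnc"],
    )


def write_um_table_tsv(ums: list[UnconnectedModule], path: str | Path) -> None:
    um_table(ums).to_csv(Path(path), sep="\t", index=False)


_EXPORTERS = {
    "graphml": nx.write_graphml,
    "gml": nx.write_gml,
    "dot": None,  # handled below
}


def export_graph(graph: nx.DiGraph, path: str | Path, format: str = "graphml") -> None:
    """Write the graph for external editors (GraphML, GML or DOT)."""
    if format not in _EXPORTERS:
        raise ValueError(
            f"unknown graph format {format!r}; supported: "
            + ", ".join(sorted(_EXPORTERS))
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "dot":
        _write_dot(graph, path)
    else:
        _EXPORTERS[format](graph, str(path))


def _write_dot(graph: nx.DiGraph, path: Path) -> None:
    lines = ["digraph metabolic {"]
    for node, attrs in graph.nodes(data=True):
        shape = "box" if attrs.get("kind") == "reaction" else "ellipse"
        label = str(attrs.get("label", node)).replace('"', "'")
        lines.append(f'  "{node}" [shape={shape}, label="{label}"];')
    for src, dst in graph.edges:
        lines.append(f'  "{src}" -> "{dst}";')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
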