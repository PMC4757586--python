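"""Typed TF–miRNA–gene regulatory network assembly and feed-forward loops.

Nodes are typed TF / miRNA / gene.  Directed regulatory edges: TF -> miRNA
(only for selected miRNAs carrying a promoter binding site, signed by their
expression direction), TF -> gene (from an explicit direct-target list) and
miRNA -> gene (from integrated target sets).  Undirected protein–protein
interaction edges are decorative context for export and never participate in
loop detection.  A feed-forward loop is a triple (TF, miRNA, gene) with all
three regulatory edges present; self-regulation (gene == TF) is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd

from .targets import IntegratedTargets

EDGE_TYPES = ("tf_mirna", "tf_gene", "mirna_gene")


class FeedForwardLoop(NamedTuple):
    tf: str
    mirna: str
    gene: str


@dataclass
class RegulatoryNetwork:
    """Directed regulatory graph + undirected PPI context graph."""

    regulatory: nx.DiGraph = field(default_factory=nx.DiGraph)
    ppi: nx.Graph = field(default_factory=nx.Graph)

    def node_type(self, node: str) -> str:
        return self.regulatory.nodes[node]["ntype"]

    def edges_of_type(self, etype: str) -> list[tuple[str, str]]:
        return [
            (u, v) for u, v, t in self.regulatory.edges(data="etype") if t == etype
        ]

    def validate(self) -> None:
        allowed = {"tf_mirna": ("TF", "miRNA"), "tf_gene": ("TF", "gene"),
                   "mirna_gene": ("miRNA", "gene")}
        for u, v, t in self.regulatory.edges(data="etype"):
            if t not in allowed:
                raise ValueError(f"unknown edge type {t!r}")
            want_u, want_v = allowed[t]
            if self.node_type(u) != want_u or self.node_type(v) != want_v:
                raise ValueError(f"edge {u}->{v} violates type constraint for {t}")
        for u, v in self.ppi.edges():
            if u == v:
                raise ValueError("PPI self-loop")


def build_network(
    dems,
    bound_mirnas: Iterable[str],
    targets: IntegratedTargets,
    p53_targets: Iterable[str],
    ppi_edges: Iterable[tuple[str, str]] = (),
    tf: str = "TP53",
    mirna_subset: Iterable[str] | None = None,
) -> RegulatoryNetwork:
    """Assemble the typed network around one transcription factor.

    TF -> miRNA edges are drawn only for DEM miRNAs in ``bound_mirnas``
    (those with >= 1 promoter binding site), carrying the DE direction as the
    edge sign.  miRNA -> gene edges come from the integrated target sets of
    those miRNAs, TF -> gene edges from ``p53_targets``, and PPI edges are
    restricted to genes already present.  ``mirna_subset`` optionally narrows
    the miRNAs included (e.g. a pathway-membership selection).
    """
    bound = set(bound_mirnas)
    known = set(dems.table.index)
    if unknown := bound - known:
        raise ValueError(f"bound miRNAs absent from the DEM set: {sorted(unknown)}")
    if mirna_subset is not None:
        bound &= set(mirna_subset)

    net = RegulatoryNetwork()
    g = net.regulatory
    g.add_node(tf, ntype="TF")
    for m in sorted(bound):
        g.add_node(m, ntype="miRNA", direction=dems.table.loc[m, "direction"])
        g.add_edge(tf, m, etype="tf_mirna", sign=dems.table.loc[m, "direction"])
        for gene in sorted(targets.genes(m)):
            if gene == tf:
                continue
            if not g.has_node(gene):
                g.add_node(gene, ntype="gene")
            g.add_edge(m, gene, etype="mirna_gene")
    for gene in sorted(set(p53_targets)):
        if gene == tf:
            continue
        if not g.has_node(gene):
            g.add_node(gene, ntype="gene")
        g.add_edge(tf, gene, etype="tf_gene")

    genes_present = {n for n, t in g.nodes(data="ntype") if t == "gene"}
    for u, v in ppi_edges:
        if u != v and u in genes_present and v in genes_present:
            net.ppi.add_edge(u, v)

    # target multiplicity: how many included miRNAs hit each gene (Fig-style flag)
    mult: dict[str, int] = {}
    for m in bound:
        for gene in targets.genes(m):
            if g.has_node(gene):
                mult[gene] = mult.get(gene, 0) + 1
    for gene, n in mult.items():
        g.nodes[gene]["targeted_by"] = n
        g.nodes[gene]["high_multiplicity"] = bool(n >= 4)

    net.validate()
    return net


def enumerate_ffls(network: RegulatoryNetwork) -> list[FeedForwardLoop]:
    """All (TF, miRNA, gene) triples with TF->miRNA, TF->gene and miRNA->gene.

    Exact enumeration, deterministic sorted output; the empty list is valid.
    """
    g = network.regulatory
    tf_mirna = {}
    tf_gene: dict[str, set[str]] = {}
    for u, v, t in g.edges(data="etype"):
        if t == "tf_mirna":
            tf_mirna.setdefault(u, set()).add(v)
        elif t == "tf_gene":
            tf_gene.setdefault(u, set()).add(v)
    loops: list[FeedForwardLoop] = []
    for tf, mirnas in tf_mirna.items():
        direct = tf_gene.get(tf, set())
        for m in mirnas:
            for gene in g.successors(m):
                if g.edges[m, gene].get("etype") == "mirna_gene" and gene in direct and gene != tf:
                    loops.append(FeedForwardLoop(tf, m, gene))
    return sorted(loops)


def ffl_table(loops: Iterable[FeedForwardLoop]) -> pd.DataFrame:
    return pd.DataFrame(list(loops), columns=["tf", "mirna", "gene"])


def export_network(network: RegulatoryNetwork, prefix: str | Path, fmt: str = "sif") -> list[Path]:
    """Write the network for external visualization.

    ``fmt='sif'`` writes <prefix>.sif plus node/edge attribute TSVs;
    ``fmt='graphml'`` writes a single <prefix>.graphml with PPI edges folded
    in as etype='ppi'.  Both round-trip through :func:`import_network`.
    """
    prefix = Path(prefix)
    fmt = fmt.lower()
    if fmt == "sif":
        sif = prefix.with_suffix(".sif")
        with open(sif, "w") as fh:
            for u, v, t in sorted(network.regulatory.edges(data="etype")):
                fh.write(f"{u}\t{t}\t{v}\n")
            for u, v in sorted(tuple(sorted(e)) for e in network.ppi.edges()):
                fh.write(f"{u}\tppi\t{v}\n")
        nodes = prefix.parent / (prefix.name + ".nodes.tsv")
        rows = [
            (n, d.get("ntype", "gene"), d.get("direction", ""),
             d.get("targeted_by", 0), d.get("high_multiplicity", False))
            for n, d in sorted(network.regulatory.nodes(data=True))
        ]
        pd.DataFrame(
            rows, columns=["node", "ntype", "direction", "targeted_by", "high_multiplicity"]
        ).to_csv(nodes, sep="\t", index=False)
        edges = prefix.parent / (prefix.name + ".edges.tsv")
        erows = [
            (u, v, t, network.regulatory.edges[u, v].get("sign", ""))
            for u, v, t in sorted(network.regulatory.edges(data="etype"))
        ] + [(u, v, "ppi", "") for u, v in sorted(tuple(sorted(e)) for e in network.ppi.edges())]
        pd.DataFrame(erows, columns=["source", "target", "etype", "sign"]).to_csv(
            edges, sep="\t", index=False
        )
        return [sif, nodes, edges]
    if fmt == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(network.regulatory.nodes(data=True))
        g.add_edges_from(network.regulatory.edges(data=True))
        for u, v in network.ppi.edges():
            a, b = sorted((u, v))
            g.add_edge(a, b, etype="ppi")
        out = prefix.with_suffix(".graphml")
        nx.write_graphml(g, out)
        return [out]
    raise ValueError(f"unknown export format {fmt!r}")


def import_network(path: str | Path) -> RegulatoryNetwork:
    """Rebuild a RegulatoryNetwork from a GraphML export."""
    g = nx.read_graphml(str(path))
    net = RegulatoryNetwork()
    for n, d in g.nodes(data=True):
        net.regulatory.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        if d.get("etype") == "ppi":
            net.ppi.add_edge(u, v)
        else:
            net.regulatory.add_edge(u, v, **d)
    # PPI endpoints that only appear in PPI edges keep their node attributes
    net.validate()
    return net
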