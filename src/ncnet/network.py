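"""Bipartite ncRNA-mRNA network container and edge-list I/O.

Every network in this package contains a single edge type: an ncRNA
connected to an mRNA, annotated with the Pearson R that put the pair over
the cutoff.  Edge identity is the (ncrna_id, mrna_id) pair; the R value is
metadata and is ignored by all set operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

Edge = tuple[str, str]  # (ncrna_id, mrna_id)


@dataclass
class BipartiteNetwork:
    """A set of ncRNA-mRNA edges carrying Pearson R values.

    ``edges`` maps ``(ncrna_id, mrna_id)`` to the Pearson R of the pair.
    ``sign`` is ``"negative"`` (all R < 0) or ``"positive"`` (all R > 0).
    """

    edges: dict[Edge, float]
    sign: str = "negative"
    condition_label: str = "derived"

    def __post_init__(self) -> None:
        if self.sign not in ("negative", "positive"):
            raise ValueError(f"sign must be negative|positive, got {self.sign!r}")
        for (nc, m), r in self.edges.items():
            if nc == m:
                raise ValueError(f"self-edge on {nc!r}")
            if self.sign == "negative" and not r < 0:
                raise ValueError(f"edge ({nc}, {m}) has r={r} in a negative network")
            if self.sign == "positive" and not r > 0:
                raise ValueError(f"edge ({nc}, {m}) has r={r} in a positive network")

    # -- basic accessors -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def ncrna_nodes(self) -> set[str]:
        return {nc for nc, _ in self.edges}

    @property
    def mrna_nodes(self) -> set[str]:
        return {m for _, m in self.edges}

    @property
    def nodes(self) -> set[str]:
        return self.ncrna_nodes | self.mrna_nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_set(self) -> set[Edge]:
        return set(self.edges)

    def outdegree(self) -> dict[str, int]:
        """Incident-edge count for ncRNA nodes; mRNA nodes get 0."""
        deg: dict[str, int] = {n: 0 for n in self.nodes}
        for nc, _ in self.edges:
            deg[nc] += 1
        for m in self.mrna_nodes:
            deg.setdefault(m, 0)
        return deg

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {n: 0 for n in self.nodes}
        for nc, m in self.edges:
            deg[nc] += 1
            deg[m] += 1
        return deg

    def to_graph(self) -> nx.Graph:
        """Undirected networkx view with node ``kind`` attributes."""
        g = nx.Graph()
        for nc in self.ncrna_nodes:
            g.add_node(nc, kind="ncRNA")
        for m in self.mrna_nodes:
            g.add_node(m, kind="mRNA")
        for (nc, m), r in self.edges.items():
            g.add_edge(nc, m, r=r)
        return g

    def subnetwork(self, keep: set[Edge], condition_label: str | None = None) -> "BipartiteNetwork":
        return BipartiteNetwork(
            edges={e: r for e, r in self.edges.items() if e in keep},
            sign=self.sign,
            condition_label=condition_label or self.condition_label,
        )


# -- edge-list formats ---------------------------------------------------


def write_edge_tsv(net: BipartiteNetwork, path: str | Path) -> None:
    """Columns: source ncRNA, interaction (neg|pos), target mRNA, r."""
    tag = "neg" if net.sign == "negative" else "pos"
    with open(path, "w") as fh:
        fh.write("source\tinteraction\ttarget\tr\n")
        for (nc, m), r in sorted(net.edges.items()):
            fh.write(f"{nc}\t{tag}\t{m}\t{r:.6g}\n")


def write_sif(net: BipartiteNetwork, path: str | Path) -> None:
    """Cytoscape SIF: source, interaction, target."""
    tag = "neg" if net.sign == "negative" else "pos"
    with open(path, "w") as fh:
        for (nc, m), _ in sorted(net.edges.items()):
            fh.write(f"{nc}\t{tag}\t{m}\n")


def read_edge_tsv(path: str | Path, condition_label: str = "derived") -> BipartiteNetwork:
    edges: dict[Edge, float] = {}
    sign = "negative"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["source", "interaction", "target", "r"]:
            raise ValueError(f"unexpected edge-list header in {path}: {header}")
        for line in fh:
            nc, tag, m, r = line.rstrip("\n").split("\t")
            edges[(nc, m)] = float(r)
            sign = "negative" if tag == "neg" else "positive"
    return BipartiteNetwork(edges=edges, sign=sign, condition_label=condition_label)
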