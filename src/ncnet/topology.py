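"""Network topology: centralities, distributions, power-law fit, descriptors.

Conventions follow the Cytoscape NetworkAnalyzer ones: betweenness is
shortest-path betweenness on the undirected graph, normalized by
(n-1)(n-2)/2 within each connected component; centralization is
(n/(n-2)) * (max_degree/(n-1) - density); heterogeneity is the coefficient
of variation of the degree sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import BipartiteNetwork


@dataclass
class PowerLawFit:
    """Least-squares log-log fit y = a * x^b to a degree histogram."""

    coefficient: float  # a
    exponent: float  # b
    fit_correlation: float  # |Pearson R| of the log-log regression

    def predict(self, degree: float) -> float:
        return self.coefficient * degree**self.exponent


@dataclass
class CentralityTable:
    """Per-node outdegree, normalized betweenness and their product."""

    outdegree: dict[str, int]
    betweenness: dict[str, float]
    combined: dict[str, float]
    node_class: dict[str, str]  # "ncRNA" | "mRNA"


@dataclass
class TopologySummary:
    """The six PCA descriptors plus basic size and path statistics."""

    n_connected_components: int
    network_centralization: float
    characteristic_path_length: float
    average_degree: float
    network_heterogeneity: float
    powerlaw_exponent: float
    n_nodes: int
    n_edges: int

    @property
    def size(self) -> int:
        return self.n_nodes + self.n_edges

    def descriptor_vector(self) -> np.ndarray:
        """The six descriptors, in the fixed PCA order."""
        return np.array(
            [
                self.n_connected_components,
                self.network_centralization,
                self.characteristic_path_length,
                self.average_degree,
                self.network_heterogeneity,
                self.powerlaw_exponent,
            ],
            dtype=float,
        )

    DESCRIPTOR_NAMES = (
        "n_connected_components",
        "network_centralization",
        "characteristic_path_length",
        "average_degree",
        "network_heterogeneity",
        "powerlaw_exponent",
    )


def degree_distribution(net: BipartiteNetwork) -> dict[int, int]:
    """Histogram degree -> node count; sums to n_nodes, weighted sum 2E."""
    if net.n_edges == 0:
        raise ValueError("degree distribution of an empty network is undefined")
    hist: dict[int, int] = {}
    for deg in net.degree().values():
        hist[deg] = hist.get(deg, 0) + 1
    return dict(sorted(hist.items()))


def fit_power_law(hist: dict[int, int]) -> PowerLawFit:
    """OLS of log10(count) on log10(degree) over nonzero bins."""
    pts = [(k, c) for k, c in hist.items() if c > 0 and k > 0]
    if len(pts) < 3:
        raise ValueError(
            f"power-law fit needs >= 3 distinct degrees, got {len(pts)}"
        )
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r):  # flat y: correlation undefined, fit exact with b=0
        r = 0.0
    return PowerLawFit(
        coefficient=float(10.0**intercept),
        exponent=float(slope),
        fit_correlation=float(abs(r)),
    )


def betweenness(net: BipartiteNetwork) -> dict[str, float]:
    """Normalized shortest-path betweenness, per connected component."""
    if net.n_edges == 0:
        raise ValueError("betweenness of an empty network is undefined")
    g = net.to_graph()
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        # networkx normalizes by (n-1)(n-2)/2 with n = subgraph size, which
        # is exactly the per-component convention wanted here
        out.update(nx.betweenness_centrality(sub, normalized=True))
    return out


def combined_centrality(net: BipartiteNetwork) -> CentralityTable:
    """betweenness x outdegree per node (outdegree 0 for mRNAs)."""
    btw = betweenness(net)
    outdeg = net.outdegree()
    combined = {n: btw[n] * outdeg[n] for n in outdeg}
    node_class = {n: "ncRNA" for n in net.ncrna_nodes}
    node_class.update({n: "mRNA" for n in net.mrna_nodes})
    return CentralityTable(
        outdegree=outdeg, betweenness=btw, combined=combined, node_class=node_class
    )


def top_central_ncrnas(
    table: CentralityTable, percentile: float = 97.5
) -> list[tuple[str, float]]:
    """ncRNAs whose combined centrality strictly exceeds the given percentile.

    The percentile is taken over the combined centralities of ncRNA nodes
    only (computing it over all nodes would swamp the cut with zero-degree
    mRNAs and inflate the hub list).  Sorted descending, ties by id.
    """
    nc = {
        n: v for n, v in table.combined.items() if table.node_class[n] == "ncRNA"
    }
    if not nc:
        raise ValueError("no ncRNA nodes in centrality table")
    cut = float(np.percentile(list(nc.values()), percentile))
    hubs = [(n, v) for n, v in nc.items() if v > cut]
    hubs.sort(key=lambda nv: (-nv[1], nv[0]))
    return hubs


def core_subnetwork(
    net: BipartiteNetwork, hubs: list[str]
) -> BipartiteNetwork:
    """Hubs plus their first neighbors, keeping hub-incident edges only."""
    unknown = [h for h in hubs if h not in net.nodes]
    if unknown:
        raise ValueError(f"hub id(s) not in network: {unknown[:5]}")
    hub_set = set(hubs)
    keep = {e for e in net.edges if e[0] in hub_set or e[1] in hub_set}
    return net.subnetwork(keep, condition_label="core")


def shortest_path_stats(net: BipartiteNetwork) -> tuple[dict[int, int], float]:
    """Histogram of shortest-path lengths over connected unordered pairs, and mean."""
    if net.n_edges == 0:
        raise ValueError("path statistics of an empty network are undefined")
    g = net.to_graph()
    hist: dict[int, int] = {}
    total = 0
    count = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, d in lengths.items():
            if target <= source:  # unordered pairs, skip self
                continue
            hist[d] = hist.get(d, 0) + 1
            total += d
            count += 1
    return dict(sorted(hist.items())), total / count


def descriptors(net: BipartiteNetwork) -> TopologySummary:
    """Assemble the six-descriptor summary used for network comparison."""
    g = net.to_graph()
    n = g.number_of_nodes()
    e = g.number_of_edges()
    degs = np.array([d for _, d in g.degree()], dtype=float)
    mean_deg = degs.mean()
    if n > 2:
        density = 2.0 * e / (n * (n - 1))
        centralization = (n / (n - 2.0)) * (degs.max() / (n - 1.0) - density)
    else:
        centralization = 0.0
    heterogeneity = float(np.sqrt(degs.var()) / mean_deg)
    _, cpl = shortest_path_stats(net)
    try:
        exponent = fit_power_law(degree_distribution(net)).exponent
    except ValueError:
        # < 3 distinct degrees (stars, matchings): no power law to fit
        exponent = float("nan")
    return TopologySummary(
        n_connected_components=nx.number_connected_components(g),
        network_centralization=float(centralization),
        characteristic_path_length=float(cpl),
        average_degree=float(mean_deg),
        network_heterogeneity=heterogeneity,
        powerlaw_exponent=exponent,
        n_nodes=n,
        n_edges=e,
    )


def subclass_membership(
    subclass_by_gene: dict[str, str], net: BipartiteNetwork, subclasses: set[str]
) -> tuple[int, int]:
    """(members in network, total) for genes whose subclass is in ``subclasses``.

    Used e.g. to tally what fraction of the filtered snoRNA probes
    (subclasses SNORA/SNORD) enter a network as mRNA-correlated nodes.
    """
    pool = {g for g, sc in subclass_by_gene.items() if sc in subclasses}
    in_net = pool & net.nodes
    return len(in_net), len(pool)
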