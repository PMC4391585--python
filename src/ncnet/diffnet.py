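"""Edge-by-edge and node-by-node comparison of condition networks.

The three condition networks are partitioned into the seven regions of a
three-set Venn diagram (for nodes and for edges separately), from which the
status-independent core (triple-shared edges) and the disease-specific
network (relapse-and-remission edges absent from controls) are derived.
Topological similarity is quantified by PCA on the six descriptors and by
correlating aligned degree / path-length histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import BipartiteNetwork
from .topology import TopologySummary

REGIONS = (
    "relapse_only",
    "remission_only",
    "control_only",
    "relapse_remission",
    "relapse_control",
    "remission_control",
    "all_three",
)


@dataclass
class VennCounts:
    """Seven-region partition of a three-set comparison plus pair overlaps.

    ``pairwise_jaccard`` is shared / union-of-pair; ``pairwise_fraction``
    holds, per ordered pair (a, b), shared / |a|.
    """

    region_counts: dict[str, int]
    union_size: int
    triple_shared_percent: float
    pairwise_jaccard: dict[tuple[str, str], float]
    pairwise_fraction: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if sum(self.region_counts.values()) != self.union_size:
            raise ValueError("Venn region counts do not sum to the union size")


def _venn(sets: dict[str, set]) -> VennCounts:
    rel, rem, con = sets["relapse"], sets["remission"], sets["control"]
    triple = rel & rem & con
    regions = {
        "all_three": triple,
        "relapse_remission": (rel & rem) - con,
        "relapse_control": (rel & con) - rem,
        "remission_control": (rem & con) - rel,
        "relapse_only": rel - rem - con,
        "remission_only": rem - rel - con,
        "control_only": con - rel - rem,
    }
    union = rel | rem | con
    jaccard: dict[tuple[str, str], float] = {}
    fraction: dict[tuple[str, str], float] = {}
    names = ("relapse", "remission", "control")
    for a in names:
        for b in names:
            if a == b:
                continue
            shared = sets[a] & sets[b]
            pair_union = sets[a] | sets[b]
            jaccard[(a, b)] = len(shared) / len(pair_union) if pair_union else 0.0
            fraction[(a, b)] = len(shared) / len(sets[a]) if sets[a] else 0.0
    return VennCounts(
        region_counts={k: len(v) for k, v in regions.items()},
        union_size=len(union),
        triple_shared_percent=100.0 * len(triple) / len(union) if union else 0.0,
        pairwise_jaccard=jaccard,
        pairwise_fraction=fraction,
    )


def _as_dict(
    relapse: BipartiteNetwork, remission: BipartiteNetwork, control: BipartiteNetwork
) -> dict[str, BipartiteNetwork]:
    return {"relapse": relapse, "remission": remission, "control": control}


def edge_intersections(
    relapse: BipartiteNetwork, remission: BipartiteNetwork, control: BipartiteNetwork
) -> VennCounts:
    """Seven-region Venn partition of the edge union (R values ignored)."""
    nets = _as_dict(relapse, remission, control)
    return _venn({k: v.edge_set() for k, v in nets.items()})


def node_intersections(
    relapse: BipartiteNetwork, remission: BipartiteNetwork, control: BipartiteNetwork
) -> VennCounts:
    """Seven-region Venn partition of the node union."""
    nets = _as_dict(relapse, remission, control)
    return _venn({k: v.nodes for k, v in nets.items()})


def status_independent_core(
    relapse: BipartiteNetwork, remission: BipartiteNetwork, control: BipartiteNetwork
) -> BipartiteNetwork:
    """Network wired by the edges present in all three condition networks.

    Edge R values are taken from the relapse network.
    """
    shared = relapse.edge_set() & remission.edge_set() & control.edge_set()
    return relapse.subnetwork(shared, condition_label="core")


def disease_specific_network(
    relapse: BipartiteNetwork, remission: BipartiteNetwork, control: BipartiteNetwork
) -> BipartiteNetwork:
    """(relapse intersect remission) minus controls, on edge identity."""
    keep = (relapse.edge_set() & remission.edge_set()) - control.edge_set()
    net = relapse.subnetwork(keep, condition_label="disease_specific")
    assert not net.edge_set() & control.edge_set()
    return net


def largest_component(net: BipartiteNetwork) -> BipartiteNetwork:
    """Component with the most nodes; ties by edge count, then smallest id."""
    if net.n_edges == 0:
        raise ValueError("largest component of an empty network is undefined")
    g = net.to_graph()
    comps = list(nx.connected_components(g))

    def keyfn(comp: set) -> tuple[int, int, str]:
        edges = sum(1 for nc, _ in net.edges if nc in comp)
        return (-len(comp), -edges, min(comp))

    best = sorted(comps, key=keyfn)[0]
    keep = {e for e in net.edges if e[0] in best}
    return net.subnetwork(keep)


def topology_pca(
    summaries: list[TopologySummary], labels: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """PCA of networks in standardized six-descriptor space.

    Returns (coordinates [n_networks x n_components], variance fractions,
    names of descriptors actually used).  Constant descriptors are dropped
    with a warning since they carry no variance to standardize.
    """
    import warnings

    if len(summaries) < 2:
        raise ValueError("PCA needs at least 2 networks")
    mat = np.vstack([s.descriptor_vector() for s in summaries])
    names = list(TopologySummary.DESCRIPTOR_NAMES)
    sd = mat.std(axis=0, ddof=1)
    keep = (sd > 0) & np.isfinite(mat).all(axis=0)
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"constant/undefined descriptor(s) dropped from PCA: {dropped}")
    mat = mat[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    if mat.shape[1] == 0:
        raise ValueError("all descriptors constant; PCA undefined")
    z = (mat - mat.mean(axis=0)) / mat.std(axis=0, ddof=1)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    coords = u * s
    total = (s**2).sum()
    var_frac = s**2 / total if total > 0 else np.zeros_like(s)
    return coords, var_frac, names


def _aligned_hist_vectors(hists: list[dict[int, int]]) -> np.ndarray:
    bins = sorted(set().union(*[h.keys() for h in hists]))
    return np.array([[h.get(b, 0) for b in bins] for h in hists], dtype=float)


def distribution_correlations(hists: list[dict[int, int]]) -> np.ndarray:
    """Pairwise Pearson R between histograms aligned on the union of bins.

    Missing bins count 0.  A histogram with no variance over the aligned
    bins yields NaN in its row/column.
    """
    vecs = _aligned_hist_vectors(hists)
    k = len(hists)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = vecs[i], vecs[j]
            if xi.std() == 0 or xj.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(xi, xj)[0, 1])
            out[i, j] = out[j, i] = r
    return out
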