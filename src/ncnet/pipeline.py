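"""End-to-end orchestration: simulate/load -> preprocess -> networks ->
topology -> differential networks -> rank products -> candidates.

Every stage writes its artifacts under the output directory and the run
finishes with a manifest listing them; a run is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diffnet, netbuild, rankprod, targets, topology
from .matrix import ExpressionMatrix, read_expression
from .network import BipartiteNetwork, write_edge_tsv, write_sif
from .preprocess import preprocess
from .simulate import SimConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

CONDITIONS = ("relapse", "remission", "control")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    outdir: str = "ncnet_run"
    # load mode
    expression: str | None = None
    samples: str | None = None
    gene_annotation: str | None = None
    # simulate mode
    sim: SimConfig | None = None
    # analysis parameters
    alpha_global: float = 0.0005
    alpha_condition: float = 0.01
    hub_percentile: float = 97.5
    mrna_intensity_threshold: float | None = None
    rp_permutations: int = 1000
    rp_pfp_cutoff: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for a in (self.alpha_global, self.alpha_condition):
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha {a} outside (0, 1)")
        if self.sim is None and (self.expression is None or self.samples is None):
            raise ValueError("need either sim config or expression+samples paths")

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_json(), "artifacts": {}}
    art = manifest["artifacts"]

    def save_net(net: BipartiteNetwork, name: str) -> None:
        tsv = outdir / f"{name}.tsv"
        sif = outdir / f"{name}.sif"
        write_edge_tsv(net, tsv)
        write_sif(net, sif)
        art[name] = {"tsv": str(tsv), "sif": str(sif), "n_nodes": net.n_nodes, "n_edges": net.n_edges}

    # -- input ----------------------------------------------------------
    truth = None
    if config.sim is not None:
        matrix, truth = generate_cohort(config.sim)
        paths = write_cohort(matrix, truth, config.sim, outdir / "cohort")
        art["cohort"] = paths
    else:
        try:
            matrix = read_expression(
                config.expression, config.samples, config.gene_annotation
            )
        except Exception as exc:
            raise StageError("preprocess", f"cannot load inputs: {exc}") from exc

    # -- preprocess ------------------------------------------------------
    try:
        matrix = preprocess(
            matrix, mrna_intensity_threshold=config.mrna_intensity_threshold
        )
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc

    # -- networks --------------------------------------------------------
    nets: dict[str, BipartiteNetwork] = {}
    try:
        nets["global"] = netbuild.build_condition_network(
            matrix, "global", config.alpha_global
        )
        for cond in CONDITIONS:
            nets[cond] = netbuild.build_condition_network(
                matrix, cond, config.alpha_condition
            )
    except Exception as exc:
        raise StageError("netbuild", str(exc)) from exc
    for name, net in nets.items():
        save_net(net, f"network_{name}")

    # -- topology --------------------------------------------------------
    summaries = {}
    hubs = {}
    try:
        for name, net in nets.items():
            if net.n_edges == 0:
                logger.warning("network %s is empty; topology skipped", name)
                continue
            try:
                summaries[name] = topology.descriptors(net)
            except ValueError as exc:
                # tiny/degenerate networks (e.g. < 3 distinct degrees) have
                # no power-law fit; skip their summary rather than abort
                logger.warning("descriptors unavailable for %s: %s", name, exc)
            table = topology.combined_centrality(net)
            hubs[name] = topology.top_central_ncrnas(table, config.hub_percentile)
            cent_path = outdir / f"centrality_{name}.tsv"
            with open(cent_path, "w") as fh:
                fh.write("node\tclass\toutdegree\tbetweenness\tcombined\n")
                for node in sorted(table.combined, key=lambda n: (-table.combined[n], n)):
                    fh.write(
                        f"{node}\t{table.node_class[node]}\t{table.outdegree[node]}"
                        f"\t{table.betweenness[node]:.6g}\t{table.combined[node]:.6g}\n"
                    )
            art[f"centrality_{name}"] = str(cent_path)
        if "global" in summaries:
            gh = [g for g, _ in hubs["global"]]
            core_global = topology.core_subnetwork(nets["global"], gh)
            save_net(core_global, "core_global")
        desc_path = outdir / "descriptors.json"
        with open(desc_path, "w") as fh:
            json.dump(
                {k: dataclasses.asdict(v) | {"size": v.size} for k, v in summaries.items()},
                fh,
                indent=2,
            )
        art["descriptors"] = str(desc_path)
    except Exception as exc:
        raise StageError("topology", str(exc)) from exc

    # -- differential networks ------------------------------------------
    try:
        rel, rem, con = nets["relapse"], nets["remission"], nets["control"]
        venn_edges = diffnet.edge_intersections(rel, rem, con)
        venn_nodes = diffnet.node_intersections(rel, rem, con)
        core = diffnet.status_independent_core(rel, rem, con)
        disease = diffnet.disease_specific_network(rel, rem, con)
        save_net(core, "core_status_independent")
        save_net(disease, "disease_specific")
        if disease.n_edges:
            save_net(diffnet.largest_component(disease), "disease_specific_largest_component")
        venn_path = outdir / "venn.json"
        with open(venn_path, "w") as fh:
            json.dump(
                {
                    "edges": _venn_json(venn_edges),
                    "nodes": _venn_json(venn_nodes),
                },
                fh,
                indent=2,
            )
        art["venn"] = str(venn_path)
        if len(summaries) >= 2:
            names = [n for n in ("relapse", "remission", "control") if n in summaries]
            if len(names) >= 2:
                coords, var_frac, used = diffnet.topology_pca(
                    [summaries[n] for n in names], names
                )
                pca_path = outdir / "topology_pca.json"
                with open(pca_path, "w") as fh:
                    json.dump(
                        {
                            "networks": names,
                            "coordinates": coords.tolist(),
                            "variance_fractions": var_frac.tolist(),
                            "descriptors_used": used,
                        },
                        fh,
                        indent=2,
                    )
                art["topology_pca"] = str(pca_path)
    except Exception as exc:
        raise StageError("diffnet", str(exc)) from exc

    # -- rank products ---------------------------------------------------
    de_relapse: set[str] = set()
    de_remission: set[str] = set()
    try:
        nc_genes = matrix.ncrna_ids
        res_rel = rankprod.rank_products(
            matrix,
            "relapse_vs_remission",
            paired=True,
            n_permutations=config.rp_permutations,
            pfp_cutoff=config.rp_pfp_cutoff,
            seed=config.seed,
            genes=nc_genes,
        )
        res_rem = rankprod.rank_products(
            matrix,
            "remission_vs_controls",
            paired=False,
            n_permutations=config.rp_permutations,
            pfp_cutoff=config.rp_pfp_cutoff,
            seed=config.seed + 1,
            genes=nc_genes,
        )
        for label, res in (("relapse", res_rel), ("remission", res_rem)):
            path = outdir / f"rankprod_{label}.tsv"
            res.table.to_csv(path, sep="\t", index_label="gene")
            art[f"rankprod_{label}"] = str(path)
        de_relapse = rankprod.de_union(res_rel)
        de_remission = rankprod.de_union(res_rem)
    except Exception as exc:
        raise StageError("rankprod", str(exc)) from exc

    # -- candidates ------------------------------------------------------
    try:
        cand = targets.select_candidates(disease, de_relapse, de_remission)
        global_hub_ids = {g for g, _ in hubs.get("global", [])}
        control_hub_ids = [g for g, _ in hubs.get("control", [])]
        cand = targets.flag_caution(cand, global_hub_ids, control_hub_ids, core)
        cand_path = outdir / "candidates.tsv"
        targets.write_candidates(cand, cand_path)
        art["candidates"] = str(cand_path)
    except Exception as exc:
        raise StageError("targets", str(exc)) from exc

    if truth is not None:
        manifest["ground_truth"] = {
            "de_ncrna_relapse": sorted(truth.de_ncrna_relapse),
            "de_ncrna_remission": sorted(truth.de_ncrna_remission),
            "disease_regulators": sorted(truth.disease_regulators),
        }

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _venn_json(v: diffnet.VennCounts) -> dict:
    return {
        "region_counts": v.region_counts,
        "union_size": v.union_size,
        "triple_shared_percent": v.triple_shared_percent,
        "pairwise_jaccard": {f"{a}|{b}": x for (a, b), x in v.pairwise_jaccard.items()},
        "pairwise_fraction": {f"{a}|{b}": x for (a, b), x in v.pairwise_fraction.items()},
    }
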