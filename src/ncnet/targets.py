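"""Therapeutic-candidate selection from the disease-specific network.

Candidates are the ncRNA nodes of the disease-specific network that are
differentially expressed in relapse (vs remission) and/or remission (vs
controls), ranked by their disease-network outdegree.  A caution flag marks
candidates that are simultaneously global-network hubs and members of the
status-independent core (manipulating such a node would perturb the
healthy network too); a softer informational note records one-sided
overlaps with the control hub list or the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .network import BipartiteNetwork


@dataclass
class CandidateTable:
    """Candidate ncRNAs with DE membership, outdegree and caution flags.

    ``table`` columns: deg_rel, deg_rem (booleans), outdegree, caution,
    caution_reason; rows sorted by outdegree descending, ties by id.
    """

    table: pd.DataFrame
    disease_nodes: set[str] = field(default_factory=set)

    def candidate_ids(self) -> list[str]:
        return self.table.index.tolist()


def _sorted(table: pd.DataFrame) -> pd.DataFrame:
    order = sorted(table.index, key=lambda g: (-table.loc[g, "outdegree"], g))
    return table.loc[order]


def select_candidates(
    disease_net: BipartiteNetwork,
    de_relapse: set[str],
    de_remission: set[str],
) -> CandidateTable:
    """ncRNA nodes of the disease network that appear in either DE list."""
    ncrnas = disease_net.ncrna_nodes
    outdeg = disease_net.outdegree()
    chosen = ncrnas & (set(de_relapse) | set(de_remission))
    rows = {
        g: {
            "deg_rel": g in de_relapse,
            "deg_rem": g in de_remission,
            "outdegree": outdeg[g],
            "caution": False,
            "caution_reason": "",
        }
        for g in chosen
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty:
        table = pd.DataFrame(
            columns=["deg_rel", "deg_rem", "outdegree", "caution", "caution_reason"]
        )
    assert set(table.index) <= ncrnas
    return CandidateTable(table=_sorted(table), disease_nodes=disease_net.nodes)


def flag_caution(
    candidates: CandidateTable,
    global_hubs: set[str],
    control_hubs: list[str] | set[str],
    core_net: BipartiteNetwork,
) -> CandidateTable:
    """Annotate candidates whose centrality elsewhere warns against manipulation.

    Hard caution (``caution=True``): candidate is a global-network hub AND a
    node of the status-independent core.  Informational note: candidate is
    in the control hub list or in the core but not both criteria; the note
    carries its control-hub rank (1-based, when ``control_hubs`` is an
    ordered list) and its core outdegree.
    """
    table = candidates.table.copy()
    core_nodes = core_net.nodes
    core_outdeg = core_net.outdegree()
    control_rank = {}
    if isinstance(control_hubs, list):
        control_rank = {g: i + 1 for i, g in enumerate(control_hubs)}
    control_set = set(control_hubs)

    for g in table.index:
        in_global_hub = g in global_hubs
        in_core = g in core_nodes
        notes = []
        if in_global_hub and in_core:
            table.loc[g, "caution"] = True
            notes.append("global-network hub and member of the status-independent core")
        else:
            if g in control_set:
                rank = control_rank.get(g)
                notes.append(
                    "control-network hub"
                    + (f" (rank {rank})" if rank is not None else "")
                )
            if in_core:
                notes.append(f"in status-independent core (outdegree {core_outdeg.get(g, 0)})")
        table.loc[g, "caution_reason"] = "; ".join(notes)
    return CandidateTable(table=_sorted(table), disease_nodes=candidates.disease_nodes)


def write_candidates(candidates: CandidateTable, path) -> None:
    out = candidates.table.copy()
    out.index.name = "ncRNA"
    out = out.rename(
        columns={"deg_rel": "DEG_REL", "deg_rem": "DEG_REM", "outdegree": "Outdegree"}
    )
    for col in ("DEG_REL", "DEG_REM"):
        out[col] = out[col].map({True: "yes", False: "no"})
    out.to_csv(path, sep="\t")
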