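"""Rank Products differential expression with permutation-based pfp.

Per comparison column (a paired within-patient difference, or one
cross-group sample pairing in the unpaired design), genes are ranked by
signed change; the rank product of a gene is the geometric mean of its
ranks across columns, computed separately for up- and down-regulation.
Significance comes from within-column rank permutations: the expected
number of null rank products at or below a gene's value, divided by the
gene's rank in the observed rank-product ordering, gives the percentage of
false prediction (pfp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

COMPARISONS = ("relapse_vs_remission", "remission_vs_controls")


@dataclass
class DEResult:
    """Per-gene rank products, expected false positives and pfp, per direction.

    ``table`` columns: rp_up, rp_down, e_up, e_down, pfp_up, pfp_down,
    rank_up, rank_down, sig_up, sig_down; index = gene ids.
    """

    table: pd.DataFrame
    comparison: str
    paired: bool
    n_columns: int
    n_permutations: int
    pfp_cutoff: float


def _change_columns(
    matrix: ExpressionMatrix,
    comparison: str,
    paired: bool,
    genes: list[str],
    rng: np.random.Generator,
    max_columns: int,
) -> np.ndarray:
    """Genes x columns matrix of signed change scores."""
    values = matrix.values.loc[genes]
    if comparison == "relapse_vs_remission":
        g1, g2 = "relapse", "remission"
    elif comparison == "remission_vs_controls":
        g1, g2 = "remission", "control"
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    s1 = matrix.samples_of(g1)
    s2 = matrix.samples_of(g2)
    if not s1 or not s2:
        raise ValueError(f"comparison {comparison!r}: a group is empty")

    if paired:
        p1 = {matrix.patient_id[s]: s for s in s1}
        p2 = {matrix.patient_id[s]: s for s in s2}
        if set(p1) != set(p2) or len(p1) != len(s1) or len(p2) != len(s2):
            raise ValueError(
                "paired comparison requires a one-to-one patient match "
                f"between {g1} and {g2} samples"
            )
        cols = [
            values[p1[p]].to_numpy() - values[p2[p]].to_numpy() for p in sorted(p1)
        ]
    else:
        pairs = [(a, b) for a in s1 for b in s2]
        if len(pairs) > max_columns:
            idx = rng.choice(len(pairs), size=max_columns, replace=False)
            pairs = [pairs[i] for i in sorted(idx)]
        cols = [values[a].to_numpy() - values[b].to_numpy() for a, b in pairs]
    return np.column_stack(cols)


def _log_rank_product(ranks: np.ndarray) -> np.ndarray:
    return np.log(ranks).mean(axis=1)


def rank_products(
    matrix: ExpressionMatrix,
    comparison: str,
    paired: bool,
    n_permutations: int = 1000,
    pfp_cutoff: float = 0.05,
    seed: int = 0,
    genes: list[str] | None = None,
    max_columns: int = 500,
) -> DEResult:
    """Rank Products over one comparison, both regulation directions.

    ``genes`` restricts the analysis (e.g. to the ncRNA panel); default is
    every gene in the matrix.  Reproducible for a fixed ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    gene_list = matrix.gene_ids if genes is None else list(genes)
    rng = np.random.default_rng(seed)
    changes = _change_columns(matrix, comparison, paired, gene_list, rng, max_columns)
    n_genes, n_cols = changes.shape

    # rank 1 = strongest change in the direction under test
    ranks_up = np.column_stack(
        [stats.rankdata(-changes[:, c]) for c in range(n_cols)]
    )
    ranks_down = np.column_stack(
        [stats.rankdata(changes[:, c]) for c in range(n_cols)]
    )

    out: dict[str, np.ndarray] = {}
    base_ranks = np.arange(1, n_genes + 1, dtype=float)
    for direction, ranks in (("up", ranks_up), ("down", ranks_down)):
        log_rp = _log_rank_product(ranks)
        # observed ordering: ascending RP, ties by gene id
        order = np.lexsort((np.array(gene_list), log_rp))
        rank_of = np.empty(n_genes, dtype=int)
        rank_of[order] = np.arange(1, n_genes + 1)

        counts = np.zeros(n_genes)
        chunk = max(1, int(2e7 / (n_genes * n_cols)))
        done = 0
        while done < n_permutations:
            k = min(chunk, n_permutations - done)
            # k independent datasets of within-column rank shuffles
            perm = rng.permuted(
                np.broadcast_to(
                    base_ranks[None, :, None], (k, n_genes, n_cols)
                ).copy(),
                axis=1,
            )
            null_rp = np.sort(np.log(perm).mean(axis=2), axis=1)
            for row in null_rp:
                counts += np.searchsorted(row, log_rp, side="right")
            done += k
        e_val = counts / n_permutations
        pfp = e_val / rank_of
        out[f"rp_{direction}"] = np.exp(log_rp)
        out[f"e_{direction}"] = e_val
        out[f"pfp_{direction}"] = pfp
        out[f"rank_{direction}"] = rank_of
        out[f"sig_{direction}"] = pfp < pfp_cutoff

    table = pd.DataFrame(out, index=gene_list)
    return DEResult(
        table=table,
        comparison=comparison,
        paired=paired,
        n_columns=n_cols,
        n_permutations=n_permutations,
        pfp_cutoff=pfp_cutoff,
    )


def de_gene_lists(result: DEResult) -> tuple[list[str], list[str]]:
    """(upregulated ids, downregulated ids) at the configured pfp cutoff."""
    t = result.table
    up = t.index[t["sig_up"]].tolist()
    down = t.index[t["sig_down"]].tolist()
    both = set(up) & set(down)
    assert not both, f"gene(s) significant in both directions: {sorted(both)[:5]}"
    return up, down


def de_union(result: DEResult) -> set[str]:
    up, down = de_gene_lists(result)
    return set(up) | set(down)
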