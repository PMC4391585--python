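"""Pairwise ncRNA-mRNA Pearson correlation and significance thresholding.

The cutoff magnitude is derived from the sample size by inverting the
t-transform t = r * sqrt((n - 2) / (1 - r^2)) at a two-sided significance
level, so smaller cohorts automatically get more stringent cutoffs.  Only
inter-class (ncRNA vs mRNA) correlations are ever computed or stored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .network import BipartiteNetwork

logger = logging.getLogger(__name__)


def critical_r(n_samples: int, alpha: float, tails: int = 2) -> float:
    """Magnitude of the Pearson R reaching significance ``alpha`` at ``n_samples``.

    Inverts t = r * sqrt((n - 2) / (1 - r^2)) against the t distribution
    with n - 2 degrees of freedom.  Strictly decreasing in ``n_samples``
    and increasing as ``alpha`` shrinks.
    """
    if n_samples < 4:
        raise ValueError(f"need n_samples >= 4 (df >= 2), got {n_samples}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if tails not in (1, 2):
        raise ValueError(f"tails must be 1 or 2, got {tails}")
    df = n_samples - 2
    t = stats.t.ppf(1.0 - alpha / tails, df)
    return float(t / np.sqrt(df + t * t))


@dataclass
class CorrelationTable:
    """Dense ncRNA x mRNA Pearson R matrix over a fixed sample subset.

    Entries are NaN where either gene had zero variance in the subset
    (undefined correlation; excluded from thresholding).
    """

    values: pd.DataFrame  # index = ncRNA ids, columns = mRNA ids
    n_samples: int

    def __post_init__(self) -> None:
        finite = self.values.values[np.isfinite(self.values.values)]
        if finite.size and (np.abs(finite) > 1.0 + 1e-9).any():
            raise ValueError("Pearson R outside [-1, 1]")


def pairwise_pearson(
    matrix: ExpressionMatrix, sample_subset: list[str] | None = None
) -> CorrelationTable:
    """Pearson R for every (ncRNA, mRNA) pair over the given samples.

    Zero-variance genes within the subset yield NaN rows/columns and a
    logged warning; the result is identical on raw or standardized input.
    """
    samples = matrix.sample_ids if sample_subset is None else list(sample_subset)
    if len(samples) < 3:
        raise ValueError(f"need at least 3 samples, got {len(samples)}")
    nc_ids = matrix.ncrna_ids
    m_ids = matrix.mrna_ids
    if not nc_ids or not m_ids:
        raise ValueError("matrix must contain both ncRNA and mRNA rows")

    sub = matrix.values.loc[:, samples]
    a = sub.loc[nc_ids].to_numpy(dtype=float)
    b = sub.loc[m_ids].to_numpy(dtype=float)
    n = len(samples)

    def center_scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((xc * xc).sum(axis=1))
        degenerate = norm == 0.0
        norm[degenerate] = 1.0
        return xc / norm[:, None], degenerate

    ac, a_bad = center_scale(a)
    bc, b_bad = center_scale(b)
    r = ac @ bc.T
    np.clip(r, -1.0, 1.0, out=r)
    if a_bad.any() or b_bad.any():
        bad = [g for g, f in zip(nc_ids, a_bad) if f] + [
            g for g, f in zip(m_ids, b_bad) if f
        ]
        logger.warning(
            "zero-variance gene(s) in sample subset, correlations undefined: %s",
            bad[:10],
        )
        r[a_bad, :] = np.nan
        r[:, b_bad] = np.nan
    return CorrelationTable(
        values=pd.DataFrame(r, index=nc_ids, columns=m_ids), n_samples=n
    )


def threshold_network(
    table: CorrelationTable,
    r_cut: float,
    sign: str = "negative",
    condition_label: str = "derived",
) -> BipartiteNetwork:
    """Keep entries strictly beyond the cutoff magnitude on one tail.

    ``sign="negative"`` keeps r < -r_cut; ``sign="positive"`` keeps
    r > +r_cut.  Ties at exactly the cutoff are excluded.
    """
    if r_cut <= 0:
        raise ValueError("r_cut is a magnitude and must be > 0")
    vals = table.values.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        mask = vals < -r_cut if sign == "negative" else vals > r_cut
    mask &= np.isfinite(vals)
    nc_idx, m_idx = np.nonzero(mask)
    nc_ids = table.values.index
    m_ids = table.values.columns
    edges = {
        (nc_ids[i], m_ids[j]): float(vals[i, j]) for i, j in zip(nc_idx, m_idx)
    }
    return BipartiteNetwork(edges=edges, sign=sign, condition_label=condition_label)


def build_condition_network(
    matrix: ExpressionMatrix,
    condition: str,
    alpha: float,
    sign: str = "negative",
    tails: int = 2,
) -> BipartiteNetwork:
    """Condition-restricted correlation + sample-size-derived threshold.

    ``condition="global"`` uses every sample.
    """
    samples = matrix.samples_of(condition)
    if len(samples) < 4:
        raise ValueError(
            f"condition {condition!r} has {len(samples)} samples; need >= 4"
        )
    table = pairwise_pearson(matrix, samples)
    r_cut = critical_r(len(samples), alpha, tails=tails)
    logger.info(
        "condition=%s n=%d alpha=%g -> |R| cutoff %.4f",
        condition,
        len(samples),
        alpha,
        r_cut,
    )
    return threshold_network(table, r_cut, sign=sign, condition_label=condition)
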