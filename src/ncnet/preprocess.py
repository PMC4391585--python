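"""Gene filtering and z-score standardization.

Two filters precede network construction: mRNAs must reach a minimum
90th-percentile intensity (probes dimmer than the negative-control level
are dropped), and ncRNA probes undetected in every sample are dropped.
After filtering, each gene row is z-scored across all retained samples so
the two platforms become comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import MRNA, NCRNA, ExpressionMatrix


class PreprocessError(ValueError):
    pass


def filter_mrna_by_intensity(
    matrix: ExpressionMatrix, threshold: float, percentile: float = 90.0
) -> ExpressionMatrix:
    """Drop mRNA rows whose per-gene ``percentile`` value is below ``threshold``.

    The rule is strict: a gene is removed iff its empirical percentile is
    strictly smaller than ``threshold``; genes sitting exactly at the
    threshold are retained.  ncRNA rows pass through untouched.
    Percentiles use linear interpolation between order statistics.
    """
    if not 0.0 < percentile < 100.0:
        raise PreprocessError(f"percentile must be in (0, 100), got {percentile}")
    is_mrna = matrix.gene_class == MRNA
    pct = matrix.values.apply(
        lambda row: np.percentile(row.values, percentile), axis=1
    )
    keep = ~is_mrna | (pct >= threshold)
    return matrix.subset(genes=matrix.values.index[keep])


def filter_ncrna_by_detection(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop ncRNA rows whose detection flag is false in every sample."""
    if matrix.detectable is None:
        raise PreprocessError(
            "detection flags missing: filter_ncrna_by_detection needs the "
            "detectable frame (vendor detection calls are inputs here)"
        )
    detected_any = matrix.detectable.any(axis=1)
    is_ncrna = matrix.gene_class == NCRNA
    keep = ~is_ncrna | detected_any
    return matrix.subset(genes=matrix.values.index[keep])


def zscore_standardize(matrix: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, sd 1 over all samples.

    Uses the sample standard deviation (``ddof=1``) by default; the choice
    does not affect any downstream Pearson correlation.  A zero-variance
    gene is an error naming the offending gene.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise PreprocessError("standardization needs at least 2 samples")
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=ddof)
    zero = sds == 0.0
    if zero.any():
        bad = values.index[zero].tolist()
        raise PreprocessError(f"zero-variance gene(s): {bad[:5]}")
    out = matrix.subset()  # copy
    out.values = values.sub(means, axis=0).div(sds, axis=0)
    return out


def preprocess(
    matrix: ExpressionMatrix,
    mrna_intensity_threshold: float | None = None,
    intensity_percentile: float = 90.0,
    apply_detection_filter: bool = True,
) -> ExpressionMatrix:
    """Filters then z-scoring, in the standard order."""
    out = matrix
    if mrna_intensity_threshold is not None:
        out = filter_mrna_by_intensity(
            out, threshold=mrna_intensity_threshold, percentile=intensity_percentile
        )
    if apply_detection_filter and out.detectable is not None:
        out = filter_ncrna_by_detection(out)
    return zscore_standardize(out)
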