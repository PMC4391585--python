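"""Expression-matrix container and its tab-separated on-disk format.

The matrix layout is genes x samples. Every gene carries a class label
(``ncRNA`` or ``mRNA``); every sample carries a condition label
(``relapse``, ``remission`` or ``control``) and, for patient samples, a
patient identifier shared by that patient's relapse and remission columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

NCRNA = "ncRNA"
MRNA = "mRNA"
GENE_CLASSES = (NCRNA, MRNA)
CONDITIONS = ("relapse", "remission", "control")


class MatrixFormatError(ValueError):
    """Raised when an expression table or sample sheet violates the format."""


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression values with gene and sample annotations.

    Parameters
    ----------
    values
        DataFrame of expression values, index = gene ids, columns = sample ids.
    gene_class
        Per-gene label, ``"ncRNA"`` or ``"mRNA"``, indexed like ``values``.
    condition
        Per-sample label in ``{"relapse", "remission", "control"}``.
    patient_id
        Per-sample patient identifier; ``None``/NaN for control samples.
    detectable
        Optional boolean genes-by-samples frame of detection calls.
        Defaults to all-true when omitted.
    ncrna_subclass
        Optional per-ncRNA label (``miRNA``, ``SNORA``, ``SNORD``, ``sdRNA``,
        ``other``).
    """

    values: pd.DataFrame
    gene_class: pd.Series
    condition: pd.Series
    patient_id: pd.Series
    detectable: pd.DataFrame | None = None
    ncrna_subclass: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate sample ids: {dups[:5]}")
        if not self.gene_class.index.equals(self.values.index):
            raise MatrixFormatError("gene_class index does not match values index")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise MatrixFormatError(f"unknown gene classes: {sorted(bad)}")
        if not self.condition.index.equals(self.values.columns):
            raise MatrixFormatError("condition index does not match sample ids")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise MatrixFormatError(f"unknown conditions: {sorted(bad)}")
        if not self.patient_id.index.equals(self.values.columns):
            raise MatrixFormatError("patient_id index does not match sample ids")
        patient_needed = self.condition.isin(["relapse", "remission"])
        missing = patient_needed & self.patient_id.isna()
        if missing.any():
            raise MatrixFormatError(
                "relapse/remission samples without patient id: "
                f"{self.condition.index[missing].tolist()[:5]}"
            )
        if self.detectable is not None:
            if not self.detectable.index.equals(self.values.index) or not (
                self.detectable.columns.equals(self.values.columns)
            ):
                raise MatrixFormatError("detectable frame misaligned with values")

    # -- accessors -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def ncrna_ids(self) -> list[str]:
        return self.values.index[self.gene_class == NCRNA].tolist()

    @property
    def mrna_ids(self) -> list[str]:
        return self.values.index[self.gene_class == MRNA].tolist()

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids of one condition; ``"global"`` returns every sample."""
        if condition == "global":
            return self.sample_ids
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return self.condition.index[self.condition == condition].tolist()

    def detection_any(self) -> pd.Series:
        """Per-gene boolean: detected in at least one sample."""
        if self.detectable is None:
            return pd.Series(True, index=self.values.index)
        return self.detectable.any(axis=1)

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        """Restrict to the given genes and/or samples (order preserved)."""
        genes = self.values.index if genes is None else pd.Index(genes)
        samples = self.values.columns if samples is None else pd.Index(samples)
        return replace(
            self,
            values=self.values.loc[genes, samples],
            gene_class=self.gene_class.loc[genes],
            condition=self.condition.loc[samples],
            patient_id=self.patient_id.loc[samples],
            detectable=None if self.detectable is None else self.detectable.loc[genes, samples],
            ncrna_subclass=None
            if self.ncrna_subclass is None
            else self.ncrna_subclass.loc[self.ncrna_subclass.index.intersection(genes)],
        )


# -- on-disk format ------------------------------------------------------
#
# Expression TSV: column 1 = gene id, column 2 = gene class, remaining
# columns = samples.  Sample sheet TSV: sample_id, condition, patient_id
# (empty patient_id for controls).  Optional gene annotation TSV:
# gene_id, ncrna_subclass, detectable (0/1, any-sample call).


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_class", matrix.gene_class)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_sample_sheet(matrix: ExpressionMatrix, path: str | Path) -> None:
    sheet = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "condition": matrix.condition.values,
            "patient_id": matrix.patient_id.values,
        }
    )
    sheet.to_csv(path, sep="\t", index=False)


def write_gene_annotation(matrix: ExpressionMatrix, path: str | Path) -> None:
    ann = pd.DataFrame(index=matrix.values.index)
    ann.index.name = "gene_id"
    sub = matrix.ncrna_subclass
    ann["ncrna_subclass"] = "" if sub is None else sub.reindex(ann.index).fillna("")
    ann["detectable"] = matrix.detection_any().astype(int)
    ann.to_csv(path, sep="\t")


def read_expression(
    expression_path: str | Path,
    sample_sheet_path: str | Path,
    gene_annotation_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read the TSV trio back into an :class:`ExpressionMatrix`."""
    try:
        table = pd.read_csv(expression_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MatrixFormatError(f"cannot parse expression table: {exc}") from exc
    if "gene_class" not in table.columns:
        raise MatrixFormatError("expression table lacks a gene_class column")
    gene_class = table["gene_class"].astype(str)
    values = table.drop(columns=["gene_class"])
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric expression values: {exc}") from exc

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "patient_id"}
    if not required.issubset(sheet.columns):
        raise MatrixFormatError(f"sample sheet needs columns {sorted(required)}")
    sheet = sheet.set_index("sample_id")
    missing = [s for s in values.columns if s not in sheet.index]
    if missing:
        raise MatrixFormatError(f"samples absent from sample sheet: {missing[:5]}")
    sheet = sheet.loc[values.columns]

    detectable = None
    ncrna_subclass = None
    if gene_annotation_path is not None:
        ann = pd.read_csv(gene_annotation_path, sep="\t", index_col=0)
        sub = ann["ncrna_subclass"].reindex(values.index)
        sub = sub[(gene_class == NCRNA) & sub.notna() & (sub != "")]
        ncrna_subclass = sub.astype(str) if len(sub) else None
        det_any = ann["detectable"].reindex(values.index).fillna(1).astype(bool)
        detectable = pd.DataFrame(
            np.repeat(det_any.values[:, None], values.shape[1], axis=1),
            index=values.index,
            columns=values.columns,
        )

    return ExpressionMatrix(
        values=values,
        gene_class=gene_class,
        condition=sheet["condition"],
        patient_id=sheet["patient_id"],
        detectable=detectable,
        ncrna_subclass=ncrna_subclass,
    )
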