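"""Synthetic expression cohorts with a planted bipartite regulatory network.

The generator emulates the paired relapse/remission + control study design:
a subset of ncRNAs ("regulators") each receive a power-law-sized set of
mRNA targets which they repress linearly; per condition a fraction of each
regulator's targets is rewired to fresh mRNAs, and selected regulators get
condition-specific mean shifts so that differential-expression recovery can
be tested against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    MRNA,
    NCRNA,
    ExpressionMatrix,
    write_expression,
    write_gene_annotation,
    write_sample_sheet,
)

CONDITIONS = ("relapse", "remission", "control")


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    ``n_patients`` patients each contribute a relapse and a remission
    sample; ``n_controls`` independent controls contribute one sample each.
    ``n_disease_regulators`` of the regulators keep identical target sets
    in relapse and remission but are fully rewired in controls, planting a
    disease-specific subnetwork; the remaining regulators are rewired
    independently per condition with probability ``rewire_fraction`` per
    edge slot.
    """

    n_patients: int = 22
    n_controls: int = 21
    n_ncrna: int = 100
    n_mrna: int = 500
    n_regulators: int = 40
    target_exponent: float = 2.0
    max_targets: int = 50
    effect_beta: float = 1.0
    noise_sd: float = 1.0
    rewire_fraction: float = 0.5
    n_de_ncrna: int = 0
    n_de_remission: int | None = None
    de_shift: float = 0.0
    patient_sd: float = 0.3
    n_disease_regulators: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_regulators > self.n_ncrna:
            raise InvalidConfigError("n_regulators exceeds n_ncrna")
        if self.max_targets > self.n_mrna:
            raise InvalidConfigError("max_targets exceeds n_mrna")
        if not 0.0 <= self.rewire_fraction <= 1.0:
            raise InvalidConfigError("rewire_fraction must be in [0, 1]")
        if self.max_targets < 1:
            raise InvalidConfigError("max_targets must be >= 1")
        if self.n_disease_regulators > self.n_regulators:
            raise InvalidConfigError("n_disease_regulators exceeds n_regulators")
        if self.n_de_ncrna > self.n_regulators:
            raise InvalidConfigError("n_de_ncrna exceeds n_regulators")
        if min(self.n_patients, self.n_controls) < 2:
            raise InvalidConfigError("need at least 2 patients and 2 controls")

    @property
    def n_de_remission_effective(self) -> int:
        return self.n_de_ncrna // 2 if self.n_de_remission is None else self.n_de_remission


@dataclass
class GroundTruth:
    """Planted structure of a cohort: per-condition edge sets and DE genes."""

    planted_edges_by_condition: dict[str, set[tuple[str, str]]]
    de_ncrna_relapse: set[str]
    de_ncrna_remission: set[str]
    disease_regulators: set[str] = field(default_factory=set)

    def all_edges(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for edges in self.planted_edges_by_condition.values():
            out |= edges
        return out


def ncrna_name(i: int) -> str:
    return f"NC{i:05d}"


def mrna_name(i: int) -> str:
    return f"MR{i:05d}"


def truncated_power_law_counts(
    rng: np.random.Generator, exponent: float, k_max: int, size: int
) -> np.ndarray:
    """Draw target-set sizes k in [1, k_max] with P(k) proportional to k^-exponent."""
    k = np.arange(1, k_max + 1)
    p = k.astype(float) ** (-exponent)
    p /= p.sum()
    return rng.choice(k, size=size, p=p)


def plant_regulatory_network(config: SimConfig) -> GroundTruth:
    """Draw the ground-truth bipartite edge sets for all three conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    regulators = [ncrna_name(i) for i in range(config.n_regulators)]
    mrnas = np.array([mrna_name(i) for i in range(config.n_mrna)])
    disease_regulators = set(regulators[: config.n_disease_regulators])

    sizes = truncated_power_law_counts(
        rng, config.target_exponent, config.max_targets, config.n_regulators
    )
    base_targets = {
        reg: set(rng.choice(config.n_mrna, size=int(k), replace=False))
        for reg, k in zip(regulators, sizes)
    }

    def rewire(targets: set[int], fraction: float) -> set[int]:
        if fraction == 0.0 or not targets:
            return set(targets)
        n_replace = int(round(fraction * len(targets)))
        if n_replace == 0:
            return set(targets)
        ordered = sorted(targets)
        drop = rng.choice(len(ordered), size=n_replace, replace=False)
        kept = set(ordered) - {ordered[i] for i in drop}
        pool = np.setdiff1d(np.arange(config.n_mrna), ordered, assume_unique=False)
        if len(pool) < n_replace:
            raise InvalidConfigError(
                "not enough non-target mRNAs to rewire; increase n_mrna"
            )
        fresh = rng.choice(pool, size=n_replace, replace=False)
        return kept | set(int(x) for x in fresh)

    edges_by_condition: dict[str, set[tuple[str, str]]] = {}
    shared_disease: dict[str, set[int]] = {}
    for reg in regulators:
        if reg in disease_regulators:
            shared_disease[reg] = set(base_targets[reg])
    for cond in CONDITIONS:
        edges: set[tuple[str, str]] = set()
        for reg in regulators:
            if reg in disease_regulators:
                # identical in relapse/remission, fully rewired for controls
                tgts = (
                    rewire(shared_disease[reg], 1.0)
                    if cond == "control"
                    else shared_disease[reg]
                )
            else:
                tgts = rewire(base_targets[reg], config.rewire_fraction)
            edges |= {(reg, str(mrnas[t])) for t in tgts}
        edges_by_condition[cond] = edges

    de_relapse = set(regulators[: config.n_de_ncrna])
    de_remission = set(regulators[: config.n_de_remission_effective])
    return GroundTruth(
        planted_edges_by_condition=edges_by_condition,
        de_ncrna_relapse=de_relapse,
        de_ncrna_remission=de_remission,
        disease_regulators=disease_regulators,
    )


def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate an expression matrix realizing the planted network.

    Per sample, regulator ncRNAs are standard normal (plus patient baseline
    and any condition mean shift); every mRNA is ``patient_baseline +
    noise_sd * z`` minus ``effect_beta`` times the sum of its regulators'
    expression under that sample's condition edge set.
    """
    config.validate()
    truth = plant_regulatory_network(config)
    rng = np.random.default_rng(config.seed + 1)

    ncrnas = [ncrna_name(i) for i in range(config.n_ncrna)]
    mrnas = [mrna_name(i) for i in range(config.n_mrna)]
    genes = ncrnas + mrnas
    n_genes = len(genes)
    mrna_pos = {g: j for j, g in enumerate(mrnas)}
    nc_pos = {g: i for i, g in enumerate(ncrnas)}

    sample_ids: list[str] = []
    conditions: list[str] = []
    patients: list[str | None] = []
    for p in range(config.n_patients):
        for cond in ("relapse", "remission"):
            sample_ids.append(f"P{p:03d}_{cond[:3]}")
            conditions.append(cond)
            patients.append(f"P{p:03d}")
    for c in range(config.n_controls):
        sample_ids.append(f"C{c:03d}")
        conditions.append("control")
        patients.append(None)
    n_samples = len(sample_ids)

    # patient-level baseline shared by a patient's two samples; controls
    # get their own independent baseline
    baseline_units = sorted({p for p in patients if p is not None}) + [
        s for s, p in zip(sample_ids, patients) if p is None
    ]
    unit_of_sample = [p if p is not None else s for s, p in zip(sample_ids, patients)]
    base_shift = {
        u: config.patient_sd * rng.standard_normal(n_genes) for u in baseline_units
    }

    ncrna_expr = rng.standard_normal((config.n_ncrna, n_samples))
    mrna_noise = config.noise_sd * rng.standard_normal((config.n_mrna, n_samples))

    values = np.empty((n_genes, n_samples))
    de_shift = np.zeros((config.n_ncrna, n_samples))
    for j, cond in enumerate(conditions):
        if cond == "relapse":
            for g in truth.de_ncrna_relapse:
                de_shift[nc_pos[g], j] = config.de_shift
        elif cond == "remission":
            for g in truth.de_ncrna_remission:
                de_shift[nc_pos[g], j] = config.de_shift

    nc_block = ncrna_expr + de_shift
    for j in range(n_samples):
        nc_block[:, j] += base_shift[unit_of_sample[j]][: config.n_ncrna]
    values[: config.n_ncrna] = nc_block

    # regulator effect per condition as a sparse sum over incoming edges
    effect = {cond: np.zeros((config.n_mrna, n_samples)) for cond in CONDITIONS}
    for cond in CONDITIONS:
        for reg, target in truth.planted_edges_by_condition[cond]:
            effect[cond][mrna_pos[target]] += ncrna_expr[nc_pos[reg]]
    m_block = mrna_noise.copy()
    for j, cond in enumerate(conditions):
        m_block[:, j] -= config.effect_beta * effect[cond][:, j]
        m_block[:, j] += base_shift[unit_of_sample[j]][config.n_ncrna :]
    values[config.n_ncrna :] = m_block

    frame = pd.DataFrame(values, index=genes, columns=sample_ids)
    gene_class = pd.Series(
        [NCRNA] * config.n_ncrna + [MRNA] * config.n_mrna, index=genes
    )
    matrix = ExpressionMatrix(
        values=frame,
        gene_class=gene_class,
        condition=pd.Series(conditions, index=sample_ids),
        patient_id=pd.Series(patients, index=sample_ids, dtype=object),
        detectable=pd.DataFrame(True, index=genes, columns=sample_ids),
        ncrna_subclass=None,
    )
    return matrix, truth


def write_cohort(
    matrix: ExpressionMatrix, truth: GroundTruth, config: SimConfig, outdir: str | Path
) -> dict[str, str]:
    """Write expression TSV, sample sheet, ground-truth edges and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(outdir / "expression.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "gene_annotation": str(outdir / "genes.tsv"),
        "truth_edges": str(outdir / "truth_edges.tsv"),
        "config": str(outdir / "sim_config.json"),
    }
    write_expression(matrix, paths["expression"])
    write_sample_sheet(matrix, paths["samples"])
    write_gene_annotation(matrix, paths["gene_annotation"])
    with open(paths["truth_edges"], "w") as fh:
        fh.write("condition\tncrna\tmrna\n")
        for cond in CONDITIONS:
            for nc, m in sorted(truth.planted_edges_by_condition[cond]):
                fh.write(f"{cond}\t{nc}\t{m}\n")
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2)
    return paths
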