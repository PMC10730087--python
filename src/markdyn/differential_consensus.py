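"""Differential-call filtering: thresholds, replicate support, dual-mutant
consensus, maintained-gene sets and the two-proportion enrichment z test.

The filters encode the consensus rules used throughout the analysis: a call
survives only at q <= 0.05 and |fold change| >= 1.5 (|log2 FC| >= log2 1.5),
must be supported in at least 2 of 3 replicates at the region level, and a
gene counts as differential only when both independent mutant lines carry a
surviving call in the same direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import AbstractSet, Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DiffRecord",
    "GeneCallSet",
    "apply_thresholds",
    "replicate_consensus",
    "dual_condition_genes",
    "maintained_genes",
    "proportion_enrichment_z",
    "simple_differential_test",
]

Q_MAX_DEFAULT = 0.05
MIN_FOLD_DEFAULT = 1.5


@dataclass(frozen=True)
class DiffRecord:
    """One differential region or transcript under one contrast."""

    target_id: str
    contrast: str
    q_value: float
    log2_fold_change: float
    replicate_support: frozenset[str] = frozenset()
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"{self.target_id}: q_value outside [0, 1]")


@dataclass(frozen=True)
class GeneCallSet:
    contrast: str
    direction: str  # increased/decreased (binding) or up/down (expression)
    genes: frozenset[str]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.genes)


def apply_thresholds(
    records: Iterable[DiffRecord],
    *,
    q_max: float = Q_MAX_DEFAULT,
    min_fold: float = MIN_FOLD_DEFAULT,
) -> list[DiffRecord]:
    """Keep records with q <= q_max and |log2 FC| >= log2(min_fold).

    Both boundaries are inclusive ("maximum q value", "minimum absolute fold
    change"). ``min_fold`` is on the linear scale and must exceed 1.
    """
    if min_fold <= 1.0:
        raise ValueError("min_fold must be > 1 (linear-scale fold change)")
    lfc_min = math.log2(min_fold)
    return [
        r
        for r in records
        if r.q_value <= q_max and abs(r.log2_fold_change) >= lfc_min - 1e-12
    ]


def replicate_consensus(
    records: Iterable[DiffRecord],
    *,
    min_support: int = 2,
    n_replicates: int = 3,
) -> list[DiffRecord]:
    """Keep region records supported in at least ``min_support`` replicates."""
    if min_support > n_replicates:
        raise ValueError(
            f"min_support {min_support} exceeds replicate count {n_replicates}"
        )
    return [r for r in records if len(r.replicate_support) >= min_support]


def records_to_gene_set(
    records: Iterable[DiffRecord], contrast: str, direction: str
) -> GeneCallSet:
    """Collapse surviving records to the genes they map to.

    A gene is called when at least one surviving record maps to it;
    ``direction`` in {increased, up} keeps positive fold changes, in
    {decreased, down} negative ones.
    """
    if direction in {"increased", "up"}:
        keep = lambda r: r.log2_fold_change > 0  # noqa: E731
    elif direction in {"decreased", "down"}:
        keep = lambda r: r.log2_fold_change < 0  # noqa: E731
    else:
        raise ValueError(f"unknown direction {direction!r}")
    genes = frozenset(
        r.gene_id or r.target_id for r in records if r.contrast == contrast and keep(r)
    )
    return GeneCallSet(contrast, direction, genes, provenance=("records_to_gene_set",))


def dual_condition_genes(
    genes_mutant1: GeneCallSet, genes_mutant2: GeneCallSet
) -> GeneCallSet:
    """Genes called in the same direction in both independent mutant lines."""
    if genes_mutant1.direction != genes_mutant2.direction:
        raise ValueError(
            f"direction mismatch: {genes_mutant1.direction} vs {genes_mutant2.direction}"
        )
    return GeneCallSet(
        contrast=f"{genes_mutant1.contrast}&{genes_mutant2.contrast}",
        direction=genes_mutant1.direction,
        genes=genes_mutant1.genes & genes_mutant2.genes,
        provenance=genes_mutant1.provenance
        + genes_mutant2.provenance
        + ("dual_condition_intersection",),
    )


def maintained_genes(
    occupied_stage1: AbstractSet[str],
    occupied_stage2: AbstractSet[str],
    decreased_set: AbstractSet[str],
) -> GeneCallSet:
    """Genes occupied at both flanking stages and not called decreased."""
    genes = frozenset(occupied_stage1) & frozenset(occupied_stage2) - frozenset(
        decreased_set
    )
    return GeneCallSet(
        contrast="stage_transition",
        direction="maintained",
        genes=genes,
        provenance=("occupied_both_stages", "minus_decreased"),
    )


def proportion_enrichment_z(
    k1: int, n1: int, k2: int, n2: int, *, one_sided: bool = True
) -> tuple[float, float]:
    """Pooled two-proportion z test.

    z = (p1 - p2) / sqrt(p(1 - p)(1/n1 + 1/n2)) with the pooled
    p = (k1 + k2) / (n1 + n2); one-sided (p1 > p2) by default.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n with n > 0 in both groups")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1)")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = float(stats.norm.sf(z)) if one_sided else float(2 * stats.norm.sf(abs(z)))
    return z, p


def simple_differential_test(
    values_group1: np.ndarray,
    values_group2: np.ndarray,
    target_ids: Sequence[str],
    contrast: str,
    *,
    gene_ids: Sequence[str] | None = None,
) -> list[DiffRecord]:
    """Plumbing stand-in for an upstream differential caller.

    Per-target Welch t test between replicate value matrices (targets x
    replicates) with Benjamini-Hochberg q-values and a log2 ratio of group
    means; exists so the consensus rules can be exercised end-to-end on
    synthetic data. It is not an affinity or likelihood model.
    """
    from statsmodels.stats.multitest import multipletests

    a = np.asarray(values_group1, dtype=float)
    b = np.asarray(values_group2, dtype=float)
    if a.shape[0] != b.shape[0] or a.shape[0] != len(target_ids):
        raise ValueError("matrices and target_ids disagree on target count")
    t_res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.nan_to_num(t_res.pvalue, nan=1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    eps = 1e-9
    lfc = np.log2((b.mean(axis=1) + eps) / (a.mean(axis=1) + eps))
    all_reps = frozenset(f"r{i + 1}" for i in range(a.shape[1]))
    return [
        DiffRecord(
            target_id=str(tid),
            contrast=contrast,
            q_value=float(q),
            log2_fold_change=float(fc),
            replicate_support=all_reps,
            gene_id=None if gene_ids is None else str(gene_ids[i]),
        )
        for i, (tid, q, fc) in enumerate(zip(target_ids, qvals, lfc))
    ]
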