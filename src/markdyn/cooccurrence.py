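"""Histone-mark co-occurrence: presence matrices and contingency analysis.

For every peak set a gene scores 1 when at least one peak overlaps its span
(gene body plus the promoter window by default). Pairs of marks are compared
in a 2x2 contingency table (both / first only / second only / neither) whose
expected cells keep the observed row and column margins fixed,
e_ij = k_i * m_j / N. Observed-vs-expected significance is a plain Pearson
chi-square with 1 df; between-stage comparisons of observed/expected ratios
use Welch's unequal-variance t test.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genomic_io import GeneModel, GenomicInterval
from .peak_annotation import PROMOTER_WINDOW

__all__ = [
    "gene_presence_matrix",
    "contingency_table",
    "fixed_margin_expected",
    "chisq_obs_exp",
    "ratio_comparison",
]


def _gene_span(gene: GeneModel, promoter_window: int, span: str) -> tuple[int, int]:
    if span == "body":
        return gene.start, gene.end
    if span == "body_plus_promoter":
        if gene.strand == "+":
            return max(0, gene.start - promoter_window), gene.end
        return gene.start, gene.end + promoter_window
    raise ValueError(f"unknown span {span!r}")


def gene_presence_matrix(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    genes: Sequence[GeneModel],
    *,
    promoter_window: int = PROMOTER_WINDOW,
    span: str = "body_plus_promoter",
) -> pd.DataFrame:
    """Binary genes x peak-sets matrix: 1 iff any peak overlaps the gene span."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, peaks in peak_sets.items():
        per_chrom: dict[str, IntervalTree] = {}
        for p in peaks:
            per_chrom.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        trees[name] = per_chrom
    data = np.zeros((len(genes), len(peak_sets)), dtype=np.int8)
    names = list(peak_sets)
    for i, gene in enumerate(genes):
        lo, hi = _gene_span(gene, promoter_window, span)
        for j, name in enumerate(names):
            tree = trees[name].get(gene.chrom)
            if tree is not None and tree.overlaps(lo, hi):
                data[i, j] = 1
    return pd.DataFrame(data, index=[g.gene_id for g in genes], columns=names)


def contingency_table(presence_a: Sequence[int], presence_b: Sequence[int]) -> np.ndarray:
    """2x2 observed table [[both, A only], [B only, neither]]."""
    a = np.asarray(presence_a, dtype=bool)
    b = np.asarray(presence_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors differ in length")
    return np.array(
        [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
    )


def fixed_margin_expected(observed: np.ndarray) -> np.ndarray:
    """Expected table under independence with fixed margins: e_ij = k_i m_j / N."""
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("negative count in contingency table")
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    k = obs.sum(axis=1)  # row sums
    m = obs.sum(axis=0)  # column sums
    return np.outer(k, m) / n


def chisq_obs_exp(observed: np.ndarray, expected: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square sum((o - e)^2 / e) with 1 df for a 2x2 table."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected shapes differ")
    if np.any(obs < 0):
        raise ValueError("negative observed count")
    if np.any(exp <= 0):
        raise ValueError("expected cell <= 0; chi-square undefined")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = 1
    return stat, float(stats.chi2.sf(stat, df)), df


def ratio_comparison(
    ratios_stage1: Sequence[float], ratios_stage2: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance two-tailed t test between per-replicate
    observed/expected ratios of two stages. Returns (t, df, p)."""
    a = np.asarray(ratios_stage1, dtype=float)
    b = np.asarray(ratios_stage2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicate ratios per stage")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
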