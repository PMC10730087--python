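"""A/B-compartment assignment of peaks and bootstrap enrichment statistics.

A peak joins the compartment interval it overlaps by at least ``min_overlap``
bp (largest overlap wins among several qualifying intervals); intervals with
a positive eigenvector score are the A compartment, negative scores the B
compartment. The expected %B under random placement is built by resampling
compartment rows with replacement until the resample has as many rows as the
peak set, repeated over bootstrap replicates; significance can be read off
either the empirical bootstrap tail or a normal approximation from the
bootstrap mean and SD. Between-stage percentages are compared with a z test
on the difference of proportions given their standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genomic_io import GenomicInterval

__all__ = [
    "BootstrapResult",
    "StageComparison",
    "load_compartments",
    "assign_compartments",
    "label_percentages",
    "bootstrap_expected",
    "enrichment_pvalue",
    "stage_compare_z",
    "all_replicates_significant",
]


@dataclass(frozen=True)
class BootstrapResult:
    """Expected %B distribution over bootstrap replicates."""

    expected: np.ndarray  # E_i, percentages
    n: int
    mean: float
    sd: float
    sem: float
    seed: int

    observed: float | None = None


@dataclass(frozen=True)
class StageComparison:
    p1: float
    p2: float
    se1: float
    se2: float
    z: float
    p_value: float


def load_compartments(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Validate compartment intervals: every row needs a nonzero signed score."""
    out = []
    for iv in intervals:
        if iv.score is None or iv.score == 0:
            raise ValueError(
                f"compartment interval {iv.chrom}:{iv.start}-{iv.end} has no "
                "nonzero eigenvector score; the A/B rule needs a sign"
            )
        out.append(iv)
    return out


def compartment_label(interval: GenomicInterval) -> str:
    return "A" if interval.score > 0 else "B"


def assign_compartments(
    peaks: Sequence[GenomicInterval],
    compartments: Sequence[GenomicInterval],
    *,
    min_overlap: int = 20,
) -> list[str]:
    """Per-peak label in {A, B, unassigned}.

    A peak must overlap a compartment interval by >= ``min_overlap`` bp to be
    assigned; with several qualifying intervals the largest overlap wins
    (ties toward the earlier interval in sorted order).
    """
    compartments = load_compartments(compartments)
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(compartments):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    labels = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        best_idx, best_ov = None, 0
        if tree is not None:
            for hit in sorted(tree.overlap(peak.start, peak.end),
                              key=lambda h: h.data):
                ov = min(peak.end, hit.end) - max(peak.start, hit.begin)
                if ov >= min_overlap and ov > best_ov:
                    best_idx, best_ov = hit.data, ov
        if best_idx is None:
            labels.append("unassigned")
        else:
            labels.append(compartment_label(compartments[best_idx]))
    return labels


def label_percentages(labels: Sequence[str]) -> dict[str, float]:
    n = len(labels)
    if n == 0:
        raise ValueError("no peaks")
    return {
        key: 100.0 * sum(1 for x in labels if x == key) / n
        for key in ("A", "B", "unassigned")
    }


def bootstrap_expected(
    compartments: Sequence[GenomicInterval],
    n_peaks: int,
    *,
    n_reps: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Expected %B from resampling compartment rows with replacement.

    Each bootstrap replicate draws ``n_peaks`` rows (matching the size of the
    peak file) and records the percentage of B rows; rows are resampled
    regardless of interval length, mirroring row-level resampling of the
    compartment file.
    """
    compartments = load_compartments(compartments)
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if not compartments:
        raise ValueError("compartment collection is empty")
    is_b = np.array([compartment_label(iv) == "B" for iv in compartments])
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(is_b), size=(n_reps, n_peaks))
    e = 100.0 * is_b[draws].mean(axis=1)
    sd = float(e.std(ddof=1)) if n_reps > 1 else 0.0
    return BootstrapResult(
        expected=e,
        n=n_reps,
        mean=float(e.mean()),
        sd=sd,
        sem=sd / np.sqrt(n_reps),
        seed=seed,
    )


def enrichment_pvalue(
    observed: float,
    boot: BootstrapResult,
    *,
    method: str = "normal",
    side: str = "greater",
) -> float:
    """P-value for the observed %B against the bootstrap expectation.

    ``empirical``: p = (1 + #{E_i >= O}) / (n + 1), bounded below by
    1/(n + 1). ``normal``: z = (O - mean E) / SD(E) referred to the standard
    normal, which reaches beyond the empirical floor.
    """
    if side not in {"greater", "less", "two_sided"}:
        raise ValueError(f"unknown side {side!r}")
    if method == "empirical":
        if side == "greater":
            extreme = np.sum(boot.expected >= observed)
        elif side == "less":
            extreme = np.sum(boot.expected <= observed)
        else:
            dev = np.abs(boot.expected - boot.mean)
            extreme = np.sum(dev >= abs(observed - boot.mean))
        return float((1 + extreme) / (boot.n + 1))
    if method == "normal":
        if boot.sd == 0:
            raise ValueError(
                "bootstrap SD is 0; the normal approximation is undefined "
                "(use method='empirical')"
            )
        z = (observed - boot.mean) / boot.sd
        if side == "greater":
            return float(stats.norm.sf(z))
        if side == "less":
            return float(stats.norm.cdf(z))
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")


def stage_compare_z(
    p1: float, se1: float, p2: float, se2: float, *, two_sided: bool = True
) -> StageComparison:
    """z test between two stage percentages given their standard errors:
    z = (p1 - p2) / sqrt(se1^2 + se2^2)."""
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be >= 0")
    if se1 == 0 and se2 == 0:
        raise ValueError("both standard errors are 0; z is undefined")
    z = (p1 - p2) / float(np.hypot(se1, se2))
    p = float(2 * stats.norm.sf(abs(z))) if two_sided else float(stats.norm.sf(z))
    return StageComparison(p1=p1, p2=p2, se1=se1, se2=se2, z=z, p_value=p)


def all_replicates_significant(
    p_values: Sequence[float], *, alpha: float = 0.05
) -> bool:
    """Per-replicate aggregation: significant only if every replicate is."""
    if not p_values:
        raise ValueError("no replicate p-values")
    return all(p < alpha for p in p_values)
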