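"""Length- and class-matched random gene sets and the gene-length null test.

The matched-set construction mirrors the random-control recipe for metagene
and full-length-transcript analyses: fit a Poisson rate to the reference
set's gene lengths, draw target lengths from that fit, and for each target
pick a random gene whose length falls within +/-10% and that carries the
required regulation class (up/down/non) in *both* mutant conditions. The
gene-length enrichment test instead draws plain quantity-matched sets and
reports the fraction of random sets whose mean length exceeds the observed
set's mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedSetSpec",
    "LengthTestResult",
    "fit_length_rate",
    "sample_matched_gene",
    "build_matched_sets",
    "length_enrichment_test",
]

REGULATION_CLASSES = {"up", "down", "non"}


@dataclass
class MatchedSetSpec:
    """Recipe for building matched random gene sets.

    ``pool`` needs columns ``gene_id``, ``length_bp`` and one column per
    condition name holding the regulation class in {up, down, non}.
    """

    reference_lengths: Sequence[float]
    pool: pd.DataFrame
    regulation_class: str
    conditions: Sequence[str]
    tolerance: float = 0.10
    n_sets: int = 10
    seed: int = 0
    rate: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.regulation_class not in REGULATION_CLASSES:
            raise ValueError(f"unknown regulation class {self.regulation_class!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        required = {"gene_id", "length_bp", *self.conditions}
        missing = required - set(self.pool.columns)
        if missing:
            raise ValueError(f"pool is missing columns {sorted(missing)}")
        if self.rate is None:
            self.rate = fit_length_rate(self.reference_lengths)


@dataclass(frozen=True)
class LengthTestResult:
    observed_mean: float
    random_means: np.ndarray
    n_sets: int
    p_value: float  # fraction of random sets with mean length > observed
    excess: float  # observed mean - mean of random means, bp


def fit_length_rate(lengths: Sequence[float]) -> float:
    """Maximum-likelihood Poisson rate for gene lengths: the sample mean."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty length collection")
    if np.any(arr < 0):
        raise ValueError("negative gene length")
    return float(arr.mean())


def _eligible_mask(
    pool: pd.DataFrame,
    target_length: float,
    regulation_class: str,
    conditions: Sequence[str],
    tolerance: float,
) -> np.ndarray:
    lengths = pool["length_bp"].to_numpy(dtype=float)
    ok = (lengths >= (1 - tolerance) * target_length) & (
        lengths <= (1 + tolerance) * target_length
    )
    for cond in conditions:
        ok &= (pool[cond] == regulation_class).to_numpy()
    return ok


def sample_matched_gene(
    target_length: float,
    pool: pd.DataFrame,
    regulation_class: str,
    conditions: Sequence[str],
    rng: np.random.Generator,
    *,
    tolerance: float = 0.10,
    max_tolerance: float = 0.25,
    widen_step: float = 0.05,
    exclude: frozenset[str] = frozenset(),
) -> str:
    """One random gene within tolerance of ``target_length`` carrying the
    required class in every condition.

    When no gene qualifies, the tolerance widens in ``widen_step`` increments
    up to ``max_tolerance`` (logged); exhaustion raises.
    """
    tol = tolerance
    while True:
        mask = _eligible_mask(pool, target_length, regulation_class, conditions, tol)
        if exclude:
            mask &= ~pool["gene_id"].isin(exclude).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size:
            return str(pool["gene_id"].iloc[int(rng.choice(idx))])
        if tol + widen_step > max_tolerance + 1e-12:
            raise ValueError(
                f"no eligible {regulation_class!r} gene within {max_tolerance:.0%} "
                f"of target length {target_length:.0f} bp"
            )
        tol += widen_step
        logger.warning(
            "no gene within %.0f%% of %.0f bp; widening tolerance to %.0f%%",
            100 * (tol - widen_step), target_length, 100 * tol,
        )


def build_matched_sets(
    spec: MatchedSetSpec, *, return_targets: bool = False
) -> list[list[str]] | tuple[list[list[str]], list[np.ndarray]]:
    """``n_sets`` gene sets, each quantity-matched to the reference set.

    Per set: draw len(reference) target lengths from Poisson(rate) and match
    each with :func:`sample_matched_gene`; sampling is without replacement
    within a set and with replacement across sets. With ``return_targets``
    the drawn target lengths are returned alongside, set by set.
    """
    rng = np.random.default_rng(spec.seed)
    n_ref = len(spec.reference_lengths)
    sets: list[list[str]] = []
    all_targets: list[np.ndarray] = []
    for _ in range(spec.n_sets):
        targets = rng.poisson(spec.rate, n_ref).astype(float)
        chosen: list[str] = []
        for target in targets:
            gene = sample_matched_gene(
                target,
                spec.pool,
                spec.regulation_class,
                spec.conditions,
                rng,
                tolerance=spec.tolerance,
                exclude=frozenset(chosen),
            )
            chosen.append(gene)
        sets.append(chosen)
        all_targets.append(targets)
    if return_targets:
        return sets, all_targets
    return sets


def length_enrichment_test(
    observed_lengths: Sequence[float],
    pool_lengths: Sequence[float],
    *,
    n_sets: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> LengthTestResult:
    """Is the observed set longer than quantity-matched random sets?

    Each of ``n_sets`` random sets draws |observed| pool members uniformly
    without replacement; p is exactly the fraction of random sets whose mean
    length exceeds the observed mean.
    """
    obs = np.asarray(observed_lengths, dtype=float)
    pool = np.asarray(pool_lengths, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observed set")
    if pool.size < obs.size:
        raise ValueError("pool smaller than the observed set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = obs.size
    # vectorized without-replacement draws: k smallest random keys per row
    keys = rng.random((n_sets, pool.size))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    random_means = pool[idx].mean(axis=1)
    observed_mean = float(obs.mean())
    p = float(np.sum(random_means > observed_mean) / n_sets)
    return LengthTestResult(
        observed_mean=observed_mean,
        random_means=random_means,
        n_sets=n_sets,
        p_value=p,
        excess=observed_mean - float(random_means.mean()),
    )
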