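"""Seeded synthetic genomes, coverage, compartments and differential tables.

Every generator is a pure function of its parameters and a seed, and every
generated entity carries a ground-truth record, so each downstream analysis
stage can be tested against planted truth without any external data.

The coverage model is the one the analyses probe: a gene-body signal with a
high 5' baseline declining linearly toward the 3' end, optionally carrying a
rectangular central bump of known amplitude (the "central accumulation"
signature of long tissue-specific genes), plus truncated-at-0 additive
Gaussian noise on binned values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel, GenomicInterval, merge_tracks

__all__ = [
    "ProfileShape",
    "TruthRecord",
    "generate_gene_set",
    "generate_coverage",
    "generate_coverage_track",
    "generate_truncation_pair",
    "generate_truncation_scenario",
    "generate_compartment_scenario",
    "generate_archetype_matrix",
    "generate_differential_frame",
]

#: Planted TSS-window profile archetypes mirroring the four occupancy classes
#: seen in real differentiation data: high (strong, slowly decaying),
#: moderate (flat intermediate), low (promoter-proximal only), none (flat 0).
ARCHETYPES = ("high", "moderate", "low", "none")


@dataclass(frozen=True)
class ProfileShape:
    """Expected binned gene-body profile, in fold-enrichment-like units."""

    five_prime_level: float = 10.0
    three_prime_level: float = 2.0
    central_bump_amplitude: float = 0.0
    central_bump_width: float = 0.2
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.five_prime_level < 0 or self.three_prime_level < 0:
            raise ValueError("baseline levels must be >= 0")
        if self.central_bump_amplitude < 0:
            raise ValueError("central bump amplitude must be >= 0")
        if not (0.0 < self.central_bump_width < 1.0):
            raise ValueError("central bump width must be a fraction in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def expected(self, t: np.ndarray) -> np.ndarray:
        """Noise-free expected value at 5'->3' gene-body fractions ``t``."""
        base = self.five_prime_level + (
            self.three_prime_level - self.five_prime_level
        ) * t
        half = self.central_bump_width / 2
        bump = np.where(np.abs(t - 0.5) <= half, self.central_bump_amplitude, 0.0)
        return base + bump


@dataclass
class TruthRecord:
    """Planted per-gene ground truth; fields filled by whichever generator."""

    gene_id: str
    shape: ProfileShape | None = None
    truncation_fraction: float | None = None
    regulation_class: dict[str, str] = field(default_factory=dict)
    compartment_label: str | None = None
    cluster_id: str | None = None


def generate_gene_set(
    n_genes: int,
    length_rate: float,
    seed: int,
    *,
    chrom: str = "chrS",
    gap: int = 10_000,
    min_length: int = 500,
    start_offset: int = 20_000,
) -> tuple[list[GeneModel], dict[str, TruthRecord]]:
    """Place ``n_genes`` non-overlapping genes on one synthetic chromosome.

    Lengths are Poisson(``length_rate``) draws (floored at ``min_length``);
    strands alternate; consecutive genes are separated by ``gap`` bp so that
    nearest-gene annotation is unambiguous by construction.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if length_rate <= 0:
        raise ValueError("length_rate must be > 0")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(rng.poisson(length_rate, n_genes), min_length)
    genes: list[GeneModel] = []
    truth: dict[str, TruthRecord] = {}
    pos = start_offset
    for i, length in enumerate(lengths):
        gene_id = f"g{i:05d}"
        strand = "+" if i % 2 == 0 else "-"
        interval = GenomicInterval(chrom, pos, pos + int(length), strand=strand)
        genes.append(
            GeneModel(gene_id=gene_id, interval=interval, transcript_id=f"{gene_id}.t1")
        )
        truth[gene_id] = TruthRecord(gene_id=gene_id)
        pos += int(length) + gap
    return genes, truth


def _binned_track(
    gene: GeneModel, values_5to3: np.ndarray, bin_size: int
) -> CoverageTrack:
    """Lay 5'->3' bin values onto genomic coordinates (mirror minus strand)."""
    n_bins = len(values_5to3)
    edges = np.linspace(gene.start, gene.end, n_bins + 1)
    starts = np.floor(edges[:-1]).astype(np.int64)
    ends = np.floor(edges[1:]).astype(np.int64)
    ends[-1] = gene.end
    keep = ends > starts
    genomic = values_5to3 if gene.strand == "+" else values_5to3[::-1]
    return CoverageTrack(
        {gene.chrom: (starts[keep], ends[keep], genomic[keep])}
    )


def generate_coverage(
    gene: GeneModel, shape: ProfileShape, seed: int, *, bin_size: int = 50
) -> CoverageTrack:
    """Binned gene-body coverage for one gene under ``shape``.

    Bin values are the expected profile at the bin midpoint (5'->3' fraction)
    plus N(0, noise_sd) noise, truncated at 0; minus-strand genes get the
    genomic mirror so the 5' end always carries the high baseline.
    """
    n_bins = max(1, gene.length_bp // bin_size)
    rng = np.random.default_rng(seed)
    t = (np.arange(n_bins) + 0.5) / n_bins
    values = shape.expected(t)
    if shape.noise_sd > 0:
        values = values + rng.normal(0.0, shape.noise_sd, n_bins)
    values = np.clip(values, 0.0, None)
    return _binned_track(gene, values, bin_size)


def generate_coverage_track(
    genes: Sequence[GeneModel],
    shapes: Mapping[str, ProfileShape] | ProfileShape,
    seed: int,
    *,
    bin_size: int = 50,
) -> CoverageTrack:
    """One track covering all genes; per-gene sub-seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed).spawn(len(genes))
    tracks = []
    for gene, sub in zip(genes, ss):
        shape = shapes[gene.gene_id] if isinstance(shapes, Mapping) else shapes
        tracks.append(
            generate_coverage(gene, shape, sub.generate_state(1)[0] % 2**31,
                              bin_size=bin_size)
        )
    return merge_tracks(tracks)


def generate_truncation_pair(
    gene: GeneModel,
    f: float,
    depth: float = 50.0,
    seed: int = 0,
    *,
    noise_sd: float = 1.0,
    stop_point: float = 0.8,
    bin_size: int = 50,
) -> tuple[CoverageTrack, CoverageTrack]:
    """WT/mutant coverage pair where a fraction ``f`` of mutant transcripts
    stop hard at ``stop_point`` of the gene length.

    Expected mutant/WT ratio is 1 before the stop point and ``1 - f`` after
    it, so the windowed log2 ratio over the final 20% is log2(1 - f).
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("truncated fraction f must be in [0, 1]")
    if not (0.0 < stop_point < 1.0):
        raise ValueError("stop_point must be in (0, 1)")
    n_bins = max(1, gene.length_bp // bin_size)
    rng = np.random.default_rng(seed)
    t = (np.arange(n_bins) + 0.5) / n_bins
    wt = np.full(n_bins, depth)
    mut = np.where(t < stop_point, depth, depth * (1.0 - f))
    if noise_sd > 0:
        wt = wt + rng.normal(0.0, noise_sd, n_bins)
        mut = mut + rng.normal(0.0, noise_sd, n_bins)
    wt = np.clip(wt, 0.0, None)
    mut = np.clip(mut, 0.0, None)
    return _binned_track(gene, wt, bin_size), _binned_track(gene, mut, bin_size)


def generate_truncation_scenario(
    genes: Sequence[GeneModel],
    truncated_gene_ids: set[str],
    f: float,
    seed: int,
    *,
    depth: float = 50.0,
    noise_sd: float = 1.0,
    n_replicates: int = 3,
    bin_size: int = 50,
) -> tuple[list[CoverageTrack], list[CoverageTrack], dict[str, TruthRecord]]:
    """Replicated WT/mutant track pairs over a whole gene set.

    Only ``truncated_gene_ids`` carry the planted 3' loss; the remaining
    genes act as the stable bulk of the library so RPM factors stay
    comparable between conditions. ``bin_size`` should not exceed the window
    width of any downstream windowed analysis, otherwise adjacent windows
    share bins and are no longer exchangeable.
    """
    wt_tracks: list[CoverageTrack] = []
    mut_tracks: list[CoverageTrack] = []
    truth = {
        g.gene_id: TruthRecord(
            gene_id=g.gene_id,
            truncation_fraction=f if g.gene_id in truncated_gene_ids else 0.0,
        )
        for g in genes
    }
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep_seed in ss:
        subs = rep_seed.spawn(len(genes))
        wt_parts, mut_parts = [], []
        for gene, sub in zip(genes, subs):
            g_f = f if gene.gene_id in truncated_gene_ids else 0.0
            wt, mut = generate_truncation_pair(
                gene, g_f, depth=depth,
                seed=int(sub.generate_state(1)[0] % 2**31), noise_sd=noise_sd,
                bin_size=bin_size,
            )
            wt_parts.append(wt)
            mut_parts.append(mut)
        wt_tracks.append(merge_tracks(wt_parts))
        mut_tracks.append(merge_tracks(mut_parts))
    return wt_tracks, mut_tracks, truth


def generate_compartment_scenario(
    n_intervals: int,
    frac_B: float,
    n_peaks: int,
    peak_bias: float,
    seed: int,
    *,
    chrom: str = "chrC",
    interval_size: int = 100_000,
    peak_size: int = 1_000,
) -> tuple[list[GenomicInterval], list[GenomicInterval], dict[str, str]]:
    """Tiled compartment intervals plus peaks with a known placement bias.

    ``peak_bias`` b mixes uniform placement over intervals (b = 0) with
    placement restricted to B intervals (b = 1). Every peak lies fully inside
    its host interval, so its overlap always clears the assignment threshold.
    Returns (compartments, peaks, truth) with truth mapping peak name -> host
    label.
    """
    if not (0.0 <= frac_B <= 1.0):
        raise ValueError("frac_B must be in [0, 1]")
    if not (0.0 <= peak_bias <= 1.0):
        raise ValueError("peak_bias must be in [0, 1]")
    if n_intervals < 1 or n_peaks < 1:
        raise ValueError("n_intervals and n_peaks must be >= 1")
    rng = np.random.default_rng(seed)
    n_b = int(round(frac_B * n_intervals))
    if peak_bias > 0 and n_b == 0:
        raise ValueError("peak_bias > 0 requires at least one B interval")
    labels = np.array(["B"] * n_b + ["A"] * (n_intervals - n_b))
    rng.shuffle(labels)
    scores = np.where(
        labels == "B", -rng.uniform(0.1, 1.0, n_intervals),
        rng.uniform(0.1, 1.0, n_intervals),
    )
    compartments = [
        GenomicInterval(chrom, i * interval_size, (i + 1) * interval_size,
                        score=float(scores[i]))
        for i in range(n_intervals)
    ]
    b_idx = np.flatnonzero(labels == "B")
    peaks: list[GenomicInterval] = []
    truth: dict[str, str] = {}
    for j in range(n_peaks):
        if rng.random() < peak_bias:
            host = int(b_idx[rng.integers(len(b_idx))])
        else:
            host = int(rng.integers(n_intervals))
        offset = int(rng.integers(0, interval_size - peak_size))
        start = host * interval_size + offset
        name = f"peak{j:05d}"
        peaks.append(GenomicInterval(chrom, start, start + peak_size, name=name))
        truth[name] = str(labels[host])
    return compartments, peaks, truth


def generate_archetype_matrix(
    n_genes: int = 400,
    seed: int = 0,
    *,
    n_bins: int = 240,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """TSS-window occupancy matrix built from four planted profile archetypes.

    Genes are split evenly over the archetypes (high / moderate / low / none);
    rows carry truncated Gaussian noise. Returns (matrix, true labels).
    """
    if n_genes < 4:
        raise ValueError("need at least 4 genes (one per archetype)")
    rng = np.random.default_rng(seed)
    bins = np.arange(n_bins)
    profiles = {
        "high": 8.0 - 3.0 * bins / n_bins,
        "moderate": np.full(n_bins, 4.0),
        "low": np.where(bins < n_bins // 3, 2.0, 0.0),
        "none": np.zeros(n_bins),
    }
    counts = np.full(4, n_genes // 4)
    counts[: n_genes % 4] += 1
    rows, labels, ids = [], [], []
    i = 0
    for arch, count in zip(ARCHETYPES, counts):
        block = profiles[arch] + rng.normal(0.0, noise_sd, (count, n_bins))
        rows.append(np.clip(block, 0.0, None))
        labels.extend([arch] * count)
        ids.extend(f"g{i + j:05d}" for j in range(count))
        i += count
    matrix = pd.DataFrame(np.vstack(rows), index=ids)
    return matrix, pd.Series(labels, index=ids, name="archetype")


def generate_differential_frame(
    genes: Sequence[GeneModel],
    true_down_ids: set[str],
    seed: int,
    *,
    contrasts: Sequence[str] = ("mut1", "mut2"),
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, dict[str, TruthRecord]]:
    """Planted per-transcript differential table for the consensus rules.

    Truly downregulated transcripts get small q-values, strong negative
    log2 fold changes and full replicate support in every contrast; null
    transcripts get uniform q-values and near-zero fold changes, so the
    planted set is recoverable at the standard thresholds.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, TruthRecord] = {}
    for gene in genes:
        is_down = gene.gene_id in true_down_ids
        rec = TruthRecord(gene_id=gene.gene_id)
        row: dict[str, object] = {
            "transcript_id": gene.transcript_id or f"{gene.gene_id}.t1",
            "gene_id": gene.gene_id,
            "tpm": float(rng.lognormal(2.0, 1.0)),
        }
        for c in contrasts:
            if is_down:
                q = float(rng.uniform(1e-6, 0.02))
                lfc = float(-rng.uniform(1.0, 2.5))
                support = 3
            else:
                q = float(rng.uniform(0.0, 1.0))
                lfc = float(rng.normal(0.0, 0.2))
                support = int(rng.integers(0, n_replicates + 1))
            row[f"q_value_{c}"] = q
            row[f"log2fc_{c}"] = lfc
            row[f"support_{c}"] = support
            rec.regulation_class[c] = "down" if is_down else "non"
        rows.append(row)
        truth[gene.gene_id] = rec
    return pd.DataFrame(rows), truth
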