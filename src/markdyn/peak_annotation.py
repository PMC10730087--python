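"""Peak-to-gene annotation, TSS-window occupancy matrices and clustering.

Peaks are matched to the gene whose TSS is nearest to the peak midpoint, with
a promoter > exon > intron > distal precedence for feature classification.
TSS-window matrices follow the (-2 kb, +10 kb) convention, strand-aware so
every row reads 5'->3'. Gene profiles are grouped by k-means; the number of
clusters is picked by an elbow rule on the within-cluster sum of squares.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genomic_io import CoverageTrack, GeneModel, GenomicInterval

__all__ = [
    "GeneAnnotation",
    "OccupancyMatrix",
    "ClusterAssignment",
    "annotate_peak",
    "annotate_peaks",
    "tss_occupancy_matrix",
    "cluster_profiles",
]

PROMOTER_WINDOW = 3_000  # bp either side of the TSS


@dataclass(frozen=True)
class GeneAnnotation:
    peak: GenomicInterval
    gene_id: str | None
    distance_to_tss: int | None  # signed, positive downstream of the TSS
    feature: str  # promoter | exon | intron | distal_intergenic


@dataclass(frozen=True)
class OccupancyMatrix:
    """Genes x TSS-window bins matrix of mean track signal."""

    values: pd.DataFrame
    window: tuple[int, int]
    bin_size: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClusterAssignment:
    labels: pd.Series  # gene_id -> cluster id
    k: int
    wcss: Mapping[int, float]
    seed: int


class _GeneIndex:
    """Per-chromosome sorted TSS positions plus gene-body lookups."""

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("gene collection is empty")
        self.by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        self.bodies: dict[str, list[GeneModel]] = {}
        for chrom in {g.chrom for g in genes}:
            sub = sorted(
                (g for g in genes if g.chrom == chrom),
                key=lambda g: (g.tss, g.gene_id),
            )
            self.by_chrom[chrom] = ([g.tss for g in sub], sub)
            self.bodies[chrom] = sorted(sub, key=lambda g: g.start)

    def nearest(self, chrom: str, pos: float) -> GeneModel | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        tss_list, sub = entry
        i = bisect.bisect_left(tss_list, pos)
        candidates = []
        if i > 0:
            candidates.append(sub[i - 1])
        if i < len(sub):
            candidates.append(sub[i])
        # ties broken toward the lexicographically smaller gene_id
        return min(candidates, key=lambda g: (abs(g.tss - pos), g.gene_id))

    def containing(self, chrom: str, pos: float) -> GeneModel | None:
        for g in self.bodies.get(chrom, ()):
            if g.start <= pos < g.end:
                return g
            if g.start > pos:
                break
        return None


def annotate_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel] | _GeneIndex,
    *,
    promoter_window: int = PROMOTER_WINDOW,
) -> GeneAnnotation:
    """Annotate one peak against a gene collection.

    Distance is measured from the peak midpoint to the nearest TSS and is
    signed in the gene's direction (positive = downstream of the TSS).
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    mid = peak.midpoint
    nearest = index.nearest(peak.chrom, mid)
    if nearest is None:
        return GeneAnnotation(peak, None, None, "distal_intergenic")
    raw = mid - nearest.tss
    signed = int(round(raw if nearest.strand == "+" else -raw))
    if abs(signed) <= promoter_window:
        feature = "promoter"
    else:
        host = index.containing(peak.chrom, mid)
        if host is None:
            feature = "distal_intergenic"
        elif host.exons is None or any(s <= mid < e for s, e in host.exons):
            feature = "exon"
        else:
            feature = "intron"
    return GeneAnnotation(peak, nearest.gene_id, signed, feature)


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    *,
    promoter_window: int = PROMOTER_WINDOW,
) -> list[GeneAnnotation]:
    index = _GeneIndex(genes)
    return [
        annotate_peak(p, index, promoter_window=promoter_window) for p in peaks
    ]


def tss_occupancy_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    *,
    window: tuple[int, int] = (-2_000, 10_000),
    bin_size: int = 50,
) -> OccupancyMatrix:
    """Mean signal in fixed-width bins across the TSS window of every gene.

    Rows are oriented 5'->3': for minus-strand genes the genomic window is
    mirrored and the bin order reversed. Window parts beyond the start of the
    chromosome read as 0.
    """
    lo, hi = window
    span = hi - lo
    if span <= 0:
        raise ValueError("window must have positive span")
    if span % bin_size != 0:
        raise ValueError(f"bin_size {bin_size} does not divide window span {span}")
    n_bins = span // bin_size
    rows = np.empty((len(genes), n_bins))
    for i, gene in enumerate(genes):
        if gene.strand == "+":
            row = track.binned_means(gene.chrom, gene.tss + lo, gene.tss + hi, n_bins)
        else:
            row = track.binned_means(gene.chrom, gene.tss - hi, gene.tss - lo, n_bins)[::-1]
        rows[i] = row
    df = pd.DataFrame(rows, index=[g.gene_id for g in genes])
    return OccupancyMatrix(values=df, window=window, bin_size=bin_size)


def _elbow(wcss: Mapping[int, float], scale: str) -> int:
    ks = sorted(wcss)
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least 3 values of k")
    w = np.array([wcss[k] for k in ks], dtype=float)
    if scale == "log":
        w = np.log(np.maximum(w, 1e-300))
    d2 = w[:-2] - 2 * w[1:-1] + w[2:]
    best = int(np.argmax(d2))  # ties -> smaller k via first argmax
    return ks[best + 1]


def cluster_profiles(
    matrix: OccupancyMatrix | pd.DataFrame,
    *,
    k: int | None = None,
    k_range: Sequence[int] = range(1, 11),
    seed: int = 0,
    elbow_scale: str = "log",
    n_init: int = 10,
) -> ClusterAssignment:
    """K-means clustering of gene profiles with elbow-based k selection.

    When ``k`` is None the within-cluster sum of squares is scanned over
    ``k_range`` and k is chosen at the point of maximum curvature (largest
    second difference) of the WCSS curve; by default the curvature is taken
    on log(WCSS), which measures the relative drop and is insensitive to the
    dominant k=1 term. Ties break toward smaller k.
    """
    df = matrix.values if isinstance(matrix, OccupancyMatrix) else matrix
    X = df.to_numpy(dtype=float)
    wcss: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    ks = sorted(set(k_range)) if k is None else sorted({*k_range, k})
    for kk in ks:
        if kk > len(df):
            raise ValueError(f"fewer rows ({len(df)}) than clusters ({kk})")
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(X)
        wcss[kk] = float(km.inertia_)
        models[kk] = km
    chosen = k if k is not None else _elbow(wcss, elbow_scale)
    labels = pd.Series(models[chosen].labels_, index=df.index, name="cluster")
    return ClusterAssignment(labels=labels, k=chosen, wcss=wcss, seed=seed)
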