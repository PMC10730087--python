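"""Configuration-driven orchestration of the stage- and mutant-comparison
analyses, plus a synthetic-scenario writer that produces a ready-to-run input
bundle.

A run is a pure function of (input files, config, seed): all randomness is
derived from the config seed through named SeedSequence spawns, and outputs
are written with fixed float formatting, so re-running a config yields
byte-identical TSVs. Every referenced path is validated before any
computation starts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import (
    compartment_enrichment as ce,
    cooccurrence as co,
    differential_consensus as dc,
    genomic_io as gio,
    matched_null as mn,
    peak_annotation as pa,
    profile_analysis as pf,
    synthetic_data as sd,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_stage_pipeline", "run_mutant_pipeline",
           "simulate_scenario"]

FLOAT_FMT = "%.8g"

DEFAULT_THRESHOLDS: dict[str, float] = {
    "q_max": 0.05,
    "min_fold": 1.5,
    "min_support": 2,
    "min_overlap": 20,
    "tolerance": 0.10,
    "promoter_window": 3000,
    "alpha": 0.05,
}


@dataclass
class RunConfig:
    seed: int
    genes: Path
    thresholds: dict[str, float]
    stages: dict[str, dict[str, list[Path]]] = field(default_factory=dict)
    compartments: Path | None = None
    conditions: dict[str, list[Path]] = field(default_factory=dict)
    abundance: Path | None = None
    contrasts: list[str] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)
    n_random_sets: int = 10
    n_bootstrap: int = 1000
    base_dir: Path = Path(".")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; every path must exist."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(p: str) -> Path:
        rp = base / p
        if not rp.exists():
            raise FileNotFoundError(f"config references missing file: {rp}")
        return rp

    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(raw.get("thresholds", {}))
    stages = {}
    for name, entry in raw.get("stages", {}).items():
        stages[name] = {
            "coverage": [resolve(p) for p in entry.get("coverage", [])],
            "peaks": [resolve(p) for p in entry.get("peaks", [])],
        }
    conditions = {
        name: [resolve(p) for p in paths]
        for name, paths in raw.get("conditions", {}).items()
    }
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        genes=resolve(raw["genes"]),
        thresholds=thresholds,
        stages=stages,
        compartments=resolve(raw["compartments"]) if raw.get("compartments") else None,
        conditions=conditions,
        abundance=resolve(raw["abundance"]) if raw.get("abundance") else None,
        contrasts=list(raw.get("contrasts", [])),
        target_genes=list(raw.get("target_genes", [])),
        n_random_sets=int(raw.get("n_random_sets", 10)),
        n_bootstrap=int(raw.get("n_bootstrap", 1000)),
        base_dir=base,
    )


class _RunLog:
    """JSON-lines structured log of parameters and counts at each step."""

    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict[str, Any]] = []

    def add(self, module: str, **fields: Any) -> None:
        self.records.append({"module": module, **fields})

    def write(self) -> None:
        with open(self.path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def _sub_seed(root: np.random.SeedSequence, *key: str) -> int:
    # zlib.crc32 is stable across processes (unlike hash() on strings)
    import zlib

    spawn_key = tuple(zlib.crc32(k.encode()) for k in key)
    ss = np.random.SeedSequence(root.entropy, spawn_key=spawn_key)
    return int(ss.generate_state(1)[0] % 2**31)


def run_stage_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Stage-transition analysis: TSS matrices and clusters, compartment
    enrichment with bootstrap expectations, co-occurrence tables, and the
    decreased/maintained gene sets across the first-to-last stage transition.
    """
    if len(config.stages) < 2:
        raise ValueError("stage pipeline needs at least 2 stages")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "stage_pipeline.log.jsonl")
    th = config.thresholds
    root = np.random.SeedSequence(config.seed)
    log.add("config", seed=config.seed, thresholds=th)

    genes = gio.read_gene_models(config.genes)
    stage_names = list(config.stages)
    tracks = {
        s: [gio.read_coverage(p) for p in config.stages[s]["coverage"]]
        for s in stage_names
    }
    peaks = {
        s: [gio.read_intervals(p) for p in config.stages[s]["peaks"]]
        for s in stage_names
    }

    # TSS matrices (replicate-averaged) and clustering on the first stage
    matrices = {}
    for s in stage_names:
        reps = [pa.tss_occupancy_matrix(t, genes) for t in tracks[s]]
        avg = sum(m.values for m in reps) / len(reps)
        matrices[s] = avg
        _write_tsv(avg, outdir / f"tss_matrix_{s}.tsv")
    clust = pa.cluster_profiles(
        matrices[stage_names[0]], seed=_sub_seed(root, "cluster")
    )
    _write_tsv(clust.labels.to_frame(), outdir / "clusters.tsv")
    _write_tsv(
        pd.DataFrame({"k": list(clust.wcss), "wcss": list(clust.wcss.values())}),
        outdir / "wcss.tsv", index=False,
    )
    log.add("peak_annotation", chosen_k=clust.k, n_genes=len(genes))

    # compartment enrichment per stage, per replicate
    if config.compartments is not None:
        comp = gio.read_intervals(config.compartments)
        rows = []
        for s in stage_names:
            rep_p = []
            for r, pk in enumerate(peaks[s]):
                labels = ce.assign_compartments(
                    pk, comp, min_overlap=int(th["min_overlap"])
                )
                pct = ce.label_percentages(labels)
                boot = ce.bootstrap_expected(
                    comp, len(pk), n_reps=config.n_bootstrap,
                    seed=_sub_seed(root, "boot", s, str(r)),
                )
                p_norm = ce.enrichment_pvalue(pct["B"], boot, method="normal")
                p_emp = ce.enrichment_pvalue(pct["B"], boot, method="empirical")
                rep_p.append(p_norm)
                rows.append(
                    {"stage": s, "replicate": r + 1, "observed_pct_B": pct["B"],
                     "expected_mean": boot.mean, "expected_sd": boot.sd,
                     "expected_sem": boot.sem, "p_normal": p_norm,
                     "p_empirical": p_emp}
                )
            sig = ce.all_replicates_significant(rep_p, alpha=th["alpha"])
            for row in rows:
                if row["stage"] == s:
                    row["stage_significant"] = sig
        comp_df = pd.DataFrame(rows)
        _write_tsv(comp_df, outdir / "compartment_report.tsv", index=False)
        first, last = stage_names[0], stage_names[-1]
        def stage_stats(s: str) -> tuple[float, float]:
            obs = comp_df.loc[comp_df["stage"] == s, "observed_pct_B"]
            return float(obs.mean()), float(obs.sem()) if len(obs) > 1 else 0.0
        p1, se1 = stage_stats(first)
        p2, se2 = stage_stats(last)
        if se1 > 0 or se2 > 0:
            cmp_ = ce.stage_compare_z(p1, se1, p2, se2)
            _write_tsv(
                pd.DataFrame([{"stage1": first, "stage2": last, "p1": p1,
                               "se1": se1, "p2": p2, "se2": se2, "z": cmp_.z,
                               "p_value": cmp_.p_value}]),
                outdir / "stage_comparison.tsv", index=False,
            )
        log.add("compartment_enrichment", n_intervals=len(comp))

    # presence matrix over every (stage, replicate) peak set + co-occurrence
    peak_sets = {
        f"{s}_r{r + 1}": pk
        for s in stage_names
        for r, pk in enumerate(peaks[s])
    }
    presence = co.gene_presence_matrix(
        peak_sets, genes, promoter_window=int(th["promoter_window"])
    )
    _write_tsv(presence, outdir / "presence_matrix.tsv")
    first, last = stage_names[0], stage_names[-1]
    n_rep = min(len(peaks[first]), len(peaks[last]))
    co_rows, ratios = [], []
    for r in range(n_rep):
        table = co.contingency_table(
            presence[f"{first}_r{r + 1}"], presence[f"{last}_r{r + 1}"]
        )
        expected = co.fixed_margin_expected(table)
        if np.all(expected > 0):
            stat, p, df_ = co.chisq_obs_exp(table, expected)
        else:
            stat, p, df_ = float("nan"), float("nan"), 1
        ratio = float(table[0, 0] / expected[0, 0]) if expected[0, 0] > 0 else float("nan")
        ratios.append(ratio)
        co_rows.append({"replicate": r + 1, "both": int(table[0, 0]),
                        "expected_both": expected[0, 0], "ratio_obs_exp": ratio,
                        "chisq": stat, "p_value": p, "df": df_})
    _write_tsv(pd.DataFrame(co_rows), outdir / "cooccurrence.tsv", index=False)
    log.add("cooccurrence", mean_ratio=float(np.nanmean(ratios)))

    # occupancy, differential stand-in, maintained genes (first -> last stage)
    min_support = int(th["min_support"])
    occupied = {}
    for s in (first, last):
        counts = sum(
            presence[f"{s}_r{r + 1}"] for r in range(len(peaks[s]))
        )
        occupied[s] = set(presence.index[counts >= min_support])
    body_means = {
        s: np.column_stack(
            [[t.mean(g.chrom, g.start, g.end) for g in genes] for t in tracks[s]]
        )
        for s in (first, last)
    }
    records = dc.simple_differential_test(
        body_means[first], body_means[last],
        [g.gene_id for g in genes], contrast=f"{first}_to_{last}",
        gene_ids=[g.gene_id for g in genes],
    )
    surviving = dc.apply_thresholds(
        records, q_max=th["q_max"], min_fold=th["min_fold"]
    )
    decreased = dc.records_to_gene_set(
        surviving, f"{first}_to_{last}", "decreased"
    )
    maintained = dc.maintained_genes(occupied[first], occupied[last], decreased.genes)
    _write_tsv(
        pd.DataFrame({"gene_id": sorted(decreased.genes)}),
        outdir / "decreased_genes.tsv", index=False,
    )
    _write_tsv(
        pd.DataFrame({"gene_id": sorted(maintained.genes)}),
        outdir / "maintained_genes.tsv", index=False,
    )
    log.add("differential_consensus", n_decreased=len(decreased),
            n_maintained=len(maintained),
            n_occupied_first=len(occupied[first]),
            n_occupied_last=len(occupied[last]))
    log.write()
    return {"clusters": clust, "decreased": decreased, "maintained": maintained,
            "outdir": outdir}


def run_mutant_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """WT-vs-mutant analysis: threshold + dual-mutant consensus gene calls,
    matched random gene sets, metagenes, windowed log2 ratios and the
    tail-loss report."""
    if config.abundance is None:
        raise ValueError("mutant pipeline needs an abundance table")
    if len(config.contrasts) < 2:
        raise ValueError(
            "dual-mutant intersection requested but fewer than 2 contrasts given"
        )
    if "wt" not in config.conditions:
        raise ValueError("mutant pipeline needs a 'wt' condition")
    mutants = [c for c in config.conditions if c != "wt"]
    if not mutants:
        raise ValueError("mutant pipeline needs at least one mutant condition")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "mutant_pipeline.log.jsonl")
    th = config.thresholds
    root = np.random.SeedSequence(config.seed)
    log.add("config", seed=config.seed, thresholds=th, contrasts=config.contrasts)

    genes = gio.read_gene_models(config.genes)
    by_id = {g.gene_id: g for g in genes}
    abundance = gio.read_abundance(config.abundance, config.contrasts)

    # consensus differential expression calls
    call_sets = {}
    for c in config.contrasts:
        records = [
            dc.DiffRecord(
                target_id=a.transcript_id, contrast=c,
                q_value=a.contrasts[c].q_value,
                log2_fold_change=a.contrasts[c].log2_fold_change,
                gene_id=a.gene_id,
            )
            for a in abundance
        ]
        surviving = dc.apply_thresholds(records, q_max=th["q_max"], min_fold=th["min_fold"])
        call_sets[c] = dc.records_to_gene_set(surviving, c, "down")
    down = call_sets[config.contrasts[0]]
    for c in config.contrasts[1:]:
        down = dc.dual_condition_genes(down, call_sets[c])
    _write_tsv(pd.DataFrame({"gene_id": sorted(down.genes)}),
               outdir / "down_genes_dual.tsv", index=False)
    log.add("differential_consensus", n_down_dual=len(down),
            per_contrast={c: len(s) for c, s in call_sets.items()})

    # pool with per-contrast regulation classes for matched nulls
    def classify(a: gio.AbundanceRecord, c: str) -> str:
        cs = a.contrasts[c]
        if cs.q_value <= th["q_max"] and abs(cs.log2_fold_change) >= np.log2(th["min_fold"]) - 1e-12:
            return "down" if cs.log2_fold_change < 0 else "up"
        return "non"

    pool_rows = []
    for a in abundance:
        g = by_id.get(a.gene_id)
        if g is None:
            continue
        row = {"gene_id": a.gene_id, "length_bp": g.length_bp}
        row.update({c: classify(a, c) for c in config.contrasts})
        pool_rows.append(row)
    pool = pd.DataFrame(pool_rows).drop_duplicates("gene_id").reset_index(drop=True)

    target_ids = config.target_genes or sorted(down.genes)
    if not target_ids:
        raise ValueError("no target genes: dual-mutant down set is empty")
    target_genes = [by_id[g] for g in target_ids if g in by_id]
    target_lengths = [g.length_bp for g in target_genes]

    # control sets: length/quantity-matched genes that are non-regulated in
    # every contrast, so they should NOT carry the planted 3' signature
    matched_sets: list[list[str]] = []
    try:
        spec = mn.MatchedSetSpec(
            reference_lengths=target_lengths, pool=pool, regulation_class="non",
            conditions=config.contrasts, tolerance=th["tolerance"],
            n_sets=config.n_random_sets, seed=_sub_seed(root, "matched"),
        )
        matched_sets = mn.build_matched_sets(spec)
    except ValueError as exc:
        log.add("matched_null", error=str(exc))
    if matched_sets:
        _write_tsv(
            pd.DataFrame(
                [(i + 1, gid) for i, s in enumerate(matched_sets) for gid in s],
                columns=["set", "gene_id"],
            ),
            outdir / "matched_sets.tsv", index=False,
        )

    length_res = mn.length_enrichment_test(
        target_lengths, pool["length_bp"].to_numpy(),
        n_sets=10_000, seed=_sub_seed(root, "lengthtest"),
    )
    _write_tsv(
        pd.DataFrame([{"observed_mean_bp": length_res.observed_mean,
                       "random_mean_bp": float(length_res.random_means.mean()),
                       "excess_bp": length_res.excess,
                       "p_value": length_res.p_value,
                       "n_sets": length_res.n_sets}]),
        outdir / "length_test.tsv", index=False,
    )

    # metagenes per condition and windowed ratios per mutant on the target set
    cond_tracks = {
        name: [gio.read_coverage(p) for p in paths]
        for name, paths in config.conditions.items()
    }
    meta_rows = {}
    for name, trk in cond_tracks.items():
        prof = pf.metagene_profile(trk, target_genes, gene_set_id=f"target_{name}")
        meta_rows[name] = prof.mean
    _write_tsv(pd.DataFrame(meta_rows), outdir / "metagene_target.tsv")

    tail_rows = []
    for mut in mutants:
        ratio = pf.windowed_log2_ratio(cond_tracks[mut], cond_tracks["wt"], target_genes)
        _write_tsv(
            pd.DataFrame({"window": np.arange(1, ratio.n_windows + 1),
                          "log2_ratio": ratio.trace}),
            outdir / f"windowed_ratio_{mut}.tsv", index=False,
        )
        stat, p = pf.tail_loss_statistic(
            ratio, seed=_sub_seed(root, "tailperm", mut)
        )
        tail_rows.append({"gene_set": "target", "condition": mut,
                          "tail_loss": stat, "p_value": p,
                          "flagged": p < th["alpha"]})
        for i, gene_set in enumerate(matched_sets):
            set_genes = [by_id[g] for g in gene_set if g in by_id]
            r2 = pf.windowed_log2_ratio(cond_tracks[mut], cond_tracks["wt"], set_genes)
            s2, p2 = pf.tail_loss_statistic(
                r2, seed=_sub_seed(root, "tailperm", mut, str(i))
            )
            tail_rows.append({"gene_set": f"matched_{i + 1}", "condition": mut,
                              "tail_loss": s2, "p_value": p2,
                              "flagged": p2 < th["alpha"]})
    _write_tsv(pd.DataFrame(tail_rows), outdir / "tail_loss.tsv", index=False)
    log.add("profile_analysis", n_target=len(target_genes),
            n_matched_sets=len(matched_sets))
    log.write()
    return {"down": down, "matched_sets": matched_sets, "tail": tail_rows,
            "length_test": length_res, "outdir": outdir}


# ---------------------------------------------------------------------------
# synthetic end-to-end scenario
# ---------------------------------------------------------------------------

def simulate_scenario(
    outdir: str | Path,
    seed: int = 0,
    *,
    n_genes: int = 60,
    length_rate: float = 20_000.0,
    n_maintained: int = 15,
    n_unoccupied: int = 10,
    n_truncated: int = 10,
    truncation_f: float = 0.5,
    n_replicates: int = 3,
) -> Path:
    """Write a complete synthetic input bundle plus a run config.

    Two stages model a transition where most occupied genes lose the mark
    (only ``n_maintained`` keep it); WT and two mutant conditions carry a
    planted hard 3' truncation (fraction ``truncation_f``) on ``n_truncated``
    target genes. Returns the path of the generated config.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    genes, _ = sd.generate_gene_set(n_genes, length_rate, _sub_seed(root, "genes"))
    gio.write_gene_models(outdir / "genes.bed12", genes)
    ids = [g.gene_id for g in genes]
    unoccupied = set(ids[:n_unoccupied])
    maintained = set(ids[n_unoccupied:n_unoccupied + n_maintained])
    occupied = [g for g in genes if g.gene_id not in unoccupied]
    truncated = set(ids[n_unoccupied:n_unoccupied + n_truncated])

    high = sd.ProfileShape(five_prime_level=8.0, three_prime_level=4.0, noise_sd=0.5)
    low = sd.ProfileShape(five_prime_level=1.0, three_prime_level=0.5, noise_sd=0.2)
    off = sd.ProfileShape(five_prime_level=0.05, three_prime_level=0.05, noise_sd=0.02)

    stages: dict[str, dict[str, list[str]]] = {}
    for s_idx, stage in enumerate(("CMes", "CP")):
        cov_paths, peak_paths = [], []
        for r in range(n_replicates):
            shapes = {}
            peak_list = []
            for g in genes:
                if g.gene_id in unoccupied:
                    shapes[g.gene_id] = off
                elif stage == "CMes" or g.gene_id in maintained:
                    shapes[g.gene_id] = high
                    peak_list.append(
                        gio.GenomicInterval(g.chrom, g.start, g.end, name=g.gene_id)
                    )
                else:
                    shapes[g.gene_id] = low
            track = sd.generate_coverage_track(
                genes, shapes, _sub_seed(root, "cov", stage, str(r))
            )
            cov = f"{stage}_r{r + 1}.bedgraph"
            pkf = f"{stage}_r{r + 1}_peaks.bed"
            gio.write_coverage(outdir / cov, track)
            gio.write_intervals(outdir / pkf, peak_list)
            cov_paths.append(cov)
            peak_paths.append(pkf)
        stages[stage] = {"coverage": cov_paths, "peaks": peak_paths}

    # compartments tiling the synthetic chromosome
    rng = np.random.default_rng(_sub_seed(root, "compartments"))
    span_end = max(g.end for g in genes) + 50_000
    comp = []
    for i, start in enumerate(range(0, span_end, 100_000)):
        score = float(rng.uniform(0.1, 1.0)) * (1 if rng.random() < 0.5 else -1)
        comp.append(gio.GenomicInterval("chrS", start, start + 100_000, score=score))
    gio.write_intervals(outdir / "compartments.bed", comp)

    # abundance with the truncated target genes planted as dual-mutant down
    frame, _ = sd.generate_differential_frame(
        genes, truncated, _sub_seed(root, "abundance")
    )
    frame.drop(columns=[c for c in frame.columns if c.startswith("support_")]).to_csv(
        outdir / "abundance.tsv", sep="\t", index=False
    )

    # WT + two mutant coverage conditions with the planted 3' truncation
    conditions: dict[str, list[str]] = {"wt": [], "mut1": [], "mut2": []}
    for mut in ("mut1", "mut2"):
        wt_tracks, mut_tracks, _ = sd.generate_truncation_scenario(
            genes, truncated, truncation_f, _sub_seed(root, "trunc", mut),
            n_replicates=n_replicates,
        )
        for r, (wt_t, mut_t) in enumerate(zip(wt_tracks, mut_tracks)):
            if mut == "mut1":
                wt_name = f"wt_r{r + 1}.bedgraph"
                gio.write_coverage(outdir / wt_name, wt_t)
                conditions["wt"].append(wt_name)
            mut_name = f"{mut}_r{r + 1}.bedgraph"
            gio.write_coverage(outdir / mut_name, mut_t)
            conditions[mut].append(mut_name)

    config = {
        "seed": seed,
        "genes": "genes.bed12",
        "stages": stages,
        "compartments": "compartments.bed",
        "conditions": conditions,
        "abundance": "abundance.tsv",
        "contrasts": ["mut1", "mut2"],
        "target_genes": sorted(truncated),
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "n_random_sets": 3,
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
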