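"""End-to-end orchestration: simulate -> DE -> diagnostics -> filter ->
classify -> report, with a machine-readable run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import de_all_pairs, estimate_common_dispersion
from .matrix import CountMatrix, read_counts, write_counts
from .normalize import compute_tmm_factors, cpm_matrix, filter_low_expression
from .orthogroups import filter_paralogous_orthogroups, size_summary, write_orthogroup_fasta
from .phenotype import (
    COMPARISONS,
    classify_all,
    novel_total,
    parent_bias_summary,
)
from .rbbh import (
    classify_pairs_de,
    coassembly_chi2,
    direction_partition,
    reciprocal_best_hits,
    write_hit_table,
)
from .simulate import (
    SimulationConfig,
    emit_hit_table,
    inject_de_paralogs,
    inject_split_orthologs,
    simulate_counts,
    simulate_orthogroup_sequences,
    write_truth,
)
from .summarize import pca, sample_correlation_matrix

__all__ = ["AnalysisConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Knobs of the analysis stages.

    ``alpha`` is the FDR cutoff for DE calls; TMM trims, the CPM
    pseudocount, the k-mer size of the orthogroup filter and the
    chi-square null option mirror the individual stage defaults.
    """

    alpha: float = 0.05
    trim_m: float = 0.30
    trim_a: float = 0.05
    cpm_pseudocount: float = 1.0
    kmer_k: int = 6
    chi2_null: str = "members"  # or "external_rate"
    min_cpm: float | None = None
    seed: int = 0
    n_ogs: int = 200
    og_paralog_fraction: float = 0.1
    og_divergence: float = 0.05
    noise_hits: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.trim_m < 0.5) or not (0 <= self.trim_a < 0.5):
            raise ValueError("trims must lie in [0, 0.5)")
        if self.chi2_null not in ("members", "external_rate"):
            raise ValueError("chi2_null must be 'members' or 'external_rate'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def _write_de_tables(de_tables, out_dir: Path) -> list[str]:
    paths = []
    for (a, b), table in de_tables.items():
        p = out_dir / f"de_{a}_{b}.tsv"
        table.to_csv(p, sep="\t", index_label="locus")
        paths.append(p.name)
    return paths


def run_pipeline(
    sim_config: SimulationConfig,
    analysis: AnalysisConfig,
    out_dir: str | Path,
    counts_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> dict:
    """Run every stage and write all artifacts under ``out_dir``.

    With ``counts_path``/``samples_path`` the count matrix is loaded
    from disk (truth-dependent stages — co-assembly diagnostics on the
    emitted hit table and recovery summaries — are then skipped);
    otherwise data are simulated from ``sim_config``.  Returns the run
    manifest, which is also written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list[dict] = []
    manifest: dict = {
        "package": "orthoexpress",
        "version": __version__,
        "config": {"simulation": asdict(sim_config), "analysis": asdict(analysis)},
        "stages": stages,
        "outputs": [],
    }

    def stage(name):
        rec = {"name": name, "started": time.time() - t0}
        stages.append(rec)
        logger.info("stage %s", name)
        return rec

    truth = None
    rec = stage("input")
    if counts_path is not None:
        if samples_path is None:
            raise ValueError("samples_path is required with counts_path")
        cm = read_counts(counts_path, samples_path)
    else:
        cm, truth = simulate_counts(sim_config)
        cm, truth = inject_split_orthologs(
            cm,
            truth,
            sim_config.split_fraction,
            seed=sim_config.seed + 1,
            leak_rate=sim_config.leak_rate,
            hybrid_lineage=sim_config.split_hybrid_lineage,
        )
        cm, truth = inject_de_paralogs(
            cm,
            truth,
            sim_config.paralog_fraction,
            seed=sim_config.seed + 2,
            effect_size=sim_config.effect_size,
            dispersion=sim_config.dispersion,
            hybrid_lineage=sim_config.split_hybrid_lineage,
        )
        write_counts(cm, out / "counts.tsv", out / "samples.tsv")
        write_truth(truth, out / "truth.tsv")
        manifest["outputs"] += ["counts.tsv", "samples.tsv", "truth.tsv"]
    rec["seconds"] = time.time() - t0 - rec["started"]

    rec = stage("normalize")
    factors = compute_tmm_factors(cm, analysis.trim_m, analysis.trim_a)
    if analysis.min_cpm is not None:
        cm = filter_low_expression(cm, factors, analysis.min_cpm)
        factors = compute_tmm_factors(cm, analysis.trim_m, analysis.trim_a)
    factors.factors.to_csv(out / "tmm_factors.tsv", sep="\t")
    log_cpm = cpm_matrix(cm, factors, log2_transform=True, pseudocount=analysis.cpm_pseudocount)
    log_cpm.to_csv(out / "log2_cpm.tsv", sep="\t", index_label="locus")
    manifest["outputs"] += ["tmm_factors.tsv", "log2_cpm.tsv"]
    rec["seconds"] = time.time() - t0 - rec["started"]

    rec = stage("differential_expression")
    dispersion = estimate_common_dispersion(cm, factors)
    de_tables = de_all_pairs(
        cm, pairs=list(COMPARISONS), factors=factors, dispersion=dispersion, alpha=analysis.alpha
    )
    manifest["outputs"] += _write_de_tables(de_tables, out)
    manifest["dispersion"] = dispersion.phi
    rec["seconds"] = time.time() - t0 - rec["started"]

    if truth is not None:
        rec = stage("coassembly_diagnostics")
        hits = emit_hit_table(truth, noise_hits=analysis.noise_hits, seed=sim_config.seed + 3)
        write_hit_table(hits, out / "hits.tsv")
        lineage_of = truth["lineage"].to_dict()
        pairs = reciprocal_best_hits(hits, "bro", "fru", taxon_of=lineage_of)
        pairs.to_csv(out / "rbbh_pairs.tsv", sep="\t", index=False)
        diag: dict = {"n_rbbh_pairs": int(len(pairs))}
        if len(pairs):
            classes = classify_pairs_de(pairs, de_tables[("bro", "fru")])
            classes.to_csv(out / "rbbh_classes.tsv", sep="\t", index=False)
            report = coassembly_chi2(classes)
            diag["contingency"] = report.as_dict()
            if report.n_both > 0:
                diag["direction"] = direction_partition(classes).as_dict()
            manifest["outputs"].append("rbbh_classes.tsv")
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diag, fh, indent=2)
        manifest["outputs"] += ["hits.tsv", "rbbh_pairs.tsv", "diagnostics.json"]
        rec["seconds"] = time.time() - t0 - rec["started"]

    rec = stage("orthogroup_filter")
    ogs, og_truth = simulate_orthogroup_sequences(
        n_ogs=analysis.n_ogs,
        paralog_fraction=analysis.og_paralog_fraction,
        divergence=analysis.og_divergence,
        seed=sim_config.seed + 4,
    )
    write_orthogroup_fasta(ogs, out / "orthogroups.fasta")
    og_truth.to_csv(out / "orthogroup_truth.tsv", sep="\t")
    kept, removed, og_report = filter_paralogous_orthogroups(ogs, k=analysis.kmer_k)
    pd.Series([og.id for og in kept]).to_csv(
        out / "orthogroups_kept.tsv", sep="\t", index=False, header=["orthogroup"]
    )
    pd.Series([og.id for og in removed]).to_csv(
        out / "orthogroups_removed.tsv", sep="\t", index=False, header=["orthogroup"]
    )
    manifest["orthogroup_filter"] = {
        "n_input": og_report.n_input,
        "n_removed": og_report.n_removed,
        "n_kept": og_report.n_kept,
        "n_untested": og_report.n_untested,
        "size_fractions": size_summary(ogs),
    }
    manifest["outputs"] += [
        "orthogroups.fasta",
        "orthogroup_truth.tsv",
        "orthogroups_kept.tsv",
        "orthogroups_removed.tsv",
    ]
    rec["seconds"] = time.time() - t0 - rec["started"]

    rec = stage("phenotype_classification")
    cpm = cpm_matrix(cm, factors)
    group_means = pd.DataFrame(
        {t: cpm[cm.samples_of(t)].mean(axis=1) for t in cm.taxa}
    )
    calls, counts = classify_all(de_tables, group_means)
    calls.to_csv(out / "phenotype_calls.tsv", sep="\t")
    counts.to_csv(out / "phenotype_counts.tsv", sep="\t", header=["n_loci"])
    bias = {}
    for hybrid in ("sun", "lem"):
        n_bro, n_fru, ratio = parent_bias_summary(counts, hybrid)
        bias[hybrid] = {"n_bro_like": n_bro, "n_fru_like": n_fru, "ratio": ratio}
    manifest["phenotypes"] = {
        "counts": {k: int(v) for k, v in counts.items()},
        "novel_total": novel_total(counts),
        "parent_bias": bias,
    }
    manifest["outputs"] += ["phenotype_calls.tsv", "phenotype_counts.tsv"]
    rec["seconds"] = time.time() - t0 - rec["started"]

    rec = stage("global_summaries")
    corr, ordering = sample_correlation_matrix(log_cpm)
    corr.to_csv(out / "sample_correlation.tsv", sep="\t")
    scores, var_frac = pca(log_cpm)
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample")
    manifest["pca_variance_fractions"] = [float(v) for v in var_frac]
    manifest["correlation_ordering"] = ordering
    manifest["outputs"] += ["sample_correlation.tsv", "pca_scores.tsv"]
    rec["seconds"] = time.time() - t0 - rec["started"]

    manifest["total_seconds"] = time.time() - t0
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"].append("manifest.json")
    return manifest
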