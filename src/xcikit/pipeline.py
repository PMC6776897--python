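"""End-to-end orchestration: synthetic demo and user-supplied runs.

``run_synthetic_demo`` wires the full chain — simulate → ChIP
normalization/accumulation → induction-corrected differential expression →
promoter classification and integration → ChIRP-MS scoring — and returns a
machine-readable report with truth-recovery diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chirp as chirp_mod
from .chipquant import (
    CountMatrix,
    accumulation_signal,
    consensus_peaks,
    filter_outlier_windows,
    read_sample_sheet,
    tmm_factors,
)
from .differential import (
    DifferentialModel,
    filter_expressed_genes,
    mixture_log2_ratio,
    tpm_from_counts,
)
from .regionstats import (
    accumulation_threshold,
    classify_promoters,
    cpg_metrics,
    integrate_silencing_accumulation,
    rank_sum_compare,
    silencing_bins,
)
from .simulate import MARKS, SimulationConfig, simulate_dataset

logger = logging.getLogger("xcikit.pipeline")

__all__ = ["PipelineConfig", "run_synthetic_demo", "run_user_pipeline"]


@dataclass
class PipelineConfig:
    """Run configuration; YAML-serializable, CLI flags override fields."""

    seed: int = 0
    outdir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    consensus_min_support: int = 2
    outlier_k: float = 1.5
    min_tpm: float = 1.0
    min_expressed_samples: int = 6
    thresholds_override: dict | None = None
    chirp_min_fc: float = 2.5
    chirp_min_annotation_score: int = 3
    chirp_top_n: int = 20
    # user-pipeline inputs
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    peptide_table_path: str | None = None
    model: str = "induction"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # output location is not an analysis parameter
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def _chip_stage(config: PipelineConfig, dataset, genotype: str) -> dict:
    """Consensus anchoring, TMM, outlier filtering and accumulation, per mark."""
    ann = dataset.annotation
    consensus = consensus_peaks(
        ann.peak_sets, min_support=config.consensus_min_support
    )
    anchor_ids = [
        rid
        for rid, iv in ann.anchors
        if any(iv.overlaps(c) for c in consensus)
    ]
    analysis_ids = [
        rid
        for part in (ann.intergenic, ann.promoters, ann.gene_bodies)
        for rid, _ in part
    ]
    out: dict = {}
    for mark in MARKS:
        cm, samples = dataset.chip[genotype][mark]
        factors = tmm_factors(
            cm.subset_regions(anchor_ids), library_sizes=cm.library_sizes
        )
        input_cm, _ = dataset.chip[genotype]["input"]
        retained = filter_outlier_windows(
            input_cm.subset_regions(analysis_ids), k=config.outlier_k
        )
        accum = accumulation_signal(cm.subset_regions(retained), factors, samples)
        out[mark] = {
            "factors": dict(zip(cm.sample_ids, factors)),
            "n_retained": len(retained),
            "accumulation": accum,
        }
    out["n_consensus_peaks"] = len(consensus)
    out["n_anchor_regions"] = len(anchor_ids)
    return out


def _rna_stage(config: PipelineConfig, dataset) -> dict:
    """Expression filter, per-genotype induction and condition fits."""
    ann = dataset.annotation
    lengths = {
        tm.gene_name: tm.exonic_length for tm in ann.transcripts
    }
    genotypes = sorted(dataset.rna)
    combined = pd.concat(
        [dataset.rna[gt][0].to_frame() for gt in genotypes], axis=1
    )
    exon_bp = np.array([lengths[g] for g in combined.index], dtype=float)
    tpm = pd.DataFrame(
        tpm_from_counts(combined.to_numpy(), exon_bp),
        index=combined.index,
        columns=combined.columns,
    )
    expressed = filter_expressed_genes(
        tpm, min_tpm=config.min_tpm, min_samples=config.min_expressed_samples
    )
    chrom_of = {g.gene_name: g.chrom for g in ann.genes}
    expressed_autosomal = [g for g in expressed if chrom_of[g] != "chrX"]

    out: dict = {"n_expressed": len(expressed)}
    for gt in genotypes:
        cm, samples = dataset.rna[gt]
        sub = cm.subset_regions(expressed)
        factors = tmm_factors(
            sub.subset_regions(expressed_autosomal), library_sizes=cm.library_sizes
        )
        results = {}
        for model in ("induction", "condition"):
            dm = DifferentialModel(
                sub, samples, model=model, factors=factors, use_voom=False
            )
            results[model] = dm.fit(moderate=False)
        out[gt] = {
            "factors": dict(zip(cm.sample_ids, factors)),
            "corrected_logfc": results["induction"].effect,
            "logfc": results["condition"].effect,
        }
    out["expressed"] = expressed
    return out


def _recovery(dataset, rna_out: dict, genotype: str) -> dict:
    """Compare estimated corrected logFC on chrX with the closed-form truth."""
    ann = dataset.annotation
    chrx = [
        g
        for g in rna_out["expressed"]
        if {x.gene_name: x.chrom for x in ann.genes}[g] == "chrX"
    ]
    est = rna_out[genotype]["corrected_logfc"].loc[chrx]
    f1, f2 = dataset.truth.induction_fractions[genotype]
    beta = dataset.truth.beta[genotype].loc[chrx].to_numpy()
    expected = 0.5 * (
        mixture_log2_ratio(f1, beta) / f1 + mixture_log2_ratio(f2, beta) / f2
    )
    return {
        "n_chrx_genes": len(chrx),
        "mean_corrected_logfc": float(est.mean()),
        "mean_expected": float(np.mean(expected)),
        "mean_abs_error": float(np.mean(np.abs(est.to_numpy() - expected))),
    }


def run_synthetic_demo(config: PipelineConfig) -> dict:
    """Simulate a full study and run every analysis stage; returns the report."""
    sim = config.simulation
    dataset = simulate_dataset(sim, config.seed)
    ann = dataset.annotation
    genotypes = sorted(sim.induction_fractions)
    chrom_of_region = {
        rid: iv.chrom
        for part in (ann.intergenic, ann.promoters, ann.gene_bodies, ann.anchors)
        for rid, iv in part
    }

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": len(ann.genes),
        "genotypes": genotypes,
    }

    chip_out = {gt: _chip_stage(config, dataset, gt) for gt in genotypes}
    rna_out = _rna_stage(config, dataset)

    # accumulation comparisons: chrX vs autosomes, per genotype and mark
    comparisons: dict = {}
    for gt in genotypes:
        comparisons[gt] = {}
        for mark in MARKS:
            accum = chip_out[gt][mark]["accumulation"]["accum_mean"]
            inter = [r for r in accum.index if r.startswith("intergenic:")]
            prom = [r for r in accum.index if r.startswith("promoter:")]
            res = {}
            for label, ids in (("intergenic", inter), ("promoter", prom)):
                on_x = [r for r in ids if chrom_of_region[r] == "chrX"]
                on_a = [r for r in ids if chrom_of_region[r] != "chrX"]
                stat_g, p_greater = rank_sum_compare(
                    accum.loc[on_x], accum.loc[on_a], alternative="greater"
                )
                _, p_two = rank_sum_compare(accum.loc[on_x], accum.loc[on_a])
                res[label] = {
                    "n_chrx": len(on_x),
                    "n_autosomal": len(on_a),
                    "median_chrx": float(accum.loc[on_x].median()),
                    "median_autosomal": float(accum.loc[on_a].median()),
                    "p_chrx_greater": p_greater,
                    "p_two_sided": p_two,
                }
            comparisons[gt][mark] = res
    report["accumulation_vs_autosomes"] = comparisons

    # paired FL vs dBC promoter accumulation on chrX (shared retained genes)
    if "FL" in genotypes and "dBC" in genotypes:
        paired: dict = {}
        for mark in MARKS:
            a_fl = chip_out["FL"][mark]["accumulation"]["accum_mean"]
            a_db = chip_out["dBC"][mark]["accumulation"]["accum_mean"]
            shared = [
                r
                for r in a_fl.index.intersection(a_db.index)
                if r.startswith("promoter:") and chrom_of_region[r] == "chrX"
            ]
            _, p = rank_sum_compare(
                a_fl.loc[shared], a_db.loc[shared], paired=True, alternative="greater"
            )
            paired[mark] = {"n": len(shared), "p_fl_greater": p}
        report["promoter_fl_vs_dbc_paired"] = paired

    # thresholds from dBC autosomal promoter accumulation; classify chrX promoters
    threshold_gt = "dBC" if "dBC" in genotypes else genotypes[0]
    thresholds: dict = {}
    for mark in MARKS:
        accum = chip_out[threshold_gt][mark]["accumulation"]["accum_mean"]
        auto_prom = [
            r
            for r in accum.index
            if r.startswith("promoter:") and chrom_of_region[r] != "chrX"
        ]
        thresholds[mark] = accumulation_threshold(accum.loc[auto_prom])
    if config.thresholds_override:
        thresholds.update(config.thresholds_override)
    report["thresholds"] = thresholds

    def _prom_accum_frame(gt: str) -> pd.DataFrame:
        frames = {}
        for mark in MARKS:
            accum = chip_out[gt][mark]["accumulation"]["accum_mean"]
            prom = {
                ann.promoters.gene_names[r]: accum.loc[r]
                for r in accum.index
                if r.startswith("promoter:") and chrom_of_region[r] == "chrX"
            }
            frames[mark] = pd.Series(prom)
        return pd.DataFrame(frames).dropna()

    prom_accum = {gt: _prom_accum_frame(gt) for gt in ("FL", threshold_gt) if gt in genotypes}
    classification = classify_promoters(prom_accum[threshold_gt], thresholds)
    report["promoter_categories"] = (
        classification["combined"].value_counts().to_dict()
    )

    # integration with RNA silencing
    chrx_genes = {g.gene_name for g in ann.genes if g.chrom == "chrX"}
    rna_logfc = {
        gt: rna_out[gt]["logfc"].loc[
            [g for g in rna_out["expressed"] if g in chrx_genes]
        ]
        for gt in genotypes
        if gt in ("FL", threshold_gt)
    }
    cpg = cpg_metrics(ann.promoter_seqs)
    integration = integrate_silencing_accumulation(
        rna_logfc, prom_accum, classification, cpg
    )
    report["integration"] = {
        "n_genes": integration["n_genes"],
        "category_vs_logfc_p": integration["category_vs_logfc_p"],
        "cpg": integration.get("cpg"),
        "by_category": integration["by_category"],
        "by_silencing_bin": integration["by_silencing_bin"],
    }

    # corrected-logFC truth recovery per genotype
    report["rna"] = {
        "n_expressed": rna_out["n_expressed"],
        "recovery": {gt: _recovery(dataset, rna_out, gt) for gt in genotypes},
    }

    # ChIRP-MS
    table = chirp_mod.add_fold_enrichments(dataset.peptides)
    detected = chirp_mod.detect_interactors(table, min_fc=config.chirp_min_fc)
    classified = chirp_mod.classify_interactors(detected)
    truth_cat = dataset.truth.peptide_categories
    merged = classified.merge(
        truth_cat.rename("true_category"), left_on="protein_id", right_index=True
    )
    eval_rows = merged[merged["true_category"].isin(["lost", "retained"])]
    recovery = (
        float((eval_rows["category"] == eval_rows["true_category"]).mean())
        if len(eval_rows)
        else float("nan")
    )
    ref_ids = table.loc[table["in_reference"], "protein_id"].tolist()
    report["chirp"] = {
        "n_detected": int(len(detected)),
        "categories": classified["category"].value_counts().to_dict(),
        "lost_retained_label_recovery": recovery,
        "reference_summary": chirp_mod.compare_reference_list(
            classified,
            ref_ids,
            top_n=config.chirp_top_n,
            min_annotation_score=config.chirp_min_annotation_score,
        ),
    }

    report = _jsonable(report)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
        for gt in genotypes:
            for mark in MARKS:
                chip_out[gt][mark]["accumulation"].to_csv(
                    outdir / f"accumulation_{gt}_{mark}.tsv", sep="\t"
                )
        classification.to_csv(outdir / "promoter_classification.tsv", sep="\t")
    return report


def run_user_pipeline(config: PipelineConfig) -> dict:
    """Differential analysis (and optional ChIRP scoring) on user tables."""
    report: dict = {"config_hash": config.config_hash(), "stages": []}
    if config.counts_path:
        if not config.sample_sheet_path:
            raise ValueError("sample_sheet_path required with counts_path")
        counts = CountMatrix.from_tsv(config.counts_path)
        samples = read_sample_sheet(config.sample_sheet_path)
        by_id = {s.sample_id: s for s in samples}
        missing = [sid for sid in counts.sample_ids if sid not in by_id]
        if missing:
            raise ValueError(
                f"sample sheet missing entries for count columns: {missing}"
            )
        if config.model == "induction":
            bad = [
                s.sample_id
                for s in samples
                if s.condition == "DOX" and s.induction_fraction == 0.0
            ]
            if bad:
                raise ValueError(
                    f"DOX samples without induction_fraction: {bad}"
                )
        dm = DifferentialModel(counts, samples, model=config.model)
        res = dm.fit()
        report["stages"].append("differential")
        report["differential"] = {
            "model": config.model,
            "n_features": int(len(res.table)),
            "mean_effect": float(res.effect.mean()),
        }
        if config.outdir:
            outdir = Path(config.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            res.table.to_csv(outdir / "differential_results.tsv", sep="\t")
    if config.peptide_table_path:
        table = chirp_mod.read_peptide_table(config.peptide_table_path)
        classified = chirp_mod.classify_interactors(
            chirp_mod.detect_interactors(
                chirp_mod.add_fold_enrichments(table), min_fc=config.chirp_min_fc
            )
        )
        report["stages"].append("chirp")
        report["chirp"] = {
            "n_detected": int(len(classified)),
            "categories": classified["category"].value_counts().to_dict(),
        }
        if config.outdir:
            outdir = Path(config.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            classified.to_csv(outdir / "interactome.tsv", sep="\t", index=False)
    report = _jsonable(report)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
    return report
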