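"""Synthetic cell-mixture datasets for the Xist induction analysis.

The generator emulates the statistical structure the pipeline assumes: a
bulk population in which only a fraction ``f`` of cells responds to DOX
induction. In induced cells, chrX genes are silenced by gene-specific
log2 effects ``beta_g`` and chrX regions gain Polycomb-mark signal by
genotype/mark/region-class-specific factors ``gamma``; the bulk signal is
the mixture ``f*gamma + (1-f)`` (or ``f*2**beta + (1-f)`` for expression).
Counts are negative binomial with variance ``mu + phi*mu**2``.

Three genotypes are modelled with study-default induction fractions and
effects: FL (full silencing and deposition), dA (A-repeat deletion: no
silencing, no deposition) and dBC (B+C-repeat deletion: silencing close to
FL, no intergenic deposition, and promoter deposition restricted to
high-CpG silenced genes — the passive-recruitment scenario).

Each operation draws from its own rng stream derived from (seed, stream
id), so adding operations never perturbs earlier draws; identical
(config, seed) give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate
from .chipquant import CountMatrix, SampleInfo
from .genome import ActiveGeneSpan, GenomicInterval, RegionSet, TranscriptModel

__all__ = [
    "SimulationConfig",
    "SyntheticAnnotation",
    "SyntheticTruth",
    "SyntheticDataset",
    "mixture_silencing_factor",
    "simulate_annotation",
    "simulate_chip_counts",
    "simulate_rna_counts",
    "simulate_peptide_table",
    "simulate_mixture_counts",
    "simulate_dataset",
]

MARKS = ("H3K27me3", "H2AK119ub")

# rng stream ids: one per operation
_STREAM_ANNOT = 1
_STREAM_BETA = 2
_STREAM_CHIP = 3
_STREAM_RNA = 4
_STREAM_PEPTIDE = 5


@dataclass
class SimulationConfig:
    """Generating conditions for the synthetic study.

    Induction fractions default to the study's RNA-FISH measurements for
    the ChIP clones (FL 46.64 % / 59.44 %, dBC 66.30 % / 56.29 %) and the
    RNA-seq dA clones (53.2 % / 54.5 %). Silencing effects are
    Normal(mu, sigma) clipped at 0 (no up-regulation), with FL mu = −2.0,
    dBC mu = −1.7 and dA fixed at 0. Deposition gains gamma apply to
    induced cells on chrX only; in dBC, promoter gain applies only to
    high-CpG silenced genes.
    """

    # genome
    n_autosomes: int = 4
    autosome_length: int = 10_000_000
    chrx_length: int = 10_000_000
    n_genes: int = 300
    chrx_gene_fraction: float = 0.25
    active_gene_fraction: float = 0.7
    gene_length_range: tuple[int, int] = (8_000, 40_000)
    window_bp: int = 10_000
    promoter_flank_bp: int = 2_000

    # induction fractions (clone1, clone2) per genotype
    induction_fractions: dict = field(
        default_factory=lambda: {
            "FL": (0.4664, 0.5944),
            "dBC": (0.6630, 0.5629),
            "dA": (0.532, 0.545),
        }
    )
    # silencing effect distribution (mu, sigma) per genotype; beta clipped at 0
    silencing: dict = field(
        default_factory=lambda: {
            "FL": (-2.0, 0.5),
            "dBC": (-1.7, 0.5),
            "dA": (0.0, 0.0),
        }
    )
    silenced_beta_max: float = -0.5  # genes at or below count as silenced
    # deposition gains gamma >= 1 in induced cells, chrX only:
    # genotype -> mark -> region class -> gamma
    deposition: dict = field(
        default_factory=lambda: {
            "FL": {
                "H3K27me3": {
                    "intergenic": 6.0,
                    "active_promoter": 8.0,
                    "active_gene_body": 4.0,
                },
                "H2AK119ub": {
                    "intergenic": 5.0,
                    "active_promoter": 6.0,
                    "active_gene_body": 3.0,
                },
            },
            "dBC": {
                "H3K27me3": {
                    "intergenic": 1.0,
                    "active_promoter": 1.0,
                    "active_gene_body": 1.0,
                },
                "H2AK119ub": {
                    "intergenic": 1.0,
                    "active_promoter": 1.0,
                    "active_gene_body": 1.0,
                },
            },
            "dA": {
                "H3K27me3": {
                    "intergenic": 1.0,
                    "active_promoter": 1.0,
                    "active_gene_body": 1.0,
                },
                "H2AK119ub": {
                    "intergenic": 1.0,
                    "active_promoter": 1.0,
                    "active_gene_body": 1.0,
                },
            },
        }
    )
    # dBC passive recruitment: promoter gain for high-CpG silenced genes
    dbc_cpg_promoter_gain: float = 3.0

    # counts
    nb_dispersion: float = 0.05
    mean_window_count: float = 100.0
    baseline_sdlog: float = 0.4
    class_baseline: dict = field(
        default_factory=lambda: {
            "anchor": 8.0,
            "intergenic": 1.0,
            "active_promoter": 2.0,
            "active_gene_body": 1.5,
        }
    )
    clone_library_factors: tuple[float, float] = (1.0, 1.35)
    n_anchor_windows: int = 150
    outlier_window_fraction: float = 0.015
    outlier_multiplier: float = 12.0
    mean_gene_count: float = 500.0
    gene_baseline_sdlog: float = 0.8

    # promoter CpG structure
    cpg_high_fraction: float = 0.5
    gc_content_high: float = 0.6
    gc_content_low: float = 0.4

    # ChIRP-MS peptide table
    n_proteins: int = 200
    peptide_category_fractions: dict = field(
        default_factory=lambda: {
            "retained": 0.15,
            "underrepresented": 0.10,
            "lost": 0.05,
            "background": 0.70,
        }
    )
    peptide_means: dict = field(
        default_factory=lambda: {
            # (FL_noDOX, FL_DOX, dBC_DOX) Poisson means per category
            "retained": (2.0, 20.0, 40.0),
            "underrepresented": (2.0, 30.0, 10.0),
            "lost": (0.5, 20.0, 0.0),
            "background": (5.0, 6.0, 6.0),
        }
    )

    def validate(self) -> None:
        for gt, fr in self.induction_fractions.items():
            if not all(0 < f <= 1 for f in fr):
                raise ValueError(f"{gt}: induction fractions must be in (0, 1]")
        for gt, marks in self.deposition.items():
            for mark, classes in marks.items():
                for cls, g in classes.items():
                    if g < 1:
                        raise ValueError(
                            f"deposition gain {gt}/{mark}/{cls} = {g} < 1"
                        )
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.chrx_gene_fraction <= 1:
            raise ValueError("chrx_gene_fraction must be in [0, 1]")

    def chrom_sizes(self) -> dict[str, int]:
        sizes = {f"chr{i + 1}": self.autosome_length for i in range(self.n_autosomes)}
        sizes["chrX"] = self.chrx_length
        return sizes


@dataclass
class SyntheticAnnotation:
    """Gene models, region sets and promoter sequences of the toy genome."""

    chrom_sizes: dict[str, int]
    transcripts: list[TranscriptModel]
    h3k27ac_peaks: list[GenomicInterval]
    genes: list[ActiveGeneSpan]
    promoters: RegionSet
    gene_bodies: RegionSet
    intergenic: RegionSet
    anchors: RegionSet
    peak_sets: list[list[GenomicInterval]]
    promoter_seqs: list[tuple[str, str]]
    cpg_class: pd.Series  # per active gene: "high" | "low"
    beta: dict[str, pd.Series]  # genotype -> per-gene silencing effect

    def analysis_regions(self) -> RegionSet:
        """Promoters + gene bodies + intergenic windows, one combined set."""
        combined = RegionSet(region_class="fixed_window")
        for part in (self.intergenic, self.promoters, self.gene_bodies):
            for rid, iv in part:
                combined.add(rid, iv, part.gene_names.get(rid))
        return combined

    def region_class_of(self) -> dict[str, str]:
        out = {}
        for part in (self.intergenic, self.promoters, self.gene_bodies, self.anchors):
            cls = "anchor" if part is self.anchors else part.region_class
            for rid, _ in part:
                out[rid] = cls
        return out


@dataclass
class SyntheticTruth:
    """Generating parameters, for recovery tests against pipeline estimates."""

    beta: dict[str, pd.Series]
    induction_fractions: dict[str, tuple[float, float]]
    cpg_class: pd.Series
    expected_gain: dict  # (genotype, mark) -> DataFrame regions x samples
    outlier_regions: list[str]
    peptide_categories: pd.Series


@dataclass
class SyntheticDataset:
    annotation: SyntheticAnnotation
    chip: dict  # genotype -> mark -> (CountMatrix, [SampleInfo])
    rna: dict  # genotype -> (CountMatrix, [SampleInfo])
    peptides: pd.DataFrame
    truth: SyntheticTruth


def mixture_silencing_factor(f: float, beta: float) -> float:
    """Bulk signal ratio when a fraction f of cells multiplies signal by 2**beta."""
    if not 0 <= f <= 1:
        raise ValueError("induction fraction must be in [0, 1]")
    return f * 2.0**beta + (1.0 - f)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_annotation(config: SimulationConfig, seed: int) -> SyntheticAnnotation:
    """Place genes, assign activity and CpG classes, build region sets.

    Genes are placed in equal slots along each chromosome (deterministic
    non-overlap); chrX receives exactly round(n_genes * chrx_gene_fraction)
    genes. H3K27ac peaks (TSS ± 500 bp) mark the initially active genes, so
    the activity flags downstream are derived by the annotate module, not
    asserted.
    """
    config.validate()
    rng = _rng(seed, _STREAM_ANNOT)
    sizes = config.chrom_sizes()

    n_x = int(round(config.n_genes * config.chrx_gene_fraction))
    n_auto = config.n_genes - n_x
    per_chrom: dict[str, int] = {}
    for i in range(config.n_autosomes):
        per_chrom[f"chr{i + 1}"] = n_auto // config.n_autosomes + (
            1 if i < n_auto % config.n_autosomes else 0
        )
    per_chrom["chrX"] = n_x

    transcripts: list[TranscriptModel] = []
    peaks: list[GenomicInterval] = []
    active_flags: dict[str, bool] = {}
    gene_idx = 0
    margin = config.promoter_flank_bp + 1000
    for chrom in sorted(per_chrom):
        n_c = per_chrom[chrom]
        if n_c == 0:
            continue
        slot = sizes[chrom] // n_c
        lmin, lmax = config.gene_length_range
        if slot < lmin + 2 * margin:
            raise ValueError(
                f"{chrom}: slot of {slot} bp cannot hold a gene of >= {lmin} bp "
                "with promoter margins; use a larger genome or fewer genes"
            )
        n_active = int(round(config.active_gene_fraction * n_c))
        active_set = set(rng.choice(n_c, size=n_active, replace=False).tolist())
        for k in range(n_c):
            length = int(rng.integers(lmin, min(lmax, slot - 2 * margin) + 1))
            start = int(
                k * slot + rng.integers(margin, slot - length - margin + 1)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene{gene_idx:04d}"
            tm = TranscriptModel(
                gene_name=name,
                tx_name=f"{name}.t1",
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=start + length,
                exon_starts=(start,),
                exon_ends=(start + length,),
            )
            transcripts.append(tm)
            if k in active_set:
                peaks.append(
                    GenomicInterval(
                        chrom, max(0, tm.tss - 500), min(sizes[chrom], tm.tss + 500)
                    )
                )
                active_flags[name] = True
            gene_idx += 1

    genes = annotate.define_initially_active_genes(transcripts, peaks)
    promoters = annotate.build_promoters(genes, sizes, config.promoter_flank_bp)
    gene_bodies = annotate.build_gene_bodies(genes, config.promoter_flank_bp)
    intergenic = annotate.build_intergenic_windows(
        genes, peaks, sizes, config.window_bp, config.promoter_flank_bp
    )

    # anchor windows: autosomal consensus-peak surrogates carved out of the
    # intergenic tiling, with replicate noDOX peak sets jittered around them
    auto_ids = [
        rid for rid, iv in intergenic if iv.chrom != "chrX"
    ]
    n_anchor = min(config.n_anchor_windows, len(auto_ids))
    anchor_ids = set(
        rng.choice(len(auto_ids), size=n_anchor, replace=False).tolist()
    )
    anchors = RegionSet(region_class="fixed_window")
    keep_intergenic = RegionSet(region_class="intergenic")
    auto_pos = {rid: i for i, rid in enumerate(auto_ids)}
    for rid, iv in intergenic:
        if rid in auto_pos and auto_pos[rid] in anchor_ids:
            anchors.add(f"anchor:{iv.chrom}:{iv.start}", iv)
        else:
            keep_intergenic.add(rid, iv)
    peak_sets: list[list[GenomicInterval]] = []
    for _ in range(4):
        one: list[GenomicInterval] = []
        for _, iv in anchors:
            if rng.random() < 0.9:
                j1 = int(rng.integers(-500, 501))
                j2 = int(rng.integers(-500, 501))
                s = max(0, iv.start + j1)
                e = min(sizes[iv.chrom], iv.end + j2)
                if s < e:
                    one.append(GenomicInterval(iv.chrom, s, e))
        peak_sets.append(one)

    # promoter sequences with a two-component CpG structure
    active_genes = [g for g in genes if g.is_active]
    cpg_class = pd.Series(
        np.where(
            rng.random(len(active_genes)) < config.cpg_high_fraction, "high", "low"
        ),
        index=[g.gene_name for g in active_genes],
        name="cpg_class",
    )
    promoter_seqs: list[tuple[str, str]] = []
    width = 2 * config.promoter_flank_bp
    bases = np.array(list("ACGT"))
    for g in active_genes:
        gc = (
            config.gc_content_high
            if cpg_class.loc[g.gene_name] == "high"
            else config.gc_content_low
        )
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(bases[rng.choice(4, size=width, p=p)])
        promoter_seqs.append((g.gene_name, seq))

    # genotype-specific silencing effects (chrX genes only)
    brng = _rng(seed, _STREAM_BETA)
    beta: dict[str, pd.Series] = {}
    gene_names = [g.gene_name for g in genes]
    on_x = np.array([g.chrom == "chrX" for g in genes])
    for gt in sorted(config.silencing):
        mu, sigma = config.silencing[gt]
        vals = np.zeros(len(genes))
        if sigma > 0:
            draw = brng.normal(mu, sigma, size=int(on_x.sum()))
            vals[on_x] = np.minimum(draw, 0.0)
        else:
            vals[on_x] = min(mu, 0.0)
        beta[gt] = pd.Series(vals, index=gene_names, name=f"beta_{gt}")

    return SyntheticAnnotation(
        chrom_sizes=sizes,
        transcripts=transcripts,
        h3k27ac_peaks=peaks,
        genes=genes,
        promoters=promoters,
        gene_bodies=gene_bodies,
        intergenic=keep_intergenic,
        anchors=anchors,
        peak_sets=peak_sets,
        promoter_seqs=promoter_seqs,
        cpg_class=cpg_class,
        beta=beta,
    )


def _chip_gain(
    config: SimulationConfig,
    annotation: SyntheticAnnotation,
    genotype: str,
    mark: str,
    region_ids: Sequence[str],
    intervals: Sequence[GenomicInterval],
    classes: Mapping[str, str],
    f: float,
) -> np.ndarray:
    """Bulk mixture gain f*gamma + (1-f) per region for one DOX sample."""
    gains = np.ones(len(region_ids))
    dep = config.deposition[genotype][mark]
    beta = annotation.beta[genotype]
    for i, (rid, iv) in enumerate(zip(region_ids, intervals)):
        if iv.chrom != "chrX":
            continue
        cls = classes[rid]
        gamma = dep.get(cls, 1.0)
        if (
            genotype == "dBC"
            and cls == "active_promoter"
        ):
            gene = rid.split(":", 1)[1]
            silenced = beta.get(gene, 0.0) <= config.silenced_beta_max
            high_cpg = annotation.cpg_class.get(gene, "low") == "high"
            if silenced and high_cpg:
                gamma = max(gamma, config.dbc_cpg_promoter_gain)
        gains[i] = f * gamma + (1.0 - f)
    return gains


def simulate_chip_counts(
    config: SimulationConfig,
    annotation: SyntheticAnnotation,
    genotype: str,
    seed: int,
) -> dict[str, tuple[CountMatrix, list[SampleInfo]]]:
    """NB window counts per mark (plus matched input) for one genotype.

    The counted universe is anchors + intergenic + promoters + gene bodies.
    Baselines are log-normal per region with class-specific scale; a small
    set of regions carries an accessibility-artifact multiplier shared by
    the marks and the input (these are what the input outlier filter should
    remove). Returns a dict also containing the expected mixture gain
    matrices under key ``"_expected_gain"``.
    """
    gt_index = sorted(config.induction_fractions).index(genotype)
    rng = _rng(seed, _STREAM_CHIP, gt_index)
    classes = annotation.region_class_of()
    universe: list[tuple[str, GenomicInterval]] = []
    for part in (
        annotation.anchors,
        annotation.intergenic,
        annotation.promoters,
        annotation.gene_bodies,
    ):
        universe.extend(list(part))
    rids = [rid for rid, _ in universe]
    ivs = [iv for _, iv in universe]

    # per-region baseline, shared across marks and input for this genotype
    base = np.exp(rng.normal(0.0, config.baseline_sdlog, size=len(rids)))
    base *= np.array([config.class_baseline[classes[r]] for r in rids])
    n_out = int(round(config.outlier_window_fraction * len(rids)))
    out_idx = rng.choice(len(rids), size=n_out, replace=False)
    base[out_idx] *= config.outlier_multiplier
    outlier_regions = [rids[i] for i in out_idx]

    f1, f2 = config.induction_fractions[genotype]
    conditions = [("c1", "noDOX", 0.0), ("c1", "DOX", f1), ("c2", "noDOX", 0.0), ("c2", "DOX", f2)]
    out: dict = {"_outlier_regions": outlier_regions, "_expected_gain": {}}
    for mark in MARKS:
        counts = np.zeros((len(rids), 4), dtype=np.int64)
        gains = np.ones((len(rids), 4))
        sample_infos = []
        sample_ids = []
        for j, (clone, cond, f) in enumerate(conditions):
            lf = config.clone_library_factors[0 if clone == "c1" else 1]
            lf *= float(np.exp(rng.normal(0.0, 0.05)))
            mean = config.mean_window_count * lf * base
            if cond == "DOX":
                gains[:, j] = _chip_gain(
                    config, annotation, genotype, mark, rids, ivs, classes, f
                )
                mean = mean * gains[:, j]
            counts[:, j] = _nb_draw(rng, mean, config.nb_dispersion)
            sid = f"{genotype}_{mark}_{clone}_{cond}"
            sample_ids.append(sid)
            sample_infos.append(
                SampleInfo(sid, clone, cond, mark, f, genotype)
            )
        out[mark] = (CountMatrix(rids, sample_ids, counts), sample_infos)
        out["_expected_gain"][mark] = pd.DataFrame(
            gains, index=rids, columns=sample_ids
        )

    # matched input: one per clone, no induction effect
    counts = np.zeros((len(rids), 2), dtype=np.int64)
    infos = []
    ids = []
    for j, clone in enumerate(("c1", "c2")):
        lf = config.clone_library_factors[j] * float(np.exp(rng.normal(0.0, 0.05)))
        counts[:, j] = _nb_draw(
            rng, config.mean_window_count * lf * base, config.nb_dispersion
        )
        sid = f"{genotype}_input_{clone}"
        ids.append(sid)
        infos.append(SampleInfo(sid, clone, "noDOX", "input", 0.0, genotype))
    out["input"] = (CountMatrix(rids, ids, counts), infos)
    return out


def simulate_rna_counts(
    config: SimulationConfig,
    annotation: SyntheticAnnotation,
    genotype: str,
    seed: int,
) -> tuple[CountMatrix, list[SampleInfo]]:
    """NB gene counts for two clones x (noDOX, DOX) of one genotype.

    DOX means are scaled by the mixture factor f*2**beta_g + (1-f);
    beta_g = 0 for autosomal genes.
    """
    gt_index = sorted(config.induction_fractions).index(genotype)
    rng = _rng(seed, _STREAM_RNA, gt_index)
    genes = [g.gene_name for g in annotation.genes]
    beta = annotation.beta[genotype].loc[genes].to_numpy()
    e_g = config.mean_gene_count * np.exp(
        rng.normal(0.0, config.gene_baseline_sdlog, size=len(genes))
    )
    f1, f2 = config.induction_fractions[genotype]
    conditions = [("c1", "noDOX", 0.0), ("c1", "DOX", f1), ("c2", "noDOX", 0.0), ("c2", "DOX", f2)]
    counts = np.zeros((len(genes), 4), dtype=np.int64)
    infos = []
    ids = []
    for j, (clone, cond, f) in enumerate(conditions):
        lf = config.clone_library_factors[0 if clone == "c1" else 1]
        lf *= float(np.exp(rng.normal(0.0, 0.05)))
        m = np.array([mixture_silencing_factor(f, b) for b in beta]) if f > 0 else 1.0
        counts[:, j] = _nb_draw(rng, e_g * lf * m, config.nb_dispersion)
        sid = f"{genotype}_RNA_{clone}_{cond}"
        ids.append(sid)
        infos.append(SampleInfo(sid, clone, cond, "RNA", f, genotype))
    return CountMatrix(genes, ids, counts), infos


def simulate_peptide_table(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Poisson peptide-count table with known interactor categories.

    Returns (table, truth categories). Reference-list flags are set for the
    non-background categories plus a sprinkle of background proteins;
    annotation scores are 3–5 for true interactors and 1–5 for background.
    """
    rng = _rng(seed, _STREAM_PEPTIDE)
    fracs = config.peptide_category_fractions
    cats: list[str] = []
    for cat in ("retained", "underrepresented", "lost"):
        cats.extend([cat] * int(round(fracs[cat] * config.n_proteins)))
    cats.extend(["background"] * (config.n_proteins - len(cats)))
    rows = []
    for i, cat in enumerate(cats):
        lam = config.peptide_means[cat]
        nod = int(rng.poisson(lam[0]))
        fld = int(rng.poisson(lam[1]))
        dbc = int(rng.poisson(lam[2]))
        if cat == "background":
            score = int(rng.integers(1, 6))
            in_ref = bool(rng.random() < 0.02)
        else:
            score = int(rng.integers(3, 6))
            in_ref = True
        rows.append((f"P{i:04d}", score, nod, fld, dbc, in_ref))
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "annotation_score",
            "FL_noDOX",
            "FL_DOX",
            "dBC_DOX",
            "in_reference",
        ],
    )
    truth = pd.Series(cats, index=table["protein_id"], name="category")
    return table, truth


def simulate_mixture_counts(
    n_features: int,
    beta: float,
    induction_fractions: Sequence[float],
    mean_count: float = 200.0,
    baseline_sdlog: float = 0.5,
    phi: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, list[SampleInfo]]:
    """Minimal mixture experiment: one effect, two clones, four samples.

    chrX-like windows with a common log2 effect ``beta`` applied in a
    fraction f_c of cells for each clone's DOX sample; used for slope
    recovery experiments without a full genome.
    """
    rng = _rng(seed, 6)
    base = mean_count * np.exp(rng.normal(0.0, baseline_sdlog, size=n_features))
    f1, f2 = induction_fractions
    conditions = [("c1", "noDOX", 0.0), ("c1", "DOX", f1), ("c2", "noDOX", 0.0), ("c2", "DOX", f2)]
    counts = np.zeros((n_features, 4), dtype=np.int64)
    ids, infos = [], []
    for j, (clone, cond, f) in enumerate(conditions):
        m = mixture_silencing_factor(f, beta) if f > 0 else 1.0
        counts[:, j] = _nb_draw(rng, base * m, phi)
        sid = f"mix_{clone}_{cond}"
        ids.append(sid)
        infos.append(SampleInfo(sid, clone, cond, "H3K27me3", f))
    lib = np.full(4, counts.mean() * n_features)  # equal libraries by design
    return CountMatrix([f"w{i}" for i in range(n_features)], ids, counts, lib), infos


def simulate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Full synthetic study: annotation, ChIP and RNA counts, peptide table."""
    annotation = simulate_annotation(config, seed)
    chip: dict = {}
    expected_gain: dict = {}
    outliers: list[str] = []
    for gt in sorted(config.induction_fractions):
        res = simulate_chip_counts(config, annotation, gt, seed)
        chip[gt] = {m: res[m] for m in (*MARKS, "input")}
        for m in MARKS:
            expected_gain[(gt, m)] = res["_expected_gain"][m]
        outliers = sorted(set(outliers) | set(res["_outlier_regions"]))
    rna = {
        gt: simulate_rna_counts(config, annotation, gt, seed)
        for gt in sorted(config.induction_fractions)
    }
    peptides, pep_truth = simulate_peptide_table(config, seed)
    truth = SyntheticTruth(
        beta=annotation.beta,
        induction_fractions={
            gt: tuple(v) for gt, v in config.induction_fractions.items()
        },
        cpg_class=annotation.cpg_class,
        expected_gain=expected_gain,
        outlier_regions=outliers,
        peptide_categories=pep_truth,
    )
    return SyntheticDataset(
        annotation=annotation, chip=chip, rna=rna, peptides=peptides, truth=truth
    )
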