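"""ChIRP-MS differential interactome scoring.

Peptide-count tables from Xist ChIRP-MS (columns: FL_noDOX control, FL_DOX
and dBC_DOX pull-downs) are scored by DOX/noDOX fold enrichment with a
zero-control rule (a zero noDOX count is treated as 1), filtered by UniProt
annotation score, ranked, and classified against a reference interactor
list (e.g. the 81-protein Chu et al. Xist interactome):

* **lost** — no dBC_DOX peptides (or exactly the control count) while the
  FL enrichment is >= 4: the protein left the ΔB+C interactome;
* **underrepresented** — detected in ΔB+C but with lower fold enrichment
  than in FL;
* **retained** — everything else among detected interactors.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "fold_enrichment",
    "add_fold_enrichments",
    "rank_hits",
    "detect_interactors",
    "classify_interactors",
    "compare_reference_list",
    "read_peptide_table",
]

REQUIRED_COLUMNS = ("protein_id", "annotation_score", "FL_noDOX", "FL_DOX", "dBC_DOX")


def fold_enrichment(dox_count: float, nodox_count: float) -> float:
    """DOX/noDOX peptide-count ratio; a zero noDOX count is treated as 1."""
    if dox_count < 0 or nodox_count < 0:
        raise ValueError("peptide counts must be non-negative")
    return dox_count / max(nodox_count, 1)


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    if "in_reference" not in df.columns:
        df["in_reference"] = False
    df["in_reference"] = df["in_reference"].astype(bool)
    return df


def add_fold_enrichments(records: pd.DataFrame) -> pd.DataFrame:
    """Append fe_FL and fe_dBC columns (zero-control rule applied)."""
    df = records.copy()
    if (df[["FL_noDOX", "FL_DOX", "dBC_DOX"]].to_numpy() < 0).any():
        raise ValueError("peptide counts must be non-negative")
    denom = df["FL_noDOX"].clip(lower=1)
    df["fe_FL"] = df["FL_DOX"] / denom
    df["fe_dBC"] = df["dBC_DOX"] / denom
    return df


def rank_hits(records: pd.DataFrame, min_annotation_score: int = 3) -> pd.DataFrame:
    """Drop weakly annotated isoforms and rank by FL fold enrichment.

    Ties break by descending FL_DOX count, then protein_id.
    """
    if len(records) == 0:
        raise ValueError("empty peptide table")
    df = records if "fe_FL" in records.columns else add_fold_enrichments(records)
    df = df[df["annotation_score"] >= min_annotation_score].copy()
    if len(df) == 0:
        warnings.warn("no records left after annotation-score filter", RuntimeWarning)
        return df
    df = df.sort_values(
        ["fe_FL", "FL_DOX", "protein_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def detect_interactors(records: pd.DataFrame, min_fc: float = 2.5) -> pd.DataFrame:
    """Records with fold enrichment >= min_fc in at least one pull-down."""
    df = records if "fe_FL" in records.columns else add_fold_enrichments(records)
    return df[(df["fe_FL"] >= min_fc) | (df["fe_dBC"] >= min_fc)].copy()


def classify_interactors(records: pd.DataFrame) -> pd.DataFrame:
    """Assign lost / underrepresented / retained categories.

    lost: (dBC_DOX == 0 or dBC_DOX == FL_noDOX) and fe_FL >= 4;
    else underrepresented iff fe_dBC < fe_FL; else retained.
    Categories are mutually exclusive and exhaustive.
    """
    df = records if "fe_FL" in records.columns else add_fold_enrichments(records)
    df = df.copy()
    lost = ((df["dBC_DOX"] == 0) | (df["dBC_DOX"] == df["FL_noDOX"])) & (
        df["fe_FL"] >= 4
    )
    under = ~lost & (df["fe_dBC"] < df["fe_FL"])
    df["category"] = np.where(lost, "lost", np.where(under, "underrepresented", "retained"))
    return df


def compare_reference_list(
    results: pd.DataFrame,
    reference_ids: Sequence[str],
    top_n: int = 20,
    min_annotation_score: int = 3,
) -> dict:
    """Category counts among reference interactors and top-N overlap."""
    if len(reference_ids) == 0:
        raise ValueError("reference_ids must be non-empty")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if "category" not in results.columns:
        results = classify_interactors(results)
    ref = set(reference_ids)
    in_ref = results[results["protein_id"].isin(ref)]
    counts = in_ref["category"].value_counts().to_dict()
    ranked = rank_hits(results, min_annotation_score=min_annotation_score)
    top = ranked.head(top_n)["protein_id"]
    return {
        "n_reference_detected": int(len(in_ref)),
        "retained": int(counts.get("retained", 0)),
        "underrepresented": int(counts.get("underrepresented", 0)),
        "lost": int(counts.get("lost", 0)),
        "top_n": int(top_n),
        "top_n_in_reference": int(top.isin(ref).sum()),
    }
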