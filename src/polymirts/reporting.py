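"""Tabular output, summary tallies and small report arithmetic.

The hits table carries the reference column set (ID, rs#, miRNA, targeted
allele, ΔScore, ΔMFE) plus extension columns (region, seed flag, regulation
class, per-allele Score/MFE, transcript).  Summaries tally hits per transcript
region, per regulation class and per-SNP miRNA multiplicity.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import pandas as pd

from .differential_pipeline import DifferentialHit
from .errors import ValidationError
from .io_annotations import Region

HIT_COLUMNS = [
    "id",
    "rs_id",
    "mirna",
    "targeted_allele",
    "delta_score",
    "delta_mfe",
    "region",
    "snp_in_seed",
    "regulation_class",
    "high_stringency",
    "score_pref",
    "mfe_pref",
    "score_other",
    "mfe_other",
    "transcript_id",
]


def hits_to_dataframe(hits: Sequence[DifferentialHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "id": h.consequence_id or "",
                "rs_id": h.rs_id,
                "mirna": h.mirna,
                "targeted_allele": h.targeted_allele,
                "delta_score": h.delta_score,
                "delta_mfe": round(h.delta_mfe, 2),
                "region": h.region.value,
                "snp_in_seed": h.snp_in_seed,
                "regulation_class": h.regulation_class,
                "high_stringency": h.high_stringency,
                "score_pref": h.score_pref,
                "mfe_pref": round(h.mfe_pref, 2),
                "score_other": h.score_other,
                "mfe_other": round(h.mfe_other, 2),
                "transcript_id": h.transcript_id,
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits_tsv(hits: Sequence[DifferentialHit], path) -> None:
    hits_to_dataframe(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValidationError(f"cannot parse hits table {path}: {exc}") from exc
    for col in ("rs_id", "mirna"):
        if col not in df.columns:
            raise ValidationError(f"hits table {path} lacks required column {col!r}")
    return df


def _region_from_id(ident: str) -> str:
    if isinstance(ident, str):
        if ident.startswith("5'UTR"):
            return Region.FIVE_UTR.value
        if ident.startswith("3'UTR"):
            return Region.THREE_UTR.value
    return Region.CDS.value


def summarize_table(df: pd.DataFrame) -> dict:
    """Region/class tallies and per-SNP multiplicity from a hits table.

    Accepts both pipeline output and the curated reference table (region
    derived from the ID prefix when absent; regulation class from the
    targeted-allele WT/SNP tag when absent).
    """
    if df.empty:
        return {
            "n_hits": 0,
            "by_region": {r.value: 0 for r in Region},
            "region_fractions": {r.value: 0.0 for r in Region},
            "by_regulation_class": {"gain_of_regulation": 0, "loss_of_regulation": 0},
            "mirnas_per_snp": {},
        }
    work = df.copy()
    if "region" not in work.columns:
        work["region"] = work["id"].map(_region_from_id)
    if "regulation_class" not in work.columns:
        cls_source = None
        if "allele_class" in work.columns:
            cls_source = work["allele_class"]
        elif "targeted_allele" in work.columns:
            cls_source = work["targeted_allele"].str.extract(r"\((WT|SNP)\)")[0]
        if cls_source is not None:
            work["regulation_class"] = cls_source.map(
                {"SNP": "gain_of_regulation", "WT": "loss_of_regulation"}
            )
    by_region = {r.value: 0 for r in Region}
    by_region.update(work["region"].value_counts().to_dict())
    total = len(work)
    by_class = {"gain_of_regulation": 0, "loss_of_regulation": 0}
    if "regulation_class" in work.columns:
        by_class.update(work["regulation_class"].value_counts().to_dict())
    multiplicity = work.groupby("rs_id")["mirna"].nunique().to_dict()
    return {
        "n_hits": total,
        "by_region": by_region,
        "region_fractions": {k: v / total for k, v in by_region.items()},
        "by_regulation_class": by_class,
        "mirnas_per_snp": dict(sorted(multiplicity.items())),
    }


def write_summary_json(summary: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# In-table arithmetic on the reference screen tallies
# ---------------------------------------------------------------------------


def snp_region_fraction(n_transcript_snps: int, n_total_snps: int) -> float:
    """Percentage of SNPs falling in 5'UTR/CDS/3'UTR of any gene."""
    if n_total_snps <= 0:
        raise ValidationError("total SNP count must be positive")
    return 100.0 * n_transcript_snps / n_total_snps


def first_pass_total(by_region: Mapping[str, int]) -> int:
    """Total differential pairs from the per-region tallies."""
    return int(sum(by_region.values()))
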