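"""Peptide-HLA binding annotation and summarisation.

Binding strength is consumed as IC50 tables (nM; lower = stronger) produced
by external predictors.  Peptides are classified as strongly bound
(SB, IC50 <= 50 nM) or bound (BP, IC50 <= 500 nM; SB is a subset of BP),
counted per HLA allele and per class with doubling for DRB1-homozygous
pairs, joined to per-gene tissue expression (RPKM over eight GVHD target
organs), and screened for genes presented on both HLA class I and class II.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SB_THRESHOLD_NM = 50.0
BP_THRESHOLD_NM = 500.0

#: the eight GVHD target organs carried through expression annotation
TISSUES = ("skin", "lung", "salivary_gland", "esophagus",
           "small_intestine", "stomach", "colon", "liver")

#: locus prefixes identifying HLA class II alleles
_CLASS_II_MARKERS = ("DRB", "DQA", "DQB", "DPA", "DPB")


def allele_class(allele: str) -> str:
    """'I' or 'II' from an HLA allele name (DRB1/DQ/DP loci are class II)."""
    return "II" if any(m in allele.upper() for m in _CLASS_II_MARKERS) else "I"


def classify_binding(ic50) -> str | np.ndarray:
    """SB (IC50 <= 50 nM), BP (<= 500 nM), NB otherwise.

    Thresholds are inclusive; SB records are also BP by definition, but the
    label reports the strongest category.  Accepts a scalar or array.
    """
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive")
    labels = np.where(arr <= SB_THRESHOLD_NM, "SB",
                      np.where(arr <= BP_THRESHOLD_NM, "BP", "NB"))
    return labels.item() if np.isscalar(ic50) else labels


@dataclass(frozen=True)
class DrpAnnotation:
    """HLA genotype and donor-type metadata for one donor-recipient pair."""

    drp_id: str
    donor_type: str                     # "MRD" or "MUD"
    class_i_alleles: tuple[str, ...]    # six alleles (HLA-A, -B, -C x2)
    drb1_alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if self.donor_type not in ("MRD", "MUD"):
            raise ValueError(f"donor_type must be MRD or MUD, "
                             f"got {self.donor_type!r}")

    @property
    def drb1_homozygous(self) -> bool:
        return self.drb1_alleles[0] == self.drb1_alleles[1]

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self.class_i_alleles) + tuple(set(self.drb1_alleles))


# ---------------------------------------------------------------------------
# affinity table ingestion

#: column maps per dialect -> canonical (peptide, allele, ic50[, gene])
_DIALECTS = {
    "generic": {"peptide": "peptide", "allele": "allele", "ic50": "ic50",
                "gene": "gene"},
    "netmhcpan": {"Peptide": "peptide", "HLA": "allele", "Aff(nM)": "ic50",
                  "ID": "gene"},
}


def parse_affinity_table(
    path: str | Path,
    dialect: str = "generic",
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a peptide-HLA IC50 table into canonical long form.

    Returns a frame with columns ``peptide``, ``allele``, ``ic50``,
    ``b_affinity`` (= 1/IC50, nM^-1) plus any mapped passthrough columns
    (``gene``, ``snp_index`` ...).  Rows with non-positive or non-numeric
    IC50 are rejected (logged); duplicate (peptide, allele) rows keep the
    last occurrence with a warning.

    ``dialect`` selects a built-in column map ("generic" TSV or
    NetMHCpan-style long output); ``columns`` overrides it with an explicit
    {source column: canonical name} mapping.
    """
    colmap = dict(columns) if columns is not None else dict(_DIALECTS[dialect])
    df = pd.read_csv(path, sep="\t")
    present = {src: dst for src, dst in colmap.items() if src in df.columns}
    needed = {"peptide", "allele", "ic50"}
    if not needed <= set(present.values()):
        raise ValueError(
            f"affinity table {path!r} lacks required columns; found "
            f"{list(df.columns)}, need sources mapping to {sorted(needed)}")
    df = df.rename(columns=present)

    df["ic50"] = pd.to_numeric(df["ic50"], errors="coerce")
    bad = df["ic50"].isna() | (df["ic50"] <= 0)
    if bad.any():
        logger.info("rejected %d affinity rows with non-positive or "
                    "non-numeric IC50", int(bad.sum()))
        df = df[~bad]
    dup = df.duplicated(subset=["peptide", "allele"], keep="last")
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate (peptide, allele) rows; "
                      "keeping the last occurrence", stacklevel=2)
        df = df[~dup]
    df = df.reset_index(drop=True)
    df["b_affinity"] = 1.0 / df["ic50"]
    return df


# ---------------------------------------------------------------------------
# per-DRP counting

def count_sb_bp(records: pd.DataFrame, drp: DrpAnnotation) -> pd.DataFrame:
    """Count unique SB/BP peptides per allele and per HLA class for a DRP.

    Peptide uniqueness follows the dedup rule: (peptide, snp_index, gene)
    when those columns are present, otherwise the sequence alone.
    DRB1-homozygous pairs have their class II counts doubled (one physical
    allele presents on both chromosomes' worth of molecules).  Class
    totals are returned in rows with allele ``ALL``.
    """
    unknown = set(records["allele"]) - set(drp.alleles)
    if unknown:
        raise ValueError(
            f"affinity records contain alleles absent from DRP "
            f"{drp.drp_id}: {sorted(unknown)}")
    key_cols = [c for c in ("peptide", "snp_index", "gene")
                if c in records.columns]
    rows = []
    class_tot = {"I": {"SB": 0, "BP": 0}, "II": {"SB": 0, "BP": 0}}
    for allele in drp.alleles:
        sub = records[records["allele"] == allele].drop_duplicates(key_cols)
        sb = int((sub["ic50"] <= SB_THRESHOLD_NM).sum())
        bp = int((sub["ic50"] <= BP_THRESHOLD_NM).sum())
        cls = allele_class(allele)
        mult = 2 if (cls == "II" and drp.drb1_homozygous) else 1
        rows.append((drp.drp_id, allele, cls, sb * mult, bp * mult))
        class_tot[cls]["SB"] += sb * mult
        class_tot[cls]["BP"] += bp * mult
    for cls in ("I", "II"):
        rows.append((drp.drp_id, "ALL", cls,
                     class_tot[cls]["SB"], class_tot[cls]["BP"]))
    return pd.DataFrame(rows, columns=["drp_id", "allele", "hla_class",
                                       "sb", "bp"])


def min_affinity_per_gene(
    records: pd.DataFrame, hla_class: str | None = None
) -> pd.DataFrame:
    """Per-gene minimum IC50 with the arg-min allele and peptide.

    ``hla_class`` ('I' or 'II') restricts to alleles of that class; None
    uses all records.  Requires a ``gene`` column.
    """
    if "gene" not in records.columns:
        raise ValueError("records lack a 'gene' column")
    df = records
    if hla_class is not None:
        df = df[df["allele"].map(allele_class) == hla_class]
    if df.empty:
        return pd.DataFrame(columns=["gene", "min_ic50", "allele", "peptide"])
    idx = df.groupby("gene")["ic50"].idxmin()
    out = df.loc[idx, ["gene", "ic50", "allele", "peptide"]]
    out = out.rename(columns={"ic50": "min_ic50"})
    return out.sort_values("gene").reset_index(drop=True)


def dual_presentation_genes(
    class_i_records: pd.DataFrame,
    class_ii_records: pd.DataFrame,
    threshold: float = SB_THRESHOLD_NM,
) -> list[str]:
    """Genes with at least one peptide at IC50 <= threshold on each class.

    Dual presentation means tissues expressing the gene can stimulate both
    cytotoxic (class I) and helper (class II) donor T cells.
    """
    if class_i_records.empty or class_ii_records.empty:
        return []
    mins_i = min_affinity_per_gene(class_i_records)
    mins_ii = min_affinity_per_gene(class_ii_records)
    ok_i = set(mins_i.loc[mins_i["min_ic50"] <= threshold, "gene"])
    ok_ii = set(mins_ii.loc[mins_ii["min_ic50"] <= threshold, "gene"])
    return sorted(ok_i & ok_ii)


def join_tissue_expression(
    peptides: pd.DataFrame,
    expression: pd.DataFrame,
    tissues: Sequence[str] = TISSUES,
    rpkm_threshold: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Attach per-gene RPKM values to SB peptides; count organ expression.

    ``expression`` must be keyed by a ``gene`` column with one column per
    tissue.  Returns (annotated frame, per-organ expressed-SB counts where
    a peptide counts in an organ when its gene's RPKM exceeds
    ``rpkm_threshold``, number of peptides with unknown gene).  Unannotated
    peptides are excluded from the organ counts and flagged in the
    ``expression_annotated`` column.
    """
    missing_tissues = [t for t in tissues if t not in expression.columns]
    if missing_tissues:
        raise ValueError(f"expression table lacks tissues: {missing_tissues}")
    sb = peptides[peptides["ic50"] <= SB_THRESHOLD_NM].copy()
    merged = sb.merge(expression[["gene", *tissues]], on="gene", how="left")
    merged["expression_annotated"] = ~merged[list(tissues)].isna().any(axis=1)
    n_unannotated = int((~merged["expression_annotated"]).sum())
    if n_unannotated:
        logger.info("%d SB peptides from genes absent in the expression "
                    "table; excluded from organ counts", n_unannotated)
    annotated = merged[merged["expression_annotated"]]
    organ_counts = {
        t: int((annotated[t] > rpkm_threshold).sum()) for t in tissues
    }
    return merged, organ_counts, n_unannotated


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Gene x tissue RPKM TSV with a ``gene`` column."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("expression table needs a 'gene' column")
    return df
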