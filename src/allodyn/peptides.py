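"""Polymorphic peptide library construction.

Each GVH-direction nonsynonymous SNP substitutes one amino acid in a
protein.  HLA class I presents ~9-mers, so every 9-mer containing the
substituted residue is a candidate minor histocompatibility antigen: for an
interior residue these are the nine 9-mers inside the 17-mer window centred
on the substitution.  HLA class II (DRB1) presents longer peptides; a fixed
15-mer length is used, giving fifteen candidates inside a 29-mer window.

Windows at protein termini are truncated, not padded, so the emitted count
falls below 9/15 near the ends.  Peptides containing non-standard residues
(X, U, B, Z, J, O, *) are dropped with a logged count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: flank width and peptide length per HLA class
FLANK = {"I": 8, "II": 14}
PEPTIDE_LENGTH = {"I": 9, "II": 15}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PolymorphicPeptide:
    """A k-mer carrying one nsSNP-encoded residue.

    ``snp_index`` is the 1-based position of the polymorphic residue within
    the peptide; ``protein_pos`` its 1-based position in the source protein.
    """

    sequence: str
    k: int
    snp_index: int
    gene_id: str = ""
    seq_id: str = ""
    protein_pos: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != self.k:
            raise ValueError(
                f"sequence length {len(self.sequence)} != k {self.k}")
        if not (1 <= self.snp_index <= self.k):
            raise ValueError(
                f"snp_index {self.snp_index} outside 1..{self.k}")


class RefResidueMismatch(ValueError):
    """Protein residue does not match the annotated reference amino acid."""


def extract_flank_window(
    protein: str,
    aa_pos: int,
    alt_aa: str,
    flank: int,
    ref_aa: str | None = None,
    on_mismatch: str = "warn",
) -> tuple[str, int]:
    """Extract the substituted window around an amino-acid substitution.

    Returns the substring covering protein positions
    ``[aa_pos - flank, aa_pos + flank]`` (intersected with the protein, so
    terminal windows are shorter), with the residue at ``aa_pos`` replaced
    by ``alt_aa``, together with the 1-based index of the substitution
    within the window.  For an interior position the window has length
    ``2*flank + 1`` and the substitution sits at its centre.

    If ``ref_aa`` is given and disagrees with the protein, a warning is
    issued and the substitution proceeds (``on_mismatch="error"`` raises).
    """
    if not (1 <= aa_pos <= len(protein)):
        raise ValueError(
            f"aa_pos {aa_pos} outside protein of length {len(protein)}")
    if ref_aa is not None and protein[aa_pos - 1] != ref_aa:
        msg = (f"protein residue {protein[aa_pos - 1]!r} at position "
               f"{aa_pos} does not match annotated ref_aa {ref_aa!r}")
        if on_mismatch == "error":
            raise RefResidueMismatch(msg)
        warnings.warn(msg, stacklevel=2)
    start = max(1, aa_pos - flank)           # 1-based, inclusive
    end = min(len(protein), aa_pos + flank)  # 1-based, inclusive
    window = (protein[start - 1:aa_pos - 1] + alt_aa
              + protein[aa_pos:end])
    return window, aa_pos - start + 1


def slide_windows(
    window: str,
    snp_window_index: int,
    k: int,
    gene_id: str = "",
    seq_id: str = "",
    protein_pos: int = 0,
) -> list[PolymorphicPeptide]:
    """Enumerate every length-``k`` substring of ``window`` that contains
    the polymorphic residue.

    For a full ``2k - 1`` window with a central substitution this yields
    exactly ``k`` peptides, with ``snp_index`` taking each value in
    ``1..k``.  Windows shorter than ``k`` yield an empty list (warned).
    """
    n = len(window)
    if k > n:
        warnings.warn(
            f"window of length {n} shorter than peptide length {k}; "
            "no peptides emitted", stacklevel=2)
        return []
    if not (1 <= snp_window_index <= n):
        raise ValueError(
            f"snp_window_index {snp_window_index} outside window")
    peptides = []
    # 1-based start positions of k-mers containing snp_window_index
    first = max(1, snp_window_index - k + 1)
    last = min(snp_window_index, n - k + 1)
    for start in range(first, last + 1):
        peptides.append(PolymorphicPeptide(
            sequence=window[start - 1:start + k - 1],
            k=k,
            snp_index=snp_window_index - start + 1,
            gene_id=gene_id,
            seq_id=seq_id,
            protein_pos=protein_pos,
        ))
    return peptides


def dedupe_peptides(
    peptides: Iterable[PolymorphicPeptide],
) -> list[PolymorphicPeptide]:
    """Collapse records identical in (sequence, snp_index, gene).

    Identical sequences whose polymorphic residue sits at a different
    position, or that derive from a different gene, arose from different
    exomic sites and are all retained.
    """
    seen: set[tuple[str, int, str]] = set()
    out = []
    for p in peptides:
        key = (p.sequence, p.snp_index, p.gene_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA keyed by record id (gene or transcript symbol)."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def build_peptide_library(
    snps: pd.DataFrame,
    proteins: Mapping[str, str],
    hla_class: str = "I",
    k: int | None = None,
    drp_id: str = "",
) -> list[PolymorphicPeptide]:
    """Build the polymorphic peptide library for one DRP and HLA class.

    ``snps`` needs columns ``gene``, ``protein_pos``, ``ref_aa``,
    ``alt_aa`` (the schema written by :meth:`GvhSnpSet.to_tsv`).  Peptides
    containing non-standard residues are dropped; genes missing from
    ``proteins`` are skipped; both are logged.  ``seq_id`` is a zero-padded
    sequential identifier per source SNP (s00001, s00002, ...).
    """
    if hla_class not in FLANK:
        raise ValueError(f"hla_class must be 'I' or 'II', got {hla_class!r}")
    flank = FLANK[hla_class]
    k = PEPTIDE_LENGTH[hla_class] if k is None else k

    library: list[PolymorphicPeptide] = []
    n_missing_gene = 0
    n_nonstandard = 0
    for i, row in enumerate(snps.itertuples(index=False), start=1):
        gene = row.gene
        if gene not in proteins:
            n_missing_gene += 1
            continue
        seq_id = f"s{i:05d}"
        window, idx = extract_flank_window(
            proteins[gene], int(row.protein_pos), row.alt_aa, flank,
            ref_aa=row.ref_aa)
        for pep in slide_windows(window, idx, k, gene_id=gene,
                                 seq_id=seq_id,
                                 protein_pos=int(row.protein_pos)):
            if set(pep.sequence) <= STANDARD_AA:
                library.append(pep)
            else:
                n_nonstandard += 1
    if n_missing_gene:
        logger.info("%d SNPs skipped: gene absent from protein FASTA (%s)",
                    n_missing_gene, drp_id)
    if n_nonstandard:
        logger.info("%d peptides dropped for non-standard residues (%s)",
                    n_nonstandard, drp_id)
    return dedupe_peptides(library)


def peptides_to_frame(peptides: Sequence[PolymorphicPeptide]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.sequence, p.k, p.snp_index, p.gene_id, p.seq_id, p.protein_pos)
         for p in peptides],
        columns=["peptide", "k", "snp_index", "gene", "seq_id",
                 "protein_pos"])


def write_peptide_fasta(
    peptides: Sequence[PolymorphicPeptide], path: str | Path
) -> None:
    """FASTA with headers ``>{gene}|{seq_id}|snp{snp_index}``, the format
    accepted by peptide-HLA binding predictors."""
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.gene_id}|{p.seq_id}|snp{p.snp_index}\n")
            fh.write(p.sequence + "\n")
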