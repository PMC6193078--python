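"""Synthetic inputs with planted, recoverable structure.

Every format the pipeline and simulator consume can be generated here:
paired donor/recipient VCFs with a controlled number of planted GVH-direction
(R+/D-) nonsynonymous SNPs and a matching protein FASTA; log-uniform
peptide-HLA IC50 tables (binding affinities span several decades, so a
log-uniform spread over 0.1-50,000 nM is the natural null); log-normal
gene x tissue RPKM tables with optional zero inflation; clone/antigen
repertoires for the simulator; and per-pair cohort summaries whose defaults
reproduce the study conditions this package models (26 matched-related and
49 matched-unrelated pairs, a ~1.72x unrelated-donor burden multiplier, and
an SB/BP log-scale correlation of 0.9).

All generators are pure functions of their seed: the same seed yields
byte-identical files, and truth files list exactly the planted structure so
pipeline recovery can be asserted end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import TISSUES
from .simulate import AntigenParams, CloneParams
from .stats import DrpSummary

AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the generators.

    The cohort block mirrors the modelled study: 26 MRD / 49 MUD pairs,
    matched-related class II BP mean 39,584 with a 67,987/39,584 unrelated
    burden multiplier, and SB tracking BP with correlation 0.9 on the log
    scale.  IC50 tables default to log-uniform over 0.1-50,000 nM
    (log10 range -1 to 4.7); simulator repertoires draw affinities from the
    bound range 1-500 nM, since complexes weaker than the BP threshold do
    not drive clonal expansion.
    """

    n_sites: int = 100
    gvh_fraction: float = 0.3
    n_genes: int = 30
    protein_length: tuple[int, int] = (120, 400)
    ic50_log10_range: tuple[float, float] = (-1.0, 4.7)
    rpkm_meanlog: float = 2.0
    rpkm_sdlog: float = 1.5
    rpkm_zero_inflation: float = 0.0
    # cohort conditions
    n_mrd: int = 26
    n_mud: int = 49
    mrd_bp_ii_mean: float = 39_584.0
    mud_burden_multiplier: float = 67_987.0 / 39_584.0
    bp_sdlog: float = 0.5
    sb_bp_log_correlation: float = 0.9
    sb_over_bp: float = 0.15           # SB is a fraction of BP
    ratio_i_over_ii: float = 0.09      # class I / class II BP ratio median
    # simulator repertoire conditions
    repertoire_ic50_range: tuple[float, float] = (1.0, 500.0)
    carrying_capacity: float = 1000.0
    cp_rate: float = 1.0
    s2_rate: float = 1.0
    cross_reactivity: float = 0.0
    class_ii_scavenging: float = 1.0   # set < 1 for class II antigens

    def __post_init__(self) -> None:
        if not (0.0 <= self.gvh_fraction <= 1.0):
            raise ValueError("gvh_fraction must be in [0, 1]")
        for name in ("ic50_log10_range", "protein_length",
                     "repertoire_ic50_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")


def synth_proteins(
    spec: SynthSpec, seed: int
) -> dict[str, str]:
    """Random proteins over the 20 standard residues, keyed GENE0001..."""
    rng = np.random.default_rng(seed)
    out = {}
    for g in range(spec.n_genes):
        length = int(rng.integers(spec.protein_length[0],
                                  spec.protein_length[1] + 1))
        seq = "".join(rng.choice(list(AA), size=length))
        out[f"GENE{g + 1:04d}"] = seq
    return out


def write_protein_fasta(proteins: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n{seq}\n")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=PPOS,Number=1,Type=Integer,Description="Protein position">
##INFO=<ID=RAA,Number=1,Type=String,Description="Reference amino acid">
##INFO=<ID=AAA,Number=1,Type=String,Description="Alternate amino acid">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _vcf_line(pos: int, ref: str, alt: str, info: str, gt: str) -> str:
    return f"1\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\t{info}\tGT\t{gt}\n"


def synth_vcf_pair(
    spec: SynthSpec,
    outdir: str | Path,
    seed: int,
    drp_id: str = "DRP01",
) -> dict[str, Path]:
    """Write a donor/recipient VCF pair, the protein FASTA they annotate
    against, and a truth TSV of the planted GVH-direction nsSNPs.

    Exactly ``round(n_sites * gvh_fraction)`` sites are planted as
    recipient-only nonsynonymous SNPs (each with a unique gene/protein
    position); the remainder are distractors: shared variants, donor-only
    variants (the HVG direction), recipient synonymous variants, and
    shared-allele sites where the recipient is homozygous alt and the donor
    heterozygous.  Each file contains only the sites where that individual
    carries an alternate allele, as a single-sample caller would emit.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins = synth_proteins(spec, seed=int(rng.integers(2**31)))
    genes = list(proteins)

    n_planted = round(spec.n_sites * spec.gvh_fraction)
    categories = (["gvh_nssnp"] * n_planted
                  + [str(rng.choice(["shared_het", "hvg", "gvh_syn",
                                     "hom_alt_vs_het"]))
                     for _ in range(spec.n_sites - n_planted)])
    rng.shuffle(categories)

    used_protein_sites: set[tuple[str, int]] = set()
    pos = 0
    donor_lines, recipient_lines, truth_rows = [], [], []
    for cat in categories:
        pos += int(rng.integers(50, 5000))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        gene = genes[int(rng.integers(len(genes)))]
        while True:
            ppos = int(rng.integers(1, len(proteins[gene]) + 1))
            if (gene, ppos) not in used_protein_sites:
                used_protein_sites.add((gene, ppos))
                break
        ref_aa = proteins[gene][ppos - 1]
        alt_aa = str(rng.choice([a for a in AA if a != ref_aa]))
        conseq = "synonymous" if cat == "gvh_syn" else "nonsynonymous"
        if conseq == "synonymous":
            alt_aa = ref_aa
        info = (f"GENE={gene};CONSEQ={conseq};PPOS={ppos};"
                f"RAA={ref_aa};AAA={alt_aa}")
        if cat in ("gvh_nssnp", "gvh_syn"):
            recipient_lines.append(_vcf_line(pos, ref, alt, info, "0/1"))
        elif cat == "hvg":
            donor_lines.append(_vcf_line(pos, ref, alt, info, "0/1"))
        elif cat == "shared_het":
            donor_lines.append(_vcf_line(pos, ref, alt, info, "0/1"))
            recipient_lines.append(_vcf_line(pos, ref, alt, info, "0/1"))
        elif cat == "hom_alt_vs_het":
            donor_lines.append(_vcf_line(pos, ref, alt, info, "0/1"))
            recipient_lines.append(_vcf_line(pos, ref, alt, info, "1/1"))
        if cat == "gvh_nssnp":
            truth_rows.append(("1", pos, ref, alt, gene, ppos,
                               ref_aa, alt_aa))

    paths = {
        "donor": outdir / f"{drp_id}_donor.vcf",
        "recipient": outdir / f"{drp_id}_recipient.vcf",
        "truth": outdir / f"{drp_id}_truth.tsv",
        "proteins": outdir / f"{drp_id}_proteins.fasta",
    }
    paths["donor"].write_text(
        _VCF_HEADER.format(sample="DONOR") + "".join(donor_lines))
    paths["recipient"].write_text(
        _VCF_HEADER.format(sample="RECIPIENT") + "".join(recipient_lines))
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "ref", "alt", "gene",
                             "protein_pos", "ref_aa", "alt_aa"])
    truth = truth.sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_protein_fasta(proteins, paths["proteins"])
    return paths


def synth_affinities(
    peptides: Sequence,
    alleles: Sequence[str],
    spec: SynthSpec,
    seed: int,
    sb_fraction: float | None = None,
) -> pd.DataFrame:
    """One IC50 per (peptide, allele), log-uniform over the configured
    range.

    ``peptides`` may be strings or objects with ``sequence`` and
    ``gene_id`` attributes (the ``gene``/``snp_index`` columns are carried
    through when available).  ``sb_fraction`` plants strong binders: each
    pair is SB (log-uniform below 50 nM) with that probability and non-SB
    (log-uniform above 50 nM) otherwise, emulating the stronger class II
    presentation seen in real cohorts when set higher for DRB1 alleles.
    """
    if len(peptides) == 0:
        raise ValueError("peptides must be non-empty")
    rng = np.random.default_rng(seed)
    lo, hi = spec.ic50_log10_range
    sb_cut = np.log10(50.0)
    rows = []
    for p in peptides:
        seq = getattr(p, "sequence", p)
        gene = getattr(p, "gene_id", "")
        snp_index = getattr(p, "snp_index", None)
        for allele in alleles:
            if sb_fraction is None:
                log_ic50 = rng.uniform(lo, hi)
            elif rng.random() < sb_fraction:
                log_ic50 = rng.uniform(lo, min(sb_cut, hi))
            else:
                log_ic50 = rng.uniform(max(sb_cut, lo), hi)
            rows.append((seq, allele, 10.0 ** log_ic50, gene, snp_index))
    df = pd.DataFrame(rows, columns=["peptide", "allele", "ic50", "gene",
                                     "snp_index"])
    df["b_affinity"] = 1.0 / df["ic50"]
    return df


def synth_expression(
    genes: Sequence[str], spec: SynthSpec, seed: int
) -> pd.DataFrame:
    """Log-normal RPKM per gene for the eight GVHD target organs, with
    optional zero inflation (a gene-tissue cell is zeroed with the
    configured probability)."""
    if len(genes) == 0:
        raise ValueError("genes must be non-empty")
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(spec.rpkm_meanlog, spec.rpkm_sdlog,
                         size=(len(genes), len(TISSUES)))
    if spec.rpkm_zero_inflation > 0:
        vals[rng.random(vals.shape) < spec.rpkm_zero_inflation] = 0.0
    df = pd.DataFrame(vals, columns=list(TISSUES))
    df.insert(0, "gene", list(genes))
    return df


def synth_repertoire(
    m_clones: int,
    spec: SynthSpec,
    seed: int,
) -> tuple[list[CloneParams], list[AntigenParams], np.ndarray]:
    """Clone and antigen parameter sets with a recognition mask.

    One antigen per clone; B and Z are 1/IC50 with IC50 log-uniform over
    the bound range; expression P log-normal; checkpoint and costimulation
    gates drawn Bernoulli at the configured rates.  Recognition defaults to
    the identity (one cognate complex per clone); ``cross_reactivity`` > 0
    switches on off-diagonal recognition with that density and uniform
    strength in (0, 1).
    """
    if m_clones < 1:
        raise ValueError("m_clones must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(spec.repertoire_ic50_range)
    b = 1.0 / 10.0 ** rng.uniform(lo, hi, size=m_clones)
    z = 1.0 / 10.0 ** rng.uniform(lo, hi, size=m_clones)
    p = rng.lognormal(spec.rpkm_meanlog, spec.rpkm_sdlog, size=m_clones)
    cp = (rng.random(m_clones) < spec.cp_rate).astype(int)
    s2 = (rng.random(m_clones) < spec.s2_rate).astype(int)
    antigens = [
        AntigenParams(antigen_id=f"ag{i:03d}", b_affinity=float(b[i]),
                      expression=float(p[i]),
                      scavenging=spec.class_ii_scavenging)
        for i in range(m_clones)
    ]
    clones = [
        CloneParams(clone_id=f"T{j:03d}", z_affinity=float(z[j]),
                    carrying_capacity=spec.carrying_capacity,
                    n0=1.0, cp=int(cp[j]), s2=int(s2[j]))
        for j in range(m_clones)
    ]
    recognition = np.eye(m_clones)
    if spec.cross_reactivity > 0:
        off = ((rng.random((m_clones, m_clones)) < spec.cross_reactivity)
               * rng.uniform(0, 1, (m_clones, m_clones)))
        recognition = np.maximum(recognition, off)
    return clones, antigens, recognition


def synth_correlated_pairs(
    n: int, rho: float, seed: int,
    mean: tuple[float, float] = (0.0, 0.0),
    sd: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal draws with the given correlation (for calibrating
    correlation estimates against a known generative value)."""
    rng = np.random.default_rng(seed)
    cov = [[sd[0] ** 2, rho * sd[0] * sd[1]],
           [rho * sd[0] * sd[1], sd[1] ** 2]]
    xy = rng.multivariate_normal(mean, cov, size=n)
    return xy[:, 0], xy[:, 1]


def synth_cohort(spec: SynthSpec, seed: int) -> list[DrpSummary]:
    """Per-pair summaries with the planted MRD < MUD class II burden.

    Class II BP counts are log-normal around the MRD mean, multiplied by
    the unrelated-donor burden factor for MUD pairs; SB counts follow BP
    with the configured log-scale correlation; class I counts scale from
    class II by the planted I/II ratio with independent noise.
    """
    rng = np.random.default_rng(seed)
    out: list[DrpSummary] = []
    sd = spec.bp_sdlog
    rho = spec.sb_bp_log_correlation
    for i in range(spec.n_mrd + spec.n_mud):
        donor_type = "MRD" if i < spec.n_mrd else "MUD"
        mean_bp = spec.mrd_bp_ii_mean * (
            spec.mud_burden_multiplier if donor_type == "MUD" else 1.0)
        mu = np.log(mean_bp) - sd ** 2 / 2
        z1, z2 = rng.standard_normal(2)
        log_bp = mu + sd * z1
        # SB shares the BP log deviation with correlation rho
        log_sb = (np.log(spec.sb_over_bp) + mu
                  + sd * (rho * z1 + np.sqrt(1 - rho ** 2) * z2))
        bp_ii = int(np.exp(log_bp)) + 1
        sb_ii = min(int(np.exp(log_sb)) + 1, bp_ii)
        ratio = spec.ratio_i_over_ii * np.exp(0.3 * rng.standard_normal())
        bp_i = max(1, int(bp_ii * ratio))
        sb_i = max(1, min(int(sb_ii * ratio), bp_i))
        out.append(DrpSummary(
            drp_id=f"DRP{i + 1:03d}", donor_type=donor_type,
            sb_class_i=sb_i, bp_class_i=bp_i,
            sb_class_ii=sb_ii, bp_class_ii=bp_ii))
    return out
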