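"""Graft-versus-host (GVH) direction variant extraction.

After an allogeneic stem cell transplant, donor T cells can recognise
recipient peptides encoded by variants the recipient carries but the donor
does not (the R+/D- or GVH direction).  This module joins per-sample VCF
variant calls for a donor-recipient pair (DRP), applies the GVH-direction
genotype filter, and restricts to nonsynonymous SNPs -- the sites that
change an amino acid and can therefore yield minor histocompatibility
antigens (mHA).

VCF parsing is delegated to :mod:`cyvcf2`; multi-allelic records are
decomposed to one site per alternate allele before filtering.  Genotypes
are treated as unordered allele multisets (phasing is ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

Consequence = Literal["synonymous", "nonsynonymous", "other"]

#: genotype allele codes after multi-allelic decomposition
REF = 0      #: the reference allele
ALT = 1      #: the alternate allele this record describes
OTHER = 2    #: some other alternate allele at the same site


@dataclass(frozen=True)
class AnnotationKeys:
    """Names of the INFO keys carrying protein-level annotation.

    The pipeline consumes annotation (it never recomputes consequences);
    these defaults match the dialect written by
    :func:`allodyn.synth.synth_vcf_pair`.
    """

    gene: str = "GENE"
    consequence: str = "CONSEQ"
    protein_pos: str = "PPOS"
    ref_aa: str = "RAA"
    alt_aa: str = "AAA"

    def required(self) -> tuple[str, ...]:
        return (self.gene, self.consequence, self.protein_pos,
                self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class VariantSite:
    """One joined donor/recipient call, decomposed per alternate allele.

    ``donor_gt`` / ``recipient_gt`` are unordered pairs of the codes
    ``REF``/``ALT``/``OTHER`` above (``None`` when the sample had no call
    and missing calls are configured to be excluded rather than treated
    as homozygous reference).
    """

    chrom: str
    pos: int                      # 1-based, VCF convention
    ref: str
    alt: str
    donor_gt: tuple[int, int] | None
    recipient_gt: tuple[int, int] | None
    gene_id: str = ""
    consequence: Consequence = "other"
    protein_pos: int | None = None   # 1-based amino-acid position
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for gt in (self.donor_gt, self.recipient_gt):
            if gt is not None and any(a not in (REF, ALT, OTHER) for a in gt):
                raise ValueError(f"invalid genotype codes {gt}")
        if self.consequence == "nonsynonymous":
            if self.protein_pos is None:
                raise ValueError("nonsynonymous site lacks protein_pos")
            if self.ref_aa == self.alt_aa:
                raise ValueError(
                    f"nonsynonymous site at {self.chrom}:{self.pos} has "
                    f"identical ref/alt amino acids ({self.ref_aa})")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)

    def carried_by(self, gt: tuple[int, int] | None) -> bool:
        return gt is not None and ALT in gt


@dataclass
class GvhSnpSet:
    """Variant sites passing the GVH-direction (R+/D-) filter for one DRP."""

    drp_id: str
    sites: list[VariantSite] = field(default_factory=list)
    #: sites excluded because the donor also carries the alt allele even
    #: though the recipient is homozygous for it (both carry: not GVH)
    n_shared_alt_excluded: int = 0

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def to_frame(self) -> pd.DataFrame:
        cols = ["chrom", "pos", "ref", "alt", "gene", "protein_pos",
                "ref_aa", "alt_aa", "consequence"]
        rows = [(s.chrom, s.pos, s.ref, s.alt, s.gene_id, s.protein_pos,
                 s.ref_aa, s.alt_aa, s.consequence) for s in self.sites]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class VcfParseError(ValueError):
    """A VCF could not be parsed or lacks a required field."""


def _consequence_label(raw: str | None) -> Consequence:
    if raw is None:
        return "other"
    raw = str(raw).strip().lower()
    if raw in ("nonsynonymous", "nonsynonymous_snv", "missense",
               "missense_variant"):
        return "nonsynonymous"
    if raw in ("synonymous", "synonymous_snv", "synonymous_variant"):
        return "synonymous"
    return "other"


def _per_alt(value, alt_index: int):
    """INFO values for multi-allelic records may be comma-joined per alt."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else value[0]
    if isinstance(value, str) and "," in value:
        parts = value.split(",")
        return parts[alt_index] if alt_index < len(parts) else parts[0]
    return value


def _read_single_sample_vcf(
    path: str | Path, keys: AnnotationKeys
) -> dict[tuple[str, int, str, str], dict]:
    """Parse one VCF into {(chrom, pos, ref, alt): record-dict}."""
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    header_info = set()
    for h in vcf.header_iter():
        if h.type == "INFO":
            header_info.add(h["ID"])
    missing = [k for k in keys.required() if k not in header_info]
    if missing:
        raise VcfParseError(
            f"VCF {path!r} header lacks required INFO annotation keys: "
            f"{', '.join(missing)}")
    if not vcf.samples:
        raise VcfParseError(f"VCF {path!r} has no sample columns (no GT)")

    out: dict[tuple[str, int, str, str], dict] = {}
    for var in vcf:
        if var.genotypes is None or not var.genotypes:
            raise VcfParseError(
                f"missing GT at {var.CHROM}:{var.POS} in {path!r}")
        raw_gt = var.genotypes[0][:2]  # first sample; drop phase flag
        for ai, alt in enumerate(var.ALT):
            if -1 in raw_gt:
                gt = None  # no call for this sample
            else:
                codes = tuple(sorted(
                    REF if a == 0 else (ALT if a == ai + 1 else OTHER)
                    for a in raw_gt))
                gt = codes
            info = var.INFO
            out[(var.CHROM, var.POS, var.REF, alt)] = {
                "gt": gt,
                "gene": _per_alt(info.get(keys.gene), ai) or "",
                "consequence": _consequence_label(
                    _per_alt(info.get(keys.consequence), ai)),
                "protein_pos": _maybe_int(
                    _per_alt(info.get(keys.protein_pos), ai)),
                "ref_aa": _maybe_str(_per_alt(info.get(keys.ref_aa), ai)),
                "alt_aa": _maybe_str(_per_alt(info.get(keys.alt_aa), ai)),
            }
    return out


def _maybe_int(v):
    return None if v is None else int(v)


def _maybe_str(v):
    return None if v is None else str(v)


def read_vcf_pair(
    donor_vcf: str | Path,
    recipient_vcf: str | Path,
    keys: AnnotationKeys = AnnotationKeys(),
    missing_as_ref: bool = True,
) -> list[VariantSite]:
    """Join donor and recipient VCFs into one :class:`VariantSite` per
    (chrom, pos, alt).

    A sample with no record at a site (or a ``./.`` call) is treated as
    homozygous reference when ``missing_as_ref`` is true (the default);
    otherwise such sites are dropped from the join.
    """
    donor = _read_single_sample_vcf(donor_vcf, keys)
    recipient = _read_single_sample_vcf(recipient_vcf, keys)

    hom_ref = (REF, REF)
    sites: list[VariantSite] = []
    for key in sorted(set(donor) | set(recipient)):
        chrom, pos, ref, alt = key
        d = donor.get(key)
        r = recipient.get(key)
        ann = r or d  # prefer the recipient's annotation
        d_gt = d["gt"] if d is not None else hom_ref
        r_gt = r["gt"] if r is not None else hom_ref
        if d_gt is None:
            d_gt = hom_ref if missing_as_ref else None
        if r_gt is None:
            r_gt = hom_ref if missing_as_ref else None
        if d_gt is None or r_gt is None:
            continue  # excluded: missing call and missing_as_ref=False
        sites.append(VariantSite(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            donor_gt=d_gt, recipient_gt=r_gt,
            gene_id=ann["gene"], consequence=ann["consequence"],
            protein_pos=ann["protein_pos"],
            ref_aa=ann["ref_aa"], alt_aa=ann["alt_aa"],
        ))
    return sites


def gvh_filter(sites: Iterable[VariantSite], drp_id: str = "") -> GvhSnpSet:
    """Retain sites whose alt allele is carried by the recipient and absent
    from the donor (the R+/D- predicate).

    Sites where both carry the alt (including recipient homozygous-alt with
    a heterozygous donor) are excluded and counted in
    ``n_shared_alt_excluded``.  Idempotent; output is deduplicated by
    (chrom, pos, alt).
    """
    out = GvhSnpSet(drp_id=drp_id)
    seen: set[tuple[str, int, str]] = set()
    for s in sites:
        r_has = s.carried_by(s.recipient_gt)
        d_has = s.carried_by(s.donor_gt)
        if r_has and d_has:
            out.n_shared_alt_excluded += 1
            continue
        if r_has and not d_has and s.key not in seen:
            seen.add(s.key)
            out.sites.append(s)
    return out


def nonsynonymous_filter(snp_set: GvhSnpSet) -> GvhSnpSet:
    """Keep only nonsynonymous sites; collapse duplicates that are identical
    in (chrom, pos, alt, protein change)."""
    seen: set[tuple] = set()
    kept: list[VariantSite] = []
    for s in snp_set.sites:
        if s.consequence != "nonsynonymous":
            continue
        k = (s.chrom, s.pos, s.alt, s.gene_id, s.protein_pos,
             s.ref_aa, s.alt_aa)
        if k in seen:
            continue
        seen.add(k)
        kept.append(s)
    return replace_sites(snp_set, kept)


def replace_sites(snp_set: GvhSnpSet, sites: Sequence[VariantSite]) -> GvhSnpSet:
    return GvhSnpSet(drp_id=snp_set.drp_id, sites=list(sites),
                     n_shared_alt_excluded=snp_set.n_shared_alt_excluded)


def gvh_nssnps(
    donor_vcf: str | Path,
    recipient_vcf: str | Path,
    drp_id: str = "",
    keys: AnnotationKeys = AnnotationKeys(),
    missing_as_ref: bool = True,
) -> GvhSnpSet:
    """Full GVH pipeline: join, direction filter, nonsynonymous filter."""
    sites = read_vcf_pair(donor_vcf, recipient_vcf, keys=keys,
                          missing_as_ref=missing_as_ref)
    return nonsynonymous_filter(gvh_filter(sites, drp_id=drp_id))
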