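"""Reference data from a published whole-exome transplant cohort.

Bundled worked-example inputs from a study of 75 evaluable HLA-matched
donor-recipient pairs (26 related, 49 unrelated donors):

* a 20-gene table of peptide-HLA IC50 values (nM) for one matched-related
  pair, covering genes whose polymorphic peptides bound both HLA class I
  (six alleles) and HLA class II (two DRB1 alleles) in the 0-50 nM range;
* the cohort's median-split contingency tables of donor type against
  class II bound-peptide burden.

These are measured values from real sequencing data, included so the
binding-annotation and statistics operations can be exercised against
published numbers without access to the original exomes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import ContingencyTable2x2

#: donor type (MUD, MRD) x class II SB burden above/at-or-below the cohort
#: median of 4,245 strongly bound peptides
SB_MEDIAN_SPLIT = ContingencyTable2x2(a=30, b=19, c=8, d=18)

#: donor type x class II BP burden above/at-or-below the cohort median of
#: 52,983 bound peptides
BP_MEDIAN_SPLIT = ContingencyTable2x2(a=34, b=15, c=4, d=22)


def load_dual_presentation_example() -> pd.DataFrame:
    """Long-format affinity table (gene, hla_class, peptide, allele, ic50)
    for the 20 dual-presented genes of the example pair."""
    ref = resources.files("allodyn.data") / "dual_presentation_mrd26.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["b_affinity"] = 1.0 / df["ic50"]
    return df
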