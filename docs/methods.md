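# Methods

## Scope and data flow

`allodyn` covers the in-silico stage of mHA analysis: it consumes variant
calls (VCF with gene/consequence/protein-change INFO annotation), protein
sequences (FASTA), peptide-HLA IC50 tables (TSV), tissue expression (TSV of
RPKM), and pair metadata; it never aligns reads, calls variants, annotates
consequences, or predicts binding. Those upstream steps are standard
tooling, and their outputs are this package's inputs.

## GVH-direction variant extraction

A site is retained when some alternate allele occurs in the recipient
genotype and not in the donor genotype (R+/D-). Genotypes are unordered
allele multisets; phasing is ignored. Multi-allelic records are decomposed
to one record per alternate allele before filtering, so "the allele" is
always unambiguous. Two conventions the input format leaves open:

* A sample with no record (or a `./.` call) at a site is treated as
  homozygous reference by default — single-sample callers emit only variant
  sites, so absence is the expected encoding of hom-ref. Setting
  `missing_as_ref=False` instead excludes such sites from the join.
* When the recipient is homozygous alt and the donor heterozygous for the
  same allele, both carry it, so the site is not R+/D- and is excluded;
  these exclusions are counted separately (`n_shared_alt_excluded`) so the
  choice is auditable downstream.

Nonsynonymous filtering trusts the annotation (a synonymous/nonsynonymous/
other label) and collapses duplicates identical in (chrom, pos, alt,
protein change).

## Peptide windows

For a substitution at protein position p, the class I window covers
[p-8, p+8] (a 17-mer with the variant residue central) and the class II
window [p-14, p+14] (a 29-mer); sliding a 9-mer (15-mer) across the window
and keeping every peptide containing the variant residue yields exactly 9
(15) peptides for interior positions. Near protein termini the window is
truncated, not padded: padding would fabricate sequence, and predictors
reject non-residue characters. A substitution d < k-1 residues from a
terminus therefore yields d+1 peptides, and library sizes fall below
9/15 per SNP accordingly (reported, not hidden). The class II length is
fixed at 15 by default — the average for the open class II groove — with
`k` exposed for the 7-18 range some workflows use. Peptides containing
non-standard residues (X, U, ...) are dropped with a logged count.

Deduplication keeps records unique in (sequence, polymorphic-position,
gene): the same string arising with its variant residue at a different
offset, or from a different gene, came from a different exomic site and is
counted separately.

## Binding classification and summaries

SB means IC50 &le; 50 nM and BP IC50 &le; 500 nM, both inclusive (the
boundary values 50 and 500 classify as SB and BP respectively; the
alternative strict-inequality convention changes only exact-boundary rows,
which the unit tests pin down). Affinity is B = 1/IC50 in nM^-1, strictly
decreasing in IC50. Duplicate (peptide, allele) rows keep the last
occurrence with a warning. Class I counts pool all six A/B/C alleles;
DRB1-homozygous pairs have class II *counts* doubled (one physical allele
on both chromosomes' worth of molecules) — IC50 values are never altered.
A gene is dual-presented when its minimum IC50 over class I
peptide-allele pairs and its minimum over class II pairs both fall at or
under the threshold (default 50 nM); taking minima is equivalent to "any
peptide qualifies" and is monotone in the threshold. "Expressed in an
organ" means RPKM > 0 by default; the cutoff is configurable since bulk
RPKM noise floors vary.

## Cohort statistics

The two-sided Fisher exact p follows the point-probability convention (sum
of hypergeometric point probabilities no larger than the observed one),
the definition shared by scipy and R; two-sided Fisher conventions differ
(tail-doubling, mid-p), so the choice is stated and the implementation is
verified against an exhaustive margin-preserving enumeration in exact
integer arithmetic on every 2x2 table with N &le; 40. The t-test is
Welch's (unequal variances cannot be assumed across donor types). Median
splits put strictly-greater-than-median pairs in the "above" cell. Ratios
with a zero class II denominator are excluded from medians with a warning.

One reference value deliberately does not reproduce: the bundled SB
median-split table (30/49 vs 8/26) is quoted in the source cohort report
at p = 0.012, but no two-sided Fisher variant gives that value (point
method 0.01577, one-sided 0.01126, two-sided mid-p 0.01149); an
uncorrected chi-square gives 0.01205. The package reports the correct
Fisher value and leaves the corresponding acceptance test red rather than
matching a number its stated test cannot produce.

## The growth model

The iteration

    N_t = K' N_0 / ((K' - N_{t-1}) e^{-r t B} + 1),   K' = P c K B Z

is an explicit logistic map whose fixed point as t grows is K'·N_0
(relative deviation bounded by e^{-r t B}, so convergence is
super-exponential in t because the exponent itself grows with t). Choices
made where the formulation is ambiguous:

* **K' is a product.** The steady-state scale multiplies P, c, K, B and Z;
  a reading in which B·Z exponentiates K was rejected — the accompanying
  description calls the steady state *proportional to the product* of the
  affinities and calls P a *coefficient/multiplier*, and an exponent would
  make the steady state dimensionally incoherent across affinity units.
* **t is the iteration index**, dimensionless; B enters the exponent as
  written, so the growth time scale depends on affinity units. A
  `SimulationConfig.exponent_affinity_scale` factor (default 1, folded
  into r) decouples the time scale when desired.
* **Cytokine amplification** multiplies the step by Ck^(t·(1 - N/K')).
  Written with N_t on both sides it is implicit; the exponent uses
  N_{t-1} to obtain an explicit iteration. The factor is exactly 1 at
  Ck = 1 (bit-identical trajectories) and tends to 1 as N approaches K',
  so amplification boosts early growth without moving the steady state.
  It requires Ck &ge; 0 (a non-integer power of a negative base is
  undefined); suppressive fields act through r instead, where a negative
  Ck flips the exponential and the clone decays.
* **Gates.** r = CP·(S2·Ck) with CP, S2 binary: PD1 engagement or CTLA4
  expression gives r = 0, hence e^0 = 1 and N_t = N_0 exactly — growth
  arrest, not slow growth.
* **Degenerate inputs.** If N_{t-1} exceeds K' by more than the decaying
  exponential can absorb, the denominator goes non-positive; the step
  clamps to the steady state with a warning rather than producing a
  negative count.
* **Multi-antigen clones.** The recognition mask supports cross-reactive
  (fractional) entries; a clone recognising several complexes is driven by
  the one maximising B_i·Z_j — the strongest cognate signal — and a clone
  recognising none stays flat at N_0. Clone-clone competition for antigen
  is out of scope.
* The cleavage probability, the presentation-competition probability and
  the clone-presence probability are supplied parameters (their estimation
  is upstream of this package); the response risk is their product.

## Synthetic data: what it emulates, what it does not

The generators produce structurally faithful inputs with planted, exactly
recoverable truth — they are the package's test bed, not a biological
simulator:

* **VCF pairs** contain an exact planted count of R+/D- nsSNPs
  (`round(n_sites · gvh_fraction)`) among distractors (shared variants,
  donor-only variants, synonymous R+/D- variants, shared-allele
  homozygous/heterozygous sites), each file listing only sites where that
  individual carries an alternate allele. No linkage, haplotype structure
  or realistic allele frequencies are modelled.
* **IC50 tables** are log-uniform over 0.1-50,000 nM (affinities span
  decades; log-uniform is the natural uninformative spread), optionally
  with a planted SB fraction per class. Real predictor output is
  sequence-dependent; these tables are not.
* **Expression tables** are log-normal (meanlog 2.0, sdlog 1.5 — a median
  around 7 RPKM with a realistically heavy right tail) with optional zero
  inflation; no tissue correlation structure.
* **Repertoires** draw B and Z from the bound range 1-500 nM: complexes
  weaker than the BP threshold do not drive expansion, and with r = 1 this
  keeps e^{-r·t·B} below 1e-8 by t = 10^4, so steady-state recovery to
  1e-6 is a meaningful test of the iteration rather than of patience.
  Checkpoint/costimulation gates default to permissive (rates 1.0).
* **Cohorts** use the modelled study's conditions: 26 related and 49
  unrelated pairs, related-donor class II BP mean 39,584, unrelated burden
  multiplier 67,987/39,584 ≈ 1.72, SB tracking BP with log-scale
  correlation 0.9, class I/II ratio median 0.09. The BP dispersion is not
  directly published; sdlog = 0.5 is the value consistent with the printed
  significance levels (Welch p < 0.001 and ~4/26 related pairs above the
  BP median at these sample sizes) and is fixed as the generating
  condition. Consequently, passing cohort tests show the statistics
  recover planted effects under these conditions — not that real exome
  data have this distributional shape.

Problem sizes in the default suite and acceptance script (e.g. 100-120
variant sites, 6-8 clones, t_max = 10^4, exhaustive Fisher enumeration to
N = 40, 1,000 random windows) were chosen so each check is decisive at
desk scale.

## Known limitations

Proteasomal cleavage, peptide competition for HLA loading, mass-spec
validation, clonal competition, APC dynamics and spatial cytokine fields
are all outside the model; cleavage and presentation enter only as
supplied probabilities. The simulator's time unit is an abstract iteration
index, so trajectories are comparable within a parameter set but not
calibrated to days. Class II scavenging c is a free parameter in (0, 1],
not estimated from data.
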