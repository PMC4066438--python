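# Methods

## The system being modelled

*S. pombe* (*Sp*) and *S. kambucha* (*Sk*) hybrids sporulate normally but
yield few viable gametes. The package models the three-chromosome hybrid
meiosis with the minimal set of mechanisms that accounts for the observed
transmission and viability patterns:

1. a ~2.23 Mb inversion on chromosome 1 (*Sp* lineage; *Sk* retains the
   ancestral arrangement) spanning reference positions 2,683,632–4,911,515;
2. a reciprocal translocation between chromosomes 2 and 3 (*Sk* lineage)
   with breakpoints at chr2:676,281 and chr3:1,932,034 — the left arm of
   *Sp* chromosome 2 travels on *Sk* chromosome 3 and the right arm of *Sp*
   chromosome 3 on *Sk* chromosome 2, and both translocated segments carry
   essential genes;
3. one trans-acting gamete killer per *Sk* chromosome, plus a hypothesized
   weaker *Sp* killer on chromosome 3 opposing the *Sk* one.

All coordinates are 1-based on the *Sp* reference; a chromatid's ancestry
is a breakpoint list in those coordinates regardless of its physical
arrangement. Chromosome lengths are the standard reference constants
(5,579,133 / 4,539,804 / 2,452,883 bp). mtDNA is not modelled: drive is
independent of mitochondrial genotype, so the nuclear model suffices.

## Meiosis

**Crossovers.** Each bivalent receives a Poisson number of exchange events
with mean 2*d*, where *d* is the genetic length in Morgans of the region of
shared homology, converted from physical length at a uniform 0.16 cM/kb
(the genome average; crossover frequencies are fairly uniform in *Sp* and
hotspot structure is deliberately ignored). Events choose one chromatid
per homolog uniformly and a position uniform in map distance. There is no
chiasma or chromatid interference; this reproduces Haldane's mapping
function r = (1 − e^(−2d))/2 exactly, and the simulator is tested against
that closed form.

Events are swept left to right along the four aligned chromatid axes of
the bivalent; each event exchanges everything downstream between whichever
recombinant products currently occupy the two chosen axes. This
bookkeeping matters: exchanging tails between the *original* strands
instead of the current axis occupants underestimates recombination.

**Rearrangement heterozygotes.** Pairing is homology-segment-wise; the
quadrivalent geometry of the translocation heterozygote is not modelled.
In a translocation heterozygote, crossovers are confined to the shared
chromosome 2 core or chromosome 3 core, and the downstream exchange moves
translocated content between karyotypes — which is precisely how the rare
viable "R"-type recombinant chromosomes arise. In an inversion
heterozygote, content is collinear in ancestry coordinates, so exchanges
proceed normally while a per-chromatid parity counter records crossovers
inside the inverted interval; odd parity marks the chromatid as a
duplication/deficiency product. The internal geometry of unbalanced
chromatids is not represented (they are dead on arrival), and for
even-parity chromatids the downstream-exchange approximation is used.

**Segregation.** A bivalent with at least one crossover always disjoins
properly at MI (missegregation of chiasmate bivalents is not modelled;
hybrids do not produce more aneuploids per meiosis than pure species, so
nothing forces a hybrid-specific nondisjunction term). An achiasmate
bivalent disjoins properly with probability `p_dist`, the fidelity of the
recombination-independent distributive system; otherwise each homolog
picks an MI pole independently, so at `p_dist = 0` a random spore carries
1 copy with probability 1/2 and 0 or 2 copies with probability 1/4 each.
MII always separates sisters. `p_dist` defaults to 0.5 for pure species
and hybrids alike: the distributive system is known only to be "partially
effective", its magnitude is unquantified, and the parameter is exposed
precisely because it is a free hypothesis.

`rec12Δ` mode replaces the crossover process with a single residual
Rec12-independent event per chromosome per meiosis at rate
`residual_rate` (default 0.005, uniform position). The true rate is
unstated; <1 % of viable recombination-free hybrid spores appear
non-parental, and the default is chosen to be of that order.

## Viability

Rules apply in a fixed order; the first failure is recorded as the cause:

1. **unbalanced** — any chromatid with odd crossover parity inside a
   heterozygous inversion;
2. **missing_essential** — the spore's content fails to cover any of the
   five essential blocks (chr1 core, chr2 left arm, chr2 core, chr3 core,
   chr3 right arm). Essential content is modelled at this coarse block
   level; the viability logic only needs "each translocated segment
   carries essential genes". This is what kills intact-K2 + intact-P3 and
   intact-P2 + intact-K3 haploids;
3. **aneuploid_lethal** — copy-number vectors other than (1,1,1), (2,2,2)
   and (1,1,2): chromosome 1 or 2 aneuploidy is lethal, chromosome 3
   disomy is tolerated;
4. **drive_killed** — independent Bernoulli killing by each active gamete
   killer: a spore lacking the killer-ancestry allele at a killer locus
   dies with probability *d* (its strength). Drive is strictly
   post-segregation trans-acting gamete killing, never biased segregation.
   A killer whose ancestry is absent from the whole cross is inert.

Resistance requires carrying the killer allele itself (a one-locus
poison/antidote), so heterozygous diploids are immune to everything and
chr3-heterozygous disomes are immune to both chromosome 3 killers. This
implements the aneuploid-rescue explanation of the heterozygous-aneuploid
excess among viable hybrid spores, rather than a dosage model. Whether
drive acts on diploid spores at reduced rather than zero intensity is
untested; the model makes carriers fully immune.

## Exact enumeration

Without crossovers the three bivalents are independent and a random
spore's per-chromosome outcome is parent-1 homolog / parent-2 homolog /
both / neither with probabilities q/2, q/2, (1−q)/2, (1−q)/2, where
q = (1 + p_dist)/2. The joint distribution over the 64 classes is exact;
deterministic viability is applied per class and drive in expectation
(survival weights rather than sampled deaths — exactness is the point,
since this is both the oracle for the simulator and the likelihood
kernel). Useful closed consequences, all covered by tests:

* at `p_dist = 0` with no rearrangement heterozygosity the viable-
  complement probability (haploid, diploid or chr3 disome) is
  13/64 ≈ 20.3 %. The commonly quoted "~25 %" for random segregation of
  three chromosome pairs is reproduced once the distributive system is
  partially effective (`p_dist ≈ 0.2` gives ≥ 25 %); both numbers are
  reported and neither is forced onto the other;
* translocation heterozygosity reduces viable haploids exactly two-fold,
  independent of `p_dist`;
* with a single killer at the assayed locus and only haploids viable,
  transmission is t = 1/(2 − d);
* a weak chromosome 2 killer drives harder in a translocation heterozygote
  containing a strong chromosome 3 killer than in a karyotypically
  homozygous cross (pseudo-linkage).

Transmission is computed among viable spores carrying exactly one allele
at the locus, mirroring the assay's exclusion of heterozygous diploids
(and of heterozygous aneuploids for chromosome 3 loci).

## Statistics

Viable spore yield is viable colonies per cell plated (a relative measure
that can exceed 4). Transmission bias uses the two-cell goodness-of-fit
G-test against 50:50, 1 df, two-sided, without Williams correction
(available as an option); it is cross-checked against scipy's
log-likelihood-ratio statistic. Two-point intervals use per-spore counts
and Haldane's function, flagging r ≥ 0.5 as unlinked. Aneuploids per
meiosis is the product of viable spore yield and the aneuploid-or-diploid
fraction of viable spores. The single-killer transmission-distance curve
is t(r) = (1 − r·d)/(2 − d); note its own algebra gives exactly 1/2 at
r = 0.5 for every d.

## Inference

For recombination-free tables the enumeration kernel gives class
probabilities in closed form, and killer strengths are estimated by a
survivorship-conditioned multinomial likelihood over observable classes
(marker calls + assay ploidy class); dead spores are unobservable and
never enter. Free parameters are the active killers whose locus is
heterozygous between the parents; the rest are flagged non-identifiable.
Optimization is bounded L-BFGS-B with 5 seeded random restarts;
confidence intervals are 95 % likelihood-ratio profiles found by
bisection. Identical seed + configuration + table give bit-identical
results. Rows whose observable class is structurally impossible without
recombination (rare residual recombinants) are dropped and counted.

Killer positions enter the recombination-free likelihood only through
which parental ancestry block contains them, so position estimation is
delegated to `localize_driver`: a binomial likelihood over per-marker
transmission counts under t(x) = (1 − r(x)·d)/(2 − d), r(x) from Haldane
at 0.16 cM/kb, scanned on a 10 kb grid with local refinement. Mapping
finer than that grid would be spurious given the coarseness of the data
the method is designed for. A single marker leaves the position
unidentifiable (the whole chromosome is returned); markers at 50 %
return d = 0 with an explicit flag. Full simulated likelihood for
crossover-mode tables is deliberately out of scope; wild-type tables are
analyzed with the marker-curve method.

The chromosome 3 *Sk* killer and the opposing *Sp* counter-killer sit at
the same locus and are only weakly jointly identifiable from viable-spore
data (every chr3-heterozygous survivor is immune to both); the fit
exposes both parameters and the profile intervals make the confounding
visible rather than hiding it.

## Synthetic data and calibration

The generator (`generate_cross_table`) simulates tetrads, applies
viability, and records viable spores (or all spores in full-census mode)
with marker calls at *lys1* (chr1), *his5* (chr2) and *ade6* (chr3) by
default, plus the codominant-marker ploidy call used in the assay: both
chr2 alleles → heterozygous diploid; both chr3 alleles with one chr2
allele → heterozygous chr3 aneuploid; everything else — including true
homozygous diploids and disomes — is deliberately miscounted as haploid,
emulating the markers' blind spot. Tables are deterministic given seed
and configuration, with a single generator threaded through all
stochastic steps.

Marker and killer coordinates are package constants: approximate
reference gene positions chosen to satisfy the published structural
constraints (*lys1*/*lys7* inside the inversion, all chromosome 2 markers
on the translocation-retained core, *ade6*/*ura4* on the chromosome 3
core) and the observed ordering of transmission biases. They are not
base-accurate annotations, and analyses here depend on them only through
relative distances.

Killer strengths for the fully heterozygous presets are calibrated as the
single-locus maximum-likelihood estimates d = 2 − 1/t from the nearest
markers' observed wild-type transmissions (t = 0.72, 0.94, 0.82 →
d ≈ 0.61, 0.94, 0.78). These are derived defaults, not measured
constants. The *Sp* chromosome 3 counter-killer defaults to strength 0.2
— a labelled hypothesis: its existence is inferred, its strength never
measured. Preset crosses default to 1,000 meioses, matching the scale of
the real cross tables (which report only lower bounds like n > 200); the
recovery experiments use 5,000 meioses so that sampling error is well
below the ±0.05 recovery tolerance, and the acceptance script states its
problem sizes in its output.

The Fig-8-style recombinant ("R") chromosomes are encoded from their
published breakpoints (midpoints of the flanking SNP pairs:
chr2 2,114,109 near *mat1*; chr3 2,291,600 and 1,559,154). The
translocated chr3 arm sits at the left tip of the *Sk* chromosome 2,
the arrangement consistent with the published recombinant genotypes.

## What the synthetic data do and do not show

The generator reproduces the *mechanistic* signatures: Mendelian
transmission when all strengths are zero, the Fig-6-style ordering of
biases by marker–killer distance, autonomous single-chromosome drive in
the R-chromosome crosses, heterozygous-aneuploid excess only when
chromosome 3 is heterozygous, a ~20-fold fertility collapse of wild-type
hybrids, and the enhancement of *his5* drive when recombination is
removed. It does not reproduce wet-lab magnitudes that depend on
unmeasured parameters: with the single-locus calibration the
recombination-free class distribution is more *Sk*-skewed than the real
tables (the real all-*Sk*:all-*Sp* haploid ratio is ~5; the calibrated
model's is far larger), and the recombination-free aneuploid fraction
(~30 % at the defaults) sits below the observed 78 % — both move with
`p_dist` and the counter-killer strength, which are hypotheses, and
neither is tuned post hoc. Passing tests therefore demonstrate internal
consistency and qualitative fidelity, not parameter-level agreement with
any particular experiment.

Two further limitations. Background (crossover-independent)
missegregation is absent, so wild-type pure-species crosses produce
essentially no aneuploid spores, whereas real assays find a few percent;
the model's aneuploids arise only from achiasmate bivalents. And
quadrivalent pairing/segregation geometry of the translocation
heterozygote is simplified to segment-wise homology, which is sufficient
for the viability accounting and the R recombinants but does not model
adjacent-segregation products explicitly.

## Numerical choices

* Probabilities in the enumeration are exact floating products; the
  pre-viability distribution sums to 1 within 1e−12 (tested).
* The G-test lets zero cells contribute zero; empty tables are domain
  errors, not NaNs.
* Haldane conversion rejects r ≥ 0.5 ("unlinked") instead of returning
  infinity.
* The likelihood floor: observable classes with zero model probability
  but positive counts make the objective +1e12, steering optimizer
  restarts away rather than producing −inf.
* Profile-CI bisection uses brentq to 1e−4 in d; bounds clamp at the
  [0, 1] box.
* `localize_driver` caps r(x) at 0.5 so that very distant candidate
  positions degrade gracefully to the unlinked expectation.
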