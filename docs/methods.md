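# Methods

## The analysis in one paragraph

Each of four family members (father, mother, two children) contributes two
DNA sources: PBMC (peripheral blood mononuclear cells, taken as germline
ground truth) and an EBV-transformed lymphoblastoid cell line (LCL), which
may carry culture-acquired mutations.  Variants are called per
sample-source from per-site read pileups under a hard-filtered Bayesian
diploid model, the two call sets of each individual are intersected, and
discordant calls are re-examined under a relaxed filter tier ("rescue") in
the source that missed them.  What survives rescue is classified with the
pedigree and a known-variant database surrogate: variants carried by a
single LCL and absent from the database are de novo candidates; everything
else is a segregating or database-known variant that fell on the wrong
side of a threshold in one source.

## Genotype model

Per site the caller considers only the best-supported non-reference allele
(ties broken lexicographically, which makes triallelic handling
deterministic).  With k alternate reads out of n = ref + alt informative
reads, likelihoods are binomial with expected alternate fraction ε, ½ and
1 − ε for hom-ref, het and hom-alt, where ε is the per-read error rate
(default 10⁻³).  The prior is {1 − θ − θ², θ, θ²} with θ the
heterozygosity prior (default 10⁻³), renormalised.  A site with no reads
yields *no posterior* — explicitly distinct from a confident hom-ref.

The MAP genotype must be non-reference, and the site must pass every hard
filter of the active stringency profile.  All comparisons are inclusive
(≥), following "minimum X" semantics.  Aggregation choices the thresholds
do not pin down themselves: "base quality" is the mean base quality of
alternate-supporting reads; "mapping quality" is the site mean; the
alternate fraction's denominator is total site depth (all alleles, both
strands).  All three are the simplest auditable choices and sit behind the
profile object, so stricter per-read minima can be emulated by adjusting
the configured values.

Posterior arithmetic is done in log space; inclusive fraction thresholds
are applied as `alt ≥ f·depth − 10⁻⁹` so that exact boundaries (e.g. 2 of
10 at 20%) are not lost to float representation.

The two built-in tiers are HIGH = {8X, BQ 40, MQ 40, 20%, both strands}
and RESCUE = {5X, BQ 40, MQ 30, 15%, both strands}.  Rescue relaxes
coverage, alternate fraction and mapping quality but never base quality or
the both-strand rule.

Indel candidates are not derived from pileups (gapped alignment is out of
scope); they enter as records carrying their own evidence and pass through
a separate filter: indel mapping quality ≥ 50, anchor (non-gapped) read
mapping quality ≥ 20, mean distance from read end ≥ 10 bp, coverage ≥ 8X,
both strands, insertion length 1–3 bp / deletion length 1–11 bp.  The
first violated rule is reported.

## Concordance, rescue and classification

Concordance is intersection-over-union of variant keys (chrom, pos, ref,
alt), zygosity-blind by default; a genotype-aware mode moves
zygosity-conflicting keys into their own category so the three Venn sets
stay disjoint.  Rescue re-calls the missing source's pileup under the
RESCUE tier and requires the *same* alternate allele; the attribution
order (alternate fraction, then coverage, then mapping quality, else
"combined") is fixed and reflects the relative effect sizes these
relaxations have in this design.  A discordant key with no pileup record
in the missing source counts as not rescued.

De novo classification enumerates carriers across all eight HIGH-tier call
sets.  The candidate rule is conjunctive: exactly one carrier, that
carrier is an LCL, and the key is absent from the known-sites set.  The
partition |shared_or_known| + |de_novo_candidate| = |remaining| is exact
and tested.  Both the pooled-deduplicated discordant count and the
per-pair sum are reported, since either convention is defensible when
individuals share discordant keys.

Mendelian checking treats an uncalled site in child or parent as hom-ref;
a depth-qualified mode (check only where both parents have ≥ 8X) is
available and off by default, since the default simulation saturates
coverage.  The substitution spectrum is strand-literal: 12 ordered ref>alt
classes, not collapsed to 6.

Validation candidates re-verify the single-LCL-carrier property (it is
already implied by the classification — the re-check is defensive), can be
restricted to children, and keep only protein-altering annotations
(non-synonymous, splice-site, nonsense).

## Annotation

Effects: nonsense > frameshift > splice-site > non-synonymous >
inframe_indel > synonymous > utr5/utr3 > near_gene > microRNA > intronic >
intergenic; most-severe-wins across overlapping transcripts, so every
variant receives exactly one collapsed effect.  Coding changes are
classified by translating the reference and mutated codon (standard
genetic code, reverse-complemented on minus-strand transcripts).  The
splice-site window is 2 bp into the intron at each exon boundary (the
canonical donor/acceptor dinucleotides); "near gene" is 50 bp upstream of
the transcript start, strand-aware, and not applied downstream.  Both
windows are configurable because the category names alone do not fix
them.  Indels overlapping a CDS are frameshift iff length mod 3 ≠ 0.
Novelty is key-absence from the known-sites set, with a position-only
matching option.

## The synthetic study

The generator emulates the study conditions, not raw reads: no FASTQ,
alignment, capture-bias or CNV/LOH modelling.

* **Targets** — 250 regions of 1,500 bp placed uniformly without overlap
  on a 30.75 Mb genome: 1.22% targeted, the exome-capture fraction, at
  1/100 scale so a default run takes under a second.  Full scale
  (~38 Mb targeted) is a configuration choice, used by the acceptance
  checks.
* **Reference** — i.i.d. uniform ACGT per region, generated lazily from
  the seed; a FASTA-backed accessor can be substituted.
* **Truth** — founder genotypes drawn per site from a Beta(0.5, 0.5)
  allele-frequency distribution under Hardy–Weinberg (a U-shaped folded
  spectrum; configurable, e.g. fixed-frequency); children receive one
  uniformly chosen allele per parent, so population variants can never
  violate transmission.  `variant_density` is calibrated as *called
  variants per sample per targeted bp* (default 19,354 / 38 Mb); the
  number of segregating sites is scaled up by the mean per-sample carrier
  probability the frequency distribution implies.  Sites are Poisson in
  number; per-sample variance is therefore Poisson-like.
* **Known-sites surrogate** — each population variant is flagged "known"
  with probability 1 − 0.0275, matching the novel share of called SNVs;
  the flags are emitted as a sites-only VCF so no external database is
  bundled.
* **LCL mutations** — per individual, Binomial(PBMC carrier count, 0.0018)
  heterozygous variants planted at positions not already variant in the
  family, substitution type drawn from a transition-heavy 12-class
  spectrum with C>T most common (25%); always absent from the known-sites
  surrogate.  With rate 0 the LCL truth is identical to the PBMC truth.
* **Pileups** — depth Poisson(125); each read's allele drawn from the
  genotype then miscalled with probability 10⁻³ to a uniform other base;
  strand Bernoulli(½); non-variant sites emitted at a configurable density
  (default 1% of targeted bp; 100% enumerates every position) so false
  positives and coverage are measurable.  All sample-sources are
  independent draws, so with no planted mutations the PBMC and LCL pileup
  distributions coincide by construction.
* **Qualities** — base and mapping qualities follow two-point
  distributions (high 40 / low 20).  The default low fraction is 0:
  because the HIGH thresholds equal the high value and apply to *means*,
  any nonzero low-quality admixture at 125X would push essentially every
  site's mean below threshold and reject the whole exome, which is not
  the regime these filters probe.  Quality-driven rejection is exercised
  by configuring nonzero low fractions or explicit pileups.

One master seed derives fixed-tag sub-streams per stage (targets,
reference, truth, mutations, pileups), so identical configurations
reproduce every table bit-for-bit and stages are independently
replayable.

### What passing tests do and do not show

The simulation has Poisson depth, independent uniform errors, no capture
bias, no mapping artifacts, no strand bias beyond Bernoulli(½), diploid
autosomes only, and SNV-only truth.  Consequently, at the default 125X the
discordance between paired sources is driven almost entirely by the
planted LCL mutations, and the recovered candidate rate matches the
planted 0.18% — which validates the *accounting machinery*, not the error
profile of any real instrument.  Threshold-marginal discordance (the
regime rescue targets in real data) appears in the simulator only at
lower depth or higher error; the rescue tests exercise it there and with
constructed pileups.  Real-data concordance figures are not reproducible
from this package because the underlying study deposited no sequence
data.

## Problem sizes used by the default checks

Default runs use the 1/100-scale exome (~200 calls/sample).  Recovery and
rate checks run at full scale (~19,000 calls/sample, 1,000 × 38 kb
regions), 20 seeds in the test suite and 5 in the acceptance script; the
error-free identifiability check uses 5 seeds at default scale; oracle
equivalence checks ≥ 1,000 random pileups.  These sizes give the binomial
intervals quoted in the tests while keeping a full run in the low
minutes.

## Known limitations

* diBayes-style callers are reimplemented here as a binomial/HW-prior MAP
  model; the original tool's internals are unpublished, so only the
  filter semantics are faithful.
* The alternate-fraction, base-quality and mapping-quality aggregation
  conventions are choices (documented above), as are the splice-site and
  near-gene windows.
* Parent no-calls are imputed hom-ref in Mendelian checks unless the
  depth-qualified mode is enabled; at low coverage this overcalls
  violations.
* Indel truth is not simulated; the indel filter is tested on constructed
  candidate records.
* Concordance with an empty union (zero variants) is undefined and
  reported as not-applicable rather than 0 or 100.
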