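# Methods

## The detection model

The package models the class of relative-matching service that calls IBS
segments on unphased genotypes.  Genotypes are minor-allele dosages
(0/1/2) with a distinct missing state.  Two kits are *incompatible* at a
site when both are homozygous for different alleles; heterozygous and
missing calls are compatible with everything.  A phase-unaware IBS
segment is a maximal run free of incompatible sites, trimmed to the
outermost compatible sites, and reported when its map length reaches
`min_len_cM` and it spans at least `min_snps` SNPs called in **both**
kits.  The jointly-called convention for the SNP count is forced by the
missing-key-bait decode: a bait whose key site is missing must produce a
segment spanning exactly one fewer counted SNP than its called sibling.

Trimming to the outermost compatible sites is the conservative reading
of "halted exactly at the first incompatible homozygous site on each
side": the reported interval contains only sites that are actually
compatible, and its cM length is measured between those sites.  The
alternative (measuring up to the breaking sites) would report slightly
longer segments; all guarantees below are stated for the trimmed form.

**Mismatch-bunch mode.**  Real services may forgive isolated opposite
homozygotes as genotyping error.  The implemented rule: an incompatible
site terminates a segment only if fewer than `mismatch_bunch_limit`
jointly-called compatible SNPs separate it from the previous
incompatible site or the chromosome start.  An isolated mismatch deep
inside a well-supported run is forgiven; a mismatch whose support run is
short (for instance, a bait flank holding only 22 called SNPs against a
25-SNP limit) still breaks.  Strict mode — every incompatible site
breaks — is the default and is what all headline analyses use.

The phase-aware detector scans one haplotype against a kit: a run
continues while the haplotype's allele is contained in the kit's
genotype.  It is used for haplotype-resolved tiling and as the model of
the phase-aware countermeasure.

## Synthetic data and the truth ledger

The generator emulates an array cohort, not a population-genetic
process:

- **Panel.**  Site positions are uniform draws over the chromosome; map
  coordinates are sorted uniforms quantized to `cM_resolution`
  (default 0.01 cM — interpolated genetic maps have finite resolution,
  so several SNPs can share a map coordinate).  Minor-allele frequencies
  are uniform on [0.05, 0.5], mirroring common-variant ascertainment.
  Alleles are drawn from strand-unambiguous pairs.
- **Haplotypes.**  Independent Bernoulli(frequency) draws per site, plus
  explicit sharing: for each sampled haplotype pair, Poisson(`pair_rate`)
  segments with exponential cM lengths (scale `segment_scale_cM`,
  default 3 cM) and uniform placement are copied verbatim from one
  haplotype to the other and recorded in the ledger.  Once an interval
  has participated in a copy it is locked; proposals that would
  overwrite a locked interval are skipped.  Every ledger interval is
  therefore letter-identical between its haplotypes at the end of
  generation, making the ledger a sound truth set for sensitivity and
  accuracy measurements.  The skip rule censors proposals in proportion
  to local sharing density, so realized segment-length means run a few
  percent below the configured scale under heavy sharing; calibration
  checks use sparse configurations.
- **Kits.**  Unphased union of two haplotypes; missingness applied per
  genotype (arrays lose calls, not chromosome copies).

What this does *not* model: linkage disequilibrium, demography and
population structure, genotyping error beyond missingness, and
IBS-vs-IBD discrimination by LOD score.  Passing tests therefore
demonstrate the mechanics and combinatorics of the attacks and the
detector contract — not empirical coverage rates on real cohorts, which
depend on real haplotype-sharing distributions.

A deterministic `dense_grid_panel` generator provides worst-case-dense
scaffolds: sites every `spacing_cM` (dyadic spacings such as 1/64 cM
keep map arithmetic exact in floating point) with a configurable number
of SNPs per map position, as happens on real data wherever SNP density
exceeds map resolution.

## Tiling

Each comparison genome is matched phase-aware against each target
haplotype; policy-surviving segments are unioned per haplotype on
half-open bp intervals.  IBS2 is the intersection of the two haplotype
tracks, IBS1+ their union, IBS1 the difference — so
`IBS1 + IBS2 = IBS1+` holds exactly by construction, and
`avg_hap_coverage = IBS1/2 + IBS2`.  Allele recovery attributes an
allele where a covering upload is homozygous; heterozygous coverers
leave the site "covered, allele-ambiguous".  Recovery fractions are
reported against both the full panel and the covered-site denominator.
Enlarging the comparison set can only add contributions, so per-
haplotype tracks and IBS1+ are monotone in sample size while IBS1 alone
may shrink as IBS2 grows.

## Probing

Anti-frequency filler draws each allele with probability one minus its
(floored at 0.10) frequency, so it is saturated with rare homozygotes.
The per-site probability that an inert call is an incompatible
homozygote against a Hardy-Weinberg genotype is
`q²(1−p)² + (1−q)²p²` with `q = 1 − max(p, 0.1)`, giving ≥ 0.12 per
site across the frequency range; the chance of a compatible run
surviving a chip-scale window decays geometrically.  Probes double a
source haplotype (homozygous) inside a symmetric cM window around the
focal site — 1.9 cM of real data for a 1-cM reporting threshold, 5.9 cM
for 3 cM — so a phase-unaware match requires the target to carry the
window haplotype.  Windows are symmetric because nothing in the problem
selects a side; asymmetric windows would trade sensitivity between the
flanks.  Sensitivity and precision are scored against ledger-derived
carrier truth, excluding probes built from the scored person's own
haplotypes.

## Baiting

Validity of a key-site plan is the reportability of the worst-case
segment around each key: the distances to the flanking key sites (or
chromosome ends) must sum to at least t.  Because the two distances
share the middle term this telescopes to `cM[k+1] − cM[k−1] ≥ t`, and
the placement routine enforces the slightly stronger *trimmed* form —
map distance from the site after key k−1 to the site before key k+1 —
because reported segments are trimmed to compatible sites.  Placement
is a left-to-right greedy over the two interleaved alternating chains,
with the first and last keys confined to `[start + t/2, end − t/2]`
(the ideal construction's end offsets; this also excludes degenerate
keys sitting exactly on a chromosome end, whose decode would hinge on
telomeric reporting behavior).  On dense panels the greedy is maximal:
`2⌊c/t⌋ − 1` keys when c is an exact multiple of t.  Nearest-target
snapping was rejected because its one-sided drift systematically
violates the spacing sum on finite panels.

Decoding: a key site covered against both called baits is heterozygous;
against exactly one, homozygous for that bait's key allele; against
neither, undetermined (flagged).  With the missing-key bait, equal
jointly-called SNP counts mean the target call is missing, a count one
higher for the called bait confirms a heterozygote.  The SNP-count
comparison is only meaningful when a reported segment covers a single
key site, i.e. with isolated bait regions (inert background between
flanks); the all-heterozygous parallel construction uses break-pattern
decoding only.

Repeated campaigns draw successive plans with all previously used key
sites excluded.  On a 100-cM chromosome at t = 1 cM, 50 disjoint
maximal plans of 199 key sites each require ~50 SNPs sharing each key
map position (plus same-position neighbours to make trimming lossless);
the acceptance configuration uses a 1/64-cM grid with 52 SNPs per
position (~3300 SNPs/cM, sequencing-scale density), yielding 9950
distinct genotypes = 99.5 per cM, each verified against simulation
truth.

## Countermeasure screens

- **Heterozygosity-run limit.**  The bypassable variant counts only
  consecutive heterozygous calls (missing breaks the run) — exactly the
  variant that het-with-missing bait flanks slip past.  The robust
  variant lets missing calls extend a run that contains at least one
  heterozygote, and rejects a strict superset of what the bypassable
  variant rejects.
- **Homozygous-upload block.**  Rejects kits with zero heterozygous
  calls among called sites.  Boundary limitation (documented and
  tested): a single heterozygote passes the strict rule.
- **Inert-segment screen.**  Sliding-window mean per-called-site
  genotype log-likelihood under panel frequencies with Hardy-Weinberg
  independence.  Anti-frequency filler minimizes this likelihood by
  construction.  The rejection threshold is calibrated as the lowest
  window score observed on simulated genuine kits minus a 30% relative
  margin — genuine uploads outside the calibration set keep headroom
  while inert windows sit far below.  The statistic is this package's
  own design; the countermeasure is named in the field without a
  prescribed method.
- **Policy countermeasures.**  Long reporting thresholds, location
  suppression (which zeroes parallel baiting but not single-site
  baiting or probing), match-count caps, and phase-aware detection
  (modeled by randomly phasing the upload's heterozygous runs, which
  destroys bait segments almost surely) are ReportPolicy/driver toggles.
  The effectiveness matrix quantifies each (countermeasure, attack)
  cell on one simulated world at a fixed seed.

## Numerical and scale choices

Problem sizes in the test suite (3,000–6,000-site panels, 60–80
haplotypes, 1,000 detector-oracle pairs, ≥10,000 decode combinations)
were chosen to exercise every guarantee at full strength while keeping
the suite around ten seconds.  Map arithmetic uses an absolute 1e-9 cM
tolerance for snapped-position comparisons; detector filters themselves
apply no tolerance.  Ties in match ranking break lexicographically by
kit id.  Degenerate inputs (empty plans, chromosomes shorter than t,
windows past a chromosome end) raise configuration errors or truncate
with a warning, as documented per function.
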