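# Methods

This note documents the models behind founderscan, the choices that were
genuinely open, and what the synthetic test bed does and does not show
about real data.

## Data model and QC

Phased diploid genotypes for one chromosome are held as a
`(2·n_samples, n_sites)` matrix coded 0 = ancestral, 1 = derived, with the
marker map as the coordinate authority. Allele orientation comes from the
VCF `AA` INFO tag when present; otherwise REF is treated as ancestral and a
loud warning is emitted, because the sign of iHS depends on orientation.
Coordinates are 1-based throughout; windows are half-open `[start, end)`.

Marker QC removes sites with call rate < 95% or an exact conditional
Hardy–Weinberg test p < 0.01 (both configurable). HWE is evaluated on
non-carrier samples only: the carrier set in a founder-mutation study is
ascertained, and ascertainment distorts genotype proportions regardless of
typing quality. Optional per-marker imputation-quality columns (`r2`,
`impute_acc`) are filtered when supplied and skipped otherwise. Residual
missing calls in surviving markers are imputed to the per-site major
allele — a deterministic rule, chosen because the EHH machinery requires
complete haplotypes and the affected fraction after the call-rate filter is
small.

## Consensus haplotype

The consensus is the per-marker majority allele among carrier chromosomes
(the phase carrying the derived core allele; both phases for homozygotes),
extended outward from the core until majority support drops below a floor
(default 0.90, configurable; ties at 0.5 also stop extension). The floor
controls extension into recombinant territory; deviations inside the
retained interval are enumerated per chromosome and marker.

## Allele age from LD decay

Model: all carrier chromosomes descend from a single founder g generations
ago. A marker at recombination fraction θ from the core retains the founder
allele with probability (1−θ)^g per chromosome; a recombined chromosome
carries the population allele, frequency P_n. Hence

    E[P_m] = P_n + (1 − P_n)(1 − θ)^g,  i.e.  E[δ] = (1 − θ)^g,
    δ = (P_m − P_n) / (1 − P_n).

θ comes from the genetic map when present, else from physical distance at a
constant rate (default 1 cM/Mb) through Haldane's map function
θ = (1 − e^(−2d))/2. The per-marker inversion g = ln δ / ln(1 − θ) is
computed and reported for every marker.

Combining markers needed care. Two failure modes make the obvious
estimator — the unweighted mean of per-marker g over a high-support
consensus interval — collapse toward zero whenever the carrier clade is
small or recently expanded:

1. δ̂ saturates at exactly 1 near the core (observed P_m = 1 with tens of
   carriers), and ln(1) = 0 regardless of the true age;
2. carrier chromosomes are genealogically correlated: they share most of
   their meioses, so the number of effectively independent observations is
   the number of distinct carrier *lineages*, not chromosomes, and a
   recombinant lineage that drifted past 50% of carriers hijacks a naive
   per-marker majority consensus.

The fitted estimator therefore

- tracks, at every marker, the majority allele **within the modal
  lineage** — carriers are grouped into lineages by exact haplotype
  identity within ±1 Mb of the core (configurable), and the largest group
  defines the tracked (founder-proxy) allele;
- estimates ĝ by least squares on the whole decay curve,
  δ_m ≈ (1 − θ_m)^g, over all markers with defined δ (δ ≤ 0 values stay in
  the fit as noise around zero rather than being truncated);
- sets the 95% CI by percentile bootstrap over lineage groups. With k
  lineages the interval reflects k independent-ish draws from the founder
  genealogy; at k = 1 the interval is degenerate and the summary warns that
  the data cannot see the age (a clade of identical chromosomes is
  compatible with any recent age).

Per-marker δ, θ and g remain in the result table, so the classic
single-marker arithmetic is always available. Markers with P_n = 1 or
θ = 0 are excluded; fewer than 3 usable markers is an error. Calendar
conversion multiplies by a generation time (default 30 years).

What the CI does *not* capture: with very few lineages the lineage
bootstrap still underestimates between-replicate variance; simulation shows
95% nominal intervals covering a true 40-generation age in ~19/20 panels at
the default study conditions, with failures confined to single-lineage
clades.

## EHH, iHS and windowed significance

EHH for an allele class is the probability that two randomly drawn class
chromosomes are identical over all sites between the core and the current
site: Σ_h C(n_h,2)/C(n,2) over the partition into extended haplotypes,
computed by incremental partition refinement (with a compiled kernel;
a pure-numpy reference path is kept and cross-checked against a brute-force
pair-counting oracle in the tests). Extension stops when EHH < 0.05
(configurable), at the chromosome end, or across an inter-marker gap larger
than 200 kb (gaps would otherwise contribute unsupported area).

iHHA/iHHD are trapezoidal areas against genetic distance (cM when mapped,
else Mb at constant rate), left plus right; the final sub-threshold segment
is included up to the linear interpolated crossing of the truncation level,
which reduces sensitivity to marker density. Sites with derived count < 2
or > n−2 are unscorable. ln(iHHA/iHHD) is standardized within
derived-allele-frequency bins (50 equal-width bins on (0,1), adjacent bins
merged left-to-right until each holds ≥ 20 scorable sites, population SD);
each bin then has mean 0 and variance 1 by construction. A bin with zero
spread leaves its sites unscorable rather than dividing by zero.

Window testing tiles the region with 0.25 Mb windows every 0.20 Mb
(half-open, configurable) and scores each window by its mean |iHS|
(alternative: proportion of sites above 2.5). Significance uses the add-one
estimator p = (1 + #{null ≥ obs})/(n_boot + 1) under one of two nulls:

- `sites` — classic resampling of individual |iHS| values from the
  chromosome-wide pool excluding the window's own sites. This matches the
  field's common practice but is **anti-conservative under LD**: iHS values
  of neighbouring sites are strongly correlated, so real window means are
  overdispersed relative to an i.i.d. null. On neutral simulated panels,
  13–27% of disjoint windows reach p < 0.05 at nominal 5%.
- `blocks` — placement null: the window statistic is compared with the same
  statistic over contiguous runs of equally many scorable sites at random
  (circular) positions along the chromosome. Window placement is
  exchangeable under neutrality, so this null is calibrated by construction
  (measured 5.2% of neutral disjoint windows at p < 0.05).

The default stays `sites` for continuity with standard chromosome-wide iHS
bootstraps; calibration-sensitive analyses should use `blocks`, and the
package's own acceptance checks do.

Cluster detection reports maximal runs of sites with |iHS| above a
threshold (default 2.5), merging runs separated by less than a join gap and
discarding runs below a minimum site count. The stratified rescan removes
every chromosome carrying any of a list of tag alleles (e.g.
inflammatory-disease-associated variants), reruns the full iHS pipeline on
the remaining haplotypes (a haploid view, since phases no longer pair), and
reports paired window results with common random numbers, so an empty
exclusion list reproduces identical p-values.

## Clades

Haplotypes are rendered as nucleotide strings through the marker map before
distance computation. TN93 distances use the closed form with the two
transition classes and pooled empirical base frequencies; sites with
non-ACGT symbols are pairwise-deleted, vanishing-frequency terms drop out,
and saturated pairs are reported at a configurable ceiling with a flag.
Neighbor joining is the classical algorithm with deterministic tie-breaking
(first minimal pair in label order) and negative branch lengths clamped to
zero with the deficit moved to the sibling, preserving the joined pair's
path length. The clade partition itself is read off five signature SNPs
against configurable allele patterns (bracketed positions accept either
allele); distance trees are supporting output, not the partition authority
— which is why a distance method suffices here in place of a
maximum-likelihood search.

## Enrichment

Allele frequencies are simple count ratios; fold enrichment is their ratio
(continuity-corrected variant behind a flag, never default); the
two-population comparison uses the two-sided Fisher exact test by
point-probability summation (mid-p variant behind a flag), delegated to
scipy and checked against exact-fraction enumeration in the tests.

## The synthetic test bed

`synthdata.simulate_panel` is a forward-time diploid Wright–Fisher
simulator chosen over a coalescent because the founder haplotype, its exact
age, and the per-generation frequency trajectory are tracked directly, and
panels at the scales used here run in about a second.

- **Founding panel**: Li-Stephens-style first-order template copying. A
  20-haplotype seed set is drawn site-independently at frequencies
  f_j ~ Uniform(0.05, 0.5); each further haplotype copies a mosaic of the
  haplotypes before it, keeping its template with probability 0.9 per site.
  Association between adjacent sites decays geometrically with the switch
  rate while allele classes keep internal mosaic diversity. (A latent-state
  copula was tried first and rejected: it makes every minor allele a single
  perfectly associated haplotype class, which mimics a sweep at every
  low-frequency site and blinds the standardized iHS to real sweeps.)
- **Dynamics**: discrete generations, fitness-weighted parent sampling
  (1, 1+s, 1+2s by core genotype), one gamete per offspring chromosome with
  Poisson(r·L) crossovers at uniform positions (default r = 10⁻⁸/bp
  = 1 cM/Mb over 4 Mb).
- **Founder introduction**: the derived core allele is placed on one
  chromosome exactly `founder_age_gen` generations before sampling
  (default 40) and conditioned on survival by rejection with fresh child
  seeds; the attempt count is recorded. `min_carrier_copies` strengthens
  the conditioning (default 1 = plain survival; analyses that require a
  datable clade condition on ≥ 2, since a single surviving chromosome
  cannot define a consensus).
- **Truth**: founder haplotype, true age, trajectory (starting at 1/2N),
  carrier ids; `emit_vcf` writes a byte-stable phased VCF with the AA tag,
  flipping REF/ALT orientation at ~20% of sites so orientation recovery is
  genuinely exercised.
- **Ascertainment**: `ascertain_case_control` builds a study-style panel —
  every carrier plus non-carriers drawn to a target carrier fraction
  (default 232/755 ≈ 31%, the composition of a carrier-enriched clinical
  cohort). Haplotype-based selection scans owe their power at low
  population frequencies to exactly this enrichment.

**Study conditions.** Age-recovery experiments use the default geometry
(500 diploids, 1000 sites, 4 Mb, 1 cM/Mb) with s = 0.08 — a selection
strength that mimics the observed frequency enrichment of the motivating
allele and keeps the surviving clade large enough to date. Selection-scan
experiments use a chromosome-scale geometry (40 Mb, 2000 sites): a
40-generation sweep at 1 cM/Mb spans 1–2 Mb, so in a 4 Mb region the sweep
*is* the chromosome and chromosome-wide standardization would absorb it by
construction; at 40 Mb the locus occupies a few percent of sites, as in a
real chromosome-scale scan.

**What passing tests do and do not show.** The generator reproduces the
qualitative structure the analyses rely on — a conserved carrier haplotype
eroding at the map-predicted rate, background LD, frequency-dependent
haplotype lengths — but not real demography (growth, bottlenecks,
admixture, consanguinity), recurrent mutation, genotyping error, or
imputation artifacts. Parameter recovery on these panels shows internal
consistency of model and estimator, not field accuracy on human cohorts.
Detectability of selection is intrinsically limited by the conditioned
trajectory: a founder lineage that survives 40 generations at s = 0.08 but
stalls at ~1% population frequency leaves little haplotype signal even in
an ascertained panel, and such replicates are a substantial minority; the
paired detection rate on simulated panels is accordingly around 80%, with
the neutral calibration of the placement null at the nominal 5%.

## Numerical details

- Exact HWE test in log-space via `gammaln`, summing configurations no more
  probable than observed (ties included with a 1e-12 relative guard).
- Degenerate standardization bins detected at SD ≤ 1e-12·max(1, |mean|).
- Bootstrap p-values use the add-one estimator, never exactly 0.
- The pipeline fans one global seed into per-stage child seeds
  (`SeedSequence.spawn`), so stages are independently reproducible; rerun
  with the same manifest reproduces every output byte-for-byte.
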