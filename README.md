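# founderscan

Haplotype analyses around a founder mutation: consensus carrier-haplotype
construction *in cis*, allele-age dating from the recombinational decay of
linkage disequilibrium, EHH/iHS positive-selection scanning with windowed
bootstrap significance and marker-stratified re-testing, distance-based
haplotype clade partitioning *in trans*, and a forward Wright–Fisher
simulator that produces phased panels containing a founder allele of known
age and selection intensity — the test bed for every analysis.

The package is aimed at statistical geneticists studying recent founder
mutations (the motivating case is a dominant disease allele at ~1%
background frequency in a North African population, carried on a single
conserved haplotype): given phased genotypes for one chromosome, a marker
map, a designated core site and carrier status per sample, it answers *how
old is the mutation?* and *is the surrounding haplotype under positive
selection?*

## The statistics

**Allele age from LD decay.** Carrier chromosomes descend from one founder.
At a marker with recombination fraction θ from the core (Haldane map from
genetic or physical distance), the excess sharing of the founder allele,

    δ = (P_m − P_n) / (1 − P_n),

with `P_m`/`P_n` the allele frequency on carrier/non-carrier chromosomes,
decays in expectation as (1 − θ)^g over g generations. Each marker gives
g = ln δ / ln(1 − θ); the model combines markers by least-squares fitting
of the whole decay curve and sets a 95% CI by percentile bootstrap over
carrier *lineages* (distinct near-core carrier haplotypes), which keeps the
interval honest when the carrier clade is small or recently expanded.

**EHH / iHS.** For each core site, extended haplotype homozygosity
EHH = Σ_h C(n_h,2) / C(n,2) is traced outward for the ancestral and derived
allele classes until it decays below 0.05; the areas under the two curves
(iHHA, iHHD) give the unstandardized score ln(iHHA/iHHD), standardized to
mean 0 / variance 1 within derived-allele-frequency bins chromosome-wide.
Window significance comes from bootstrap resampling of the chromosome-wide
|iHS| pool — either the classic per-site resampling, or a calibrated
contiguous-placement null that preserves local LD.

**Clades.** Haplotypes *in trans* are partitioned by signature-SNP patterns
(with TN93 distances and neighbor joining available for tree building), and
two-population allele-frequency comparisons (fold enrichment, Fisher exact
test) quantify local enrichment of the core allele.

## Worked example

```python
from founderscan import SimConfig, simulate_panel, AlleleAgeModel
from founderscan.synthdata import core_site_of

# a 4 Mb phased panel of 500 diploids; the founder allele is 40
# generations old and carries an 8% additive fitness advantage
hm, mm, truth = simulate_panel(SimConfig(seed=1, selection_s=0.08))
result = AlleleAgeModel(hm, mm, core_site_of(mm)).fit(seed=2)
print(result.summary())
```

```
Allele age estimate (LD decay)
==============================================
markers used / total     930 / 999
carrier chromosomes      45
carrier lineages         7
age (generations)        15.2  [95% CI 8.5-128.9]
generation time (years)  30
age (years)              455  [95% CI 255-3866]
```

The 95% interval covers the simulated truth of 40 generations. The point
estimate is noisy by nature — 45 carrier chromosomes fall into only 7
distinct lineages, so the data carry roughly 7 independent observations of
the founder's recombinational erosion — and the lineage bootstrap makes the
interval honestly wide; across 20 such panels the interval covers the true
age about 95% of the time (see `scripts/acceptance.py`).

The same objects drive the scan:

```python
from founderscan import IhsScan, make_windows, window_bootstrap
scan = IhsScan(hm, mm).fit()
print(scan.summary())                     # sites scored, mean |iHS|, tails
windows = make_windows(0.0, 4.0, 0.25, 0.20)
res = window_bootstrap(scan.table, windows, n_boot=100_000, seed=3)
```

A command-line interface mirrors the library (`founderscan simulate | qc |
age | ihs | scan | clades | enrich | run-all`); `run-all` chains the whole
pipeline and writes per-stage reports plus a reproducibility manifest.

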