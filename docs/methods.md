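# Methods

`admixbreed` re-creates, at desk scale, the genomic characterization of a
recently founded hybrid breed: a wolf x dog cross-breed with a recorded
pedigree, a handful of wild founders, and a closed studbook. Because the
SNP-chip genotypes of such studies are not redistributable, the package
pairs every estimator with a forward-in-time simulator that produces
genotypes, phased haplotypes, the full pedigree and exact ground-truth local
ancestry, so every claim the package makes is tested against truth it can
compute.

## The simulator

**Founder gene pools.** Per site, an ancestral allele frequency is drawn
from Beta(0.8, 0.8) (clipped to [0.02, 0.98]) and each parental population's
frequency from the Balding–Nichols distribution
Beta(c·p, c·(1−p)) with c = (1−F)/F. For two populations this makes the
expected pairwise F_ST between them equal the divergence parameter F
(default 0.35, the wolf-vs-shepherd regime); a test checks the realized
Weir–Cockerham estimate lands in [0.30, 0.40]. Founder haplotypes are drawn
independently per site — there is **no background LD**. All LD in the breed
therefore arises from admixture and drift, which is exactly the signal the
dating methods exploit, and which keeps their behaviour interpretable.

**Sampled parental individuals** carry site-wise autozygosity (two alleles
identical by descent with probability 0.08 for wolves, 0.16 for dogs),
mirroring the inbreeding of real wolf populations and working-dog breeds.
Without it a Hardy–Weinberg parental panel would be more heterozygous than
any admixed breed can be, inverting the breed-vs-parent heterozygosity
contrast that real data show. Because the autozygosity is site-wise, the
parental samples do not carry realistic long ROH tracts; parental ROH
statistics reflect only chance homozygosity and should be read as a floor.

**Breeding schedule.** Events are per-generation: `found_f1` (every
offspring is a wolf x dog F1), `wolf_introgression` (one new wild founder
parents a fraction of the generation — a single registered wolf, as in the
historical record), `dog_backcross` (new domestic founders, one per
litter-sized batch of ~5 offspring, parent a fraction of the generation) and
`closed_breeding`. Sires are drawn with Dirichlet-weighted usage
(concentration 1.0 by default), modelling the popular-sire effect. The
default schedule founds the F1 in 1958, backcrosses to the domestic parent
in generations 2, 4, 6, 7, takes single wolf introgressions in generations
1, 3, 5, 8 (≈1960, 1968, 1974, 1983 at 3 years/generation), and breeds
closed to generation 18 (sampling ≈2012) with the census declining 40 → 20.
The pedigree expectation of wolf ancestry at sampling is ≈0.28–0.31 and
pedigree COI of the sampled cohort sits around 0.2 — both in the regime
reported for the real breed. The per-generation census values are free
parameters of the simulator, not estimates of the true studbook.

**Meiosis.** Crossovers are Poisson with mean equal to the chromosome's
genetic length (default map: linear, 100 Mb = 1 Morgan), positions uniform
in genetic distance, no interference. Ancestry segments are spliced exactly,
so per-haplotype truth tracks tile each chromosome without gaps and
`truth_q` is the exact wolf-origin fraction of the genome. No mutation
occurs during the simulated generations: the expected new-variant fraction
over the breed's life, p = mu x generations x N_E = 1e-8 x 20 x 20,000 =
0.004, is negligible.

**Scale.** The default genome is 5 chromosomes x 50 Mb with 2,000 evenly
spaced SNPs each (10k sites) and 12 + 12 parental reference individuals —
sized so the full pipeline runs in well under a minute and the test suite's
twenty-seed directional batteries in a few minutes. A 38-autosome preset
exists for demonstrations. Simulated missingness defaults to 3% per call in
the pipeline (typical pre-QC array regime); the injection operation itself
takes any rate in [0, 1).

## Filtering cascade

Sex-chromosome removal (labels X/Y plus a configurable alias list including
"39"); call-rate filtering at threshold 0.95 with *samples first, then
sites*, reading "call rate ≤ 95%" literally (a rate exactly at the threshold
is removed); LD pruning with 50-SNP windows stepping by 5 at genotypic
r² > 0.2 — greedy left-to-right, removing the lower-call-rate site of an
offending pair (ties: the later site), with passes repeated to a fixpoint so
the operation is idempotent; and an optional complete-case step keeping only
sites with zero missing calls.

## Statistics

* **H_o** — fraction of called sites heterozygous; group value is the mean
  over members.
* **Individual F** — method of moments,
  (observed hom − expected hom) / (called polymorphic sites − expected hom),
  with expected homozygosity from the sample's own group frequencies.
* **F_ST** — Weir & Cockerham (1984) per-site variance components; the
  genome-wide value is the ratio of summed components (ratio of averages),
  and per-site theta values (which may be negative) are retained untruncated
  for marker selection.
* **PCA** — SVD of the per-site mean-imputed, centered dosage matrix; plain
  centering by default (the additive model), frequency standardization
  behind a flag.
* **LD r²** — squared Pearson correlation of 0/1/2 dosages over samples
  called at both sites (genotypic association, not haplotype r²).
* **IBD pi-hat** — PLINK-style method-of-moments IBS→IBD with
  finite-sample-corrected frequency moments (falling-factorial estimators),
  P(IBD = 0/1/2) clipped and normalized, pi-hat = P1/2 + P2; pairs with
  fewer than 100 shared called sites are flagged low-confidence.
* **Pedigree** — tabular recursive kinship; COI = kinship of parents;
  COR = 2f(i,j)/sqrt((1+COI_i)(1+COI_j)) (Wright), with the raw numerator
  relationship 2f available behind a flag since pedigree software differs.

## Runs of homozygosity

The declared scan contract (array-vendor defaults for such scans are rarely
published, so this package states its own): a run is grown greedily left to
right while it contains at most 1 heterozygous and 2 missing calls and no
inter-SNP gap above 1 Mb; on violation the run is closed, trimmed to called
homozygous endpoints, kept if it spans ≥ 25 SNPs and ≥ 500 kb, and the scan
restarts after the violating site, so runs never overlap. Coordinates are
first-to-last SNP positions. F_ROH divides total run length by the
SNP-covered genome length (sum per chromosome of last − first SNP).
Defaults resolve the 1–7 Mb ROH regime of dense canine arrays and are all
config-exposed. Shared-ROH regions are the interval intersection of
per-sample ROH unions across a cohort.

## Local ancestry

Haplotypes are cut into non-overlapping blocks of 10 consecutive SNPs
(trailing partial blocks dropped). Per block, a PCA over the pooled parental
haplotypes gives a 1-D score; the parental classes are modelled as Gaussians
with a common SD (floored at 1e-3), and blocks whose class means are closer
than 0.5 pooled SD are flagged uninformative. A query block's posterior
P(wolf) comes from the two class likelihoods; an optional two-state HMM
(forward–backward) smooths along each chromosome with switch probability
1 − exp(−g·d), d the inter-block genetic distance and g a prior of 10
generations, capped at 0.5. Hard calls require posterior > 0.8, else the
block is uncalled. This is a deliberately minimal PCA-based deconvolution —
one component, shared-variance Gaussians — and its adequacy is gated by
tests: >95% block accuracy and mean |q̂ − truth| < 0.03 on the default
simulation (measured ≈99.5% and ≈0.003).

Global ancestry q is the wolf fraction of called blocks (also reported
length-weighted); a supervised maximum-likelihood q (1-D bounded
optimization of the binomial dosage likelihood under mixed frequencies
q·p_wolf + (1−q)·p_dog, frequencies clipped by 1/(2n+1), tolerance 1e-6)
serves as the assignment-test stand-in. Switch counts compare adjacent
called blocks per haplotype per chromosome, skipping uncalled blocks.

## Dating

* **N_E trajectory.** Within-chromosome SNP pairs are binned by genetic
  distance with edges c = 1/(2t), t = 1..20 (the Hayes/Sved mapping of
  distance to look-back time), and each bin inverts
  E(r²) = 1/(1 + 4·N_E·c) + 1/n at its mean distance. Because the package's
  r² is the squared correlation of *unphased dosages*, the finite-sample
  floor between unlinked loci is ≈ 1/N for N individuals (not 1/(2N) as for
  haplotype r²), so n = number of individuals. This choice is validated
  against a constant-size coalescent simulation: all bins t ∈ [1, 20]
  recover N_E = 100 within a factor ~1.5, while the 2N convention fails by
  more than factor 2 at short look-back times. Bins with mean r² ≤ 1/n are
  reported NaN, never fabricated.
* **Weighted-LD decay.** Per pair, the breed's dosage covariance times the
  parental frequency contrasts (p_wolf − p_dog) at both sites, averaged in
  genetic-distance bins (default 0.002–0.25 M, 30 bins), fit by nonlinear
  least squares to a·exp(−g·d) + k (starts: g = 10, a = first bin minus
  tail, k = tail mean); CI by percentile bootstrap over chromosomes
  (resampling precomputed per-chromosome bin components). With admixture
  arriving in several pulses, the fitted g estimates the pulse-weighted mean
  age of the events (founding weight 1, later events their outcross
  fraction), the quantity the recovery test checks to ±30%.
* **Switch dating.** g = 1 + S / (4·L·q·(1−q)) with S the diploid junction
  count, L the map length in Morgans and q the admixture fraction — a
  deliberately simple declared form isolated in one function for easy
  substitution. For an F1-founded cohort it runs ≈ +1 generation high at
  small g (the first post-F1 meiosis creates junctions at rate 1 per
  Morgan, not 2q(1−q), because F1 haplotype ancestries are perfectly
  anti-correlated); the calibration test therefore asserts the pooled median
  relative error over true ages {3, 6, 10, 15} ≤ 25%.
* **Calendar conversion** uses 3 years/generation and requires an explicit
  reference (sampling) year.

## Outlier panels

Panel 1: blocks called the same ancestry in every haplotype of every breed
individual (any uncalled haplotype excludes the block). Panel 2: shared-ROH
regions. Panel 3: among SNPs fixed for opposite alleles in the two parents
(per-site parental F_ST = 1 on called chromosomes), the lowest-1%-quantile
of breed-vs-parent F_ST per contrast, for single SNPs or 10-SNP blocks
scored by mean theta; ties at the boundary are all retained, and a site
where the breed is fixed for the same allele as a parent scores 0 (WC theta
is undefined for a monomorphic pair, but identical fixation is zero
differentiation). Hits are expanded by ±50 kb (clipped to chromosome
bounds, half-open BED coordinates, merging optional) and consolidated by
within-direction interval overlap into records listing every contributing
method; records of conflicting direction stay separate and are flagged.

## What passing tests do and do not show

The simulator reproduces the *mechanisms* — admixture-boosted
heterozygosity, long breed ROHs, junction accumulation, admixture LD,
declining LD-based N_E — not the magnitudes of any particular real
dataset: founder counts are tiny, the genome is 250 Mb, and founders carry
no background LD or ascertainment bias. Accordingly the directional
batteries (breed ROH longer than parental; dog-fixed blocks outnumber
wolf-fixed at q < 0.5; F_ROH–COI and pi-hat–COR correlations positive) are
asserted as directions over 20 seeds, not as magnitudes. Two known
limitations: (1) a single introgression pulse does **not** produce a local
peak in the estimated N_E trajectory here — the admixture-LD inflation of
r² cancels the new-haplotype effect when the pulse is one migrant without
background LD, whereas real crossings coincided with census growth; the
trajectory is still computed and reported. (2) Parental panels lack tract-
level autozygosity (site-wise only), so parental ROH lengths are not
calibrated to real populations.

## Numerical conventions

Missing calls are −1 internally and NaN in dosage space; positions are
1-based in PED/MAP and the site table, 0-based half-open in BED output.
PED text carries no allele columns, so alleles are assigned lexically on
read and a site never observed carrying allele1 re-polarizes on a round
trip (equivalent genotypes, flipped coding). All randomness flows from
integer seeds through `numpy.random.default_rng`; the pipeline derives
per-stage seeds as (seed x 1000003 + stage index) mod 2^31 so stages can be
rerun in isolation, and identical seeds give bit-identical results.
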