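# Methods

This note documents the models, estimators and numerical choices behind
herdscan, the assumptions each one makes, and what the synthetic-data tests
do and do not establish.

## Cohort representation

Genotypes are alt-allele dosages (0/1/2) with a distinct missing sentinel
that is never imputed; phased data additionally carry a haplotype matrix
with two columns per sample.  Coordinates are 1-based inclusive everywhere
a user sees them; BED import/export converts to 0-based half-open in a
single, property-tested place (`pipeline.to_bed` / `from_bed`).  Variants
must be strictly sorted within chromosome blocks — every windowed statistic
relies on that.

## Differentiation (Hudson F_ST)

Per site, with alt frequencies p₁, p₂ and called allele counts n₁, n₂:

    N = (p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1)
    D = p₁q₂ + p₂q₁

and all aggregation — genome-wide, per pair, per window — is the ratio of
sums ΣN/ΣD (ratio of averages).  The average-of-ratios alternative is
biased at low-frequency sites and is deliberately not offered.  Sites with
fewer than two called alleles in either population contribute N = D = 0 and
drop out.  Pairwise comparisons are computed on the variants segregating in
the pool of the two populations, each pair on its own subset.

Windowed F_ST uses 10-kb tiling windows and discards windows with fewer
than five usable variants.  Top-region extraction selects the
⌈top_fraction·N⌉ highest windows ("top 0.01 percentile" is read as the top
10⁻⁴ fraction, which on 250,000 windows yields 25), reports the smallest
selected value as the threshold, and merges windows that tile consecutively.
Negative window values are not excluded before selection.

## Nucleotide diversity and heterozygosity

π per site is the mean pairwise allele difference n_ref·n_alt/C(n,2) =
2pq·n/(n−1); window values divide the site sum by the window width in bp
and are expressed in percent (×100).  Windows with no usable site count as
zero and are *included* in chromosome and genome means/medians (the windows
tile the genome; excluding empty windows is an option).

Per-individual H_o, H_e and F_Hom are computed against a fixed external
variant denominator (defaulting to the cohort variant count) so that breeds
genotyped on one shared variant set stay comparable; expected homozygosity
per called site is 1 − 2pq·n/(n−1) with frequencies taken within the focal
population by default (`freq_scope="cohort"` switches to cohort-wide
frequencies; which scope the original per-individual tools use is
tool-dependent, and breed-level H_e is the biologically intended quantity
here).  Breed values are unweighted means over individuals.  The H_o-vs-H_e
test is a 1-df goodness-of-fit χ² on breed-summed het/hom counts; for a
two-cell table this equals the squared binomial z-score, so its type-I
error is nominal (verified by simulation).

## Runs of homozygosity

A two-state HMM over hard genotype calls, states HW (outbred) and AZ
(autozygous).  Emissions with f the site's alt frequency, ε the genotype
error rate and e′ an optional het-miscall mass folded into HW homozygote
classes (default 0):

    HW: P(het) = 2f(1−f);  P(hom-ref) = (1−f)² + f(1−f)e′;  P(hom-alt) = f² + f(1−f)e′
    AZ: P(het) = ε;        P(hom-ref) = (1−ε)(1−f);          P(hom-alt) = (1−ε)f

Missing genotypes emit 1 in both states; sites with no called allele in the
frequency source are skipped.  Between adjacent sites at distance d bp the
chain switches with P(HW→AZ) = 1−exp(−α·d) and P(AZ→HW) = 1−exp(−β·d);
defaults α = 6.6×10⁻⁹/bp and β = 10⁻⁸/bp (the 1 cM/Mb recombination-rate
convention), initial probabilities from the rate-balance stationary
distribution.  Viterbi decoding defines segments (first to last AZ site);
forward–backward posteriors provide a per-segment mean quality.  The exact
parameterisation of the widely used external caller is not published, so
correctness is defined by truth-recovery on planted autozygosity, not
bit-compatibility: on gridded 1-SNP/kb cohorts with planted segments the
caller reaches 100 % planted-base sensitivity, ≲0.2 % false-positive bases
and a **median** boundary error of one marker spacing.  A per-boundary
maximum below one spacing is unattainable for *any* decoder: outside a true
segment the evidence against autozygosity arrives only at the first
heterozygous marker, so the per-boundary overshoot is geometric with mean
(1−h)/h marker spacings (h ≈ 0.36 het rate under the default allele
frequency law).  The median is therefore the statistic tested.

F_RoH sums segment lengths at least as long as each minimum-length class
{50 kb, 100 kb, 1 Mb, 2 Mb, 4 Mb} and divides by the SNP-covered genome
length (default 2,487,849,970 bp, the cattle autosome figure; always
override for synthetic genomes).  RoH islands: per variant, the fraction of
a population's animals with a covering segment; the ⌈0.0005·N⌉ highest
frequencies define membership (threshold = smallest member, ties at the
threshold included); member SNPs within 100 kb (configurable — no merge
distance is standard) merge into islands, recording the largest internal
gap.  Island frequencies use all called segments; restricting to a minimum
length class is an option.

## XP-EHH

Site-EHH (population-level, allele-agnostic): haplotypes are partitioned by
their allele string from the core outward; EHHS(x) = Σn_k(n_k−1)/(n(n−1))
normalised to 1 at the core, non-increasing by construction.  Haplotypes
hitting a missing allele leave the partition from that extension onward.
iES integrates EHHS over physical distance (no genetic map is assumed) with
the trapezoid rule, each side truncated at the linearly interpolated
crossing of the 0.05 cutoff; at a chromosome edge the integral simply stops
at the last variant.  The score is ln iES_A − ln iES_B — the difference of
logs rather than the log of the ratio, which makes the A/B swap antisymmetry
bit-exact — standardised genome-wide over all scanned cores without
frequency binning.  Two-sided normal p-values are Bonferroni-corrected over
the scanned-core count; consecutive significant cores of one sign merge
into regions (no maximum gap: "neighbouring" means adjacent scan rows).

A caution the tests encode: because standardisation is genome-wide, a
planted sweep occupying a sizeable fraction of the scanned cores inflates
the score dispersion and can mask itself.  Detection worlds therefore keep
the swept interval a few percent of the genome, which is also the realistic
regime.

## Phylogeny, kinship, f3

Manhattan distances between animals sum |dosage differences| over
pairwise-complete sites and rescale by (total sites / complete sites);
UPGMA merges the closest pair at height d/2 with size-weighted average
linkage, ties broken by the lexicographically smallest pair of cluster
representative labels (representative = smallest member label) so trees are
deterministic.  Breed curation keeps, per breed, the largest clade whose
leaves are all of that breed (ties again by smallest label), removes that
breed's other animals, and collapses surviving clades to breed-labelled
leaves.  Newick branch lengths are height differences written at full
precision; round-trips are lossless to well under 1e−9.

The GRM is VanRaden method 1 (dosages centred by 2p, cross-product scaled
by 2Σp(1−p), monomorphic sites excluded, missing dosages contributing zero
after centring).  Centring by sample frequencies forces the off-diagonal
mean to −1/(n−1), and the tests assert that exact expectation rather than
zero.  Least-related subset selection is greedy from a seeded random start,
repeatedly adding the animal with the smallest mean relationship to the
chosen set.

f3(C; A, B) averages (p_C−p_A)(p_C−p_B) − p_C q_C/(n_C−1) over usable
sites (bias correction for the target only); the SE is a delete-one block
jackknife over consecutive 10,000-variant blocks (the last block may be
short; blocks are equally weighted).  Because simulated sites are i.i.d.,
the block jackknife SE is also an estimate of the across-replicate SD, which
the tests verify to 20 %.

## Synthetic cohorts

The generator is a stated world, not a tuning knob.  Per site an ancestral
frequency is uniform on [0.05, 0.95] (the floor avoids monomorphic draws);
population frequencies follow the Balding–Nichols Beta distribution with
per-population drift F, under which Hudson's estimator converges to
(F_a+F_b)/2 — so target differentiation is known exactly.  Alleles are
i.i.d. Bernoulli given frequencies: there is **no background LD**, no
mutation model and no recombination map.  That choice keeps every oracle
exact (π, EHHS, F_ST) and suffices for parameter-recovery tests, but it
means green tests say nothing about behaviour under realistic LD, allele
frequency spectra or genotyping artefacts beyond the planted error models.
Site positions are uniform-random at the stated density by default; a
`grid` mode places them at exact 1/density spacing, used where a test's
tolerance is expressed in marker spacings.  Default scale (two populations
of 30 diploids, 10-Mb chromosome at 1 SNP/kb, F = 0.05) mirrors the
per-breed sample caps and the 0.03–0.08 differentiation range typical of
taurine cattle breeds, at desk-scale genome size.

Planted truth: autozygosity copies haplotype 1 over haplotype 2 inside
stated intervals, then flips genotypes to het with a given error rate;
sweeps copy one template haplotype onto a seeded fraction of a population's
haplotypes across [core−extent, core+extent].  Truth is recorded in JSON
next to the VCF fixture.

## Orchestration and determinism

`pipeline.run_config` executes stages in dependency order (filter →
prune/diversity/F_ST/RoH/tree/XP-EHH → regions → annotation) with one seed
for all randomness and a fixed float format for every table, so reruns are
byte-identical.  QTL annotation keeps intervals strictly shorter than 10 kb
with a recognised trait class {production, exterior, meat, milk, health,
reproduction}; gene hits are classed `inside` (overlapping the unflanked
region) or `flank` (only within the ±250-kb extension).  Flanked regions
that overlap each other are annotated independently.  Database retrieval is
replaced by local GFF3/BED inputs to keep everything offline-testable.

## Known limitations

- Hard genotype calls only: no genotype-likelihood emissions in the RoH
  HMM, no phasing, no variant calling or recalibration.
- LD pruning follows a documented greedy rule (drop the lower-MAF member of
  the worst pair, ties by later position); it is PLINK-*style*, not
  PLINK-identical.
- XP-EHH integrates in physical distance; with a genetic map the scores
  would differ in recombination-rate-variable regions.
- The simulator's independence of sites understates the window-to-window
  correlation of every windowed statistic on real data; empirical
  percentile thresholds are exact, but their sampling variability on real
  genomes is not modelled.
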