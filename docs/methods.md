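# Methods

This note documents the statistical models, the defaults and why they
were chosen, the numerical details, and what the synthetic data does and
does not emulate.

## Genotype model

Genotypes are diploid biallelic dosages: 0/1/2 copies of allele B, with
an explicit MISSING sentinel that is never imputed. Coordinates are
1-based physical bp throughout; distances are computed in bp and
reported in Mb/Kb. VCF input consumes only the GT field; phased and
unphased separators are both accepted and treated as unphased.
Half-missing PED genotypes become MISSING. PED carries no canonical
allele order, so the reader assigns allele A/B lexicographically per
marker; a column homozygous-alt in every sample exposes only one allele
and therefore cannot round-trip through PED (it re-reads as code 0) —
an inherent limitation of the format, not of the reader.

Founder panels must be (nearly) homozygous; founders with residual
heterozygosity above 1% are rejected at load rather than allowed to
corrupt HMM emissions. When aligning a colony to a founder panel,
markers are matched by id, allele labels reconciled by swap or strand
complement, and strand-ambiguous (A/T, C/G) markers with colony MAF in
(0.4, 0.6) are dropped because their orientation is undecidable;
ambiguous markers with a clear minor allele are oriented by matching
minor alleles.

## Inbreeding and diversity metrics

Per marker: MAF from plug-in allele frequencies over non-missing calls;
observed heterozygosity as the het fraction, averaged over markers. The
Hardy–Weinberg test is the exact conditional test: given the allele
counts and N, each heterozygote count h (same parity as the rare-allele
count) has probability proportional to N!/(n_AA! h! n_BB!)·2^h, and the
two-sided p sums every h whose probability does not exceed the observed
one. Monomorphic markers return p = 1 and are excluded from the
"% failing HWE" denominator by default (they cannot fail); the α for
that column defaults to 0.05 and is configurable, since the classical
presentation of this statistic leaves both choices open.

The individual inbreeding coefficient is
F = (O_hom − E_hom)/(L − E_hom) over the individual's non-missing calls
at colony-polymorphic markers, with E_hom = Σ(1 − 2p_j q_j) from
colony-level plug-in frequencies. F is reported ×100 and may be
negative (excess heterozygosity). Note the plug-in estimator is the
single-population convention: a sample measured against itself, not
against an external reference.

Suitability cut-offs: heterozygosity < 5% ⇒ almost inbred; 5–10% ⇒ low
heterozygosity; mean F% > 20 ⇒ strongly inbred; 10–20% ⇒ elevated. A
colony is flagged unusable for mapping when almost inbred, low-het, or
F% > 20.

## Linkage disequilibrium

Pairwise r² is the squared Pearson correlation of dosages over
pairwise-complete samples (composite/genotypic r²). This needs no
phasing and is deterministic; with unphased colony data it is the
natural estimator. The decay radius bins within-chromosome pairs by
distance (default 100 Kb bins, ≥ 10 pairs/bin), smooths binned means
with an isotonic non-increasing regression weighted by pair counts, and
takes the first 0.5 crossing by linear interpolation between bin
midpoints. Smoothing is required to make "drops below 0.5" well defined
when raw binned means are non-monotone; a curve that never crosses is
reported as "> span", one starting below 0.5 as "< first bin".

Blocks use the confidence-interval |D′| rule: two-SNP haplotype
frequencies by EM (50 iterations or Δlog-likelihood < 1e-8, initialized
at linkage equilibrium; only the double-heterozygote cell is phase
ambiguous), then a likelihood profile of |D′| on a 101-point grid with
allele frequencies fixed at their estimates, normalized into a
distribution whose 5th/95th cumulative points give the CI. A pair is in
strong LD when CI ∈ [0.70, 1] with upper ≥ 0.98, in strong
recombination when the upper bound < 0.90. Windows in which ≥ 95% of
informative pairs are strong-LD qualify; blocks are chosen greedily,
longest (bp) first, without overlap. Thresholds are configurable but
default to the standard values. Block output is BED (0-based
half-open, converted from the internal 1-based coordinates).

## Population structure

IBS distance = mean |dosage difference|/2 over pairwise-complete
markers. MDS is classical metric scaling (double-centering +
eigendecomposition), deterministic up to sign; signs are fixed by
making each axis's largest-magnitude loading positive. The structure
flag runs k-means (k ∈ {2,3,4}, 10 restarts, fixed seed) and compares
the best silhouette to 0.40. Silhouettes of k-means partitions of pure
noise are inflated in very low dimension, so the flag is evaluated on
the four leading MDS axes, where null colonies score ≈ 0.2 and planted
two-population mixtures ≈ 0.7. The threshold replaces a visual
judgement and is configurable.

F_ST is the Weir–Cockerham θ with loci combined as the ratio of summed
variance components (ratio-of-sums avoids small-sample bias relative to
averaging per-locus ratios). θ of a sample against itself is slightly
negative, about −1/(2n−1) under HWE — a property of the estimator, not
a bug. Colony trees are average-linkage agglomerative clustering on the
θ matrix (negative entries clamped to 0), with colonies pre-sorted
lexicographically so ties resolve deterministically; output serializes
to Newick.

The admixture model: individual i draws each of its 2 alleles at marker
j from ancestral population k with probability q_ik, and the allele is
B with probability p_kj, giving the binomial likelihood
Π_ij Binom(g_ij; 2, Σ_k q_ik p_kj). EM updates both Q and P; the
log-likelihood is non-decreasing every iteration (asserted in tests),
iterations cap at 10,000 with Δll < 1e-6 stopping, and the best of 5
random restarts is kept. P is clipped to [1e-6, 1−1e-6]. No LD thinning
is applied by default — dense markers in LD bias ancestry estimates, a
caveat the interface documents rather than hides.

## Founder-mosaic HMM

Hidden states are unordered founder pairs (S(S+1)/2) since genotypes
are unphased; computation runs in the ordered S² space where the
transition kernel factorizes per haplotype and one step costs two S×S
multiplications. Across an interval of genetic length d cM a haplotype
switches ancestry with probability r = 1 − e^{−G·d/100}, and a switch
lands on any of the S founders uniformly (so P(stay) = (1−r) + r/S); at
large d this reaches the uniform stationary distribution. The genetic
map is uniform at 0.5 cM/Mb by default (no hotspot data is assumed),
and G defaults to 30 expected breeding generations; both are
parameters, and the scans that consume the posteriors are insensitive
to moderate G error because it rescales all intervals jointly.

Emissions: founder allele-B probabilities are 0/1 for clean homozygous
calls and 0.5 for residual-het or missing founder calls; each
transmitted allele flips with error ε (default 0.01), and MISSING
observations emit 1 in every state. States are defined at marker loci
(emission at each marker, transitions between consecutive markers);
"interval" weights for genome-fraction summaries are the half-spans
around each marker. Forward–backward is scaled per marker; the forward
scaling product equals the backward-computed likelihood to 1e-8
(tested), and posteriors match exhaustive path enumeration to 1e-10 on
small instances. Founder contributions average posterior founder
dosages/2 over individuals with bp weights and are normalized to sum
to 1.

## QTL mapping

Traits are rank-inverse-normal transformed within colony (ties by
average rank) and standardized to mean 0, sd 1 — the concrete
realization of "transform to Gaussian deviates". Covariates pass a
one-way ANOVA screen at p < 0.01 (regression F for continuous ones);
retained categoricals enter as dummies, numerics standardized.

All scans are nested linear-model partial F tests computed by least
squares, with degrees of freedom taken from design-matrix ranks so
collinear or degenerate designs are handled explicitly: a term adding
no rank yields logP = 0 (e.g. conditioning a marker on itself), a
founder-dosage interval with no dosage variation is skipped with a
diagnostic. logP is capped at 300. Variance explained is the partial
R² = (RSS₀ − RSS₁)/RSS₀. The single-marker scan treats genotype as a
factor (up to 2 df); the conditional scan adds the conditioning
marker's factor to the covariates (missing conditioning genotypes form
their own level so samples are kept); the haplotype scan regresses on
the S expected founder dosages with one column dropped for
identifiability.

Region-wide 5% thresholds are the 95th percentile of the
per-permutation maximum logP over within-colony permutations of the
transformed trait (default 1,000), covariates staying attached to
samples — permuting within colony preserves colony-level trait
differences, the conservative choice for merged analyses. Scans accept
a matrix of trait columns so all permutations are processed by the same
vectorized code path.

The shared-effect test stacks colonies at one interval (the pooled-scan
peak by default, matching "test at the peak of association"): null =
covariates + colony + one shared set of founder dosages; full =
covariates + colony + colony-specific dosages; the partial F p-value is
returned. Non-rejection supports the same QTL alleles segregating in
every colony.

## Synthetic colonies

The simulator breeds diploid genomes forward in time from S synthetic
homozygous founders. Founder divergence d is the target mean pairwise
allele difference: per-marker frequencies are Beta(a, a) with
a = d/(1 − 2d) (so E[2pq] = d); d > 0.5 is possible only for two
founders via anti-correlated alleles. Defaults (S = 8, d = 0.3,
351 markers, N = 100, G = 30) mirror a mid-sized commercial colony
descended from a handful of laboratory strains.

Schemes: random pair mating; circular ring-neighbour mating; rotational
group mating (the named breeder rotation systems are idealized into
one); and IGS-style re-introgression, where a small reservoir
population (default 8) is bred in parallel and replaces a fraction
(default 0.5) of colony parents each generation — spreading few
chromosomes widely and inflating LD, as expected of such schemes.
Meiosis draws Poisson crossovers without interference on the same
uniform 0.5 cM/Mb map the HMM assumes, so recovery tests are internally
consistent. Genotype error flips each allele independently with rate ε
(matching the HMM emission model) and missingness masks calls at a
configurable rate. Truth records haplotype founder labels per marker,
the pedigree, length-weighted true founder fractions, the expected-
heterozygosity trajectory, and realized gamete counts per parent (from
which N_e is estimated as (N·k̄ − 2)/(k̄ − 1 + Var(k)/k̄)).

Phenotypes: trait = scaled genetic value + covariate effects + Gaussian
noise, with the genetic value standardized in-sample so the planted
variance share is exact in expectation. `marker_additive` uses the
pre-error dosage at the QTL marker (the most central clearly
polymorphic marker by default); `founder_allele` assigns per-founder
haplotype effects, enabling shared- versus colony-specific-effect
designs for the partial-F calibrations. Variant tables draw calls from
a catalogue plus novel positions at a set fraction, with Poisson depths
and uniform read-end/restriction-site distances.

What the simulator does not emulate: real founder haplotypes carry
internal ancestral LD, which the independent-marker founder model
omits — simulated baseline r² between linked markers is ≈ 1/S rather
than near 1, so LD-decay tests use two-founder colonies where the
baseline is high. There is no selection, no sex chromosomes, no litter
structure, and no breeder-specific protocol fidelity; passing tests
demonstrate correctness of the estimators under the stated model, not
calibration to any particular commercial colony.

## Problem sizes and numerical choices

The test suite exercises colonies of 20–500 individuals and 60–1,200
markers, 100–1,000 permutations, and 12–200 Monte-Carlo replicates per
calibration — sizes chosen so each statistical property is testable
with comfortable margins while the whole suite stays quick. Tolerances:
HMM oracle agreement 1e-10; posterior normalization 1e-9;
forward/backward likelihood 1e-8 relative; EM log-likelihood
monotonicity 1e-8; calibration bands as stated per test (e.g. type-I
error in [0.02, 0.09] at α = 0.05 over 200 replicates). All stochastic
steps take explicit seeds; identical seeds give bit-identical outputs.

## Known limitations

- The decay radius is undefined (and reported as such) when too few
  polymorphic pairs exist or the smoothed curve starts below 0.5.
- Admixture ancestry estimates are LD-biased without thinning; a
  one-marker-per-block thinning option is available.
- The HMM's uniform genetic map ignores hotspots, so haplotype-scan
  localization is block-level rather than marker-level.
- Sex chromosomes are not treated specially anywhere; all markers are
  assumed autosomal.
- No kinship/mixed-model correction in the scans; colonies flagged as
  structured should be interpreted with care.
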