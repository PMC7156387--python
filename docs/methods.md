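# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## CCF estimation and clonality

For a mutation observed with VAF `v` in a region of purity `ρ`, local
total tumour copy number `CN_t` and mutation multiplicity `m`,

    CCF = v · (ρ·CN_t + (1−ρ)·2) / (ρ·m).

Normal cells are assumed diploid at every somatic site (autosomes only;
the modelled cohort is female, and no X-ploidy handling is attempted).
Multiplicity is the rounded inversion of the same relation, clamped to
[1, major copy number]; a mutation observed inside a homozygous deletion
is an inconsistency and falls back to m = 1 with a warning. The 95%
interval is the Clopper–Pearson interval on alt/depth pushed through the
same linear map — it ignores uncertainty in purity and copy number, which
are treated as known inputs. CCF estimates above 1.5 indicate
misspecified inputs and are capped with a warning.

Presence is a two-stage rule emulating caller-plus-review practice: a
region is "called" at ≥5% VAF with ≥3 alt reads, and an uncalled region is
rescued if the variant was called elsewhere in the patient and reaches
≥1% VAF with ≥2 alt reads locally. The two-read guard exists because at
2000–3000× a single mismatching read clears 1% × depth far too easily.
Clonality within a compartment ("primary" / "metastasis") requires
presence in every region with CCF ≥ 0.8 and CI-upper ≥ 0.9 everywhere;
these cut-offs operationalise a verbal clonal/subclonal definition and are
exposed in `ClonalityConfig`. Contralateral-ovary regions count as
metastatic by default (a flag switches to three-way reporting).

## Mutation clustering

Mutations are clustered by a finite mixture over per-region binomial read
counts: cluster k has CCF centre c[k,r] per region, and a member variant's
alt count in region r is Binomial(depth, c[k,r]·f[i,r]) with f the
CCF→VAF factor above. Absent variants contribute their observed zero
counts at observed depth — absence is informative. The M-step solves a
weighted one-dimensional binomial MLE per (cluster, region) by bisection
(closed form when f is constant); EM runs from two k-means inits and two
random restarts (four total — the restart count was raised after observing
occasional local optima at the true k); k over a configurable range
(default 1–10) is selected by BIC with parameter count k·R + (k−1) and
sample size n = number of variants. Clusters below `min_cluster_size`
(default 3) are dissolved into the nearest surviving centre. Cluster ids
are assigned 1..k by descending total CCF, so the truncal cluster is
always id 1. Reported cluster means are responsibility- and
depth-weighted averages of per-variant CCF estimates, which keeps them
inside the convex hull of member CCFs per region.

This replaces the Dirichlet-process clustering used in the original
analysis workflow with a deterministic, dependency-light finite mixture
serving the same inferential role.

## Clone-tree search

Trees are rooted at the unique truncal cluster (CCF ≥ 0.8 in all
regions). The search enumerates parent assignments depth-first in
decreasing-CCF order under two hard constraints with tolerance 0.1 CCF:
containment (child ≤ parent per region) and the pigeonhole sum rule
(children of a node sum ≤ the node per region). Among valid trees the
winner minimises, lexicographically, (1) the total constraint violation
absorbed by the tolerance — summed per-region CCF excess of children over
parents and sibling sums over parents — and (2) the total containment
margin, so each clone attaches to the closest clone able to contain it.
Violation-first scoring matters: with noisy estimates, a tolerance-sized
containment breach under a wrong but tight "parent" would otherwise beat
the true, roomier parent. Remaining ties break on the lexicographically
smallest parent map, making the output deterministic. Exhaustive search
is capped at 12 clusters; beyond that a greedy closest-parent pass runs
with a warning.

## Molecular time and progression model

A cluster is shared when its mean CCF reaches 0.05 (config-exposed) in at
least one primary and one metastatic region. Molecular time is the
mutation-count-weighted fraction of clustered mutations in shared
clusters — weighting by mutations rather than clusters matches the
interpretation of divergence time as mutational "clock" progress; an
unweighted variant is available behind a flag. The denominator is all
clustered mutations of the patient (not primary-only), the more
symmetric reading of an ambiguous definition. Progression is linear
(late dissemination) at shared fraction ≥ 0.5, else parallel (early);
the 0.5 boundary is config-exposed.

## Parallel evolution and MSAI

A parallel-evolution event is one gene carrying ≥2 variants assigned to
clusters neither of which is an ancestor of the other. MSAI scans pairs
of overlapping segments from different regions that are both allelically
imbalanced (major ≠ minor) with known, opposite major-haplotype labels;
haplotype-unlabelled segments are skipped.

## Presence test (dissemination timing)

For each metastasis-private variant and each primary region, a one-sided
likelihood-ratio test compares a shared beta-binomial success rate (H0)
against metastasis rate > primary rate (H1), with overdispersion ρ
estimated once from ≥20 error-only control sites by the moment estimator
ρ̂ = (X² − n)/Σ(depth−1) floored at 0 (reducing to a binomial). Because
H1 touches the boundary, the null distribution of the statistic is the
half-mixture ½·χ²(1) + ½·δ(0); p = 1 when the unconstrained fit is already
ordered the wrong way. A variant significant against *every* primary
region is `late_supported`; anything less leaves `early_possible`. Raw
p-values at α = 0.05 are the default, matching the reporting convention
of the emulated analysis; `adjust_bh` applies Benjamini–Hochberg across a
cohort family first when correction is wanted. Within a single variant's
all-significant rule BH cannot change the verdict (the largest adjusted p
equals the largest raw p), which is why correction is offered at the
family level rather than as a per-variant flag.

## dN/dS

All 3L possible SNVs of an in-frame coding reference are enumerated and
classified synonymous/missense/nonsense by codon substitution, binned by
96-channel trinucleotide context into the site-opportunity matrix L.
Channel rates come from observed synonymous counts with empirical-Bayes
shrinkage toward the global synonymous rate, `r_j = (s_j + ½)/(L_j + ½/r̄)`
— plain additive smoothing toward rate 1 assigns absurd rates to channels
with few or no synonymous sites and was verified (on neutral simulations)
to bias the ratio several-fold. The ratio for impact class c is
`(n_obs/n_exp)/(s_obs/s_exp)`; its CI comes from the profile likelihood of
the two-Poisson rate ratio, equivalent to a binomial likelihood in the
observed nonsynonymous share, so both numerator and denominator noise are
propagated. Strata with zero synonymous mutations are reported undefined,
and selection calls use CI-excludes-1. Conventions: terminal-base
trinucleotide contexts are completed with an 'A' placeholder (identically
for site enumeration and simulated mutations, leaving neutral calibration
unaffected); the bundled toy reference (50 stop-free genes of 120 codons,
deterministic) avoids stop-codon edge cases, and for user references a
stop→stop change counts synonymous and stop-loss counts missense. Indels
and splice variants are excluded.

## Mutational signatures

Catalogues are counts over the standard 96-channel lexicon with purine
strand collapse. Exposures are fitted by non-negative least squares on
channel frequencies; signatures with normalised weight < 0.06 are removed
and the fit repeated until all survivors clear the threshold (the common
sparse-refit heuristic for 30-signature references; threshold
config-exposed). Reported weights sum to 1 and carry the reconstruction
cosine. The bundled reference is a deterministic *synthetic* stand-in
whose first columns qualitatively mimic well-known processes (C>T at
NpCpG deamination; a flat homologous-recombination-deficiency-like
profile; C>A-dominated tobacco-like); analyses of real data should load
the published reference via `read_signature_matrix`. Spearman
correlations between exposure and burden use midranks, exact permutation
p-values up to n = 9 and the t-approximation beyond.

## Cohort statistics

Sharing percentages are printed to one decimal with round-half-up.
Contingency tests are Pearson chi-squared without continuity correction —
verified to reproduce the reference metastasis-specific 2×2 p = 0.0009
from the printed counts (with Yates correction it does not). Mann–Whitney
U uses the exact tie-free distribution when the smaller group has ≤8
observations, otherwise the normal approximation with tie correction.

## Synthetic-data generator

Each simulated patient has: a uniform random labelled rooted clone tree
(truncal root, CCF 1 everywhere); a connected shared subtree sized to hit
the target shared-mutation fraction, with every remaining subtree private
to one compartment; per-region CCFs drawn top-down, the children of a
node jointly occupying a uniform 50–85% budget of the parent's CCF split
by a minimum-fraction Dirichlet, independently per region. Defaults: 3
primary + 3 metastasis regions, 7 clusters × 20 mutations, 200× mean
depth (Poisson), purity U(0.2, 1.0) per region, symmetric sequencing
error 10⁻³, shared-fraction target 0.75 (late dissemination, the typical
regime in the emulated setting), trinucleotide contexts drawn from a
0.25/0.55/0.20 mixture of the sig1/sig3/sig15-like synthetic signatures
(an HRD-dominated spectrum), one truncal TP53 driver, diploid copy number
(CNV scenarios configurable per region/chromosome).

Two admissibility constraints are applied by rejection sampling (topology
included), emulating the fact that a study can only report cluster
structures its data can resolve: cluster CCF profiles must differ
pairwise by ≥0.25 in some region and ≥0.5 summed over regions (pairs
closer than that carry too little read-count information at exome depth
to be separated by any method), and every cluster must exceed each
non-ancestor by ≥0.1 in some region (otherwise several placements of the
clone are consistent with even the noise-free CCF matrix and no topology
is recoverable). Without these, a fraction of instances is unidentifiable
by construction rather than hard.

The generator does **not** emulate: subclonal copy-number evolution,
strand/position-specific or context-dependent sequencing error, caller
artefacts and mapping error, mutation hotspots, kataegis, or
metastasis-to-metastasis seeding. Recovery results on synthetic cohorts
therefore demonstrate the statistical machinery under the stated
conditions, not robustness to the full messiness of real sequencing data.

## Problem sizes used in tests and the acceptance script

Recovery rates are measured over 50 single-patient seeds for clustering
(200×) and tree topology (500×, the regime where per-cluster CCF noise is
~0.02 and topology becomes decidable), 8 patients for progression calling
(10 clusters, shared fractions 0.1/0.9), 100 replicates × 500 mutations
for dN/dS calibration, 10,000 null pairs at 200× for the presence test,
and 50 random 3-signature mixtures × 5,000 mutations for exposures.

## Known limitations

Purity is an input, never estimated; subclonal copy number is not
deconvolved; multiplicity is per-region integer, so early/late timing of
mutations relative to copy gains is not modelled; the clustering assumes
a common CCF per cluster per region (no mixture within regions); the tree
search returns a single best tree rather than the posterior over trees;
dN/dS is global (no per-gene covariates); signature fitting is refitting
against a fixed reference, not de-novo extraction.
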