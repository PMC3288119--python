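# Methods

This note records the models, parameter choices and numerical conventions
behind `diallelgg`, and what the synthetic data do and do not emulate.

## Pedigree and genotype model

The population is a partial diallel: two maternal and two paternal parents
crossed into four full-sib families (48/36/50/54 progeny, 188 in total).
Parents carry phased genotypes over a framework map of 252 SNP markers on
13 linkage groups at ~10 cM spacing.  Each parent is heterozygous at a
Bernoulli(h) subset of markers; the default h = 0.28 makes
1 − (1 − h)² ≈ 48% of markers segregate per cross, i.e. about 122 of 252,
the study-scale average for informative loci.

Progeny genotypes are encoded as transmitted-allele indicators: for each
parental meiosis, x_p ∈ {0,1} records which of the parent's two haplotypes
was transmitted, and is observable only where that parent is heterozygous.
Recombination follows the Haldane map function r = ½(1 − e^(−2d/100))
with independent linkage groups and no crossover interference — the
simplest standard model, with a closed form that doubles as the test
oracle.  Haldane is also the assumption least likely to distort
marker-level mapping at 10 cM spacing; interference would matter mainly
for multi-locus haplotype probabilities, which nothing downstream uses.

## Trait architectures

An expression trait's latent genetic value is
Σ β_p·(x_p − ½) over its planted QTLs, plus a polygenic background (a sum
of many tiny per-parent marker effects, default SD 0.3 — this is what
makes the family term of the network residualization non-trivial), plus
N(0, σ²) biological noise (default σ = 0.5).  β_p is the allele
substitution effect of parent p's two haplotypes.  Half of the genes in
the default panel are grouped into co-expression modules of ~8 genes
sharing a latent factor (SD 0.5 per individual), emulating pathway
co-regulation; without such modules an expression panel of mutually
independent genes would make the network stage vacuous.

Phenotypes use a liability model: heights and leader length are the
liability itself (plus a trait mean); weevil attack is the liability cut
at two thresholds into three classes (no attack / failed attack / top
kill) and oviposition at four thresholds into five egg-count classes;
yearly sums are computed from the class scores.  Ordinal traits enter the
QTL scan as numeric scores — the source analysis gives no ordinal link,
and at three to five classes the score regression loses little power
relative to a threshold model while keeping the LOD machinery uniform
across trait types.

## Microarray generation and normalization

Raw two-channel intensities invert the normalization model: the
arsinh-scale signal h = μ + gene mean + genetic value + dye + block +
batch + person + ε (effect tables sum to zero; μ = 8, measurement
ε SD 0.1) becomes a foreground sinh(h)·scale plus a per-(slide, subgrid)
background.  Background subtraction recovers sinh(h) exactly; negative
net intensities are retained because arsinh is defined on all reals.

The stabilizing transform is a robust-affine arsinh,
h = arsinh((x − median)/MAD) per slide-channel, followed by simultaneous
calibration of all channels to median 0 and MAD 1.  This keeps the
monotone, variance-stabilizing contract of maximum-likelihood VSN while
remaining exactly testable; since everything downstream consumes
residuals, absolute scale is irrelevant.  The stabilization is only as
good as the robust calibration: it equalizes spread when the additive
noise scale is comparable to the channel MAD (the usual regime when most
spots are dim), and a panel of very few spots makes the per-channel
median/MAD estimates — and hence the residuals — unreliable.

Residualization fits, per gene, ordinary least squares with sum-to-zero
coded fixed effects: dye + block + batch + person for the eQTL input, and
additionally family for the network input (the family term absorbs
between-cross means, including the polygenic part).  Rank deficiency
raises an error naming the aliased factors.  When an individual is
measured on more than one channel its residuals are averaged — the
simplest defensible convention for dye-swap reuse.

## QTL mapping

At each marker the full model is cross means plus Σ_p β_p·(x_p − ½) over
the parents heterozygous there, against cross means alone;
LOD = (n/2)·log10(RSS0/RSS1), capped at 99 on exact fits.  Scanning is at
framework markers only: the ~10 cM spacing already matches the support
definition of the published threshold, and pseudomarker interval mapping
is out of scope.  Per-parent detection drops that parent's term and
re-tests at the same threshold (3.84, inclusive); a QTL must be detected
in at least one parent.  Percent variance explained is
100·(1 − RSS1/RSS0).

Significant markers of one trait on one linkage group are merged to the
peak-LOD marker whenever their support intervals (peak ± 10 cM) overlap,
i.e. peaks at most 20 cM apart.  A literal 10 cM merge distance cannot
bridge a framework marker skipped for uninformativeness — at 10 cM
spacing it never merges anything beyond immediate neighbors — so a single
strong QTL would frequently be counted twice in the hotspot tallies; the
overlapping-support rule is the smallest change that restores the
merge's purpose.

Null calibration: at LOD 3.84 the implied likelihood-ratio statistic is
2·ln(10)·3.84 ≈ 17.7, whose chi-square tail at 2–4 df is below 0.1%; the
test suite verifies the empirical rate on null traits.

## Hotspots

eQTLs are tallied once per (trait, support interval) at the peak marker.
Uniformity is tested with Pearson's chi-square against N/M expected per
marker (df = M − 1).  The hotspot threshold drops the N mapped eQTLs
independently and uniformly on the M markers, takes each replicate's
maximum per-marker cluster, and uses the maximum over 1,000 replicates
(the published convention; a 95th-percentile-of-maxima mode is provided
for sensitivity).  For N = 4,221 and M = 252 the threshold is 38 ± 1
across seeds.  Hotspot markers are classified by the significant pQTLs
collocated at the same marker: none (< 3), resistance, growth, or both.

Known limitation: the randomization null assumes independent eQTLs.
Genes sharing a causal locus have correlated expression, so chance
finite-sample correlations between their shared genotype vector and other
markers leak coherently into many genes at once and can raise ghost
clusters near — or even unlinked to — a true hotspot.  The planted-hotspot
generator therefore spreads effects over the parents informative at the
hotspot marker (one meiosis vector per gene, rotating, at a marker
segregating in ≥ 3 parents) and keeps single-marker LODs near 6–8 so that
linked markers two intervals away stay under the significance threshold.
Even so, the inclusive "count ≥ max of 1,000 replicates" rule lets the
real background occasionally tie the randomization maximum; this is
intrinsic to a discrete extreme-value threshold, not an implementation
artifact.

## Positional candidates

The collocation fraction is |gene eQTL markers ∩ trait pQTL markers| /
|gene eQTL markers| over distinct framework markers (all QTLs live at
peak markers after merging, so marker identity, not a cM window, is the
natural collocation unit; a window option exists).  The permutation null
re-places the gene's distinct eQTL markers uniformly without replacement
over all mapped markers, conditioning on the observed pQTL landscape;
its null count is exactly hypergeometric, which the tests exploit as an
enumeration oracle.  A gene is a candidate when the fraction is ≥ 0.40
and the add-one permutation p = (1 + #{null ≥ obs})/(n_perm + 1) is
≤ 0.05 (10,000 permutations by default).

Two p-values are computed.  The add-one estimator is conservative on a
discrete null — its null distribution is super-uniform, never exceeding
uniform — and is the value used for candidate calls.  For calibration
diagnostics the randomized p-value
p = (#{null > obs} + U·(1 + #{null = obs}))/(n_perm + 1), U ~ Uniform(0,1),
is also reported; it is exactly uniform under the null and is the
quantity checked by the uniformity tests.  "General resistance"
candidates are genes that are candidates for every one of the six
resistance traits (attack and oviposition in both years plus their sums).

## Co-expression network

Expression residuals (family-adjusted model) feed a shrinkage graphical
Gaussian model.  The sample correlation matrix is shrunk toward the
identity, R* = (1 − λ)R + λI, with the analytic optimal intensity
λ = Σ Var̂(r_ij)/Σ r_ij² over off-diagonal entries (clipped to [0, 1]);
R* is positive definite whenever λ > 0, so partial correlations
pcor_ij = −ω_ij/√(ω_ii·ω_jj), Ω = (R*)⁻¹, are defined even when genes
outnumber individuals.  Off-diagonal partial correlations are modeled as
a mixture η₀·f₀(r; κ) + (1 − η₀)·f_A(r) with f₀ ∝ (1 − r²)^((κ−3)/2) (the
null density of a correlation coefficient with κ degrees of freedom) and
f_A flat on (−1, 1); (η₀, κ) are fit by maximum likelihood with a coarse
geometric grid over κ refined around the optimum, and EM for η₀ at each
κ.  The posterior probability of an edge is 1 − η₀·f₀(r)/f(r), clipped to
[0, 1]; edges need probability ≥ 0.80 (inclusive, mirroring the inclusive
LOD convention).  The flat alternative is deliberately weakly informative:
it only has to absorb the mass f₀ cannot explain.

## Array design

Genetic distance between two full sibs is the mismatch fraction of their
combined transmitted-allele states over the cross's segregating loci,
missing loci excluded — the simplest metric consistent with maximizing
different-allele contrasts.  The optimizer is greedy farthest-pair
construction plus 2-exchange hill climbing, best of 10 random restarts;
instance sizes (≤ 54 per cross) make this reliably optimal in practice,
and exact brute force over all perfect matchings serves as the test
oracle at n ≤ 8.  Odd cross sizes profile one individual on two slides
with opposite dyes.  Improvement over random pairing is
100·(objective − mean random objective)/mean random objective over
uniformly random within-cross matchings; on simulated crosses the
optimized design improves on random pairing by roughly 20%, the same
order as reported for the original design.  Dye assignment canonicalizes
each slide's orientation and alternates it within every
(block, batch, person, cross) stratum, so per-stratum orientation counts
differ by at most one.

## Seeding and determinism

Every stochastic step draws from a named substream of one global seed
(SeedSequence spawned with a CRC of the stream name), so each pipeline
stage can be re-run in isolation and full runs reproduce every output
file bit for bit.  The run manifest records per-stage row counts and
SHA-256 digests of all written files.

## Problem sizes in the test suite

Map-function and fairness checks use 5,000–10,000 simulated meioses;
mapping calibration uses 200 null traits on the full 188-individual
population; power uses 100 replicate populations with one planted QTL at
25% explained variance; the end-to-end hotspot run uses the full
252-marker / 188-individual / 428-gene scale; network recovery uses a
20-gene chain with partial correlation 0.4 at n = 150 over 20 seeds; the
collocation calibration uses 500 null genes at 800–1,000 permutations.
These sizes keep the oracle quantities (binomial and hypergeometric
tails, chi-square statistics, Haldane fractions) within tight Monte-Carlo
error of their closed forms.

## What the generator does not emulate

Spot-level artifacts (print-tip trends, saturation, cross-hybridization
between homologous family members), genotyping error and missing data,
segregation distortion, crossover interference, linkage disequilibrium
between founder haplotypes beyond the pedigree itself, and
genotype-by-environment interaction are all absent.  Passing tests
therefore demonstrate that the statistical machinery is correct under its
own model assumptions, not that the pipeline is robust to every artifact
of real two-color array data.
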