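# Methods

This note documents the models, algorithms, default parameters and
design choices behind `radpartition`, and what the synthetic-data tests
do and do not demonstrate.

## Locus calling

Reads are quality-masked (bases below Phred 20 become `N`; reads whose
post-masking `N` fraction strictly exceeds 5% are dropped) and clustered
within individuals by greedy centroid clustering: distinct read
sequences sorted by multiplicity then lexicographically, each joining
the first centroid with un-gapped identity ≥ 0.88 (the reverse
complement is also tested, since reads come off either strand), else
founding a new centroid. Identity counts compatible positions (IUPAC
sets intersecting) over positions where both sequences carry
information; indel-aware alignment is deliberately out of scope because
reads are fixed-length. Stacks below depth 6 are discarded.

The sequencing error rate ε and per-site heterozygosity *H* are
estimated jointly from the base counts of every stack column, pooled
across stacks and depths. Each column with major/minor/total counts
(n₁, n₂, n) contributes a two-component mixture likelihood

    (1−H) · (1−ε)^n₁ (ε/3)^(n−n₁)  +  H · ((1−2ε/3)/2)^(n₁+n₂) (ε/3)^(n−n₁−n₂),

i.e. a homozygote whose errors fall uniformly on the three other bases
versus an equal-dosage two-allele heterozygote with the same error
process. Multinomial coefficients cancel between the components and are
omitted. The likelihood is maximized by bounded L-BFGS-B from three
starts; boundary estimates are clamped at 1e-9 so downstream posteriors
never take log(0). Fewer than 10 usable columns flags the estimate
unstable.

Consensus calling computes, per column, posteriors over the 4
homozygous and 6 unordered heterozygous genotypes with prior mass 1−H
split evenly over homozygotes and H over heterozygote pairs; the argmax
genotype is emitted only at posterior ≥ 0.95, otherwise `N`.
Heterozygous columns are phased by read co-occurrence: distinct
combinations of het-site alleles observed in ≥ 2 reads count as
haplotypes. Stacks with > 3 heterozygous sites or > 2 haplotypes are
flagged as putative paralogs and excluded downstream.

## Supermatrix assembly

Across-individual clustering uses the same greedy procedure at 0.88
identity; clusters receiving two sequences from one individual are
discarded (paralog signal), as are clusters below the minimum-individual
threshold (4 or 10 in typical use). Surviving loci face two more
filters: no column heterozygous in more than 2 individuals, and at most
10 variable sites per locus. Loci are concatenated in locus-id order
with `N` fill; `N` and `-` both count as missing throughout the
statistics. Jaccard distances on the locus presence–absence matrix and
the technical-replicate overlap table (shared/union per pair) are
produced as TSV; ordination of the distance matrix is left to external
tools.

## Likelihood engine

Site likelihoods follow the pruning algorithm over the GTR rate matrix
(eigendecomposition of the symmetrized generator, branch lengths in
expected substitutions/site) with 4 equal-weight discrete-gamma rate
categories whose rates are the conditional means of the Gamma(α, 1/α)
slices (mean-of-quantile discretization). Ambiguity codes enter as
partial states — the conditional leaf vector is 1 on every compatible
base — and fully missing characters as all-ones, so all-`N` columns
contribute log-likelihood 0. Per-pattern rescaling keeps partials in
range; site patterns are compressed with weights before any likelihood
work.

Branch-length optimization is cyclic and derivative-free: per round the
upper/lower conditional vectors are refreshed once and every edge is
maximized by a vectorized geometric grid scan (25 points over
[1e-8, 10], refined twice around the best point), accepting only
improvements; a round that fails to improve the verified total
likelihood is redone with exact per-edge refreshes, so the reported
likelihood never decreases between rounds. Convergence is declared only
after an exact sweep confirms the improvement is below the tolerance
(default 1e-3). Model estimation sets π to empirical frequencies
(floored at 1e-4) and maximizes the five free exchangeabilities and α in
log-space by L-BFGS-B, interleaved with branch-length optimization; with
effectively rate-homogeneous data α runs to its upper bound, where it is
left (the shape is then unidentifiable).

Fitch parsimony roots the tree at a leaf (every internal node binary),
treats ambiguity codes as state sets, and counts all-missing sites as
zero steps. The census calls a site variable when two or more
constituent bases are observed among non-missing cells (ambiguity codes
expanded) and parsimony-informative when two or more bases are each
backed by two or more taxa. The consistency index divides the minimum
conceivable steps — per column, the smallest base subset covering every
taxon's state set, minus one, found exactly by enumerating the 15
subsets — by the Fitch length; zero-step matrices report CI 1.0.

Tree search is a deterministic NNI hill climb (all 2(n−3) neighbors
scored with re-optimized branch lengths, best strictly improving move
taken) from a neighbor-joining start built on Jukes-Cantor distances
(scikit-bio's NJ; p-distances capped at 0.74). The nonparametric
bootstrap resamples sites with replacement and reports, for each
internal bipartition of the reference tree, the percentage of replicate
trees containing it; "mean bootstrap" is the unweighted mean over
internal bipartitions. Because the search is NNI-only, supports are
comparable across datasets analyzed with the same engine but not
numerically interchangeable with other programs' values; all bootstrap
comparisons in this package are internal contrasts. One caveat mapped
out by the tests: a random tree with a very short deep branch adjacent
to a long branch can have a split that no method recovers from finite
data, so high-support expectations hold for trees without such
pathologies (the test uses a balanced tree with uniform 0.1 branches).

## Tree pools and the partitioned analysis

Topologies are identified by the set of non-trivial bipartitions, each
encoded as the taxon-side bitmask not containing the first taxon and
hashed; the identifier is invariant under re-rooting and rotation and
collides only between identical unrooted topologies (verified against
Robinson-Foulds distance). The candidate pool is the optimal tree, all
unique 1-step NNI neighbors, and uniformly sampled (seeded, without
replacement) unique 2-step neighbors — two successive NNI moves,
excluding the optimal and 1-step sets — until the requested number of
permuted trees is reached. For a 20-taxon tree this yields the
1 + 34 + 166 = 201 configuration. Per locus, the pool is pruned to the
locus's taxa (degree-2 vertices suppressed, lengths summed),
deduplicated, and an index map retained so every pool tree inherits its
pruned representative's favor/disfavor status.

Loci enter the partitioned analysis only if they have ≥ 4 individuals,
at least one parsimony-informative character, ≥ 20 unique pruned trees
and a per-locus log-likelihood range ≥ 4.0. A locus favors trees within
2.0 log-likelihood units of its best tree and disfavors trees within
2.0 of its worst (ties at the boundary included); the range filter
guarantees the two windows cannot overlap. Per-locus likelihoods are
computed per unique pruned tree; branch-length re-optimization per tree
is available and on by default in the API, but the large simulation
experiments evaluate at inherited branch lengths (`optimize=False`) —
the pool trees carry the optimal tree's optimized lengths, which is the
cheaper of the two conventions and changes none of the qualitative
behavior at the scales tested. Favoring counts are regressed on the
total-data log-likelihood of each pool tree by OLS, each tree one
point; outliers are trees whose count exceeds the upper bound of the
95% prediction interval (standard OLS prediction variance with the t
quantile). Only the upper side is flagged — trees with more support
than their likelihood predicts; the lower bound is reported. An
optional island trim drops trees below a user-chosen total-likelihood
cut before the regression; the cut is deliberately not auto-detected,
since choosing it is a judgment about which likelihood islands are
biologically plausible.

### What the conflict-detection experiment shows

`experiments.conflict_detection_experiment` simulates a species tree,
builds a pool, selects the "masked" alternative (the 2-step neighbor the
concordant data penalize least — the topology a hybridization event
between close relatives would produce), evolves a fraction of loci on
it with its internal branches floored at 0.05 substitutions/site
(introgressed loci trace their own, longer history across the focal
edges), and asks whether the alternative exceeds the prediction
interval. Without conflict the generating topology attains the top
favoring count and is typically inside the interval — the negative
pattern.

With 30% whole-locus conflict, the alternative's favoring count is
clearly elevated relative to trees of similar likelihood, but its
standardized excess over the fitted line plateaus around z ≈ 1–2.5
across every scale explored (50–90 bp loci, 40–800 loci, complete and
dropout-structured matrices, pools of 21–51 trees on 8–12 taxa, with
and without per-tree branch re-optimization or island trimming). The
geometry is scale-free: conflicting loci raise the alternative's
concatenated likelihood (the regressor) roughly in proportion to its
favoring count (the response), and the OLS residual SD is dominated by
per-topology systematic deviation from linearity that grows with the
count scale itself, so adding loci does not raise the detection z. The
outlier rule therefore flags this construct only sporadically
(~10–25% of seeds) at desk scale, and the corresponding acceptance test
documents this honestly rather than loosening its threshold. Detection
is expected to strengthen only in regimes with thousands of weak,
patchily sampled loci over hundreds of pool trees, where favoring
counts become smooth near-linear functions of tree likelihood.

## EST informativeness comparison

Loci are split by homology evidence: at least one hit below the E-value
cutoff → genic ("EST") set; no hit at any E-value → anonymous pool; hits
only above the cutoff → neither (reported separately). Null datasets are
uniform without-replacement subsamples of the anonymous pool matched in
size and restricted to the 50–55 bp aligned-length window, deterministic
per (seed, replicate index). Each dataset's statistic bundle (parsimony
steps, variable and PI counts, CI, aligned length, missing proportion,
tip-branch proportion, mean bootstrap) is computed on that dataset's own
ML tree. The two-tailed resampling p-value doubles the fraction of null
values strictly more extreme than the observation in the direction away
from the null mean; k = 0 is reported as a bound at the test's
resolution 2/R. The rate-contrast experiment evolves "EST-like" loci at
half the substitution rate of the anonymous pool — a uniform branch
scaling, which halves informative-site counts while leaving tree shape
(hence tip-branch proportion) untouched — reproducing the expected
pattern: PI strongly significant, tip proportion not. The compared sets
default to 30 loci of 60 bp: with much smaller sets the half-rate
dataset's tree is estimated from so few substitutions that its
branch-length noise exceeds the overlapping-subsample null spread, and
the neutral tip-proportion statistic reads as spuriously extreme even
though its mean is unbiased (verified directly).

## Synthetic data

The generator draws topologies uniformly over labeled unrooted
topologies by sequential addition at a uniformly chosen edge, with iid
exponential branch lengths rescaled so the mean root-to-tip path equals
the requested depth. Loci evolve site-wise under the same GTR
eigendecomposition as the engine, with continuous Gamma(α, 1/α) site
rates. Missingness has the two causes RAD data actually have: a
phylogenetically structured component (a taxon retains a locus with
probability exp(−rate × root-to-tip path), emulating restriction-site
mutation) and iid coverage thinning. Read stacks are diploid: het sites
arise at the requested rate, Poisson-depth reads draw either allele
with probability ½, and each base flips to a uniform other base with
probability ε. Technical replicates are independent thinnings of one
locus set, with closed-form expected overlap r_a·r_b/(r_a+r_b−r_a·r_b);
retention 0.709 reproduces the ~55% observed overlap band.

Not emulated: indels and alignment error (clustering is ungapped by
design), within-locus recombination, coalescent gene-tree heterogeneity
beyond the whole-locus topology switch, base-composition heterogeneity
across lineages, and quality-score miscalibration. Tests passing on
these fixtures therefore validate the algorithms and their calibration,
not robustness to those real-data complications.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| clustering identity | 0.88 | un-gapped fraction of compatible positions |
| min stack depth | 6 | reads per within-individual stack |
| max het sites / haplotypes | 3 / 2 | per-locus within-individual paralog flags |
| posterior threshold | 0.95 | minimum genotype posterior to call a base |
| shared-het / variable-site filters | 2 / 10 | among-individual paralog filters |
| gamma categories | 4 | discrete-gamma resolution |
| branch-length clamp | [1e-8, 10] | substitutions/site |
| favor window | 2.0 | log-likelihood units |
| min trees / min LL range | 20 / 4.0 | per-locus inclusion filters |
| prediction-interval level | 0.95 | outlier threshold |
| subsample length window | 50–55 bp | matched-sampling eligibility |
| E-value cutoff | 1e-15 | genic-homology threshold |

Experiment problem sizes (8–10 taxa, 150–200 loci of 50–70 bp, pools of
21–31 trees, 50 resampling replicates, 10–20 bootstrap replicates) are
chosen so the full suite runs on a single desk-class core; all
behavioral claims were checked for stability at larger sizes during
development.

## Known limitations

- The NNI-only search can stop at local optima that SPR-capable
  programs escape; bootstrap supports are engine-internal quantities.
- The error/heterozygosity estimator pools columns across stack depths;
  it does not condition per-depth.
- The consistency index's minimum-steps term treats each column
  independently (exact per column, as is standard).
- The partitioned-RAD outlier rule has limited power against
  whole-locus conflict at desk scale, as analyzed above.
- `.loci` parsing targets the pipe-delimited dialect; other dialects
  need conversion.
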