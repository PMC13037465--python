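# Methods

This note documents the models, the synthetic study conditions, and the
design choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Cumulative aggregation and normalisation

LCA-style classifiers report *assigned-only* counts: reads attributed to a
higher rank do not include those assigned to subordinate taxa. Community
analyses need the cumulative convention, so for every sample

    cum(t) = assigned(t) + Σ_{c child of t} cum(c),

computed in a single post-order pass over the closure of observed taxa
under ancestry. Relative abundances are cumulative counts divided by the
cumulative count of an explicit *scope* taxon — the taxonomy root for
"share of all mapped reads", the virus superkingdom for "share of viral
reads". Reads assigned above a scope root's observed children (e.g.
unclassified within the virus realm) stay in the scope denominator, so the
scope root's own abundance is exactly 1 whenever it has reads. Samples
with zero scope reads are flagged missing (NaN), never zero: downstream
correlations drop them explicitly instead of treating absence of evidence
as evidence of absence.

Degenerate-input conventions: duplicated taxon rows in input tables are
summed with a warning (robust to concatenated exports); rank labels
outside the canonical eight (superkingdom…strain) pass through aggregation
unchanged and are simply never matched by rank walks; the
Holocene/Pleistocene boundary defaults to 11.7 cal ka BP (the standard
geological boundary; the epoch label is Holocene iff age ≤ boundary) and
is configurable everywhere it is used.

## Damage authentication

Post-mortem cytosine deamination enriches C→T substitutions at 5′ fragment
ends, decaying into the read. Per contig we observe conversion counts k_x
out of opportunity counts n_x at positions x = 0…P−1 (default P = 25,
configurable; plots in the literature often show only the first ~10
positions) and fit, by maximum likelihood under independent binomials,

    f(x) = b + A(1−λ)^x,   b ≥ 0, A ≥ 0, 0 < λ ≤ 1,

the simplest end-enriched geometric-decay-plus-background model consistent
with a binomial likelihood-ratio framework. The null is the flat fit
f(x) = Σk/Σn. The statistic 2(ll_alt − ll_null) is referred to χ² with 2
degrees of freedom (A and λ added over the null); A = 0 lies on the
boundary of the parameter space under the null, which makes this reference
conservative — acceptable for an authentication screen, and verified
empirically by the type-I test (≤ 8 % rejections at nominal 5 % over 500
flat replicates). Optimisation is bounded L-BFGS-B from four fixed starts
(one informed by the empirical position-0 rate), with the null solution as
a floor so ll_alt ≥ ll_null always holds; tolerance 1e-12 on the
log-likelihood. Retention filters are inclusive: accuracy ≥ 0.6 and
length ≥ 1000 bp. The prediction-accuracy field is an input (the upstream
classifier is not reimplemented); per-group summaries report both the
fitted f0 = b + A and the raw k_0/n_0 frequency, since published
first-position rates do not always state which is meant.

## Overlap and rarefaction

A species is *present* in an environment when it has ≥ 1 cumulative read in
any of that environment's samples. "Species" means taxa whose rank label is
species; strain-level reads roll into their species row automatically in
cumulative mode. Percentages of distinct species round half away from
zero, which is the convention that reproduces printed triples such as
43/39/18 from their raw counts. Rarefaction subsamples without replacement
(multivariate hypergeometric; depth at or above the vector total returns
the vector unchanged). Because the unit of subsampling was an open
question, both modes exist: per-sample rarefaction followed by pooled
presence (default — the semantics of per-row rarefying in community
ecology toolkits) and pooled-environment rarefaction.

## Time-binned core dissimilarity

Cores are sampled at irregular, core-specific ages. For a pair, the bin
width is the larger of the two cores' median successive-age intervals; the
tiling is anchored at the start of the age overlap (the reference
procedure is silent on anchoring) and the last bin is closed so the oldest
overlapping sample is never dropped. "Shared" bins hold ≥ 1 sample from
each core — the only reading under which the mean over shared bins is
well-defined. Within each shared bin, each core's species abundance
vectors (relative to viral reads) are averaged — over relative abundances,
not re-normalised pooled counts; the alternative was an open question and
this choice is the documented assumption — the union species set is used
with absent species at 0, excluded taxa are dropped *before* the Hellinger
transform (renormalisation is implicit in the transform), and the
statistic is the unweighted mean Euclidean distance between transformed
vectors. Pairs without age overlap carry a flagged missing value in the
site × site matrix. Ordination (NMDS/RDA) is out of scope by design: the
package emits the Hellinger-transformed matrix and distance tables that
standard ordination tools consume.

## Virus–host co-occurrence

Hosts aggregate at a domain-dependent rank — genus for bacteria, phylum
for eukaryotes, superkingdom for archaea — reflecting the broader host
ranges of eukaryotic viruses. A virus paired to several hosts contributes
to each group (inclusion semantics; a unique-assignment mode is not
provided because the curated table drives membership and double counting
is visible there). Per site and group, the virus series is the summed
relative abundance (all-mapped-reads scope) of the group's viruses and the
host series is the host group's cumulative relative abundance, minus the
cumulative abundances of any explicitly excluded member taxa (strain
exclusion). Spearman's ρ uses average ranks; p-values are exact by full
permutation enumeration for n ≤ 9 and t-approximate otherwise. Constant
series are flagged undefined and excluded from shift tests — zeros would
bias a signed-rank test. The shift test is one-sided Wilcoxon signed-rank
against zero with zeros dropped (classical convention), exact for n ≤ 25
via dynamic-programming enumeration of the 2^n sign assignments, normal
approximation with continuity and tie corrections above. Trivial-name host
inference returns the token immediately before a case-insensitive "phage"
token iff it exactly matches a known genus — no fuzzy matching, because a
false pairing is worse than a miss. For bacteriophage–class analyses the
resolution order is curated pair → VMR-style table → name inference, with
curated entries winning logged conflicts.

## Synthetic study conditions

The generator's defaults define the study conditions; all randomness flows
from one seed through a fixed spawn order of numpy `SeedSequence` streams
(pool weights, one stream per site, blanks, damage).

* **Sites:** 2 lake + 2 marine cores, 30 samples each, ages uniform over
  site-specific ranges spanning the epoch boundary (0.1–30 cal ka BP).
* **Depth:** lognormal(ln 2×10⁵, 0.3) reads per sample. With a viral share
  of 0.5 % of mapped reads this yields ~10³ viral reads per sample — the
  order of magnitude of per-sample viral reads in published sedaDNA
  viromes, preserved at desk-scale depth.
* **Pools:** 120 viral species per environment with a planted shared
  fraction of 0.2 of distinct species (shared count S solves
  S = 2Pf/(1+f)); base weights lognormal(0, 1); one hyper-dominant taxon
  per environment whose weight is 50× the largest other weight, giving it
  a majority of viral reads in most samples of its environment.
* **Trajectories:** host groups follow logistic-transformed Gaussian
  latent walks with epoch change-point drifts and mild mean reversion
  (rate 0.08/ka). The reversion keeps latent states in the responsive
  range of the logistic; without it, walks that wander into logistic
  saturation flatten the abundance signal and sampling noise scrambles
  ranks. Virus groups combine the host latent state with an independent
  walk: z_v = s·strength·z_h + (1−strength)·z_i for planted sign s ∈
  {+1, −1}, and z_v = z_i for null couplings. Six couplings are planted —
  positive, antagonistic and null in each environment, exercising all
  three host-domain aggregation ranks.
* **Decoupled strain:** one host strain follows an independent
  rise/plateau/decline pulse (logistic shoulders) anchored between a
  configured event age (12.4 cal ka BP) and end age (4.7), at 6× the host
  group's base weight, emulating the introduction of an exogenous strain
  that its local viruses do not track. The strain-bearing coupling uses
  strength 0.99 and a 25 % share of the viral block so the underlying
  coupling is identifiable in the ~14-sample Holocene window.
* **Mixed-rank assignment:** 3 % of each viral genus's reads sit on the
  genus node and 4 % of the viral share on the virus superkingdom node
  (unclassified within the realm); a few species carry strain children
  receiving 30 % of the species weight — exercising cumulative aggregation
  exactly where LCA tables are ragged.
* **Blanks:** 12 blanks draw Poisson(150) reads from the pooled sample
  composition (contamination-as-carryover), so most blanks are clean for
  viruses and blank viral fractions land at the 10⁻²–10⁻³ % scale.
* **Damage truth:** b = 0.01, A = 0.15, λ = 0.35 (f0 = 0.16, inside the
  0.11–0.19 first-position band reported for authentic ancient viral and
  bacterial DNA), n_x = 10⁴ opportunities per position, 30 contigs per
  class; accuracy uniform on [0, 1] and lengths uniform on 0.8–5 kb so the
  retention filter is genuinely exercised.

What the generator does **not** emulate: read-level sequences (no FASTQ),
fragment-length distributions, reference-database bias, taphonomic decay
of richness with age, spatial structure within an environment beyond
independent site trajectories, and compositional correlations among
non-coupled taxa. Passing recovery tests therefore show that the
*computational pipeline* recovers planted structure under realistic count
noise — not that real sedaDNA data satisfy the generator's assumptions.

## Replicated recovery loops

Replicated checks use a documented compact variant of the conditions to
keep a hundred replicates affordable: one site per environment with
60-species pools for coupling-sign and strain-exclusion loops, and four
sites at 16 samples with 60-species pools for the within- vs
cross-environment dissimilarity ordering. Sign recovery demands the
correct ρ sign for every non-null coupling at every site; strain exclusion
demands that the strain-excluded Holocene ρ exceed the baseline and be
positive (> 0.5). The criterion that a single replicate lands in a fixed
(baseline < 0.3, excluded > 0.7) band is *not* a reliable property of an
independently pulsed strain: the baseline ρ between two autocorrelated
series over ~14 samples is intrinsically broad, so the band holds in only
about half of replicates even when exclusion restores the correlation —
the ordering formulation is the meaningful statement.

## Known limitations

* The χ²(2) reference for the damage LRT is conservative at the A = 0
  boundary; p-values near the threshold understate significance.
* Exact Spearman permutation p-values are limited to n ≤ 9 (9! ≈ 3.6×10⁵
  permutations); above that the t approximation is used, as in standard
  statistical libraries.
* Blank accounting reports the blank fraction under both readings of
  whether a printed viral total includes blank-derived reads; at realistic
  contamination levels the two round to the same two-significant-figure
  value.
* The core-dissimilarity statistic assumes ages are known; age–depth
  modelling uncertainty is out of scope and ages are taken as given.
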