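# Methods

This note records the models implemented in `famevo`, the defaults and
their rationale, the numerical choices, what the synthetic-data
generators do and do not emulate, and known limitations.

## Birth-death model of family size (`famevo.birthdeath`)

**Model.** Family size evolves along a dated species tree as a linear
birth-death chain with equal per-copy gain and loss rate λ (units: events
per gene per Myr). With a = λt/(1 + λt), the transition probability from
s to c copies over t Myr is the classical closed form

    P(s→c) = Σ_{j≥1} C(s, j) C(c−1, j−1) a^{s−j} a^{c−j} (1−a)^{2j},
    P(s→0) = a^s,

where j counts ancestral copies leaving at least one descendant. Size 0
is absorbing: an extinct family cannot re-arise. The implementation
evaluates the sum in log space as a scaled matrix product (both factors
have non-positive log row/column maxima, so it cannot overflow) over a
truncated state space; the truncation cap defaults to
`2 × max(observed count) + 10`, at which the per-row mass deficit is far
below 1e-8 for the rate regimes of interest. The kernel is cross-checked
in the tests against the matrix exponential of the tridiagonal generator.

**Likelihood and λ.** Family likelihoods are computed by postorder
pruning with per-node rescaling, vectorized across families. The root
prior is uniform over {1..cap} (a non-extinct root, with no preference
among sizes); λ is estimated by bounded scalar ML (`minimize_scalar`,
bounds 1e-8..1, xatol 1e-6) over the pooled log-likelihood. A table in
which every family is constant across species sits at the λ = 0 boundary
and is reported as such with a flag rather than optimized.

**Family test.** The p-value of a family is a Monte Carlo likelihood
ranking: simulate n_null families from the fitted model (root from the
root prior, branches from the exact kernel), and report
`(1 + #{logL_null ≤ logL_obs}) / (n_null + 1)`. The +1 correction keeps
p > 0; the statistic is distribution-free and reproducible from the
seed. The test is calibrated under its own generative model (rejection
rate ≈ 5% at the 0.05 level, verified in the acceptance tests); when the
observed families come from a different root-size distribution than the
prior the test is conservative, which we consider the right failure
mode for an incompatibility screen.

**Ancestral sizes and branch calls.** Node posteriors come from the
standard inside-outside recursion; the reported ancestral count is the
max-posterior state, ties broken toward the smaller count and flagged.
Each branch is then tested with the two-sided exact tail
P(|C − ŝ| ≥ |ĉ − ŝ|) of its parent→child transition; a branch is flagged
(direction = sign of the change) only within families whose family-wise
p ≤ 0.05. No multiple-testing correction is applied across branches by
default — the per-lineage flags are descriptive, mirroring how such
analyses are usually read; a correction can be layered on the returned
per-branch p-values if desired.

## Duplication-loss reconciliation (`famevo.reconcile`)

Rooted gene trees only. Each gene node maps to the species-tree LCA of
its descendant species; a node is a duplication iff its mapping equals a
child's mapping. Losses are counted along skipped species edges (d − 1
for a speciation spanning d edges, d for a duplication) and attributed
to the species branch whose subtree retained no descendant; losses above
the species root are not counted (no information exists there). The LCA
embedding minimizes duplications and losses simultaneously, hence also
the weighted cost 1.5·D + 1·L; the tests verify this against an
exhaustive search over all valid embeddings.

Edges with bootstrap support below the cutoff (default 90%) are
collapsed to polytomies and re-resolved at minimum cost. Because a
polytomy's root mapping (the LCA of all its children) is invariant under
re-resolution, each polytomy can be optimized locally without affecting
the rest of the tree: exhaustively over all rooted shapes up to degree
6 (945 shapes), by greedy cheapest-pair joining beyond. The returned
reconciliation never costs more than the input resolution's (enforced by
falling back to the input if the search cannot improve it).

## Reverse conservation analysis (`famevo.conservation`)

Columns gapped in more than 50% of sequences are excluded first. The
per-column S score is the posterior mean relative rate under a fixed
reversible amino-acid model with a discretized gamma prior
(K = 16 equal-probability categories, mean-of-bin rates, shape α = 1 —
a deliberately uninformative default that spans rates from ~0.03 to
~5). The exchangeabilities are reconstructed from the BLOSUM62 log-odds
scores (2^(score/2), i.e. inverting the matrix's own log-odds
definition), paired with alignment-derived amino-acid frequencies
(floored at 1e-4). This keeps the empirical substitution model fully
reproducible from code; any other exchangeability matrix can be passed
in. Guide trees are user-supplied; absent one, an identity-fraction
neighbor-joining tree (scikit-bio) is built as declared plumbing —
adequate for rate profiling, not a published phylogeny.

Scores are z-normalized over included columns with the *population*
standard deviation (bit-reproducibility; no n−1 convention ambiguity),
then averaged in a centred window of width 7 over included columns in
alignment order, shrinking symmetrically at the edges (≤3 neighbours per
side). Variable regions are maximal runs of W ≥ I (default I = 0.5, in
sd units); runs separated by fewer than `min_gap = 3` included columns
are merged — the merge distance is an artifact knob recorded in the run
manifest, not a biological constant. Regions are reported in 1-based
residue coordinates of a named reference sequence; zero-variance
profiles (e.g. identical sequences) are flagged degenerate and yield no
regions. Two-group divergence classification evaluates each region's
group-mean W against I in both groups independently normalized profiles
mapped through the shared reference: ≥ I in exactly one group is a
divergence call for that group.

## REL site-selection scan (`famevo.selection`)

The codon model is MG94-style on the 61 sense codons of the universal
code: a single-nucleotide change has rate R(nt pair) × f_pos(target) ×
(dS if synonymous else dN), with A↔C = A↔G = C↔G = 1 and free R_AT,
R_CT, R_GT, F3x4 position frequencies from the alignment (pseudocount
1), and normalization to one expected substitution per codon per unit
branch length under the neutral (dS = dN = 1) matrix. Gapped or
ambiguous codons are missing data and are marginalized.

Site effects are a K_s × K_n product grid (default 3 × 3) of free dS
and dN class values with independent weight simplices — small enough to
fit at desk scale, expressive enough to place mass on dN > dS. The scale
degeneracy (class values vs branch scale) is fixed by renormalizing the
weighted mean dS to 1 after every update, compensating dN and the branch
scale so the likelihood is untouched. Fitting alternates (i) closed-form
EM updates of the two weight vectors (monotone by construction) with
(ii) L-BFGS-B on the logs of R_AT, R_CT, R_GT, the branch scale and the
class values, keeping the previous point whenever the inner optimizer
fails to improve — so the outer log-likelihood path is non-decreasing,
which is asserted at every iteration. Default 3 seeded restarts
(jittered class values), convergence at ΔlogL < 1e-6 within 8 outer
iterations (a convergence flag records truncation).

Per-site posteriors over the grid give PP = P(dN > dS | site) and the
Bayes factor BF⁺ = posterior odds / prior odds with π⁺ the prior mass of
dN > dS (BF ≡ 0 when π⁺ = 0; ∞ when PP = 1). Negative selection uses the
symmetric BF⁻ on dN < dS at the same strong threshold, since a separate
convention is rarely stated. Categories: strong positive BF⁺ ≥ 50, weak
positive 10 ≤ BF⁺ < 50, negative BF⁻ ≥ 50 (if not positive), else
neutral. Site positions are reported as residue numbers of a reference
sequence when one is named.

## qPCR expression analysis (`famevo.qpcr`)

Technical replicates are averaged into one Ct per biological replicate
before anything else. ΔCt = Ct_target − Ct_reference per replicate;
ΔΔCt subtracts the mean control ΔCt; relative expression is 2^−ΔΔCt
with an assumed ideal doubling (measured primer efficiencies are
reported as QC alongside, not substituted into the formula). Statistics
run on the log2 scale (−ΔΔCt), where the additive Gaussian error model
is natural, and group means are back-transformed — which makes the
control's reported mean exactly 1 by construction and the whole analysis
invariant to per-replicate plate offsets. Per gene: one-way ANOVA, then
all-pairs Fisher LSD (pooled MSE, two-sided t at α = 0.05) summarized as
a compact letter display built by insert-and-absorb, so treatments that
do not differ always share a letter ('a' = highest expression).
"N/D" (undetected) is a first-class state — excluded from the model and
printed as N/D, never imputed as a large Ct; detectable treatments with
fewer than 3 biological replicates are reported as "D" without
statistics. Replicate exclusions are only ever explicit (named
gene/treatment/replicate) and logged; there is no automatic outlier
rule.

## Synthetic data (`famevo.simulate`)

Every generator is a pure function of its parameters and seed and emits
a manifest with the full parameterization and the ground truth needed to
score its downstream stage (true λ, event counts and placements, block
coordinates, site classes, fold changes).

* **Species tree fixture.** An 11-taxon tree with the shape of a
  Hypocreales phylogeny plus outgroup, in both published placements of
  *C. rosea* (sister to *Fusarium*, or basal). Branch lengths are
  synthetic plausible ages anchored on a 29-Myr
  *H. minnesotensis*/*H. sinensis* split; they are stand-ins, not
  literature estimates.
* **Family counts** evolve by exact event-driven (Gillespie) simulation
  of the equal-rate birth-death chain; root sizes default to uniform on
  1..10 (modest ancestral families). The tests verify single-branch
  transition frequencies against the analytic kernel.
* **Gene trees** arise from duplication-loss branching inside the
  species tree (rates per lineage per Myr); extinct lineages are pruned
  in place so recorded duplication events can be checked for survival.
  Supports default to 100 with an optional degradation knob.
* **Protein alignments** evolve under the BLOSUM62-derived model with
  per-column rate multipliers in planted blocks; **codon alignments**
  under the MG94-style model with per-site (dN, dS) classes.
* **Ct tables**: reference Ct ~ N(20, σ), target = reference + baseline
  ΔCt − log2(fold) + N(0, σ), with N/D cells emitted as flagged rows and
  technical replicates repeating the biological value (technical noise
  is deliberately out of scope; the replicates exercise the averaging
  path).

What passing tests on these data do **not** show: robustness to
annotation error in real gene counts, to alignment error or
long-branch effects in real alignments, to model misspecification
(rate variation across families, non-equal birth/death rates, codon
usage beyond F3x4), or to qPCR efficiencies far from 2. The generators
produce data *from* the fitted model classes; recovery results are
internal-consistency and calibration checks, not field validation.

## Problem sizes and numerical defaults

Recovery and calibration checks run at the study scale the models are
meant for while staying desk-sized: 500 families on the 11-taxon tree
for λ recovery and null calibration (1000 null draws per family),
400-column/10-taxon alignments for conservation recovery, 500-codon
neutral and 300-codon planted alignments on a 6-taxon tree for the REL
scan (restarts reduced to 1 in batch runs; the default is 3).
Exhaustive reconciliation cross-checks cover every gene tree with up to
4 leaves on a 4-taxon species tree and a seeded random sample of 5-6
leaf trees — the brute-force oracle grows too fast for literal
exhaustion beyond that, and the sampled instances exercise every event
pattern. Tolerances: kernel vs matrix exponential 1e-8; pruning vs
enumeration and grid likelihood vs enumeration 1e-10; z-score moments
1e-9.

## Known limitations

* One λ for all families and branches; no gain/loss asymmetry, no
  annotation-error model.
* Reconciliation is duplication-loss only (no transfers), on binary
  rooted inputs; polytomy re-resolution beyond degree 6 is greedy.
* Rate4Site-style scores depend on the guide tree; the NJ fallback is
  crude when sequences are few or alignment quality is poor.
* The REL grid is coarse (3 × 3) by default; Bayes factors inherit the
  usual empirical-Bayes caveat that the prior is estimated from the same
  alignment.
* The ΔΔCT model assumes a shared reference-gene stability across
  treatments and ideal amplification.
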