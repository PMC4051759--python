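# Methods

This note records the statistical models implemented in `phylorates`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for reproducing
results.

## Tree container and calibration

Trees are rooted, with branch lengths in Myr; node ages are root age minus
root-to-node depth, and a tree is treated as ultrametric when tip depths
agree to a relative 1e−6. Newick parsing is delegated to dendropy;
serialization is canonical (children ordered by smallest descendant tip
label, full float precision) so that equal trees produce byte-identical
strings. Unlabeled internal nodes are auto-named `nd<i>` by preorder index;
these names are how age constraints, stochastic maps and regime matrices
address nodes.

**Age smoothing.** Given a constraint table (node label → age, root
mandatory), every unconstrained internal node is aged by even interpolation
between its nearest constrained ancestor and nearest constrained descendant,
counted in topological steps, with extant tips acting as age-0 constraints.
When several constrained descendants are equally near, the oldest is used,
which keeps ancestors old. Because interpolation looks only at the original
constraints, a contrived constraint set can put a child above its
unconstrained parent; a final preorder clamp (child age ≤ parent age)
restores monotonicity. Ages are a pure function of (topology, constraints),
so smoothing is idempotent. The even-interpolation rule reproduces the
behaviour of branch-length adjustment tools used for supertrees, minus their
processing-order dependence.

**Polytomies** are resolved randomly (seeded) by pairing children under
zero-length nodes, which leaves every path length — hence all cophenetic
distances and the Brownian covariance — unchanged. The zero branches are
kept at exactly 0; the one place that cannot tolerate them (independent
contrasts) applies a jitter of 1e−8 × tree depth locally.

**Pruning** returns the induced subtree rooted at the MRCA of the retained
taxa, with degree-2 nodes suppressed and lengths summed, preserving all
pairwise distances among the kept species.

## Mk model and stochastic character mapping

Growth form evolves by a continuous-time 2-state Markov chain. The
likelihood is Felsenstein's pruning recursion with the closed-form 2×2
transition matrix. Defaults, chosen for identifiability at n ≈ 134 with a
character that changes a handful of times:

* model form: equal rates (one parameter); all-rates-different by flag;
* root prior: the stationary distribution of Q (uniform under equal rates);
* ensemble size: 100 maps.

Maps are drawn exactly: node states by backward filtering / forward sampling
on the pruning recursion, then each branch's internal history by rejection
sampling of unconditional paths until the endpoint matches (bound: 10,000
attempts per branch, then a hard error rather than a silently biased map).
Rejection is exact and cheap at the transition rates this design produces
(q ≈ 0.01–0.1 per Myr on branches of a few tens of Myr).

## Brownian rates

Single-rate model: y ~ N(μ1, σ²C) with C the shared-path-length matrix;
μ̂ is the GLS mean and σ̂² = (y−μ̂1)ᵀC⁻¹(y−μ̂1)/n (ML divisor n, matching
the likelihood framing; REML is not implemented). State-dependent model:
V = σ²_liana·C_liana + σ²_tree·C_tree, with the per-state matrices read off
one stochastic map; their sum equals C exactly (checked to 1e−9 in tests).
The joint fit profiles μ in closed form and optimizes the two log-rates by
Nelder-Mead from three starts (the single-rate estimate, and ×4/÷4 splits)
to avoid the ridge local optima this surface can have. If the optimizer ever
lands below the nested single-rate likelihood, the single-rate solution is
returned (nesting is then exact by construction).

The LRT statistic 2(lnL_multi − lnL_single) is clipped at 0 and referred to
χ²₁. CIs are profile-likelihood intervals (χ²₁ 95% cutoff, other parameters
re-optimized at each profile point; bracket expansion with a root-finder).
Across a map ensemble, point estimates and log-likelihoods are averaged,
their dispersion reported, and the CI computed on the mean profile; to keep
this affordable the averaged profile uses at most 10 evenly thinned maps.

**Trait preprocessing.** Strictly positive traits are natural-log
transformed, then z-scored over the analyzed species set ("auto" mode; can
be forced or disabled). Reported rates are therefore on a
standardized-trait-variance-per-Myr scale; raw-scale rates differ by the
square of the trait's SD. Species missing a trait are pruned per
trait/group combination before any fit.

Covariance factorizations add escalating diagonal jitter (starting at
1e−10 × mean diagonal) with a warning when a matrix is numerically
singular, which happens only with duplicated rows from zero-length branches.

## SES of phylogenetic and trait distance

MPD is the arithmetic mean of the n(n−1)/2 pairwise distances. The null
draws |group| labels without replacement from the pool (equivalent, for
MPD-type statistics, to shuffling labels across the distance matrix);
default 999 iterations. z standardizes by the null SD; the quantile p is
(rank + 1)/(n_reps + 1) with ties counted as ≤, with the numerator capped
at n_reps so p stays strictly inside (0, 1) even when the observation
exceeds every null draw. The pool for growth-form comparisons is the full
pooled species list; trait distances are computed per trait (absolute
differences of standardized values), never on a multi-trait composite, and
species lacking the trait are dropped from both group and pool.

## Phylogenetic signal

K follows the variance-ratio definition: (MSE₀/MSE) divided by its BM
expectation (tr C − n/(1ᵀC⁻¹1))/(n−1); on a star phylogeny this is
identically 1 for any non-constant trait, which the tests use as an exact
anchor. Significance is one-sided: the observed variance of standardized
contrasts is compared with 1000 tip-shuffling permutations (signal = low
contrast variance), p floored at 1/(n_perm+1). The permutation machinery
computes contrasts for all permutations in one vectorized pass.

λ multiplies the off-diagonal of C; μ and σ² are profiled in closed form,
so the search is a bounded 1-D optimization on [0, 1] (endpoints checked
explicitly). The default bracket stops at 1 because C(λ) on an ultrametric
tree is guaranteed positive definite there; an extension flag allows
λ_max > 1 at the user's risk. The LRT against λ = 1 is clipped at 0 and
referred to χ²₁; fits with λ̂ at either bracket end are flagged, because the
boundary makes the test conservative and the p-value there should be read
with care.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analyses assume: a
pure-birth ultrametric tree rescaled to a 150 Myr root (relative node depths
are birth-rate-invariant after rescaling), a phylogenetically structured
binary growth form (symmetric Mk, q = 0.02/Myr; the default conditions the
simulation on exactly 63 lianas / 71 trees by seeded redraws), three traits
under state-dependent BM at rates of order 0.1/Myr on a standardized scale
(A_max-like 0.075/0.075, R_d-like 0.148/0.083, SLA-like 0.093/0.103), and
per-trait/group missingness masking an exact seeded count of cells so the
available sample sizes span 26 (R_d/lianas) to 67 (A_max/trees). The 26 and
67 anchors are design targets; the four intermediate counts (51, 46, 49, 60)
are plausible compilation values, not estimates.

It does **not** emulate: extinction (no birth–death), topological error in
the backbone, non-BM trait evolution (no OU, trends, or measurement error),
site structure in the traits (the `site` column is cosmetic), or
correlations among the three traits. Passing calibration tests therefore
demonstrates correctness of the estimators under the assumed model, not
robustness to the ways real compiled field data violate it.

## Problem sizes used in the checks

The automated suites run at the design's scale where it matters and smaller
where it does not: rate recovery and LRT calibration on 134-tip trees
(100–200 replicates), K/λ calibration on 100-tip trees (200–500
replicates), SES null calibration with 500 (tests) or 200 (acceptance
script) random 63-species groups at 999 null iterations, and micro-examples
with closed-form answers. Oracle cross-checks (matrix vs contrasts
likelihood, pruning vs brute-force state enumeration, regime-matrix
conservation, interpolation smoothing) run on small random fixtures where
exhaustive computation is exact.

## Known limitations

* Two states only; no hidden-rate or >2-state models.
* Rejection-based path sampling can fail (by design, loudly) when a long
  branch must contain a transition under a near-zero fitted rate.
* The λ LRT at the λ = 1 boundary is conservative; no mixture-χ² correction
  is applied, the boundary hit is just flagged.
* Profile CIs assume a unimodal profile; multimodal surfaces (tiny n with
  extreme regime imbalance) would need a grid scan instead.
* MPD-based SES only; no nearest-taxon metrics or abundance weighting.
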