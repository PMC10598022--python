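# Methods

This note records the models implemented in `halcyon`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Trees and node identity

Trees are rooted with nonnegative branch lengths: time (arbitrary units,
typically My) for species trees, expected substitutions per site for gene
trees. Internal node ids are postorder indices of the canonical
ladderized tree (children ordered by clade size, then smallest descendant
label), so the same Newick string always produces the same ids — node ids
are therefore stable keys for ancestral-state tables and random-effect
levels. Ultrametricity is checked with a relative tolerance of 1e-6 of
tree height, because published timetrees carry rounding noise.

Phylogenetic covariance between any two nodes is the length of the shared
root path (the depth of their MRCA); it is computed for tips and internal
nodes alike, since the pairwise mixed model needs covariances among MRCA
nodes.

## Substitution model and ancestral reconstruction

Reconstruction uses a 20-state equal-exchangeability model with uniform
stationary frequencies and unit-rate normalization, the amino-acid
analogue of Jukes–Cantor:

    P_ii(t) = 1/20 + (19/20)·exp(−20t/19).

This is deliberately the simplest model whose marginal reconstruction is
exactly checkable against exhaustive enumeration; externally computed
states (e.g. from codon-model software) can be supplied instead and flow
through the same counting code. Likelihoods are computed by Felsenstein
pruning vectorized over sites, with per-site max-rescaling to avoid
underflow. Marginal posteriors multiply inside (subtree) and outside
messages; the stored state is the argmax with ties resolved
alphabetically — implemented as "first state within 1e-10 of the
maximum", so exact symmetric ties are deterministic.

Fitch parsimony is the cheap alternative: first-pass
intersection/union sets, second pass inheriting the parent state when it
is in the node's set and otherwise taking the alphabetical minimum.
Posteriors are reported as 1; the reconstruction is a minimum-change
labeling.

## Convergent and divergent counts

A site contributes to a pair (i, j) only when the MRCA state m and both
tip states are unambiguous amino acids and the MRCA posterior clears
`posterior_floor` (default 0, i.e. no filtering). Convergent: s_i = s_j ≠
m. Divergent: s_i ≠ s_j with both ≠ m. A single-lineage change (s_i = m ≠
s_j) counts as neither; a looser reading (any s_i ≠ s_j) is available via
`loose_divergent` for sensitivity analysis. Gaps are skipped, never
imputed. Counts are summed over genes; the response can be the total or
the per-gene mean (`response="per_gene"`), default total.

A pair is *focal* for a trait when both tips carry it and the parsimony
reconstruction of the trait at their MRCA is absence — i.e. the two tips
acquired the trait through independent origins.

## The pairwise mixed model

Fixed effects: intercept, divergent count D, divergence time t, plunge
focality, island focality, D×t. Random effects: one intercept per lineage
and one per MRCA node, the latter with covariance proportional to the
diag-normalized phylogenetic covariance of the MRCA nodes (plus 1e-8
jitter, since nodes adjacent to the root have near-zero depth).

Each lineage gets a single random effect that enters through whichever
role (a or b) it occupies in a pair. This makes the fit exactly invariant
to role shuffling, which is the point of the shuffling step; the literal
two-vector formulation (independent role-a and role-b effects, only
approximately invariant) is available as `lineage_effect="separate"`.
The shared component is reported under both `lineage_a` and `lineage_b`
keys so the signal denominator Σσ² reflects the two lineage slots of
every pair.

REML (default) profiles log-variances with L-BFGS-B from two starting
points; fixed-effect inference uses t statistics with n − p residual
degrees of freedom (no small-sample correction). The Gibbs sampler uses
flat priors on fixed effects and inverse-gamma(0.001, 0.001) on
variances; pMCMC = 2·min(P(β>0), P(β<0)), floored at 1/n_draws.
Phylogenetic signal is σ²_MRCA / (σ²_lineage·2 + σ²_MRCA + σ²_resid); a
latent-scale variant adds π²/3 to the denominator, appropriate only for
non-Gaussian links and therefore off by default.

η² is computed from an OLS fit with sequential sums of squares, plunge
entered last (after D, t, D·t, island): η² = SS(plunge)/SS(total).

The response is Gaussian. Counts are nonnegative, so for strongly skewed
data a log1p transform of the response column before fitting is the
recommended route; the model itself stays linear.

## Demographic curve shapes

PSMC plain-text output is parsed from the final iteration block
(convergence assumption), with bin size s defaulting to 100 — the common
practice value; it is exposed because the rescaling N0 = θ0/(4μs) is
linear in 1/s. Times are years before present, obtained as 2·N0·t_k·g
with generation time g in years (4.8 for kingfishers); sizes are
individuals.

The common grid is `n_points` (default 64) log-spaced times inside the
intersection of all species' supports — log-spaced because PSMC
resolution is log-time. A zero lower edge (PSMC's first knot) is replaced
by the largest first-positive knot. Trajectories are evaluated as
right-continuous step functions and natural-log transformed.

The group test premultiplies curves and design by C^(−1/2) (eigendecomposition,
eigenvalue floor 1e-12·max), fits the multivariate linear model on the
group indicator, and uses SS_effect = trace of the hypothesis
cross-product with F = (SS_effect/df_eff)/(SS_resid/df_res). The null
distribution permutes reduced-model (intercept-only) residual rows, and
P_rand = (1 + #{F* ≥ F}) / (n_perm + 1). An observed SS_effect below
1e-10 of the total response magnitude is treated as exactly null
(P_rand = 1) to keep identical-input edge cases deterministic.

## Gene sets, PGLS and enrichment

Benjamini–Hochberg q-values are computed per test family; records may
carry precomputed q-values, which are then used as-is. The
adaptively-convergent set is the intersection of (1) branch-site
q < 0.05 confirmed by the relaxed-selection test, (2) per-branch adaptive
significance on ≥ 2 focal lineages, (3) residue-convergence posterior
≥ 0.8. All thresholds are arguments. The confirmation percentage is
100·|BS ∩ RELAX|/|BS| rounded to one decimal.

PGLS uses V(λ) = λ·C + (1−λ)·diag(C); λ is profiled by bounded ML
(tolerance 1e-6) with explicit boundary checks, and a flat profile
(λ unidentifiable, e.g. a star tree) resolves to the smaller λ. AIC
counts p + 2 parameters (σ², λ). Stepwise selection is bi-directional
greedy with the hierarchy constraint (an interaction requires both main
effects) and deterministic tie-breaking; p-values are plain t with n − k
degrees of freedom.

Hypergeometric enrichment computes exact upper tails P(X ≥ k) against a
caller-supplied background; terms with zero overlap are not tested. The
compact letter display is a greedy insert by descending group mean —
adequate for the handful of groups this analysis compares, without a
letter-minimization search.

## Rate convergence

RERs are residuals of sqrt gene branch lengths regressed (with intercept,
by ordinary least squares) on sqrt master branch lengths over shared
branches, then column-centered. The sqrt transform stabilizes the
mean–variance relationship of branch lengths; the cited methodology's
weighted heteroscedasticity correction is intentionally not reproduced.
Branches are matched between gene and master trees by the tip clade they
subtend; genes sharing fewer than 5 usable branches (master length ≥
1e-6) are skipped with a warning.

The association statistic is the tie-corrected Wilcoxon rank-sum z of
foreground vs background RERs (positive = foreground acceleration); the
parametric p applies a 0.5-unit continuity correction so it tracks the
exact tail within 0.01 at typical branch counts. Permulations redraw the
foreground tip set by simulating Brownian motion and taking the k
top-ranked tips (k fixed at the observed count; optional rejection until
the number of maximal foreground clades matches the observed origin
count, at most `max_tries` = 10000 draws). Foreground branches are all
branches inside each maximal foreground-only clade including its stem,
consistent with path-as-lineage counting. Empirical p is the smoothed
tail (1 + hits)/(n_perm + 1), two-sided on |z| by default with a
one-sided acceleration option, and q-values are BH over genes.

## Synthetic generators

All generators are pure functions of (config, seed) and return ground
truth alongside the data.

*Trees and traits.* Yule trees grown forward and rescaled to height 1;
trait origins are k edges sampled uniformly under three constraints:
pairwise non-nested, at least one background tip, and a parsimony origin
count equal to k (this excludes sister foreground clades, which parsimony
would merge). ln-mass is Brownian (σ² = 0.5) around 4.0 ln g — a
mid-sized kingfisher.

*Alignments.* Node states are sampled exactly from the model's transition
probabilities branch by branch from a uniform root — distributionally
identical to event-level simulation for end-of-branch states, which is
all the truth tables need. Convergence is injected as attraction: on
foreground branches, a convergent site's end state is replaced by its
site-specific target amino acid with probability `attraction` (default
0.5); `convergent_fraction` of sites (default 5%) are eligible. This is
the minimal mechanism producing excess C at matched D. Defaults:
root-to-tip height 0.5 expected substitutions, 50–200 genes of 100–300
sites in the examples and tests. Not emulated: indels, codon structure,
among-site rate variation, selection-coefficient dynamics — so passing
tests demonstrate the statistical machinery, not robustness to real
protein heterogeneity.

*Demography.* log-Ne random walks on a 64-point log grid spanning
10³–10⁶ years, anchored at baseline ln(2·10⁵) at the oldest point, with
full-history SD 0.6 for island and 0.3 for continental species, plus an
island-only decline over the most recent decade of log-time scaling
present-day Ne to (1 − 0.8) of its undeclined value. These magnitudes
mirror the qualitative regime contrast (islands fluctuate more and
decline toward the present) at sizes detectable in a 16-species design.
Coalescent noise and PSMC's own estimation error are not emulated.

*Gene tests.* A planted subset (default 20 of 500 genes) receives
p ~ U(0, 10⁻⁵) in every test and residue posterior ≥ 0.85; null genes are
uniform with sub-threshold posteriors. PSG totals follow
log-mean = ln 150 + 0.3·plunge − 0.2·(ln-mass, centered) + 0.3·island
with log-normal dispersion 0.15; plunge species preferentially include
the planted genes, which gives focal pairs elevated overlap. One term of
the term map covers the planted subset.

## Problem sizes

The test suite and acceptance script run at deliberately small scale:
15–16 tips (105–120 pairs), 10–30 genes of 150 sites for sequence-based
checks, 100–500 genes for table-based checks, 99–999 permutations, and
100–200 replicates for calibration/recovery simulations. Exhaustive
oracles (all internal labelings) run on trees of at most 5–6 tips. These
sizes were chosen so every statistical property is measured with usable
Monte-Carlo precision while the whole suite completes in minutes.

## Known limitations

- The equal-rates amino-acid model ignores exchangeability structure and
  stationary-frequency variation; with supplied ancestral states this
  does not matter, but internally reconstructed states on real proteins
  will be less accurate than codon/empirical-matrix reconstructions.
- REML p-values use residual degrees of freedom without a Satterthwaite
  or Kenward–Roger correction; at 105+ pairs the calibration tests show
  this is adequate, but very small pair tables should use the Gibbs mode.
- The RER scan assumes gene trees share the species topology over matched
  clades; discordant gene trees simply drop unmatched branches.
- Permulation draws are unconstrained by default; origin-matched draws
  can be slow or fail on trees where the observed origin count is rare
  under Brownian rankings (an explicit error reports the achieved range).
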