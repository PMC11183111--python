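# Methods

This note records the models the package implements, the conventions
chosen where several are defensible, and what the synthetic experiments
do and do not demonstrate.

## Dated trees and megatree assembly

A `DatedTree` is a rooted tree with nonnegative branch lengths in Myr.
Node ages are derived as the distance to the deepest descendant tip, so
an ultrametric tree has all tips at age 0; ultrametricity is asserted at
1e-6 Myr throughout.

**Grafting.** A genus missing from the backbone attaches as sister to a
named relative: a new node is inserted at the midpoint of the sister
clade's stem branch (between the clade's crown age c and its parent's
age s, at (s+c)/2) and the representative tip descends from it with
branch length equal to that age, preserving ultrametricity.  Sister
choices are an input table, not inferred — picking sisters is curation
against prior phylogenies, not computation.  If the sister genus is not
monophyletic, the most recent common ancestor of its tips is used and a
warning logged; backbone trees routinely contain such genera.

**Species binding.** A species absent from the backbone attaches on its
genus' stem branch at the midpoint between stem and crown ages (for a
monotypic genus, at half the stem-to-tip branch).  When several species
bind to one genus they form a pectinate series at that age; successive
attachment ages are offset downward by 1e-8 Myr so nodes stay strictly
ordered without visible age distortion.  How such simultaneous
attachments should be mutually arranged is underdetermined; the
pectinate-with-epsilon rule is this package's convention.  A species'
age is read as its parent node's age, equivalently its terminal branch
length — the natural reading when ages are extracted from a dated
megatree.

**Age smoothing.** Undated internal nodes receive ages by even
interpolation: between a dated ancestor at age a and its nearest dated
descendant at age d with m undated nodes between them, node i gets
a − i(a−d)/(m+1).  Tips are implicitly dated at 0 and the root must be
dated.  When undated nodes lie on several ancestor–descendant segments
(the interior of one segment branches toward two dated descendants),
segments are resolved longest-interior-first, ties by older ancestor;
each resolution fixes its nodes for the remaining segments.  This
deterministic order reproduces the classic chain behaviour exactly and
handles branching cases without iteration-order ambiguity.  Inconsistent
constraints (a descendant at least as old as its ancestor) raise an
error rather than being clipped.

## Diversity indices and the uniform null

PD is the sum of branch lengths of the minimal subtree spanning the
community, **without** forcing the root: a singleton community has PD 0.
The alternative (Faith's original, rooted) convention is available via
`pd_include_root=True`; the two differ by the stem path but give
identical z-scores on communities whose spanning subtree reaches the
root.  MPD averages all unordered pairwise patristic distances; MNTD
averages each member's distance to its nearest co-occurring relative.

The null model is *uniform*: every size-k subset of the supplied tree's
tips is equally likely.  The pool is therefore defined by the tree —
prune it to the union of matrix species first; a tip absent from every
site still widens the null.  Three engines supply null moments:

- **enumerate** — all C(n,k) subsets, exact mean, *population* sd
  (divide by N: it is the full distribution, not a sample).  Guarded by
  a cap (default 100,000 subsets).
- **montecarlo** — n_rand seeded uniform draws without replacement,
  sample sd (N−1).  Default n_rand = 999.
- **analytic** — exact means only: for PD, each edge e with m_e tips
  below enters the spanning subtree with probability
  p_e = 1 − [C(n−m_e,k) + C(m_e,k)]/C(n,k) (drop the C(m_e,k) term when
  the root path is forced), so E[PD] = Σ l_e p_e; for MPD the mean is
  the k-free average of all pairwise distances.  No closed form is
  implemented for MNTD; sd is delegated to Monte-Carlo.

The engines are mutually validating: analytic means must equal
enumeration to 1e-10, and Monte-Carlo moments must be statistically
calibrated against enumeration (standardized errors behaving as standard
normals across a suite of random trees and community sizes — a family
level check, since hundreds of per-comparison 3σ rules would flag a few
comparisons by chance even for a perfect engine).  The 3-tip worked
example in the README is exact by enumeration and was additionally
cross-checked against an independent community-phylogenetics
implementation.

SES values where the null sd is 0 (e.g. a site holding the entire pool)
are recorded as missing and the affected site is dropped per response in
the regression stage, with a log message.

## Age structure

MDT is the arithmetic mean species age of a flora; MDT_oldest and
MDT_youngest average the oldest and youngest quartiles.  Quartile size
is ceil(0.25·SR) with a minimum of 1 — the ceiling rule keeps tail sets
nonempty for any SR and is the convention adopted for SR not divisible
by four; ties at the cut are kept in stable sorted order.  Between-
landform contrasts use the pooled-variance (Student) two-sample t test,
df = n1+n2−2, two-sided, with significance stars at P < 0.00001, 0.0001,
0.001, 0.05; Welch's test is available by flag.  Pooled is the default
because it is the common default of the plotting conventions these
contrasts accompany; with ≥10 sites per group the two rarely differ in
star assignment.

## Regression stage

Numeric predictors are min-max standardized to [0,1]; a constant column
is an error naming the column.  Area and species richness enter models
log-transformed; the SES and MDT responses are untransformed.  The
collinearity filter repeatedly finds the most correlated pair above the
threshold (default |r| > 0.95) and drops the member with the larger mean
absolute correlation to the remaining columns (ties: the later column).

GLMs are Gaussian with identity link (least squares), categorical terms
treatment-coded — landform against Danxia, tectonic against craton by
default, both configurable.  Deviance explained is
100·(1 − residual/null deviance), which for this family equals R².
Interactions expand as products of the landform dummies with a covariate;
the default interaction scope is landform × {TCQ, PREC, PCQ}.  Stepwise
AIC moves in both directions over *term groups* (a categorical's dummies
move together) and respects marginality: an interaction is only added
when both mains are present and blocks dropping them.  Leave-one-out
importance reports the drop in deviance explained when a term group is
removed; removing a main also removes its interactions so the reduced
model stays hierarchical.  The per-group deltas need not sum to the total
deviance explained under collinearity, and no such identity is enforced.

Spatial weights are k-nearest-neighbour (default k = 8) on great-circle
distance, binary then row-standardized; k is a configuration knob and is
recorded in output metadata.  Moran's I uses the textbook statistic with
expectation −1/(n−1) and the normality-approximation variance for z and
two-sided p.

The spatial error model y = Xβ + u, u = λWu + ε is fitted by maximum
likelihood: the log-likelihood is concentrated in λ, evaluated with
log|I − λW| = Σ log(1 − λe_i) over the (complex) eigenvalues of W, and
maximized by bounded scalar search on (−0.999, 0.999) to 1e-6; β and σ²
follow by least squares on the spatially filtered system.  AIC counts
p + 2 parameters (β, λ, σ²).  The reported "variance explained" analogue
is a Nagelkerke-style pseudo-R², 1 − exp(−2(ℓ − ℓ₀)/n) against the
intercept-only non-spatial null — a stated convention, since no standard
definition exists for SEM deviance.  The residual diagnostic after an
SEM fit applies Moran's I to the filtered innovations (I − λ̂W)û, the
quantity the model claims is spatially independent.

## Synthetic data: what it emulates

The generators reproduce the statistical structure the analysis assumes,
not any real geography or macroevolutionary history:

- **Tree** — pure-birth (Yule) with all tips extant; ultrametric by
  construction.  Birth rate 1 (time is in units of expected waiting
  times); tree shape, not absolute depth, is what the metrics consume.
- **Trait** — Brownian motion (variance σ²·branch length, default σ²=1),
  giving the phylogenetic signal that lets environmental filtering
  produce phylogenetic clustering.
- **Assemblages** — five landforms mirroring the karst / karst-granitic /
  granitic / Danxia / desert design.  Neutral sites draw species
  uniformly without replacement (and therefore calibrate the uniform
  null exactly).  Clustered sites draw without replacement with weight
  exp(−τ(trait − optimum)²), the landform optima sitting at equally
  spaced quantiles (i+1)/(L+1) of the trait distribution so landforms
  differentiate compositionally; default filter strength τ = 5 in units
  of inverse squared trait.  Overdispersed sites are a deterministic
  greedy maximin: seed with the two most distant species, then add the
  species with the largest minimum distance to the chosen set, ties by
  lexicographic label.
- **Spatial fields** — covariates and errors as simultaneous
  autoregressions x = (I − λW)⁻¹ε on k-NN weights, site coordinates
  uniform on a rectangle (coordinates matter only through the weights).

Passing tests on these data show the pipeline's internal consistency —
null calibration, sign recovery of imposed clustering/overdispersion,
λ recovery — not that real floras obey Brownian traits, Gaussian
filters, or SAR errors; real data add taxonomic error, richness
gradients, dispersal limitation and non-stationary climate structure
that the generators deliberately omit.

## Problem sizes and numerical choices

The shipped experiments use sizes at which every stochastic check is
statistically decisive: 10-tip trees for engine equivalence (where
enumeration is exact), a 200-tip tree with 200 neutral sites for null
calibration, a 64-tip tree with 15 sites × 50 replicates for
assembly-signal recovery, and n = 200 sites × 30–50 replicates for
spatial-error recovery.  Enumeration is capped at 100,000 subsets;
Monte-Carlo defaults to 999 draws per community size with moments cached
per distinct SR.  All generators take explicit seeds, and the pipeline
derives per-stage substreams from a single configuration seed by
hashing, so outputs are bitwise reproducible.

## Known limitations

- The grafting/binding rules are the deterministic midpoint conventions
  stated above; they do not attempt to resolve within-genus topology.
- Only the uniform null is provided; abundance-weighted metrics and
  richness- or occupancy-constrained swap nulls are out of scope.
- The SEM assumes row-standardized weights and a scalar error process;
  no spatial-lag model or explicit covariance-function GLS is provided.
- Moran's inference uses the normality approximation, adequate at the
  n ≈ 140–200 scale the pipeline targets but approximate for tiny n.
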