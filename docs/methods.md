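# Methods

`salmodiv` implements the analytical chain used to ask two questions about a
lineage that experienced an ancient whole-genome duplication (WGD): *when*
did the duplicated loci become usable, independently evolving genes
(diploidization resolution, DR), and *what* drove the lineage's subsequent
species diversification.  Salmonid fishes — subfamilies Salmoninae,
Thymallinae and Coregoninae, with a family-specific WGD long predating the
crown radiation — are the motivating system, and the binary ecological trait
throughout is life history: 0 = freshwater resident (F), 1 = anadromous (A).

All ages are measured backwards from the present in Ma (present = 0), all
rates are per lineage per Myr, and trees are rooted `dendropy` objects with
branch lengths required on every non-root edge.

## Paralogue curation

### Diploidization-resolution classifier

A WGD paralogue dataset is a gene tree containing up to two sequences per
species plus outgroups that diverged before the duplication.  The
classifier, `classify_diploidization`, decides among four patterns:

1. **resolved_ancestral** — rooted on the outgroup, the ingroup is
   monophyletic and its basal split separates two *paralogous clades*, each
   containing every species (and every subfamily present).  DR predates the
   first speciation; the paralogue divergence is datable on a common clock.
   Only these datasets receive `keep = True`.
2. **lineage_specific** — the paralogue split is nested within a crown
   lineage (a node whose two children carry identical species sets).
3. **unresolved_tetrasomic** — a species' two sequence variants are sister
   tips, the signature of ongoing tetrasomic inheritance with gene
   conversion homogenising the pair.
4. **ambiguous** — anything else, including a missing subfamily in one
   paralogous clade, non-monophyletic ingroup, or (when `min_support` is
   set) an unannotated or weakly supported paralogue-split node.

The decision uses only species/subfamily sets of clades, so it is invariant
to tip order and to rerooting along the outgroup branch.  Support values are
read from internal-node labels; no numeric default threshold is imposed
because none is canonical — `min_support` is exposed and `None` by default.
Note the order of checks: same-species cherries are tested before nested
duplicated species sets, so a dataset mixing both patterns is reported as
unresolved.  For single-species lineages the two patterns are topologically
identical and the classifier reports `unresolved_tetrasomic`; guaranteed
discrimination requires at least two species per subfamily.

### Concatenation machinery

For k paralogue pairs there are 2^k ways to line the loci up into the two
rows of a concatenated matrix (2^(k-1) after fixing the global row swap);
`ConcatenationSet` enumerates them lazily and `sample_concatenations` draws
uniformly without replacement.  Two matrix conventions are produced:

- *paralogue mode* (`ConcatenationSet.build`): rows are `taxon|A` /
  `taxon|B`, width = sum of per-locus block lengths.  This retains the
  duplication signal.
- *orthologue mode* (`concat_orthologs`): one row per species spanning both
  paralogue blocks (`[locus-1 blocks | locus-2 blocks]`), width twice the
  per-paralogue sum; each column block contains only orthologues, removing
  the paralogous signal.  Outgroups carry one sequence per gene, duplicated
  across the blocks by default (policy `"single"` gap-fills instead).
  Missing ingroup sequences are gap-filled with a logged warning so matrix
  dimensions stay reproducible.

`codon_partition` filters columns by codon position on an in-frame
alignment; partitioning commutes with concatenation.

### Clock diagnostics

`tajima_rrt` is Tajima's relative-rate test: over sites with no gap/N in any
of the three sequences, m1 counts sites where only taxon A differs from the
outgroup, m2 where only B does; chi2 = (m1-m2)^2/(m1+m2), df = 1, with
p = 1 when m1 + m2 = 0.  `saturation_scan` tabulates, per sequence pair,
raw differences, transitions and transversions, and the Kimura
two-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)); pairs beyond the
K2P domain (saturated) are flagged and excluded from the least-squares
regression of raw differences on distance.  The closed-form K2P distance is
used deliberately in place of composite-likelihood distances tied to
specific GUI software; for saturation diagnostics the difference is
immaterial.

## Diversification inference

### Branching times, LTT, gamma

`branching_times` requires an ultrametric (default relative tolerance 1e-6,
absorbing rounding noise from external dating software) binary tree and
derives the internode durations g_k (exactly k lineages, k = 2..n),
cumulative sums T_i and total lineage-time T.  `gamma_test` computes

    gamma = [ (1/(n-2)) sum_{i=2}^{n-1} T_i  -  T/2 ] / [ T sqrt(1/(12(n-2))) ]

which is asymptotically standard normal under constant-rate pure birth;
the p-value is two-tailed normal.  Positive gamma = nodes crowded towards
the present.

### Survival models A/B/C

Branching times are treated as N = n-1 uncensored waiting times measured
from the present; no extinction/censoring correction is applied (the
convention is stated rather than hidden, and is the main caveat of this
framework).  Model A: constant hazard, closed form delta = N / sum x_i.
Model B: Weibull hazard h(x) = delta beta (delta x)^(beta-1); the shape is
profiled (delta has a closed form given beta) by bounded scalar
minimisation over log beta in [log 0.02, log 50], with beta = 1 evaluated
explicitly so model A is always nested exactly.  beta < 1 concentrates the
hazard near the present — the recent-acceleration reading.  Model C:
piecewise-constant hazard with a single shift at Tc; for fixed Tc the MLEs
are closed-form occurrence/exposure rates, and `breakpoint="profile"`
maximises over midpoints of adjacent observed times.  LRTs use chi-square
with df = 1 (A-vs-B, and A-vs-C with fixed Tc) or df = 2 (profiled Tc; a
warning notes that a profiled changepoint is not a regular parameter).
Akaike weights over {B, C} use AIC = 2k - 2 logL with k = 2 for B and
k = 3 (profiled) or 2 (fixed) for C.

### BiSSE

`bisse_loglik` implements the Binary State Speciation and Extinction
likelihood: along each branch, backwards in time,

    dE_i/dt = mu_i - (lambda_i + mu_i + q_ij) E_i + lambda_i E_i^2 + q_ij E_j
    dD_i/dt = -(lambda_i + mu_i + q_ij) D_i + q_ij D_j + 2 lambda_i E_i D_i

with tip conditions D_i = 1{state = i}, E_i = 0 (complete sampling) and
node rule D_i <- D_i^L D_i^R lambda_i.  Numerical scheme: for an
ultrametric, completely sampled tree E depends only on age, so E(t) is
integrated once per call (adaptive RK45, rtol 1e-10) onto a ~2000-point
grid; the D system is then linear, and every branch reduces to a 2x2
transfer matrix integrated with a fixed-step RK4 (>= 60 steps per branch,
scaled up with rate x branch-length stiffness and vectorised across
branches).  D is renormalised at every node with an accumulated log-scaler
to prevent underflow on deep trees.  Regimes too stiff for the step cap
(rate-length products ~10^3, astronomically unlikely on a dated tree)
report -inf rather than failing.  Accuracy is validated in the test suite
against a naive per-branch fine-step integrator (agreement 1e-5 on small
trees) and against the exact factorisation into a constant-rate birth-death
likelihood times a two-state Markov trait likelihood when rates are
state-independent (1e-6).

Root treatment defaults to weighting the two root states by their relative
D values ("obs"), with `"equal"` and fixed-state alternatives; survival
conditioning (dividing by the probability that both root lineages leave
surviving descendants) is off by default and exposed as a flag — both
follow common practice in the model's reference implementation, which the
source analyses used.

`bisse_ml` optimises the log rates with L-BFGS-B inside [1e-8, 1e3],
multi-start (default 5: a growth-rate heuristic — Yule-type net rate from
tip count and crown age, transition rate from a Fitch parsimony count over
tree length — plus log-normal jitter, sd 0.75); ties break towards the
smaller parameter norm.  The constrained model enforces lambda0 = lambda1
and mu0 = mu1 with transition rates left free, so the
constrained-vs-unconstrained LRT has df = 2.  (A df = 1 convention — also
constraining nothing else but reading the contrast as one parameter — is
sometimes seen in published chi-square/p pairs; `bisse_lrt` derives df from
the actual parameter counts and the choice is visible in its result.)
`extra_starts` lets the free fit be seeded from the constrained optimum,
guaranteeing a non-negative LRT statistic.

`bisse_mcmc` samples the six log rates by adaptive random-walk Metropolis:
independent exponential priors on the rates (default mean = twice a
Yule-rate estimate (n-2)/tree-length), Jacobian included, global proposal
scale adapted towards 23% acceptance during burn-in only (so the kept chain
is a valid Markov chain), default 10,000 steps with 10% burn-in.  Reported:
posterior means, central 95% credibility intervals, autocorrelation-based
effective sample sizes (warning below 50), and whether the lambda and mu
interval pairs overlap — the non-overlap of speciation-rate intervals being
the qualitative signature of trait-dependent diversification.

## Synthetic data

The generator exists so that every stage can be tested against known ground
truth; it emulates the statistical structure of the real inputs, not their
content.

- **Birth-death / BiSSE trees** (`simulate_bd_tree`, `simulate_bisse`):
  forward Gillespie simulation from a single stem lineage, conditioned on n
  extant tips by rejection (extinct or runaway attempts discarded, retry
  cap 1000).  When the extant count first reaches n, the present is placed
  one full waiting time (exponential in the total event rate) after that
  birth, so the complete n-lineage internode interval is observed; stopping
  exactly at the n-th birth would zero the last interval and shift the
  pure-birth gamma null upward by about sqrt(3/(n-2)).  With that
  convention the gamma null is exactly standard normal under pure birth,
  which the acceptance suite verifies.  The returned tree is the pruned
  (reconstructed) crown tree of the survivors.  Conditioning-by-rejection
  still carries the usual mild bias for birth-death parameter combinations;
  it is accepted for fixture purposes and shared by both simulators.
- **WGD gene trees** (`simulate_wgd_gene_tree`): deterministic construction
  from a dated species tree, a WGD age, and per-lineage DR ages; scenario b
  splices two renamed copies of the ingroup at the ancestral DR age,
  scenario c duplicates each crown lineage at its own DR age, scenario d
  leaves chosen lineages tetrasomic — their within-species paralogue pairs
  coalesce at (1 - conversion_strength) times the species' stem age, a
  deliberately simple stand-in for concerted-evolution dynamics whose true
  mechanism the scenario picture does not specify.  Outgroups must subtend
  the ingroup as successive lone tips older than the WGD.
- **Codon alignments** (`simulate_alignment`): HKY with per-codon-position
  rate multipliers (default third-position acceleration), branch lengths
  converted from Myr to substitutions/site by an explicit `clock_rate` so
  time and divergence units never mix; transition matrices by matrix
  exponential, sites independent.
- **Sea-level series** (`make_sealevel_fixture`): piecewise-linear trend
  (default: high Late-Cretaceous stand falling steeply towards the present,
  ~1100 points over 130 Ma — the density of published eustatic
  compilations) plus Gaussian noise; ages stratified-jittered so every
  1-Myr bin is populated.

What the synthetic data do **not** emulate: rate variation among lineages
and genes, alignment error, incomplete taxon sampling, fossil-calibration
uncertainty, and gene-tree discordance from coalescent processes.  Passing
tests therefore demonstrate correctness of the statistics and the internal
consistency of the pipeline, not robustness of the biological conclusions
to those real-data complications.

## Climate overlay

`bin_time_series` summarises a series over half-open bins [k w, (k+1) w)
from 0 (default width 1 Myr, first bin 0-1 Ma; a point exactly on a
boundary belongs to the older bin's successor, i.e. the bin it opens);
standard deviations are the sample (n-1) form, undefined for single-point
bins.  `overlay_report` joins the binned series with an LTT curve at bin
midpoints, dropping bins older than the root and warning when the covered
ranges are disjoint.

## Problem sizes used in the shipped checks

The acceptance suite and `scripts/acceptance.py` use 20 BiSSE trees of 65
tips for rate recovery (the study's tip count; the unconstrained fits use 3
optimiser starts, which matched the 5-start default's optima on these
surfaces in spot checks), 500 pure-birth 50-tip trees for the gamma null,
200 replicates of N = 200 waiting times for survival-model size and
Weibull-shape recovery, trees of <= 6 tips for oracle agreement, and a
26-dataset classifier screen.

## Known limitations

- The survival framework ignores extinction (uncensored waiting times); its
  parameters describe the reconstructed tree, not the true process.
- ML BiSSE estimates on single trees of ~65 tips are noisy; with few tips
  in one state the corresponding rates are weakly identified and boundary
  estimates (rate 0) are common — means across replicate trees inherit
  some downward bias for the rare state's speciation rate.
- The tip-count conditioning of the simulators is the simple
  forward/rejection scheme, not a uniform draw from the exact conditioned
  distribution.
- Polytomies are storable but rejected by every statistic that assumes a
  binary tree; trees with sampling fractions < 1 are out of scope.
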