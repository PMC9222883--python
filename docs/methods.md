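# Methods

## The substitution model

All analyses share one likelihood core: a continuous-time Markov model on
the 61 sense codons of the standard genetic code. The instantaneous rate
from codon *i* to codon *j* is zero unless the codons differ at exactly one
nucleotide position, and otherwise proportional to

    q_ij ∝ π_j × (κ if the change is a transition) × (ω if it is nonsynonymous)

where π is the equilibrium codon frequency vector, κ > 0 the
transition/transversion rate ratio, and ω ≥ 0 the nonsynonymous/synonymous
rate ratio (dN/dS). Q is rescaled so that one unit of branch length equals
one expected substitution per codon. Changes to or from a stop codon do not
occur (stops are excluded from the state space); the nucleotide-level bias
is HKY-style (κ only, not GTR). Codon frequencies default to F3x4 —
products of the three position-specific nucleotide frequencies observed in
the alignment, renormalized over sense codons — with equal-frequency
(`CodonFreq = 0`) and pooled F1x4 (`CodonFreq = 1`) options.

Because the chain is reversible (π_i q_ij = π_j q_ji), transition matrices
are computed spectrally: with D = diag(π), B = D^{1/2} Q D^{-1/2} is
symmetric, so P(t) = D^{-1/2} U e^{Λt} Uᵀ D^{1/2} from one symmetric
eigendecomposition per (κ, ω) pair. Decompositions are cached per engine;
during optimization, evaluations that perturb only branch lengths or
mixture weights reuse them, which is the main performance lever.

Likelihoods use Felsenstein pruning with per-node rescaling of partial
likelihoods (underflow-safe for deep trees); per-site likelihoods are
floored at 1e-300 so the objective stays finite at parameter corners.
Rooted input trees are collapsed at a basal bifurcation before fitting,
since only the sum of the two root-adjacent branch lengths is identifiable
under a reversible model.

## Model families and tests

Site-to-site ω variation is a finite mixture; each site class may carry a
different ω on a single marked foreground branch:

| family | classes | free mixture parameters |
|---|---|---|
| M0 | one ω everywhere | ω |
| M1a | ω₀ ∈ (0,1), ω₁ = 1 | p₀, ω₀ |
| M2a | M1a + ω₂ ≥ 1 | p₀, p₁ (stick-breaking), ω₀, ω₂ |
| M7 | Beta(p, q) on (0,1), K = 10 equal-probability categories | p, q |
| M8 | M7 + extra class ω_s ≥ 1 | p₀, p, q, ω_s |
| branch | one background ω, one foreground ω | ω_bg, ω_fg |
| branch-site (model A) | classes 0, 1, 2a, 2b; foreground ω₂ on 2a/2b | p₀, p₁, ω₀, ω₂ |

Beta categories are equal-probability quantile bins whose value is the mean
of the beta density within the bin; K = 10 is the conventional resolution.
The branch-site grid keeps the constraint p₂ₐ/p₂ᵦ = p₀/p₁ by construction
through the stick-breaking coordinates (q₀ = p₀+p₁ mass, q₁ = p₀ fraction).

Nested comparisons are tested with 2Δ(lnL) against χ²: M1a/M2a and M7/M8
with df = 2; branch (foreground ω free vs fixed at 1, df = 1 — only the
foreground is constrained in the null, the background ω stays free); and
branch-site (ω₂ free vs fixed at 1, df = 1). For the branch-site null the
tested parameter sits on its boundary, where the plain χ²(1) reference is
the conventional, slightly conservative choice. Negative 2Δ values —
possible when null and alternative are optimized independently — are
clamped to zero (p = 1) with a logged warning. M8's ω_s is constrained ≥ 1
so its LRT specifically targets positive selection.

Site identification is empirical Bayes. NEB evaluates the posterior of the
ω > 1 class per site at the MLEs. BEB additionally integrates the mixture
weights and the positive-selection ω over a uniform 10-point grid per
dimension (weights via stick-breaking coordinates on (0,1); ω₂/ω_s over
(1, 11); κ, branch lengths, and the remaining shape parameters held at
their MLEs), weighting grid points by their full-data likelihood. Site
records are only emitted when the companion LRT is significant. p-values
across enumerated foreground branches are reported raw, matching
per-branch reporting practice; the summary also prints a
Benjamini–Hochberg-adjusted `p_bh` column, clearly marked as an extension,
while significance verdicts are taken on the raw values.

## FEL

The FEL scan is two-staged: an M0 fit pins down κ, π and all branch
lengths; then each codon column receives its own synonymous rate α and
nonsynonymous rate β, maximized with everything else frozen, via the site
rate matrix (α·S + β·N)/c, where S and N are the synonymous and
nonsynonymous parts of Q at the global κ and c is the global fit's
normalization — so (α, β) = (1, ω̂) reproduces the global model exactly.
The α = β null is tested with χ²(1), two-sided; the direction (positive if
β > α, negative if β < α) is assigned only at p ≤ s. Bounds are
α ∈ [1e-6, 100], β ∈ [0, 100]; sites whose free optimum collapses onto the
α = β line get p = 1. The κ-based baseline means site counts can differ
slightly from FEL implementations that use a GTR nucleotide model.

## Optimization

Bounded L-BFGS-B on (κ, model parameters, branch lengths), with bounds
ω ∈ [1e-6, 999], κ ∈ [0.01, 100], branch lengths ∈ [0, 50], proportions in
(1e-6, 1−1e-6), beta shapes in [5e-3, 99]; convergence tolerance 0.5e-6
(the `Small_Diff` control value). Defaults: initial ω = 1, initial κ = 2,
three starts (one deterministic, two jittered by a seeded RNG). Ties
resolve to the highest lnL, then the lexicographically smallest parameter
vector. Alternatives fitted through `fit_nested_pair` are warm-started at
the null optimum mapped so the extra class begins empty (weight ε, ω at
its boundary), which guarantees lnL(alt) ≥ lnL(null). Branch lengths are
re-optimized under every model by default (`fix_blength −1` semantics: any
input lengths only seed the optimizer); `FitOptions.fix_branch_lengths`
freezes them — e.g. at the M0 estimates — for calibration sweeps where the
4-fit-per-replicate cost matters.

In the orchestrator, each alternative-model task refits its own null for
warm-starting rather than reading the null task's result; the two nulls
can differ by optimizer noise at the 1e-3 lnL scale, which the LRT clamp
absorbs. The per-task optimizer seed derives from the task fingerprint, so
results are reproducible without a user seed and invariant to scheduling;
`--seed` XORs a user value into it.

## The simulator and what the tests show

The simulator draws root codons from π and evolves them with the exact
P(t) of the likelihood core; site classes are i.i.d. per codon from the
mixture (the models' own assumption — no autocorrelation along the
sequence), and foreground ω applies on `#1`-marked branches. It therefore
emulates data that satisfy the model assumptions exactly: no indels, no
recombination, no among-site rate autocorrelation, no codon-usage structure
beyond π, and selection regimes constant within a class. Passing
calibration tests demonstrates that the estimators and tests behave
correctly *under the model*; they do not certify robustness to alignment
error or model misspecification in real data.

Calibration study conditions:

* Type-I error: 200 replicates of strictly neutral data (ω = 1, κ = 2) on
  a 3-taxon tree with 0.3-substitution branches, 200 codons — the scale of
  the smallest worked dataset. Empirical rejection rates of M1a/M2a and
  M7/M8 at s = 0.05 are required to fall in [0.01, 0.09].
* Power: 20% of sites at ω = 5 (background ω₀ = 0.2), 500 codons, on an
  8-leaf tree with 0.5-substitution branches. Three-taxon trees of the
  neutral regime carry too little per-site information to separate ω = 5
  from ω = 1 — the likelihood of the nearly-neutral null exceeds that of
  the truth — so the power regime uses a moderately informative phylogeny,
  as a power study would. Required power > 0.8 for both comparisons
  (20 replicates).
* Consistency: the RMSE of ω̂ under M0 (true ω = 0.3) shrinks from 100 to
  1000 codons.

These replicate counts and tree sizes are the package's chosen study
design; the replication seeds are fixed in the tests.

## Pipeline and report conventions

Tasks are one model fit (or one FEL scan) each; the branch and branch-site
tests contribute two tasks per enumerated foreground topology. Branches
are enumerated depth-first with children in input order; a fully resolved
unrooted n-leaf tree yields 2n−3 topologies, polytomies one per actual
edge, and rooted binary input is counted as unrooted. Branch identities
are the sorted leaf set under the branch, which survives serialization.
Results are written atomically (write-then-rename) with a SHA-256
fingerprint of alignment bytes, tree string, model and the
result-affecting control parameters; resume skips fingerprint-matching
tasks and interruption can corrupt nothing. When several ctl files are
present, all datasets' tasks feed one rolling worker pool (`run_many`), so
the next dataset starts as soon as a worker frees up. Codon indices in all outputs
are 1-based on the cleaned alignment (gap and N-containing columns removed
codon-wise across all sequences), with the column map back to original
coordinates in the overview table. Codons containing N are treated as gap
codons so every test sees identical data. Terminal stop codons are
rejected rather than silently stripped; `strip_terminal_stops` exists for
inputs that carry them. The report format (summary sections per test, then
the codon table, highlighted FASTA and p-value-annotated Newick lines) is
this package's own stable layout.

Control files accept the full conventional codeml key set; keys with no
counterpart in this native core (`Mgene`, `rho`, `clock`, …) are accepted,
validated and logged as no-ops so existing ctl files keep working.

## Known limitations

* No clade models (C/D), amino-acid models, GTR-based codon models, or
  ancestral reconstruction; only the standard genetic code (`icode 0`).
* χ²(1) for the boundary branch-site null is approximate (conservative).
* BEB integrates a reduced parameter subset (weights + positive ω) rather
  than the full YWN grid over ω₀; on informative data NEB and BEB agree
  closely (tested), but BEB posteriors here can be more conservative when
  the positive-class ω MLE is extreme.
* FEL uses the κ-based baseline, not GTR; published FEL counts obtained
  with richer baselines may differ by a few sites.
* Exact reproduction of published example-dataset results additionally
  depends on optimizer details and is validated only when those alignments
  are supplied locally (see `tests/test_acceptance.py`).
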