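# Methods

## Model

A subject's filtered read counts are modelled as an LDA "document": with *T*
latent sub-communities (topics), each subject draws topic proportions
`θ ~ Dir(α)` (symmetric) and each read independently draws a topic
`z ~ Mult(θ)` and a taxon `w ~ Mult(β_z)`. The per-subject total read count
is ancillary to `(θ, β)` and is therefore modelled only in the simulator
(Poisson), never at fit time. The assumptions worth keeping in mind: reads
are exchangeable within a subject (no phylogenetic or co-occurrence
structure beyond topic membership), topics are shared across subjects, and
zero counts are ordinary multinomial zeros — the model has no explicit
zero-inflation component even though real 16S tables are zero-inflated (the
simulator can inject zero-inflation precisely to probe this mismatch).

### Estimation

`fit_lda` runs batch variational EM with the standard mean-field family
`q(θ_d) = Dir(γ_d)`, `q(z)` factorized per (subject, taxon). `β` is a MAP
point estimate under a symmetric `Dir(η)` smoothing prior (η = 0.1 per
taxon) so every entry is strictly positive — required for finite perplexity.
Every coordinate update (φ, γ, β, and the optional α step) maximizes the
penalized evidence lower bound, so the per-sweep bound recorded in the fit
metadata is non-decreasing; this is asserted in the tests. The symmetric α
is by default re-estimated each sweep by safeguarded Newton ascent starting
from 50/T (the convention of the usual VEM implementations); passing a float
fixes it. Only the β initialization is random (seeded); E-steps are
deterministic, so fold-in inference (`infer_theta`, β held fixed) and
perplexity are reproducible without a seed. Convergence: relative bound
change below 1e-6, cap 100 sweeps; the inner E-step iterates to a mean γ
change below 1e-8, cap 60.

Perplexity is `exp(−ℓ/N)` with `ℓ` the log-likelihood of the counts under
each subject's inferred plug-in mixture `θ_i β` — simple, deterministic, and
exactly reproducible by a token-by-token oracle, which the tests exploit.

### Matching and metrics

With `C = T` status levels, all `T!` bijections are enumerated (constraints
restricting a topic's admissible levels simply filter the enumeration) and
scored by `A_w = Σ_t w_t · TPR_t`. Confusion matrices use **rows =
predicted, columns = true** throughout; this orientation is stated in the
`confusion_matrix.tsv` header because the convention is easy to flip
silently. Weighted precision, which the weighted-accuracy definition does
not cover, is defined symmetrically with row (predicted) sums and 0/0 → 0.
A class with positive weight but no true instances makes `A_w` undefined
(0/0) and is an error rather than a silent skip. Ties between matchings are
broken by enumeration (lexicographic) order; argmax ties in hard topic
assignment and in the second-highest topic for similarity labels break
toward the lowest topic index — the choice that also makes the worked
four-subject similarity example come out as printed.

### Feature search

The search state is a taxon subset (sorted indices). Moves: a fair coin over
{swap, remove, add} of `c` features (default 1), with infeasible coins
(subset size would leave [1, n]) redrawn uniformly among feasible ones.
Improving proposals are always accepted; non-improving ones move with
probability `1 − u` (u = 0.5 by default — the stay probability is a free
parameter of the method with no published value, and 1/2 is the
least-informative choice). "No significant improvement" is made concrete as:
stop when the best score has not improved by more than `t0 = 1e-4` for
`patience` (default 100) consecutive moves, hard cap `max_moves = 2000`.
The subset scorer refits the LDA + matching pipeline on the restricted table
with a fixed LDA seed, making it deterministic per subset; scores are cached
by subset (shared across restarts), and a scorer failure (e.g. a subset that
zeroes out a subject's reads) scores −∞ and is logged in the trace. `R`
restarts run from independent uniform random size-`p` subsets
(p = ⌈n/2⌉; the ceiling resolves the odd-n ambiguity) with child seeds
spawned from the master seed; the winner is the restart with the highest
best score, ties to the lowest index. Dropped features are excluded
outright — the "Others" column is not re-aggregated — because the search
operates on the already-aggregated feature space.

### Preprocessing

Proportions are plain row normalization (no rarefaction or CLR — out of
scope by design). The top-K concordance filter orders taxa by descending
rank-sum of (rank by abundance, rank by prevalence), ties broken
lexicographically by name for determinism, then backward-eliminates from the
tail any taxon whose removal strictly increases the Kendall tau between
abundance and prevalence on the retained set, removing the tail-most taxon
when no removal helps, until K remain. This is a deterministic,
brute-force-verifiable surrogate for tau-path-style concordance filtering;
it is greedy, so on adversarial inputs it may miss the global
maximum-concordance subset (on small instances it typically attains it, and
the tests verify one such instance exhaustively). Degenerate tau (constant
vectors, fewer than two taxa) is defined as 1.0. The detection threshold
defaults to ω = 0.001 (0.1% relative abundance, a standard detection limit)
and is configurable. A per-class mode applies the filter within each status
class and unions the selections.

### Balancing

SCUT-style: per class, SMOTE oversampling up to the target (synthetic row =
`x + δ(x_nn − x)`, δ ~ U[0,1], `x_nn` among the k = 5 nearest same-class
neighbours, clamped to class size − 1; rounded to non-negative integers so
the result is still a count table) or seeded k-means undersampling down to
it (one representative per sub-cluster, remaining slots filled by
next-nearest rows; every kept row is an original row). The default target
`round(M/C)` turns 89 subjects with classes (66, 6, 17) into 90 with 30 per
class. Balancing operates on raw counts (LDA needs integer tokens); a
single-member class degenerates to replication since it has no neighbour.

### Evaluation protocol

The 80–20 split uses per-class floor rounding — class c contributes
`floor(0.8 · n_c)` training subjects — which is the unique rounding rule
that sends 89 subjects with classes (66, 6, 17) to a 69/20 split. k-fold
evaluation uses seeded stratified folds. Fitting and matching see training
subjects only; test subjects are classified by fold-in inference with the
trained `β` and the trained matching. A test class absent from training is
an error (its matching is undefined).

## Synthetic data

The generator follows the generative model exactly (Poisson totals,
resampled if zero; Dirichlet mixtures; multinomial reads), with additions
that emulate the structure of the motivating study: exact unbalanced class
sizes via rejection sampling on the dominant topic; fuzzy labels (a noise
rate ρ flips a label to a uniformly random other level); zero-inflation as
independent Bernoulli cell-zeroing after generation (re-drawn for a row that
would become empty); and a planted-feature design for benchmarking the
search. The "study-shaped" preset is M=89, B=109, T=3, class sizes
(66, 6, 17), ~5000 reads per subject, 30% zero-inflation. What the
simulator does **not** emulate: real taxonomic correlation structure,
overdispersion beyond the topic mixture, or compositional artefacts — so
passing tests demonstrate correctness of the machinery under the model's own
assumptions, not performance on real gut data.

The planted benchmark gives each topic a contiguous block of the 5
informative taxa and spreads the remaining mass identically (uniformly) over
the 10 noise taxa, so noise taxa carry zero information about topic
membership. For the recovery benchmark the informative mass is set to 0.4
and read depth to ~60 reads/subject over 80 subjects: at shallow depth each
additional informative taxon still contributes estimation signal, so subsets
missing informative taxa score strictly worse and the search is actually
asked to find all of them; at high depth a single taxon per block saturates
the score and the remaining informative taxa would be statistically
redundant, which would make "recover all informative taxa" an ill-posed
target. Search settings for the benchmark (patience 50, move cap 200,
reduced 40-sweep LDA fits) keep one 20-run benchmark around two minutes.

## Problem sizes in the test suite

Unit tests run on tables of 3–100 subjects and 4–40 taxa; the recovery
acceptance checks use M=200/B=40 (LDA), M=80/B=15 (feature search) and
M=90/B=25 (end-to-end), sizes at which the checked effects are already
clearly resolved. The full suite runs in about two minutes on one core.

## Known limitations

- The concordance filter is a documented greedy surrogate; an exact
  tau-path implementation can be plugged in via `taupath_rank`'s interface.
- Only the variational estimator is implemented; a collapsed Gibbs sampler
  would satisfy the same contracts but adds no tested surface.
- `A_w` is undefined for classes with no true instances; evaluation on very
  small classes can therefore error by design rather than report a
  misleading number.
- SMOTE on raw counts ignores compositionality; synthetic subjects are
  convex mixtures in count space, not on the simplex.
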