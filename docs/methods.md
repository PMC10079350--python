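# Methods

## Model

The unit of inference is a binary matrix **TI** (isoforms × GO terms), one
matrix per subontology (MF, BP, CC). The gene-level annotation map **TG**
constrains it: isoform *i* of gene *g* may only receive terms annotated to
*g* (after domain-evidence augmentation, below) that pass the specific-term
filter.

For a pair of isoforms (*i*, *j*) let τᵢⱼ = Σₜ TIᵢₜ·TIⱼₜ, the number of
shared terms, and let Sᵢⱼ be the pair's standardized sequence similarity.
The generative assumption is

    Sᵢⱼ = β₂·τᵢⱼ² + β₁·τᵢⱼ + β₀ + εᵢⱼ,   εᵢⱼ ~ N(0, 1) i.i.d.

so the total log-likelihood over n pairs is −SSR/2 − n·log(2π)/2, where SSR
is the sum of squared residuals. Maximizing it alternates:

- **E-step** (assignments given β): minimize SSR over the mutable bits of
  TI. This binary quadratic problem is searched by a genetic algorithm per
  mini-batch subset; `brute_force_min_ssr` provides the exact optimum for
  certification on small instances, decomposing the chromosome into
  connected components of the position-coupling graph (exact, because SSR is
  additive over pairs and each pair's positions lie in one component).
- **M-step** (β given assignments): ordinary least squares of S on
  [1, τ, τ²] over the pairs of the final E pass. The Gaussian noise SD is
  fixed at 1 and never re-estimated; a Kolmogorov–Smirnov diagnostic
  (`normality_diagnostic`) reports, but never gates, departures from N(0, 1).

### Pipeline per subontology

1. Parse inputs; drop GAF rows with a `NOT` qualifier; drop obsolete
   ontology terms.
2. Augment TG with GO terms implied by isoform domain matches through the
   InterPro-to-GO mapping (a domain present in an isoform is evidence about
   its gene too).
3. Keep only *specific* terms: terms annotating strictly fewer than
   `specific_threshold` of genes (default 10 %).
4. Build the candidate mask (gene terms × isoforms of that gene, active
   namespace only) and seed bits where an isoform's own domains imply the
   term.
5. Initialize β by OLS on one random subset of isoforms scored under the
   seed assignment; rank-deficient draws are resampled, then degraded to a
   lower-degree fit (see "Numerical choices").
6. Alternate E-phases and M-steps until the relative coefficient change
   falls below `beta_tol`.

Subontologies run MF → BP → CC. The CC run attaches the finished BP
assignment as frozen surrogate bits: they raise τ (functionally related
isoforms look related across subontologies) but are never searched, and they
are stripped from the CC output.

### Mini-batch E-step and convergence

Each E iteration draws a fresh uniform partition of all isoforms into
`n_subsets` subsets (sizes are binomial, not equalized). Within a subset,
the *eligible* pairs are those whose genes share ≥ 1 TG term in the active
namespace (same-gene pairs qualify whenever the gene is annotated); their
raw Smith–Waterman scores are standardized per subset, and the GA optimizes
the subset's mutable bits. The iteration records

    σᵢ = Σ over subsets (λ / λ*)

with λ the subset's total pair log-likelihood and λ* its pair count. The
E-phase declares convergence when σ_last − σ_(last−window) < threshold
(signed by default: any decrease also stops the phase, since σ is expected
to rise while the search improves).

## Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| `specific_threshold` | 0.10 | Broad terms (≥ 10 % of genes) are uninformative for discriminating isoforms and would dominate τ; strict `<` keeps the boundary case out. |
| `n_subsets` | 200 | Caps per-subset pair counts (alignment is O(subset²)) while leaving enough pairs per subset for the likelihood average to be meaningful at genome scale. Desk-scale corpora use proportionally fewer (e.g. 20 for 80 isoforms). |
| convergence `window` / `threshold` | 25 / 1⁄3 | σ is noisy across random partitions; a 25-iteration telescoped change smooths single-iteration jitter, and 1/3 is small relative to typical early-phase gains. |
| GA population / generations | 50 / 50 | Subset problems are small (tens of bits); this budget reaches the exhaustive optimum on ≤ 12-bit certification instances in ≥ 19/20 runs (acceptance criterion) at modest cost. |
| crossover / mutation / elitism | 0.8 / 0.1 / 1 | Standard GA settings; single-individual elitism makes the best-fitness trace monotone and guarantees the E-step never worsens a subset. |
| alignment | BLOSUM62, open 10, extend 4 | Conventional protein local-alignment scoring; an L-residue gap costs 10 + 4·(L−1). |
| noise SD | 1 (fixed) | Scores are standardized per batch, so the scale is absorbed by normalization; fixing σ=1 turns likelihood maximization into least squares in both steps. |
| `beta_tol` | 1e−4 | Relative coefficient change max|Δβ|/(1+|β|); below this the E-step landscape is unchanged for practical purposes. |
| `max_e_iterations` / `max_cycles` | 100 / 10 | Safety bounds; converged runs stop earlier via the σ rule and `beta_tol`. |
| seeding fraction (synthetic) | 0.3 | Emulates partial InterPro coverage: some, but far from all, true bits have domain evidence. |

## Score normalization

Raw Smith–Waterman scores within a batch are mapped through
y = log₁₀(x + a) with a = 0 when all scores are positive, otherwise
a = 10⁻⁶ − min(x), then z-scored with the sample standard deviation
(ddof = 1). The log tames the heavy right tail of alignment scores; the
offset keeps zero or negative batch minima finite while preserving rank
order. Batches with fewer than two scores or zero variance cannot be
standardized and are skipped.

## Synthetic generator: what it does and does not emulate

`simulate_universe` plants a truth with realistic *structure*: genes with a
fixed isoform count, a shared term universe, per-gene term draws, Bernoulli
isoform assignment with coverage repair (every gene term annotates ≥ 1
isoform, so the truth satisfies the coverage assumption by construction).
Two score pathways exist:

- **Model-derived** (`PlantedScoreProvider`): similarities drawn exactly
  from the quadratic model of the planted τ, with cached per-pair noise
  (noiseless mode available). This isolates the EM machinery from alignment
  behaviour.
- **Sequence-derived** (`simulate_sequences` + real alignment): each term
  gets a fixed random motif; an isoform concatenates the motifs of its
  planted terms with random filler, so alignment scores rise with shared
  terms. This exercises the full pipeline including Smith–Waterman and
  normalization.

Not emulated: realistic GO DAG topology (the emitted OBO stub has no
hierarchy), evidence-code mixtures, paralogy (cross-gene sequence
similarity unrelated to shared function), isoform expression biases,
sequencing or annotation errors, and realistic length/composition
distributions of proteins. Synthetic results therefore validate the
*mechanics* (recovery, convergence, determinism), not biological accuracy.

## Numerical choices

- **Likelihood identity.** All likelihood values are computed as
  −SSR/2 − n·log(2π)/2; a single zero-residual pair gives −0.9189385332….
- **OLS via `numpy.linalg.lstsq`** on the explicit [1, τ, τ²] design; a
  design spanning fewer than three distinct τ values (or rank < 3) raises a
  rank-deficiency error. During EM the M-step then keeps the previous
  coefficients; during initialization the subset is resampled up to 10
  times, after which the fit degrades to the highest identifiable
  polynomial degree (linear, then constant, missing coefficients zero) —
  the first genuine M-step replaces the guess anyway.
- **GA vectorization.** Each subset precomputes, per pair, the constant τ
  contribution of fixed bits, the chromosome positions contributing
  linearly (mutable-vs-fixed) and the position pairs contributing jointly
  (mutable-vs-mutable), so a whole population is evaluated with array
  products rather than per-individual matrix rebuilds.
- **Exhaustive tie-breaking.** `brute_force_min_ssr` enumerates components
  most-significant-bit first, so the first minimum encountered is the
  lexicographically smallest chromosome; components above `max_bits`
  (default 20) raise rather than silently explode.
- **Determinism.** Every stochastic element (partitions, GA, initialization
  subsets, synthetic corpora) draws from seeds derived from a single
  configured seed; repeated runs are bitwise identical (acceptance
  criterion 9 checks byte-identical output files).

## Limitations

- The quadratic similarity model is an assumption, not a finding; with
  per-batch standardization the intercept and curvature are weakly
  identified when τ spans few values (small subsets), which is why
  rank-deficiency fallbacks exist.
- The unit-variance Gaussian noise model is fixed rather than estimated;
  real alignment-score residuals are likely heteroscedastic (the KS
  diagnostic gives a first check).
- The E-step is a stochastic search: per-subset optima are certified only
  at small scale, and nothing guarantees a global optimum over the full
  matrix — mini-batching itself makes the objective a moving target across
  iterations.
- Eligibility, candidacy and τ are all namespace-local (except the frozen
  BP surrogates in CC); cross-namespace correlations are otherwise unused.
- The coverage assumption (every gene function realized by ≥ 1 isoform) is
  reported (`uncovered_terms_<NS>.tsv`) but not enforced; the GA may leave
  a gene term unassigned if the similarity evidence favors it.
- Domain seeds are trusted and, like all bits, may be flipped by the GA in
  later iterations; only cross-subontology surrogate bits are frozen.
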