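# Methods

## Model and procedure

The pipeline quantifies how strongly gene **functional category** and gene
**expression level** each predict the retention of duplicate genes after a
shared whole-genome duplication, in a clade of S species (default 3).

**Retention index.** For family *f* with per-species copy counts
*c₁…c_S*, the index is `r(f) = #{s : c_s ≥ t}` with duplicate threshold
*t* = 2. The threshold is configurable because lineages with extra
polyploidies can hold more than two syntenic copies; *t* = 2 is the minimal
reading of "maintained in duplicate". Species in which the family was lost
entirely (count 0) count as non-duplicated, exactly like singletons. The
labels all/mostly singletons/duplicates map indices 0–3 for three-species
clades.

**Functional rollup.** A gene matches low-level category Zij when the
scheme's GO term for Zij lies in the reflexive transitive closure of any of
the gene's direct GO annotations. Closure propagates over `is_a` edges only
by default; `part_of` can be enabled (`propagate_part_of`) since published
analyses do not always state which relations they rolled up over. The
closure is reflexive so that direct annotation with a scheme term counts.
Genes matching several low-level terms contribute one record per matched
term, including across high-level categories — no deduplication rule is
imposed. The shipped scheme maps 18 low-level GO terms (6 per high-level
category Z1/Z2/Z3) and can be replaced by any TSV with the same columns.

**Expression.** The analysis is gene-level (family-level averages are
distorted by order-of-magnitude spread and by family size), restricted to
one designated species per clade. A gene's score is its maximum normalized
expression over organs (missing organs ignored). Within each functional
category, genes scoring at or above the category's midpoint median are
HighExp, the rest LowExp; ties at the median go high. The median is taken
within the *low-level* term by default, because the design's atomic cells
are low-level term × bin; a `high` switch is provided. No log transform is
applied before splitting: the split depends only on ranks, which are
invariant to monotone transforms. Genes from families that are singletons
everywhere are included by default (`include_singleton_genes=False` to
drop them). Each gene inherits its family's retention index.

**Balanced design and inference.** Gene counts per category differ by an
order of magnitude, so the ANOVA response is the mean retention index of
each (low-level term, bin) cell — 36 rows, perfectly balanced (6 terms per
high-level category × 2 bins). An incomplete design (any empty cell) is an
error naming the cells. The two-way model `mean_retention ~ GOf * ExpQ` is
fitted by OLS and Type II sums of squares are computed (each main effect
adjusted for the other; on this balanced design Types I, II and III
coincide, which the tests verify). Effect sizes are partial eta squared
`SS_e/(SS_e + SS_res)`. Tukey HSD compares the three GOf levels over their
12 design rows each, using the *two-way model's* residual mean square and
df (30) — matching intervals computed from a fitted factorial model — with
the one-way pooled variance available as an option.

`gof_levels=4` splits Z3 into its regulation (Z31–Z33) and response
(Z34–Z36) halves, giving GOf df 3 and residual df 28. Published F values
for this analysis are more consistent with df 3 while the category scheme
itself defines three levels; both readings are supported and the default
is 3.

## Synthetic data

Per family: a low-level term is drawn uniformly from the scheme; a latent
expression `e ~ LogNormal(mu_expr[term], sigma_expr)` with z the
within-category standardized log expression; each species independently
retains the family in duplicate with probability
`expit(alpha + beta[Z] + (gamma + delta[Z])·z)`. Retaining species get 2
copies (more with `max_copies > 2`), others 1. Organ expression is `e`
times per-organ factors (max 1, geometric decay 0.8, randomly permuted per
gene) with multiplicative log-normal noise, so the organ max estimates
`e`. Every gene is annotated with its family's scheme term or (with
probability `child_annotation_prob`, default 0.5) a synthetic child of it,
so the end-to-end path genuinely exercises the DAG rollup; the generated
miniature ontology nests all scheme terms at least two `is_a` levels below
the three GO roots and includes an obsolete decoy.

Defaults are chosen to mimic the reported biology: `beta = {Z1: −1.0,
Z2: −0.8, Z3: +1.0}` (category spread 2.0 log-odds, metabolic most
fractionation-prone with enzymes close behind, regulation/response
resistant), `gamma = 0.2` (weak positive expression effect), `delta = {}`
(no interaction), `sigma_expr = 1` on the natural-log scale, 6 organs,
organ noise SD 0.25. The `rosid_like` preset (α = −1.5) yields a
retention distribution dominated by all-singleton families; `asterid_like`
(α = −0.6) a flatter one with all-singletons still modal.

What the generator does *not* emulate: lineage-correlated loss (species
are independent given the family's predictor), synteny structure,
annotation noise beyond optional random extra terms, family-size variation
within species beyond the copy-number cap, and tissue-specific expression
architecture. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under the stated generative model, not
that real genomes satisfy that model.

Standardization note: z is standardized within the gene's category
(`z = (log e − mu[term])/sigma`), which keeps `gamma` interpretable as
log-odds per within-category SD and makes
`expected_mean_retention = S·expit(·)` exact for tests. A consequence of
the logistic link is that a nonzero `gamma` induces a small cell-mean
interaction even at `delta = 0` (the logistic slope `p(1−p)` varies across
categories); with the default β pattern this curvature term is small and
the interaction test stays non-significant at the scales analyzed.

## Numerical choices

* Sums of squares within `1e-8` (relative to the response's total square)
  of zero are treated as exactly zero; genuinely negative SS beyond that
  tolerance is an internal error. With a constant response all effect SS,
  F and partial η² are reported as 0 (p = 1) rather than NaN.
* The studentized-range survival function is evaluated by a vectorized
  64×96-node Gauss–Legendre double quadrature (outer over the scaled chi
  variable, inner over the normal), cached per (k, df); it agrees with
  scipy's implementation to ~1e-10 and is two orders of magnitude faster,
  which the familywise-error calibration loop needs. Critical values come
  from Brent root-finding on that survival function.
* Median = midpoint median (`numpy.median`); with all scores equal the
  LowExp bin is empty by construction (every score ≥ median), which the
  design check then reports as an incomplete cell.
* Pipeline outputs are sorted with stable keys and written with pandas
  defaults, making repeated runs byte-identical.

## Problem sizes

Tests run the generator at 500–20,000 families: 10,000 for closed-form
recovery checks, 20,000 for the end-to-end effect-size ordering (the full
file-based pipeline in ~20 s), 500 replicates of 720 families for null
calibration of the F-tests, and 10,000 replicates for the Tukey
familywise-error calibration. Oracle suites use 1,000 random DAGs (≤ 30
nodes), all 543 labeled DAGs on 4 nodes, all 64 copy-count vectors in
{0..3}³, and 200 random balanced designs.

## Known limitations

* Retention labels are defined for three-species clades; other clade sizes
  get indices but no labels.
* The cell-mean strategy deliberately discards within-cell sample-size
  information (the price of balance); no weighted or mixed-model variant
  is provided.
* GAF parsing uses columns 2/5/7 only (object id, GO id, evidence) and
  drops `NOT`-qualified rows; no taxon or aspect filtering.
* Tukey p-values assume the studentized-range null; with the design's 12
  rows per level this is an approximation inherited from the published
  procedure, not a finite-sample exactness claim.
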