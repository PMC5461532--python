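# fracres

**Fractionation resistance of duplicate genes after whole-genome duplication.**

After a whole-genome duplication (WGD) or triplication, plant genomes shed most
of the duplicated gene copies — a process called *fractionation*. Two models
compete to explain which duplicates survive: the **Gene Balance Hypothesis**
(stoichiometric constraints preserve duplicates of regulatory and
stimulus-response genes) and the **Gene Dosage Hypothesis** (highly expressed
genes are kept in duplicate because halving their dose is costly). `fracres`
implements a statistical pipeline that weighs these two forces against each
other on gene-family data from a clade of post-polyploid species, and a
synthetic-data generator so every stage can be exercised and calibrated without
genome-scale inputs.

## The analysis

For a clade of *S* species (typically 3) descending from one shared polyploidy:

1. **Retention index** — per gene family, the number of species in which the
   family is still maintained in duplicate (copy count ≥ 2):
   *r* ∈ {0, …, S}, from "all singletons" (*r* = 0) to "all duplicates"
   (*r* = S).
2. **Functional rollup** — each gene's direct GO annotations are closed over
   the ontology DAG (`is_a` edges by default) and matched against a fixed
   scheme of 18 low-level GO terms, six per high-level category:
   **Z1** metabolic process, **Z2** enzyme class, **Z3** regulation & response.
3. **Expression binning** — each gene of a designated species is scored by its
   maximum normalized expression across organs, then split at the *median of
   its own functional category* into HighExp / LowExp (**ExpQ**).
4. **Balanced cell-mean ANOVA** — because raw gene counts per category are
   wildly unbalanced, the response is the *mean retention index* of each
   (low-level term × expression bin) cell: an 18 × 2 = 36-row balanced design.
   A two-way Type II ANOVA of `mean_retention ~ GOf * ExpQ` is fitted
   (GOf = high-level category), with the effect size of each term measured as
   partial eta squared, η²ₚ = SS_effect / (SS_effect + SS_residual), and the
   three pairwise GOf contrasts tested by Tukey's HSD (studentized-range
   familywise correction, CIs from the model residual).

The headline question — does functional category or expression level explain
more of duplicate retention? — is answered by comparing η²ₚ(GOf) against
η²ₚ(ExpQ) and checking the interaction.

The synthetic generator draws, per family, a functional category and a latent
log-normal expression level, then retains the family in duplicate in each
species independently with probability
`inverse_logit(α + β[Z] + (γ + δ[Z])·z)` — β carrying the category (balance)
effect, γ the expression (dosage) effect, δ their interaction — and emits the
exact TSV/GAF/OBO dialects the pipeline reads, including a miniature ontology.

## Worked example

```bash
fracres simulate --n-families 3000 --seed 11 --out demo/sim
fracres run \
    --families demo/sim/families.tsv --obo demo/sim/ontology.obo \
    --annotations demo/sim/annotations.gaf --expression demo/sim/expression.tsv \
    --scheme demo/sim/scheme.tsv --out demo/out
```

prints

```
Anova Table (Type II tests)
           Partial eta^2    Sum Sq   Df   F value  Pr(>F)
GOf              0.98017   11.3478    2  741.3205  2.8892e-26 ***
ExpQ             0.56856    0.3026    1   39.5342  6.258e-07 ***
GOf:ExpQ         0.19131    0.0543    2    3.5484  0.041378 *
Residual                    0.2296   30

Tukey HSD (95% family-wise confidence)
  Z2-Z1: +0.1915 [+0.1034, +0.2795]  p_adj=2.4481e-05 ***
  Z3-Z1: +1.2751 [+1.1871, +1.3632]  p_adj=1.9873e-13 ***
  Z3-Z2: +1.0836 [+0.9956, +1.1717]  p_adj=1.9873e-13 ***
```

Read this as: across the 36 balanced cells, high-level functional category
(GOf) explains far more of the variation in mean retention (η²ₚ = 0.98) than
the expression bin does (η²ₚ = 0.57), and the regulation-and-response category
Z3 is retained about 1.1–1.3 index points above the metabolic and enzymatic
categories — the generator's built-in category effect (β spread 2.0 log-odds,
weak γ = 0.2) recovered by the pipeline. `fracres report --run-dir demo/out`
re-renders the tables and the per-category family counts.

The same analysis runs on real inputs: a family table (TSV, one row per gene
copy), a GO ontology (OBO), annotations (GAF 2.x or two-column TSV), and a
genes × organs expression matrix (TSV). All thresholds (duplicate cutoff,
median-split level, 3- vs 4-level GOf factor, `part_of` propagation) are CLI
flags; the Python API (`fracres.run_pipeline`, `fracres.simulate`, …) exposes
the same knobs.

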