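# lifecal

Tools for studying the **genetic lifespan calendar** of brain gene
expression: per-gene expression trajectories across the lifespan, the
turning points where those trajectories peak and plateau or reverse, and
what those turning points say about cell types, gene sets, disease
susceptibility and the age of a tissue sample.

The package is aimed at transcriptomics researchers working with bulk
expression matrices sampled across a lifespan (human cortex in years,
mouse hippocampus in days), plus the usual satellite inputs: GMT gene
sets, gene × cell-type specificity matrices from single-cell data, and
gene-level association z-scores (the MAGMA `.genes.out` dialect).

## The model

For each gene *g*, expression *E* is regressed on age *A* with a natural
cubic spline (default 3 degrees of freedom, interior knots at age
quantiles, covariates such as sex/strain held constant for
interpolation).  A **turning point** is the first age where the
interpolated trajectory's derivative d*E*/d*A* equals zero and changes
sign; Δ*E* is the signed expression change from the start of the
lifespan to the turning age *A_g*.  Genes are scored per target age *T*:

- **age-linked score**  `S(g,T) = 1.5^(−|A_g − T|) · |ΔE|`
  (mouse day-distances are divided by 650/78 so a day counts as the same
  fraction of lifespan as a human year).  Six years of distance leaves
  ≈ 9 % of the zero-distance score.
- **decile score** — |ΔE| in the one turning-count-decile age set
  containing *A_g*, zero elsewhere.
- **peak score** — the age-linked score at the modal turning year.

Gene sets are tested for elevated scores against random same-length
lists (10,000 bootstrap lists by default; one-sided
`p = (1 + #{null ≥ obs}) / (1 + n)`), optionally matched on transcript
length × GC deciles; GWAS gene-level z-scores are coupled to scores by
`Σ_g z_g·S_g` under 20,000 z permutations with the extended MHC
excluded.  Cell-type enrichment follows the expression-weighted scheme:
per age window and trajectory direction, the top 10 % of turning genes
by |ΔE| are compared with bootstrap nulls in units of null standard
deviations *d*, normalized to max |d| = 1 per (cell type, direction).
Sample age is predicted from expression by RBF support-vector
regression under nested 10×10-fold cross-validation with per-fold
linear-model probe ranking (top *N* probes; two-stage base-2 grid search
over kernel width and cost).

Everything runs on a bundled synthetic-cohort generator with known
ground truth (planted turning ages, amplitudes, sex delay, gene sets,
cell-type marker blocks), so the whole pipeline is testable offline.

## Worked example

```python
import lifecal as lc

# a 200-sample human-like cohort; 60 genes planted to turn at ~24 y
spec = lc.SimulationSpec(
    seed=7, n_samples=200, n_genes=1000, fraction_simple=0.5,
    planted_sets={"synaptic": lc.PlantedSet(size=60, turn_age_mean=24.0,
                                            turn_age_sd=1.5)})
ds, truth = lc.simulate_dataset(spec)

trajs = lc.dataset_trajectories(ds, df=3)          # natural splines
table = lc.classify_turning_points(ds, lc.detect_all(trajs))
print(f"{table.n_turning} of {len(table.table)} genes turn; "
      f"mean turning age {table.turning['age'].mean():.1f} y")

ali = lc.aliget_matrix(table)
windows, per_age = lc.enrichment_windows(
    ali, truth.gene_sets()["synaptic"], n_boot=2000, seed=7)
for w in windows:
    print(f"enrichment window: {w.start:.0f}-{w.end:.0f} y")

result = lc.nested_cv_predict(ds, lc.PredictionModelSpec(
    n_cutoff=40, seed=7, fine_step=0.25))
print(f"age prediction: accuracy {result.accuracy:.1f} y, "
      f"R^2 {result.r_squared:.2f}")
```

prints

```
504 of 1000 genes turn; mean turning age 39.0 y
enrichment window: 29-39 y
age prediction: accuracy 3.0 y, R^2 0.98
```

So half the genes carry a detectable turning point, the planted
"synaptic" set produces a Bonferroni-significant young-adult enrichment
window, and expression predicts sample age to 3 years (R² = 0.98).
Note the window sits later than the planted 24 y: the 3-df spline
smoother localizes turns with a systematic late bias on plateau-type
trajectories (quantified in `docs/methods.md`) — a property shared with
the analysis it implements, where the mean turning age moves by ~10 y
between 3-df, 4-df and loess smoothers.

The same stages are available from the shell:

```sh
lifecal simulate --seed 7 --out-dir sim/
lifecal tttp --matrix sim/matrix.tsv --meta sim/meta.tsv --out tttp.tsv
lifecal score --tttp tttp.tsv --method peget --out peget.tsv
lifecal enrich --tttp tttp.tsv --sets sets.gmt --mode windows --out enrich.tsv
lifecal predict-age --matrix sim/matrix.tsv --meta sim/meta.tsv --out pred.tsv
```

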