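# itvsample

Sampling-effort optimization for intraspecific trait variability (ITV) in
tree canopies.

## The problem

Leaf functional traits — here specific leaf area (SLA, mm²/mg) and the
magnitude of leaf osmotic potential (π, −MPa) — vary not only between
populations and between individual trees, but also *within* a single crown,
along vertical (height class) and horizontal (external/internal) light
gradients. Field campaigns must decide how many trees and how many leaves
per tree to sample, and from which canopy strata, to estimate a population's
trait mean with acceptable precision and accuracy at minimal effort.
`itvsample` turns that decision into a reproducible computation for
ecologists planning trait surveys.

The pipeline has four stages:

1. **Variance partitioning.** A permutational ANOVA (Euclidean distance,
   univariate, all factors fixed, individuals nested in quadrats) splits the
   total sum of squares over quadrat, individual(quadrat), height class
   `h_class` ∈ {a, b}, canopy position ∈ {E, I} and their interactions. The
   share of a term is SS_term/SS_total; pseudo-F = MS_term/MS_residual is
   tested by permutation of residuals under the reduced model
   (Freedman–Lane), p = (1 + #{F* ≥ F}) / (1 + n_perm).
2. **Precision curve.** For each sample size n, leaves are resampled without
   replacement (4999 replicates by default), each replicate scoring
   SE = SD/√n. A broken-line model y = β₀ + β₁n + β₂(n − ψ)₊ fitted to the
   mean-SE curve gives the flex point ψ; the fitted value there, SE_min,
   defines the minimum acceptable precision.
3. **Strategy simulation.** A registry of multistage sampling strategies
   (random; quadrat-balanced; canopy-stratified; external-only and
   upper-external-only protocol variants) is simulated over the full grid of
   sampling sizes (individuals × leaves per individual), recording per-cell
   mean, SE and CV per trait.
4. **Selection.** Strategies whose aggregated means fall outside the 95% CI
   of the whole-data mean, or whose SE exceeds SE_min, are discarded. Within
   the most accurate admissible strategy, sizes are scored by the
   standardized deviation S = |x̄_m − x̄_whole| / SD_whole summed over traits;
   the cheapest size meeting both criteria is the *minimum*, and the size
   with the largest one-step drop in ΣS along the effort-ordered sequence is
   the *optimal* compromise.

A synthetic-data generator reproduces the hierarchical design of a real
holm-oak (*Quercus ilex*) campaign — 3 quadrats with 5/17/12 trees and
12 leaves per tree, 3 per canopy stratum (408 leaves) — with configurable
variance fractions per model term, so the whole pipeline is testable
end-to-end without field data.

## Worked example

```python
import itvsample as iv

dataset = iv.generate_dataset(iv.study_config(), seed=1)
print(iv.summarize_design(dataset).individuals_per_quadrat)

table = iv.fit_anova(dataset, "sla")
table = iv.permutation_pvalues(dataset, "sla", table,
                               iv.PermutationConfig(n_perm=999, seed=0))
print(table.to_frame().round(3).head(5).to_string(index=False))

curve = iv.resample_se_curve(dataset, "sla", reps=1999, seed=0)
fit = iv.fit_breakpoint(curve)
print(f"flex point: n = {fit.psi:.1f}, SE_min = {fit.se_min:.3f}")

stats = {t: iv.whole_data_stats(dataset, t) for t in dataset.trait_names}
print(f"SLA whole-data mean {stats['sla'].mean:.2f} "
      f"CI [{stats['sla'].ci_low:.2f}, {stats['sla'].ci_high:.2f}]")
```

prints

```
{'Q1': 5, 'Q2': 17, 'Q3': 12}
           term  df     SS     MS  pseudo_F  p_perm  variance_percent
        quadrat   2  4.501  2.251     2.603   0.077               1.2
        h_class   1 69.392 69.392    80.255   0.001              18.5
       position   1  9.752  9.752    11.279   0.002               2.6
     individual  31 56.264  1.815     2.099   0.002              15.0
quadrat:h_class   2  0.000  0.000     0.000   1.000               0.0
flex point: n = 31.4, SE_min = 0.116
SLA whole-data mean 8.02 CI [7.93, 8.11]
```

The height class dominates SLA variation (18.5% of total SS, pseudo-F 80,
p at the permutation floor), individuals carry 15%, and precision gains
flatten beyond roughly 31 leaves, where the mean SE of a random subsample
reaches 0.116 mm²/mg. With this generator configuration the variance
percentages recover the configured fractions exactly; interaction terms
given no variance score zero.

The same stages are scriptable from the shell:

```bash
itvsample simulate-data --seed 1 --out leaves.csv
itvsample partition-variance --input leaves.csv --trait sla --out anova.csv
itvsample precision-curve --input leaves.csv --reps 4999 --out curve.csv
itvsample run-all --seed 1 --out results_dir
```

`run-all` executes every stage with substream seeding and writes delimited
tables plus a `manifest.json` (config, config hash, seed, versions); reruns
with the same seed are bit-identical.

## Layout

- `itvsample.data` — trait-table model, delimited I/O, design summaries, SLA utility
- `itvsample.simulate` — hierarchical synthetic-data generator and exposure scheme
- `itvsample.anova` — permutational ANOVA and variance percentages
- `itvsample.precision` — resampling SE/CV curves, broken-line flex point
- `itvsample.strategies` — strategy registry, multistage sampler, grid simulation
- `itvsample.selection` — screening, standardized deviation, size selection
- `itvsample.pipeline` / `itvsample.cli` — orchestration, manifest, CLI

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
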