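# operonwave

Toolkit for operon-aware analysis of genome-wide transcriptional stress
responses in bacteria.

When a stress perturbs transcription globally (RNA polymerase depletion,
initiation inhibitors, gyrase inhibitors), the genes of an operon do not
respond identically: premature termination of elongating RNA polymerase makes
downstream genes respond more weakly than their upstream neighbours, while
internal promoters re-boost the genes they control. Pooled over all operons,
the mean absolute difference in log2 fold change between two genes of the same
operon, μ_|ΔLFC|, varies with their gene-unit distance L_G as a wave:

    μ_|ΔLFC|(L_G) = A0 + A·L_G + B·sin(k·L_G),    k = 2πf

with amplitude B set by the premature-termination rate and spatial frequency f
set by the spacing of internal promoters. In operons without internal TSSs the
relation is instead a rising line. `operonwave` implements the full analysis
chain around this statistic, plus a stochastic kinetic model that reproduces
it from first principles, for anyone studying operon architecture, polarity,
or internal-promoter function from RNA-seq fold-change tables.

## What's in the box

- **`operon_io`** — RegulonDB-style annotation tables (operons, TSSs, TTSs),
  DESeq2-style fold-change tables and featureCounts-style start/end region
  counts; structural summaries, downstream-gap/TTS statistics, and a
  uniform-placement null for internal-TSS positioning.
- **`pair_stats`** — within-operon pair enumeration, μ_|ΔLFC|(L_G) distance
  curves with SEM and bootstrap CIs, internal-TSS and supercoiling-sensitivity
  stratification, response vs. position and vs. promoter distance L_P,
  fold-change standard errors, unbiased spatial autocorrelation.
- **`wave_fit`** — the wave and linear models, 100-restart nonlinear least
  squares, R²/BIC/AIC model selection, and amplitude flatness tests against
  null ensembles.
- **`null_models`** — the four randomizations: gene positions within operons,
  operon membership, both, internal-TSS label flips, and internal-promoter
  position shuffles.
- **`termination`** — premature-termination estimation from start/end read
  counts: r_f = (start − end)/start per gene, position profile R_f(P), TPM
  normalization, replicate t-tests, condition comparisons.
- **`annotation_stats`** — GO co-function statistic P_c = n_c/(N_i·N_j) with a
  cross-operon random-pair null, L_P cohort statistics with KS tests, promoter
  AT-richness (−60..+20 window), exact/1-mismatch motif scans.
- **`ssa`** — Gillespie model of operon transcription: multistep initiation
  (closed → open complex → escape), gene-granular elongation, spontaneous
  falloff, and RNAP–RNAP collisions at occupied internal promoters, with an
  analytic rate oracle and a tandem-promoter interference experiment.
- **`synthetic_data`** — seeded generators for every input above, so the whole
  pipeline runs without any external download.
- **`experiments`** — end-to-end drivers chaining the simulator into the curve
  pipeline.

## Worked example

```python
from operonwave.synthetic_data import SyntheticConfig, generate_annotation, generate_expression
from operonwave.pair_stats import enumerate_pairs, delta_lfc_curve
from operonwave.wave_fit import fit_wave, fit_linear, select_model

config = SyntheticConfig(seed=0)                      # ~300 operons, s = 0.8, TSS every 4 genes
annotation = generate_annotation(config)
expression = generate_expression(annotation, config)  # per-gene log2 fold changes + noise

pairs = enumerate_pairs(annotation, expression)
curve = delta_lfc_curve(pairs, max_lg=8, seed=0)
wave = fit_wave(curve, n_restarts=100, seed=0)
line = fit_linear(curve)
choice = select_model(wave, line)

print(f"{len(pairs)} within-operon gene pairs from {len(annotation.operons)} operons")
print(curve.data[["x", "mean", "sem", "n"]].round(3).to_string(index=False))
print(f"selected model: {choice.selected} (by {choice.by})")
print(f"wave fit: B = {wave.B:.3f}, f = {wave.f:.3f} oscillations/gene, R^2 = {wave.r2:.3f}")
print(f"linear fit: slope = {line.slope:.3f}, R^2 = {line.r2:.3f}")
```

prints

```
3215 within-operon gene pairs from 300 operons
 x  mean   sem   n
 1 0.388 0.007 880
 2 0.556 0.007 655
 3 0.447 0.019 487
 4 0.235 0.007 359
 5 0.561 0.010 262
 6 0.674 0.023 188
 7 0.533 0.047 136
 8 0.361 0.017  95
selected model: wave (by r2)
wave fit: B = 0.142, f = 0.208 oscillations/gene, R^2 = 0.600
linear fit: slope = 0.008, R^2 = 0.022
```

The bin means oscillate with distance rather than rising monotonically — genes
separated by about half the internal-promoter spacing (here, promoters every 4
genes) diverge most, genes a full spacing apart are re-synchronized by the
next internal promoter, and model selection picks the wave over the line.
Setting `internal_tss_spacing=0` in the config removes internal promoters, and
the same pipeline then selects the linear model: divergence grows steadily
with distance because premature terminations attenuate only the single
upstream promoter's signal.

## Command line

Five thin subcommands wrap the library:

```bash
operonwave simulate-data --out data/ --seed 7
operonwave curves --annotation data/annotation.tsv --expression data/expression.tsv \
                  --out curve.tsv --max-lg 8
operonwave null --annotation data/annotation.tsv --expression data/expression.tsv \
                --kind positions --reps 1000 --seed 1 --out null.tsv
operonwave termination --annotation data/annotation.tsv --counts data/region_counts.tsv \
                       --condition control --out rf.tsv
operonwave simulate-ssa --model model.yaml --runs 200 --horizon 1e5 --seed 3 --out ssa.tsv
```

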