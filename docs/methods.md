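# Methods

This note documents the models, estimators, numerical choices and limitations
behind `operonwave`, in the order a user meets them.

## Coordinate and distance conventions

Genomic coordinates are 1-based inclusive (RegulonDB convention). Within an
operon, gene positions `P = 1..n` count from the operon's 5' gene along its
own strand; minus-strand operons are ordered at parse time so all downstream
computations are strand-free. Distances between genes (`L_G`) and between
promoters (`L_P`) are in gene units, adjacent = 1. A TSS is assigned
`first_gene_index` = the first gene whose coding start lies strictly
downstream of it on the operon strand; a TSS downstream of every coding start
is dropped with a warning (there is nothing it can transcribe within the
operon). "An internal TSS between genes i < j" means a promoter with
`i < first_gene_index ≤ j`, so at `L_G = 1` it denotes a TSS in the
intergenic region between the two genes. TSSs inside coding regions are
treated identically to intergenic ones — annotations rarely distinguish the
two reliably, and the assignment rule above is well-defined either way. The
genome is treated as circular: the gap downstream of the last operon wraps to
the first gene.

Two conventions exist for a promoter with no downstream TSS in its operon:
`L_P = 0` (the "next TSS is not downstream" rule used for the per-promoter
response statistic) or `L_P` = number of genes remaining to the operon end
("remaining", flagged `open_ended`). Both are implemented and switchable;
cohort statistics default to "zero", while the synthetic generator's
compensation structure uses "remaining" (see below).

## The divergence statistic and the wave model

For each condition, all unordered within-operon gene pairs with known LFCs
contribute `|ΔLFC|` at their distance `L_G`; pairs with a missing LFC are
dropped and counted. The distance curve reports per-bin mean, SEM
(`sd/√n_pairs`) and a seeded nonparametric bootstrap 95% CI (2000 resamples by
default; the bootstrap is used because the binned statistic is a mean of
strongly non-Gaussian folded differences).

The wave model `μ(L_G) = A0 + A·L_G + B·sin(2πf·L_G)` is fitted by bounded
nonlinear least squares (scipy TRF) on the binned means, best-of-100 random
restarts, with `B ≥ 0` and `f ∈ (f_min, 0.5]`:

- **Upper bound 0.5** is the Nyquist frequency at unit gene spacing;
  unconstrained sine fits alias.
- **Lower bound** `f_min = 1/(4·range)` and **amplitude cap** `B ≤ ptp(y)`
  are identifiability guards: as `f → 0`, `B·sin(2πfx)` degenerates into a
  low-order polynomial mimic with arbitrarily large `B` and a compensating
  linear term, which makes the fitted amplitude meaningless as a wave
  statistic. A sine that does not complete a quarter oscillation within the
  fitted range, or whose amplitude exceeds the curve's total span, is not
  evidence of a wave. Both bounds are overridable.
- The model has no phase term, so the sign of the oscillation is carried by
  `f`, not by `B`; this matches the convention that `B` is an amplitude.
- Restarts draw `f` uniformly within bounds and `B` uniformly in
  `[0, ptp(y)]`; `A0, A` start from the OLS line plus jitter. The restart
  winner is chosen on the optimizer's own objective (weighted when
  `weights=True` uses 1/SEM²), and fits are seed-deterministic.
- A fitted `B` below 10⁻⁶ of the data range is flagged `degenerate`
  (frequency unidentifiable).

Linear fits are ordinary least squares with a t-test of the slope against a
horizontal line.

### Model selection

Selection between the wave and the line follows highest R², then lowest BIC,
then lowest AIC, with a full tie going to the fewer-parameter model. Two
numerical choices matter:

- R² values within `r2_tol = 0.01` (the precision at which R² is normally
  reported) are treated as tied; otherwise the 4-parameter wave, which nests
  the line at `B = 0`, would win every comparison by an infinitesimal margin
  and the line could never be selected.
- BIC/AIC are evaluated on the pair-level Gaussian likelihood whenever the
  curve carries bin counts: `N` = total pairs, RSS = within-bin sum of squares
  plus the n-weighted between-bin misfit. A bins-only likelihood (n ≈ 10
  points) lets the sine's tunable frequency always harvest enough bin-level
  residual to beat the 2·ln(n) penalty — under it, simulated operons with *no*
  internal promoters select the wave in ~90% of replicates, i.e. the selection
  loses all power against overfitting. The pair data are what the bins
  summarize, so they are the honest evaluation set; bare `(x, y)` input falls
  back to the bins-only formula.

### Flatness testing

`flatness_test` compares an observed curve's fitted amplitude `B` (and |OLS
slope|) against the same statistic computed on a shuffle ensemble, with
`p = (1 + #{null ≥ obs})/(n_null + 1)`. Observed and null fits use identical
restart counts and tolerances so the two statistics are exchangeable under the
null. Because every observed curve is compared against the same estimated null
tail, the ensemble should be large (default 1000 replicates; 500 in the
package's own timed experiments) — a small ensemble correlates repeated tests
through its quantile-estimation noise. Null-ensemble fits use 10–15 restarts
at tolerance 1e−10 (amplitude estimation does not need the 1e−14 used for
exact parameter recovery).

## Null models

All four randomizations operate on annotation copies and never touch the
expression table, so the LFC multiset entering the statistic is identical in
every replicate:

- **positions**: gene identities permuted over each operon's position slots
  (promoter `first_gene_index` stays bound to the slot).
- **operons**: gene identities permuted globally across all operon slots,
  preserving every operon size (the conservative choice; a size-free variant
  would confound size structure with membership).
- **both**: composition of the two.
- **promoters**: each internal promoter's `first_gene_index` resampled
  uniformly over `2..n`.

## Premature-termination estimator

`r_f(i,j) = (reads_start − reads_end)/reads_start` per gene;
`R_f(P) = Σ_j r_f(P,j)/k` over the `k` genes at position `P`. Counts are
TPM-normalized with one scaling per replicate library (start and end regions
come from the same library; separate normalizations would distort the ratio),
then averaged over replicates before forming `r_f` (a per-replicate option
exists). Genes whose coding regions contain an annotated TTS are excluded
(their termination is not premature), as are genes with zero start reads.
Negative `r_f` values are retained — internal promoters can add flux near gene
ends, and the estimator does not truncate. Error bars carry both the SE of the
mean (`sd/√k`) and the SE of the sum (`sd·√k`); positions with a single gene
report NaN (no variance estimate from one observation). `R_f(P) = 1 − s` in
expectation when each gene transmits a fraction `s` of its incoming
polymerases, with a downward bias of order `s/E[reads_start]` from the ratio
of Poisson counts — negligible at the read depths used here.

## Stochastic model of operon transcription

State: each promoter is free, in closed complex, or in open complex; each
elongating RNAP occupies one gene-granular lattice site. Channels:

- promoter cycle free →(k_bind) closed →(k_cc) open →(k_oc) escape, the escape
  spawning an elongating RNAP at the promoter's first gene. An explicit
  `k_escape` is folded into the open→escape step harmonically
  (1/k = 1/k_oc + 1/k_escape), which preserves the steady-state escape flux
  `1/(1/k_bind + 1/k_cc + 1/k_oc)` exactly.
- per elongating RNAP: traversal (`k_elong`, increments the gene's completed
  transcript count, advances or finishes) competing with spontaneous falloff
  (`k_falloff`), so per-gene survival is `s = k_elong/(k_elong + k_falloff)`.
- collisions: an RNAP stepping onto a promoter site holding a closed or open
  complex draws an outcome — pass through / elongating terminates / bound RNAP
  displaced (closed) or both terminate (open). Defaults split the
  non-pass outcomes 50:50; a pass-through policy disables interference
  entirely. Probabilities are fully configurable.

Defaults (`k_bind = 0.1/s`, `k_cc = k_oc = 0.02/s`, `k_elong = 1/s`,
`k_falloff = 0.25/s`) make closed/open-complex formation rate-limiting
(initiation interval ≈ 110 s) and give per-gene survival 0.8, the same
survival the synthetic read-count conditions use. Stress multiplies `k_cc` and
`k_oc` by 2 and scales per-gene falloff rates by a multiplier, optionally with
mean-one lognormal gene-to-gene variability. Gene-granular positions are used
because every statistic downstream is in gene units; a finer lattice adds
parameters with no testable counterpart. No RNA degradation is modelled (LFCs
compare production); the RNAP pool is infinite by default (`k_bind` is
pseudo-first-order), with an optional hard pool cap.

The simulator is an exact direct-method SSA. Two engines implement the same
process: a numba-compiled kernel (default) and a pure-Python reference with an
event log; they are cross-checked statistically in the test suite. Ensembles
derive independent sub-seeds from a master seed, so experiments differing only
in a rate multiplier share random streams (coupled-seed comparisons). The
analytic oracle `rate(g) = Σ_p flux_p Π_{h=fg(p)}^{g} s_h` is valid whenever
collisions are disabled and is the simulator's correctness reference.

The tandem-interference experiment measures `(E_U + E_D)/E_T` on a two-site
construct (upstream promoter at site 1, downstream at site 2, reporter = site
2, no falloff): 1 under pass-through collisions, rising above 1 — and rising
further as the downstream promoter's escape rate drops (longer occupancy) —
when collisions terminate polymerases.

## Synthetic data: what it emulates, what it does not

The generator lays out operons with geometric-like sizes (p = 0.25 truncated
at 15: median 3, mean ≈ 3.7 genes), ~50 nt intragenic-operon spacing, ~900 nt
genes, a primary promoter per operon, internal promoters every 4 genes
(regular grid, or random placement with the same count), and TTSs in a
configurable fraction (default 0.2) of downstream gaps, with TTS-bearing gaps
drawn shorter (200 vs 400 nt means) so the downstream-gap/TTS asymmetry is
present as ground truth.

Expected expression of the gene at position `P` is
`Σ_{promoters p: fg ≤ P} flux_p(condition) · s^(P − fg)`; LFC =
log2(stress/control) + Gaussian noise (default sd 0.1 log2 units — DESeq2
LFCs are approximately normal at moderate counts). Stress doubles every
promoter's flux (1.0 log2 units) and doubles the per-gene termination hazard
`−ln s` (survival 0.8 → 0.64). Region counts are Poisson with
`E[end] = s·E[start]` at depth 500. GO terms propagate down the operon with a
per-gene retention probability (default 0.7), so expected term sharing decays
geometrically with distance. An optional compensation structure
(`lp_response_slope`) makes a promoter's stress response grow with the number
of genes it must cover before the next TSS (the "remaining" convention — a
last promoter covering the operon tail is strong, not `L_P = 0` weak); it is
off by default and switched on only for the L_P–response experiments.

Passing tests on these data show that the estimators recover the generative
structure they are designed for. They do not show robustness to features of
real RNA-seq the generator omits: dispersion beyond Poisson, coverage bias
along genes, operon-specific regulation, mixed-strand artifacts, incomplete
or wrong TSS annotations, or LFC shrinkage by the differential-expression
model.

## Experiment design notes

- The simulator-to-curve experiments use a single 12-gene operon, 200 runs of
  10⁵ s per condition (scaled down from ensembles of 1000 × 10⁶ s; at these
  rates ~900 initiations per promoter per run leave Monte-Carlo error an order
  of magnitude below the wave amplitude, and a self-consistency test confirms
  short-horizon ensembles reproduce long-horizon means).
- Genome-scale curve analyses restrict to bins with ≥ ~100 pairs (`L_G ≤ 8`
  under the default 300-operon genome): sparse tail bins contribute only
  noise, and amplitude statistics computed on them swamp the real wave.
- In the shuffle-null experiments each trial must be independent: null
  ensembles are kept large (≥ 500) because all trials share the estimated
  null tail, and the L_P null draws fresh LFC noise per trial — reusing one
  noise realization conditions every t-test on the same draw.
- Empirical p-values use the add-one convention `(1 + #{null ≥ obs})/(n + 1)`,
  which is exact (slightly conservative) under exchangeability.

## Known limitations

- Collisions between two elongating RNAPs are not modelled (only
  elongating-vs-promoter-bound), and promoter sites do not exclude binding
  while an elongating RNAP passes; both effects are second-order at the
  default initiation rates.
- The gene-granularity lattice cannot represent sub-gene pausing or terminator
  read-through kinetics; supercoiling enters only as falloff-rate modulation.
- `motif_scan` is exact/1-mismatch literal matching; gapped alignment of
  degenerate pause motifs is out of scope (for the ungapped homopolymer and
  pause motifs involved, mismatch scanning is equivalent and deterministic).
- The GO statistic uses direct term lists (`P_c = n_c/(N_i·N_j)`,
  implemented verbatim — note it is not a Jaccard index and its denominator
  can push values far below 1 even for identical annotations with many
  terms); no ontology-graph propagation.
- The wave/line dichotomy is a property of binned curves with enough pairs per
  bin; with fewer than 5 bins the wave model is not fitted at all.
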