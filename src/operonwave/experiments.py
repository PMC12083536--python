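"""End-to-end experiment helpers chaining the simulator into the curve pipeline.

These functions reproduce the in-silico experiments that connect the stochastic
operon model to the distance-resolved divergence statistic: simulate a control
and a stress ensemble, form per-gene LFCs, enumerate within-operon pairs, bin
μ_|ΔLFC|(L_G) and fit the wave and linear models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operon_io import GeneRecord, GenomeAnnotation, PromoterRecord
from .pair_stats import delta_lfc_curve, enumerate_pairs
from .ssa import (
    CollisionPolicy,
    EnsembleResult,
    OperonKineticModel,
    PromoterSpec,
    ensemble_lfc,
    run_ensemble,
)
from .wave_fit import ModelSelection, fit_linear, fit_wave, select_model


def operon_model(
    n_genes: int = 12,
    internal_tss_spacing: int = 4,
    k_bind: float = 0.1,
    k_cc: float = 0.02,
    k_oc: float = 0.02,
    k_elong: float = 1.0,
    k_falloff: float = 0.25,
    collision_policy: CollisionPolicy | None = None,
) -> OperonKineticModel:
    """A single-operon kinetic model with internal promoters every ``d`` genes.

    ``internal_tss_spacing=0`` yields a primary-promoter-only operon.  Default
    rates put the rate-limiting steps at closed/open complex formation and give
    per-gene survival s = k_elong / (k_elong + k_falloff) = 0.8.
    """
    proms = [PromoterSpec(1, k_bind, k_cc, k_oc)]
    d = internal_tss_spacing
    if d and d > 0:
        proms += [PromoterSpec(fg, k_bind, k_cc, k_oc) for fg in range(1 + d, n_genes + 1, d)]
    return OperonKineticModel(
        n_genes=n_genes, promoters=proms, k_elong=k_elong, k_falloff=k_falloff,
        collision_policy=collision_policy or CollisionPolicy.passthrough(),
    )


def annotation_from_model(model: OperonKineticModel, operon_id: str = "op1") -> GenomeAnnotation:
    """A one-operon GenomeAnnotation whose gene ids match ensemble_lfc's defaults."""
    genes, promoters = [], []
    start = 100
    for g in range(1, model.n_genes + 1):
        genes.append(GeneRecord(f"g{g}", operon_id, g, start, start + 899, "+"))
        start += 950
    for i, p in enumerate(model.promoters):
        tss = genes[p.first_gene_index - 1].start_nt - 20
        promoters.append(PromoterRecord(f"{operon_id}_p{i + 1}", operon_id, tss, p.first_gene_index))
    return GenomeAnnotation(genes=genes, promoters=promoters, terminators=[], genome_length_nt=start + 1000)


@dataclass
class WaveExperimentResult:
    curve: object
    selection: ModelSelection
    control: EnsembleResult
    stress: EnsembleResult
    lfc: object


def ssa_wave_experiment(
    model: OperonKineticModel,
    seed: int,
    n_runs: int = 200,
    horizon_s: float = 1e5,
    init_multiplier: float = 2.0,
    falloff_multiplier: float = 2.0,
    falloff_sigma: float = 0.0,
    n_restarts: int = 100,
) -> WaveExperimentResult:
    """Control vs stress ensembles -> LFC -> μ_|ΔLFC|(L_G) -> wave/linear selection.

    Stress doubles the initiation rate constants (k_cc, k_oc) of every promoter
    and scales per-gene falloff rates by ``falloff_multiplier`` (optionally
    with lognormal gene-to-gene variability).  Sub-seeds are derived from the
    master seed, so two calls differing only in a multiplier share their random
    streams (coupled-seed comparisons).
    """
    s1, s2, s3 = (int(x) % (2**31) for x in np.random.SeedSequence(seed).generate_state(3))
    stress_model = model.with_stress(init_multiplier, falloff_multiplier, falloff_sigma, seed=s3)
    control = run_ensemble(model, n_runs, horizon_s, s1, condition="control")
    stress = run_ensemble(stress_model, n_runs, horizon_s, s2, condition="stress")
    lfc = ensemble_lfc(control, stress)
    ann = annotation_from_model(model)
    pairs = enumerate_pairs(ann, lfc)
    curve = delta_lfc_curve(pairs, n_boot=0)
    wave = fit_wave(curve, n_restarts=n_restarts, seed=s1)
    line = fit_linear(curve)
    return WaveExperimentResult(
        curve=curve, selection=select_model(wave, line), control=control, stress=stress, lfc=lfc,
    )


def flatness_null_experiment(
    annotation,
    expression,
    kind: str,
    n_reps: int = 500,
    n_seeds: int = 20,
    seed: int = 0,
    max_lg: int = 8,
    n_restarts: int = 10,
) -> dict:
    """Shuffle-null flattening check for one randomization kind.

    Builds a null curve ensemble, then asks (a) whether the unshuffled curve's
    wave amplitude is atypical of the null (it should be: the wave is real) and
    (b) whether curves from ``n_seeds`` fresh shuffles are typical of it
    (flatness_test p > 0.05).  The analysis range is restricted to bins with
    enough pairs (``max_lg``); sparse tail bins carry no usable signal.  The
    ensemble is kept large because every observed shuffle is compared against
    the same estimated null tail: a small ensemble correlates the trials
    through its quantile-estimation noise.
    """
    from .null_models import apply_shuffle, build_null_ensemble
    from .pair_stats import delta_lfc_curve, enumerate_pairs
    from .wave_fit import flatness_test, null_curve_stats

    s_ens, s_stats, s_obs = np.random.SeedSequence(seed).spawn(3)
    ens = build_null_ensemble(
        annotation, expression, kind, n_reps=n_reps,
        seed=int(s_ens.generate_state(1)[0]) % (2**31), max_lg=max_lg,
    )
    stats = null_curve_stats(ens.curves, n_restarts=n_restarts,
                             seed=int(s_stats.generate_state(1)[0]) % (2**31))
    identity_curve = delta_lfc_curve(enumerate_pairs(annotation, expression), max_lg=max_lg, n_boot=0)
    identity = flatness_test(identity_curve, ens, null_stats=stats, n_restarts=n_restarts, seed=1)
    pvals = []
    for s in s_obs.generate_state(n_seeds):
        shuffled = apply_shuffle(annotation, kind, int(s) % (2**31))
        curve = delta_lfc_curve(enumerate_pairs(shuffled, expression), max_lg=max_lg, n_boot=0)
        res = flatness_test(curve, ens, null_stats=stats, n_restarts=n_restarts, seed=int(s) % 10007)
        pvals.append(res.p_amplitude)
    return dict(
        kind=kind, pvals=pvals, n_pass=sum(p > 0.05 for p in pvals), n_seeds=n_seeds,
        identity_p=identity.p_amplitude, identity_amplitude=identity.observed_amplitude,
    )


def lp_slope_null_experiment(annotation, config, n_seeds: int = 20, seed: int = 0) -> dict:
    """Promoter-position shuffle null for the μ_|LFC| vs L_P regression.

    Each trial pairs a fresh LFC noise draw with a fresh promoter shuffle, so
    the ``n_seeds`` slope p-values are independent; reusing one expression
    realization would correlate them through its particular noise.  Under a
    valid null each p-value should be non-significant.
    """
    from .null_models import shuffle_promoter_positions
    from .pair_stats import response_vs_lp
    from .synthetic_data import generate_expression

    pvals = []
    for s in np.random.SeedSequence(seed).spawn(n_seeds):
        s_noise, s_shuf = (int(x) % (2**31) for x in s.generate_state(2))
        expression = generate_expression(annotation, config, seed=s_noise)
        shuffled = shuffle_promoter_positions(annotation, s_shuf)
        _, fit = response_vs_lp(expression, shuffled)
        pvals.append(fit.slope_p_value)
    return dict(pvals=pvals, n_pass=sum(p > 0.05 for p in pvals), n_seeds=n_seeds)
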