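"""Synthetic genomes, expression tables, region counts and GO maps.

The generator emulates the statistical structure the downstream analyses
assume: a bacterial genome organised into operons (sizes drawn from a
geometric-like distribution with median 3, ~50 nt intergenic spacing), a
primary promoter per operon plus internal promoters on a regular gene-unit
spacing, per-gene survival of elongating RNA polymerase (probability ``s`` of
traversing one gene without premature termination), and promoters whose
initiation flux responds to stress in log2 units.

The generative expectation for the expression level of the gene at position
``P`` of an operon is

    E(P) = sum over promoters with first_gene_index g0 <= P of
           flux(promoter, condition) * s(condition)^(P - g0)

i.e. each promoter's flux is attenuated by one survival factor per gene the
polymerase traverses before reaching gene ``P``.  The log2 fold change of a
gene is log2(E_stress / E_control) plus Gaussian noise (DESeq2 LFCs are
approximately normal at moderate counts).  Stress multiplies the per-gene
termination hazard -ln(s) by ``stress_survival_multiplier``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .operon_io import (
    GeneRecord,
    GeneSet,
    GenomeAnnotation,
    PromoterRecord,
    TerminatorRecord,
)

__all__ = [
    "SyntheticConfig",
    "default_size_pmf",
    "generate_annotation",
    "generate_expression",
    "generate_region_counts",
    "generate_go_annotation",
    "generate_genome_sequence",
    "generate_gene_sets",
    "expected_expression",
    "expected_lfc",
]


def default_size_pmf(max_size: int = 15, p: float = 0.25) -> dict[int, float]:
    """Truncated geometric pmf over operon gene counts (median 3, mean ~3.7)."""
    sizes = np.arange(1, max_size + 1)
    w = p * (1 - p) ** (sizes - 1)
    w /= w.sum()
    return dict(zip(sizes.tolist(), w.tolist()))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome and its stress response.

    Defaults encode the conditions the analyses assume: ~300 operons with a
    median size of 3 genes, an internal promoter every 4 genes (the
    genome-wide average promoter spacing), per-gene survival s = 0.8, a
    two-fold initiation response to stress at every promoter (1.0 log2 unit),
    a doubling of the termination hazard under stress, LFC noise of 0.1 log2
    units and a mean read depth of 500 per gene start.
    """

    n_operons: int = 300
    operon_size_pmf: dict[int, float] = field(default_factory=default_size_pmf)
    internal_tss_spacing: int = 4          # a promoter every d genes; 0 disables
    internal_tss_placement: str = "regular"  # "regular" grid or "random" positions (same count)
    survival: float = 0.8                  # per-gene elongation survival s in (0, 1]
    promoter_base_response: float = 1.0    # log2 stress response of primary promoters
    internal_response: float = 1.0         # log2 stress response of internal promoters
    internal_flux_ratio: float = 1.0       # control-condition internal/primary flux
    lp_response_slope: float = 0.0         # extra log2 stress response per gene of L_P
    stress_survival_multiplier: float = 2.0  # multiplies the hazard -ln(s) under stress
    noise_sd: float = 0.1                  # Gaussian LFC noise, log2 units
    read_depth: float = 500.0              # expected start-region reads per unit flux
    n_replicates: int = 3
    intergenic_mean_nt: float = 50.0
    intergenic_operon_gap_nt: tuple[float, float] = (200.0, 400.0)  # (with TTS, without TTS)
    gene_length_mean_nt: float = 900.0
    tts_fraction: float = 0.2              # fraction of operons followed by a TTS
    go_terms_per_gene: int = 3
    go_term_pool: int = 300
    go_sharing_decay: float = 0.7          # per-gene-unit term retention probability
    seed: int = 0

    def __post_init__(self):
        total = sum(self.operon_size_pmf.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"operon size pmf sums to {total}, not 1")
        if not 0 < self.survival <= 1:
            raise ValueError("survival must be in (0, 1]")
        if self.noise_sd < 0 or self.read_depth < 0:
            raise ValueError("noise_sd and read_depth must be non-negative")

    @property
    def stress_survival(self) -> float:
        """Per-gene survival under stress: hazard scaled by the multiplier."""
        return float(self.survival ** self.stress_survival_multiplier)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_annotation(config: SyntheticConfig, seed: int | None = None) -> GenomeAnnotation:
    """Lay out ``n_operons`` operons on a linear coordinate axis (circular genome).

    Each operon gets a primary promoter just upstream of gene 1 and, when
    ``internal_tss_spacing = d > 0``, internal promoters at first_gene_index
    1+d, 1+2d, ... (an operon shorter than d+1 genes gets only its primary).
    A TTS is placed in the downstream gap of a ``tts_fraction`` share of
    operons; gaps with a TTS are drawn shorter than gaps without one
    (``intergenic_operon_gap_nt``), reproducing the TTS/no-TTS gap asymmetry.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = np.array(sorted(config.operon_size_pmf))
    probs = np.array([config.operon_size_pmf[s] for s in sizes])
    genes: list[GeneRecord] = []
    promoters: list[PromoterRecord] = []
    terminators: list[TerminatorRecord] = []

    pos_nt = 1000
    for o in range(config.n_operons):
        oid = f"op{o:04d}"
        n = int(rng.choice(sizes, p=probs))
        strand = "+"  # operon-internal statistics are strand-symmetric; see methods note
        tss = pos_nt
        start = pos_nt + 40  # short 5' UTR
        gene_records = []
        for p in range(1, n + 1):
            length = max(90, int(rng.normal(config.gene_length_mean_nt, config.gene_length_mean_nt / 4)))
            end = start + length - 1
            gid = f"{oid}_g{p}"
            gene_records.append(GeneRecord(gid, oid, p, start, end, strand))
            gap = max(1, int(rng.exponential(config.intergenic_mean_nt)))
            start = end + gap + 1
        genes.extend(gene_records)
        promoters.append(PromoterRecord(f"{oid}_p1", oid, tss, 1))
        d = config.internal_tss_spacing
        if d and d > 0:
            if config.internal_tss_placement == "random":
                n_int = (n - 1) // d
                fgs = sorted(rng.choice(np.arange(2, n + 1), size=min(n_int, n - 1), replace=False).tolist()) if n > 1 else []
            else:
                fgs = list(range(1 + d, n + 1, d))
            for k, fg in enumerate(fgs, start=2):
                g = gene_records[fg - 1]
                promoters.append(
                    PromoterRecord(f"{oid}_p{k}", oid, g.start_nt - 20, fg)
                )
        op_end = gene_records[-1].end_nt
        has_tts = rng.random() < config.tts_fraction
        mean_gap = config.intergenic_operon_gap_nt[0] if has_tts else config.intergenic_operon_gap_nt[1]
        gap = max(20, int(rng.exponential(mean_gap)))
        if has_tts:
            terminators.append(TerminatorRecord(tts_nt=op_end + max(5, gap // 4), operon_id=oid))
        pos_nt = op_end + gap + 1

    return GenomeAnnotation(
        genes=genes, promoters=promoters, terminators=terminators,
        genome_length_nt=pos_nt + 1000,
    )


# ---------------------------------------------------------------------------
# generative expectations (closed forms used as oracles downstream)
# ---------------------------------------------------------------------------

def _promoter_flux(
    p: PromoterRecord, config: SyntheticConfig, condition: str, lp: int = 0
) -> float:
    base = 1.0 if p.first_gene_index == 1 else config.internal_flux_ratio
    if condition == "control":
        return base
    r = config.promoter_base_response if p.first_gene_index == 1 else config.internal_response
    # optional compensation structure: promoters covering more genes before the
    # next downstream TSS respond more strongly (in log2 units per gene of L_P)
    r += config.lp_response_slope * lp
    return base * 2.0 ** r


def _promoter_lp_map(annotation: GenomeAnnotation) -> dict[str, int]:
    # generation uses the "remaining" convention: a promoter's compensation
    # scales with the genes it must cover, so a last promoter covering the
    # operon tail is strong, not L_P = 0 weak
    from .pair_stats import promoter_lp

    lp = promoter_lp(annotation, convention="remaining")
    return dict(zip(lp["promoter_id"], lp["L_P"]))


def expected_expression(
    annotation: GenomeAnnotation, config: SyntheticConfig, condition: str
) -> pd.Series:
    """Noise-free expected expression level per operon gene (indexed by gene_id)."""
    s = config.survival if condition == "control" else config.stress_survival
    lp_map = _promoter_lp_map(annotation) if config.lp_response_slope else {}
    out: dict[str, float] = {}
    for oid, gids in annotation.operons.items():
        proms = annotation.promoters_by_operon.get(oid, [])
        for gid in gids:
            P = annotation.gene_index[gid].position
            level = sum(
                _promoter_flux(p, config, condition, lp_map.get(p.promoter_id, 0))
                * s ** (P - p.first_gene_index)
                for p in proms
                if p.first_gene_index <= P
            )
            out[gid] = level
    return pd.Series(out, name=condition)


def expected_lfc(annotation: GenomeAnnotation, config: SyntheticConfig) -> pd.Series:
    """Noise-free expected log2 fold change (stress vs control) per operon gene."""
    c = expected_expression(annotation, config, "control")
    s = expected_expression(annotation, config, "stress")
    return pd.Series(np.log2(s / c), index=c.index, name="lfc")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def generate_expression(
    annotation: GenomeAnnotation,
    config: SyntheticConfig,
    conditions: Sequence[str] = ("stress",),
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene LFC table: closed-form expectation plus Gaussian noise.

    All listed conditions share the configured response structure (they model
    replicate stress exposures); each gets an independent noise draw.  The
    p_value column is a one-sample z-test of the noisy LFC against zero at the
    configured noise sd, which mimics DESeq2 Wald p-values under the generative
    model.
    """
    from scipy import stats as _st

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    mu = expected_lfc(annotation, config)
    frames = []
    for cond in conditions:
        lfc = mu.to_numpy() + rng.normal(0.0, config.noise_sd, size=len(mu))
        if config.noise_sd > 0:
            p = 2 * _st.norm.sf(np.abs(lfc) / config.noise_sd)
        else:
            p = np.where(np.abs(lfc) > 0, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                dict(gene_id=mu.index, condition_id=cond, lfc=lfc, p_value=p)
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_region_counts(
    annotation: GenomeAnnotation,
    config: SyntheticConfig,
    conditions: Sequence[str] = ("control", "stress"),
    seed: int | None = None,
) -> pd.DataFrame:
    """Poisson start/end region counts per gene, replicate and condition.

    reads_start ~ Poisson(depth * flux reaching the gene start); reads_end ~
    Poisson(depth * flux * s), so the expected normalized termination rate
    (start - end)/start equals 1 - s.  With depth 0 all counts are zero and the
    table is flagged (``attrs['all_zero']``) since r_f is then undefined.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    lp_map = _promoter_lp_map(annotation) if config.lp_response_slope else {}
    rows = []
    for cond in conditions:
        s = config.survival if cond == "control" else config.stress_survival
        flux_at_start: dict[str, float] = {}
        for oid, gids in annotation.operons.items():
            proms = annotation.promoters_by_operon.get(oid, [])
            for gid in gids:
                P = annotation.gene_index[gid].position
                flux_at_start[gid] = sum(
                    _promoter_flux(p, config, cond, lp_map.get(p.promoter_id, 0))
                    * s ** (P - p.first_gene_index)
                    for p in proms
                    if p.first_gene_index <= P
                )
        gids = list(flux_at_start)
        lam_start = config.read_depth * np.array([flux_at_start[g] for g in gids])
        lam_end = lam_start * s
        for rep in range(1, config.n_replicates + 1):
            rows.append(
                pd.DataFrame(
                    dict(
                        gene_id=gids, replicate_id=f"rep{rep}", condition_id=cond,
                        reads_start=rng.poisson(lam_start).astype(float),
                        reads_end=rng.poisson(lam_end).astype(float),
                    )
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df.attrs["all_zero"] = bool((df[["reads_start", "reads_end"]].to_numpy() == 0).all())
    return df


def generate_go_annotation(
    annotation: GenomeAnnotation, config: SyntheticConfig, seed: int | None = None
) -> dict[str, list[str]]:
    """Gene -> GO-term lists with within-operon sharing decaying with distance.

    Gene 1 of each operon draws ``go_terms_per_gene`` terms from the pool; each
    subsequent gene retains each of its upstream neighbour's terms with
    probability ``go_sharing_decay`` and replaces losses with fresh draws, so
    the expected number of common terms between genes at distance L_G is
    K * decay^L_G.  decay = 1 gives identical lists along the operon; decay = 0
    reduces sharing to the random-pair background.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    K = config.go_terms_per_gene
    pool = np.array([f"GO:{i:07d}" for i in range(config.go_term_pool)])
    out: dict[str, list[str]] = {}
    for oid, gids in annotation.operons.items():
        prev: list[str] = list(rng.choice(pool, size=K, replace=False))
        out[gids[0]] = list(prev)
        for gid in gids[1:]:
            kept = [t for t in prev if rng.random() < config.go_sharing_decay]
            need = K - len(kept)
            fresh = [t for t in rng.permutation(pool) if t not in kept][:need]
            prev = kept + list(fresh)
            out[gid] = list(prev)
    return out


def generate_genome_sequence(
    annotation: GenomeAnnotation, seed: int | None = None, gc: float = 0.5
):
    """Random genome sequence consistent with the annotation's coordinate span.

    Returns a Bio.SeqRecord (single circular contig named ``synthetic``).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    seq = rng.choice(list("ATGC"), size=annotation.genome_length_nt, p=[p_at, p_at, p_gc, p_gc])
    return SeqRecord(Seq("".join(seq)), id="synthetic", description="synthetic genome")


def generate_gene_sets(
    annotation: GenomeAnnotation,
    seed: int | None = None,
    n_essential: int = 150,
    promoter_adjacent_bias: float = 4.0,
) -> dict[str, GeneSet]:
    """Synthetic gene sets: an "essential" cohort biased toward promoter-adjacent genes.

    Genes sitting at a promoter's first_gene_index are ``promoter_adjacent_bias``
    times as likely to be sampled, emulating the enrichment of essential genes
    close to their upstream promoters.
    """
    rng = np.random.default_rng(seed)
    gids, weights = [], []
    for oid, genes in annotation.operons.items():
        fg = {p.first_gene_index for p in annotation.promoters_by_operon.get(oid, [])}
        for gid in genes:
            gids.append(gid)
            weights.append(promoter_adjacent_bias if annotation.gene_index[gid].position in fg else 1.0)
    w = np.array(weights) / np.sum(weights)
    chosen = rng.choice(gids, size=min(n_essential, len(gids)), replace=False, p=w)
    return {"essential": GeneSet("essential", set(map(str, chosen)))}
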