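"""Shuffle null models for the distance-resolved divergence statistics.

Each randomization operates on an annotation copy and never mutates the
expression table, so the multiset of LFC values entering the statistic is
preserved exactly and only genome structure is randomized:

- ``shuffle_gene_positions``: permute gene identities over the position slots
  within each operon (promoter first_gene_index stays tied to the slot index).
- ``shuffle_operon_membership``: redistribute operon genes across operons,
  preserving every operon's size.
- ``flip_internal_tss_labels``: invert the "has an internal TSS in between"
  label for a random fraction of gene pairs.
- ``shuffle_promoter_positions``: resample each internal promoter's
  first_gene_index uniformly over 2..n within its operon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .operon_io import GenomeAnnotation, PromoterRecord
from .pair_stats import DistanceCurve, delta_lfc_curve, enumerate_pairs

KINDS = ("positions", "operons", "both", "promoters")


def _relabel(annotation: GenomeAnnotation, mapping: dict[str, str]) -> GenomeAnnotation:
    """Return a copy with gene ids permuted according to ``mapping`` (slot -> new id)."""
    from dataclasses import replace

    genes = [replace(g, gene_id=mapping.get(g.gene_id, g.gene_id)) for g in annotation.genes]
    return GenomeAnnotation(
        genes=genes, promoters=list(annotation.promoters),
        terminators=list(annotation.terminators),
        genome_length_nt=annotation.genome_length_nt,
    )


def shuffle_gene_positions(annotation: GenomeAnnotation, seed: int | None = None) -> GenomeAnnotation:
    """Permute gene positions uniformly within each operon.

    Implemented by permuting gene identities across the operon's position
    slots; coordinates and promoter first_gene_index stay bound to the slots,
    so the TSS layout is untouched while every gene's position is randomized.
    """
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    for gids in annotation.operons.values():
        perm = rng.permutation(len(gids))
        for slot, src in zip(gids, (gids[i] for i in perm)):
            mapping[slot] = src
    return _relabel(annotation, mapping)


def shuffle_operon_membership(annotation: GenomeAnnotation, seed: int | None = None) -> GenomeAnnotation:
    """Reassign genes across operons, preserving all operon sizes; order random."""
    rng = np.random.default_rng(seed)
    slots = [g for gids in annotation.operons.values() for g in gids]
    pool = list(rng.permutation(slots))
    mapping = dict(zip(slots, pool))
    return _relabel(annotation, mapping)


def flip_internal_tss_labels(
    pairs: pd.DataFrame, fraction: float, seed: int | None = None
) -> pd.DataFrame:
    """Invert ``has_internal_tss_between`` for a uniformly chosen fraction of pairs."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = pairs.copy()
    n_flip = int(round(fraction * len(out)))
    idx = rng.choice(len(out), size=n_flip, replace=False)
    col = out.columns.get_loc("has_internal_tss_between")
    flipped = out["has_internal_tss_between"].to_numpy().copy()
    flipped[idx] = ~flipped[idx]
    out.iloc[:, col] = flipped
    out["n_internal_tss_between"] = np.where(
        flipped, np.maximum(out["n_internal_tss_between"], 1), 0
    )
    return out


def shuffle_promoter_positions(annotation: GenomeAnnotation, seed: int | None = None) -> GenomeAnnotation:
    """Resample each internal promoter's first_gene_index uniformly over 2..n.

    Promoter counts per operon and all primary promoters are preserved;
    operons without internal promoters are returned unchanged.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    new_promoters = []
    for p in annotation.promoters:
        if p.first_gene_index > 1:
            n = annotation.operon_size(p.operon_id)
            new_promoters.append(replace(p, first_gene_index=int(rng.integers(2, n + 1))))
        else:
            new_promoters.append(p)
    return GenomeAnnotation(
        genes=list(annotation.genes), promoters=new_promoters,
        terminators=list(annotation.terminators),
        genome_length_nt=annotation.genome_length_nt,
    )


def apply_shuffle(annotation: GenomeAnnotation, kind: str, seed: int | None = None) -> GenomeAnnotation:
    if kind == "positions":
        return shuffle_gene_positions(annotation, seed)
    if kind == "operons":
        return shuffle_operon_membership(annotation, seed)
    if kind == "both":
        return shuffle_gene_positions(shuffle_operon_membership(annotation, seed), None if seed is None else seed + 1)
    if kind == "promoters":
        return shuffle_promoter_positions(annotation, seed)
    raise ValueError(f"unknown shuffle kind {kind!r} (choose from {KINDS})")


@dataclass
class NullEnsemble:
    """Distance curves recomputed under repeated shuffles of one kind."""

    curves: list[DistanceCurve]
    kind: str
    seed: int
    quantiles: pd.DataFrame = field(default=None)  # per-bin 2.5/97.5% bands

    def __len__(self) -> int:
        return len(self.curves)


def build_null_ensemble(
    annotation: GenomeAnnotation,
    expression: pd.DataFrame,
    kind: str,
    n_reps: int = 1000,
    seed: int = 0,
    condition: str | None = None,
    max_lg: int | None = None,
) -> NullEnsemble:
    """Recompute μ_|ΔLFC|(L_G) under ``n_reps`` independent shuffles.

    The expression table is held fixed; only the annotation is randomized.
    Per-bin 2.5/97.5% null quantiles are stored alongside the replicate curves.
    Curves are computed without the bootstrap CI (the ensemble itself is the
    uncertainty model here).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_reps)
    curves = []
    for s in rep_seeds:
        ann = apply_shuffle(annotation, kind, int(s) % (2**31))
        pairs = enumerate_pairs(ann, expression, condition)
        curves.append(delta_lfc_curve(pairs, max_lg=max_lg, n_boot=0))
    grid = sorted({int(x) for c in curves for x in c.x})
    mat = np.full((len(curves), len(grid)), np.nan)
    for i, c in enumerate(curves):
        lut = dict(zip(c.x.tolist(), c.mean.tolist()))
        mat[i] = [lut.get(x, np.nan) for x in grid]
    with np.errstate(all="ignore"):
        q = pd.DataFrame(
            dict(
                x=grid,
                q025=np.nanquantile(mat, 0.025, axis=0),
                q975=np.nanquantile(mat, 0.975, axis=0),
                null_mean=np.nanmean(mat, axis=0),
            )
        )
    return NullEnsemble(curves=curves, kind=kind, seed=seed, quantiles=q)
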