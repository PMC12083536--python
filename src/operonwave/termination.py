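"""Premature-termination estimation from start/end region read counts.

For a gene at position ``i`` of operon ``j`` the normalized premature
termination rate is

    r_f(i, j) = (reads_start - reads_end) / reads_start

and the genome-wide position profile averages it over the ``k`` genes at each
position:

    R_f(P) = sum_j r_f(P, j) / k .

Counts are TPM-normalized per replicate library (start and end regions share a
library, so a single scaling is applied to the stacked vector), r_f is computed
on replicate-averaged values by default, genes whose coding regions contain an
annotated TTS are excluded (their termination is not "premature"), and genes
with zero start reads are excluded and logged.  Negative r_f values are
retained: internal promoters can add flux near gene ends and Eq.-style
arithmetic does not truncate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .operon_io import GenomeAnnotation

logger = logging.getLogger(__name__)


def tpm_normalize(counts: pd.DataFrame | pd.Series, gene_lengths: pd.Series) -> pd.DataFrame | pd.Series:
    """Transcripts-per-million normalization, per column.

    ``counts`` is indexed by gene id (columns = samples); ``gene_lengths`` is
    in nucleotides.  TPM = (count / length_kb) / sum(count / length_kb) * 1e6.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1e3, axis=0)
    total = rate.sum(axis=0)
    if np.any(np.asarray(total) == 0):
        raise ValueError("zero total counts in at least one sample")
    return rate.div(total, axis=1) * 1e6


def normalize_region_counts(region_counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """TPM-normalize start/end counts with one scaling per replicate library.

    Start and end region counts of a replicate come from the same sequencing
    library, so they are stacked into a single vector before normalization
    (normalizing the two regions separately would distort r_f).  Region widths
    are equal by construction, so the gene length enters only through the
    shared per-library scaling.
    """
    out = []
    for (cond, rep), sub in region_counts.groupby(["condition_id", "replicate_id"]):
        sub = sub.set_index("gene_id")
        stacked = pd.concat([sub["reads_start"], sub["reads_end"]]).to_numpy(float)
        lens = np.concatenate([gene_lengths.reindex(sub.index).to_numpy(float)] * 2)
        if np.isnan(lens).any():
            raise ValueError("missing gene lengths")
        rate = stacked / (lens / 1e3)
        total = rate.sum()
        if total == 0:
            raise ValueError(f"zero total counts in library ({cond}, {rep})")
        tpm = rate / total * 1e6
        n = len(sub)
        norm = sub.copy()
        norm["reads_start"], norm["reads_end"] = tpm[:n], tpm[n:]
        norm["condition_id"], norm["replicate_id"] = cond, rep
        out.append(norm.reset_index())
    return pd.concat(out, ignore_index=True)


def replicate_ttest(region_counts: pd.DataFrame, gene: str, condition: str | None = None) -> float:
    """Equal-variance two-sample t test between a gene's start and end replicate counts.

    Returns the p-value; NaN (flagged via log) with fewer than two replicates.
    Identical replicate vectors (zero variance, zero difference) give p = 1.
    """
    sub = region_counts[region_counts["gene_id"] == gene]
    if condition is not None:
        sub = sub[sub["condition_id"] == condition]
    s, e = sub["reads_start"].to_numpy(float), sub["reads_end"].to_numpy(float)
    if len(s) < 2:
        logger.warning("gene %s: <2 replicates, t test undefined", gene)
        return float("nan")
    if np.allclose(s, e) and s.std() == 0 and e.std() == 0:
        return 1.0
    return float(stats.ttest_ind(s, e, equal_var=True).pvalue)


def gene_rf(reads_start, reads_end):
    """Normalized premature termination rate (start - end) / start.

    Accepts scalars or arrays; zero start reads give NaN (gene excluded
    downstream).  Values can be negative when end counts exceed start counts.
    """
    s = np.asarray(reads_start, float)
    e = np.asarray(reads_end, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = np.where(s > 0, (s - e) / np.where(s > 0, s, 1.0), np.nan)
    return float(rf) if rf.ndim == 0 else rf


@dataclass
class TerminationProfile:
    """Per-gene r_f and the position-averaged profile R_f(P) for one condition."""

    condition: str
    per_gene: pd.DataFrame       # gene_id, operon_id, position, r_f
    profile: pd.DataFrame        # P, R_f, se_mean, se_sum, k
    excluded: list[str] = field(default_factory=list)


def _tts_genes(annotation: GenomeAnnotation) -> set[str]:
    """Operon genes whose coding regions contain an annotated TTS."""
    out = set()
    for t in annotation.terminators:
        if t.within_gene_id:
            out.add(t.within_gene_id)
            continue
        for g in annotation.genes:
            if g.operon_id is not None and g.start_nt <= t.tts_nt <= g.end_nt:
                out.add(g.gene_id)
    return out


def positional_rf(
    region_counts: pd.DataFrame,
    annotation: GenomeAnnotation,
    condition: str,
    gene_lengths: pd.Series | None = None,
    exclude_tts_genes: bool = True,
    per_replicate: bool = False,
) -> TerminationProfile:
    """R_f(P): position-averaged premature termination rate for one condition.

    Counts are TPM-normalized per library (skipped when ``gene_lengths`` is
    None — the raw counts are then used directly, which leaves r_f unchanged
    when region widths are uniform), averaged over replicates (or kept per
    replicate with ``per_replicate=True``, each replicate then contributing one
    r_f value per gene), and converted to r_f.  Error bars carry both the SE of
    the mean (sd/sqrt(k)) and the SE of the sum (sd*sqrt(k)).
    """
    sub = region_counts[region_counts["condition_id"] == condition]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    if gene_lengths is not None:
        sub = normalize_region_counts(sub, gene_lengths)
        sub = sub[sub["condition_id"] == condition]

    if per_replicate:
        grouped = sub[["gene_id", "reads_start", "reads_end"]].copy()
    else:
        grouped = sub.groupby("gene_id", as_index=False)[["reads_start", "reads_end"]].mean()

    excluded: list[str] = []
    tts = _tts_genes(annotation) if exclude_tts_genes else set()
    rows = []
    for _, r in grouped.iterrows():
        gid = r["gene_id"]
        g = annotation.gene_index.get(gid)
        if g is None or g.operon_id is None:
            continue
        if gid in tts:
            if gid not in excluded:
                excluded.append(gid)
            continue
        if r["reads_start"] <= 0:
            logger.info("gene %s: zero start reads, excluded from R_f", gid)
            if gid not in excluded:
                excluded.append(gid)
            continue
        rows.append(
            dict(gene_id=gid, operon_id=g.operon_id, position=g.position,
                 r_f=gene_rf(r["reads_start"], r["reads_end"]))
        )
    per_gene = pd.DataFrame(rows)
    prof_rows = []
    for P, s in per_gene.groupby("position"):
        v = s["r_f"].to_numpy(float)
        k = len(v)
        sd = float(v.std(ddof=1)) if k > 1 else np.nan  # SE undefined for a single gene
        prof_rows.append(
            dict(P=int(P), R_f=float(v.mean()), se_mean=sd / np.sqrt(k),
                 se_sum=sd * np.sqrt(k), k=k)
        )
    profile = pd.DataFrame(prof_rows).sort_values("P").reset_index(drop=True)
    return TerminationProfile(condition=condition, per_gene=per_gene, profile=profile, excluded=excluded)


def condition_rf_compare(
    profiles: dict[str, TerminationProfile],
    reference: str = "control",
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-position R_f differences of each condition against a reference.

    Gene sets are intersected (with a warning when they differ).  Bootstrap
    (over genes within a position) gives a 95% CI per position; the table's
    ``attrs['global_shift']`` holds each condition's mean per-gene difference.
    """
    if reference not in profiles:
        raise ValueError(f"missing reference condition {reference!r}")
    rng = np.random.default_rng(seed)
    ref = profiles[reference].per_gene.set_index("gene_id")
    rows = []
    shifts: dict[str, float] = {}
    for cond, prof in profiles.items():
        if cond == reference:
            continue
        other = prof.per_gene.set_index("gene_id")
        common = ref.index.intersection(other.index)
        if len(common) < len(ref.index) or len(common) < len(other.index):
            logger.warning("condition %s: gene sets differ from reference; intersecting", cond)
        d = (other.loc[common, "r_f"] - ref.loc[common, "r_f"]).to_frame("diff")
        d["position"] = ref.loc[common, "position"]
        shifts[cond] = float(d["diff"].mean())
        for P, s in d.groupby("position"):
            v = s["diff"].to_numpy(float)
            if len(v) > 1 and n_boot:
                idx = rng.integers(0, len(v), size=(n_boot, len(v)))
                bm = v[idx].mean(axis=1)
                lo, hi = np.quantile(bm, [0.025, 0.975])
            else:
                lo = hi = float(v.mean())
            rows.append(dict(condition=cond, P=int(P), diff=float(v.mean()),
                             ci_lo=float(lo), ci_hi=float(hi), k=len(v)))
    out = pd.DataFrame(rows)
    out.attrs["global_shift"] = shifts
    return out
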