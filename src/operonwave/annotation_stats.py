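"""GO co-function statistics, promoter-distance cohort tests and sequence scans.

The co-function statistic for a gene pair with term lists of sizes N_i and N_j
sharing n_c terms is P_c = n_c / (N_i * N_j) — the count of common terms over
the number of possible term combinations (note this is *not* a Jaccard index;
the product denominator is implemented verbatim).  Cohort statistics compare
per-gene promoter distances L_P between a gene set and all operon genes with a
two-sample Kolmogorov-Smirnov test.  Sequence operations: promoter AT richness
over a -60..+20 window around the TSS, and exact / 1-mismatch motif scanning
(homopolymer tracts, pause-like motifs) normalized per operon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .operon_io import GeneSet, GenomeAnnotation
from .pair_stats import gene_lp


# ---------------------------------------------------------------------------
# GO co-function
# ---------------------------------------------------------------------------

def go_common_fraction(terms_i: Sequence[str], terms_j: Sequence[str]) -> float:
    """P_c = n_c / (N_i * N_j); raises for empty term lists (pair must be discarded)."""
    ni, nj = len(set(terms_i)), len(set(terms_j))
    if ni == 0 or nj == 0:
        raise ValueError("P_c undefined for a gene without GO terms")
    nc = len(set(terms_i) & set(terms_j))
    return nc / (ni * nj)


def go_distance_relation(
    annotation: GenomeAnnotation,
    go_map: Mapping[str, Sequence[str]],
    n_shuffles: int = 1000,
    seed: int = 0,
    max_lg: int | None = None,
) -> pd.DataFrame:
    """Mean P_c per within-operon distance L_G against a cross-operon random-pair null.

    Observed pairs are all same-operon pairs where both genes carry terms
    (term-less pairs discarded and counted in ``attrs``).  The null redraws
    each pair's partners from different operons ``n_shuffles`` times; per-L_G
    bin the empirical p is the fraction of null-mean resamples (matched bin
    size, drawn from the null pool) at or above the observed bin mean.
    """
    rng = np.random.default_rng(seed)
    genes_with_terms = [
        g for gids in annotation.operons.values() for g in gids if len(go_map.get(g, [])) > 0
    ]
    operon_of = {g: annotation.gene_index[g].operon_id for g in genes_with_terms}
    obs_rows, discarded = [], 0
    for oid, gids in annotation.operons.items():
        pos = {g: annotation.gene_index[g].position for g in gids}
        for a in range(len(gids)):
            for b in range(a + 1, len(gids)):
                gi, gj = gids[a], gids[b]
                if not go_map.get(gi) or not go_map.get(gj):
                    discarded += 1
                    continue
                lg = abs(pos[gi] - pos[gj])
                if max_lg is not None and lg > max_lg:
                    continue
                obs_rows.append((lg, go_common_fraction(go_map[gi], go_map[gj])))
    obs = pd.DataFrame(obs_rows, columns=["L_G", "P_c"])

    # null pool: random cross-operon pairs of term-carrying genes
    n_pool = min(n_shuffles * max(len(obs), 1), 200_000)
    gl = np.array(genes_with_terms)
    pool = []
    while len(pool) < n_pool:
        i, j = rng.integers(0, len(gl), size=2)
        if i != j and operon_of[gl[i]] != operon_of[gl[j]]:
            pool.append(go_common_fraction(go_map[gl[i]], go_map[gl[j]]))
    pool = np.array(pool)

    rows = []
    for lg, sub in obs.groupby("L_G"):
        v = sub["P_c"].to_numpy(float)
        k = len(v)
        resamples = pool[rng.integers(0, len(pool), size=(min(n_shuffles, 2000), k))].mean(axis=1)
        p = float((1 + np.sum(resamples >= v.mean())) / (len(resamples) + 1))
        rows.append(
            dict(L_G=int(lg), mean_Pc=float(v.mean()), n_pairs=k,
                 null_mean=float(pool.mean()), p_value=p)
        )
    out = pd.DataFrame(rows)
    out.attrs["n_discarded_pairs"] = discarded
    out.attrs["null_pool_mean"] = float(pool.mean())
    return out


# ---------------------------------------------------------------------------
# L_P cohorts (Table-1-style)
# ---------------------------------------------------------------------------

@dataclass
class CohortStats:
    name: str
    n_genes: int
    mean_lp: float
    sd_lp: float
    ks_p: float | None
    stars: str = ""


def lp_cohort_stats(
    annotation: GenomeAnnotation,
    gene_sets: Mapping[str, GeneSet] | Mapping[str, set],
    convention: str = "zero",
) -> list[CohortStats]:
    """Per-cohort mean/SD of per-gene L_P with a KS test against all operon genes.

    Cohorts of one gene report their stats but skip the KS test; a cohort equal
    to the full background is degenerate (p reported as 1.0).  Stars mark
    0.05 / 0.01 / 0.001.
    """
    lp = gene_lp(annotation, convention=convention)
    background = lp.to_numpy(float)
    results = [
        CohortStats("all_operon_genes", len(background), float(background.mean()),
                    float(background.std(ddof=1)), None)
    ]
    for name, gs in gene_sets.items():
        members = gs.members if isinstance(gs, GeneSet) else set(gs)
        vals = lp[lp.index.isin(members)].to_numpy(float)
        if len(vals) == 0:
            continue
        if len(vals) < 2:
            results.append(CohortStats(name, len(vals), float(vals.mean()), 0.0, None))
            continue
        if len(vals) == len(background) and np.allclose(np.sort(vals), np.sort(background)):
            ks_p = 1.0  # self-comparison is degenerate
        else:
            ks_p = float(stats.ks_2samp(vals, background).pvalue)
        stars = "***" if ks_p <= 0.001 else "**" if ks_p <= 0.01 else "*" if ks_p <= 0.05 else ""
        results.append(
            CohortStats(name, len(vals), float(vals.mean()), float(vals.std(ddof=1)), ks_p, stars)
        )
    return results


# ---------------------------------------------------------------------------
# sequence statistics
# ---------------------------------------------------------------------------

def _contigs(genome) -> dict[str, str]:
    """Accept a FASTA path, a Bio.SeqRecord, an iterable of records, or a dict."""
    from Bio import SeqIO

    if isinstance(genome, dict):
        return {k: str(v) for k, v in genome.items()}
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        return {r.id: str(r.seq) for r in SeqIO.parse(str(genome), "fasta")}
    if hasattr(genome, "seq"):
        return {genome.id: str(genome.seq)}
    return {r.id: str(r.seq) for r in genome}


def promoter_at_richness(
    genome,
    annotation: GenomeAnnotation,
    upstream: int = 60,
    downstream: int = 20,
    contig: str | None = None,
) -> pd.DataFrame:
    """AT fraction of the -60..+20 window around each promoter's TSS (strand-aware).

    With the TSS at +1 (there is no position 0) the window covers 80 nt:
    positions -60..-1 and +1..+20.  Promoters whose window exceeds the contig
    bounds are skipped and counted in ``attrs['n_skipped']``.
    """
    contigs = _contigs(genome)
    seq = contigs[contig] if contig else next(iter(contigs.values()))
    L = len(seq)
    rows, skipped = [], 0
    for p in annotation.promoters:
        strand = annotation.operon_genes(p.operon_id)[0].strand
        if strand == "+":
            lo, hi = p.tss_nt - upstream, p.tss_nt + downstream - 1  # 1-based inclusive
        else:
            lo, hi = p.tss_nt - downstream + 1, p.tss_nt + upstream
        if lo < 1 or hi > L:
            skipped += 1
            continue
        window = seq[lo - 1 : hi].upper()
        at = sum(1 for c in window if c in "AT") / len(window)
        rows.append(dict(promoter_id=p.promoter_id, operon_id=p.operon_id,
                         is_internal=p.is_internal, at_fraction=at))
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = skipped
    return out


@dataclass
class MotifHit:
    contig: str
    start_nt: int  # 1-based
    motif_id: str
    mismatches: int


def motif_scan(
    genome,
    motifs: Mapping[str, str],
    max_mismatch: int = 1,
    n_operons: int | None = None,
) -> tuple[list[MotifHit], pd.DataFrame]:
    """Exact and 1-mismatch occurrences of literal motifs, with per-operon rates.

    Ambiguous bases (anything outside ACGT) count as mismatches.  Returns the
    hit list and a per-motif summary with counts per mismatch degree and, when
    ``n_operons`` is given, rates normalized by the operon count.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    contigs = _contigs(genome)
    hits: list[MotifHit] = []
    for cid, seq in contigs.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for mid, motif in motifs.items():
            m = np.frombuffer(motif.upper().encode(), dtype=np.uint8)
            k = len(m)
            if k == 0 or k > len(arr):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, k)
            mism = (windows != m).sum(axis=1)
            for pos in np.nonzero(mism <= max_mismatch)[0]:
                hits.append(MotifHit(cid, int(pos) + 1, mid, int(mism[pos])))
    rows = []
    for mid in motifs:
        exact = sum(1 for h in hits if h.motif_id == mid and h.mismatches == 0)
        one = sum(1 for h in hits if h.motif_id == mid and h.mismatches == 1)
        row = dict(motif_id=mid, exact_hits=exact, one_mismatch_hits=one)
        if n_operons:
            row["exact_rate_per_operon"] = exact / n_operons
            row["one_mismatch_rate_per_operon"] = one / n_operons
        rows.append(row)
    return hits, pd.DataFrame(rows)


def homopolymer_motifs(base_a: int = 8, base_t: int = 8) -> dict[str, str]:
    """Default premature-termination-prone homopolymer tracts (poly-A / poly-T)."""
    return {"polyA": "A" * base_a, "polyT": "T" * base_t}
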