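"""Pairwise and positional response-strength statistics for operon genes.

Everything here works in gene units: ``L_G`` is the distance between two genes
of the same operon (adjacent genes are at L_G = 1), ``P`` a gene's position
from the operon's 5' end and ``L_P`` the gene-unit distance between consecutive
TSSs.  The workhorse objects are a pair table (one row per unordered
within-operon gene pair with |LFC_i - LFC_j|) and :class:`DistanceCurve`
(binned means with SEM and bootstrap confidence band).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .operon_io import GenomeAnnotation

PAIR_COLUMNS = [
    "operon_id", "gene_i", "gene_j", "L_G", "abs_delta_lfc",
    "n_internal_tss_between", "has_internal_tss_between",
    "supercoiling_sensitive", "condition_id",
]


@dataclass
class DistanceCurve:
    """Binned mean of a per-pair (or per-gene) statistic vs an integer distance."""

    data: pd.DataFrame  # columns: x, mean, sem, ci_lo, ci_hi, n
    label: str = ""

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy()

    @property
    def mean(self) -> np.ndarray:
        return self.data["mean"].to_numpy()

    @property
    def sem(self) -> np.ndarray:
        return self.data["sem"].to_numpy()

    @property
    def n(self) -> np.ndarray:
        return self.data["n"].to_numpy()

    def restrict(self, max_x: int) -> "DistanceCurve":
        return DistanceCurve(self.data[self.data["x"] <= max_x].reset_index(drop=True), self.label)

    def __len__(self) -> int:
        return len(self.data)


def _binned_curve(
    x: np.ndarray, y: np.ndarray, label: str = "", *,
    n_boot: int = 0, seed: int | None = None,
) -> DistanceCurve:
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    rows = []
    rng = np.random.default_rng(seed)
    for xv, sub in df.groupby("x"):
        v = sub["y"].to_numpy(float)
        m = float(v.mean())
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        if n_boot and len(v) > 1:
            idx = rng.integers(0, len(v), size=(n_boot, len(v)))
            bm = v[idx].mean(axis=1)
            lo, hi = np.quantile(bm, [0.025, 0.975])
        else:
            lo, hi = m - 1.96 * sem, m + 1.96 * sem
        rows.append(dict(x=int(xv), mean=m, sem=sem, ci_lo=float(lo), ci_hi=float(hi), n=len(v)))
    out = pd.DataFrame(rows).sort_values("x").reset_index(drop=True)
    return DistanceCurve(out, label)


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

def enumerate_pairs(
    annotation: GenomeAnnotation,
    expression: pd.DataFrame,
    condition: str | None = None,
) -> pd.DataFrame:
    """All unordered within-operon gene pairs with both LFCs known.

    Pairs with either LFC missing are dropped and counted in
    ``attrs['n_dropped']``.  Each pair carries L_G, |ΔLFC|, the number of
    internal TSSs strictly between the two genes (a TSS whose first gene is the
    downstream member counts, per the intergenic-TSS convention) and a
    placeholder supercoiling flag.
    """
    expr = expression
    if condition is not None:
        expr = expr[expr["condition_id"] == condition]
    conds = expr["condition_id"].unique()
    if len(conds) != 1:
        raise ValueError("expression table must be restricted to one condition for pair enumeration")
    cond = conds[0]
    lfc = expr.set_index("gene_id")["lfc"]
    rows, dropped = [], 0
    for oid, gids in annotation.operons.items():
        if len(gids) < 2:
            continue
        pos = {g: annotation.gene_index[g].position for g in gids}
        known = [g for g in gids if g in lfc.index]
        dropped += _n_pairs(len(gids)) - _n_pairs(len(known))
        for a in range(len(known)):
            for b in range(a + 1, len(known)):
                gi, gj = known[a], known[b]
                i, j = pos[gi], pos[gj]
                if i > j:
                    gi, gj, i, j = gj, gi, j, i
                n_tss = annotation.internal_tss_between(oid, i, j)
                rows.append(
                    (oid, gi, gj, j - i, abs(lfc[gi] - lfc[gj]), n_tss, n_tss > 0, False, cond)
                )
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    out.attrs["n_dropped"] = int(dropped)
    return out


def _n_pairs(n: int) -> int:
    return n * (n - 1) // 2


# ---------------------------------------------------------------------------
# distance curves
# ---------------------------------------------------------------------------

def delta_lfc_curve(
    pairs: pd.DataFrame, max_lg: int | None = None, *,
    n_boot: int = 2000, seed: int = 0, label: str = "",
) -> DistanceCurve:
    """μ_|ΔLFC|(L_G): per-distance mean of |ΔLFC| with SEM and bootstrap 95% CI."""
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    sub = pairs if max_lg is None else pairs[pairs["L_G"] <= max_lg]
    return _binned_curve(
        sub["L_G"].to_numpy(), sub["abs_delta_lfc"].to_numpy(),
        label or "mu_abs_dLFC", n_boot=n_boot, seed=seed,
    )


@dataclass
class StratifiedCurves:
    """A pooled statistic split by a boolean pair attribute, with linear fits."""

    with_stratum: DistanceCurve
    without_stratum: DistanceCurve
    fit_with: "object" = None     # LinearFitResult, filled by stratified_delta_curve
    fit_without: "object" = None
    stratifier: str = ""


def stratified_delta_curve(
    pairs: pd.DataFrame,
    stratifier: str | pd.Series = "internal_tss",
    max_lg: int = 5,
    *, n_boot: int = 2000, seed: int = 0,
) -> StratifiedCurves:
    """μ_|ΔLFC|(L_G) split by internal-TSS presence, supercoiling flag or a custom mask.

    Restricted to L_G <= ``max_lg`` (genome data get too sparse for the
    no-TSS stratum beyond 5).  Each stratum curve carries an ordinary
    least-squares line with its slope p-value.
    """
    from .wave_fit import fit_linear

    if isinstance(stratifier, str):
        col = {
            "internal_tss": "has_internal_tss_between",
            "supercoiling": "supercoiling_sensitive",
        }.get(stratifier, stratifier)
        mask = pairs[col].astype(bool)
        name = stratifier
    else:
        mask = stratifier.astype(bool)
        name = getattr(stratifier, "name", "custom") or "custom"
    sub = pairs[pairs["L_G"] <= max_lg]
    m = mask[sub.index]
    if m.all() or not m.any():
        raise ValueError("one stratum is empty at every distance")
    cw = delta_lfc_curve(sub[m], n_boot=n_boot, seed=seed, label=f"{name}=True")
    co = delta_lfc_curve(sub[~m], n_boot=n_boot, seed=seed + 1, label=f"{name}=False")
    # a stratum occupying fewer than 3 distance bins carries no fittable trend
    return StratifiedCurves(
        with_stratum=cw, without_stratum=co,
        fit_with=fit_linear(cw) if len(cw) >= 3 else None,
        fit_without=fit_linear(co) if len(co) >= 3 else None,
        stratifier=name,
    )


def classify_supercoiling_pairs(
    annotation: GenomeAnnotation,
    expression_ref: pd.DataFrame,
    pairs: pd.DataFrame,
    lfc_threshold: float = 0.4,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, set[str]]:
    """Flag pairs spanning supercoiling-sensitive genes under the reference condition.

    A gene is sensitive when |LFC| > ``lfc_threshold`` with p < ``p_threshold``
    in the reference (gyrase-inhibition) expression table; genes without a
    p-value are treated as non-sensitive.  A pair is sensitive when either
    member, or any gene located between them, is sensitive.  Returns the pair
    table with the flag filled and the gene-level sensitivity set.
    """
    ref = expression_ref.set_index("gene_id")
    pv = ref["p_value"] if "p_value" in ref.columns else pd.Series(np.nan, index=ref.index)
    sens = set(
        ref.index[(ref["lfc"].abs() > lfc_threshold) & (pv.fillna(1.0) < p_threshold)]
    )
    out = pairs.copy()
    flags = np.zeros(len(out), dtype=bool)
    for oid, sub in out.groupby("operon_id"):
        gids = annotation.operons[oid]
        pos_of = {g: annotation.gene_index[g].position for g in gids}
        by_pos = {p: g for g, p in pos_of.items()}
        for idx, row in sub.iterrows():
            i, j = pos_of[row["gene_i"]], pos_of[row["gene_j"]]
            if i > j:
                i, j = j, i
            span = {by_pos[p] for p in range(i, j + 1)}
            flags[out.index.get_loc(idx)] = bool(span & sens)
    out["supercoiling_sensitive"] = flags
    return out, sens


def response_vs_position(
    expression: pd.DataFrame,
    annotation: GenomeAnnotation,
    mode: Literal["abs_lfc", "delta_to_others"] = "delta_to_others",
    *, n_boot: int = 0, seed: int = 0,
) -> DistanceCurve:
    """μ_|LFC|(P) or μ_|ΔLFC|(P): response strength (or divergence) vs operon position."""
    lfc = expression.set_index("gene_id")["lfc"]
    xs, ys = [], []
    for oid, gids in annotation.operons.items():
        known = [(annotation.gene_index[g].position, float(lfc[g])) for g in gids if g in lfc.index]
        if mode == "abs_lfc":
            for p, v in known:
                xs.append(p)
                ys.append(abs(v))
        else:
            if len(known) < 2:
                continue
            for p, v in known:
                others = [abs(v - w) for q, w in known if q != p]
                xs.append(p)
                ys.append(float(np.mean(others)))
    return _binned_curve(np.array(xs), np.array(ys), f"mode={mode}", n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# promoter distances (L_P)
# ---------------------------------------------------------------------------

def promoter_lp(
    annotation: GenomeAnnotation,
    convention: Literal["zero", "remaining"] = "zero",
) -> pd.DataFrame:
    """Per-promoter L_P: gene-unit distance from a TSS to the next downstream TSS.

    ``zero``: promoters with no downstream TSS get L_P = 0 (the "if k is not
    larger than j" convention).  ``remaining``: they get the number of genes
    they control to the operon end, flagged ``open_ended``.
    """
    rows = []
    for oid, proms in annotation.promoters_by_operon.items():
        n = annotation.operon_size(oid)
        fgs = sorted({p.first_gene_index for p in proms})
        for p in proms:
            later = [f for f in fgs if f > p.first_gene_index]
            if later:
                lp, open_ended = later[0] - p.first_gene_index, False
            elif convention == "remaining":
                lp, open_ended = n - p.first_gene_index + 1, True
            else:
                lp, open_ended = 0, False
            rows.append(
                dict(promoter_id=p.promoter_id, operon_id=oid,
                     first_gene_index=p.first_gene_index, L_P=int(max(lp, 0)),
                     open_ended=open_ended)
            )
    return pd.DataFrame(rows)


def gene_lp(
    annotation: GenomeAnnotation,
    convention: Literal["zero", "remaining"] = "zero",
) -> pd.Series:
    """Per-gene L_P: distance between the closest TSS at/upstream of the gene and
    the closest TSS strictly downstream; 0 when no downstream TSS exists."""
    out = {}
    for oid, gids in annotation.operons.items():
        fgs = sorted({p.first_gene_index for p in annotation.promoters_by_operon.get(oid, [])})
        n = len(gids)
        for gid in gids:
            P = annotation.gene_index[gid].position
            up = [f for f in fgs if f <= P]
            down = [f for f in fgs if f > P]
            if not up:
                continue  # no upstream promoter: L_P undefined for this gene
            if down:
                lp = down[0] - up[-1]
            elif convention == "remaining":
                lp = n - up[-1] + 1
            else:
                lp = 0
            out[gid] = int(lp)
    return pd.Series(out, name="L_P", dtype=int)


def response_vs_lp(
    expression: pd.DataFrame,
    annotation: GenomeAnnotation,
    convention: Literal["zero", "remaining"] = "zero",
    *, include_open_ended: bool = True, n_boot: int = 0, seed: int = 0,
):
    """μ_|LFC| of each promoter's immediately downstream gene vs L_P, with a linear fit.

    One point per promoter (promoters sharing a first gene each contribute).
    Returns (DistanceCurve over L_P, LinearFitResult on the per-promoter points).
    """
    from .wave_fit import fit_linear_points

    lfc = expression.set_index("gene_id")["lfc"]
    lp = promoter_lp(annotation, convention)
    xs, ys = [], []
    for _, row in lp.iterrows():
        if row["open_ended"] and not include_open_ended:
            continue
        gids = annotation.operons[row["operon_id"]]
        if row["first_gene_index"] > len(gids):
            continue
        gid = gids[row["first_gene_index"] - 1]
        if gid not in lfc.index:
            continue
        xs.append(int(row["L_P"]))
        ys.append(abs(float(lfc[gid])))
    curve = _binned_curve(np.array(xs), np.array(ys), "mu_abs_LFC_vs_LP", n_boot=n_boot, seed=seed)
    fit = fit_linear_points(np.array(xs, float), np.array(ys, float))
    return curve, fit


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------

def fold_change_se(mean_a: float, sem_a: float, mean_b: float, sem_b: float) -> float:
    """Standard error of the fold change B/A by first-order error propagation:

        SE = (B/A) * sqrt(sem_A^2/A^2 + sem_B^2/B^2)
    """
    if mean_a == 0 or mean_b == 0:
        raise ValueError("fold-change SE undefined for zero means")
    fc = mean_b / mean_a
    return abs(fc) * float(np.sqrt((sem_a / mean_a) ** 2 + (sem_b / mean_b) ** 2))


def operon_autocorrelation(
    expression: pd.DataFrame,
    annotation: GenomeAnnotation,
    cohort_filter: Callable[[str], bool] | None = None,
    max_lag: int | None = None,
) -> pd.DataFrame:
    """Mean normalized unbiased spatial autocorrelation of LFC-by-position series.

    Each operon's LFC series (ordered by position, mean-centered per operon)
    contributes an unbiased autocovariance c(k) = sum_i x_i x_{i+k} / (N - k),
    normalized by its own c(0).  Operons with any unknown LFC are removed; so
    are zero-variance series (normalization undefined).  Returns per-lag means
    with SEM and the number of contributing operons.
    """
    lfc = expression.set_index("gene_id")["lfc"]
    per_lag: dict[int, list[float]] = {}
    for oid, gids in annotation.operons.items():
        if cohort_filter is not None and not cohort_filter(oid):
            continue
        if any(g not in lfc.index for g in gids) or len(gids) < 2:
            continue
        x = np.array([lfc[g] for g in gids], float)
        x = x - x.mean()
        c0 = float(np.dot(x, x)) / len(x)
        if c0 == 0:
            continue
        top = len(x) - 1 if max_lag is None else min(max_lag, len(x) - 1)
        for k in range(0, top + 1):
            ck = float(np.dot(x[: len(x) - k], x[k:])) / (len(x) - k)
            per_lag.setdefault(k, []).append(ck / c0)
    rows = [
        dict(lag=k, mean=float(np.mean(v)),
             sem=float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
             n_operons=len(v))
        for k, v in sorted(per_lag.items())
    ]
    return pd.DataFrame(rows)


def pooled_curve_identity(strata: StratifiedCurves) -> DistanceCurve:
    """n-weighted average of a stratification's two curves (equals the pooled curve)."""
    a, b = strata.with_stratum.data, strata.without_stratum.data
    merged = a.merge(b, on="x", how="outer", suffixes=("_a", "_b")).fillna(0.0)
    n = merged["n_a"] + merged["n_b"]
    mean = (merged["mean_a"] * merged["n_a"] + merged["mean_b"] * merged["n_b"]) / n
    out = pd.DataFrame(dict(x=merged["x"], mean=mean, sem=np.nan, ci_lo=np.nan, ci_hi=np.nan, n=n.astype(int)))
    return DistanceCurve(out.sort_values("x").reset_index(drop=True), "pooled(weighted)")
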