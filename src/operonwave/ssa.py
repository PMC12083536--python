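"""Stochastic model of operon transcription: multistep initiation, elongation,
spontaneous falloff and collision-induced premature terminations.

The promoter cycle is free ->(k_bind) closed ->(k_cc) open ->(k_oc) escaped;
an optional distinct k_escape step is folded into the open->escape rate
harmonically (1/k = 1/k_oc + 1/k_escape), which preserves the steady-state
escape flux exactly.  Elongation is gene-granular: one lattice site per gene,
traversal rate k_elong competing with spontaneous falloff k_falloff, so the
per-gene survival probability is s = k_elong / (k_elong + k_falloff).
Collisions are resolved only at promoter-bearing sites, when an elongating
RNAP steps onto a site whose promoter holds a closed or open complex.

Two interchangeable engines: a numba-compiled direct-method kernel (default)
and a pure-Python reference with an optional event log, used as a mutual
cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MAX_RNAPS = 512


@dataclass(frozen=True)
class CollisionPolicy:
    """Outcome probabilities when an elongating RNAP hits a promoter-bound RNAP.

    For a closed complex: pass through / elongating terminates / bound RNAP
    displaced.  For an open complex: pass through / elongating terminates /
    both terminate.  Each triple sums to 1; the classic two-outcome policy is
    the ``p_pass_* = 0`` sub-case.
    """

    p_pass_closed: float = 0.0
    p_elong_term_closed: float = 0.5
    p_bound_displaced_closed: float = 0.5
    p_pass_open: float = 0.0
    p_elong_term_open: float = 0.5
    p_both_term_open: float = 0.5

    def __post_init__(self):
        for trio in (
            (self.p_pass_closed, self.p_elong_term_closed, self.p_bound_displaced_closed),
            (self.p_pass_open, self.p_elong_term_open, self.p_both_term_open),
        ):
            if any(p < 0 for p in trio) or not math.isclose(sum(trio), 1.0, abs_tol=1e-9):
                raise ValueError(f"collision outcome probabilities must be >=0 and sum to 1, got {trio}")

    @classmethod
    def passthrough(cls) -> "CollisionPolicy":
        """No interference: elongating RNAPs ignore promoter-bound RNAPs."""
        return cls(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    @property
    def is_passthrough(self) -> bool:
        return self.p_pass_closed == 1.0 and self.p_pass_open == 1.0


@dataclass(frozen=True)
class PromoterSpec:
    """A promoter's position (1-based first gene transcribed) and cycle rates (1/s)."""

    first_gene_index: int
    k_bind: float = 0.1
    k_cc: float = 0.02
    k_oc: float = 0.02
    k_escape: float | None = None  # folded into k_oc when given

    @property
    def k_escape_effective(self) -> float:
        if self.k_escape is None:
            return self.k_oc
        return 1.0 / (1.0 / self.k_oc + 1.0 / self.k_escape)

    @property
    def flux(self) -> float:
        """Steady-state escape rate of the promoter cycle (closed form)."""
        rates = [self.k_bind, self.k_cc, self.k_escape_effective]
        if any(r <= 0 for r in rates):
            return 0.0
        return 1.0 / sum(1.0 / r for r in rates)


@dataclass
class OperonKineticModel:
    n_genes: int
    promoters: list[PromoterSpec]
    k_elong: float | Sequence[float] = 1.0
    k_falloff: float | Sequence[float] = 0.25
    collision_policy: CollisionPolicy = field(default_factory=CollisionPolicy)
    rnap_pool: int | None = None  # None = infinite (k_bind is pseudo-first-order)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for p in self.promoters:
            if not 1 <= p.first_gene_index <= self.n_genes:
                raise ValueError(f"promoter first_gene_index {p.first_gene_index} outside 1..{self.n_genes}")
            for r in (p.k_bind, p.k_cc, p.k_oc):
                if r < 0:
                    raise ValueError("rates must be >= 0")
        ke = self.k_elong_array
        if np.any(ke[:-1] == 0):
            logger.warning("k_elong is zero mid-operon: downstream genes unreachable")
        if np.any(ke < 0) or np.any(self.k_falloff_array < 0):
            raise ValueError("rates must be >= 0")

    @property
    def k_elong_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.k_elong, float), (self.n_genes,)).copy()

    @property
    def k_falloff_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.k_falloff, float), (self.n_genes,)).copy()

    @property
    def survival(self) -> np.ndarray:
        """Per-gene probability that an elongating RNAP traverses the gene."""
        ke, kf = self.k_elong_array, self.k_falloff_array
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(ke + kf > 0, ke / (ke + kf), 0.0)
        return s

    def with_stress(
        self,
        init_multiplier: float = 2.0,
        falloff_multiplier: float = 1.0,
        falloff_sigma: float = 0.0,
        seed: int | None = None,
    ) -> "OperonKineticModel":
        """Stress variant: k_cc and k_oc of all promoters multiplied by
        ``init_multiplier``; per-gene falloff rates multiplied by
        ``falloff_multiplier``, optionally drawn from a mean-one lognormal
        around it (``falloff_sigma`` on the log scale, seeded) to model
        gene-to-gene variability of falloff rates."""
        proms = [
            replace(p, k_cc=p.k_cc * init_multiplier, k_oc=p.k_oc * init_multiplier)
            for p in self.promoters
        ]
        kf = self.k_falloff_array * falloff_multiplier
        if falloff_sigma > 0:
            rng = np.random.default_rng(seed)
            kf = kf * rng.lognormal(-0.5 * falloff_sigma**2, falloff_sigma, size=self.n_genes)
        return OperonKineticModel(
            n_genes=self.n_genes, promoters=proms, k_elong=self.k_elong_array,
            k_falloff=kf, collision_policy=self.collision_policy, rnap_pool=self.rnap_pool,
        )

    def has_internal_promoters(self) -> bool:
        return any(p.first_gene_index > 1 for p in self.promoters)


# ---------------------------------------------------------------------------
# reaction enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    name: str
    kind: str     # bind | isomerize | escape | traverse | falloff | collision
    rate: float   # rate constant (or outcome probability for collision channels)
    where: int    # promoter index or 0-based gene index


def build_reactions(model: OperonKineticModel) -> list[Reaction]:
    """Explicit channel list of the model (zero-rate channels are omitted).

    Per promoter: bind (free->closed), isomerize (closed->open) and escape
    (open->free + new elongating RNAP at the promoter's gene).  Per gene:
    traverse (increments the gene's transcript count, moves the RNAP on or
    completes) and, when the falloff rate is nonzero, spontaneous falloff.
    Internal promoters with a non-pass-through policy additionally list their
    closed- and open-complex collision channels.
    """
    rxns: list[Reaction] = []
    for i, p in enumerate(model.promoters):
        for kind, rate in (("bind", p.k_bind), ("isomerize", p.k_cc), ("escape", p.k_escape_effective)):
            if rate > 0:
                rxns.append(Reaction(f"promoter{i}_{kind}", kind, rate, i))
    ke, kf = model.k_elong_array, model.k_falloff_array
    for g in range(model.n_genes):
        if ke[g] > 0:
            rxns.append(Reaction(f"gene{g + 1}_traverse", "traverse", float(ke[g]), g))
        if kf[g] > 0:
            rxns.append(Reaction(f"gene{g + 1}_falloff", "falloff", float(kf[g]), g))
    cp = model.collision_policy
    for i, p in enumerate(model.promoters):
        if p.first_gene_index > 1 and not cp.is_passthrough:
            if cp.p_pass_closed < 1:
                rxns.append(Reaction(f"promoter{i}_collision_closed", "collision", 1 - cp.p_pass_closed, i))
            if cp.p_pass_open < 1:
                rxns.append(Reaction(f"promoter{i}_collision_open", "collision", 1 - cp.p_pass_open, i))
    return rxns


def initial_propensity_sum(model: OperonKineticModel) -> float:
    """Total propensity at the empty initial state (all promoters free, no RNAPs)."""
    return float(sum(p.k_bind for p in model.promoters))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    counts: np.ndarray        # per-gene completed transcripts
    n_events: int
    horizon_s: float
    events: list | None = None
    ended_early: bool = False


def _kernel_args(model: OperonKineticModel):
    fg = np.array([p.first_gene_index - 1 for p in model.promoters], dtype=np.int64)
    kb = np.array([p.k_bind for p in model.promoters], float)
    kcc = np.array([p.k_cc for p in model.promoters], float)
    koc = np.array([p.k_escape_effective for p in model.promoters], float)
    cp = model.collision_policy
    pool = -1 if model.rnap_pool is None else int(model.rnap_pool)
    return fg, kb, kcc, koc, model.k_elong_array, model.k_falloff_array, cp, pool


def simulate_ssa(
    model: OperonKineticModel,
    horizon_s: float,
    seed: int,
    method: Literal["compiled", "python"] = "compiled",
    record_events: bool = False,
) -> SimResult:
    """One exact SSA trajectory; returns per-gene completed-transcript counts.

    ``method="python"`` runs the pure-Python reference engine and can record an
    event log; the two engines implement the same process (cross-checked
    statistically in the test suite, not trajectory-by-trajectory — their RNG
    streams differ).  A state with all-zero propensities terminates the run
    early (flagged).
    """
    if horizon_s <= 0:
        raise ValueError("horizon must be > 0")
    seed = int(seed) % (2**31)
    if method == "compiled" and not record_events:
        from ._ssa_core import ssa_run

        fg, kb, kcc, koc, ke, kf, cp, pool = _kernel_args(model)
        rna, n_events = ssa_run(
            seed, float(horizon_s), model.n_genes, fg, kb, kcc, koc, ke, kf,
            cp.p_pass_closed, cp.p_elong_term_closed,
            cp.p_pass_open, cp.p_elong_term_open, pool, _MAX_RNAPS,
        )
        ended_early = initial_propensity_sum(model) == 0.0
        return SimResult(np.asarray(rna), int(n_events), horizon_s, None, ended_early)
    return _simulate_python(model, horizon_s, seed, record_events)


def _simulate_python(model, horizon_s, seed, record_events=False) -> SimResult:
    rng = np.random.RandomState(seed)
    fg, kb, kcc, koc, ke, kf, cp, pool = _kernel_args(model)
    n_prom, n_genes = len(fg), model.n_genes
    prom_state = np.zeros(n_prom, int)
    rnaps: list[int] = []
    rna = np.zeros(n_genes, dtype=np.int64)
    events = [] if record_events else None
    t, n_events = 0.0, 0
    ended_early = False
    while True:
        props = []
        n_busy = int((prom_state > 0).sum()) + len(rnaps)
        for p in range(n_prom):
            st = prom_state[p]
            if st == 0:
                props.append(0.0 if (pool >= 0 and n_busy >= pool) else kb[p])
            else:
                props.append(kcc[p] if st == 1 else koc[p])
        for g in rnaps:
            props.extend((ke[g], kf[g]))
        props = np.array(props)
        total = props.sum()
        if total <= 0:
            ended_early = True
            logger.info("all propensities zero at t=%.3g; run ended early", t)
            break
        t += rng.exponential(1.0 / total)
        if t > horizon_s:
            break
        n_events += 1
        chan = int(np.searchsorted(np.cumsum(props), rng.random() * total, side="right"))
        chan = min(chan, len(props) - 1)
        if chan < n_prom:
            st = prom_state[chan]
            if st < 2:
                prom_state[chan] = st + 1
                if events is not None:
                    events.append((t, "bind" if st == 0 else "isomerize", chan))
            else:
                prom_state[chan] = 0
                rnaps.append(int(fg[chan]))
                if events is not None:
                    events.append((t, "escape", chan))
        else:
            r, is_move = (chan - n_prom) // 2, (chan - n_prom) % 2 == 0
            g = rnaps[r]
            if not is_move:
                rnaps.pop(r)
                if events is not None:
                    events.append((t, "falloff", g))
            else:
                rna[g] += 1
                if events is not None:
                    events.append((t, "traverse", g))
                if g == n_genes - 1:
                    rnaps.pop(r)
                else:
                    newg, survived = g + 1, True
                    for p in range(n_prom):
                        if fg[p] == newg and prom_state[p] > 0:
                            u = rng.random()
                            if prom_state[p] == 1:
                                if u < cp.p_pass_closed:
                                    pass
                                elif u < cp.p_pass_closed + cp.p_elong_term_closed:
                                    survived = False
                                else:
                                    prom_state[p] = 0
                            else:
                                if u < cp.p_pass_open:
                                    pass
                                elif u < cp.p_pass_open + cp.p_elong_term_open:
                                    survived = False
                                else:
                                    survived = False
                                    prom_state[p] = 0
                            if events is not None:
                                events.append((t, "collision", newg))
                            break
                    if survived:
                        rnaps[r] = newg
                    else:
                        rnaps.pop(r)
    return SimResult(rna, n_events, horizon_s, events, ended_early)


@dataclass
class EnsembleResult:
    """Per-run per-gene completed-transcript counts with derived rates."""

    counts: np.ndarray      # (n_runs, n_genes)
    horizon_s: float
    condition: str = ""

    @property
    def n_runs(self) -> int:
        return self.counts.shape[0]

    @property
    def mean_rate(self) -> np.ndarray:
        """Per-gene mean transcript production rate (1/s)."""
        return self.counts.mean(axis=0) / self.horizon_s

    @property
    def se_rate(self) -> np.ndarray:
        return self.counts.std(axis=0, ddof=1) / np.sqrt(self.n_runs) / self.horizon_s


def run_ensemble(
    model: OperonKineticModel,
    n_runs: int,
    horizon_s: float,
    seed: int,
    condition: str = "",
    method: Literal["compiled", "python"] = "compiled",
) -> EnsembleResult:
    """Independent seeded runs (distinct sub-seeds spawned from the master seed)."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    sub = np.random.SeedSequence(seed).generate_state(n_runs)
    assert len(set(sub.tolist())) == n_runs, "sub-seeds must be distinct"
    counts = np.empty((n_runs, model.n_genes), dtype=np.int64)
    for i, s in enumerate(sub):
        counts[i] = simulate_ssa(model, horizon_s, int(s), method=method).counts
    return EnsembleResult(counts=counts, horizon_s=horizon_s, condition=condition)


# ---------------------------------------------------------------------------
# analytic oracle and derived statistics
# ---------------------------------------------------------------------------

def analytic_expected_rates(model: OperonKineticModel) -> np.ndarray:
    """Expected per-gene transcript production rate for the collision-free model.

    rate(g) = sum over promoters with first_gene_index <= g of
              flux_p * prod_{h=first..g} s_h,
    with s_h = k_elong_h / (k_elong_h + k_falloff_h) and flux_p the closed-form
    steady-state escape rate of the promoter cycle.  Raises when collisions are
    active and an internal promoter exists (superposition then fails).
    """
    if model.has_internal_promoters() and not model.collision_policy.is_passthrough:
        raise ValueError("analytic oracle invalid: collisions are active")
    s = model.survival
    rates = np.zeros(model.n_genes)
    for p in model.promoters:
        flux = p.flux
        surv = 1.0
        for g in range(p.first_gene_index - 1, model.n_genes):
            surv *= s[g]
            rates[g] += flux * surv
    return rates


def ensemble_lfc(
    control: EnsembleResult,
    stress: EnsembleResult,
    gene_ids: Sequence[str] | None = None,
    condition_id: str = "stress",
) -> pd.DataFrame:
    """Per-gene LFC = log2(mean stress rate / mean control rate) as an expression table.

    Genes with a zero control mean (or zero/zero) are excluded and logged.
    """
    if control.counts.shape[1] != stress.counts.shape[1]:
        raise ValueError("ensembles have different gene counts")
    n = control.counts.shape[1]
    ids = list(gene_ids) if gene_ids is not None else [f"g{i + 1}" for i in range(n)]
    rows = []
    for i, gid in enumerate(ids):
        c, s = control.mean_rate[i], stress.mean_rate[i]
        if c == 0:
            logger.info("gene %s: zero control mean, excluded from LFC", gid)
            continue
        rows.append(dict(gene_id=gid, condition_id=condition_id, lfc=float(np.log2(s / c)), p_value=np.nan))
    return pd.DataFrame(rows)


def tandem_interference_ratio(
    upstream: PromoterSpec,
    downstream: PromoterSpec,
    n_runs: int = 200,
    horizon_s: float = 1e5,
    seed: int = 0,
    collision_policy: CollisionPolicy | None = None,
    condition_multipliers: tuple[float, float] = (1.0, 1.0),
) -> dict:
    """(E_U + E_D) / E_T: summed single-promoter expression over tandem expression.

    Three two-site models share a common reporter (site 2, no falloff): the
    upstream promoter alone at site 1, the downstream promoter alone at site 2,
    and both in non-overlapping tandem.  ``condition_multipliers`` scales
    (k_cc, k_oc) of both promoters to mimic a stress.  Coupled sub-seeds are
    used across the three models.  Returns the ratio with a Monte-Carlo SE.
    """
    cp = collision_policy or CollisionPolicy()
    mult = condition_multipliers[0]
    up = replace(upstream, first_gene_index=1, k_cc=upstream.k_cc * mult, k_oc=upstream.k_oc * mult)
    down = replace(downstream, first_gene_index=2, k_cc=downstream.k_cc * mult, k_oc=downstream.k_oc * mult)

    def make(proms):
        return OperonKineticModel(
            n_genes=2, promoters=proms, k_elong=1.0, k_falloff=0.0, collision_policy=cp
        )

    reporter = 1  # 0-based index of the reporter gene
    res = {}
    for name, proms in (("U", [up]), ("D", [down]), ("T", [up, down])):
        ens = run_ensemble(make(proms), n_runs, horizon_s, seed, condition=name)
        res[name] = (float(ens.mean_rate[reporter]), float(ens.se_rate[reporter]))
    (eu, su), (ed, sd), (et, st) = res["U"], res["D"], res["T"]
    ratio = (eu + ed) / et
    se = abs(ratio) * np.sqrt((su**2 + sd**2) / (eu + ed) ** 2 + st**2 / et**2)
    return dict(ratio=float(ratio), se=float(se), E_U=eu, E_D=ed, E_T=et)
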