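"""Compiled Gillespie kernel for the operon transcription model.

One lattice site per gene.  State: per-promoter occupancy (free / closed
complex / open complex) and the gene positions of elongating RNA polymerases.
Channels: promoter free->closed (k_bind, gated by a finite RNAP pool when
given), closed->open (k_cc), open->escape (k_oc; escape spawns an elongating
RNAP at the promoter's first gene); per elongating RNAP, traversal of its
current gene (k_elong, increments that gene's completed-transcript count and
moves on or finishes) competing with spontaneous falloff (k_falloff).  An RNAP
stepping onto a promoter-bearing site whose promoter holds a closed or open
complex triggers a collision resolved by the (pass / elongating-terminates /
displace-or-both-terminate) probabilities.

Direct-method SSA; the numpy legacy RNG inside numba gives platform-stable
streams for a given integer seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def ssa_run(
    seed,
    horizon,
    n_genes,
    prom_fg,      # int64[:] 0-based first-gene index per promoter
    prom_kb,      # float64[:]
    prom_kcc,
    prom_koc,
    k_elong,      # float64[n_genes]
    k_falloff,    # float64[n_genes]
    p_pass_c,     # collision outcome probabilities, closed complex
    p_et_c,
    p_pass_o,     # ... open complex (remainders: displace / both terminate)
    p_et_o,
    pool,         # RNAP pool size; -1 = infinite
    max_rnaps,
):
    np.random.seed(seed)
    n_prom = prom_fg.shape[0]
    prom_state = np.zeros(n_prom, dtype=np.int64)  # 0 free, 1 closed, 2 open
    rnap_pos = np.empty(max_rnaps, dtype=np.int64)
    n_rnap = 0
    rna = np.zeros(n_genes, dtype=np.int64)
    props = np.empty(n_prom + 2 * max_rnaps, dtype=np.float64)
    t = 0.0
    n_events = 0

    while True:
        total = 0.0
        n_bound = 0
        for p in range(n_prom):
            if prom_state[p] > 0:
                n_bound += 1
        for p in range(n_prom):
            st = prom_state[p]
            if st == 0:
                if pool >= 0 and (n_bound + n_rnap) >= pool:
                    a = 0.0
                else:
                    a = prom_kb[p]
            elif st == 1:
                a = prom_kcc[p]
            else:
                a = prom_koc[p]
            props[p] = a
            total += a
        for r in range(n_rnap):
            g = rnap_pos[r]
            props[n_prom + 2 * r] = k_elong[g]
            props[n_prom + 2 * r + 1] = k_falloff[g]
            total += k_elong[g] + k_falloff[g]
        if total <= 0.0:
            break  # all propensities zero: nothing can ever fire again
        u = np.random.random()
        if u < 1e-300:
            u = 1e-300
        t += -np.log(u) / total
        if t > horizon:
            break
        n_events += 1

        target = np.random.random() * total
        acc = 0.0
        chan = n_prom + 2 * n_rnap - 1
        for c in range(n_prom + 2 * n_rnap):
            acc += props[c]
            if target < acc:
                chan = c
                break

        if chan < n_prom:
            st = prom_state[chan]
            if st == 0:
                prom_state[chan] = 1
            elif st == 1:
                prom_state[chan] = 2
            else:
                prom_state[chan] = 0
                if n_rnap < max_rnaps:
                    rnap_pos[n_rnap] = prom_fg[chan]
                    n_rnap += 1
        else:
            r = (chan - n_prom) // 2
            is_move = ((chan - n_prom) % 2) == 0
            g = rnap_pos[r]
            if not is_move:
                rnap_pos[r] = rnap_pos[n_rnap - 1]
                n_rnap -= 1
            else:
                rna[g] += 1
                if g == n_genes - 1:
                    rnap_pos[r] = rnap_pos[n_rnap - 1]
                    n_rnap -= 1
                else:
                    newg = g + 1
                    survived = True
                    for p in range(n_prom):
                        if prom_fg[p] == newg and prom_state[p] > 0:
                            u2 = np.random.random()
                            if prom_state[p] == 1:
                                if u2 < p_pass_c:
                                    pass
                                elif u2 < p_pass_c + p_et_c:
                                    survived = False
                                else:
                                    prom_state[p] = 0
                            else:
                                if u2 < p_pass_o:
                                    pass
                                elif u2 < p_pass_o + p_et_o:
                                    survived = False
                                else:
                                    survived = False
                                    prom_state[p] = 0
                            break
                    if survived:
                        rnap_pos[r] = newg
                    else:
                        rnap_pos[r] = rnap_pos[n_rnap - 1]
                        n_rnap -= 1
    return rna, n_events
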