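"""Compiled Metropolis update kernel.

Single tight loop over site-copy attempts; neighbour lookups go through
precomputed torus tables and the two contact matrices are packed into one
flat table indexed by (same_cluster, type_a, type_b), so the inner loop is
load-dominated.  Volumes are updated in place; the caller owns all other
bookkeeping between chunks.

RNG: xorshift64* seeded per chunk by the caller's master generator.  The
Metropolis rule only needs uniform variates; reproducibility is guaranteed
by the chunk seeds, not by matching any numpy stream.
"""

import numba
import numpy as np

_N_TYPES = 10


def pack_contact_tables(internal_j, external_J):
    """Flat (2*N*N,) table: [same_cluster * N*N + ta * N + tb]."""
    tab = np.empty(2 * _N_TYPES * _N_TYPES, dtype=np.float64)
    tab[: _N_TYPES * _N_TYPES] = np.asarray(external_J, dtype=np.float64).ravel()
    tab[_N_TYPES * _N_TYPES:] = np.asarray(internal_j, dtype=np.float64).ravel()
    return tab


@numba.njit(cache=True)
def run_attempts_kernel(sites, nbr3, nbr4, ctype, cluster, volume, target,
                        lam, frozen, ctab, T, n_attempts, seed):
    """Perform n_attempts Metropolis site-copy attempts in place.

    Returns (accepted_count, sum_of_accepted_dH).
    """
    n_sites = sites.shape[0]
    accepted = 0
    dh_sum = 0.0
    inv_T = 1.0 / T
    x = np.uint64(seed) | np.uint64(1)
    NN = _N_TYPES * _N_TYPES
    for _ in range(n_attempts):
        # xorshift64* — three draws per attempt from one advance each
        x ^= x << np.uint64(13)
        x ^= x >> np.uint64(7)
        x ^= x << np.uint64(17)
        u = np.float64(x >> np.uint64(11)) * (1.0 / 9007199254740992.0)
        j = np.int64(u * n_sites)
        x ^= x << np.uint64(13)
        x ^= x >> np.uint64(7)
        x ^= x << np.uint64(17)
        u = np.float64(x >> np.uint64(11)) * (1.0 / 9007199254740992.0)
        i = nbr3[j, np.int64(u * 12.0)]
        si = np.int64(sites[i])
        sj = np.int64(sites[j])
        if si == sj:
            continue
        if frozen[si] or frozen[sj]:
            continue
        if sj != 0 and volume[sj] <= 1:  # extinction guard
            continue
        dh = 0.0
        if si != 0:
            dh += lam[si] * (2.0 * (volume[si] - target[si]) + 1.0)
        if sj != 0:
            dh += lam[sj] * (-2.0 * (volume[sj] - target[sj]) + 1.0)
        ti = np.int64(ctype[si]) * _N_TYPES
        tj = np.int64(ctype[sj]) * _N_TYPES
        cli = cluster[si]
        clj = cluster[sj]
        for m in range(20):
            sk = np.int64(sites[nbr4[j, m]])
            if sk != si:
                tk = np.int64(ctype[sk])
                if si != 0 and sk != 0 and cli == cluster[sk]:
                    dh += ctab[NN + ti + tk]
                else:
                    dh += ctab[ti + tk]
            if sk != sj:
                tk = np.int64(ctype[sk])
                if sj != 0 and sk != 0 and clj == cluster[sk]:
                    dh -= ctab[NN + tj + tk]
                else:
                    dh -= ctab[tj + tk]
        if dh > 0.0:
            x ^= x << np.uint64(13)
            x ^= x >> np.uint64(7)
            x ^= x << np.uint64(17)
            u = np.float64(x >> np.uint64(11)) * (1.0 / 9007199254740992.0)
            if u >= np.exp(-dh * inv_T):
                continue
        sites[j] = np.int32(si)
        volume[si] += 1
        volume[sj] -= 1
        accepted += 1
        dh_sum += dh
    return accepted, dh_sum
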