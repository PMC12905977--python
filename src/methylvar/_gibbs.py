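"""Numba inner loop for the single-site Gibbs sampler.

One call performs one full sweep over all markers (in the caller-supplied
random order), updating the residual vector, effect vector and component
indicators in place.  All random numbers are drawn by the caller from a
seeded ``numpy.random.Generator`` and passed in, so the kernel itself is
deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def gibbs_sweep(Zt, r, beta, comp, ztz, set_idx, comp_var, log_pi, sigma_e2,
                order, unif, norm):
    """One Gibbs sweep.

    Zt        : (p, n) marker matrix, one row per standardized marker
    r         : (n,) current residual y - Z beta (updated in place)
    beta      : (p,) current effects (updated in place)
    comp      : (p,) current component indicator, 0 = spike (updated in place)
    ztz       : (p,) precomputed squared column norms
    set_idx   : (p,) marker-set index of each marker
    comp_var  : (n_sets, K) per-component effect variance; column 0 is the spike (0)
    log_pi    : (n_sets, K) log mixture proportions
    sigma_e2  : residual variance for this sweep
    order     : (p,) update order
    unif,norm : (p,) U(0,1) and N(0,1) draws, one of each per marker
    """
    p, n = Zt.shape
    K = comp_var.shape[1]
    logl = np.empty(K)
    for t in range(p):
        j = order[t]
        zj = Zt[j]
        bj = beta[j]
        rhs = 0.0
        for i in range(n):
            rhs += zj[i] * r[i]
        if bj != 0.0:
            rhs += ztz[j] * bj  # residual excluding marker j
        s = set_idx[j]
        logl[0] = log_pi[s, 0]
        mx = logl[0]
        for k in range(1, K):
            ck = comp_var[s, k]
            d = ck * ztz[j] + sigma_e2
            logl[k] = (log_pi[s, k]
                       - 0.5 * np.log(d / sigma_e2)
                       + 0.5 * rhs * rhs * ck / (sigma_e2 * d))
            if logl[k] > mx:
                mx = logl[k]
        tot = 0.0
        for k in range(K):
            logl[k] = np.exp(logl[k] - mx)
            tot += logl[k]
        u = unif[t] * tot
        acc = 0.0
        newk = K - 1
        for k in range(K):
            acc += logl[k]
            if u <= acc:
                newk = k
                break
        if newk == 0:
            newb = 0.0
        else:
            ck = comp_var[s, newk]
            d = ck * ztz[j] + sigma_e2
            newb = ck * rhs / d + np.sqrt(sigma_e2 * ck / d) * norm[t]
        diff = bj - newb
        if diff != 0.0:
            for i in range(n):
                r[i] += zj[i] * diff
        beta[j] = newb
        comp[j] = newk
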