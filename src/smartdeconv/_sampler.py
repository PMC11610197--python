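"""Numba kernels for the collapsed Gibbs sweep.

The sweep visits every molecule in fixed spot-major order, removes its
weighted count from the tables, draws a new (cell type, marker-branch) pair
from the collapsed full conditional, and adds the weight back.  The branch
probabilities implemented here must stay in lock-step with the pure-Python
reference in :func:`smartdeconv.core.conditional_probs`, which the test
suite checks against exhaustive enumeration of the collapsed joint.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def gibbs_sweep_kernel(doc, word, weight, z, s,
                       n_dk, n_kv, nt_kv, n_k, nt_k,
                       alpha_dk, is_marker, n_markers,
                       n_marked, beta, beta_tilde, gamma1, gamma2):
    n_tokens = doc.shape[0]
    K = n_dk.shape[1]
    V = n_kv.shape[1]
    p0 = np.empty(K)
    p1 = np.empty(K)
    for t in range(n_tokens):
        d = doc[t]
        v = word[t]
        m = weight[t]
        k_old = z[t]
        # remove this molecule's weighted count ("-di" state)
        n_dk[d, k_old] -= m
        if s[t] == 1:
            nt_kv[k_old, v] -= m
            nt_k[k_old] -= m
        else:
            n_kv[k_old, v] -= m
            n_k[k_old] -= m
        total = 0.0
        for k in range(K):
            a = n_dk[d, k] + alpha_dk[d, k]
            std = (n_kv[k, v] + beta) / (n_k[k] + beta * V)
            if k < n_marked:
                denom = n_k[k] + nt_k[k] + gamma1 + gamma2
                p0[k] = a * ((n_k[k] + gamma2) / denom) * std
                if is_marker[k, v]:
                    p1[k] = a * ((nt_k[k] + gamma1) / denom) * (
                        (nt_kv[k, v] + beta_tilde)
                        / (nt_k[k] + beta_tilde * n_markers[k])
                    )
                else:
                    p1[k] = 0.0
            else:
                p0[k] = a * std
                p1[k] = 0.0
            total += p0[k] + p1[k]
        u = np.random.random() * total
        k_new = K - 1
        s_new = 0
        acc = 0.0
        for k in range(K):
            acc += p0[k]
            if u < acc:
                k_new = k
                s_new = 0
                break
            acc += p1[k]
            if u < acc:
                k_new = k
                s_new = 1
                break
        z[t] = k_new
        s[t] = s_new
        n_dk[d, k_new] += m
        if s_new == 1:
            nt_kv[k_new, v] += m
            nt_k[k_new] += m
        else:
            n_kv[k_new, v] += m
            n_k[k_new] += m
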