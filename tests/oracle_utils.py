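"""Independent brute-force oracle for the collapsed joint of the model.

Written directly from the generative story (Dirichlet-multinomial and
Beta-Bernoulli marginalization), without reference to the sampler code: for
unit gene weights and fixed alpha, the probability of an assignment
configuration (z, s) is proportional to

    prod_d prod_k  Gamma(n_dk + alpha_k)                    [theta collapsed]
  x prod_k  prod_v Gamma(n_kv + beta) / Gamma(n_k + beta V) [phi collapsed]
  x prod_{k marked} prod_{v in sup_k} Gamma(nt_kv + beta~)
        / Gamma(nt_k + beta~ L_k)                           [phi~ collapsed]
  x prod_{k marked} Gamma(nt_k + g1) Gamma(n_k + g2)
        / Gamma(n_k + nt_k + g1 + g2)                       [pi collapsed]

(constant factors across configurations omitted).
"""

import itertools

import numpy as np
from scipy.special import gammaln


def admissible_states(word, support, K, n_marked):
    """Per-token list of admissible (type, branch) pairs."""
    out = []
    for v in word:
        opts = [(k, 0) for k in range(K)]
        opts += [(k, 1) for k in range(n_marked) if support[k, v]]
        out.append(opts)
    return out


def log_joint(cfg, doc, word, support, alpha, beta, beta_tilde, g1, g2,
              D, K, V, n_marked):
    L = support.sum(axis=1)
    n_dk = np.zeros((D, K))
    n_kv = np.zeros((K, V))
    nt_kv = np.zeros((K, V))
    for t, (k, s) in enumerate(cfg):
        n_dk[doc[t], k] += 1
        if s:
            nt_kv[k, word[t]] += 1
        else:
            n_kv[k, word[t]] += 1
    n_k, nt_k = n_kv.sum(axis=1), nt_kv.sum(axis=1)
    lp = float(np.sum(gammaln(n_dk + alpha[None, :])))
    lp += float(np.sum(gammaln(n_kv + beta)) - np.sum(gammaln(n_k + beta * V)))
    for k in range(n_marked):
        sup = np.flatnonzero(support[k])
        lp += float(np.sum(gammaln(nt_kv[k, sup] + beta_tilde)))
        lp -= float(gammaln(nt_k[k] + beta_tilde * L[k]))
        lp += float(gammaln(nt_k[k] + g1) + gammaln(n_k[k] + g2)
                    - gammaln(n_k[k] + nt_k[k] + g1 + g2))
    return lp


def enumerate_posterior(doc, word, support, alpha, beta, beta_tilde,
                        g1, g2, D, K, V, n_marked):
    """Exact posterior over all (z, s) configurations and the per-token
    marginal occupancy, a (T, K, 2) array."""
    states = admissible_states(word, support, K, n_marked)
    configs = list(itertools.product(*states))
    logps = np.array([
        log_joint(cfg, doc, word, support, alpha, beta, beta_tilde,
                  g1, g2, D, K, V, n_marked)
        for cfg in configs
    ])
    p = np.exp(logps - logps.max())
    p /= p.sum()
    marg = np.zeros((len(doc), K, 2))
    for ci, cfg in enumerate(configs):
        for t, (k, s) in enumerate(cfg):
            marg[t, k, s] += p[ci]
    return configs, p, marg
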