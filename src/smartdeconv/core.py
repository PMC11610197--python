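"""Marker-guided topic model for spot deconvolution: collapsed Gibbs sampler.

The generative model treats every mRNA molecule in a spot as drawn from one
of ``K`` cell types. Each spot has a Dirichlet-distributed cell-type
proportion vector theta_d with concentration alpha; each cell type has a
standard gene distribution phi_k ~ Dirichlet(beta). The first ``K~`` types
also carry a marker-restricted distribution phi~_k ~ Dirichlet(beta~) whose
support is the type's marker genes, and each molecule of such a type uses
phi~_k with probability pi_k ~ Beta(gamma1, gamma2). Because
``beta~ > beta``, marker genes get a higher prior mean inside their own
type, which anchors topic identity to the supplied marker lists.

Inference integrates out (theta, phi, phi~, pi) and samples the discrete
per-molecule assignments (z, s) by collapsed Gibbs sampling, with an
optional inverse-frequency weighting of genes so that ubiquitously expressed
genes do not dominate the inferred types. alpha is resampled once per sweep
by slice sampling under type-class-specific Gamma priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _sampler
from .data import DeconvolutionResult, MarkerSpec, ModelConfig, SpotCounts

logger = logging.getLogger("smartdeconv")

__all__ = [
    "gene_weights", "initialize_state", "conditional_probs", "gibbs_sweep",
    "sample_alpha", "estimate_pi", "estimate_result", "fit", "ModelState",
    "Snapshot", "slice_sample",
]

_SEED_MOD = 2**31 - 1


def gene_weights(counts: SpotCounts, use_weighting: bool = True) -> np.ndarray:
    """Inverse-frequency gene weights ``m_v``, normalized so the average
    weight per molecule is 1.

    With weighting enabled, a gene with corpus-wide relative frequency
    ``f_v`` gets raw weight ``-log2(f_v)``, then the vector is scaled by the
    token-weighted mean so that total weighted mass equals total molecule
    count. Rare genes therefore count for more than ubiquitous ones, which
    keeps a handful of highly expressed genes from dominating every inferred
    cell type. Genes absent from the corpus get weight 0.
    """
    total = counts.matrix.sum()
    if total == 0:
        raise ValueError("all-zero counts matrix")
    if not use_weighting:
        return np.ones(counts.n_genes)
    f = counts.matrix.sum(axis=1) / total
    raw = np.zeros_like(f)
    nz = f > 0
    raw[nz] = -np.log2(f[nz])
    mean_w = float(np.sum(f * raw))  # average weight per molecule
    if mean_w == 0:
        # single expressed gene: -log2(1) = 0; fall back to unit weights
        return (nz).astype(float)
    return raw / mean_w


@dataclass
class ModelState:
    """Mutable sampler state: token assignments plus weighted count tables.

    ``n_dk`` (spot x type) counts weighted molecules per spot and type;
    ``n_kv``/``n_k`` count the standard-branch (s=0) molecules per type and
    gene, ``nt_kv``/``nt_k`` the marker-branch (s=1) molecules (zero outside
    each type's marker support). ``alpha_dk`` holds the per-spot Dirichlet
    concentration; in the base model every row equals the shared ``alpha``.
    """

    doc: np.ndarray          # token -> spot index (spot-major order)
    word: np.ndarray         # token -> gene index
    weight: np.ndarray       # token -> gene weight m_v
    z: np.ndarray            # token -> cell type
    s: np.ndarray            # token -> marker-branch indicator
    n_dk: np.ndarray
    n_kv: np.ndarray
    nt_kv: np.ndarray
    n_k: np.ndarray
    nt_k: np.ndarray
    alpha: np.ndarray        # shared concentration (length K)
    alpha_dk: np.ndarray     # per-spot concentration (D x K)
    weights: np.ndarray      # gene weights m (length V)
    support: np.ndarray      # bool (K, V) marker membership
    n_markers: np.ndarray    # per-type marker count L_k (length K)
    n_marked: int            # K~
    N_dw: np.ndarray         # weighted library size per spot
    gene_ids: list[str] = field(default_factory=list)
    spot_ids: list[str] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)

    @property
    def n_types(self) -> int:
        return self.n_dk.shape[1]

    @property
    def n_genes(self) -> int:
        return self.n_kv.shape[1]

    @property
    def n_spots(self) -> int:
        return self.n_dk.shape[0]

    def rebuild_tables(self) -> tuple[np.ndarray, ...]:
        """Recompute all count tables from (z, s); used to check consistency."""
        D, K, V = self.n_spots, self.n_types, self.n_genes
        n_dk = np.zeros((D, K))
        n_kv = np.zeros((K, V))
        nt_kv = np.zeros((K, V))
        np.add.at(n_dk, (self.doc, self.z), self.weight)
        std = self.s == 0
        np.add.at(n_kv, (self.z[std], self.word[std]), self.weight[std])
        mk = ~std
        np.add.at(nt_kv, (self.z[mk], self.word[mk]), self.weight[mk])
        return n_dk, n_kv, nt_kv, n_kv.sum(axis=1), nt_kv.sum(axis=1)

    def sync_alpha_dk(self) -> None:
        self.alpha_dk[:] = self.alpha[None, :]


def _expand_tokens(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unroll the count matrix into per-molecule (spot, gene) token arrays in
    spot-major order."""
    V, D = matrix.shape
    docs, words = [], []
    for d in range(D):
        col = matrix[:, d]
        nz = np.flatnonzero(col)
        w = np.repeat(nz, col[nz])
        words.append(w)
        docs.append(np.full(w.size, d, dtype=np.int32))
    return np.concatenate(docs), np.concatenate(words).astype(np.int32)


def initialize_state(counts: SpotCounts, markers: MarkerSpec,
                     config: ModelConfig, seed: int) -> ModelState:
    """Build an initial sampler state.

    Every molecule gets a uniform-random type; molecules of a marker gene
    are instead, with probability 0.5, seeded onto a uniformly chosen type
    that lists the gene as a marker, with the marker branch (s=1) switched
    on. alpha starts from a draw of its Gamma priors.
    """
    if markers.n_types == 0:
        raise ValueError("no cell types declared")
    if counts.matrix.sum() == 0:
        raise ValueError("empty counts matrix")
    rng = np.random.default_rng(seed)
    K, Kt = markers.n_types, markers.n_marked
    V, D = counts.n_genes, counts.n_spots
    support = markers.support_matrix(counts.gene_ids)
    n_markers = support.sum(axis=1).astype(float)
    m = gene_weights(counts, config.use_weighting)
    doc, word = _expand_tokens(counts.matrix)
    T = doc.size
    z = rng.integers(0, K, size=T).astype(np.int32)
    s = np.zeros(T, dtype=np.int8)
    marker_of = [np.flatnonzero(support[:, v]) for v in range(V)]
    is_marker_gene = support.any(axis=0)
    cand = np.flatnonzero(is_marker_gene[word])
    if cand.size:
        pick = cand[rng.random(cand.size) < 0.5]
        for t in pick:
            owners = marker_of[word[t]]
            z[t] = owners[rng.integers(owners.size)]
            s[t] = 1
    weight = m[word]
    alpha = np.empty(K)
    alpha[:Kt] = rng.gamma(config.eta_tilde1, 1.0 / config.eta_tilde2, size=Kt)
    alpha[Kt:] = rng.gamma(config.eta1, 1.0 / config.eta2, size=K - Kt)
    alpha = np.maximum(alpha, 1e-6)
    state = ModelState(
        doc=doc, word=word, weight=weight, z=z, s=s,
        n_dk=np.zeros((D, K)), n_kv=np.zeros((K, V)),
        nt_kv=np.zeros((K, V)), n_k=np.zeros(K), nt_k=np.zeros(K),
        alpha=alpha, alpha_dk=np.tile(alpha, (D, 1)),
        weights=m, support=support, n_markers=n_markers, n_marked=Kt,
        N_dw=np.zeros(D), gene_ids=list(counts.gene_ids),
        spot_ids=list(counts.spot_ids), cell_types=list(markers.cell_types),
    )
    state.n_dk, state.n_kv, state.nt_kv, state.n_k, state.nt_k = state.rebuild_tables()
    state.N_dw = state.n_dk.sum(axis=1)
    return state


def conditional_probs(state: ModelState, d: int, v: int,
                      config: ModelConfig) -> np.ndarray:
    """Collapsed full conditional over (type, branch) for one molecule of
    gene ``v`` in spot ``d``, given that the molecule's own count has already
    been removed from the tables.

    Returns a ``(K, 2)`` array; column 0 is the standard branch, column 1 the
    marker branch (zero wherever ``v`` is not a marker of the type or the
    type has no markers). Entries sum to 1.
    """
    K, V = state.n_types, state.n_genes
    Kt = state.n_marked
    b, bt = config.beta, config.beta_tilde
    g1, g2 = config.gamma1, config.gamma2
    a = state.n_dk[d] + state.alpha_dk[d]
    std = (state.n_kv[:, v] + b) / (state.n_k + b * V)
    p = np.zeros((K, 2))
    p[:, 0] = a * std
    if Kt:
        denom = state.n_k[:Kt] + state.nt_k[:Kt] + g1 + g2
        p[:Kt, 0] *= (state.n_k[:Kt] + g2) / denom
        mk = state.support[:Kt, v]
        p[:Kt, 1] = np.where(
            mk,
            a[:Kt] * ((state.nt_k[:Kt] + g1) / denom)
            * (state.nt_kv[:Kt, v] + bt)
            / (state.nt_k[:Kt] + bt * state.n_markers[:Kt]),
            0.0,
        )
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate conditional: probabilities sum to zero")
    return p / total


def gibbs_sweep(state: ModelState, config: ModelConfig) -> ModelState:
    """One full pass over all molecules in spot-major order (in place)."""
    _sampler.gibbs_sweep_kernel(
        state.doc, state.word, state.weight, state.z, state.s,
        state.n_dk, state.n_kv, state.nt_kv, state.n_k, state.nt_k,
        state.alpha_dk, state.support, state.n_markers,
        state.n_marked, config.beta, config.beta_tilde,
        config.gamma1, config.gamma2,
    )
    return state


def slice_sample(logpdf, x0: float, rng: np.random.Generator,
                 width: float = 1.0, max_steps: int = 64) -> float:
    """Univariate slice sampler with stepping-out and shrinkage."""
    ly0 = logpdf(x0)
    if not np.isfinite(ly0):
        raise ValueError(f"non-finite log-density at slice start x0={x0!r}")
    logy = ly0 + np.log(rng.random())
    u = rng.random()
    left, right = x0 - width * u, x0 - width * u + width
    steps = max_steps
    while steps > 0 and logpdf(left) > logy:
        left -= width
        steps -= 1
    steps = max_steps
    while steps > 0 and logpdf(right) > logy:
        right += width
        steps -= 1
    while True:
        x1 = left + (right - left) * rng.random()
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def _alpha_logpost(a_k: float, k: int, alpha: np.ndarray, n_dk: np.ndarray,
                   N_dw: np.ndarray, shape: float, rate: float) -> float:
    if a_k <= 0 or not np.isfinite(a_k):
        return -np.inf
    other = alpha.sum() - alpha[k]
    A = other + a_k
    D = n_dk.shape[0]
    lp = (shape - 1.0) * np.log(a_k) - rate * a_k
    lp += D * gammaln(A) - np.sum(gammaln(N_dw + A))
    lp += np.sum(gammaln(n_dk[:, k] + a_k)) - D * gammaln(a_k)
    return float(lp)


def sample_alpha(state: ModelState, config: ModelConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Resample each alpha_k by slice sampling its collapsed full
    conditional (Gamma prior x Dirichlet-multinomial likelihood over the
    weighted spot-type counts), updating the state in place."""
    for k in range(state.n_types):
        if k < state.n_marked:
            shape, rate = config.eta_tilde1, config.eta_tilde2
        else:
            shape, rate = config.eta1, config.eta2

        def logpdf(t: float, _k: int = k, _s: float = shape, _r: float = rate) -> float:
            # sample on the log scale; +t is the Jacobian
            return _alpha_logpost(np.exp(t), _k, state.alpha, state.n_dk,
                                  state.N_dw, _s, _r) + t

        t_new = slice_sample(logpdf, float(np.log(state.alpha[k])), rng)
        state.alpha[k] = np.exp(t_new)
    state.sync_alpha_dk()
    return state.alpha


def estimate_pi(state: ModelState, config: ModelConfig) -> np.ndarray:
    """Posterior-mean marker-branch probability per marked type:
    ``(nt_k + gamma1) / (n_k + nt_k + gamma1 + gamma2)``."""
    Kt = state.n_marked
    return (state.nt_k[:Kt] + config.gamma1) / (
        state.n_k[:Kt] + state.nt_k[:Kt] + config.gamma1 + config.gamma2
    )


@dataclass
class Snapshot:
    """Copies of the count tables (and alpha) at one post-burn-in sweep."""

    n_dk: np.ndarray
    n_kv: np.ndarray
    nt_kv: np.ndarray
    n_k: np.ndarray
    nt_k: np.ndarray
    alpha_dk: np.ndarray
    cond: dict | None = None  # per-condition restricted tables, if requested

    @classmethod
    def of(cls, state: ModelState) -> "Snapshot":
        return cls(state.n_dk.copy(), state.n_kv.copy(), state.nt_kv.copy(),
                   state.n_k.copy(), state.nt_k.copy(), state.alpha_dk.copy())


def _snapshot_estimates(snap: Snapshot, state: ModelState, config: ModelConfig):
    K, V, Kt = state.n_types, state.n_genes, state.n_marked
    b, bt = config.beta, config.beta_tilde
    A = snap.alpha_dk.sum(axis=1)
    theta = (snap.n_dk + snap.alpha_dk) / (state.N_dw + A)[:, None]
    phi = (snap.n_kv + b) / (snap.n_k + b * V)[:, None]
    phi_tilde = np.zeros((Kt, V))
    if Kt:
        phi_tilde = state.support[:Kt] * (snap.nt_kv[:Kt] + bt) / (
            snap.nt_k[:Kt] + bt * state.n_markers[:Kt]
        )[:, None]
    pi = (snap.nt_k[:Kt] + config.gamma1) / (
        snap.n_k[:Kt] + snap.nt_k[:Kt] + config.gamma1 + config.gamma2
    )
    phi_star = phi.copy()
    if Kt:
        phi_star[:Kt] = (1.0 - pi)[:, None] * phi[:Kt] + pi[:, None] * phi_tilde
    return theta, phi, phi_tilde, pi, phi_star


def combine_phi(phi: np.ndarray, phi_tilde: np.ndarray,
                pi: np.ndarray) -> np.ndarray:
    """Reported per-type expression: ``(1 - pi) phi + pi phi~`` on the marked
    rows, plain ``phi`` on the no-marker rows."""
    Kt = pi.shape[0]
    out = np.array(phi, dtype=float, copy=True)
    if Kt:
        out[:Kt] = (1.0 - pi)[:, None] * phi[:Kt] + pi[:, None] * phi_tilde[:Kt]
    return out


def estimate_result(snapshots: list[Snapshot], state: ModelState,
                    config: ModelConfig) -> dict[str, np.ndarray]:
    """Average the per-snapshot posterior-mean estimates and renormalize
    rows. Returns raw arrays keyed theta/phi/phi_tilde/pi/phi_star/alpha."""
    if not snapshots:
        raise ValueError("no post-burn-in snapshots to estimate from")
    acc = None
    for snap in snapshots:
        est = _snapshot_estimates(snap, state, config)
        al = snap.alpha_dk.mean(axis=0)
        if acc is None:
            acc = [np.array(e, dtype=float) for e in est] + [al]
        else:
            for a, e in zip(acc, list(est) + [al]):
                a += e
    out = [a / len(snapshots) for a in acc]
    theta, phi, phi_tilde, pi, phi_star, alpha = out
    theta /= theta.sum(axis=1, keepdims=True)
    phi /= phi.sum(axis=1, keepdims=True)
    if phi_tilde.shape[0]:
        phi_tilde /= phi_tilde.sum(axis=1, keepdims=True)
    phi_star /= phi_star.sum(axis=1, keepdims=True)
    return {"theta": theta, "phi": phi, "phi_tilde": phi_tilde, "pi": pi,
            "phi_star": phi_star, "alpha": alpha}


def run_chain(state: ModelState, config: ModelConfig, chain_seed: int,
              update_alpha: bool = True,
              snapshot_hook=None) -> list[Snapshot]:
    """Run one Gibbs chain on ``state`` and return post-burn-in snapshots."""
    _sampler.seed_rng(int(chain_seed) % _SEED_MOD)
    alpha_rng = np.random.default_rng((int(chain_seed) + 1) % _SEED_MOD)
    snapshots: list[Snapshot] = []
    for it in range(config.iterations):
        gibbs_sweep(state, config)
        if update_alpha:
            sample_alpha(state, config, alpha_rng)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            snap = Snapshot.of(state)
            if snapshot_hook is not None:
                snapshot_hook(state, snap)
            snapshots.append(snap)
        if (it + 1) % 100 == 0:
            logger.info("sweep %d/%d: log-joint %.1f", it + 1,
                        config.iterations, collapsed_log_joint(state, config))
    return snapshots


def collapsed_log_joint(state: ModelState, config: ModelConfig) -> float:
    """Log of the collapsed joint density of the current assignments (up to
    the constant multinomial permutation factor); used for progress logging
    and convergence monitoring."""
    b, bt = config.beta, config.beta_tilde
    g1, g2 = config.gamma1, config.gamma2
    K, V, Kt = state.n_types, state.n_genes, state.n_marked
    A = state.alpha_dk.sum(axis=1)
    lp = float(np.sum(gammaln(A) - gammaln(state.N_dw + A)))
    lp += float(np.sum(gammaln(state.n_dk + state.alpha_dk)
                       - gammaln(state.alpha_dk)))
    lp += float(np.sum(gammaln(state.n_kv + b))) - K * V * gammaln(b)
    lp += float(np.sum(K * gammaln(b * V) - gammaln(state.n_k + b * V)))
    if Kt:
        sup = state.support[:Kt]
        lp += float(np.sum(sup * (gammaln(state.nt_kv[:Kt] + bt) - gammaln(bt))))
        lp += float(np.sum(gammaln(bt * state.n_markers[:Kt])
                           - gammaln(state.nt_k[:Kt] + bt * state.n_markers[:Kt])))
        lp += float(np.sum(
            gammaln(state.nt_k[:Kt] + g1) + gammaln(state.n_k[:Kt] + g2)
            - gammaln(state.n_k[:Kt] + state.nt_k[:Kt] + g1 + g2)
        )) + Kt * (gammaln(g1 + g2) - gammaln(g1) - gammaln(g2))
    return lp


def _match_unmarked(phi_ref: np.ndarray, phi_new: np.ndarray,
                    Kt: int) -> np.ndarray:
    """Permutation aligning a repeat's no-marker types to the reference
    repeat by greedy maximum correlation of phi rows (ties by index)."""
    K = phi_ref.shape[0]
    perm = np.arange(K)
    free_ref = list(range(Kt, K))
    free_new = list(range(Kt, K))
    while free_ref:
        best = None
        for i in free_ref:
            for j in free_new:
                r = _safe_corr(phi_ref[i], phi_new[j])
                if best is None or r > best[0] + 1e-15:
                    best = (r, i, j)
        _, i, j = best
        perm[i] = j
        free_ref.remove(i)
        free_new.remove(j)
    return perm


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def fit(counts: SpotCounts, markers: MarkerSpec,
        config: ModelConfig | None = None) -> DeconvolutionResult:
    """Deconvolve ``counts`` into the cell types of ``markers``.

    Runs ``config.n_repeats`` independent chains with derived seeds, averages
    their posterior-mean estimates (no-marker types are matched across
    repeats by profile correlation; marked types are identity-anchored by
    their markers), and returns row-renormalized estimates.
    """
    if config is None:
        config = ModelConfig()
    markers = markers.resolve(counts.gene_ids)
    support = markers.support_matrix(counts.gene_ids)
    zero_marker = [
        markers.cell_types[k]
        for k in range(markers.n_marked)
        if counts.matrix[support[k]].sum() == 0
    ]
    if zero_marker:
        logger.warning("marker-bearing types with zero marker counts in the "
                       "data (weakly identified): %s", zero_marker)
    per_repeat = []
    state = None
    for r in range(config.n_repeats):
        chain_seed = (int(config.seed) * 1000003 + 7919 * r) % _SEED_MOD
        state = initialize_state(counts, markers, config, chain_seed)
        try:
            snapshots = run_chain(state, config, chain_seed)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"repeat {r} failed: {exc}") from exc
        per_repeat.append(estimate_result(snapshots, state, config))
    ref = per_repeat[0]
    Kt = markers.n_marked
    acc = {k: np.array(v, dtype=float) for k, v in ref.items()}
    for est in per_repeat[1:]:
        perm = _match_unmarked(ref["phi"], est["phi"], Kt)
        acc["theta"] += est["theta"][:, perm]
        acc["phi"] += est["phi"][perm]
        acc["phi_star"] += est["phi_star"][perm]
        acc["alpha"] += est["alpha"][perm]
        acc["pi"] += est["pi"]
        acc["phi_tilde"] += est["phi_tilde"]
    for k in acc:
        acc[k] /= config.n_repeats
    acc["theta"] /= acc["theta"].sum(axis=1, keepdims=True)
    acc["phi"] /= acc["phi"].sum(axis=1, keepdims=True)
    acc["phi_star"] /= acc["phi_star"].sum(axis=1, keepdims=True)
    if Kt:
        acc["phi_tilde"] /= acc["phi_tilde"].sum(axis=1, keepdims=True)
    cts = markers.cell_types
    return DeconvolutionResult(
        theta=pd.DataFrame(acc["theta"], index=counts.spot_ids, columns=cts),
        phi=pd.DataFrame(acc["phi"], index=cts, columns=counts.gene_ids),
        phi_tilde=pd.DataFrame(acc["phi_tilde"], index=cts[:Kt],
                               columns=counts.gene_ids),
        pi=pd.Series(acc["pi"], index=cts[:Kt], name="pi"),
        phi_star=pd.DataFrame(acc["phi_star"], index=cts,
                              columns=counts.gene_ids),
        alpha=pd.Series(acc["alpha"], index=cts, name="alpha"),
        provenance={"config": config.to_dict(), "n_repeats": config.n_repeats,
                    "seed": config.seed},
    )
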