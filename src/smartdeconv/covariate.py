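"""Covariate extension: spot-level covariates on the proportion prior.

Instead of a shared Dirichlet concentration alpha, each spot gets
``theta_d ~ Dirichlet(exp(lambda^T x_d))`` where ``x_d`` is the spot's
covariate vector (first entry 1 for the intercept) and ``lambda`` is an
``M x K`` coefficient matrix with independent Normal(mu, sigma2) priors.
A positive coefficient lambda_mk raises the prior prevalence of type ``k``
where covariate ``m`` is high. The same collapsed Gibbs sweep is used; in
place of resampling alpha, every lambda_mk is slice-sampled against its
Dirichlet-multinomial likelihood each sweep.

Condition-specific expression profiles are obtained by restricting the
assignment count tables to the spots of each condition and applying the
usual smoothing formulas, so the per-condition profiles partition the
global counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _sampler
from .core import (ModelState, Snapshot, _match_unmarked, _snapshot_estimates,
                   combine_phi, estimate_result, gibbs_sweep, initialize_state,
                   slice_sample)
from .data import MarkerSpec, ModelConfig, SpotCounts

logger = logging.getLogger("smartdeconv")

_SEED_MOD = 2**31 - 1

__all__ = ["CovariateDesign", "CovariateResult", "fit_covariate",
           "sample_lambda", "condition_specific_expression",
           "log2_fold_change"]


@dataclass
class CovariateDesign:
    """Spot-by-covariate design matrix (first column = intercept of ones)."""

    X: np.ndarray
    names: list[str]
    condition: np.ndarray | None = None  # categorical per-spot labels

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("X must be D x M with M >= 1")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names length must match X columns")
        if self.condition is not None:
            self.condition = np.asarray(self.condition, dtype=object)
            if self.condition.size != self.X.shape[0]:
                raise ValueError("condition labels must align with X rows")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            logger.warning("design matrix is rank-deficient; the Gaussian "
                           "prior keeps the posterior proper")

    @classmethod
    def intercept_only(cls, n_spots: int,
                       condition=None) -> "CovariateDesign":
        return cls(np.ones((n_spots, 1)), ["intercept"], condition)

    @property
    def conditions(self) -> list:
        if self.condition is None:
            return []
        seen: dict = {}
        for c in self.condition:
            seen.setdefault(c, None)
        return list(seen)


@dataclass
class CovariateResult:
    lam: pd.DataFrame                  # M x K coefficients
    theta: pd.DataFrame
    phi: pd.DataFrame
    phi_tilde: pd.DataFrame
    pi: pd.Series
    phi_star: pd.DataFrame
    condition_phi_star: dict = field(default_factory=dict)
    prior: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _lambda_logpost(lam_mk: float, x_m: np.ndarray, base_eta: np.ndarray,
                    lam0: float, A_rest: np.ndarray, n_dk_col: np.ndarray,
                    N_dw: np.ndarray, mu: float, sigma2: float) -> float:
    col = np.exp(base_eta + x_m * (lam_mk - lam0))
    if not np.all(np.isfinite(col)) or np.any(col <= 0):
        return -np.inf
    A = A_rest + col
    lp = -0.5 * (lam_mk - mu) ** 2 / sigma2
    lp += float(np.sum(gammaln(A) - gammaln(N_dw + A)))
    lp += float(np.sum(gammaln(n_dk_col + col) - gammaln(col)))
    if not np.isfinite(lp):
        return -np.inf
    return lp


def sample_lambda(state: ModelState, X: np.ndarray, lam: np.ndarray,
                  mu: float, sigma2: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Slice-sample every coefficient lambda_mk from its full conditional
    (Normal prior x Dirichlet-multinomial likelihood on the weighted
    spot-type counts), then refresh ``state.alpha_dk``."""
    M, K = lam.shape
    eta = X @ lam
    alpha = np.exp(eta)
    for k in range(K):
        A_rest = alpha.sum(axis=1) - alpha[:, k]
        base = eta[:, k].copy()
        for m in range(M):
            lam0 = lam[m, k]
            x_m = X[:, m]

            def logpdf(val: float) -> float:
                return _lambda_logpost(val, x_m, base, lam0, A_rest,
                                       state.n_dk[:, k], state.N_dw,
                                       mu, sigma2)

            new = slice_sample(logpdf, lam0, rng,
                               width=max(np.sqrt(sigma2), 1e-4))
            base = base + x_m * (new - lam0)
            lam[m, k] = new
        eta[:, k] = base
        alpha[:, k] = np.exp(base)
    state.alpha_dk[:] = alpha
    return lam


def _condition_tables(state: ModelState, spot_condition: np.ndarray,
                      conditions: list) -> dict:
    out = {}
    token_cond = spot_condition[state.doc]
    for c in conditions:
        mask = token_cond == c
        K, V = state.n_types, state.n_genes
        n_kv = np.zeros((K, V))
        nt_kv = np.zeros((K, V))
        std = mask & (state.s == 0)
        np.add.at(n_kv, (state.z[std], state.word[std]), state.weight[std])
        mk = mask & (state.s == 1)
        np.add.at(nt_kv, (state.z[mk], state.word[mk]), state.weight[mk])
        out[c] = (n_kv, nt_kv, n_kv.sum(axis=1), nt_kv.sum(axis=1))
    return out


def condition_specific_expression(snapshots: list[Snapshot],
                                  state: ModelState,
                                  config: ModelConfig) -> dict:
    """Per-condition phi* matrices from condition-restricted count tables.

    Each snapshot must carry ``cond`` tables (attached by
    :func:`fit_covariate` when the design declares condition labels). For a
    condition ``c`` the smoothing formulas are applied to the counts of
    molecules in spots labeled ``c`` only; snapshot estimates are averaged
    and rows renormalized.
    """
    if not snapshots:
        raise ValueError("no snapshots")
    if snapshots[0].cond is None:
        raise ValueError("snapshots carry no condition-restricted tables")
    K, V, Kt = state.n_types, state.n_genes, state.n_marked
    b, bt = config.beta, config.beta_tilde
    g1, g2 = config.gamma1, config.gamma2
    out: dict = {}
    for c in snapshots[0].cond:
        acc = np.zeros((K, V))
        for snap in snapshots:
            n_kv, nt_kv, n_k, nt_k = snap.cond[c]
            phi = (n_kv + b) / (n_k + b * V)[:, None]
            phi_tilde = np.zeros((Kt, V))
            if Kt:
                phi_tilde = state.support[:Kt] * (nt_kv[:Kt] + bt) / (
                    nt_k[:Kt] + bt * state.n_markers[:Kt])[:, None]
            pi = (nt_k[:Kt] + g1) / (n_k[:Kt] + nt_k[:Kt] + g1 + g2)
            acc += combine_phi(phi, np.vstack([phi_tilde, np.zeros((K - Kt, V))]),
                               pi)
        acc /= len(snapshots)
        acc /= acc.sum(axis=1, keepdims=True)
        out[c] = acc
    return out


def log2_fold_change(phi_a: np.ndarray, phi_b: np.ndarray,
                     pseudo: float = 1e-6) -> np.ndarray:
    """Per-gene ``log2((a + pseudo) / (b + pseudo))`` between two expression
    distributions (e.g. two conditions of one cell type)."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape:
        raise ValueError("distributions must have equal length")
    if np.any(phi_a < 0) or np.any(phi_b < 0):
        raise ValueError("negative entries in a distribution")
    return np.log2((phi_a + pseudo) / (phi_b + pseudo))


def fit_covariate(counts: SpotCounts, markers: MarkerSpec,
                  design: CovariateDesign,
                  config: ModelConfig | None = None,
                  mu: float = 0.0, sigma2: float = 1.0) -> CovariateResult:
    """Fit the covariate model.

    Identical to the base fit except that the per-spot concentration is
    ``alpha_dk = exp((lambda^T x_d)_k)`` with ``lambda`` resampled each
    sweep; with an intercept-only design this reduces to the base model with
    a shared (log-normal-prior) alpha.
    """
    if config is None:
        config = ModelConfig()
    if design.X.shape[0] != counts.n_spots:
        raise ValueError("design rows must align with spots")
    markers = markers.resolve(counts.gene_ids)
    M = design.X.shape[1]
    conditions = design.conditions
    per_repeat = []
    state = None
    for r in range(config.n_repeats):
        chain_seed = (int(config.seed) * 1000003 + 7919 * r) % _SEED_MOD
        state = initialize_state(counts, markers, config, chain_seed)
        rng = np.random.default_rng((chain_seed + 1) % _SEED_MOD)
        _sampler.seed_rng(chain_seed % _SEED_MOD)
        lam = np.full((M, state.n_types), mu, dtype=float)
        state.alpha_dk[:] = np.exp(design.X @ lam)
        snapshots: list[Snapshot] = []
        lam_acc = np.zeros_like(lam)
        for it in range(config.iterations):
            gibbs_sweep(state, config)
            sample_lambda(state, design.X, lam, mu, sigma2, rng)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                snap = Snapshot.of(state)
                if conditions:
                    snap.cond = _condition_tables(state, design.condition,
                                                  conditions)
                snapshots.append(snap)
                lam_acc += lam
        est = estimate_result(snapshots, state, config)
        est["lam"] = lam_acc / len(snapshots)
        if conditions:
            est["cond"] = condition_specific_expression(snapshots, state,
                                                        config)
        per_repeat.append(est)
    ref = per_repeat[0]
    Kt = markers.n_marked
    acc = {k: np.array(v, dtype=float) for k, v in ref.items()
           if k not in ("cond", "alpha")}
    cond_acc = {c: np.array(m) for c, m in ref.get("cond", {}).items()}
    for est in per_repeat[1:]:
        perm = _match_unmarked(ref["phi"], est["phi"], Kt)
        acc["theta"] += est["theta"][:, perm]
        acc["phi"] += est["phi"][perm]
        acc["phi_star"] += est["phi_star"][perm]
        acc["lam"] += est["lam"][:, perm]
        acc["pi"] += est["pi"]
        acc["phi_tilde"] += est["phi_tilde"]
        for c in cond_acc:
            cond_acc[c] += est["cond"][c][perm]
    n = config.n_repeats
    for k in acc:
        acc[k] /= n
    for k in ("theta", "phi", "phi_star"):
        acc[k] /= acc[k].sum(axis=1, keepdims=True)
    if Kt:
        acc["phi_tilde"] /= acc["phi_tilde"].sum(axis=1, keepdims=True)
    cond_out = {}
    for c in cond_acc:
        m = cond_acc[c] / n
        cond_out[c] = pd.DataFrame(m / m.sum(axis=1, keepdims=True),
                                   index=markers.cell_types,
                                   columns=counts.gene_ids)
    cts = markers.cell_types
    return CovariateResult(
        lam=pd.DataFrame(acc["lam"], index=design.names, columns=cts),
        theta=pd.DataFrame(acc["theta"], index=counts.spot_ids, columns=cts),
        phi=pd.DataFrame(acc["phi"], index=cts, columns=counts.gene_ids),
        phi_tilde=pd.DataFrame(acc["phi_tilde"], index=cts[:Kt],
                               columns=counts.gene_ids),
        pi=pd.Series(acc["pi"], index=cts[:Kt], name="pi"),
        phi_star=pd.DataFrame(acc["phi_star"], index=cts,
                              columns=counts.gene_ids),
        condition_phi_star=cond_out,
        prior={"mu": mu, "sigma2": sigma2},
        provenance={"config": config.to_dict(), "seed": config.seed,
                    "covariates": list(design.names)},
    )
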