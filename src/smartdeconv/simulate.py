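"""Synthetic data generation.

Two routes are provided. ``grid_bin`` builds pseudo-spots from annotated
single-cell-resolution ST data (e.g. MERFISH- or CosMx-style point clouds)
by cutting the tissue into contiguous squares and aggregating the cells in
each square, which yields spot counts together with ground-truth cell-type
proportions and profiles. ``generate_from_model`` draws data directly from
the topic model's own generative process, which is the right input for
parameter-recovery experiments. ``derive_markers`` reproduces the standard
one-vs-rest differential-expression route to marker lists (Wilcoxon
rank-sum, Benjamini-Hochberg, fold-change filter, specificity pruning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import MarkerSpec, ModelConfig, SpotCounts

logger = logging.getLogger("smartdeconv")

__all__ = ["SingleCellST", "SimulatedST", "grid_bin", "ground_truth_profiles",
           "derive_markers", "generate_from_model",
           "generate_subtype_scenario", "generate_covariate_scenario"]


@dataclass
class SingleCellST:
    """Point-located, type-annotated single cells with per-cell counts.

    ``counts`` is gene-by-cell (``V x C``); ``x``/``y`` are per-cell
    coordinates in platform units; ``cell_type`` labels every cell.
    """

    x: np.ndarray
    y: np.ndarray
    cell_type: np.ndarray
    counts: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.counts = np.asarray(self.counts)
        C = self.x.size
        if not (self.y.size == C == self.cell_type.size == self.counts.shape[1]):
            raise ValueError("per-cell fields must share one length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite coordinates")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.x.size

    @property
    def types(self) -> list[str]:
        seen: dict = {}
        for t in self.cell_type:
            seen.setdefault(t, None)
        return list(seen)


@dataclass
class SimulatedST:
    """Pseudo-spot dataset with ground truth attached."""

    counts: SpotCounts
    squares: pd.DataFrame          # per spot: x0, y0, side
    gt_theta: pd.DataFrame         # spot x cell type true proportions
    gt_profiles: pd.DataFrame      # gene x cell type mean expression
    n_cells: pd.Series


def grid_bin(cells: SingleCellST, side: float) -> SimulatedST:
    """Aggregate single cells into square pseudo-spots of width ``side``.

    The grid origin sits at the minimum x/y coordinate; square ``(i, j)``
    covers the half-open box ``[x0+i*side, x0+(i+1)*side) x [y0+j*side,
    y0+(j+1)*side)``. Squares extending past the maximum coordinate (they
    would overlap the image edge) are removed, as are squares holding fewer
    than two cells. Spot counts are the elementwise sums of member-cell
    counts; the true proportions are the member-cell type fractions.
    """
    if side <= 0:
        raise ValueError("side must be > 0")
    if cells.n_cells == 0:
        raise ValueError("no cells")
    x0, y0 = cells.x.min(), cells.y.min()
    xmax, ymax = cells.x.max(), cells.y.max()
    tol = 1e-9 * max(1.0, abs(xmax), abs(ymax))
    ix = np.floor((cells.x - x0) / side).astype(int)
    iy = np.floor((cells.y - y0) / side).astype(int)
    types = cells.types
    t_index = {t: i for i, t in enumerate(types)}
    t_codes = np.array([t_index[t] for t in cells.cell_type])
    keys: dict[tuple[int, int], list[int]] = {}
    for c, (i, j) in enumerate(zip(ix, iy)):
        keys.setdefault((int(i), int(j)), []).append(c)
    rows = []
    for (i, j) in sorted(keys):
        # edge rule: the square's far corner must not exceed the image extent
        if x0 + (i + 1) * side > xmax + tol or y0 + (j + 1) * side > ymax + tol:
            continue
        members = keys[(i, j)]
        if len(members) < 2:
            continue
        rows.append((i, j, members))
    if not rows:
        raise ValueError("no square survives the edge and >=2-cell filters")
    K = len(types)
    spot_ids, sq, th, nc, cols = [], [], [], [], []
    for i, j, members in rows:
        spot_ids.append(f"spot_{i}_{j}")
        sq.append((x0 + i * side, y0 + j * side, side))
        cols.append(cells.counts[:, members].sum(axis=1))
        frac = np.bincount(t_codes[members], minlength=K) / len(members)
        th.append(frac)
        nc.append(len(members))
    counts = SpotCounts(np.column_stack(cols).astype(np.int64),
                        list(cells.gene_ids), spot_ids,
                        coords=np.array([(a + side / 2, b + side / 2)
                                         for a, b, _ in sq]))
    return SimulatedST(
        counts=counts,
        squares=pd.DataFrame(sq, index=spot_ids, columns=["x0", "y0", "side"]),
        gt_theta=pd.DataFrame(np.array(th), index=spot_ids, columns=types),
        gt_profiles=ground_truth_profiles(cells),
        n_cells=pd.Series(nc, index=spot_ids, name="n_cells"),
    )


def ground_truth_profiles(cells: SingleCellST) -> pd.DataFrame:
    """Per-type mean expression: the arithmetic mean of the count vectors of
    all cells carrying that type label (gene x cell type)."""
    out = {}
    for t in cells.types:
        members = np.flatnonzero(cells.cell_type == t)
        if members.size == 0:  # pragma: no cover - types come from the data
            logger.warning("cell type %r has no cells; omitted", t)
            continue
        out[t] = cells.counts[:, members].mean(axis=1)
    return pd.DataFrame(out, index=list(cells.gene_ids))


def derive_markers(cells: SingleCellST, fdr: float = 0.05,
                   min_fc: float = 2.0, max_per_type: int = 10) -> MarkerSpec:
    """Derive marker genes by one-vs-rest differential expression.

    Per-cell expression is normalized to relative frequencies before a
    two-sided Wilcoxon rank-sum test per gene; p-values are
    Benjamini-Hochberg adjusted within each cell type. A gene is a candidate
    marker of a type if its adjusted p < ``fdr``, it is up-regulated in the
    type, and the fold change (type mean over rest mean, pseudocount 1e-9)
    exceeds ``min_fc``. Genes passing for more than one type are pruned as
    non-specific; survivors are ranked by fold change and truncated to
    ``max_per_type``. Types left with no markers keep an empty set (with a
    warning).
    """
    types = cells.types
    if len(types) < 2:
        raise ValueError("need >= 2 cell types for one-vs-rest testing")
    totals = cells.counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    norm = cells.counts / totals  # counts-per-total within each cell
    eps = 1e-9
    V = len(cells.gene_ids)
    passing: dict[str, list[tuple[float, int]]] = {}
    pass_count = np.zeros(V, dtype=int)
    for t in types:
        in_t = cells.cell_type == t
        a, b = norm[:, in_t], norm[:, ~in_t]
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        padj = multipletests(res.pvalue, method="fdr_bh")[1]
        fc = (a.mean(axis=1) + eps) / (b.mean(axis=1) + eps)
        hits = (padj < fdr) & (fc > min_fc)
        passing[t] = [(fc[v], v) for v in np.flatnonzero(hits)]
        pass_count[[v for _, v in passing[t]]] += 1
    markers: dict[str, list[str]] = {}
    for t in types:
        # specificity pruning: discard genes significant in multiple types
        keep = [(f, v) for f, v in passing[t] if pass_count[v] == 1]
        keep.sort(key=lambda fv: (-fv[0], fv[1]))
        markers[t] = [cells.gene_ids[v] for _, v in keep[:max_per_type]]
        if not markers[t]:
            logger.warning("no marker genes identified for type %r", t)
    return MarkerSpec(list(types), markers)


def generate_from_model(V: int, D: int, K: int, K_tilde: int,
                        markers_per_type: int, N_d, seed: int,
                        config: ModelConfig | None = None) -> dict:
    """Draw a dataset from the model's own generative process.

    Marker supports are disjoint random gene sets of size
    ``markers_per_type`` for each of the first ``K_tilde`` types. Per type,
    phi_k ~ Dirichlet(beta 1_V) and (for marked types) phi~_k ~
    Dirichlet(beta~ 1_L) on its support, pi_k ~ Beta(gamma1, gamma2); alpha
    follows its class-specific Gamma priors and theta_d ~ Dirichlet(alpha).
    Each spot then emits ``N_d`` molecules through z -> s -> w.

    Returns a dict with keys ``counts`` (SpotCounts), ``markers``
    (MarkerSpec), ``theta`` (D x K true proportions), ``phi_star`` (K x V
    true mixture frequencies), ``pi``, ``alpha``, ``phi``, ``phi_tilde``.
    """
    if config is None:
        config = ModelConfig()
    if min(V, D, K, markers_per_type) < 1 or K_tilde < 0 or K_tilde > K:
        raise ValueError("invalid sizes")
    if markers_per_type * K_tilde > V:
        raise ValueError("not enough genes for disjoint marker supports")
    rng = np.random.default_rng(seed)
    N_d = np.broadcast_to(np.asarray(N_d, dtype=int), (D,))
    gene_ids = [f"g{v:04d}" for v in range(V)]
    cell_types = [f"CT{k + 1}" for k in range(K)]
    perm = rng.permutation(V)
    supports = [perm[k * markers_per_type:(k + 1) * markers_per_type]
                for k in range(K_tilde)]
    phi = rng.dirichlet(np.full(V, config.beta), size=K)
    phi_tilde = np.zeros((K_tilde, V))
    for k, sup in enumerate(supports):
        phi_tilde[k, sup] = rng.dirichlet(
            np.full(markers_per_type, config.beta_tilde))
    pi = rng.beta(config.gamma1, config.gamma2, size=K_tilde)
    alpha = np.empty(K)
    alpha[:K_tilde] = rng.gamma(config.eta_tilde1, 1.0 / config.eta_tilde2,
                                size=K_tilde)
    alpha[K_tilde:] = rng.gamma(config.eta1, 1.0 / config.eta2,
                                size=K - K_tilde)
    alpha = np.maximum(alpha, 1e-3)
    theta = rng.dirichlet(alpha, size=D)
    mat = np.zeros((V, D), dtype=np.int64)
    for d in range(D):
        n_per_type = rng.multinomial(N_d[d], theta[d])
        for k in range(K):
            n = n_per_type[k]
            if n == 0:
                continue
            if k < K_tilde:
                n_marker = rng.binomial(n, pi[k])
                if n_marker:
                    mat[:, d] += rng.multinomial(n_marker, phi_tilde[k])
                n -= n_marker
            if n:
                mat[:, d] += rng.multinomial(n, phi[k])
    keep = mat.sum(axis=0) > 0  # a spot can only be empty if N_d == 0
    counts = SpotCounts(mat[:, keep], gene_ids,
                        [f"spot{d:04d}" for d in np.flatnonzero(keep)])
    markers = MarkerSpec(
        cell_types,
        {ct: [gene_ids[v] for v in supports[k]] if k < K_tilde else []
         for k, ct in enumerate(cell_types)},
    )
    phi_star = phi.copy()
    if K_tilde:
        phi_star[:K_tilde] = ((1 - pi)[:, None] * phi[:K_tilde]
                              + pi[:, None] * phi_tilde)
    return {
        "counts": counts, "markers": markers,
        "theta": pd.DataFrame(theta[keep],
                              index=counts.spot_ids, columns=cell_types),
        "phi_star": pd.DataFrame(phi_star, index=cell_types, columns=gene_ids),
        "pi": pd.Series(pi, index=cell_types[:K_tilde], name="pi"),
        "alpha": pd.Series(alpha, index=cell_types, name="alpha"),
        "phi": pd.DataFrame(phi, index=cell_types, columns=gene_ids),
        "phi_tilde": pd.DataFrame(phi_tilde, index=cell_types[:K_tilde],
                                  columns=gene_ids),
    }


def generate_subtype_scenario(seed: int, D: int = 150,
                              depth: int = 400) -> dict:
    """Synthetic major-type/subtype benchmark for two-stage deconvolution.

    Five true cell types are generated: two subtypes A1 and A2 of a major
    type A (sharing a strong lineage gene block, differing in moderate
    subtype blocks), majors B and C, and an unlisted residual type E that no
    marker list mentions (it is what the no-marker topic should absorb).
    A2 is rare, and both subtype-specific blocks are expressed even more
    strongly in B than in the subtypes themselves, so the subtype markers
    are non-specific at the whole-tissue level — the regime where fitting
    all subtypes in one pass struggles and a second, restricted
    deconvolution round with the companion type included helps.

    Returns a dict with ``counts``; the subtype-level true ``theta``
    (columns A1, A2, B, C, E); ``major_markers`` (A/B/C lineage-level
    lists); ``subtype_markers`` (stage-two lists: each subtype's specific
    block plus the re-used shared lineage block); ``subtype_markers_specific``
    (specific blocks only, the lists a one-pass subtype fit would be given);
    and ``major_of`` mapping subtypes to their major type.
    """
    rng = np.random.default_rng(seed)
    V = 70
    gene_ids = [f"g{v:04d}" for v in range(V)]
    blocks = {"lineage": range(0, 10), "sub1": range(10, 20),
              "sub2": range(20, 30), "bown": range(30, 40),
              "cmark": range(40, 50), "emark": range(50, 60),
              "bg": range(60, 70)}
    jitter = rng.uniform(0.5, 1.5, size=V)

    def profile(weights: dict) -> np.ndarray:
        w = np.full(V, 0.1)
        for name, scale in weights.items():
            w[list(blocks[name])] = scale
        w = w * jitter
        return w / w.sum()

    phi = np.vstack([
        profile({"lineage": 4.0, "sub1": 1.5, "bg": 1.0}),   # A1
        profile({"lineage": 4.0, "sub2": 1.5, "bg": 1.0}),   # A2 (rare)
        profile({"sub1": 3.0, "sub2": 3.0, "bown": 4.0, "bg": 1.0}),  # B
        profile({"cmark": 4.0, "bg": 1.0}),                  # C
        profile({"emark": 4.0, "bg": 1.0}),                  # E (unlisted)
    ])
    types = ["A1", "A2", "B", "C", "E"]
    theta = rng.dirichlet(np.array([1.0, 0.3, 1.0, 1.0, 0.6]), size=D)
    mat = np.zeros((V, D), dtype=np.int64)
    for d in range(D):
        n_per = rng.multinomial(depth, theta[d])
        for k in range(len(types)):
            if n_per[k]:
                mat[:, d] += rng.multinomial(n_per[k], phi[k])
    counts = SpotCounts(mat, gene_ids, [f"spot{d:03d}" for d in range(D)])
    g = lambda block: [gene_ids[v] for v in blocks[block]]
    major_markers = MarkerSpec(["A", "B", "C"], {
        "A": g("lineage"), "B": g("bown"), "C": g("cmark")})
    subtype_markers = MarkerSpec(["A1", "A2"], {
        "A1": g("sub1") + g("lineage"), "A2": g("sub2") + g("lineage")})
    subtype_markers_specific = MarkerSpec(["A1", "A2"], {
        "A1": g("sub1"), "A2": g("sub2")})
    return {
        "counts": counts,
        "theta": pd.DataFrame(theta, index=counts.spot_ids, columns=types),
        "major_markers": major_markers,
        "subtype_markers": subtype_markers,
        "subtype_markers_specific": subtype_markers_specific,
        "major_of": {"A1": "A", "A2": "A", "B": "B", "C": "C"},
    }


def generate_covariate_scenario(seed: int, D: int = 120, V: int = 45,
                                K: int = 3, depth: int = 300,
                                effect: float = float(np.log(2.0))) -> dict:
    """Synthetic binary-covariate benchmark for the covariate model.

    Spots split into two equal groups; the prior odds of cell type 1 are
    multiplied by ``exp(effect)`` (default: doubled) in group 1 through the
    log-linear concentration model, and per-spot proportions are drawn from
    the resulting Dirichlet. Each marked type over-expresses a 5-gene block
    used as its marker list.

    Returns ``counts``, ``markers``, the ``design`` (intercept + group
    indicator), the true ``theta`` and the true coefficient matrix ``lam``.
    """
    from .covariate import CovariateDesign

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{v}" for v in range(V)]
    phi = rng.dirichlet(np.full(V, 0.3), size=K)
    sup = [list(range(k * 5, k * 5 + 5)) for k in range(K)]
    for k in range(K):
        phi[k, sup[k]] += 0.06
    phi /= phi.sum(axis=1, keepdims=True)
    x = np.repeat([0, 1], D - D // 2)[:D]
    lam_true = np.zeros((2, K))
    lam_true[1, 0] = effect
    X = np.column_stack([np.ones(D), x])
    alpha = np.exp(X @ lam_true)
    theta = np.vstack([rng.dirichlet(a) for a in alpha])
    mat = np.zeros((V, D), dtype=np.int64)
    for d in range(D):
        n_per = rng.multinomial(depth, theta[d])
        for k in range(K):
            if n_per[k]:
                mat[:, d] += rng.multinomial(n_per[k], phi[k])
    counts = SpotCounts(mat, gene_ids, [f"s{d:03d}" for d in range(D)])
    markers = MarkerSpec(
        [f"T{k + 1}" for k in range(K)],
        {f"T{k + 1}": [gene_ids[v] for v in sup[k]] for k in range(K)})
    design = CovariateDesign(X, ["intercept", "group"],
                             condition=np.where(x == 1, "grp1", "grp0"))
    return {"counts": counts, "markers": markers, "design": design,
            "theta": pd.DataFrame(theta, index=counts.spot_ids,
                                  columns=markers.cell_types),
            "lam": pd.DataFrame(lam_true, index=["intercept", "group"],
                                columns=markers.cell_types)}
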