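"""Evaluation metrics for deconvolution output.

Covers the standard benchmarking quantities: global Pearson correlation and
RMSE between predicted and true proportion matrices, per-spot and per-type
breakdowns, a Diebold-Mariano comparison of paired per-spot loss series,
and Fisher-exact enrichment of each type's top-ranked genes in its marker
list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import MarkerSpec

logger = logging.getLogger("smartdeconv")

__all__ = ["MetricsReport", "proportion_metrics", "diebold_mariano",
           "top_gene_enrichment"]


@dataclass
class MetricsReport:
    pcc_all: float
    rmse_all: float
    per_spot_rmse: pd.Series
    per_type_pcc: pd.Series
    per_type_rmse: pd.Series

    def to_dict(self) -> dict:
        return {
            "pcc_all": self.pcc_all,
            "rmse_all": self.rmse_all,
            "mean_per_spot_rmse": float(self.per_spot_rmse.mean()),
            "per_type_pcc": self.per_type_pcc.to_dict(),
            "per_type_rmse": self.per_type_rmse.to_dict(),
        }


def proportion_metrics(pred: pd.DataFrame,
                       truth: pd.DataFrame) -> MetricsReport:
    """Compare predicted and true spot-by-type proportion matrices.

    Cell types are aligned by column name (order-free); spots by row order.
    ``pcc_all``/``rmse_all`` are computed on the flattened D*K vectors;
    ``per_spot_rmse`` averages squared errors across types within each spot;
    per-type metrics work on each type's D-vector. A type whose vectors have
    zero variance gets a NaN correlation (logged).
    """
    missing = [c for c in pred.columns if c not in truth.columns]
    extra = [c for c in truth.columns if c not in pred.columns]
    if missing or extra:
        raise ValueError(f"cell-type names do not match; pred-only: "
                         f"{missing}, truth-only: {extra}")
    if pred.shape[0] != truth.shape[0]:
        raise ValueError("spot counts differ between pred and truth")
    truth = truth[pred.columns]
    P, T = pred.to_numpy(dtype=float), truth.to_numpy(dtype=float)
    err = P - T
    rmse_all = float(np.sqrt(np.mean(err ** 2)))
    pcc_all = float(stats.pearsonr(P.ravel(), T.ravel())[0])
    per_spot = pd.Series(np.sqrt(np.mean(err ** 2, axis=1)),
                         index=pred.index, name="per_spot_rmse")
    pcc_t, rmse_t = [], []
    n_undef = 0
    for j in range(P.shape[1]):
        rmse_t.append(float(np.sqrt(np.mean(err[:, j] ** 2))))
        if np.std(P[:, j]) == 0 or np.std(T[:, j]) == 0:
            pcc_t.append(np.nan)
            n_undef += 1
        else:
            pcc_t.append(float(stats.pearsonr(P[:, j], T[:, j])[0]))
    if n_undef:
        logger.warning("%d cell type(s) have zero-variance proportions; "
                       "their PCC is undefined (NaN)", n_undef)
    return MetricsReport(
        pcc_all=pcc_all, rmse_all=rmse_all, per_spot_rmse=per_spot,
        per_type_pcc=pd.Series(pcc_t, index=pred.columns, name="pcc"),
        per_type_rmse=pd.Series(rmse_t, index=pred.columns, name="rmse"),
    )


def diebold_mariano(loss_a: np.ndarray,
                    loss_b: np.ndarray) -> tuple[float, float]:
    """Diebold-Mariano comparison of two paired loss series.

    Spots carry no ordering, so the lag-0 variance is used: with
    ``d_i = loss_a_i - loss_b_i``, the statistic is ``mean(d) /
    sqrt(var(d) / D)`` and the two-sided p-value comes from the standard
    normal. A negative statistic favors method A (smaller losses).
    """
    a = np.asarray(loss_a, dtype=float)
    b = np.asarray(loss_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("loss series must be 1-D with equal length")
    if a.size < 10:
        raise ValueError("need at least 10 paired losses")
    d = a - b
    v = float(np.var(d, ddof=1))
    if v == 0:
        if np.mean(d) == 0:
            return 0.0, 1.0
        raise ValueError("degenerate loss differential: constant non-zero")
    dm = float(np.mean(d) / np.sqrt(v / d.size))
    p = float(2 * stats.norm.sf(abs(dm)))
    return dm, p


def top_gene_enrichment(phi_star: pd.DataFrame, markers: MarkerSpec,
                        n_top: int = 10) -> pd.DataFrame:
    """Fisher-exact enrichment of each marked type's top-``n_top`` genes
    (by phi*) in its own marker list.

    Ties in the ranking are broken by input gene order. Returns a frame
    indexed by cell type with columns ``overlap``, ``n_markers``, ``p``
    (one-sided, enrichment direction). No-marker types are skipped.
    """
    V = phi_star.shape[1]
    if not 1 <= n_top <= V:
        raise ValueError("n_top must be in [1, V]")
    rows = {}
    for ct in markers.cell_types:
        mset = set(markers.markers[ct])
        if not mset or ct not in phi_star.index:
            continue
        vals = phi_star.loc[ct].to_numpy()
        # stable sort on negated values keeps gene order among ties
        top = np.argsort(-vals, kind="stable")[:n_top]
        genes = phi_star.columns.to_numpy()
        is_marker = np.array([g in mset for g in genes])
        in_top = np.zeros(V, dtype=bool)
        in_top[top] = True
        a = int(np.sum(in_top & is_marker))
        table = [[a, int(np.sum(in_top & ~is_marker))],
                 [int(np.sum(~in_top & is_marker)),
                  int(np.sum(~in_top & ~is_marker))]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows[ct] = {"overlap": a, "n_markers": int(is_marker.sum()),
                    "p": float(p)}
    return pd.DataFrame.from_dict(rows, orient="index")
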