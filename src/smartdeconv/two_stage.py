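"""Two-stage subtype deconvolution.

Stage one deconvolves the spots into major cell types. The molecule counts
attributable to a target major type — plus the transcriptomically most
similar companion type, to recapture counts misallocated between the two —
are then reconstructed per spot as ``N_d * theta_dk * phi*_k`` and handed to
a second deconvolution that splits them into subtypes. Separating the
stages lets subtype markers that are shared between major types (and were
therefore useless or discarded in stage one) discriminate the subtypes in
stage two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import fit
from .data import DeconvolutionResult, MarkerSpec, ModelConfig, SpotCounts

logger = logging.getLogger("smartdeconv")

__all__ = ["TwoStageConfig", "ExtractedCounts", "TwoStageResult",
           "cell_type_library_size", "extract_cell_type_counts",
           "most_similar_cell_type", "two_stage_fit"]

UNKNOWN = "unknown"


@dataclass
class TwoStageConfig:
    target_type: str
    subtype_markers: MarkerSpec
    companion: str = "auto"
    similarity_metric: str = "pearson"
    include_unknown: bool = True
    extraction: str = "responsibility"

    def __post_init__(self) -> None:
        if self.similarity_metric not in ("pearson", "euclidean"):
            raise ValueError("similarity_metric must be 'pearson' or 'euclidean'")
        if self.companion != "auto" and self.companion == self.target_type:
            raise ValueError("companion must differ from the target type")
        if self.extraction not in ("responsibility", "expected"):
            raise ValueError("extraction must be 'responsibility' or 'expected'")


@dataclass
class ExtractedCounts:
    """Rounded expected per-spot counts attributed to a set of cell types."""

    matrix: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    types_extracted: list[str] = field(default_factory=list)

    def to_spot_counts(self) -> tuple[SpotCounts, np.ndarray]:
        """Drop spots whose extracted library size rounds to zero; returns
        the validated counts and the indices of the retained spots."""
        keep = np.flatnonzero(self.matrix.sum(axis=0) > 0)
        if keep.size == 0:
            raise ValueError("extraction is empty for every spot")
        sc = SpotCounts(self.matrix[:, keep], self.gene_ids,
                        [self.spot_ids[i] for i in keep])
        return sc, keep


@dataclass
class TwoStageResult:
    stage_one: DeconvolutionResult
    stage_two: DeconvolutionResult
    extracted: ExtractedCounts
    target: str
    companion: str
    dropped_spots: list[str]

    def subtype_theta_full(self) -> pd.DataFrame:
        """Stage-two proportions re-expressed on the original-spot scale:
        ``(theta1_target + theta1_companion) * theta2``, so each spot's row
        sums to the stage-one target + companion share. Spots dropped from
        stage two get NaN rows."""
        share = (self.stage_one.theta[self.target]
                 + self.stage_one.theta[self.companion])
        scaled = self.stage_two.theta.mul(
            share.reindex(self.stage_two.theta.index), axis=0)
        return scaled.reindex(self.stage_one.theta.index)


def cell_type_library_size(result: DeconvolutionResult, counts: SpotCounts,
                           cell_type: str) -> np.ndarray:
    """Per-spot library size attributable to one type: ``N_dk = N_d *
    theta_dk`` (real-valued; ``N_d`` is the raw library size)."""
    if cell_type not in result.theta.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    return counts.library_size * result.theta[cell_type].to_numpy()


def extract_cell_type_counts(result: DeconvolutionResult, counts: SpotCounts,
                             types: list[str],
                             method: str = "expected") -> ExtractedCounts:
    """Per-spot gene counts attributed to the given cell types, summed over
    the types and rounded half-up to integers.

    Two attribution rules are offered. ``"expected"`` reconstructs the
    counts a pure type-``t`` compartment of the fitted size would emit:
    ``c_dv = round(sum_t N_dt * phi*_tv)``. ``"responsibility"`` splits the
    *observed* counts by posterior responsibility, ``c_dv = round(x_dv *
    sum_t theta_dt phi*_tv / sum_j theta_dj phi*_jv)``; its expectation
    under the model equals the expected rule, but it keeps the spot-specific
    composition of the observed data, which is what a second-stage
    deconvolution needs to resolve substructure within the target type.
    """
    if not types:
        raise ValueError("no cell types to extract")
    V, D = counts.n_genes, counts.n_spots
    if method == "expected":
        out = np.zeros((V, D))
        for t in types:
            n_dt = cell_type_library_size(result, counts, t)
            out += result.phi_star.loc[t].to_numpy()[:, None] * n_dt[None, :]
    elif method == "responsibility":
        theta = result.theta.to_numpy()          # D x K
        phi = result.phi_star.to_numpy()         # K x V
        mix = (theta @ phi).T                    # V x D: per-spot gene rates
        sel = [result.cell_types.index(t) for t in types]
        part = (theta[:, sel] @ phi[sel]).T
        with np.errstate(invalid="ignore", divide="ignore"):
            resp = np.where(mix > 0, part / mix, 0.0)
        out = counts.matrix * resp
    else:
        raise ValueError("method must be 'expected' or 'responsibility'")
    rounded = np.floor(out + 0.5).astype(np.int64)
    return ExtractedCounts(rounded, list(counts.gene_ids),
                           list(counts.spot_ids), list(types))


def most_similar_cell_type(result: DeconvolutionResult, cell_type: str,
                           metric: str = "pearson") -> str:
    """The fitted type whose expression profile phi* is closest to
    ``cell_type``'s, by Pearson correlation (argmax) or Euclidean distance
    (argmin). No-marker types are excluded as candidates; ties go to the
    earlier type in the declared order."""
    if cell_type not in result.theta.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    marked = list(result.pi.index)
    candidates = [t for t in marked if t != cell_type]
    if not candidates:
        raise ValueError("need at least two marker-bearing cell types")
    ref = result.phi_star.loc[cell_type].to_numpy()
    best, best_score = None, None
    for t in candidates:
        v = result.phi_star.loc[t].to_numpy()
        if metric == "pearson":
            score = float(np.corrcoef(ref, v)[0, 1])
        else:
            score = -float(np.linalg.norm(ref - v))
        if best_score is None or score > best_score + 1e-15:
            best, best_score = t, score
    return best


def _with_unknown(markers: MarkerSpec, tag: str) -> MarkerSpec:
    name = f"{UNKNOWN}_{tag}"
    if any(not markers.markers[t] for t in markers.cell_types):
        return markers  # already carries a no-marker type
    return MarkerSpec(markers.cell_types + [name],
                      {**markers.markers, name: []})


def two_stage_fit(counts: SpotCounts, major_markers: MarkerSpec,
                  ts_config: TwoStageConfig,
                  model_config: ModelConfig | None = None) -> TwoStageResult:
    """Run the full two-stage procedure.

    Stage one fits the major types (plus a no-marker type when
    ``include_unknown``). The companion is resolved (``"auto"`` picks the
    most similar marked type), the target + companion counts are extracted,
    and stage two refits them with the subtype markers plus the companion
    carrying its stage-one markers (plus a no-marker type). Spots whose
    extracted counts round to zero are dropped from stage two and listed in
    ``dropped_spots``.
    """
    if model_config is None:
        model_config = ModelConfig()
    if ts_config.target_type not in major_markers.cell_types:
        raise ValueError(f"target type {ts_config.target_type!r} not in "
                         "stage-one cell types")
    stage1_markers = (_with_unknown(major_markers, "major")
                      if ts_config.include_unknown else major_markers)
    stage_one = fit(counts, stage1_markers, model_config)
    if ts_config.companion == "auto":
        companion = most_similar_cell_type(stage_one, ts_config.target_type,
                                           ts_config.similarity_metric)
    else:
        if ts_config.companion not in stage_one.cell_types:
            raise ValueError(f"companion {ts_config.companion!r} not fitted "
                             "in stage one")
        companion = ts_config.companion
    extracted = extract_cell_type_counts(
        stage_one, counts, [ts_config.target_type, companion],
        method=ts_config.extraction)
    sub_counts, keep = extracted.to_spot_counts()
    dropped = [s for i, s in enumerate(extracted.spot_ids) if i not in set(keep)]
    if dropped:
        logger.warning("%d spot(s) dropped from stage two (zero extracted "
                       "counts)", len(dropped))
    sub_types = list(ts_config.subtype_markers.cell_types)
    sub_markers = {t: list(ts_config.subtype_markers.markers[t])
                   for t in sub_types}
    if companion not in sub_markers:
        sub_types.append(companion)
        sub_markers[companion] = list(stage1_markers.markers.get(companion, []))
    stage2_spec = MarkerSpec(sub_types, sub_markers)
    if ts_config.include_unknown:
        stage2_spec = _with_unknown(stage2_spec, "sub")
    stage_two = fit(sub_counts, stage2_spec, model_config)
    return TwoStageResult(stage_one=stage_one, stage_two=stage_two,
                          extracted=extracted, target=ts_config.target_type,
                          companion=companion, dropped_spots=dropped)
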