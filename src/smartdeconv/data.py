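"""Core data containers for spot-level ST deconvolution.

The model treats each capture spot as a bag of mRNA molecules: a spot is a
"document", a gene symbol is a "word", and a cell type is a "topic" whose
identity is anchored by a short list of marker genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("smartdeconv")

__all__ = ["SpotCounts", "MarkerSpec", "ModelConfig", "DeconvolutionResult"]


@dataclass
class SpotCounts:
    """Gene-by-spot matrix of non-negative integer molecule counts.

    Parameters
    ----------
    matrix
        ``(V, D)`` array of counts; genes as rows, spots as columns.
        Values must be non-negative integers (normalized expression must be
        rounded to integers before construction).
    gene_ids
        ``V`` unique gene symbols.
    spot_ids
        ``D`` unique spot identifiers.
    coords
        Optional ``(D, 2)`` x/y spot coordinates in platform units.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("counts matrix must be 2-D (genes x spots)")
        if np.any(self.matrix < 0):
            raise ValueError("counts matrix contains negative values")
        if not np.issubdtype(self.matrix.dtype, np.integer):
            if not np.allclose(self.matrix, np.round(self.matrix)):
                raise ValueError(
                    "counts matrix must be integral; round normalized "
                    "expression to integers before constructing SpotCounts"
                )
            self.matrix = np.round(self.matrix).astype(np.int64)
        else:
            self.matrix = self.matrix.astype(np.int64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        if len(self.gene_ids) != self.matrix.shape[0]:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.spot_ids) != self.matrix.shape[1]:
            raise ValueError("spot_ids length does not match matrix columns")
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene identifiers: {sorted(dup_g)[:10]}")
        dup_s = _duplicates(self.spot_ids)
        if dup_s:
            raise ValueError(f"duplicate spot identifiers: {sorted(dup_s)[:10]}")
        empty = np.flatnonzero(self.library_size == 0)
        if empty.size:
            names = [self.spot_ids[i] for i in empty[:10]]
            raise ValueError(f"spots with zero total counts: {names}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n_spots, 2):
                raise ValueError("coords must have shape (n_spots, 2)")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[1]

    @property
    def library_size(self) -> np.ndarray:
        """Per-spot total molecule count ``N_d`` (length ``D``)."""
        return self.matrix.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.spot_ids)

    def subset_spots(self, keep: np.ndarray) -> "SpotCounts":
        keep = np.asarray(keep)
        return SpotCounts(
            self.matrix[:, keep],
            self.gene_ids,
            [self.spot_ids[i] for i in keep],
            None if self.coords is None else self.coords[keep],
        )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


@dataclass
class MarkerSpec:
    """Ordered cell types with per-type marker gene sets.

    Types carrying at least one marker come first; the remaining "no-marker"
    types are fitted without keyword guidance and absorb signal the marked
    types cannot explain.  ``markers`` maps every cell-type name to a list of
    gene symbols (possibly empty).  Marker sets may overlap between types.
    """

    cell_types: list[str]
    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.cell_types = [str(c) for c in self.cell_types]
        if not self.cell_types:
            raise ValueError("at least one cell type is required")
        if _duplicates(self.cell_types):
            raise ValueError("duplicate cell-type names")
        unknown = set(self.markers) - set(self.cell_types)
        if unknown:
            raise ValueError(f"markers given for undeclared cell types: {unknown}")
        self.markers = {c: list(dict.fromkeys(self.markers.get(c, []))) for c in self.cell_types}
        marked = [c for c in self.cell_types if self.markers[c]]
        unmarked = [c for c in self.cell_types if not self.markers[c]]
        if self.cell_types != marked + unmarked:
            logger.warning(
                "reordering cell types so that marker-bearing types come first"
            )
            self.cell_types = marked + unmarked

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    @property
    def n_marked(self) -> int:
        """Number of types with a non-empty marker set (they lead the order)."""
        return sum(1 for c in self.cell_types if self.markers[c])

    def marker_counts(self) -> list[int]:
        return [len(self.markers[c]) for c in self.cell_types]

    def resolve(self, gene_ids: list[str]) -> "MarkerSpec":
        """Match marker symbols against ``gene_ids`` (case-insensitive).

        Unmatched symbols are dropped with a warning; a marker-bearing type
        losing all of its markers is an error because its identity would be
        lost.  Matched symbols are replaced by the data's spelling.
        """
        lookup = {g.lower(): g for g in gene_ids}
        resolved: dict[str, list[str]] = {}
        for ct in self.cell_types:
            hits, misses = [], []
            for g in self.markers[ct]:
                m = lookup.get(g.lower())
                (hits if m is not None else misses).append(m if m is not None else g)
            if misses:
                logger.warning(
                    "cell type %r: %d marker(s) not found in data: %s",
                    ct, len(misses), misses[:10],
                )
            if self.markers[ct] and not hits:
                raise ValueError(
                    f"cell type {ct!r}: none of its markers match the data"
                )
            resolved[ct] = hits
        return MarkerSpec(list(self.cell_types), resolved)

    def support_matrix(self, gene_ids: list[str]) -> np.ndarray:
        """Boolean ``(K, V)`` matrix: entry ``(k, v)`` true iff gene ``v`` is a
        marker of type ``k``."""
        idx = {g: i for i, g in enumerate(gene_ids)}
        out = np.zeros((self.n_types, len(gene_ids)), dtype=bool)
        for k, ct in enumerate(self.cell_types):
            for g in self.markers[ct]:
                if g in idx:
                    out[k, idx[g]] = True
        return out


@dataclass
class ModelConfig:
    """Hyperparameters and sampler settings.

    ``beta`` and ``beta_tilde`` are the symmetric Dirichlet concentrations of
    the standard and marker-restricted gene distributions; ``beta_tilde >
    beta`` is required so that marker genes receive a higher prior mean than
    non-marker genes within their cell type.  ``gamma1``/``gamma2`` form the
    Beta prior on the per-type probability pi_k of drawing a molecule from
    the marker-restricted distribution.  The Gamma(shape, rate) priors on the
    Dirichlet concentration alpha_k differ between marked types
    (``eta_tilde1``, ``eta_tilde2``; smaller prior mean, so spots lean on the
    marked types) and no-marker types (``eta1``, ``eta2``).
    """

    beta: float = 0.01
    beta_tilde: float = 0.1
    gamma1: float = 1.0
    gamma2: float = 1.0
    eta_tilde1: float = 1.0
    eta_tilde2: float = 2.0
    eta1: float = 2.0
    eta2: float = 1.0
    iterations: int = 1500
    burn_in: int = 750
    thin: int = 5
    n_repeats: int = 1
    use_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta", "beta_tilde", "gamma1", "gamma2",
                     "eta_tilde1", "eta_tilde2", "eta1", "eta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.beta_tilde <= self.beta:
            raise ValueError("beta_tilde must exceed beta (marker genes need a "
                             "higher prior mean than non-marker genes)")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("require 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "beta_tilde": self.beta_tilde,
            "gamma1": self.gamma1, "gamma2": self.gamma2,
            "eta_tilde1": self.eta_tilde1, "eta_tilde2": self.eta_tilde2,
            "eta1": self.eta1, "eta2": self.eta2,
            "iterations": self.iterations, "burn_in": self.burn_in,
            "thin": self.thin, "n_repeats": self.n_repeats,
            "use_weighting": self.use_weighting, "seed": self.seed,
        }


@dataclass
class DeconvolutionResult:
    """Posterior-mean estimates from one deconvolution run.

    ``theta`` is the spot-by-cell-type proportion matrix (rows sum to 1).
    ``phi`` holds the standard per-type gene frequencies, ``phi_tilde`` the
    marker-restricted frequencies (zero off the marker support), ``pi`` the
    per-type mixing probability, and ``phi_star`` the reported cell
    type-specific expression ``(1 - pi) * phi + pi * phi_tilde`` (equal to
    ``phi`` for no-marker types).
    """

    theta: pd.DataFrame
    phi: pd.DataFrame
    phi_tilde: pd.DataFrame
    pi: pd.Series
    phi_star: pd.DataFrame
    alpha: pd.Series
    provenance: dict = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.theta.columns)

    @property
    def n_marked(self) -> int:
        return len(self.pi)

    def __post_init__(self) -> None:
        for name, df in (("theta", self.theta), ("phi", self.phi),
                         ("phi_star", self.phi_star)):
            sums = df.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError(f"rows of {name} must sum to 1")
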