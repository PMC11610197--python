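"""Readers and writers for counts, marker lists, designs and results."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .covariate import CovariateDesign
from .data import DeconvolutionResult, MarkerSpec, ModelConfig, SpotCounts

logger = logging.getLogger("smartdeconv")

__all__ = ["read_counts", "write_counts_mtx", "read_markers", "write_markers",
           "read_covariates", "write_result", "RunConfig"]


def read_counts(path: str | Path, fmt: str = "auto") -> SpotCounts:
    """Load a gene-by-spot count matrix.

    Accepts a Matrix Market file with ``genes.tsv``/``features.tsv`` and
    ``barcodes.tsv`` sidecars in the same directory (10X layout, genes as
    rows), a directory containing those three files, or a dense CSV/TSV
    with gene symbols as row names and spot ids as the header. Non-integer
    values (normalized expression) are rounded half-up with a logged count;
    negative values are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        if path.is_dir() or path.suffix == ".mtx":
            fmt = "mtx"
        else:
            fmt = "csv"
    if fmt == "mtx":
        mtx_path = path if path.suffix == ".mtx" else _find_one(path, "*.mtx")
        folder = mtx_path.parent
        genes = _read_sidecar(folder, ("genes.tsv", "features.tsv"))
        barcodes = _read_sidecar(folder, ("barcodes.tsv",))
        mat = spio.mmread(mtx_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, index_col=0, sep=sep)
        genes = [str(g) for g in df.index]
        barcodes = [str(c) for c in df.columns]
        mat = df.to_numpy()
    if np.any(mat < 0):
        raise ValueError("negative values in counts input")
    if not np.issubdtype(mat.dtype, np.integer):
        rounded = np.floor(mat + 0.5)
        n_changed = int(np.sum(rounded != mat))
        if n_changed:
            logger.info("rounded %d non-integer entries half-up", n_changed)
        mat = rounded.astype(np.int64)
    if mat.size == 0:
        raise ValueError("empty counts matrix")
    return SpotCounts(mat, genes, barcodes)


def _find_one(folder: Path, pattern: str) -> Path:
    hits = sorted(folder.glob(pattern))
    if len(hits) != 1:
        raise FileNotFoundError(f"expected exactly one {pattern} in {folder}")
    return hits[0]


def _read_sidecar(folder: Path, names: tuple[str, ...]) -> list[str]:
    for name in names:
        p = folder / name
        if p.exists():
            col = pd.read_csv(p, sep="\t", header=None)[0]
            return [str(x) for x in col]
    raise FileNotFoundError(f"none of {names} found in {folder}")


def write_counts_mtx(counts: SpotCounts, outdir: str | Path) -> None:
    """Write counts in 10X layout: matrix.mtx + genes.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(counts.matrix))
    (outdir / "genes.tsv").write_text("\n".join(counts.gene_ids) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(counts.spot_ids) + "\n")


def read_markers(path: str | Path, unknown_types: int = 0) -> MarkerSpec:
    """Load a marker specification.

    JSON: ``{"CellType": ["gene1", ...], "Other": []}`` (an empty list
    declares a no-marker type). CSV: two columns ``cell_type,gene``.
    Declared order is preserved (marker-bearing types first).
    ``unknown_types`` appends that many extra no-marker types.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty marker file: {path}")
    if path.suffix == ".json":
        raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ValueError("marker JSON must map cell types to gene lists")
        types = list(raw)
        markers = {str(k): [str(g) for g in v] for k, v in raw.items()}
    else:
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("marker CSV needs cell_type and gene columns")
        ct_col, g_col = df.columns[:2]
        types = list(dict.fromkeys(df[ct_col].astype(str)))
        markers = {t: list(df.loc[df[ct_col].astype(str) == t, g_col]
                           .astype(str)) for t in types}
    for i in range(unknown_types):
        name = f"unknown_{i + 1}"
        types.append(name)
        markers[name] = []
    return MarkerSpec(types, markers)


def write_markers(markers: MarkerSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(markers.markers, indent=1) + "\n")


def read_covariates(path: str | Path, spot_ids: list[str],
                    condition_col: str | None = None) -> CovariateDesign:
    """Load a spot-by-covariate CSV (first column = spot id), align rows to
    ``spot_ids``, and prepend an intercept column of ones."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in spot_ids if s not in df.index]
    if missing:
        raise ValueError(f"covariate rows missing for spots: {missing[:10]}")
    df = df.loc[spot_ids]
    condition = None
    if condition_col is not None:
        if condition_col not in df.columns:
            raise ValueError(f"condition column {condition_col!r} not found")
        condition = df[condition_col].to_numpy(dtype=object)
        df = df.drop(columns=[condition_col])
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float)
                                              for c in df.columns])
    return CovariateDesign(X, ["intercept"] + list(df.columns), condition)


def write_result(result: DeconvolutionResult, outdir: str | Path) -> None:
    """Emit theta.csv (spots x types), phi_star.csv (genes x types), pi.csv,
    alpha.csv and a metadata JSON with config, seed and library versions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.theta.to_csv(outdir / "theta.csv")
    result.phi_star.T.to_csv(outdir / "phi_star.csv")
    result.pi.to_csv(outdir / "pi.csv")
    result.alpha.to_csv(outdir / "alpha.csv")
    import scipy
    meta = {
        "provenance": result.provenance,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "scipy": scipy.__version__},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=1) + "\n")


_RUNCONFIG_KEYS = {"counts", "markers", "covariates", "condition_col",
                   "outdir", "unknown_types", "model"}


@dataclass
class RunConfig:
    """File-backed run configuration mirroring the CLI flags."""

    counts: str | None = None
    markers: str | None = None
    covariates: str | None = None
    condition_col: str | None = None
    outdir: str = "."
    unknown_types: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        model_raw = raw.pop("model", {}) or {}
        known_model = set(ModelConfig().to_dict())
        bad = set(model_raw) - known_model
        if bad:
            raise ValueError(f"unknown model config key(s): {sorted(bad)}")
        return cls(model=ModelConfig(**model_raw), **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["model"] = self.model.to_dict()
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
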