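"""Readers and writers for the on-disk formats.

Count matrices travel as a Cell Ranger-style Matrix Market triplet
(``matrix.mtx`` genes x cells, with ``genes.tsv`` and ``barcodes.tsv``
companions) or as a dense CSV/TSV with gene rows and a header of cell ids.
Cell metadata and doublet scores are TSVs with a header.  Images are 8- or
16-bit grayscale PNG/TIFF; ROIs are label images (0 outside, 1-4 the laminae
in SuG, Op, InG/InWh, DpG order, 5 background) or JSON polygon files
rasterized with even-odd fill.  All text readers are gzip-transparent, and
every table written carries ``#`` header lines with the tool version and the
config hash.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from . import __version__
from .config import RunConfig
from .expression import make_expression_matrix, compute_qc_metrics
from .ish import LAYERS, ISHImage, ROISet

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "attach_cell_metadata",
    "read_doublet_scores",
    "read_image",
    "write_image",
    "read_roi_labels",
    "write_roi_labels",
    "read_roi_polygons",
    "rasterize_polygon",
    "write_table",
    "read_table",
    "write_results",
]


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find(base: Path, names: Sequence[str]) -> Path:
    for n in names:
        for cand in (base / n, base / (n + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {list(names)} found under {base}")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> AnnData:
    """Read a count matrix from a triplet directory or a dense CSV/TSV.

    A directory (or a path to a ``.mtx``/``.mtx.gz`` file) is read as the
    triplet layout; the matrix on disk is genes x cells and label files must
    match its dimensions.  A ``.csv``/``.tsv`` file is read dense with genes
    as rows.  QC metrics are computed on load.
    """
    path = Path(path)
    if path.is_dir() or path.suffix in {".mtx"} or path.name.endswith(".mtx.gz"):
        base = path if path.is_dir() else path.parent
        mtx_path = path if not path.is_dir() else _find(base, ["matrix.mtx"])
        try:
            mat = scipy.io.mmread(str(mtx_path))
        except Exception as e:  # noqa: BLE001 - rewrap with file context
            raise ValueError(f"malformed Matrix Market file {mtx_path}: {e}") from e
        mat = sp.csr_matrix(mat)
        genes_path = _find(base, ["genes.tsv", "features.tsv"])
        cells_path = _find(base, ["barcodes.tsv"])
        with _open_text(genes_path) as fh:
            gene_ids = [line.split("\t")[0].strip() for line in fh if line.strip()]
        with _open_text(cells_path) as fh:
            cell_ids = [line.split("\t")[0].strip() for line in fh if line.strip()]
        if mat.shape[0] != len(gene_ids):
            raise ValueError(
                f"dimension mismatch: matrix has {mat.shape[0]} gene rows but "
                f"{genes_path.name} lists {len(gene_ids)} genes"
            )
        if mat.shape[1] != len(cell_ids):
            raise ValueError(
                f"dimension mismatch: matrix has {mat.shape[1]} cell columns but "
                f"{cells_path.name} lists {len(cell_ids)} barcodes"
            )
        return make_expression_matrix(mat, gene_ids, cell_ids, genes_as_rows=True)
    if path.suffix in {".csv", ".tsv"} or path.name.endswith((".csv.gz", ".tsv.gz")):
        sep = "," if ".csv" in path.name else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        return make_expression_matrix(
            df.to_numpy(), list(df.index), list(df.columns), genes_as_rows=True
        )
    raise ValueError(f"unrecognized count-matrix path: {path}")


def write_count_matrix(outdir: str | Path, adata: AnnData) -> None:
    """Write the triplet layout (genes x cells mtx + genes.tsv + barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat)
    (outdir / "genes.tsv").write_text("".join(f"{g}\n" for g in adata.var_names))
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in adata.obs_names))
    meta_cols = [c for c in ("cluster", "doublet_score") if c in adata.obs]
    if meta_cols:
        adata.obs[meta_cols].to_csv(outdir / "cell_meta.tsv", sep="\t", index_label="cell_id")


def attach_cell_metadata(adata: AnnData, path: str | Path) -> AnnData:
    """Merge a TSV of per-cell columns (cell_id + cluster, doublet_score, ...)."""
    meta = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    missing = adata.obs_names.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata file lacks {len(missing)} cells, e.g. {list(missing[:3])}")
    for col in meta.columns:
        adata.obs[col] = meta.loc[adata.obs_names, col].to_numpy()
    return adata


def read_doublet_scores(path: str | Path) -> pd.Series:
    """Read the (cell_id, score) doublet-score TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("doublet-score file needs cell_id and score columns")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))


# ---------------------------------------------------------------------------
# images & ROIs
# ---------------------------------------------------------------------------

def read_image(path: str | Path, gene: str = "", slice_id: str = "") -> ISHImage:
    """Read a grayscale PNG/TIFF slice; multi-channel images are rejected."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        # tolerate a trivial single channel; reject real color
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"non-grayscale image ({arr.shape[2]} channels): {path}")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}: {path}")
    sid = slice_id or Path(path).stem
    return ISHImage(arr, gene=gene, slice_id=sid)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a 2-D array as 8-bit (values <= 255) or 16-bit grayscale."""
    import tifffile
    import imageio.v3 as iio

    px = np.asarray(pixels)
    dtype = np.uint8 if px.max() <= 255 else np.uint16
    px = np.round(px).astype(dtype)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)


def read_roi_labels(path: str | Path) -> ROISet:
    """ROI set from a label image: 1-4 = laminae in fixed order, 5 = background."""
    img = read_image(path)
    lab = img.pixels.astype(int)
    masks = {name: lab == (i + 1) for i, name in enumerate(LAYERS)}
    return ROISet(layer_masks=masks, background=lab == 5)


def write_roi_labels(path: str | Path, rois: ROISet) -> None:
    lab = np.zeros(rois.shape, dtype=np.uint8)
    for i, name in enumerate(LAYERS):
        lab[rois.layer_masks[name]] = i + 1
    lab[rois.background] = 5
    write_image(path, lab)


def rasterize_polygon(
    vertices: Sequence[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Even-odd rasterization of a polygon given as (row, col) vertices.

    A pixel is inside when a ray from its center crosses the polygon
    boundary an odd number of times (so self-intersecting polygons punch
    holes).  Coordinates are 0-based, row-major.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows) + 0.0, np.arange(cols) + 0.0, indexing="ij")
    inside = np.zeros(shape, dtype=bool)
    n = verts.shape[0]
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if r1 == r2:
            continue
        cond = (rr >= min(r1, r2)) & (rr < max(r1, r2))
        c_int = c1 + (rr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= cond & (cc < c_int)
    return inside


def read_roi_polygons(path: str | Path, shape: tuple[int, int]) -> ROISet:
    """ROI set from a JSON polygon file.

    Format: ``{"SuG": [[r, c], ...], ..., "background": [[r, c], ...]}`` with
    one vertex list (or a list of vertex lists) per region.
    """
    spec = json.loads(Path(path).read_text())
    need = set(LAYERS) | {"background"}
    if set(spec) != need:
        raise ValueError(f"polygon file must define exactly {sorted(need)}")

    def build(entry) -> np.ndarray:
        polys = entry if isinstance(entry[0][0], (list, tuple)) else [entry]
        mask = np.zeros(shape, dtype=bool)
        for p in polys:
            mask |= rasterize_polygon(p, shape)
        return mask

    masks = {name: build(spec[name]) for name in LAYERS}
    return ROISet(layer_masks=masks, background=build(spec["background"]))


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def _header(config: RunConfig | None) -> str:
    h = f"# laminamap v{__version__}\n"
    if config is not None:
        h += f"# config_hash={config.hash()}\n"
    return h


def write_table(
    path: str | Path, df: pd.DataFrame, config: RunConfig | None = None, index: bool = False
) -> None:
    """Write a TSV with provenance header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_results(outdir: str | Path, result, config: RunConfig | None = None) -> None:
    """Write the pipeline outputs: tables, per-subtype summary and JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(outdir / "qc_report.tsv", result.qc_report, config, index=True)
    write_table(outdir / "deg_table.tsv", result.deg_table, config)
    write_table(outdir / "specificity.tsv", result.specificity, config)
    write_table(outdir / "intensities.tsv", result.intensities, config, index=True)
    write_table(outdir / "layer_scores.tsv", result.summary(), config, index=True)
    write_table(outdir / "heatmap_table.tsv", result.heatmap_table(), config)
    summary = {
        "version": __version__,
        "config": config.to_dict() if config else None,
        "reference_genes": result.reference_genes,
        "assigned_layers": {st: r.assigned_layer for st, r in result.results.items()},
        "anova_p": {st: r.anova_p for st, r in result.results.items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
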