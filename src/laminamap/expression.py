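"""Count-matrix QC, normalization, differential expression and gene scoring.

The in-memory container for expression data is :class:`anndata.AnnData` in the
standard cells x genes orientation.  Per-cell QC fields live in ``.obs``:

``cluster``
    subtype / cluster label (string).
``n_gene``
    number of genes with a nonzero count in the cell.
``n_umi``
    total UMI count of the cell.
``mito_frac``
    fraction of the cell's UMIs on mitochondrial genes (prefix match).
``ercc_frac``
    fraction of the cell's UMIs on spike-in genes (prefix match).
``doublet_score``
    externally computed doublet score (optional; consumed, never computed).

Droplet snRNA-seq and full-length patch-seq data go through the same
functions; only the threshold presets differ (:data:`SNRNA_QC` and
:data:`PATCHSEQ_QC`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCThresholds",
    "SNRNA_QC",
    "PATCHSEQ_QC",
    "make_expression_matrix",
    "compute_qc_metrics",
    "validate_expression",
    "qc_filter_cells",
    "qc_filter_genes",
    "log_normalize",
    "wilcoxon_deg",
    "roc_deg",
    "mean_profiles",
    "specificity_scores",
    "select_reference_genes",
    "map_clusters_by_correlation",
]

MITO_PREFIXES = ("mt-", "MT-", "Mt-")
ERCC_PREFIXES = ("ERCC-",)


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level quality-control bounds.

    All bounds are inclusive on the *keep* side: a cell sitting exactly on a
    limit (e.g. ``n_gene == n_gene_min``) is retained, because the discard
    rules are phrased strictly ("below" / "above" / "greater than").
    """

    n_gene_min: int = 800
    n_gene_max: int = 6000
    n_umi_max: int | None = 20_000
    mito_max: float = 0.03
    ercc_max: float | None = None
    min_cells_per_gene: int = 3
    doublet_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.n_gene_min > self.n_gene_max:
            raise ValueError("n_gene_min must be <= n_gene_max")
        if not 0.0 <= self.mito_max <= 1.0:
            raise ValueError("mito_max must be a fraction in [0, 1]")
        if self.ercc_max is not None and not 0.0 <= self.ercc_max <= 1.0:
            raise ValueError("ercc_max must be a fraction in [0, 1]")
        if self.min_cells_per_gene < 1:
            raise ValueError("min_cells_per_gene must be >= 1")


#: Droplet snRNA-seq preset: nGene in [800, 6000], nUMI <= 20k, mito <= 3%,
#: genes expressed in >= 3 cells, doublet score <= 0.16.
SNRNA_QC = QCThresholds(
    n_gene_min=800,
    n_gene_max=6000,
    n_umi_max=20_000,
    mito_max=0.03,
    min_cells_per_gene=3,
    doublet_cutoff=0.16,
)

#: Patch-seq preset: nGene in [200, 10000], mito <= 10%, spike-in <= 5%,
#: genes expressed in >= 2 cells.  Patch-seq has no UMIs and no doublets.
PATCHSEQ_QC = QCThresholds(
    n_gene_min=200,
    n_gene_max=10_000,
    n_umi_max=None,
    mito_max=0.10,
    ercc_max=0.05,
    min_cells_per_gene=2,
)


# ---------------------------------------------------------------------------
# construction & validation
# ---------------------------------------------------------------------------

def make_expression_matrix(
    counts,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    clusters: Sequence[str] | None = None,
    doublet_scores: Sequence[float] | None = None,
    *,
    genes_as_rows: bool = True,
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES,
    ercc_prefixes: tuple[str, ...] = ERCC_PREFIXES,
) -> AnnData:
    """Assemble an AnnData from a raw count matrix and id lists.

    ``counts`` may be dense or sparse; by default it is genes x cells (the
    on-disk triplet orientation) and is transposed into the AnnData
    cells x genes convention.  QC metrics are computed immediately.
    """
    counts = sp.csr_matrix(counts) if not sp.issparse(counts) else counts.tocsr()
    if genes_as_rows:
        counts = counts.T.tocsr()
    gene_ids = [str(g) for g in gene_ids]
    cell_ids = [str(c) for c in cell_ids]
    if counts.shape != (len(cell_ids), len(gene_ids)):
        raise ValueError(
            f"count matrix shape {counts.shape} does not match "
            f"{len(cell_ids)} cells x {len(gene_ids)} genes"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids contain duplicates")
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("cell_ids contain duplicates")
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("counts must be non-negative")

    adata = AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    if clusters is not None:
        adata.obs["cluster"] = pd.Categorical([str(c) for c in clusters])
    if doublet_scores is not None:
        adata.obs["doublet_score"] = np.asarray(doublet_scores, dtype=float)
    compute_qc_metrics(adata, mito_prefixes=mito_prefixes, ercc_prefixes=ercc_prefixes)
    return adata


def compute_qc_metrics(
    adata: AnnData,
    *,
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES,
    ercc_prefixes: tuple[str, ...] = ERCC_PREFIXES,
) -> AnnData:
    """Fill ``n_gene``, ``n_umi``, ``mito_frac`` and ``ercc_frac`` in ``.obs``."""
    X = adata.X
    if sp.issparse(X):
        n_gene = X.getnnz(axis=1)
        n_umi = np.asarray(X.sum(axis=1)).ravel()
    else:
        n_gene = np.count_nonzero(X, axis=1)
        n_umi = X.sum(axis=1)
    adata.obs["n_gene"] = n_gene.astype(int)
    adata.obs["n_umi"] = n_umi

    names = pd.Index(adata.var_names.astype(str))
    is_mito = np.asarray(names.str.startswith(mito_prefixes))
    is_ercc = np.asarray(names.str.startswith(ercc_prefixes))
    adata.var["mito"] = is_mito
    adata.var["ercc"] = is_ercc
    with np.errstate(invalid="ignore", divide="ignore"):
        for col, mask in (("mito_frac", is_mito), ("ercc_frac", is_ercc)):
            sub = X[:, mask]
            subsum = np.asarray(sub.sum(axis=1)).ravel() if sp.issparse(sub) else sub.sum(axis=1)
            frac = np.divide(subsum, n_umi, out=np.zeros(adata.n_obs), where=n_umi > 0)
            adata.obs[col] = frac
    return adata


def validate_expression(adata: AnnData) -> None:
    """Check the expression-matrix invariants; raise ValueError on violation."""
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X).ravel()
    if data.size and data.min() < 0:
        raise ValueError("counts must be non-negative")
    if adata.obs_names.duplicated().any():
        raise ValueError("duplicate cell ids")
    if adata.var_names.duplicated().any():
        raise ValueError("duplicate gene ids")
    n_gene = X.getnnz(axis=1) if sp.issparse(X) else np.count_nonzero(X, axis=1)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    if "n_gene" in adata.obs and not np.array_equal(adata.obs["n_gene"].to_numpy(), n_gene):
        raise ValueError("stored n_gene does not match counts")
    if "n_umi" in adata.obs and not np.allclose(adata.obs["n_umi"].to_numpy(), n_umi):
        raise ValueError("stored n_umi does not match counts")
    for col in ("mito_frac", "ercc_frac"):
        if col in adata.obs:
            v = adata.obs[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{col} outside [0, 1]")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def qc_filter_cells(
    adata: AnnData, thresholds: QCThresholds = SNRNA_QC
) -> tuple[AnnData, pd.DataFrame]:
    """Drop low-quality cells; return (filtered matrix, per-cell report).

    The report has one row per input cell with columns ``pass`` (bool) and
    ``failed_rule`` (name of the first rule the cell failed, or "").  Rules
    are evaluated in a fixed order: doublet score, nGene low, nGene high,
    nUMI, mitochondrial fraction, spike-in fraction.
    """
    if adata.n_obs == 0:
        raise ValueError("empty expression matrix: no cells to filter")
    if "n_gene" not in adata.obs:
        compute_qc_metrics(adata)
    obs = adata.obs
    if thresholds.doublet_cutoff is not None and "doublet_score" not in obs:
        raise ValueError(
            "doublet_cutoff is set but the matrix carries no doublet_score column"
        )

    rules: list[tuple[str, np.ndarray]] = []
    if thresholds.doublet_cutoff is not None:
        rules.append(
            ("doublet", obs["doublet_score"].to_numpy(dtype=float) > thresholds.doublet_cutoff)
        )
    n_gene = obs["n_gene"].to_numpy()
    rules.append(("n_gene_low", n_gene < thresholds.n_gene_min))
    rules.append(("n_gene_high", n_gene > thresholds.n_gene_max))
    if thresholds.n_umi_max is not None:
        rules.append(("n_umi_high", obs["n_umi"].to_numpy() > thresholds.n_umi_max))
    rules.append(("mito_frac", obs["mito_frac"].to_numpy(dtype=float) > thresholds.mito_max))
    if thresholds.ercc_max is not None:
        if "ercc_frac" not in obs:
            raise ValueError("ercc_max is set but ercc_frac is missing")
        rules.append(("ercc_frac", obs["ercc_frac"].to_numpy(dtype=float) > thresholds.ercc_max))

    failed_rule = np.full(adata.n_obs, "", dtype=object)
    for name, failed in rules:
        newly = failed & (failed_rule == "")
        failed_rule[newly] = name
    keep = failed_rule == ""
    report = pd.DataFrame(
        {"pass": keep, "failed_rule": failed_rule}, index=adata.obs_names.copy()
    )
    return adata[keep].copy(), report


def qc_filter_genes(adata: AnnData, min_cells: int = 3) -> AnnData:
    """Keep genes with a nonzero count in at least ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if adata.n_vars == 0:
        raise ValueError("empty expression matrix: no genes to filter")
    X = adata.X
    n_cells = X.getnnz(axis=0) if sp.issparse(X) else np.count_nonzero(X, axis=0)
    out = adata[:, n_cells >= min_cells].copy()
    compute_qc_metrics(out)
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def log_normalize(adata: AnnData, scale: float = 1e4, layer: str = "lognorm") -> AnnData:
    """Library-size normalize and natural-log transform the counts.

    value(c, g) = ln(1 + scale * count(c, g) / n_umi(c)); the result is stored
    in ``adata.layers[layer]`` (sparse, zeros stay zeros).
    """
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    if np.any(n_umi <= 0):
        bad = adata.obs_names[n_umi <= 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad[:5]}")
    norm = X.astype(float).copy()
    # divide each row by its total, scale, then log1p on the stored nonzeros
    row_scale = scale / n_umi
    norm.data *= np.repeat(row_scale, np.diff(norm.indptr))
    norm.data = np.log1p(norm.data)
    adata.layers[layer] = norm
    return adata


def _dense_layer(adata: AnnData, layer: str) -> np.ndarray:
    if layer in adata.layers:
        M = adata.layers[layer]
    else:
        raise ValueError(f"layer {layer!r} not found; run log_normalize first")
    return M.toarray() if sp.issparse(M) else np.asarray(M, dtype=float)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

EXACT_MAX_N = 10  # total group size at or below which the exact Wilcoxon path runs


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks along the last axis (ties share the average rank)."""
    return stats.rankdata(values, axis=-1)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all in-group assignments.

    The test statistic is the in-group midrank sum; the p-value is the
    fraction of the C(n, n1) equally likely assignments whose statistic is at
    least as far from its null mean as the observed one.  With no ties this
    reproduces the classical exact two-sided Wilcoxon rank-sum p.
    """
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n, n1 = pooled.size, x.size
    obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        s = ranks[list(idx)].sum()
        if abs(s - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def _ranksum_z_p(rank_in_sum: np.ndarray, tie_term: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Vectorized normal-approximation two-sided p with tie and continuity correction."""
    n = n1 + n2
    u = rank_in_sum - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u - mu) - 0.5) / np.sqrt(var)
    z = np.where(var <= 0, 0.0, np.maximum(z, 0.0))
    return np.minimum(1.0, 2.0 * stats.norm.sf(z))


def _group_stats(dense: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return dense[mask].mean(axis=0), dense[~mask].mean(axis=0)


def _tie_terms(ranks_matrix: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Sum over tie groups of t^3 - t, per gene (row of ``values``)."""
    out = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        out[i] = np.sum(counts.astype(float) ** 3 - counts)
    return out


def wilcoxon_deg(
    adata: AnnData,
    groupby: str = "cluster",
    p_adj_cutoff: float = 0.05,
    min_log_fc: float = 0.25,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum DE for every gene and subtype.

    Uses exact enumeration over rank assignments when the total number of
    cells is <= 10, otherwise the normal approximation with tie and
    continuity correction.  P-values are Benjamini-Hochberg adjusted within
    each subtype.  A row is flagged as a DEG iff ``p_adj < p_adj_cutoff`` and
    ``log_fc >= min_log_fc`` (positive enrichment in the subtype).
    """
    return _deg_table(
        adata, groupby, layer, method="wilcox",
        p_adj_cutoff=p_adj_cutoff, power_cutoff=None, min_log_fc=min_log_fc,
    )


def roc_deg(
    adata: AnnData,
    groupby: str = "cluster",
    power_cutoff: float = 0.4,
    min_log_fc: float = 0.25,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """One-vs-rest ROC classification power for every gene and subtype.

    power = \\|2*AUC - 1\\| with AUC the Mann-Whitney probability (ties count
    one half) that an in-group cell exceeds an out-group cell.  A row is
    flagged as a DEG iff ``power > power_cutoff`` and the gene is positively
    enriched (``log_fc >= min_log_fc``).  The signed ``auc`` column is also
    reported.
    """
    return _deg_table(
        adata, groupby, layer, method="roc",
        p_adj_cutoff=None, power_cutoff=power_cutoff, min_log_fc=min_log_fc,
    )


def _deg_table(adata, groupby, layer, *, method, p_adj_cutoff, power_cutoff, min_log_fc):
    if groupby not in adata.obs:
        raise ValueError(f"missing obs column {groupby!r}")
    labels = adata.obs[groupby].astype(str).to_numpy()
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("differential expression needs at least two subtypes")
    dense = _dense_layer(adata, layer)  # cells x genes
    genes = adata.var_names.to_numpy()
    values = dense.T  # genes x cells
    ranks = _midranks(values)
    tie_term = _tie_terms(ranks, values)
    n = values.shape[1]

    frames = []
    for g in groups:
        mask = labels == g
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 < 2 or n2 < 2:
            warnings.warn(f"subtype {g!r} has fewer than 2 cells on one side; skipped")
            continue
        mean_in = values[:, mask].mean(axis=1)
        mean_out = values[:, ~mask].mean(axis=1)
        log_fc = mean_in - mean_out
        rank_in = ranks[:, mask].sum(axis=1)
        auc = (rank_in - n1 * (n1 + 1) / 2.0) / (n1 * n2)
        df = pd.DataFrame(
            {
                "gene": genes,
                "subtype": g,
                "mean_in": mean_in,
                "mean_out": mean_out,
                "log_fc": log_fc,
                "method": method,
            }
        )
        if method == "wilcox":
            if n <= EXACT_MAX_N:
                p_raw = np.array(
                    [_exact_ranksum_p(values[i, mask], values[i, ~mask]) for i in range(len(genes))]
                )
            else:
                p_raw = _ranksum_z_p(rank_in, tie_term, n1, n2)
            _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
            df["p_raw"] = p_raw
            df["p_adj"] = p_adj
            df["is_deg"] = (p_adj < p_adj_cutoff) & (log_fc >= min_log_fc)
        else:
            power = np.abs(2.0 * auc - 1.0)
            df["auc"] = auc
            df["power"] = power
            df["is_deg"] = (power > power_cutoff) & (log_fc >= min_log_fc)
        frames.append(df)
    if not frames:
        raise ValueError("no subtype had enough cells for testing")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# specificity scores & marker selection
# ---------------------------------------------------------------------------

def mean_profiles(
    adata: AnnData,
    groupby: str = "cluster",
    layer: str = "lognorm",
    scale: str = "linear",
) -> pd.DataFrame:
    """Per-subtype mean expression profiles: genes x subtypes.

    With ``scale="linear"`` (the default, and what the specificity score
    expects) the log-normalized values are mapped back through expm1 before
    averaging, giving library-size-normalized linear expression; with
    ``scale="log"`` the log values are averaged directly.
    """
    dense = _dense_layer(adata, layer)
    if scale == "linear":
        dense = np.expm1(dense)
    elif scale != "log":
        raise ValueError("scale must be 'linear' or 'log'")
    labels = adata.obs[groupby].astype(str).to_numpy()
    groups = sorted(set(labels))
    prof = {g: dense[labels == g].mean(axis=0) for g in groups}
    return pd.DataFrame(prof, index=adata.var_names)


def specificity_scores(profiles: pd.DataFrame) -> pd.DataFrame:
    """Subtype specificity of each gene from its cross-subtype mean profile.

    The gene's profile is normalized to a distribution ``p_g`` over the K
    subtypes and compared with the one-hot indicator ``e_k`` of each subtype
    by Jensen-Shannon divergence with base-2 entropies (so JSD is in [0, 1]):

        S_gk = 1 - sqrt(JSD(p_g, e_k))

    S_gk = 1 iff the gene is expressed in subtype k only.  Returns a long
    table of (gene, subtype, specificity).
    """
    P = np.asarray(profiles, dtype=float)
    if np.any(P < 0):
        raise ValueError("mean profiles must be non-negative")
    rowsum = P.sum(axis=1)
    if np.any(rowsum <= 0):
        bad = profiles.index[rowsum <= 0].tolist()
        raise ValueError(f"genes with all-zero profiles have no distribution: {bad[:5]}")
    p = P / rowsum[:, None]
    K = p.shape[1]

    def h(q: np.ndarray) -> np.ndarray:
        """Base-2 entropy along axis 1 with 0*log0 = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
        return -t.sum(axis=1)

    h_p = h(p)
    rows = []
    for k in range(K):
        e = np.zeros(K)
        e[k] = 1.0
        m = (p + e) / 2.0
        jsd = h(m) - 0.5 * h_p  # H(e_k) = 0
        jsd = np.clip(jsd, 0.0, 1.0)
        s = 1.0 - np.sqrt(jsd)
        rows.append(
            pd.DataFrame(
                {"gene": profiles.index, "subtype": profiles.columns[k], "specificity": s}
            )
        )
    return pd.concat(rows, ignore_index=True)


def select_reference_genes(
    degs: pd.DataFrame, spec: pd.DataFrame, n: int = 10
) -> dict[str, list[str]]:
    """Per subtype, the top-n DEG-flagged genes ranked by specificity.

    Ranking is by the gene's specificity for its *own* subtype, descending;
    ties break by smaller adjusted p (where available), then by gene id.
    Subtypes with fewer than n DEGs return a shorter list with a warning.
    """
    if "is_deg" not in degs.columns:
        raise ValueError("DEG table must carry an 'is_deg' flag column")
    spec_idx = spec.set_index(["gene", "subtype"])["specificity"]
    out: dict[str, list[str]] = {}
    for subtype, sub in degs.groupby("subtype", sort=True):
        flagged = sub[sub["is_deg"]].copy()
        if flagged.empty:
            warnings.warn(f"subtype {subtype!r} has no DEGs; empty reference list")
            out[str(subtype)] = []
            continue
        key = pd.MultiIndex.from_arrays([flagged["gene"], flagged["subtype"]])
        missing = ~key.isin(spec_idx.index)
        if missing.any():
            raise ValueError(
                f"specificity table is missing {int(missing.sum())} flagged genes "
                f"for subtype {subtype!r}"
            )
        flagged["specificity"] = spec_idx.loc[key].to_numpy()
        if "p_adj" not in flagged.columns:
            flagged["p_adj"] = 1.0
        ordered = flagged.sort_values(
            ["specificity", "p_adj", "gene"], ascending=[False, True, True]
        )
        genes = ordered["gene"].tolist()
        if len(genes) < n:
            warnings.warn(
                f"subtype {subtype!r} has only {len(genes)} DEGs (< {n} requested)"
            )
        out[str(subtype)] = genes[:n]
    return out


# ---------------------------------------------------------------------------
# cluster correlation mapping
# ---------------------------------------------------------------------------

def map_clusters_by_correlation(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    gene_set: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlation between two sets of cluster mean profiles.

    Both inputs are genes x clusters tables of log-normalized (or externally
    integrated) mean expression.  Rows are restricted to ``gene_set`` (or the
    intersection of the indices when not given); at least 3 shared genes are
    required.  Returns the clusters_a x clusters_b correlation matrix and the
    best-match (argmax per row) assignment.  Correlations involving a
    constant profile are undefined and reported as NaN, never as zero.
    """
    if gene_set is None:
        genes = profiles_a.index.intersection(profiles_b.index)
    else:
        genes = pd.Index(list(gene_set))
        for name, prof in (("A", profiles_a), ("B", profiles_b)):
            missing = genes.difference(prof.index)
            if len(missing):
                raise ValueError(f"profile set {name} is missing genes: {list(missing)[:5]}")
    if len(genes) < 3:
        raise ValueError("need at least 3 shared genes for correlation mapping")
    A = profiles_a.loc[genes].to_numpy(dtype=float)
    B = profiles_b.loc[genes].to_numpy(dtype=float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.sqrt((Ac**2).sum(axis=0))
    sb = np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Ac.T @ Bc) / np.outer(sa, sb)
    corr[np.outer(sa == 0, np.ones_like(sb, dtype=bool))] = np.nan
    corr[np.outer(np.ones_like(sa, dtype=bool), sb == 0)] = np.nan
    cm = pd.DataFrame(corr, index=profiles_a.columns, columns=profiles_b.columns)
    best = cm.idxmax(axis=1, skipna=True)
    best[cm.isna().all(axis=1)] = pd.NA
    return cm, best
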