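"""End-to-end pipeline: counts -> markers -> ISH quantification -> layer call.

Stages, in order: cell/gene QC, log-normalization, one-vs-rest differential
expression, JSD specificity scoring, top-n reference-gene selection, per-gene
ISH quantification, per-subtype layer scoring with ANOVA + Tukey, and the
final lamina assignment.  Any stage failure is re-raised as a
:class:`PipelineError` labeled with the stage name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import expression as expr
from . import ish, layers
from .config import RunConfig

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message starts with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineResult:
    """Outputs of a full run."""

    qc_report: pd.DataFrame
    deg_table: pd.DataFrame
    specificity: pd.DataFrame
    reference_genes: dict[str, list[str]]
    intensities: pd.DataFrame            # gene x 4 layers
    results: dict[str, layers.LayerScoreResult]

    def summary(self) -> pd.DataFrame:
        """One row per subtype: layer scores, ANOVA stats, assigned layer."""
        rows = [r.to_series() for r in self.results.values()]
        df = pd.DataFrame(rows)
        df.index.name = "subtype"
        return df

    def heatmap_table(self) -> pd.DataFrame:
        """Long genes x layers table of normalized intensities (heatmap-ready)."""
        frames = []
        for st, res in self.results.items():
            f = pd.DataFrame(res.normalized, index=res.genes, columns=list(ish.LAYERS))
            f.insert(0, "subtype", st)
            f.index.name = "gene"
            frames.append(f.reset_index())
        return pd.concat(frames, ignore_index=True)


def _stage(stage: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(
    adata,
    images: Mapping[str, Sequence[tuple[ish.ISHImage, ish.ROISet]]],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the complete spatial-classification pipeline.

    ``adata`` is a raw count AnnData with a ``cluster`` obs column (and a
    ``doublet_score`` column when the config sets a doublet cutoff);
    ``images`` maps gene id -> list of (slice image, ROI set), or is a
    callable gene -> slices (raising KeyError for unknown genes).  Every
    reference gene selected for a subtype must have at least one slice,
    otherwise the quantification stage raises a missing-input error.
    """
    cfg = config or RunConfig()

    with _stage("qc"):
        filtered, qc_report = expr.qc_filter_cells(adata, cfg.qc_thresholds())
        filtered = expr.qc_filter_genes(filtered, cfg.min_cells_per_gene)
        if filtered.n_obs == 0:
            raise ValueError("no cells survived QC")
    with _stage("normalize"):
        expr.log_normalize(filtered, scale=cfg.norm_scale)
    with _stage("deg"):
        if cfg.deg_method == "wilcox":
            degs = expr.wilcoxon_deg(
                filtered, p_adj_cutoff=cfg.p_adj_cutoff, min_log_fc=cfg.min_log_fc
            )
        elif cfg.deg_method == "roc":
            degs = expr.roc_deg(
                filtered, power_cutoff=cfg.power_cutoff, min_log_fc=cfg.min_log_fc
            )
        else:
            raise ValueError(f"unknown DEG method {cfg.deg_method!r}")
    with _stage("specificity"):
        profiles = expr.mean_profiles(filtered)
        flagged_genes = degs.loc[degs["is_deg"], "gene"].unique()
        spec = expr.specificity_scores(profiles.loc[profiles.index.isin(flagged_genes)])
    with _stage("select-genes"):
        reference = expr.select_reference_genes(degs, spec, n=cfg.top_n)
    with _stage("quantify-ish"):
        needed = sorted({g for gs in reference.values() for g in gs})
        if callable(images):
            slices_by_gene = {}
            for g in needed:
                try:
                    slices_by_gene[g] = list(images(g))
                except KeyError as e:
                    raise ValueError(f"missing ISH images for selected gene: {g}") from e
        else:
            missing = [g for g in needed if g not in images or len(images[g]) == 0]
            if missing:
                raise ValueError(f"missing ISH images for selected genes: {missing[:10]}")
            slices_by_gene = {g: images[g] for g in needed}
        intensities, n_slices = ish.quantify_gene(
            slices_by_gene, manual_threshold=cfg.manual_threshold
        )
        intensities["n_slices"] = n_slices
    with _stage("layer-score"):
        results = {}
        for st, genes in reference.items():
            if len(genes) < 2:
                results[st] = layers.LayerScoreResult(
                    subtype=st,
                    genes=list(genes),
                    normalized=np.zeros((len(genes), 4)),
                    layer_scores=np.full(4, np.nan),
                    anova_F=np.nan,
                    anova_p=np.nan,
                    posthoc_p=np.ones((4, 4)),
                    assigned_layer=layers.UNASSIGNED,
                )
                continue
            results[st] = layers.score_subtype(
                st,
                intensities.loc[genes, list(ish.LAYERS)],
                alpha=cfg.alpha,
                epsilon=cfg.epsilon,
            )
    return PipelineResult(
        qc_report=qc_report,
        deg_table=degs,
        specificity=spec,
        reference_genes=reference,
        intensities=intensities,
        results=results,
    )
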