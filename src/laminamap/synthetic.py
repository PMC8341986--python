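"""Synthetic expression matrices and layered ISH-like images with known truth.

The generator emulates the statistical structure the pipeline assumes:

* a negative-binomial UMI count background (overdispersed, the standard model
  for droplet data) with a configurable number of subtypes and, for each
  subtype, a set of planted marker genes whose mean is multiplied by
  ``marker_fold`` in that subtype only;
* grayscale "slices" in which the four laminae are horizontal bands; signal
  pixels are Bernoulli-dense inside a gene's true layer and sparse elsewhere,
  drawn bright on a dark base with additive Gaussian noise;
* a complete study bundle pairing the two, with a truth manifest (subtype ->
  planted layer, subtype -> marker genes) for parameter-recovery tests.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config, so identical seed + config gives identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from anndata import AnnData

from .expression import make_expression_matrix
from .ish import LAYERS, ISHImage, ROISet

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "simulate_expression",
    "band_roi_set",
    "simulate_ish_image",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults give a clearly layered study.

    ``nb_mean`` is the average background expression per gene per cell (UMI
    scale); ``nb_dispersion`` is the NB dispersion alpha in
    var = mu + alpha * mu^2.  ``marker_fold`` multiplies a marker's mean in
    its own subtype.  Image signal densities are the Bernoulli probability of
    a signal pixel inside vs outside the gene's true layer band.
    """

    n_subtypes: int = 4
    cells_per_subtype: int = 50
    n_genes: int = 2000
    n_markers_per_subtype: int = 10
    marker_fold: float = 8.0
    nb_mean: float = 1.0
    nb_dispersion: float = 0.5
    mito_gene_fraction: float = 0.02
    ercc_gene_fraction: float = 0.02
    image_size: tuple[int, int] = (240, 200)
    layer_band_fractions: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.2)
    signal_density_in: float = 0.4
    signal_density_out: float = 0.02
    noise_sd: float = 8.0
    slices_per_gene: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subtypes", "cells_per_subtype", "n_genes", "n_markers_per_subtype"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.marker_fold < 1.0:
            raise ValueError("marker_fold must be >= 1")
        for name in ("signal_density_in", "signal_density_out"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.layer_band_fractions) != 4:
            raise ValueError("layer_band_fractions must have 4 entries")
        if sum(self.layer_band_fractions) > 1.0 + 1e-9:
            raise ValueError("layer band fractions must sum to <= 1")
        if self.n_genes < self.n_subtypes * self.n_markers_per_subtype:
            raise ValueError("n_genes too small for the requested marker count")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + alpha mu^2 (gamma-Poisson)."""
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_expression(config: SimulationConfig) -> tuple[AnnData, dict]:
    """Simulate a clustered count matrix with planted subtype markers.

    Returns the AnnData (QC metrics filled, ``cluster`` labels in ``.obs``)
    and a truth dict with ``markers`` (subtype -> list of marker gene ids)
    and ``subtypes``.  Mitochondrial and spike-in genes are tagged by the
    ``mt-`` / ``ERCC-`` prefix so QC fractions are exercised; markers are
    drawn from the remaining untagged genes.
    """
    rng = config.rng(salt=1)
    K, n_cells = config.n_subtypes, config.n_subtypes * config.cells_per_subtype
    G = config.n_genes
    n_mito = int(round(config.mito_gene_fraction * G))
    n_ercc = int(round(config.ercc_gene_fraction * G))
    n_plain = G - n_mito - n_ercc
    if n_plain < config.n_subtypes * config.n_markers_per_subtype:
        raise ValueError("not enough untagged genes to plant the markers")

    gene_ids = (
        [f"g{i:04d}" for i in range(n_plain)]
        + [f"mt-g{i:04d}" for i in range(n_mito)]
        + [f"ERCC-{i:05d}" for i in range(n_ercc)]
    )
    subtypes = [f"ST{k + 1}" for k in range(K)]
    clusters = np.repeat(subtypes, config.cells_per_subtype)

    # per-gene baseline means, lognormal spread around nb_mean
    base = config.nb_mean * rng.lognormal(mean=-0.125, sigma=0.5, size=G)

    marker_idx = rng.choice(n_plain, size=K * config.n_markers_per_subtype, replace=False)
    markers = {
        subtypes[k]: sorted(
            gene_ids[i]
            for i in marker_idx[k * config.n_markers_per_subtype : (k + 1) * config.n_markers_per_subtype]
        )
        for k in range(K)
    }

    mean_matrix = np.tile(base, (n_cells, 1))  # cells x genes
    for k, st in enumerate(subtypes):
        cell_rows = np.where(clusters == st)[0]
        cols = [gene_ids.index(g) for g in markers[st]]
        mean_matrix[np.ix_(cell_rows, cols)] *= config.marker_fold

    counts = _nb_counts(rng, mean_matrix, config.nb_dispersion)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    # plausible doublet-score distribution: most cells well below the 0.16 cutoff
    doublet_scores = rng.beta(2.0, 30.0, size=n_cells)
    adata = make_expression_matrix(
        counts, gene_ids, cell_ids, clusters=clusters,
        doublet_scores=doublet_scores, genes_as_rows=False,
    )
    truth = {"subtypes": subtypes, "markers": markers}
    return adata, truth


def band_roi_set(config: SimulationConfig) -> ROISet:
    """Horizontal-band ROI layout: 4 layer bands then a background strip.

    Band heights follow ``layer_band_fractions`` of the image height; the
    rows left over at the bottom form the background ROI (so the fractions
    must leave at least one row).
    """
    rows, cols = config.image_size
    edges = [0]
    for f in config.layer_band_fractions:
        edges.append(edges[-1] + int(round(f * rows)))
    if edges[-1] >= rows:
        raise ValueError("layer bands leave no rows for the background strip")
    masks = {}
    for name, lo, hi in zip(LAYERS, edges[:-1], edges[1:]):
        m = np.zeros((rows, cols), dtype=bool)
        m[lo:hi] = True
        masks[name] = m
    bg = np.zeros((rows, cols), dtype=bool)
    bg[edges[-1] :] = True
    return ROISet(layer_masks=masks, background=bg)


BASE_LEVEL = 30.0
SIGNAL_LEVEL = 220.0


def simulate_ish_image(
    config: SimulationConfig,
    true_layer: str | None,
    gene: str = "",
    slice_id: str = "",
    rng: np.random.Generator | None = None,
) -> tuple[ISHImage, ROISet, np.ndarray]:
    """One synthetic slice: bright signal pixels dense in the gene's layer.

    ``true_layer`` is one of the lamina names or None for a gene with no
    layer preference (uniform sparse signal).  Returns the image, its band
    ROI set and the true signal mask.  Pass an explicit ``rng`` to draw
    several distinct slices reproducibly.
    """
    if rng is None:
        rng = config.rng(salt=2)
    rois = band_roi_set(config)
    if true_layer is not None and true_layer not in LAYERS:
        raise ValueError(f"unknown layer {true_layer!r}")
    rows, cols = config.image_size
    density = np.full((rows, cols), config.signal_density_out)
    if true_layer is not None:
        density[rois.layer_masks[true_layer]] = config.signal_density_in
    signal = rng.random((rows, cols)) < density
    px = np.where(signal, SIGNAL_LEVEL, BASE_LEVEL)
    if config.noise_sd > 0:
        px = px + rng.normal(0.0, config.noise_sd, size=(rows, cols))
    px = np.clip(px, 0.0, 255.0)
    return ISHImage(px, gene=gene, slice_id=slice_id), rois, signal


@dataclass
class StudyBundle:
    """Everything a full pipeline run needs, plus the planted truth."""

    adata: AnnData
    images: dict[str, list[tuple[ISHImage, ROISet]]]  # gene -> slices
    truth: dict
    config: SimulationConfig

    def image_provider(self, synthesize_null: bool = True):
        """Callable gene -> slices for :func:`laminamap.pipeline.run_pipeline`.

        Serves the stored slices; for genes without stored images it either
        synthesizes deterministic no-layer-preference (null) slices — a
        background gene has no planted lamina, so a uniform sparse stain is
        its ground truth — or raises KeyError when ``synthesize_null`` is
        off.
        """
        import zlib

        cfg = self.config

        def provider(gene: str):
            if gene in self.images:
                return self.images[gene]
            if not synthesize_null:
                raise KeyError(gene)
            rng = np.random.default_rng((cfg.seed, 4, zlib.crc32(gene.encode())))
            slices = []
            for s in range(cfg.slices_per_gene):
                img, rois, _ = simulate_ish_image(
                    cfg, None, gene=gene, slice_id=f"s{s}", rng=rng
                )
                slices.append((img, rois))
            return slices

        return provider

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["image_size"] = list(cfg["image_size"])
        cfg["layer_band_fractions"] = list(cfg["layer_band_fractions"])
        return {
            "config": cfg,
            "subtypes": self.truth["subtypes"],
            "markers": self.truth["markers"],
            "layer_of_subtype": self.truth["layer_of_subtype"],
            "genes_with_images": sorted(self.images),
        }


def simulate_study(
    config: SimulationConfig,
    images_for: str = "markers",
    null_images: bool = False,
) -> StudyBundle:
    """Simulate a complete study: counts + ISH slices + truth manifest.

    Subtype k is planted in layer k (cycling if there are more subtypes than
    laminae).  ``images_for`` selects which genes get slices: "markers"
    (default, the planted markers only) or "all".  With ``null_images`` the
    in-layer density is replaced by the out-of-layer density, producing
    images with no layer preference (the spatial null).
    """
    adata, truth = simulate_expression(config)
    subtypes = truth["subtypes"]
    layer_of_subtype = {st: LAYERS[k % len(LAYERS)] for k, st in enumerate(subtypes)}
    truth["layer_of_subtype"] = layer_of_subtype

    gene_layer: dict[str, str | None] = {}
    for st in subtypes:
        for g in truth["markers"][st]:
            gene_layer[g] = layer_of_subtype[st]
    if images_for == "all":
        for g in adata.var_names:
            gene_layer.setdefault(g, None)
    elif images_for != "markers":
        raise ValueError("images_for must be 'markers' or 'all'")

    img_cfg = config
    if null_images:
        img_cfg = SimulationConfig(
            **{**asdict(config), "signal_density_in": config.signal_density_out}
        )

    rng = config.rng(salt=3)
    images: dict[str, list[tuple[ISHImage, ROISet]]] = {}
    for g in sorted(gene_layer):
        slices = []
        for s in range(config.slices_per_gene):
            img, rois, _ = simulate_ish_image(
                img_cfg, gene_layer[g], gene=g, slice_id=f"s{s}", rng=rng
            )
            slices.append((img, rois))
        images[g] = slices
    return StudyBundle(adata=adata, images=images, truth=truth, config=config)
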