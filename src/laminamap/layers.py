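"""Layer specificity scoring and lamina assignment for one neuron subtype.

Given the background-subtracted ISH intensities of a subtype's reference
genes in the four laminae, the subtype's spatial profile is summarized by:

1. per-gene min-max normalization of the 4 layer intensities to [0, 1];
2. the layer specificity score, ln(mean normalized intensity + epsilon) per
   layer (the log only changes display scale — score ordering equals the
   ordering of the means);
3. a one-way ANOVA across the four layers with genes as replicates, plus a
   Tukey HSD post hoc over all six layer pairs;
4. assignment of the top-scoring layer iff the ANOVA p and every Tukey p of
   the winner against the other three layers fall below alpha; otherwise the
   subtype is left "unassigned" (its neurons may span several laminae).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .ish import LAYERS

__all__ = [
    "LayerScoreResult",
    "normalize_gene_intensities",
    "layer_specificity_score",
    "layer_anova",
    "assign_layer",
    "score_subtype",
]

UNASSIGNED = "unassigned"


@dataclass
class LayerScoreResult:
    """Full layer-scoring output for one subtype."""

    subtype: str
    genes: list[str]
    normalized: np.ndarray          # genes x 4, in [0, 1]
    layer_scores: np.ndarray        # 4 log-mean scores
    anova_F: float
    anova_p: float
    posthoc_p: np.ndarray           # 4 x 4 symmetric, diagonal 1
    assigned_layer: str             # one of LAYERS or "unassigned"

    def to_series(self) -> pd.Series:
        s = pd.Series(self.layer_scores, index=list(LAYERS))
        s["anova_F"] = self.anova_F
        s["anova_p"] = self.anova_p
        s["assigned_layer"] = self.assigned_layer
        s.name = self.subtype
        return s


def normalize_gene_intensities(intensity: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Per-gene min-max normalization of layer intensities to [0, 1].

    A constant (degenerate) row becomes all zeros.
    """
    X = np.asarray(intensity, dtype=float)
    if X.ndim != 2:
        raise ValueError("intensity must be a genes x layers matrix")
    if np.any(X < 0):
        raise ValueError("intensities must be non-negative")
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(X)
    nz = span.ravel() > 0
    out[nz] = (X[nz] - lo[nz]) / span[nz]
    return out


def layer_specificity_score(normalized: np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """ln(mean normalized intensity + epsilon) for each layer.

    epsilon keeps the log finite when a layer's mean is exactly zero; the
    ordering of the four scores always equals the ordering of the means.
    """
    normalized = np.asarray(normalized, dtype=float)
    if normalized.ndim != 2 or normalized.shape[0] < 1:
        raise ValueError("need a genes x layers matrix with at least one gene")
    return np.log(normalized.mean(axis=0) + epsilon)


def layer_anova(normalized: np.ndarray) -> tuple[float, float, np.ndarray]:
    """One-way ANOVA across layers (genes as replicates) + Tukey HSD post hoc.

    Returns (F, p, posthoc_p) where posthoc_p is the 4x4 symmetric matrix of
    Tukey p-values with a diagonal of 1.  Degenerate input (zero between- and
    within-group variance) returns F = 0, p = 1 and all post hoc p = 1.
    """
    X = np.asarray(normalized, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("ANOVA needs at least 2 genes (replicates)")
    n, k = X.shape[0], X.shape[1]
    grand = X.mean()
    col_means = X.mean(axis=0)
    ss_between = n * ((col_means - grand) ** 2).sum()
    ss_within = ((X - col_means) ** 2).sum()
    df_between, df_within = k - 1, k * n - k

    posthoc = np.ones((k, k))
    scale = max(1.0, abs(grand))
    if ss_between <= 1e-12 * scale and ss_within <= 1e-12 * scale:
        return 0.0, 1.0, posthoc
    if ss_within <= 1e-12 * scale:
        posthoc = np.where(np.eye(k, dtype=bool), 1.0, 0.0)
        return float("inf"), 0.0, posthoc

    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))

    values = X.ravel(order="F")
    groups = np.repeat(np.arange(k), n)
    tukey = pairwise_tukeyhsd(values, groups, alpha=0.05)
    pair_p = np.asarray(tukey.pvalues, dtype=float)
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            posthoc[i, j] = posthoc[j, i] = pair_p[idx]
            idx += 1
    return float(F), p, posthoc


def assign_layer(
    scores: np.ndarray,
    anova_p: float,
    posthoc_p: np.ndarray,
    alpha: float = 0.05,
) -> str:
    """Assign the top-scoring layer, or "unassigned" when not significant.

    The winner must clear two hurdles: the overall ANOVA p < alpha, and its
    Tukey p against *every* other layer < alpha.  A subtype whose signal does
    not single out one lamina stays unassigned rather than being forced into
    the top-scoring one.
    """
    scores = np.asarray(scores, dtype=float)
    top = int(np.argmax(scores))
    if np.sum(scores == scores[top]) > 1:
        return UNASSIGNED
    if not (anova_p < alpha):
        return UNASSIGNED
    others = [j for j in range(len(scores)) if j != top]
    if all(posthoc_p[top, j] < alpha for j in others):
        return LAYERS[top]
    return UNASSIGNED


def score_subtype(
    subtype: str,
    intensity: pd.DataFrame,
    alpha: float = 0.05,
    epsilon: float = 1e-3,
) -> LayerScoreResult:
    """Run the full layer-scoring chain for one subtype.

    ``intensity`` is the genes x 4 table of background-subtracted ISH
    intensities of the subtype's reference genes (columns in LAYERS order).
    """
    intensity = intensity.loc[:, list(LAYERS)]
    normalized = normalize_gene_intensities(intensity.to_numpy())
    scores = layer_specificity_score(normalized, epsilon=epsilon)
    F, p, posthoc = layer_anova(normalized)
    label = assign_layer(scores, p, posthoc, alpha=alpha)
    return LayerScoreResult(
        subtype=subtype,
        genes=list(intensity.index),
        normalized=normalized,
        layer_scores=scores,
        anova_F=F,
        anova_p=p,
        posthoc_p=posthoc,
        assigned_layer=label,
    )
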