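"""Run configuration: every pipeline parameter with its published default.

The defaults are the study's values: nGene in [800, 6000], nUMI <= 20,000,
mitochondrial fraction <= 3%, genes in >= 3 cells, doublet score <= 0.16,
adjusted p < 0.05 (Wilcoxon route), power > 0.4 (ROC route), 10 reference
genes per subtype, assignment alpha 0.05.

A config round-trips losslessly through a flat ``key = value`` text file and
through JSON; :meth:`RunConfig.hash` gives a short digest that is stamped
into every output file header for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path

from .expression import QCThresholds

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # cell/gene QC
    n_gene_min: int = 800
    n_gene_max: int = 6000
    n_umi_max: int | None = 20_000
    mito_max: float = 0.03
    ercc_max: float | None = None
    min_cells_per_gene: int = 3
    doublet_cutoff: float | None = 0.16
    # normalization
    norm_scale: float = 1e4
    # differential expression
    deg_method: str = "wilcox"
    p_adj_cutoff: float = 0.05
    power_cutoff: float = 0.4
    min_log_fc: float = 0.25
    # reference-gene selection
    top_n: int = 10
    # ISH quantification
    manual_threshold: float | None = None
    # layer scoring
    alpha: float = 0.05
    epsilon: float = 1e-3

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            n_gene_min=self.n_gene_min,
            n_gene_max=self.n_gene_max,
            n_umi_max=self.n_umi_max,
            mito_max=self.mito_max,
            ercc_max=self.ercc_max,
            min_cells_per_gene=self.min_cells_per_gene,
            doublet_cutoff=self.doublet_cutoff,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def write(self, path: str | Path) -> None:
        """Write as a flat ``key = value`` file (None written as 'none')."""
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {'none' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        d: dict = {}
        types = {f.name: f for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            d[key] = _parse_value(val, key)
        return cls.from_dict(d)

    def hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


_INT_KEYS = {"n_gene_min", "n_gene_max", "n_umi_max", "min_cells_per_gene", "top_n"}
_STR_KEYS = {"deg_method"}


def _parse_value(val: str, key: str):
    if val.lower() in {"none", "null", ""}:
        return None
    if key in _STR_KEYS:
        return val
    if key in _INT_KEYS:
        return int(val)
    return float(val)
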