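"""Core containers shared across the pipeline.

All containers are thin, validated wrappers around pandas/numpy objects:
genes are rows, samples are columns, and gene/sample identifiers are
kept on the objects so every downstream table can be written and
re-read losslessly as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

#: Label used for genes not assigned to any module.
GREY = "grey"

#: Fixed ordered module color list; labels are assigned by decreasing
#: module size (ties broken by smallest member gene ID) so runs are
#: comparable. Overflow modules get "module_<rank>".
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown",
    "steelblue", "paleturquoise", "violet", "darkolivegreen",
    "darkmagenta", "sienna", "yellowgreen", "skyblue3", "plum",
    "orangered", "mediumpurple", "lightsteelblue", "lightcyan1",
    "ivory", "floralwhite", "darkslateblue", "brown4", "bisque4",
    "darkorange2", "navajowhite", "thistle",
)


def color_for_rank(rank: int) -> str:
    """Module label for a 0-based size rank on the fixed color list."""
    if rank < len(MODULE_COLORS):
        return MODULE_COLORS[rank]
    return f"module_{rank + 1}"


@dataclass
class CountMatrix:
    """Raw integer gene x sample counts with per-sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, genes in rows, samples in columns.
    sample_meta
        DataFrame indexed by sample ID with at least ``condition`` and
        ``batch`` columns, one row per sample, same order as columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(
                f"samples missing from metadata: {missing[:5]}"
            )
        for col in ("condition", "batch"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
        self.sample_meta = self.sample_meta.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class ExpressionMatrix:
    """Normalized log-scale expression used for correlation.

    ``values`` holds log2(count / size_factor + 1), optionally
    batch-centered. ``qc_report`` accumulates removed samples/genes with
    reasons as the ingest steps run.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    size_factors: pd.Series
    qc_report: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            bad = self.size_factors[self.size_factors <= 0].index[0]
            raise ValueError(f"non-positive size factor for sample {bad!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ModulePartition:
    """Gene -> module-color assignment, with ``grey`` for unassigned."""

    assignment: pd.Series  # index = gene_id, values = color labels
    provenance: str = "unmerged"  # "unmerged" | "merged"

    def __post_init__(self) -> None:
        self.assignment = self.assignment.astype(str)

    @property
    def modules(self) -> list[str]:
        """Non-grey module labels ordered by decreasing size."""
        counts = self.assignment[self.assignment != GREY].value_counts()
        return list(counts.index)

    def members(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts()

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": self.assignment, "provenance": self.provenance}
        ).rename_axis("gene_id")


@dataclass
class Eigengenes:
    """Module eigengenes: first PC of each module's standardized rows.

    ``values`` is module x sample, each row unit-norm and sign-oriented
    to correlate non-negatively with the module mean profile.
    """

    values: pd.DataFrame
    variance_explained: pd.Series

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.values.to_numpy(), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("eigengenes must be unit-norm")
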