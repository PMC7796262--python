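"""Expression-matrix clustering, differential-expression filtering, and
report assembly.

Hierarchical clustering uses complete linkage on Euclidean distances (the
merge criterion is the smallest maximum pairwise distance, which makes the
merge heights monotone). The DE filter applies the inclusive thresholds
|log2FC| >= 1.2 and adjusted p <= 0.05. Log2 expression values are banded
into low / moderate / high named levels; the gap the prose bands leave
between 2.0 and 4.0 is mapped to an explicit ``moderate_low`` level rather
than silently absorbed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io_formats import ZipperscanError

__all__ = [
    "Dendrogram",
    "DERecord",
    "DEFAULT_BANDS",
    "hcluster",
    "de_filter",
    "expression_band",
    "build_report",
]


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"{self.gene_id}: padj {self.padj} outside [0, 1]")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree for ``n`` leaves.

    ``merges`` lists n-1 tuples (cluster_i, cluster_j, height, size) in
    merge order, with original leaves numbered 0..n-1 and merged clusters
    n, n+1, ... in order of creation, as in the scipy linkage encoding.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(m[2] for m in self.merges)

    @property
    def _linkage(self) -> np.ndarray:
        return np.array([[i, j, h, s] for i, j, h, s in self.merges], dtype=float)

    @property
    def leaf_order(self) -> tuple[str, ...]:
        order = hierarchy.leaves_list(self._linkage)
        return tuple(self.labels[i] for i in order)

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster membership when cutting the tree into ``k`` clusters."""
        assignments = hierarchy.fcluster(self._linkage, t=k, criterion="maxclust")
        return {label: int(c) for label, c in zip(self.labels, assignments)}

    def to_newick(self) -> str:
        n = self.n_leaves
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for idx, (i, j, height, _size) in enumerate(self.merges):
            nodes[n + idx] = f"({nodes[i]},{nodes[j]}):{height:g}"
        return nodes[n + len(self.merges) - 1].rsplit(":", 1)[0] + ";"


def hcluster(
    matrix: pd.DataFrame, axis: Literal["genes", "samples"] = "genes"
) -> Dendrogram:
    """Complete-linkage hierarchical clustering with Euclidean distances.

    ``axis="genes"`` clusters rows, ``axis="samples"`` columns. Ties are
    resolved deterministically (smallest index pair, the scipy
    convention).
    """
    if axis == "samples":
        matrix = matrix.T
    elif axis != "genes":
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    if matrix.shape[0] < 2:
        raise ZipperscanError("clustering requires at least two items")
    if matrix.isna().any().any():
        raise ZipperscanError("expression matrix contains missing values")
    linkage = hierarchy.linkage(matrix.to_numpy(dtype=float), method="complete", metric="euclidean")
    merges = tuple(
        (int(i), int(j), float(h), int(s)) for i, j, h, s in linkage
    )
    return Dendrogram(labels=tuple(str(x) for x in matrix.index), merges=merges)


def de_filter(
    records: Sequence[DERecord] | pd.DataFrame, lfc: float = 1.2, alpha: float = 0.05
) -> tuple[list[DERecord], list[DERecord]]:
    """Split records into (up, down) lists with inclusive boundaries:
    up when log2fc >= lfc and padj <= alpha, down when log2fc <= -lfc and
    padj <= alpha."""
    if isinstance(records, pd.DataFrame):
        records = [
            DERecord(gene_id=str(r.gene_id), log2fc=float(r.log2fc), padj=float(r.padj))
            for r in records.itertuples()
        ]
    up = [r for r in records if r.log2fc >= lfc and r.padj <= alpha]
    down = [r for r in records if r.log2fc <= -lfc and r.padj <= alpha]
    return up, down


#: Banding of log2 expression values: (name, lower, upper,
#: upper_inclusive); lower bounds inclusive, first match wins. The 2.0-4.0
#: range falls between the named low and moderate bands and is mapped
#: explicitly to ``moderate_low``.
DEFAULT_BANDS: tuple[tuple[str, float, float, bool], ...] = (
    ("low", float("-inf"), 2.0, False),
    ("moderate_low", 2.0, 4.0, False),
    ("moderate", 4.0, 6.0, True),
    ("high", 6.0, float("inf"), True),
)


def expression_band(
    value: float, bands: tuple[tuple[str, float, float, bool], ...] = DEFAULT_BANDS
) -> str:
    """Named expression level of a log2 value.

    With the default table: < 2.0 low, [2.0, 4.0) moderate_low,
    [4.0, 6.0] moderate, > 6.0 high. The named band edges overlap at 6.0,
    so its assignment (here: moderate) is a configuration choice, not a
    biological one.
    """
    for name, lo, hi, upper_inclusive in bands:
        if lo <= value < hi or (upper_inclusive and value == hi):
            return name
    raise ValueError(f"value {value} not covered by banding table")


def build_report(
    outdir: str | Path,
    stages: dict[str, pd.DataFrame | dict | list | str],
    config: dict | None = None,
    seed: int | None = None,
    expected_stages: Iterable[str] = (),
) -> Path:
    """Assemble a reproducible report directory.

    Each stage output is written as a TSV (DataFrames) or JSON
    (dicts/lists) or plain text; a ``run.json`` manifest records the
    configuration, seed, package version, files written, and any expected
    stage that was skipped. Reruns with identical inputs are
    byte-identical (no timestamps).
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name in sorted(stages):
        value = stages[name]
        if isinstance(value, pd.DataFrame):
            path = outdir / f"{name}.tsv"
            value.to_csv(path, sep="\t")
        elif isinstance(value, str):
            path = outdir / f"{name}.txt"
            path.write_text(value)
        else:
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(value, indent=2, sort_keys=True) + "\n")
        written.append(path.name)
    skipped = sorted(set(expected_stages) - set(stages))
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "files": written,
        "skipped_stages": skipped,
    }
    (outdir / "run.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
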