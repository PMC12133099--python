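"""Replicate QC and hierarchical clustering of environmental conditions.

All information footprints of one experiment (condition x replicate) are
concatenated into one row of a condition matrix whose columns are
(promoter, position) pairs.  Rows are compared by Pearson correlation over
mutually observed columns; hierarchical clustering with average linkage on
the 1 - r distance groups environments by regulatory response, per promoter
or globally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .classification import LABEL_SITES
from .footprints import Footprint

DEFAULT_QC_THRESHOLD = 0.2
MIN_OVERLAP = 50


@dataclass
class ConditionMatrix:
    """Experiments x (promoter, position) matrix of mi values; missing
    entries are NaN (masked, never zero-filled)."""

    values: np.ndarray
    row_labels: list[tuple[str, int]]          # (condition, replicate)
    col_labels: list[tuple[str, int]]          # (promoter, position label)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape inconsistent with labels")

    @property
    def n_experiments(self) -> int:
        return len(self.row_labels)

    @classmethod
    def from_footprints(cls, footprints: Sequence[Footprint], use_smoothed: bool = False) -> "ConditionMatrix":
        cols: list[tuple[str, int]] = []
        col_index: dict[tuple[str, int], int] = {}
        rows: list[tuple[str, int]] = []
        row_index: dict[tuple[str, int], int] = {}
        for fp in footprints:
            rkey = (fp.condition, fp.replicate)
            if rkey not in row_index:
                row_index[rkey] = len(rows)
                rows.append(rkey)
            for lab in fp.labels:
                ckey = (fp.promoter, int(lab))
                if ckey not in col_index:
                    col_index[ckey] = len(cols)
                    cols.append(ckey)
        values = np.full((len(rows), len(cols)), np.nan)
        for fp in footprints:
            r = row_index[(fp.condition, fp.replicate)]
            data = fp.mi_smoothed if use_smoothed and fp.mi_smoothed is not None else fp.mi
            for lab, v in zip(fp.labels, data):
                values[r, col_index[(fp.promoter, int(lab))]] = v
        return cls(values=values, row_labels=rows, col_labels=cols)


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form."""

    linkage: np.ndarray          # (n-1, 4) scipy linkage matrix
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(a), int(b), float(h), int(size))
            for a, b, h, size in self.linkage
        ]

    def root_split(self) -> tuple[set[str], set[str]]:
        """Leaf label sets of the two subtrees under the final merge."""
        n = self.n_leaves
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for k, (a, b, _, _) in enumerate(self.merges()):
            members[n + k] = members[a] | members[b]
        a, b, _, _ = self.merges()[-1]
        return (
            {self.leaf_labels[i] for i in members[a]},
            {self.leaf_labels[i] for i in members[b]},
        )


def _pairwise_pearson(values: np.ndarray, min_overlap: int = 1) -> np.ndarray:
    """Pairwise-complete Pearson correlation between rows; pairs with fewer
    than ``min_overlap`` mutually observed columns are NaN."""
    n = values.shape[0]
    r = np.full((n, n), np.nan)
    for i in range(n):
        r[i, i] = 1.0
        for j in range(i + 1, n):
            both = np.isfinite(values[i]) & np.isfinite(values[j])
            if both.sum() < min_overlap:
                continue
            a, b = values[i, both], values[j, both]
            if a.std() == 0 or b.std() == 0:
                continue
            r[i, j] = r[j, i] = np.corrcoef(a, b)[0, 1]
    return r


@dataclass
class QcReport:
    experiments: list[tuple[str, int]]
    pairwise_r: np.ndarray
    mean_r: np.ndarray
    excluded: list[bool]
    threshold: float

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "condition": [c for c, _ in self.experiments],
                "replicate": [r for _, r in self.experiments],
                "mean_correlation": self.mean_r,
                "excluded": self.excluded,
            }
        ).to_csv(path, sep="\t", index=False)


def replicate_qc(
    footprints: Sequence[Footprint],
    threshold: float = DEFAULT_QC_THRESHOLD,
    min_overlap: int = MIN_OVERLAP,
) -> QcReport:
    """Flag experiments poorly correlated with the rest.

    Builds the condition matrix, computes the pairwise Pearson matrix over
    concatenated footprints, and excludes experiments whose mean correlation
    to all others falls below ``threshold``.
    """
    matrix = ConditionMatrix.from_footprints(footprints)
    if matrix.n_experiments < 2:
        raise ValueError("replicate QC needs at least 2 experiments")
    if threshold > 1.0:
        warnings.warn(
            f"QC threshold {threshold} exceeds the maximum attainable "
            "correlation of 1; every experiment will be flagged"
        )
    r = _pairwise_pearson(matrix.values, min_overlap)
    off = r.copy()
    np.fill_diagonal(off, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = np.nanmean(off, axis=1)
    excluded = [bool(m < threshold) if np.isfinite(m) else True for m in mean_r]
    return QcReport(
        experiments=matrix.row_labels,
        pairwise_r=r,
        mean_r=mean_r,
        excluded=excluded,
        threshold=threshold,
    )


def cluster_conditions(
    matrix: ConditionMatrix,
    linkage_method: str = "average",
    min_overlap: int = MIN_OVERLAP,
) -> Dendrogram:
    """Agglomerative clustering of experiments with 1 - Pearson distance.

    Rows with zero variance or with any missing pairwise distance (fewer
    than ``min_overlap`` shared columns with some other row) are dropped
    with a warning.  Ties are broken deterministically by row order (scipy's
    deterministic linkage).
    """
    values = matrix.values
    labels = [f"{c}|{r}" for c, r in matrix.row_labels]
    finite = [np.isfinite(v) for v in values]
    variances = np.array(
        [values[i][finite[i]].std() if finite[i].any() else 0.0 for i in range(len(labels))]
    )
    keep = variances > 0
    if not keep.all():
        dropped = [labels[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance rows: {dropped}")
    values = values[keep]
    labels = [l for l, k in zip(labels, keep) if k]
    if len(labels) < 2:
        raise ValueError("clustering needs at least 2 usable rows")
    r = _pairwise_pearson(values, min_overlap)
    dist = 1.0 - r
    # drop rows with missing pair distances until the matrix is complete
    while True:
        off = dist.copy()
        np.fill_diagonal(off, 0.0)
        bad = np.isnan(off).sum(axis=1)
        if bad.max() == 0:
            break
        worst = int(bad.argmax())
        warnings.warn(f"dropping row {labels[worst]} with missing pair distances")
        sel = np.ones(len(labels), dtype=bool)
        sel[worst] = False
        dist = dist[np.ix_(sel, sel)]
        labels = [l for l, k in zip(labels, sel) if k]
        if len(labels) < 2:
            raise ValueError("too few rows left after dropping incomplete pairs")
    iu = np.triu_indices(len(labels), 1)
    condensed = dist[iu]
    condensed = np.maximum(condensed, 0.0)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    return Dendrogram(linkage=Z, leaf_labels=labels)


def cluster_promoter_conditions(
    footprints: Sequence[Footprint],
    classifications: Mapping[tuple[str, int], str] | None = None,
    restrict_to_sites: bool = True,
    linkage_method: str = "average",
    min_overlap: int = MIN_OVERLAP,
) -> Dendrogram | None:
    """Cluster the conditions of a single promoter.

    When ``restrict_to_sites`` is set, only experiments classified as SITES
    (keyed by (condition, replicate) in ``classifications``) participate.
    Returns None (an informative no-op) when fewer than 2 experiments are
    eligible.
    """
    promoters = {fp.promoter for fp in footprints}
    if len(promoters) > 1:
        raise ValueError(f"footprints span multiple promoters: {sorted(promoters)}")
    eligible = list(footprints)
    if restrict_to_sites:
        if classifications is None:
            raise ValueError("restrict_to_sites requires a classification mapping")
        eligible = [
            fp
            for fp in footprints
            if classifications.get((fp.condition, fp.replicate)) == LABEL_SITES
        ]
    if len({(fp.condition, fp.replicate) for fp in eligible}) < 2:
        warnings.warn("fewer than 2 eligible experiments; nothing to cluster")
        return None
    matrix = ConditionMatrix.from_footprints(eligible)
    return cluster_conditions(matrix, linkage_method, min_overlap)


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick serialization with ultrametric branch lengths.

    A node's elevation is half its merge height (so the cophenetic distance
    between two leaves equals their merge height); each branch length is the
    parent's elevation minus the child's.
    """
    n = dendrogram.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h, _) in enumerate(dendrogram.merges()):
        node = n + k
        heights[node] = h / 2.0
        children[node] = (a, b)

    def render(node: int, parent_height: float) -> str:
        length = parent_height - heights[node]
        if node < n:
            return f"{_escape(dendrogram.leaf_labels[node])}:{length:.10g}"
        a, b = children[node]
        return f"({render(a, heights[node])},{render(b, heights[node])}):{length:.10g}"

    root = n + len(children) - 1
    a, b = children[root]
    return f"({render(a, heights[root])},{render(b, heights[root])});"


def _escape(label: str) -> str:
    if any(ch in label for ch in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_distance_tsv(matrix: ConditionMatrix, path: str | Path, min_overlap: int = MIN_OVERLAP) -> None:
    labels = [f"{c}|{r}" for c, r in matrix.row_labels]
    dist = 1.0 - _pairwise_pearson(matrix.values, min_overlap)
    pd.DataFrame(dist, index=labels, columns=labels).to_csv(path, sep="\t")
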