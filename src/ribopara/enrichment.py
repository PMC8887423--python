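"""Pairwise tissue comparisons, enrichment calls and hierarchical clustering.

For each protein quantified in two sample groups (a tissue/complex pair
each), the log2 fold-change is the difference of per-channel log2 means,
and significance comes from a two-sided t-test on the log2 values (Welch,
i.e. unequal-variance, by default; a pooled-variance variant is one flag
away). A protein is called *enriched* when its fold change exceeds a
threshold (1.5-fold on the linear scale by default) and its P-value falls
below 0.05 -- the cut-offs used for volcano-plot calls. No multiple-testing
correction is applied to these per-protein tests.

Row clustering of Z-scored abundances uses standard agglomerative
clustering; the leaf order is re-derived deterministically
(smaller-cluster-first traversal, ties to the lower row index) so repeated
runs produce identical dendrograms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist
from scipy import stats

from .quantify import AbundanceMatrix, SampleDesign

logger = logging.getLogger(__name__)

NEITHER = "neither"


@dataclass(frozen=True)
class ComparisonResult:
    """One protein's a-vs-b comparison: log2FC, Welch P, enrichment call."""

    protein: str
    group_a: str
    group_b: str
    log2fc: float
    p_value: float  # NaN when undefined (n < 2 in either group)
    n_a: int
    n_b: int
    enriched_in: str = NEITHER  # "a", "b" or "neither"


def _resolve_group(matrix: AbundanceMatrix, group, design: SampleDesign | None):
    """A group is a selector dict ({"tissue": ..., "complex": ...}) or an
    explicit list of (run, channel) columns. Returns (columns, label)."""
    if isinstance(group, Mapping):
        if design is None:
            raise ValueError("selector groups require a sample design")
        cols = design.sample_columns(**group)
        label = ":".join(
            str(group[k]) for k in ("tissue", "complex", "replicate")
            if group.get(k) is not None
        )
        return cols, label
    cols = [tuple(c) for c in group]
    return cols, ",".join(f"{r}/{c}" for r, c in cols)


def compare(
    matrix: AbundanceMatrix,
    group_a,
    group_b,
    design: SampleDesign | None = None,
    *,
    label_a: str | None = None,
    label_b: str | None = None,
    test: str = "welch",
) -> list[ComparisonResult]:
    """Per-protein log2 fold-change (a relative to b) with t-test P-values.

    Non-positive and missing cells are excluded before taking log2; the
    t-test runs only when both groups retain at least two values, otherwise
    the P-value is NaN. Proteins quantified in only one group are reported
    with NaN log2fc and P rather than silently dropped.
    """
    matrix.require_stage("normalized", "scaled")
    design = design or matrix.design
    cols_a, auto_a = _resolve_group(matrix, group_a, design)
    cols_b, auto_b = _resolve_group(matrix, group_b, design)
    if not cols_a or not cols_b:
        raise ValueError("empty group selection")
    label_a = label_a or auto_a
    label_b = label_b or auto_b

    results = []
    for acc in matrix.values.index:
        va = _log2_values(matrix, acc, cols_a)
        vb = _log2_values(matrix, acc, cols_b)
        if len(va) and len(vb):
            log2fc = float(np.mean(va) - np.mean(vb))
            if len(va) >= 2 and len(vb) >= 2:
                p = float(
                    stats.ttest_ind(va, vb, equal_var=(test == "pooled")).pvalue
                )
            else:
                p = math.nan
        else:
            log2fc, p = math.nan, math.nan
        results.append(
            ComparisonResult(
                protein=str(acc),
                group_a=label_a,
                group_b=label_b,
                log2fc=log2fc,
                p_value=p,
                n_a=len(va),
                n_b=len(vb),
            )
        )
    return results


def _log2_values(matrix: AbundanceMatrix, acc, cols) -> np.ndarray:
    vals = np.asarray(
        [matrix.values.at[acc, c] for c in cols if c in matrix.values.columns],
        dtype=float,
    )
    vals = vals[np.isfinite(vals) & (vals > 0)]
    return np.log2(vals)


def call_enriched(
    results: Sequence[ComparisonResult],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    scale: str = "linear",
) -> list[ComparisonResult]:
    """Annotate comparisons with enrichment calls at the given cut-offs.

    With ``scale="linear"`` (default) the fold-change condition is
    ``2**|log2fc| > fc_threshold`` (e.g. 1.5-fold); with ``scale="log2"``
    the threshold is applied to |log2fc| directly. Raising ``fc_threshold``
    or lowering ``p_threshold`` can only remove calls, never add them.
    """
    if scale == "linear":
        if fc_threshold <= 1:
            raise ValueError("linear fc_threshold must be > 1")
        log2_cut = math.log2(fc_threshold)
    elif scale == "log2":
        if fc_threshold <= 0:
            raise ValueError("log2 fc_threshold must be > 0")
        log2_cut = fc_threshold
    else:
        raise ValueError(f"unknown threshold scale {scale!r}")

    out = []
    for r in results:
        enriched = NEITHER
        if math.isfinite(r.log2fc) and math.isfinite(r.p_value) and r.p_value < p_threshold:
            if r.log2fc > log2_cut:
                enriched = "a"
            elif -r.log2fc > log2_cut:
                enriched = "b"
        out.append(replace(r, enriched_in=enriched))
    return out


def write_comparisons(results: Sequence[ComparisonResult], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("protein\tgroup_a\tgroup_b\tlog2fc\tp_value\tn_a\tn_b\tenriched_in\n")
        for r in results:
            fh.write(
                f"{r.protein}\t{r.group_a}\t{r.group_b}\t{r.log2fc:.10g}\t"
                f"{r.p_value:.10g}\t{r.n_a}\t{r.n_b}\t{r.enriched_in}\n"
            )


@dataclass
class Dendrogram:
    """Agglomerative merge history plus a deterministic leaf order.

    ``merges`` is the usual linkage matrix: row k merges clusters
    ``merges[k, 0]`` and ``merges[k, 1]`` at height ``merges[k, 2]``
    (cluster ids >= n refer to earlier merges).
    """

    merges: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, height: float) -> dict[str, int]:
        """Flat partition: label -> cluster id for merges at or below height."""
        n = len(self.labels)
        parent = list(range(2 * n - 1))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for k, (i, j, h, _) in enumerate(self.merges):
            if h <= height:
                parent[find(int(i))] = n + k
                parent[find(int(j))] = n + k
        roots = {}
        out = {}
        for idx, lab in enumerate(self.labels):
            r = find(idx)
            out[lab] = roots.setdefault(r, len(roots))
        return out

    def to_newick(self) -> str:
        """Newick export with branch lengths from merge-height differences."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}

        def node(idx: int) -> str:
            if idx < n:
                return self.labels[idx]
            i, j, h, _ = self.merges[idx - n]
            children = sorted(
                (int(i), int(j)), key=lambda c: (_cluster_size(self.merges, n, c), _min_leaf(self.merges, n, c))
            )
            parts = [
                f"{node(c)}:{h - height[c]:.6g}" for c in children
            ]
            height[idx] = h
            return "(" + ",".join(parts) + ")"

        for k, row in enumerate(self.merges):
            height[n + k] = row[2]
        return node(2 * n - 2) + ";"


def _cluster_size(merges: np.ndarray, n: int, idx: int) -> int:
    if idx < n:
        return 1
    return int(merges[idx - n, 3])


def _min_leaf(merges: np.ndarray, n: int, idx: int) -> int:
    if idx < n:
        return idx
    i, j = int(merges[idx - n, 0]), int(merges[idx - n, 1])
    return min(_min_leaf(merges, n, i), _min_leaf(merges, n, j))


def _leaf_order(merges: np.ndarray, n: int) -> list[int]:
    """Recursive traversal, smaller cluster first; ties to lower leaf index."""

    def walk(idx: int) -> list[int]:
        if idx < n:
            return [idx]
        i, j = int(merges[idx - n, 0]), int(merges[idx - n, 1])
        first, second = sorted(
            (i, j), key=lambda c: (_cluster_size(merges, n, c), _min_leaf(merges, n, c))
        )
        return walk(first) + walk(second)

    return walk(2 * n - 2)


def cluster_rows(
    matrix: AbundanceMatrix, metric: str = "euclidean", method: str = "complete"
) -> Dendrogram:
    """Hierarchically cluster Z-scored rows.

    Rows containing missing cells are excluded (and logged); at least two
    usable rows are required. Merge heights are non-decreasing for the
    default complete linkage.
    """
    matrix.require_stage("zscore")
    usable = matrix.values.dropna(axis=0)
    dropped = len(matrix.values) - len(usable)
    if dropped:
        logger.info("cluster_rows excluded %d rows with missing cells", dropped)
    if len(usable) < 2:
        raise ValueError("clustering needs at least 2 complete rows")
    dist = pdist(usable.to_numpy(dtype=float), metric=metric)
    merges = scipy_linkage(dist, method=method)
    labels = [str(i) for i in usable.index]
    order = _leaf_order(merges, len(labels))
    return Dendrogram(
        merges=merges, labels=labels, leaf_order=[labels[i] for i in order]
    )
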