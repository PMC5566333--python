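"""Global quantitative similarity of runs: pairwise Pearson correlation of
log2 protein abundances and hierarchical clustering.

Correlations are pairwise-complete (each run pair uses its common proteins);
clustering uses Euclidean distance with complete linkage on the
complete-case protein subset, the default behaviour of the R dist/hclust
functions this analysis is conventionally run with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "pearson_matrix",
    "CorrelationMatrix",
    "hierarchical_cluster",
    "Dendrogram",
    "similarity_summary",
    "cluster_purity",
]


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # run x run Pearson coefficients
    n_common: pd.DataFrame  # proteins shared per pair
    excluded_runs: list[str]

    @property
    def median(self) -> float:
        return float(self._offdiag().median())

    @property
    def minimum(self) -> float:
        return float(self._offdiag().min())

    def _offdiag(self) -> pd.Series:
        vals = self.r.to_numpy(float)
        iu = np.triu_indices_from(vals, k=1)
        return pd.Series(vals[iu]).dropna()


def pearson_matrix(log2_matrix: pd.DataFrame, min_common: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between runs (columns).

    Pairs sharing fewer than ``min_common`` proteins are NaN; runs with no
    present protein are excluded entirely.
    """
    present = log2_matrix.notna().sum(axis=0)
    excluded = [c for c in log2_matrix.columns if present[c] < 1]
    mat = log2_matrix.drop(columns=excluded)
    r = mat.corr(method="pearson", min_periods=max(min_common, 2))
    notna = mat.notna().astype(int)
    n_common = pd.DataFrame(notna.T.to_numpy() @ notna.to_numpy(), index=mat.columns, columns=mat.columns)
    r = r.where(n_common >= min_common)
    np.fill_diagonal(r.to_numpy(), 1.0)
    return CorrelationMatrix(r=r, n_common=n_common, excluded_runs=excluded)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over runs with merge heights."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> pd.Series:
        """Assignments from cutting into ``k`` flat clusters."""
        return pd.Series(fcluster(self.linkage_matrix, k, criterion="maxclust"), index=self.labels)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.labels[i]
            a, b, h, _ = self.linkage_matrix[i - n]
            a, b = int(a), int(b)
            return (
                f"({node(a)}:{heights[i] - heights[a]:.10g},"
                f"{node(b)}:{heights[i] - heights[b]:.10g})"
            )

        for row_i, (_, _, h, _) in enumerate(self.linkage_matrix):
            heights[n + row_i] = float(h)
        return node(2 * n - 2) + ";"


def hierarchical_cluster(
    log2_matrix: pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
    missing: str = "complete-case",
) -> Dendrogram:
    """Cluster runs on their log2 protein profiles.

    ``missing='complete-case'`` restricts to proteins observed in every run
    (how missing cells enter R's dist is otherwise undefined);
    ``'median-impute'`` fills each protein's missing cells with its row
    median instead. Columns are processed in sorted run-id order so merges
    are deterministic under input permutation.
    """
    if log2_matrix.shape[1] < 2:
        raise ValueError("need at least two runs to cluster")
    mat = log2_matrix[sorted(log2_matrix.columns)]
    if missing == "complete-case":
        mat = mat.dropna(axis=0)
        if mat.empty:
            raise ValueError("no complete-case proteins; consider missing='median-impute'")
    elif missing == "median-impute":
        mat = mat.apply(lambda row: row.fillna(row.median()), axis=1)
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    dist = pdist(mat.to_numpy(float).T, metric=metric)
    Z = linkage(dist, method=method)
    return Dendrogram(linkage_matrix=Z, labels=list(mat.columns))


def similarity_summary(corr: CorrelationMatrix, site_of_run: pd.Series) -> dict:
    """Within-site vs between-site Pearson medians.

    Returns the per-site medians, their range, the pooled within-site
    median, and the between-site median.
    """
    runs = list(corr.r.columns)
    vals = corr.r.to_numpy(float)
    within, between = [], []
    per_site: dict[str, list[float]] = {}
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            v = vals[i, j]
            if not np.isfinite(v):
                continue
            si, sj = site_of_run[runs[i]], site_of_run[runs[j]]
            if si == sj:
                within.append(v)
                per_site.setdefault(si, []).append(v)
            else:
                between.append(v)
    site_medians = {s: float(np.median(v)) for s, v in sorted(per_site.items())}
    return {
        "median_all": corr.median,
        "minimum": corr.minimum,
        "median_within_site": float(np.median(within)) if within else float("nan"),
        "median_between_site": float(np.median(between)) if between else float("nan"),
        "site_medians": site_medians,
        "site_median_range": (
            (min(site_medians.values()), max(site_medians.values())) if site_medians else (float("nan"),) * 2
        ),
    }


def cluster_purity(assignments: pd.Series, true_labels: pd.Series) -> float:
    """Fraction of runs whose cluster's majority label matches their own."""
    df = pd.DataFrame({"cluster": assignments, "label": true_labels.reindex(assignments.index)})
    correct = 0
    for _, grp in df.groupby("cluster"):
        correct += grp["label"].value_counts().iloc[0]
    return correct / len(df)
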