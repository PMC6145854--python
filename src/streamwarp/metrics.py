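"""Connectome comparison machinery: similarity, network metrics, effect
sizes, and cohort pairwise analysis.

The generalized Jaccard distance between two count matrices N, T is

    D_j = 1 - sum_i min(N_i, T_i) / sum_i max(N_i, T_i)

over the flattened upper triangles: 0 means identical connectivity, 1
disjoint support; it is a true metric (triangle inequality included).

Graph metrics follow the binary-edge formulas used for structural brain
networks: an edge exists wherever the count is nonzero, node degree is the
number of incident edges, average degree <k> = 2E/N, density
D = 2E/(N(N-1)) (so <k> = (N-1) D identically), and assortativity is the
Pearson degree-degree correlation over edges

    A = [E^-1 sum j_i k_i - (E^-1 sum (j_i + k_i)/2)^2]
        / [E^-1 sum (j_i^2 + k_i^2)/2 - (E^-1 sum (j_i + k_i)/2)^2]

with (j_i, k_i) the endpoint degrees of edge i.  A is undefined (returned
as None, never silently 0) when every node has the same degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .core import StreamwarpError

__all__ = [
    "MetricRecord",
    "generalized_jaccard_distance",
    "average_degree",
    "density",
    "assortativity",
    "network_metrics",
    "glass_delta",
    "cohort_pairwise_analysis",
]

METRIC_NAMES = ("average_degree", "density", "assortativity")


def _counts(M) -> np.ndarray:
    if isinstance(M, ConnectivityMatrix):
        return M.counts
    arr = np.asarray(M)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {arr.shape}")
    return arr


def _upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def generalized_jaccard_distance(Nmat, Tmat) -> float:
    """Weighted Jaccard distance between two connectivity matrices.

    Computed over the flattened upper triangles (diagonal excluded; for
    symmetric matrices including both triangles would change nothing).
    Raises when both matrices are all-zero (the ratio is undefined) or the
    shapes/node sets differ.
    """
    A, B = _counts(Nmat), _counts(Tmat)
    if A.shape != B.shape:
        raise StreamwarpError(f"matrix shapes differ: {A.shape} vs {B.shape}")
    if isinstance(Nmat, ConnectivityMatrix) and isinstance(Tmat, ConnectivityMatrix):
        if not np.array_equal(Nmat.node_ids, Tmat.node_ids):
            raise StreamwarpError("matrices are over different node sets")
    a, b = _upper(A), _upper(B)
    denom = np.maximum(a, b).sum()
    if denom == 0:
        raise StreamwarpError(
            "Jaccard distance undefined: both matrices are all-zero"
        )
    return float(1.0 - np.minimum(a, b).sum() / denom)


def _binary_graph(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(adjacency bool, integer degrees) of the binarized network."""
    adj = _counts(M) != 0
    np.fill_diagonal(adj, False)
    return adj, adj.sum(axis=0).astype(np.int64)


def average_degree(M) -> float:
    """Mean binary degree <k> = 2E/N; E counts nonzero upper-tri edges."""
    adj, deg = _binary_graph(M)
    n = adj.shape[0]
    if n == 0:
        raise StreamwarpError("average degree undefined for an empty network")
    return 2.0 * _upper(adj).sum() / n


def density(M) -> float:
    """Fraction of possible edges present: D = 2E/(N(N-1))."""
    adj, _ = _binary_graph(M)
    n = adj.shape[0]
    if n < 2:
        raise StreamwarpError("density needs at least 2 nodes")
    return 2.0 * _upper(adj).sum() / (n * (n - 1))


def assortativity(M) -> float | None:
    """Degree assortativity over the E undirected edges; None if undefined.

    Evaluates the Pearson-correlation form with binary degrees.  Returns
    None (an explicit undefined flag) when the denominator vanishes, i.e.
    the graph is regular; raises when there are no edges at all.
    """
    adj, deg = _binary_graph(M)
    ii, jj = np.triu_indices(adj.shape[0], k=1)
    mask = adj[ii, jj]
    if not mask.any():
        raise StreamwarpError("assortativity undefined: network has no edges")
    j, k = deg[ii[mask]].astype(float), deg[jj[mask]].astype(float)
    m_jk = np.mean(j * k)
    m_sum = np.mean(0.5 * (j + k))
    m_sq = np.mean(0.5 * (j ** 2 + k ** 2))
    denom = m_sq - m_sum ** 2
    if np.isclose(denom, 0.0, atol=1e-12):
        return None
    return float((m_jk - m_sum ** 2) / denom)


@dataclass
class MetricRecord:
    """Binary network metrics of one connectivity matrix."""

    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    assortativity: float | None

    @property
    def assortativity_defined(self) -> bool:
        return self.assortativity is not None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_degree": self.average_degree,
            "density": self.density,
            "assortativity": self.assortativity,
            "assortativity_defined": self.assortativity_defined,
        }


def network_metrics(M) -> MetricRecord:
    adj, _ = _binary_graph(M)
    n = adj.shape[0]
    e = int(_upper(adj).sum())
    try:
        assort = assortativity(M) if e else None
    except StreamwarpError:
        assort = None
    return MetricRecord(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n if n else 0.0,
        density=2.0 * e / (n * (n - 1)) if n >= 2 else 0.0,
        assortativity=assort,
    )


def glass_delta(native_values, template_values) -> float:
    """Glass's delta: (mean_N - mean_T) / sd_N, sd from the native group
    only (sample sd, n-1 denominator)."""
    nat = np.asarray(native_values, dtype=float)
    tem = np.asarray(template_values, dtype=float)
    if nat.size < 2:
        raise StreamwarpError("Glass's delta needs >= 2 native values")
    s = nat.std(ddof=1)
    if s == 0:
        raise StreamwarpError(
            "Glass's delta undefined: native group has zero variance"
        )
    return float((nat.mean() - tem.mean()) / s)


def _pair_metric_frame(matrices: Mapping[str, ConnectivityMatrix],
                       pairs: Sequence[tuple[str, str, str]]) -> pd.DataFrame:
    records = []
    cache: dict[str, MetricRecord] = {}

    def rec(subject: str) -> MetricRecord:
        if subject not in matrices:
            raise StreamwarpError(f"unknown subject {subject!r}")
        if subject not in cache:
            cache[subject] = network_metrics(matrices[subject])
        return cache[subject]

    for sa, sb, pair_type in pairs:
        ra, rb = rec(sa), rec(sb)
        row = {
            "subject_a": sa,
            "subject_b": sb,
            "pair_type": pair_type,
            "jaccard_distance": generalized_jaccard_distance(
                matrices[sa], matrices[sb]),
        }
        for name in METRIC_NAMES:
            va, vb = getattr(ra, name), getattr(rb, name)
            row[f"{name}_a"] = np.nan if va is None else va
            row[f"{name}_b"] = np.nan if vb is None else vb
        records.append(row)
    return pd.DataFrame.from_records(records)


def cohort_pairwise_analysis(
    matrices: Mapping[str, ConnectivityMatrix],
    pairs: Sequence[tuple[str, str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise similarity and metric concordance across a cohort.

    ``pairs`` lists (subject_a, subject_b, pair_type) with pair types such
    as identical / fraternal / nontwin_sibling / unrelated.  Returns

    * a per-pair table: Jaccard distance plus both members' metric values;
    * a per-group summary: pair count, mean and SD of the distance, and
      for each metric the Pearson correlation r between members across the
      group's pairs together with r**2.  Groups with fewer than two pairs
      (or a constant metric) leave the correlation undefined (NaN).

    Output is deterministic given the input order.
    """
    table = _pair_metric_frame(matrices, pairs)
    summaries = []
    for pair_type, grp in table.groupby("pair_type", sort=False):
        row = {
            "pair_type": pair_type,
            "n_pairs": len(grp),
            "distance_mean": grp["jaccard_distance"].mean(),
            "distance_sd": grp["jaccard_distance"].std(ddof=1),
        }
        for name in METRIC_NAMES:
            a = grp[f"{name}_a"].to_numpy(dtype=float)
            b = grp[f"{name}_b"].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            r = np.nan
            if ok.sum() >= 2 and a[ok].std() > 0 and b[ok].std() > 0:
                r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            row[f"{name}_r"] = r
            row[f"{name}_r2"] = r ** 2 if np.isfinite(r) else np.nan
        summaries.append(row)
    return table, pd.DataFrame.from_records(summaries)
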