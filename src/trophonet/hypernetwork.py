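"""Hypernetwork analysis of interface-gene co-expression.

A hypernetwork summarizes how strongly a set of interface genes is coupled
to the rest of the transcriptome.  For interface genes S and transcriptome
T, a correlation matrix r (|S| x |T|) is binarized against the spread of
its own r-value distribution (entries further than ``sd_multiplier``
standard deviations from the mean r, both tails, become 1) giving the
incidence matrix M.  H = M @ M.T then counts, for every pair of interface
genes, the transcriptome genes they are both strongly correlated with
("shared correlations").  Hierarchical clustering of H exposes a central
cluster of highly inter-connected genes, whose

* connectivity — the off-diagonal H values over within-cluster pairs — and
* organization — Shannon entropy of the normalized within-cluster pair
  weights (low entropy = weight concentrated on few pairs = more organized)

are compared against a permutation null built by redrawing random gene
sets of the same size and re-running the identical pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationIncidence",
    "Hypernetwork",
    "NetworkMetrics",
    "NullDistribution",
    "correlation_incidence",
    "binarize",
    "build_hypernetwork",
    "extract_central_cluster",
    "connectivity",
    "cluster_entropy",
    "connected_gene_set",
    "permutation_null",
    "rank_sum_compare",
    "analyze_subset",
]


@dataclass
class CorrelationIncidence:
    """Correlation of each interface gene against the whole transcriptome.

    ``r_matrix`` is interface genes x transcriptome genes; ``mean_r`` and
    ``sd_r`` are computed over all retained entries excluding self-pairs
    (an interface gene against its own transcriptome column).
    """

    r_matrix: pd.DataFrame
    mean_r: float
    sd_r: float
    method: str


@dataclass
class Hypernetwork:
    M: pd.DataFrame  # binary incidence, interface x transcriptome
    H: pd.DataFrame  # shared-correlation counts, interface x interface
    row_order: list[str] = field(default_factory=list)
    central_cluster: list[str] = field(default_factory=list)


@dataclass
class NetworkMetrics:
    connectivity_values: np.ndarray
    mean_connectivity: float
    entropy_bits: float
    relative_entropy: float | None
    connected_gene_set: list[str]


@dataclass
class NullDistribution:
    n_permutations: int
    seed: int
    set_size: int
    connectivity_samples: np.ndarray
    entropy_samples: np.ndarray


def correlation_incidence(
    interface_genes: list[str],
    matrix: ExpressionMatrix,
    cells: list[str] | None = None,
    method: str = "pearson",
    *,
    log_transform: bool = True,
) -> CorrelationIncidence:
    """Correlate each interface gene with every transcriptome gene.

    Pearson on log(1+x)-transformed expression by default (Spearman
    available).  Genes with zero variance over the selected cells are
    excluded from the transcriptome axis (and rejected on the interface
    axis) with a warning.  Requires >=3 cells.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    sub = matrix.subset_obs(cells) if cells is not None else matrix
    if sub.n_obs < 3:
        raise ValidationError(f"need >=3 cells, got {sub.n_obs}")
    missing = [g for g in interface_genes if g not in sub.values.index]
    if missing:
        raise ValidationError(f"interface genes absent from matrix: {missing[:5]}")

    x = sub.values.to_numpy(dtype=float)
    if log_transform:
        x = np.log1p(x)
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)

    sd = x.std(axis=1)
    keep = sd > 0
    dropped_ifc = [g for g, k in zip(sub.values.index, keep) if not k and g in set(interface_genes)]
    if dropped_ifc:
        logger.warning("zero-variance interface genes excluded: %s", dropped_ifc[:5])
    genes_kept = sub.values.index[keep]
    interface_kept = [g for g in interface_genes if g in set(genes_kept)]
    if not interface_kept:
        raise ValidationError("no interface gene with nonzero variance")

    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    zdf = pd.DataFrame(z, index=genes_kept)
    zi = zdf.loc[interface_kept].to_numpy()
    r = (zi @ zdf.to_numpy().T) / x.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    r_df = pd.DataFrame(r, index=interface_kept, columns=genes_kept)

    mask = np.ones(r.shape, dtype=bool)  # self-pairs excluded from mean/sd
    col_pos = {g: j for j, g in enumerate(genes_kept)}
    for i, g in enumerate(interface_kept):
        mask[i, col_pos[g]] = False
    vals = r[mask]
    return CorrelationIncidence(r_df, float(vals.mean()), float(vals.std()), method)


def binarize(ci: CorrelationIncidence, sd_multiplier: float = 1.0) -> pd.DataFrame:
    """Threshold |r - mean_r| > sd_multiplier * sd_r (both tails) to {0,1}.

    Self-pairs are forced to 0 so a gene cannot share itself as a
    connection.  A degenerate r distribution (sd_r = 0) yields an all-zero
    incidence with a warning.
    """
    if sd_multiplier <= 0:
        raise ValidationError("sd_multiplier must be > 0")
    if ci.sd_r == 0:
        logger.warning("sd of r-values is 0; incidence matrix is all zeros")
        return pd.DataFrame(
            np.zeros(ci.r_matrix.shape, dtype=np.int8),
            index=ci.r_matrix.index,
            columns=ci.r_matrix.columns,
        )
    m = (np.abs(ci.r_matrix.to_numpy() - ci.mean_r) > sd_multiplier * ci.sd_r).astype(np.int8)
    col_pos = {g: j for j, g in enumerate(ci.r_matrix.columns)}
    for i, g in enumerate(ci.r_matrix.index):
        j = col_pos.get(g)
        if j is not None:
            m[i, j] = 0
    return pd.DataFrame(m, index=ci.r_matrix.index, columns=ci.r_matrix.columns)


def build_hypernetwork(M: pd.DataFrame) -> Hypernetwork:
    """H = M @ M.T plus a hierarchical-clustering row order for display."""
    if M.size == 0:
        raise ValidationError("empty incidence matrix")
    arr = M.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("incidence matrix must be binary")
    h = arr.astype(np.int64) @ arr.astype(np.int64).T
    H = pd.DataFrame(h, index=M.index, columns=M.index)
    order = list(M.index)
    if len(order) > 1:
        d = pdist(h.astype(float))
        if d.max() == 0:
            pass  # identical rows: keep input order
        else:
            link = hierarchy.linkage(d, method="average")
            order = [M.index[i] for i in hierarchy.leaves_list(link)]
    return Hypernetwork(M, H, row_order=order)


def extract_central_cluster(hn: Hypernetwork) -> list[str]:
    """Two-way cut of the average-linkage tree over H rows; denser branch wins.

    The branch with the higher mean off-diagonal H value within it is the
    central cluster.  Ties go to the larger branch, then to the branch whose
    lexicographically smallest member sorts first.  All-zero H returns an
    empty cluster with a warning.
    """
    genes = list(hn.H.index)
    if len(genes) < 2:
        raise ValidationError("need >=2 interface genes to cluster")
    h = hn.H.to_numpy().astype(float)
    if not h.any():
        logger.warning("all-zero hypernetwork; no central cluster")
        hn.central_cluster = []
        return []
    d = pdist(h)
    if d.max() == 0:
        # identical rows: the whole set is one cluster
        hn.central_cluster = list(genes)
        return list(genes)
    link = hierarchy.linkage(d, method="average")
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")

    def branch_stats(lab: int) -> tuple[float, int, str]:
        idx = np.flatnonzero(labels == lab)
        members = [genes[i] for i in idx]
        if len(idx) < 2:
            mean_od = -np.inf
        else:
            block = h[np.ix_(idx, idx)]
            od = block[~np.eye(len(idx), dtype=bool)]
            mean_od = float(od.mean())
        return mean_od, len(idx), min(members)

    best = None
    for lab in np.unique(labels):
        mean_od, size, first = branch_stats(lab)
        key = (mean_od, size, _NegStr(first))
        if best is None or key > best[0]:
            best = (key, lab)
    cluster = [g for g, l in zip(genes, labels) if l == best[1]]
    hn.central_cluster = cluster
    return cluster


class _NegStr(str):
    """Reverses string comparison so max() prefers the smallest name."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def connectivity(hn: Hypernetwork, cluster: list[str]) -> tuple[np.ndarray, float]:
    """Off-diagonal H values over unordered within-cluster pairs, plus mean."""
    if len(cluster) < 2:
        raise ValidationError("cluster must contain >=2 genes")
    block = hn.H.loc[cluster, cluster].to_numpy()
    iu = np.triu_indices(len(cluster), k=1)
    vals = block[iu].astype(float)
    return vals, float(vals.mean())


def cluster_entropy(hn: Hypernetwork, cluster: list[str]) -> float:
    """Shannon entropy (bits) of normalized within-cluster pair weights.

    Pair weights are the off-diagonal H entries; zero-weight pairs
    contribute nothing.  Returns NaN (not applicable) when the total
    within-cluster weight is zero.
    """
    vals, _ = connectivity(hn, cluster)
    total = vals.sum()
    if total == 0:
        logger.warning("zero within-cluster weight; entropy undefined")
        return float("nan")
    p = vals[vals > 0] / total
    return float(-(p * np.log2(p)).sum())


def connected_gene_set(
    hn: Hypernetwork, cluster: list[str], *, require_all: bool = False
) -> list[str]:
    """Transcriptome genes linked to the central cluster.

    By default a gene qualifies if it is incident to at least one cluster
    gene; ``require_all=True`` demands incidence to every cluster gene.
    """
    if not cluster:
        return []
    block = hn.M.loc[cluster].to_numpy()
    hit = block.all(axis=0) if require_all else block.any(axis=0)
    return [g for g, h in zip(hn.M.columns, hit) if h]


def analyze_subset(
    interface_genes: list[str],
    matrix: ExpressionMatrix,
    cells: list[str] | None = None,
    *,
    method: str = "pearson",
    sd_multiplier: float = 1.0,
    log_transform: bool = True,
) -> tuple[Hypernetwork, np.ndarray, float, float]:
    """Correlate -> binarize -> hypernetwork -> central cluster -> metrics.

    Returns (hypernetwork, connectivity values, mean connectivity,
    entropy in bits).  This is the unit of work repeated verbatim inside
    the permutation null.
    """
    ci = correlation_incidence(interface_genes, matrix, cells, method, log_transform=log_transform)
    m = binarize(ci, sd_multiplier)
    hn = build_hypernetwork(m)
    cluster = extract_central_cluster(hn)
    if len(cluster) < 2:
        return hn, np.array([]), float("nan"), float("nan")
    vals, mean_c = connectivity(hn, cluster)
    ent = cluster_entropy(hn, cluster)
    return hn, vals, mean_c, ent


def permutation_null(
    matrix: ExpressionMatrix,
    cells: list[str] | None,
    set_size: int,
    n_permutations: int = 1000,
    seed: int = 0,
    *,
    method: str = "pearson",
    sd_multiplier: float = 1.0,
    log_transform: bool = True,
) -> NullDistribution:
    """Null connectivity/entropy from random gene sets of the same size.

    Each permutation draws ``set_size`` genes uniformly without replacement
    from the eligible (nonzero-variance) transcriptome and runs the whole
    pipeline including central-cluster extraction, so null and observed
    metrics are computed identically.  Fully reproducible from ``seed``.
    """
    if n_permutations < 1:
        logger.warning("n_permutations < 1; returning empty null")
        return NullDistribution(0, seed, set_size, np.array([]), np.array([]))
    sub = matrix.subset_obs(cells) if cells is not None else matrix
    x = np.log1p(sub.values.to_numpy(dtype=float)) if log_transform else sub.values.to_numpy()
    eligible = list(sub.values.index[x.std(axis=1) > 0])
    if set_size > len(eligible):
        raise ValidationError(
            f"set_size {set_size} exceeds {len(eligible)} eligible genes"
        )
    rng = np.random.default_rng(seed)
    conn, ent = [], []
    for _ in range(n_permutations):
        draw = [eligible[i] for i in rng.choice(len(eligible), size=set_size, replace=False)]
        _, _, mean_c, e = analyze_subset(
            draw, sub, None, method=method, sd_multiplier=sd_multiplier,
            log_transform=log_transform,
        )
        conn.append(mean_c)
        ent.append(e)
    return NullDistribution(
        n_permutations, seed, set_size, np.asarray(conn), np.asarray(ent)
    )


def rank_sum_compare(values_a, values_b) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of all group assignments when n_a + n_b <= 12 and
    there are no ties; otherwise the normal approximation with tie
    correction and continuity correction.  Returns (p, direction) where
    direction is "a_greater", "b_greater" or "equal" by rank-sum.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = ranks[:na].sum() - na * (na + 1) / 2  # Mann-Whitney U for sample a
    mu = na * nb / 2
    direction = "a_greater" if u_a > mu else ("b_greater" if u_a < mu else "equal")

    no_ties = np.unique(pooled).size == pooled.size
    if na + nb <= 12 and no_ties:
        from itertools import combinations

        order = np.argsort(pooled)
        rank_vals = np.empty_like(order, dtype=float)
        rank_vals[order] = np.arange(1, na + nb + 1)
        dev_obs = abs(u_a - mu)
        count = 0
        total = 0
        for comb in combinations(range(na + nb), na):
            u = rank_vals[list(comb)].sum() - na * (na + 1) / 2
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return count / total, direction

    n = na + nb
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = ((t_counts**3 - t_counts).sum()) / (n * (n - 1))
    var = na * nb / 12 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0, direction
    z = (abs(u_a - mu) - 0.5) / np.sqrt(var)  # continuity-corrected
    p = 2 * stats.norm.sf(max(z, 0.0))
    return float(min(p, 1.0)), direction
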