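"""Construction of the in-silico TE-EEC implantation interface.

The interface is built in four steps mirroring how a receptive uterus
presents candidate ligands to the embryo:

1. one-way ANOVA between non-receptive (proliferative) and receptive
   (mid-secretory) endometrial epithelium identifies receptivity DEGs
   (strict p < alpha, uncorrected);
2. DEGs are refined to gene products localized to the cell surface or
   extracellular space, since only those can engage the trophectoderm;
3. protein-protein interaction partners of those genes are mapped to
   candidate trophectoderm (TE) binding partners, self-symbol pairs
   permitted;
4. candidate TE partners are refined to those localized as above and
   detected in the Day 6 TE single-cell transcriptomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    InteractionGraph,
    InterfaceTable,
    LocalizationTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LOCALIZATION_TERMS",
    "CandidatePair",
    "differential_expression",
    "filter_by_localization",
    "map_binding_partners",
    "filter_expressed",
    "summarize_interface",
    "build_interface",
]

#: Localization terms admitting a gene product to the cell-cell interface.
DEFAULT_LOCALIZATION_TERMS = frozenset(
    {
        "extracellular space",
        "extracellular matrix",
        "proteinaceous extracellular matrix",
        "cell surface",
    }
)


@dataclass(frozen=True)
class CandidatePair:
    """An EEC gene and a candidate cognate TE binding partner."""

    eec_gene: str
    te_gene: str
    source: str = "edge"  # "self" when both sides carry the same symbol


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
    *,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA between two observation groups.

    Returns a DataFrame indexed by gene with columns ``f_statistic``,
    ``p_value``, ``mean_<group>`` for each group, ``significant`` (strict
    p < alpha, uncorrected) and ``degenerate`` (zero variance both within
    and between groups: flagged, F reported as 0, not significant).

    Genes with zero within-group variance but distinct group means are the
    F -> infinity limit; they are flagged significant with p reported as 0
    (below machine epsilon).  Expression is log(1+x)-transformed by default
    so the F-test operates on roughly homoscedastic values.
    """
    if matrix.obs_groups is None:
        raise ValidationError("matrix has no group labels")
    obs_a = matrix.obs_in_group(group_a)
    obs_b = matrix.obs_in_group(group_b)
    if len(obs_a) < 2 or len(obs_b) < 2:
        raise ValidationError(
            f"each group needs >=2 observations (got {len(obs_a)} and {len(obs_b)})"
        )
    xa = matrix.values[obs_a].to_numpy(dtype=float)
    xb = matrix.values[obs_b].to_numpy(dtype=float)
    if log_transform:
        xa, xb = np.log1p(xa), np.log1p(xb)
    na, nb = xa.shape[1], xb.shape[1]
    n = na + nb
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    grand = (na * ma + nb * mb) / n
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    dfb, dfw = 1, n - 2
    msb = ssb / dfb
    msw = ssw / dfw

    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    degenerate = (ssw == 0) & (ssb == 0)
    forced = (ssw == 0) & (ssb > 0)
    f = np.where(degenerate, 0.0, f)
    f = np.where(forced, np.inf, f)
    p = np.empty_like(f)
    finite = np.isfinite(f)
    p[finite] = stats.f.sf(f[finite], dfb, dfw)
    p[forced] = 0.0
    p[degenerate] = 1.0

    out = pd.DataFrame(
        {
            "f_statistic": f,
            "p_value": p,
            f"mean_{group_a}": ma,
            f"mean_{group_b}": mb,
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    out["significant"] = (out["p_value"] < alpha) & ~out["degenerate"]
    return out


def filter_by_localization(
    genes: list[str],
    table: LocalizationTable,
    allowed: frozenset[str] | set[str] = DEFAULT_LOCALIZATION_TERMS,
) -> list[str]:
    """Retain genes whose localization terms intersect ``allowed``; order kept."""
    if not allowed:
        raise ValidationError("allowed localization term set must be nonempty")
    allowed = set(allowed)
    return [g for g in genes if table.terms(g) & allowed]


def map_binding_partners(
    eec_genes: list[str], graph: InteractionGraph
) -> list[CandidatePair]:
    """All interaction partners of each EEC gene become candidate TE partners.

    One-to-many mappings are retained; a self-loop yields a same-symbol pair.
    EEC genes absent from the graph contribute nothing (logged).
    """
    pairs: list[CandidatePair] = []
    for eec in eec_genes:
        if eec not in graph:
            logger.warning("EEC gene %s absent from interaction graph", eec)
            continue
        for te in sorted(graph.partners(eec)):
            pairs.append(CandidatePair(eec, te, "self" if te == eec else "edge"))
    return pairs


def filter_expressed(
    pairs: list[CandidatePair],
    te_matrix: ExpressionMatrix,
    min_fraction: float = 0.1,
) -> InterfaceTable:
    """Retain pairs whose TE partner is detected (value > 0) in enough cells.

    ``min_fraction`` is the minimum fraction of TE cells with nonzero
    expression.  Partners absent from the matrix are dropped and logged.
    Returns an interface table with membership/classifier fields ``pending``.
    """
    if not 0 <= min_fraction <= 1:
        raise ValidationError("min_fraction must lie in [0, 1]")
    frac = (te_matrix.values > 0).mean(axis=1)
    kept, seen = [], set()
    for pair in pairs:
        if pair.te_gene not in frac.index:
            logger.warning("TE partner %s absent from TE matrix; dropped", pair.te_gene)
            continue
        key = (pair.eec_gene, pair.te_gene)
        if key in seen:
            continue
        if frac.loc[pair.te_gene] >= min_fraction:
            seen.add(key)
            kept.append(key)
    rows = pd.DataFrame(kept, columns=["eec_gene", "te_gene"])
    rows["cluster_membership"] = "pending"
    rows["classifier_status"] = "pending"
    return InterfaceTable(rows)


def summarize_interface(table: InterfaceTable) -> dict:
    """Row counts by cluster membership and classifier status.

    ``classifier_percent`` is yes / (yes + no) x 100 over the determined
    rows; ``None`` when no row was determined.
    """
    if len(table) == 0:
        raise ValidationError("interface table is empty")
    cm = table.rows["cluster_membership"].value_counts().to_dict()
    cs = table.rows["classifier_status"].value_counts().to_dict()
    n_yes, n_no = cs.get("yes", 0), cs.get("no", 0)
    pct = 100.0 * n_yes / (n_yes + n_no) if (n_yes + n_no) else None
    return {
        "n_rows": len(table),
        "cluster_membership": cm,
        "classifier_status": cs,
        "classifier_percent": pct,
    }


def build_interface(
    eec_matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    localization: LocalizationTable,
    graph: InteractionGraph,
    te_matrix: ExpressionMatrix,
    *,
    alpha: float = 0.01,
    allowed_terms: frozenset[str] | set[str] = DEFAULT_LOCALIZATION_TERMS,
    min_fraction: float = 0.1,
) -> InterfaceTable:
    """Full interface construction: DEGs -> localization -> partners -> TE expression.

    The localization refinement is applied on both sides of the interface
    with the same term set.
    """
    deg = differential_expression(eec_matrix, group_a, group_b, alpha)
    deg_genes = list(deg.index[deg["significant"]])
    surface = filter_by_localization(deg_genes, localization, allowed_terms)
    candidates = map_binding_partners(surface, graph)
    localized = {
        c.te_gene
        for c in candidates
        if localization.terms(c.te_gene) & set(allowed_terms)
    }
    candidates = [c for c in candidates if c.te_gene in localized]
    return filter_expressed(candidates, te_matrix, min_fraction)
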