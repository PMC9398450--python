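"""Signed-log display transform for RNA velocity and the clustered heatmap.

Velocity estimation itself (spliced/unspliced dynamics) is consumed, not
computed.  For display, per-gene per-cell velocities v are compressed with
the odd transform f(v) = sign(v) * ln(1 + |v|), which preserves the sign
and order of velocities while taming large magnitudes, and genes are
ordered by hierarchical clustering of their transformed profiles with cell
columns grouped by blastocyst day and TE subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ValidationError

__all__ = ["VelocityMatrix", "signed_log_velocity", "velocity_heatmap"]


@dataclass
class VelocityMatrix:
    """Signed velocities, genes x cells, with per-cell day and subset labels."""

    values: pd.DataFrame
    cell_day: pd.Series
    cell_subset: pd.Series

    def __post_init__(self) -> None:
        self.cell_day = pd.Series(self.cell_day)
        self.cell_subset = pd.Series(self.cell_subset)
        for lab, name in ((self.cell_day, "cell_day"), (self.cell_subset, "cell_subset")):
            if list(lab.index) != list(self.values.columns):
                if set(lab.index) != set(self.values.columns):
                    raise ValidationError(f"{name} labels do not match cells")
        self.cell_day = self.cell_day.loc[self.values.columns]
        self.cell_subset = self.cell_subset.loc[self.values.columns]


def signed_log_velocity(v, *, literal: bool = False):
    """sign(v) * ln(1 + |v|), elementwise; 0 maps to 0.

    Continuous extension of (v/|v|) * ln(1+|v|) at the origin.  With
    ``literal=True`` the inflating product form v * |v| * ln(1+|v|) is
    used instead (kept for comparison; not a display transform).  Rejects
    non-finite input.
    """
    arr = np.asarray(v, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("velocity values must be finite")
    if literal:
        out = arr * np.abs(arr) * np.log1p(np.abs(arr))
    else:
        out = np.sign(arr) * np.log1p(np.abs(arr))
    if np.isscalar(v) or np.ndim(v) == 0:
        return float(out)
    return out


def velocity_heatmap(
    matrix: VelocityMatrix, gene_subset: list[str], annotation: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transformed heatmap matrix plus its column annotation track.

    Rows (genes) are ordered by average-linkage hierarchical clustering of
    the transformed profiles (Euclidean distance; when all rows are
    equidistant at zero the input order is kept).  Columns are grouped by
    (day, subset), stably preserving input order within a block.  Returns
    (ordered transformed matrix, annotation DataFrame with rows day,
    subset, and optionally a per-gene classifier annotation attached as
    ``matrix.attrs["gene_annotation"]``).
    """
    missing = [g for g in gene_subset if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"genes absent from velocity matrix: {missing[:5]}")
    if not gene_subset:
        raise ValidationError("gene_subset must be nonempty")
    vals = signed_log_velocity(matrix.values.loc[gene_subset].to_numpy())
    tdf = pd.DataFrame(vals, index=gene_subset, columns=matrix.values.columns)

    order = list(gene_subset)
    if len(gene_subset) > 1:
        d = pdist(vals)
        if d.max() > 0:
            link = hierarchy.linkage(d, method="average")
            order = [gene_subset[i] for i in hierarchy.leaves_list(link)]

    col_order = sorted(
        tdf.columns,
        key=lambda c: (str(matrix.cell_day.loc[c]), str(matrix.cell_subset.loc[c])),
    )
    out = tdf.loc[order, col_order]
    ann = pd.DataFrame(
        {
            c: [matrix.cell_day.loc[c], matrix.cell_subset.loc[c]]
            for c in col_order
        },
        index=["day", "subset"],
    )
    if annotation is not None:
        out.attrs["gene_annotation"] = {g: annotation.get(g, "nd") for g in order}
    return out, ann
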