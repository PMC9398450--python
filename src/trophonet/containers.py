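"""Core in-memory containers shared across the pipeline.

The pipeline moves between three kinds of data: expression matrices
(genes x observations, bulk samples or single cells), a protein-protein
interaction graph used to map binding partners across the embryo-uterus
interface, and the interface table itself (endometrial epithelial gene
paired with its cognate trophectoderm gene, annotated with hypernetwork
cluster membership and classifier status).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "InteractionGraph",
    "LocalizationTable",
    "InterfaceTable",
    "CLUSTER_MEMBERSHIPS",
    "CLASSIFIER_STATUSES",
    "ValidationError",
    "FormatError",
]

CLUSTER_MEMBERSHIPS = ("polar_and_mural", "polar", "mural", "neither", "pending")
CLASSIFIER_STATUSES = ("yes", "no", "nd_not_expressed", "nd", "pending")


class ValidationError(ValueError):
    """A container or configuration violates one of its invariants."""


class FormatError(ValueError):
    """An input file is malformed; the message names the offending line."""


@dataclass
class ExpressionMatrix:
    """Non-negative expression values, genes in rows, observations in columns.

    ``obs_groups`` maps each observation id to a group label, e.g.
    proliferative / mid-secretory for bulk endometrial epithelium, or
    polar / mural for Day 6 trophectoderm cells.
    """

    values: pd.DataFrame
    obs_groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate observation ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValidationError("expression values must be non-negative")
        if self.obs_groups is not None:
            self.obs_groups = pd.Series(self.obs_groups)
            unknown = set(self.obs_groups.index) - set(self.values.columns)
            if unknown:
                raise ValidationError(
                    f"obs_groups refers to unknown observations: {sorted(unknown)[:5]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def obs_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def obs_in_group(self, group: str) -> list[str]:
        if self.obs_groups is None:
            raise ValidationError("matrix has no group labels")
        return list(self.obs_groups.index[self.obs_groups == group])

    def subset_obs(self, obs_ids: Iterable[str]) -> "ExpressionMatrix":
        obs_ids = list(obs_ids)
        groups = self.obs_groups.loc[obs_ids] if self.obs_groups is not None else None
        return ExpressionMatrix(self.values[obs_ids], groups)


@dataclass
class InteractionGraph:
    """Undirected protein-protein interaction graph at gene-symbol level.

    Self-loops are allowed: a secreted protein can bind the product of the
    same gene symbol on the opposing cell surface (e.g. AMBP-AMBP).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionGraph":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def partners(self, gene: str) -> set[str]:
        """All interaction partners of ``gene`` (including itself for self-loops)."""
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class LocalizationTable:
    """Gene symbol -> set of subcellular/extracellular localization terms."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.entries.items():
            bad = [t for t in terms if not isinstance(t, str) or not t]
            if bad:
                raise ValidationError(f"empty localization term for gene {gene!r}")

    def terms(self, gene: str) -> set[str]:
        return self.entries.get(gene, set())


@dataclass
class InterfaceTable:
    """EEC gene <-> cognate TE gene pairs with hypernetwork and classifier calls.

    Columns: ``eec_gene``, ``te_gene``, ``cluster_membership``
    (polar_and_mural / polar / mural / neither), ``classifier_status``
    (yes / no / nd_not_expressed / nd).
    """

    rows: pd.DataFrame

    COLUMNS = ("eec_gene", "te_gene", "cluster_membership", "classifier_status")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"interface table missing columns: {missing}")
        self.rows = self.rows.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        pairs = list(zip(self.rows["eec_gene"], self.rows["te_gene"]))
        if len(pairs) != len(set(pairs)):
            raise ValidationError("duplicate (eec_gene, te_gene) pairs")
        bad_cm = set(self.rows["cluster_membership"]) - set(CLUSTER_MEMBERSHIPS)
        if bad_cm:
            raise ValidationError(f"unknown cluster_membership values: {sorted(bad_cm)}")
        bad_cs = set(self.rows["classifier_status"]) - set(CLASSIFIER_STATUSES)
        if bad_cs:
            raise ValidationError(f"unknown classifier_status values: {sorted(bad_cs)}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def te_genes(self) -> list[str]:
        return list(self.rows["te_gene"])

    @property
    def eec_genes(self) -> list[str]:
        return list(self.rows["eec_gene"])

    def with_updates(self, column: str, mapping: Mapping[tuple[str, str], str]) -> "InterfaceTable":
        """Return a copy with ``column`` updated for the given (eec, te) pairs."""
        rows = self.rows.copy()
        for (eec, te), value in mapping.items():
            mask = (rows["eec_gene"] == eec) & (rows["te_gene"] == te)
            rows.loc[mask, column] = value
        return InterfaceTable(rows)
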