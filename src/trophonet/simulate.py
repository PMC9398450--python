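"""Synthetic-data generators with planted ground truth.

These emulate the statistical structure of the study's inputs so the whole
pipeline can be exercised with a known answer:

* a two-condition bulk endometrial epithelium dataset (4 vs 4 samples)
  with planted receptivity DEGs;
* Day 6 trophectoderm single cells (86 polar, 245 mural by default) with a
  planted co-expression module anchored on interface genes, stronger in
  the polar-analog subset (latent-factor Poisson-lognormal counts);
* a protein-interaction edge list joining the two compartments;
* a TSC/STB two-class bulk contrast with a planted informative gene
  subset; and
* a per-gene per-cell velocity matrix with day-dependent dynamic genes.

Every generator is bitwise reproducible from its seed.  The latent-factor
construction makes the planted within-module correlation analytically
known: genes i, j in the module share a per-cell factor with loading
sqrt(rho), so their latent log-rates correlate at rho; Poisson sampling
and the small measurement noise attenuate the observed correlation of
log counts by the factor A^2 / (A^2 + noise_sd^2 + E[1/lambda]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InteractionGraph, ValidationError
from .velocity import VelocityMatrix

__all__ = [
    "SyntheticTruth",
    "default_interface_genes",
    "generate_receptivity_dataset",
    "generate_te_single_cells",
    "generate_interaction_graph",
    "generate_localization_table",
    "generate_tsc_stb_bulk",
    "generate_velocity_matrix",
]

#: Amplitude of the log-scale biological signal in single-cell simulations.
SIGNAL_AMPLITUDE = 1.2
#: Log-scale within-group noise SD for the bulk generators; planted effects
#: are expressed in multiples of this SD.
BULK_NOISE_SD = 0.5


@dataclass
class SyntheticTruth:
    """Which genes/edges were planted, with the parameters that shaped them."""

    planted_degs: set[str] = field(default_factory=set)
    planted_surface_genes: set[str] = field(default_factory=set)
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_modules: dict[str, dict] = field(default_factory=dict)
    informative_classifier_genes: set[str] = field(default_factory=set)
    dynamic_genes: set[str] = field(default_factory=set)
    seeds: dict[str, int] = field(default_factory=dict)
    sparsity: float | None = None


def default_interface_genes(n: int = 39) -> list[str]:
    return [f"IFC{i:03d}" for i in range(n)]


def generate_receptivity_dataset(
    n_genes: int = 2000,
    n_per_group: int = 4,
    n_degs: int = 200,
    effect_sd: float = 5.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-condition bulk dataset with planted receptivity DEGs.

    Log-normal baseline expression; the first ``n_degs`` genes get a mean
    shift of ``effect_sd`` noise-SDs (random sign) in the mid-secretory
    group.  Groups are labelled proliferative / mid_secretory.
    """
    if n_degs > n_genes or n_genes < 1 or n_per_group < 2:
        raise ValidationError("invalid sizes for receptivity dataset")
    rng = np.random.default_rng(seed)
    genes = [f"EEC{i:04d}" for i in range(n_genes)]
    obs = [f"prolif_{i}" for i in range(n_per_group)] + [
        f"midsec_{i}" for i in range(n_per_group)
    ]
    base = rng.normal(3.0, 1.0, size=n_genes)
    logx = base[:, None] + rng.normal(0.0, BULK_NOISE_SD, size=(n_genes, 2 * n_per_group))
    signs = rng.choice([-1.0, 1.0], size=n_degs)
    logx[:n_degs, n_per_group:] += (signs * effect_sd * BULK_NOISE_SD)[:, None]
    values = pd.DataFrame(np.exp(logx), index=genes, columns=obs)
    groups = pd.Series(
        ["proliferative"] * n_per_group + ["mid_secretory"] * n_per_group, index=obs
    )
    truth = SyntheticTruth(
        planted_degs=set(genes[:n_degs]), seeds={"receptivity": seed}
    )
    return ExpressionMatrix(values, groups), truth


def generate_te_single_cells(
    n_genes: int = 2000,
    n_polar: int = 86,
    n_mural: int = 245,
    interface_genes: list[str] | None = None,
    module_size: int = 40,
    rho_polar: float = 0.8,
    rho_mural: float = 0.4,
    noise_sd: float = 0.1,
    seed: int = 0,
    *,
    polar_module_n: int = 11,
    mural_module_n: int = 21,
    module_overlap: int = 7,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Day 6 TE single cells with subset-specific planted modules.

    A per-cell latent factor drives a subset of the interface genes plus
    ``module_size`` background genes with loading sqrt(rho); rho differs
    between the polar- and mural-analog subsets.  The polar module covers
    ``polar_module_n`` interface genes and the mural module
    ``mural_module_n``, sharing ``module_overlap`` genes (defaults mirror
    the 11- and 21-gene clusters with 7 genes in common).  Counts are
    Poisson-lognormal to give realistic single-cell sparsity.
    """
    if interface_genes is None:
        interface_genes = default_interface_genes()
    for rho in (rho_polar, rho_mural):
        if not 0 <= rho < 1:
            raise ValidationError("rho must lie in [0, 1)")
    if module_size + len(interface_genes) > n_genes:
        raise ValidationError("module_size + interface genes exceed n_genes")
    if mural_module_n > len(interface_genes) or polar_module_n > len(interface_genes):
        raise ValidationError("module membership exceeds interface gene count")

    rng = np.random.default_rng(seed)
    n_bg = n_genes - len(interface_genes)
    bg_genes = [f"TEG{i:04d}" for i in range(n_bg)]
    genes = interface_genes + bg_genes
    module_bg = bg_genes[:module_size]

    # overlapping interface membership: polar = [0, polar_n); mural starts
    # so that exactly `module_overlap` genes are shared
    start = polar_module_n - module_overlap
    polar_ifc = interface_genes[:polar_module_n]
    mural_ifc = interface_genes[start : start + mural_module_n]

    cells = [f"polar_{i}" for i in range(n_polar)] + [f"mural_{i}" for i in range(n_mural)]
    groups = pd.Series(["polar"] * n_polar + ["mural"] * n_mural, index=cells)

    base = np.empty(len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    module_all = set(polar_ifc) | set(mural_ifc) | set(module_bg)
    for g in genes:
        base[gene_pos[g]] = np.log(50.0) if g in module_all else rng.normal(np.log(2.0), 1.0)

    logrates = np.empty((len(genes), len(cells)))
    col0 = 0
    for subset, n_cells, rho, members in (
        ("polar", n_polar, rho_polar, set(polar_ifc) | set(module_bg)),
        ("mural", n_mural, rho_mural, set(mural_ifc) | set(module_bg)),
    ):
        cols = slice(col0, col0 + n_cells)
        z = rng.normal(size=n_cells)  # shared latent factor per cell
        eps = rng.normal(size=(len(genes), n_cells))
        meas = rng.normal(0.0, noise_sd, size=(len(genes), n_cells))
        in_mod = np.array([g in members for g in genes])
        sig = np.where(
            in_mod[:, None],
            SIGNAL_AMPLITUDE * (np.sqrt(rho) * z[None, :] + np.sqrt(1 - rho) * eps),
            SIGNAL_AMPLITUDE * eps,
        )
        logrates[:, cols] = base[:, None] + sig + meas
        col0 += n_cells

    counts = rng.poisson(np.exp(logrates)).astype(float)
    values = pd.DataFrame(counts, index=genes, columns=cells)
    truth = SyntheticTruth(
        planted_modules={
            "polar": {
                "interface": list(polar_ifc),
                "background": list(module_bg),
                "rho": rho_polar,
                "noise_sd": noise_sd,
            },
            "mural": {
                "interface": list(mural_ifc),
                "background": list(module_bg),
                "rho": rho_mural,
                "noise_sd": noise_sd,
            },
        },
        seeds={"te_single_cells": seed},
        sparsity=float((counts == 0).mean()),
    )
    return ExpressionMatrix(values, groups), truth


def generate_interaction_graph(
    eec_genes: list[str],
    te_genes: list[str],
    n_true_edges: int | None = None,
    n_decoy_edges: int = 50,
    seed: int = 0,
    *,
    include_self_pairs: bool = False,
    decoy_pool: list[str] | None = None,
) -> tuple[InteractionGraph, SyntheticTruth]:
    """Edge list joining EEC genes one-to-one to TE partner genes.

    The first ``n_true_edges`` (eec, te) index pairs become true edges;
    with ``include_self_pairs`` the first true edge uses the same symbol on
    both sides.  Decoys connect random genes outside the planted sets.
    """
    if n_true_edges is None:
        n_true_edges = min(len(eec_genes), len(te_genes))
    if n_true_edges > min(len(eec_genes), len(te_genes)):
        raise ValidationError("n_true_edges exceeds available genes")
    rng = np.random.default_rng(seed)
    te_side = list(te_genes[:n_true_edges])
    if include_self_pairs and n_true_edges:
        te_side[0] = eec_genes[0]
    true_edges = set(zip(eec_genes[:n_true_edges], te_side))

    planted = set(eec_genes[:n_true_edges]) | set(te_side)
    if decoy_pool is None:
        decoy_pool = [f"DECOY{i:04d}" for i in range(max(2 * n_decoy_edges, 10))]
    decoy_pool = [g for g in decoy_pool if g not in planted]
    decoys = set()
    while len(decoys) < n_decoy_edges and len(decoy_pool) >= 2:
        a, b = rng.choice(len(decoy_pool), size=2, replace=False)
        decoys.add((decoy_pool[a], decoy_pool[b]))
    graph = InteractionGraph.from_edges(list(true_edges) + sorted(decoys))
    truth = SyntheticTruth(planted_edges=true_edges, seeds={"interaction_graph": seed})
    return graph, truth


def generate_localization_table(
    surface_genes: list[str],
    other_genes: list[str] | None = None,
    seed: int = 0,
):
    """Annotation table placing ``surface_genes`` at the cell surface.

    Surface genes each get one of the four interface-admissible terms;
    other genes get intracellular terms only.  Stands in for a curated
    protein-localization annotation.
    """
    from .containers import LocalizationTable
    from .interface import DEFAULT_LOCALIZATION_TERMS

    rng = np.random.default_rng(seed)
    allowed = sorted(DEFAULT_LOCALIZATION_TERMS)
    intracellular = ["nucleus", "cytoplasm", "mitochondrion", "endoplasmic reticulum"]
    entries: dict[str, set[str]] = {}
    for g in surface_genes:
        entries.setdefault(g, set()).add(allowed[int(rng.integers(len(allowed)))])
    for g in other_genes or []:
        if g in entries:
            continue
        entries[g] = {intracellular[int(rng.integers(len(intracellular)))]}
    return LocalizationTable(entries)


def generate_tsc_stb_bulk(
    genes: list[str],
    n_per_group: int = 4,
    informative_genes: set[str] | None = None,
    effect_sd: float = 3.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """TSC vs STB bulk contrast with a planted informative gene subset.

    Informative genes shift by ``effect_sd`` noise-SDs (random sign) in
    the STB class; all other genes are exchangeable between classes.
    """
    if n_per_group < 2 or not genes:
        raise ValidationError("invalid sizes for TSC/STB dataset")
    informative_genes = set(informative_genes or set())
    unknown = informative_genes - set(genes)
    if unknown:
        raise ValidationError(f"informative genes not in gene list: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    obs = [f"TSC_{i}" for i in range(n_per_group)] + [f"STB_{i}" for i in range(n_per_group)]
    base = rng.normal(3.0, 1.0, size=len(genes))
    logx = base[:, None] + rng.normal(0.0, BULK_NOISE_SD, size=(len(genes), 2 * n_per_group))
    for i, g in enumerate(genes):
        if g in informative_genes:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            logx[i, n_per_group:] += sign * effect_sd * BULK_NOISE_SD
    values = pd.DataFrame(np.exp(logx), index=genes, columns=obs)
    groups = pd.Series(["TSC"] * n_per_group + ["STB"] * n_per_group, index=obs)
    truth = SyntheticTruth(
        informative_classifier_genes=informative_genes, seeds={"tsc_stb": seed}
    )
    return ExpressionMatrix(values, groups), truth


def generate_velocity_matrix(
    genes: list[str],
    cells_per_day_subset: int = 20,
    dynamic_genes: set[str] | None = None,
    amplitude: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> tuple[VelocityMatrix, SyntheticTruth]:
    """Signed per-gene per-cell velocities across blastocyst days 5-7.

    Day 5 cells are unassigned (polar/mural distinction unavailable); days
    6 and 7 have polar and mural blocks.  Dynamic genes get a
    day-increasing signed velocity of magnitude ~``amplitude``; all other
    entries are near-zero noise.
    """
    dynamic_genes = set(dynamic_genes or set())
    unknown = dynamic_genes - set(genes)
    if unknown:
        raise ValidationError(f"dynamic genes not in gene list: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    blocks = [("5", "unassigned"), ("6", "polar"), ("6", "mural"), ("7", "polar"), ("7", "mural")]
    cells, day_lab, subset_lab = [], [], []
    for day, subset in blocks:
        for i in range(cells_per_day_subset):
            cells.append(f"d{day}_{subset}_{i}")
            day_lab.append(day)
            subset_lab.append(subset)
    day_factor = {"5": 0.5, "6": 1.0, "7": 1.5}
    vals = rng.normal(0.0, noise_sd, size=(len(genes), len(cells)))
    for i, g in enumerate(genes):
        if g in dynamic_genes:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for j, d in enumerate(day_lab):
                vals[i, j] += sign * amplitude * day_factor[d]
    vm = VelocityMatrix(
        pd.DataFrame(vals, index=genes, columns=cells),
        pd.Series(day_lab, index=cells),
        pd.Series(subset_lab, index=cells),
    )
    truth = SyntheticTruth(dynamic_genes=dynamic_genes, seeds={"velocity": seed})
    return vm, truth
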