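"""Shadow-feature random-forest classification of interface genes.

Tests whether interface genes can classify a two-class differentiation
contrast (trophoblast stem cells vs syncytiotrophoblast, n = 4 + 4).
Each iteration augments the real genes with "shadow" copies whose sample
values are independently permuted — an empirical noise floor — fits a
random forest, and records each gene's permutation importance (Breiman's
mean per-tree accuracy decrease) together with the maximum shadow
importance.  A gene scores a "hit" when it beats the best shadow.  Over
many iterations the hit count is tested against a fair coin (two-sided
binomial, Bonferroni across genes): significantly many hits confirms the
gene as informative, significantly few rejects it, anything else stays
tentative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .containers import InterfaceTable, ValidationError

__all__ = [
    "ImportanceTable",
    "shadow_augment",
    "importance_iteration",
    "boruta_classify",
    "annotate_interface",
]

SHADOW_PREFIX = "shadow__"


@dataclass
class ImportanceTable:
    """Per-gene iteration history and the resulting decision.

    ``z_scores``: genes x iterations, importance standardized against the
    shadow-importance distribution of that iteration.  ``summary`` has one
    row per gene: hits, n_iterations, median_z, p_value, status
    (confirmed / rejected / tentative).
    """

    z_scores: pd.DataFrame
    shadow_max_track: np.ndarray
    summary: pd.DataFrame

    @property
    def n_iterations(self) -> int:
        return self.z_scores.shape[1]

    def status(self, gene: str) -> str:
        return str(self.summary.loc[gene, "status"])


def shadow_augment(features: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Append a permuted (shadow) copy of every feature row.

    ``features`` is genes x samples.  Each shadow holds the same multiset
    of values as its original, in an independently shuffled sample order,
    severing any relationship with the class labels.
    """
    if features.shape[0] < 2:
        raise ValidationError("need >=2 features to augment")
    if features.shape[1] < 2:
        raise ValidationError("need >=2 samples to permute")
    rng = np.random.default_rng(seed)
    arr = features.to_numpy(dtype=float)
    shadows = np.empty_like(arr)
    for i in range(arr.shape[0]):
        shadows[i] = arr[i, rng.permutation(arr.shape[1])]
    shadow_idx = [f"{SHADOW_PREFIX}{g}" for g in features.index]
    return pd.DataFrame(
        np.vstack([arr, shadows]),
        index=list(features.index) + shadow_idx,
        columns=features.columns,
    )


def _oob_permutation_importance(
    X: np.ndarray, y_enc: np.ndarray, n_trees: int, rng
) -> np.ndarray:
    """Breiman permutation importance: mean per-tree OOB accuracy decrease.

    An explicit bagging loop over decision trees (mtry = sqrt(p)): each
    tree is fit on a bootstrap sample and its accuracy on the out-of-bag
    samples is compared before and after permuting each feature column.
    Out-of-bag evaluation is what separates signal from noise here — a
    tree that split on a noise (or shadow) feature predicts its OOB
    samples at chance whether or not that feature is permuted, while a
    tree that used an informative feature loses real accuracy.  Per-tree
    evaluation also keeps correlated informative features visible: every
    tree that split on the feature degrades even when an ensemble vote
    would be rescued by its siblings.
    """
    n_samples, n_features = X.shape
    # one stacked matrix of every feature's permuted version; a tree only
    # needs the blocks for features it actually split on (permuting an
    # unused feature cannot change its predictions, so the drop is 0)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    stacked = np.tile(X32, (n_features, 1, 1))
    for f in range(n_features):
        stacked[f, :, f] = X32[rng.permutation(n_samples), f]

    drops = np.zeros(n_features)
    n_used = 0
    all_idx = np.arange(n_samples)
    for _ in range(n_trees):
        boot = rng.integers(n_samples, size=n_samples)
        oob = np.setdiff1d(all_idx, boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        # trees are fit on integer-coded classes so tree_.predict leaf
        # counts argmax directly to the class index (fast path)
        tree.fit(X32[boot], y_enc[boot], check_input=False)
        y_oob = y_enc[oob]
        base = tree.tree_.predict(np.ascontiguousarray(X32[oob])).argmax(axis=1)
        base_acc = (base == y_oob).mean()
        feats = np.unique(tree.tree_.feature)
        feats = feats[feats >= 0]
        if feats.size:
            block = stacked[np.ix_(feats, oob)].reshape(feats.size * oob.size, n_features)
            preds = tree.tree_.predict(np.ascontiguousarray(block)).argmax(axis=1)
            perm_acc = (preds.reshape(feats.size, oob.size) == y_oob).mean(axis=1)
            drops[feats] += base_acc - perm_acc
        n_used += 1
    if n_used == 0:
        raise ValidationError("no tree had out-of-bag samples")
    return drops / n_used


def importance_iteration(
    augmented: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_trees: int = 300,
    seed: int = 0,
) -> tuple[pd.Series, float]:
    """One bagged-forest fit on the shadow-augmented features.

    Returns (importance per real feature, max shadow importance).
    ``augmented`` is features x samples as produced by ``shadow_augment``.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("labels must contain both classes")
    if n_trees < 50:
        raise ValidationError("n_trees must be >= 50")
    X = augmented.to_numpy(dtype=float).T  # samples x features
    y_enc = np.searchsorted(classes, y).astype(float)
    rng = np.random.default_rng(seed)
    imp = _oob_permutation_importance(X, y_enc, n_trees, rng)
    names = list(augmented.index)
    is_shadow = np.array([n.startswith(SHADOW_PREFIX) for n in names])
    real = pd.Series(imp[~is_shadow], index=[n for n in names if not n.startswith(SHADOW_PREFIX)])
    shadow_max = float(imp[is_shadow].max())
    return real, shadow_max


def boruta_classify(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_iterations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    n_trees: int = 300,
) -> ImportanceTable:
    """Iterated shadow-feature selection with a binomial decision test.

    ``features`` is genes x samples.  Per gene, the count of iterations
    where its importance exceeded the iteration's best shadow is tested
    two-sided against Binomial(n_iterations, 0.5) with Bonferroni
    correction over genes.  Significantly many hits -> confirmed,
    significantly few -> rejected, otherwise tentative.
    """
    if n_iterations < 10:
        raise ValidationError("n_iterations must be >= 10")
    genes = list(features.index)
    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(2**31, size=2 * n_iterations)

    z_rows = np.empty((len(genes), n_iterations))
    shadow_track = np.empty(n_iterations)
    hits = np.zeros(len(genes), dtype=int)
    for it in range(n_iterations):
        aug = shadow_augment(features, int(iter_seeds[2 * it]))
        imp, shadow_max = importance_iteration(
            aug, labels, n_trees=n_trees, seed=int(iter_seeds[2 * it + 1])
        )
        # Z against this iteration's noise floor: scale = best shadow (eps-guarded)
        scale = max(abs(shadow_max), 1e-6)
        z_rows[:, it] = imp.loc[genes].to_numpy() / scale
        shadow_track[it] = shadow_max
        hits += (imp.loc[genes].to_numpy() > shadow_max).astype(int)

    thresh = alpha / len(genes)  # Bonferroni
    statuses, pvals = [], []
    for h in hits:
        res = stats.binomtest(int(h), n_iterations, 0.5)
        p = res.pvalue
        pvals.append(p)
        if p < thresh and h > n_iterations / 2:
            statuses.append("confirmed")
        elif p < thresh and h < n_iterations / 2:
            statuses.append("rejected")
        else:
            statuses.append("tentative")
    summary = pd.DataFrame(
        {
            "hits": hits,
            "n_iterations": n_iterations,
            "median_z": np.median(z_rows, axis=1),
            "p_value": pvals,
            "status": statuses,
        },
        index=genes,
    )
    zdf = pd.DataFrame(z_rows, index=genes, columns=[f"iter_{i}" for i in range(n_iterations)])
    return ImportanceTable(zdf, shadow_track, summary)


def annotate_interface(
    table: InterfaceTable,
    importance: ImportanceTable | None,
    *,
    expressed_genes: set[str] | None = None,
) -> InterfaceTable:
    """Fill the classifier_status column from a Boruta run.

    confirmed -> yes; rejected -> no; tentative -> nd (ran but undecided);
    expressed_genes given and gene absent -> nd_not_expressed; gene never
    run -> nd.  Duplicate TE genes with conflicting statuses are an error.
    """
    status_map: dict[str, str] = {}
    if importance is not None:
        for gene, row in importance.summary.iterrows():
            mapped = {"confirmed": "yes", "rejected": "no", "tentative": "nd"}[row["status"]]
            if gene in status_map and status_map[gene] != mapped:
                raise ValidationError(f"conflicting duplicate statuses for {gene}")
            status_map[str(gene)] = mapped
    updates = {}
    for _, row in table.rows.iterrows():
        te = row["te_gene"]
        if te in status_map:
            status = status_map[te]
        elif expressed_genes is not None and te not in expressed_genes:
            status = "nd_not_expressed"
        else:
            status = "nd"
        updates[(row["eec_gene"], te)] = status
    return table.with_updates("classifier_status", updates)
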