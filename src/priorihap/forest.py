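"""Random-forest variable-importance SNP selection.

A data-driven alternative to knowledge-based prioritization: grow an ensemble
of bootstrap classification trees on case/control status and rank markers by
mean decrease in Gini node impurity.  Markers with zero observed variance are
filtered first; remaining missing dosages are imputed to the per-marker
median (trees require complete data).  Importance here is the *unnormalized*
mean decrease in impurity — the average over trees of the total
sample-weighted impurity decrease attributed to splits on the marker — so a
pure-noise marker's importance shrinks toward zero rather than being inflated
by renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .genio import GenotypeMatrix
from .prioritize import PrioritySet

__all__ = [
    "ImportanceResult",
    "variance_filter",
    "rf_importance",
    "select_important",
]


@dataclass
class ImportanceResult:
    marker_id: str
    importance: float
    rank: int


def variance_filter(G: GenotypeMatrix) -> list[str]:
    """Marker ids whose observed (non-missing) dosages are not all identical."""
    keep = []
    for j, mid in enumerate(G.marker_ids):
        col = G.dosage[:, j]
        obs = col[~np.isnan(col)]
        if obs.size and obs.min() != obs.max():
            keep.append(mid)
    return keep


def _impute_median(dosage: np.ndarray) -> np.ndarray:
    X = dosage.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        nan = np.isnan(col)
        if nan.any():
            med = np.nanmedian(col) if (~nan).any() else 0.0
            col[nan] = med
    return X


def rf_importance(
    G: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    n_trees: int = 1000,
    mtry: int | None = None,
    seed: int = 0,
    n_repeats: int = 1,
) -> list[ImportanceResult]:
    """Mean-decrease-in-impurity importance from a bootstrap forest.

    ``mtry`` (features per split) defaults to sqrt(M).  ``n_repeats`` > 1
    averages importances over independently seeded forests (importance
    stabilization).  Results are sorted by rank (1 = most important); ties
    broken by marker id.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    ph = phenotypes.set_index("individual_id").loc[G.individual_ids]
    y = (ph["status"] == "case").astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has a single class")
    X = _impute_median(G.dosage)
    max_features = mtry if mtry is not None else "sqrt"

    imp = np.zeros(G.n_markers)
    for r in range(n_repeats):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="gini",
            max_features=max_features,
            bootstrap=True,
            random_state=seed + r,
            n_jobs=1,
        )
        rf.fit(X, y)
        # unnormalized mean decrease in impurity, averaged over trees
        per_tree = np.stack(
            [t.tree_.compute_feature_importances(normalize=False) for t in rf.estimators_]
        )
        imp += per_tree.mean(axis=0)
    imp /= n_repeats

    order = sorted(range(G.n_markers), key=lambda j: (-imp[j], G.marker_ids[j]))
    results = [
        ImportanceResult(G.marker_ids[j], float(imp[j]), rank)
        for rank, j in enumerate(order, start=1)
    ]
    return results


def select_important(
    importances: list[ImportanceResult],
    rule: str = "top_k",
    k: int | None = None,
    fraction: float | None = None,
    threshold: float | None = None,
    label: str = "RF",
) -> PrioritySet:
    """Select markers into a PrioritySet by one of three rules.

    ``top_k``: the k best ranks; ``top_fraction``: the best ceil(fraction*M)
    (0 selects none); ``importance_gt``: importance strictly above the cut.
    """
    by_rank = sorted(importances, key=lambda r: r.rank)
    if rule == "top_k":
        if k is None:
            raise ValueError("top_k rule needs k")
        chosen = by_rank[: max(k, 0)]
    elif rule == "top_fraction":
        if fraction is None:
            raise ValueError("top_fraction rule needs fraction")
        n = int(np.ceil(fraction * len(by_rank)))
        chosen = by_rank[:n]
    elif rule == "importance_gt":
        if threshold is None:
            raise ValueError("importance_gt rule needs threshold")
        chosen = [r for r in by_rank if r.importance > threshold]
    else:
        raise ValueError(f"unknown selection rule: {rule}")
    if not chosen:
        warnings.warn("empty importance selection", stacklevel=2)
    return PrioritySet(
        label=label,
        marker_ids={r.marker_id for r in chosen},
        provenance=f"random-forest {rule}",
    )
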