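"""Sparse logistic regression ranking TFs by their importance for
discriminating up- from down-regulated genes (DYNAMITE-style).

Features are per-gene contrasts of TF-gene scores between a treated and a
control condition (log2 ratio by default).  An elastic-net logistic
regression is fitted with nested cross-validation: the penalty strength
is chosen on inner folds by accuracy, coefficients are averaged over the
outer folds, and absolute coefficients are normalized to [0, 1] for
ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .affinity_model import TFGeneScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TFImportance",
    "build_feature_matrix",
    "fit_sparse_classifier",
    "normalize_and_rank",
    "DEFAULT_PENALTY_GRID",
]

# penalty strengths C for sklearn, logarithmic over 6 decades
DEFAULT_PENALTY_GRID = tuple(np.logspace(-3, 2, 6))


@dataclass(frozen=True)
class TFImportance:
    """Classifier importance of a single TF."""

    tf_name: str
    raw_coefficient: float
    normalized_coefficient: float | None = None
    rank: int | None = None


def _as_frame(scores) -> pd.DataFrame:
    return scores.scores if isinstance(scores, TFGeneScoreMatrix) else scores


def build_feature_matrix(
    scores_control,
    scores_treated,
    deg_table: pd.DataFrame,
    labeled_genes: Sequence[str] | None = None,
    epsilon: float = 1e-3,
    kind: str = "ratio",
) -> tuple[pd.DataFrame, pd.Series]:
    """Condition-contrast features and up/down labels.

    Features are ``log2((treated + eps) / (control + eps))`` per gene and
    TF (or the plain difference with ``kind='difference'``).  Labels come
    from the sign of ``log2fc`` in ``deg_table``; genes with a zero fold
    change are excluded, as are genes missing from either score matrix
    (with a warning).
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if kind not in ("ratio", "difference"):
        raise ValueError(f"unknown feature kind {kind!r}")
    control = _as_frame(scores_control)
    treated = _as_frame(scores_treated)
    tfs = sorted(set(control.columns) & set(treated.columns))
    if not tfs:
        raise ValueError("score matrices share no TF columns")
    lfc = deg_table.set_index("gene_id")["log2fc"]
    genes = list(labeled_genes) if labeled_genes is not None else list(lfc.index)
    usable: list[str] = []
    for gene in genes:
        if gene not in lfc.index or lfc[gene] == 0:
            continue
        if gene not in control.index or gene not in treated.index:
            logger.warning("gene %s missing from a score matrix; excluded", gene)
            continue
        usable.append(gene)
    c = control.loc[usable, tfs].to_numpy(dtype=float)
    t = treated.loc[usable, tfs].to_numpy(dtype=float)
    if kind == "ratio":
        values = np.log2((t + epsilon) / (c + epsilon))
    else:
        values = t - c
    features = pd.DataFrame(values, index=usable, columns=tfs)
    labels = (lfc.loc[usable] > 0).astype(int)
    labels.name = "up"
    return features, labels


def fit_sparse_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
    n_outer_folds: int = 6,
    n_inner_folds: int = 6,
    l1_ratio: float = 0.1,
    seed: int = 0,
) -> tuple[list[TFImportance], dict]:
    """Nested-CV elastic-net logistic regression.

    The penalty strength is selected on inner folds by accuracy (ties
    broken toward stronger regularization); one model per outer fold is
    fitted on the outer training split (features standardized on that
    split) and coefficients are averaged across outer folds.  The result
    is deterministic given ``seed``.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if not np.any(X):
        logger.warning("all-zero feature matrix; returning zero coefficients")
        raw = [TFImportance(tf, 0.0) for tf in features.columns]
        return raw, {"fold_accuracies": [], "chosen_penalties": [], "seed": seed}

    min_class = int(class_counts.min())
    outer_k = min(n_outer_folds, min_class)
    if outer_k < 2:
        raise ValueError("too few samples in the minority class for CV")
    if outer_k < n_outer_folds:
        logger.warning("reducing outer folds from %d to %d", n_outer_folds, outer_k)

    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    coefs = []
    fold_accuracies = []
    chosen = []
    for fold_idx, (train, test) in enumerate(outer.split(X, y)):
        Xtr, ytr = X[train], y[train]
        inner_k = min(n_inner_folds, int(np.bincount(ytr).min()))
        best_c, best_acc = None, -np.inf
        if inner_k >= 2:
            inner = StratifiedKFold(
                n_splits=inner_k, shuffle=True, random_state=seed + 1
            )
            for c in sorted(penalty_grid):
                accs = []
                for itr, ite in inner.split(Xtr, ytr):
                    model = _make_model(c, l1_ratio, seed)
                    scaler = StandardScaler().fit(Xtr[itr])
                    model.fit(scaler.transform(Xtr[itr]), ytr[itr])
                    accs.append(
                        model.score(scaler.transform(Xtr[ite]), ytr[ite])
                    )
                acc = float(np.mean(accs))
                if acc > best_acc:  # ties keep the smaller (stronger) penalty
                    best_acc, best_c = acc, c
        else:
            best_c = sorted(penalty_grid)[0]
        scaler = StandardScaler().fit(Xtr)
        model = _make_model(best_c, l1_ratio, seed)
        model.fit(scaler.transform(Xtr), ytr)
        coefs.append(model.coef_.ravel())
        fold_accuracies.append(
            float(model.score(scaler.transform(X[test]), y[test]))
        )
        chosen.append(float(best_c))
    mean_coef = np.mean(coefs, axis=0)
    raw = [
        TFImportance(tf, float(c)) for tf, c in zip(features.columns, mean_coef)
    ]
    metadata = {
        "fold_accuracies": fold_accuracies,
        "chosen_penalties": chosen,
        "n_outer_folds": outer_k,
        "n_inner_folds": n_inner_folds,
        "l1_ratio": l1_ratio,
        "seed": seed,
        "n_genes": int(len(y)),
        "fold_sizes": [int(len(test)) for _, test in outer.split(X, y)],
    }
    return raw, metadata


def _make_model(c: float, l1_ratio: float, seed: int) -> LogisticRegression:
    # elastic net: penalty defaults are governed by l1_ratio in sklearn >= 1.8
    return LogisticRegression(
        solver="saga",
        C=c,
        l1_ratio=l1_ratio,
        max_iter=20_000,
        tol=1e-6,
        random_state=seed,
    )


def normalize_and_rank(
    raw_importances: Sequence[TFImportance],
) -> list[TFImportance]:
    """Normalize |coefficients| to [0, 1] and rank by descending value.

    Normalization divides by the maximum absolute coefficient (all zeros
    stay zero).  Ties are broken alphabetically by TF name, so the output
    is a deterministic permutation of ranks 1..n.
    """
    if not raw_importances:
        raise ValueError("no coefficients to normalize")
    max_abs = max(abs(imp.raw_coefficient) for imp in raw_importances)
    normalized = [
        (abs(imp.raw_coefficient) / max_abs if max_abs > 0 else 0.0, imp)
        for imp in raw_importances
    ]
    ordered = sorted(normalized, key=lambda pair: (-pair[0], pair[1].tf_name))
    return [
        TFImportance(
            tf_name=imp.tf_name,
            raw_coefficient=imp.raw_coefficient,
            normalized_coefficient=norm,
            rank=i + 1,
        )
        for i, (norm, imp) in enumerate(ordered)
    ]


def importance_table(importances: Sequence[TFImportance]) -> pd.DataFrame:
    """Tabular view (tf, raw, normalized, rank) of ranked importances."""
    return pd.DataFrame(
        [
            {
                "tf_name": imp.tf_name,
                "raw_coefficient": imp.raw_coefficient,
                "normalized_coefficient": imp.normalized_coefficient,
                "rank": imp.rank,
            }
            for imp in importances
        ]
    )
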