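"""Multivariate procedures: LDA tissue separation and random-forest genotype
prediction.

The tissue discriminant projects samples onto the top linear-discriminant
axes and quantifies separation by the mean silhouette of the projections
under the true labels, with a label-permutation null for calibration.

The genotype classifier is a random forest (bootstrap-aggregated trees with
sqrt(p) candidate features per split) whose accuracy is estimated out-of-bag:
each tree is evaluated on the samples left out of its bootstrap, and the
cumulative OOB error over the growing ensemble gives an error trajectory.
Feature importance is permutation-based: a metabolite's values are shuffled
across samples and the increase in final OOB error recorded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import silhouette_score
from sklearn.tree import DecisionTreeClassifier

from ._errors import ValidationError

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
class TissueDiscriminant(BaseEstimator):
    """Multi-class LDA with a silhouette separation score.

    ``fit(X, y)`` fits standard linear discriminant axes to a samples x
    metabolites matrix with class labels ``y`` (tissue types), projects onto
    the top ``n_components`` axes (at most n_classes - 1) and scores the
    separation as the mean silhouette of the projections under the true
    labels.  Metabolites whose pooled within-class variance falls below
    ``var_tol`` (relative to the largest) are dropped before fitting, since
    they carry no discriminative signal and destabilise the within-class
    scatter.
    """

    def __init__(self, n_components: int = 3, var_tol: float = 1e-8):
        self.n_components = n_components
        self.var_tol = var_tol

    def fit(self, X, y) -> "TissueDiscriminant":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValidationError("LDA needs at least 2 classes")
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise ValidationError(
                f"class {small!r} has fewer than 2 samples"
            )
        within_var = np.zeros(X.shape[1])
        for c in classes:
            within_var += X[y == c].var(axis=0) * (y == c).sum()
        within_var /= len(y)
        ref = within_var.max() if within_var.size else 0.0
        keep = within_var > self.var_tol * max(ref, 1.0)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d near-constant metabolites before LDA", n_drop)
        self.kept_features_ = keep
        n_comp = min(self.n_components, len(classes) - 1, int(keep.sum()))
        self._lda = LinearDiscriminantAnalysis(n_components=n_comp)
        self.projections_ = self._lda.fit_transform(X[:, keep], y)
        self.axes_ = self._lda.scalings_[:, :n_comp]
        self.labels_ = y
        self.classes_ = classes
        if len(classes) > 1 and self.projections_.shape[0] > len(classes):
            self.separation_score_ = float(
                silhouette_score(self.projections_, y)
            )
        else:  # pragma: no cover - degenerate
            self.separation_score_ = np.nan
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return self._lda.transform(X[:, self.kept_features_])

    # ------------------------------------------------------------------
    def permutation_null(
        self, X, y, n_perm: int = 100, random_state: int | None = None
    ) -> np.ndarray:
        """Separation scores after uniformly shuffling the labels.

        Each permutation reshuffles all labels without replacement and
        refits the discriminant from scratch; the unshuffled labelling is
        never part of the null.  Returns the permuted scores and stores them
        as ``permuted_scores_`` alongside the empirical p-value
        (1 + #{permuted >= observed}) / (n_perm + 1).
        """
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(random_state)
        scores = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(len(y))
            shuffled = y[perm]
            try:
                est = TissueDiscriminant(self.n_components, self.var_tol)
                est.fit(X, shuffled)
                scores[i] = est.separation_score_
            except ValidationError:
                scores[i] = np.nan
        self.permuted_scores_ = scores
        valid = scores[np.isfinite(scores)]
        self.permutation_pvalue_ = float(
            (1.0 + np.sum(valid >= self.separation_score_)) / (len(valid) + 1.0)
        )
        return scores


def fit_lda(table, labels=None, n_components: int = 3) -> TissueDiscriminant:
    """Fit a :class:`TissueDiscriminant` on a PeakTable (labels = tissue)."""
    y = (
        np.asarray(labels)
        if labels is not None
        else table.samples["tissue"].to_numpy()
    )
    return TissueDiscriminant(n_components=n_components).fit(table.values, y)


def permutation_control(
    table, labels=None, n_perm: int = 100, seed: int | None = None
) -> np.ndarray:
    """Label-permutation null of the LDA separation score."""
    y = (
        np.asarray(labels)
        if labels is not None
        else table.samples["tissue"].to_numpy()
    )
    est = TissueDiscriminant().fit(table.values, y)
    return est.permutation_null(table.values, y, n_perm=n_perm, random_state=seed)


# ----------------------------------------------------------------------
class GenotypeForest(ClassifierMixin, BaseEstimator):
    """Random-forest genotype classifier with an OOB error trajectory.

    Implemented as bagged decision trees with sqrt(p) candidate features per
    split (the classical random-forest construction).  After fitting, the
    out-of-bag predictions of each tree are combined cumulatively to give
    ``oob_error_trajectory_`` (one entry per ensemble size 1..n_trees) and
    ``final_oob_error_``.  ``permutation_importance`` shuffles one
    metabolite's values at a time and reports the increase in final OOB
    error, in percentage points.

    Missing values must be encoded as zero (non-detections) before fitting.
    """

    def __init__(self, n_trees: int = 500, random_state: int | None = None):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y) -> "GenotypeForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValidationError("both genotypes must be present")
        self._bag = BaggingClassifier(
            estimator=DecisionTreeClassifier(
                max_features="sqrt", random_state=0
            ),
            n_estimators=self.n_trees,
            bootstrap=True,
            random_state=self.random_state,
        )
        self._bag.fit(X, y)
        self._X = X
        self._y_codes = np.searchsorted(self.classes_, y)
        n = len(y)
        # per-tree OOB masks from the public bootstrap-sample lists
        self._oob_masks = np.ones((self.n_trees, n), dtype=bool)
        for t, idx in enumerate(self._bag.estimators_samples_):
            self._oob_masks[t, idx] = False
        votes = self._tree_votes(X)
        self.oob_error_trajectory_ = self._trajectory(votes)
        self.final_oob_error_ = float(self.oob_error_trajectory_[-1])
        return self

    # ------------------------------------------------------------------
    def _tree_votes(self, X) -> np.ndarray:
        """(n_trees, n_samples) predicted class codes for every tree."""
        votes = np.empty((self.n_trees, len(X)), dtype=np.int64)
        # inner trees are fitted on label-encoded y, codes follow classes_
        for t, tree in enumerate(self._bag.estimators_):
            votes[t] = np.asarray(tree.predict(X), dtype=np.int64)
        return votes

    def _oob_error(self, votes: np.ndarray) -> float:
        """Ensemble OOB error from a full vote matrix."""
        n = votes.shape[1]
        k = len(self.classes_)
        tally = np.zeros((n, k))
        for c in range(k):
            tally[:, c] = ((votes == c) & self._oob_masks).sum(axis=0)
        covered = tally.sum(axis=1) > 0
        pred = tally.argmax(axis=1)
        wrong = (pred != self._y_codes) & covered
        return float(wrong.sum() / max(covered.sum(), 1))

    def _trajectory(self, votes: np.ndarray) -> np.ndarray:
        n = votes.shape[1]
        k = len(self.classes_)
        tally = np.zeros((n, k))
        out = np.empty(self.n_trees)
        for t in range(self.n_trees):
            oob = self._oob_masks[t]
            for c in range(k):
                tally[oob & (votes[t] == c), c] += 1
            covered = tally.sum(axis=1) > 0
            pred = tally.argmax(axis=1)
            wrong = (pred != self._y_codes) & covered
            out[t] = wrong.sum() / max(covered.sum(), 1)
        return out

    def predict(self, X):
        return self._bag.predict(np.asarray(X, dtype=float))

    # ------------------------------------------------------------------
    def permutation_importance(
        self,
        feature_names=None,
        random_state: int | None = None,
    ) -> pd.DataFrame:
        """Increase in final OOB error (in %) after permuting each metabolite.

        One seeded permutation of the feature's values across samples; the
        trees are not refitted (standard permutation importance).  Returns a
        frame sorted descending by importance, ties broken by name, and
        stores it as ``importances_``.
        """
        if not hasattr(self, "_bag"):
            raise ValidationError("fit the forest before computing importance")
        X = self._X
        n, p = X.shape
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"feature_{j}" for j in range(p)]
        )
        if len(names) != p:
            raise ValidationError("feature_names length mismatch")
        rng = np.random.default_rng(
            random_state if random_state is not None else self.random_state
        )
        base = self.final_oob_error_
        # build one stacked matrix with every single-feature permutation and
        # run each tree once over it, instead of p x n_trees predict calls
        stacked = np.tile(X, (p, 1))
        for j in range(p):
            perm = rng.permutation(n)
            stacked[j * n : (j + 1) * n, j] = X[perm, j]
        votes = np.empty((self.n_trees, p * n), dtype=np.int64)
        for t, tree in enumerate(self._bag.estimators_):
            votes[t] = np.asarray(tree.predict(stacked), dtype=np.int64)
        increases = np.empty(p)
        for j in range(p):
            vj = votes[:, j * n : (j + 1) * n]
            increases[j] = (self._oob_error(vj) - base) * 100.0
        frame = pd.DataFrame({"metabolite": names, "importance": increases})
        frame = frame.sort_values(
            by=["importance", "metabolite"], ascending=[False, True]
        ).reset_index(drop=True)
        frame.insert(0, "rank", np.arange(1, p + 1))
        self.importances_ = frame
        return frame


def fit_genotype_forest(
    table, n_trees: int = 500, seed: int | None = None
) -> GenotypeForest:
    """Fit a genotype random forest on one tissue's PeakTable."""
    tissues = set(table.samples["tissue"])
    if len(tissues) != 1:
        raise ValidationError(
            f"genotype forest expects a single-tissue table, got {sorted(tissues)}"
        )
    est = GenotypeForest(n_trees=n_trees, random_state=seed)
    est.fit(table.values.to_numpy(dtype=float), table.samples["genotype"].to_numpy())
    return est


def permutation_importance(
    forest: GenotypeForest, table, seed: int | None = None
) -> pd.DataFrame:
    """Ranked permutation importance for a fitted genotype forest."""
    return forest.permutation_importance(
        feature_names=table.metabolites, random_state=seed
    )
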