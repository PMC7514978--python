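"""scikit-learn style estimators for the discrete BNC family.

All classifiers take an integer-coded categorical matrix ``X`` (missing
cells as -1 or NaN) and a label vector ``y``.  Attribute domains and the
class domain are frozen at fit time; values unseen in training are treated
as missing at prediction time, which keeps every count table index stable.

``UKDBClassifier`` is the ensemble of two unrestricted k-dependence
sub-models: one learned once from the training set (domain knowledge) and
one re-learned lazily for every prediction target from the value-level
dependence statistics of that instance (personalized knowledge).  Their
posteriors are averaged with uniform weights.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import MISSING, from_codes
from .inference import (
    augment_pseudo,
    ensemble_posterior,
    fit_cpts,
    log_posterior,
)
from .info_theory import build_counts
from .structure import (
    BNCStructure,
    learn_kdb,
    learn_nb,
    learn_tan,
    learn_ukdb_p,
    learn_ukdb_t,
)


def _encode_missing(X: np.ndarray) -> np.ndarray:
    """Float/int matrix -> int codes with MISSING for NaN or negatives."""
    X = check_array(X, dtype=float, ensure_all_finite=False)
    out = np.where(np.isnan(X) | (X < 0), MISSING, X).astype(int)
    return out


class BaseBNC(ClassifierMixin, BaseEstimator):
    """Shared fit/predict plumbing for the discrete BNC estimators."""

    def __init__(self, alpha: float = 1.0, log_base: float = 2.0):
        self.alpha = alpha
        self.log_base = log_base

    # subclasses: build the training-set structure from the fitted cache
    def _learn_structure(self) -> BNCStructure:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y):
        X = _encode_missing(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of rows")
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        if len(self.classes_) < 1:
            raise ValueError("no classes in y")
        self.n_features_in_ = X.shape[1]
        # attribute domains frozen at training time
        self.attribute_values_ = [
            np.unique(col[col != MISSING]) for col in X.T
        ]
        for i, vals in enumerate(self.attribute_values_):
            if vals.size == 0:
                raise ValueError(f"attribute {i} has no observed values")
        Xe = self._transform(X)
        sizes = [len(v) for v in self.attribute_values_]
        self._train_ds_ = from_codes(Xe, y_codes, sizes,
                                     class_domain=tuple(self.classes_))
        # training-mode fill values: used to impute test cells for
        # training-set models (the lazy sub-model skips missing instead)
        self.fill_values_ = np.array([
            int(np.argmax(np.bincount(col[col != MISSING], minlength=s)))
            for col, s in zip(Xe.T, sizes)
        ])
        self.cache_ = build_counts(self._train_ds_, log_base=self.log_base)
        self.structure_ = self._learn_structure()
        self.model_ = fit_cpts(self.structure_, self._train_ds_, self.alpha)
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        """Map raw values onto frozen domain codes; unseen -> MISSING."""
        out = np.full(X.shape, MISSING, dtype=int)
        for j, vals in enumerate(self.attribute_values_):
            col = X[:, j]
            pos = np.searchsorted(vals, col)
            pos = np.clip(pos, 0, len(vals) - 1)
            ok = (col != MISSING) & (vals[pos] == col)
            out[ok, j] = pos[ok]
        return out

    def _impute(self, Xe: np.ndarray) -> np.ndarray:
        out = Xe.copy()
        miss = out == MISSING
        out[miss] = np.broadcast_to(self.fill_values_, out.shape)[miss]
        return out

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        Xe = self._impute(self._transform(_encode_missing(X)))
        out = np.empty((Xe.shape[0], len(self.classes_)))
        for r in range(Xe.shape[0]):
            _, out[r] = log_posterior(self.model_, Xe[r])
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        return tags


class NaiveBayesClassifier(BaseBNC):
    """0-dependence naive Bayes over frozen categorical domains."""

    def _learn_structure(self) -> BNCStructure:
        return learn_nb(self.n_features_in_)


class TANClassifier(BaseBNC):
    """Tree-augmented naive Bayes (Chow–Liu maximum spanning tree on CMI)."""

    def _learn_structure(self) -> BNCStructure:
        return learn_tan(self.cache_)


class KDBClassifier(BaseBNC):
    """Sahami's k-dependence Bayesian classifier.

    Parameters
    ----------
    k : int, default 2
        Maximum number of attribute-parents per attribute.
    alpha : float, default 1.0
        Additive smoothing pseudo-count for the CPTs (0 = MLE).
    """

    def __init__(self, k: int = 2, alpha: float = 1.0, log_base: float = 2.0):
        super().__init__(alpha=alpha, log_base=log_base)
        self.k = k

    def _learn_structure(self) -> BNCStructure:
        return learn_kdb(self.cache_, self.k)


class UKDBClassifier(BaseBNC):
    """Unrestricted k-dependence ensemble (training-set + target model).

    The training-set sub-model selects the k attributes with the largest
    sum of pairwise CMI as the Markov-blanket parent set X_p; the lazy
    sub-model re-ranks by the value-level analogue (sum of CLMI) for each
    prediction target, after adding one pseudo instance per class so the
    target's values have well-defined statistics.  Missing values in the
    target are excluded from the lazy structure; the training-set sub-model
    sees them imputed with training modes.

    Attributes
    ----------
    structure_ : BNCStructure
        The training-set (domain knowledge) structure.
    """

    def __init__(
        self,
        k: int = 2,
        alpha: float = 1.0,
        log_base: float = 2.0,
        ensemble: bool = True,
    ):
        super().__init__(alpha=alpha, log_base=log_base)
        self.k = k
        self.ensemble = ensemble

    def _learn_structure(self) -> BNCStructure:
        return learn_ukdb_t(self.cache_, self.k)

    def fit(self, X, y):
        super().fit(X, y)
        codes = self._train_ds_.codes()
        y_codes = self._train_ds_.labels
        # per-class row matrices for lazy conditional-probability queries
        self._rows_by_class_ = [
            codes[y_codes == c] for c in range(len(self.classes_))
        ]
        return self

    # -- lazy (target) sub-model ----------------------------------------
    def _local_log_posterior(self, instance: np.ndarray) -> np.ndarray:
        """Posterior of the per-instance structure, computed lazily.

        Only the conditionals at the target's own values are needed, so the
        factors are estimated by direct (Laplace-smoothed) config counting
        against the class-partitioned training rows.
        """
        cache = augment_pseudo(self.cache_, instance)
        struct = learn_ukdb_p(cache, instance, self.k)
        m = len(self.classes_)
        alpha = self.alpha
        scores = np.zeros(m)
        # class factor P(c | x_p)
        xp = list(struct.xp)
        num = np.empty(m)
        for c, rows in enumerate(self._rows_by_class_):
            num[c] = np.count_nonzero(
                np.all(rows[:, xp] == instance[xp], axis=1)
            )
        scores += np.log((num + alpha) / (num.sum() + alpha * m))
        # attribute factors P(x_i | parents, c)
        for i in struct.attr_order:
            pa = list(struct.parents[i])
            v_i = int(self.cache_.domain_sizes[i])
            for c, rows in enumerate(self._rows_by_class_):
                pa_match = np.all(rows[:, pa] == instance[pa], axis=1)
                den = np.count_nonzero(pa_match & (rows[:, i] != MISSING))
                num_c = np.count_nonzero(pa_match & (rows[:, i] == instance[i]))
                scores[c] += np.log((num_c + alpha) / (den + alpha * v_i))
        return scores

    def predict_proba_parts(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Posteriors of the two sub-models separately (training-set, lazy)."""
        check_is_fitted(self, "model_")
        Xe = self._transform(_encode_missing(X))
        Xt = self._impute(Xe)
        m = len(self.classes_)
        p_t = np.empty((Xe.shape[0], m))
        p_p = np.empty((Xe.shape[0], m))
        for r in range(Xe.shape[0]):
            _, p_t[r] = log_posterior(self.model_, Xt[r])
            s = self._local_log_posterior(Xe[r])
            e = np.exp(s - s.max())
            p_p[r] = e / e.sum()
        return p_t, p_p

    def predict_proba(self, X):
        p_t, p_p = self.predict_proba_parts(X)
        if not self.ensemble:
            return p_t
        return np.vstack([
            ensemble_posterior(a, b) for a, b in zip(p_t, p_p)
        ])
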