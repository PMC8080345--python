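"""Group discrimination and assignment of unknown specimens.

Canonical variate analysis (CVA) on a reduced set of PC scores,
leave-one-out cross-validation, Mahalanobis distances, and the two
complementary membership measures used to place subfossil material:

* **typicality probability** — the probability that a genuine member of a
  group lies at least as far from the group mean as the observed specimen;
  an *absolute* membership test that can reject every group;
* **posterior probability** — the relative probability of membership among
  the candidate groups (sums to one), which always picks a winner however
  atypical the specimen is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import AlignedDataset, Configuration
from .morphospace import ShapePCA
from .procrustes import align_to_reference, procrustes_distance

__all__ = [
    "CanonicalVariateClassifier",
    "cva_fit",
    "loo_crossvalidate",
    "mahalanobis_d2",
    "typicality_probability",
    "posterior_probability",
    "classify_unknowns",
    "ClassificationReport",
    "retained_pcs",
]


class CanonicalVariateClassifier(ClassifierMixin, BaseEstimator):
    """Canonical variate analysis with Mahalanobis-distance assignment.

    Solves the generalized eigenproblem of the between-group covariance B
    against the pooled within-group covariance W on retained PC scores.
    Canonical axes are scaled so the pooled within-group variance is 1 on
    every axis (the Mahalanobis property): squared Euclidean distance in the
    full canonical space equals Mahalanobis D² in the original score space.
    Only min(G−1, k) axes carry between-group variance.

    Parameters
    ----------
    typicality : {"chisq", "f"}
        Distribution used for typicality probabilities: chi-square with
        df = number of variables (default), or a small-sample F form based
        on Hotelling's T² with the pooled error df.
    priors : None or dict
        Group prior probabilities for posteriors (default equal).

    Attributes
    ----------
    classes_ : (G,) group labels.
    means_ : (G, k) group mean scores.
    pooled_cov_ : (k, k) pooled within-group covariance W (divisor N − G).
    between_cov_ : (k, k) between-group covariance B (divisor G − 1).
    scalings_ : (k, k) generalized eigenvectors, columns W-orthonormal.
    eigenvalues_ : (k,) generalized eigenvalues, descending.
    n_canonical_axes_ : min(G − 1, k).
    among_group_fractions_ : share of among-group variance per canonical axis.
    """

    def __init__(self, typicality: str = "chisq", priors: dict | None = None):
        self.typicality = typicality
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, k = X.shape
        classes, counts = np.unique(y, return_counts=True)
        g = len(classes)
        if g < 2:
            raise ValueError("need at least two groups")
        if counts.min() < 2:
            raise ValueError("every group needs at least two members")
        if k > n - g:
            raise ValueError(
                f"{k} variables with only {n - g} within-group df: pooled "
                "covariance singular; retain fewer PCs"
            )
        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        grand = X.mean(axis=0)
        W = np.zeros((k, k))
        for c, mu in zip(classes, means):
            d = X[y == c] - mu
            W += d.T @ d
        W /= n - g
        B = np.zeros((k, k))
        for cnt, mu in zip(counts, means):
            d = (mu - grand)[:, None]
            B += cnt * (d @ d.T)
        B /= g - 1
        try:
            evals, evecs = linalg.eigh(B, W)
        except linalg.LinAlgError as e:
            raise ValueError("singular pooled covariance; retain fewer PCs") from e
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.where(np.abs(evals) < 1e-10, 0.0, evals)

        self.classes_ = classes
        self.group_sizes_ = counts
        self.means_ = means
        self.grand_mean_ = grand
        self.pooled_cov_ = W
        self.between_cov_ = B
        self.scalings_ = evecs  # columns satisfy vᵀ W v = 1
        self.eigenvalues_ = evals
        self.n_canonical_axes_ = min(g - 1, k)
        pos = evals[: self.n_canonical_axes_]
        self.among_group_fractions_ = pos / pos.sum() if pos.sum() > 0 else pos
        self.n_features_in_ = k
        self.n_samples_ = n
        self._cho = linalg.cho_factor(W)
        return self

    # -- geometry ---------------------------------------------------------

    def canonical_scores(self, X) -> np.ndarray:
        """Project score vectors onto the canonical axes (grand-mean
        centred); all k W-whitened axes are returned, the first
        ``n_canonical_axes_`` carry the between-group separation."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.grand_mean_) @ self.scalings_

    def mahalanobis_d2(self, X, group=None) -> np.ndarray:
        """Mahalanobis D² to one group mean, or to all (columns) if
        ``group`` is None: D² = (x − μ_g)ᵀ W⁻¹ (x − μ_g)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"point has {X.shape[1]} features, model fitted with {self.n_features_in_}"
            )
        targets = self.means_ if group is None else self.means_[[self._gidx(group)]]
        out = np.empty((X.shape[0], targets.shape[0]))
        for j, mu in enumerate(targets):
            d = X - mu
            out[:, j] = (d * linalg.cho_solve(self._cho, d.T).T).sum(axis=1)
        return out if group is None else out[:, 0]

    def _gidx(self, group) -> int:
        idx = np.nonzero(self.classes_ == group)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown group {group!r}")
        return int(idx[0])

    # -- probabilities ----------------------------------------------------

    def typicality_probability(self, X, group=None) -> np.ndarray:
        """Upper-tail probability that a genuine group member is at least as
        far (in D²) from the group mean as the observation."""
        d2 = self.mahalanobis_d2(X, group)
        k = self.n_features_in_
        if self.typicality == "chisq":
            return sps.chi2.sf(d2, df=k)
        if self.typicality == "f":
            m = self.n_samples_ - len(self.classes_)  # pooled error df
            fstat = d2 * (m - k + 1) / (m * k)
            return sps.f.sf(fstat, k, m - k + 1)
        raise ValueError(f"unknown typicality variant {self.typicality!r}")

    def posterior_probability(self, X) -> np.ndarray:
        """Posterior membership probabilities over groups,
        P(g|x) ∝ prior_g · exp(−D²_g / 2), computed with max-subtraction."""
        d2 = self.mahalanobis_d2(X)
        if self.priors is None:
            log_prior = np.zeros(len(self.classes_))
        else:
            pr = np.array([self.priors[c] for c in self.classes_], dtype=float)
            log_prior = np.log(pr / pr.sum())
        log_w = -0.5 * d2 + log_prior
        log_w -= log_w.max(axis=1, keepdims=True)
        w = np.exp(log_w)
        return w / w.sum(axis=1, keepdims=True)

    def predict(self, X):
        d2 = self.mahalanobis_d2(np.atleast_2d(X))
        if self.priors is None:
            return self.classes_[np.argmin(d2, axis=1)]
        return self.classes_[np.argmax(self.posterior_probability(X), axis=1)]

    def predict_proba(self, X):
        return self.posterior_probability(X)


def cva_fit(scores: np.ndarray, groups, **kwargs) -> CanonicalVariateClassifier:
    """Fit a CVA model to retained PC scores and group labels."""
    return CanonicalVariateClassifier(**kwargs).fit(scores, groups)


def mahalanobis_d2(model: CanonicalVariateClassifier, point, group):
    return float(model.mahalanobis_d2(np.atleast_2d(point), group)[0])


def typicality_probability(model: CanonicalVariateClassifier, point, group):
    return float(model.typicality_probability(np.atleast_2d(point), group)[0])


def posterior_probability(model: CanonicalVariateClassifier, point) -> np.ndarray:
    return model.posterior_probability(np.atleast_2d(point))[0]


def loo_crossvalidate(scores: np.ndarray, groups) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated assignment accuracy.

    Each specimen is assigned to the nearest group by Mahalanobis D² under a
    model refitted without it (group means and pooled within-group
    covariance recomputed). Returns (accuracy, confusion table with true
    groups as rows).
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    classes, counts = np.unique(groups, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs at least two members for LOO")
    n = scores.shape[0]
    preds = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = CanonicalVariateClassifier().fit(scores[mask], groups[mask])
        preds[i] = model.predict(scores[i][None])[0]
        mask[i] = True
    correct = float((preds == groups).mean())
    confusion = pd.crosstab(
        pd.Series(groups, name="true"), pd.Series(preds, name="assigned")
    ).reindex(index=classes, columns=classes, fill_value=0)
    return correct, confusion


def retained_pcs(space: ShapePCA, min_variance: float = 0.90, cap: int | None = None) -> int:
    """Smallest number of leading PCs whose cumulative variance fraction
    reaches ``min_variance``, optionally capped (e.g. at N − G − 1 so the
    pooled covariance stays invertible)."""
    cum = np.cumsum(space.variance_fractions_)
    k = int(np.searchsorted(cum, min_variance) + 1)
    if cap is not None:
        k = min(k, cap)
    return max(k, 1)


@dataclass
class ClassificationReport:
    """Per-unknown distances, probabilities and calls against the reference
    groups. The typicality call requires p > ``typicality_threshold`` (no
    call otherwise); the posterior call is the maximum-posterior group,
    reported regardless of absolute fit."""

    groups: list[str]
    table: pd.DataFrame
    typicality_threshold: float = 0.20
    errors: dict[str, str] = field(default_factory=dict)


def classify_unknowns(
    model: CanonicalVariateClassifier,
    space: ShapePCA,
    dataset: AlignedDataset,
    unknowns: list[Configuration],
    n_retained: int | None = None,
    typicality_threshold: float = 0.20,
    no_affinity_threshold: float = 0.05,
) -> ClassificationReport:
    """Assign unknown configurations to the reference groups.

    Pipeline per unknown: mirror (if left) → align + slide against the fixed
    training consensus → PC projection → Mahalanobis D², typicality and
    posterior probabilities per group → calls. Also reports the Procrustes
    distance from the aligned unknown to each group's mean shape. A specimen
    whose best typicality falls below ``no_affinity_threshold`` is flagged
    as showing no clear affinity. Per-specimen projection failures are
    collected and the remaining specimens processed.
    """
    k = n_retained or model.n_features_in_
    glabels = [str(c) for c in model.classes_]
    genus_all = dataset.column("genus").astype(str)
    group_mean_shapes = {
        g: dataset.shapes[genus_all == g].mean(axis=0) for g in glabels
    }
    rows = []
    errors: dict[str, str] = {}
    for cfg in unknowns:
        try:
            aligned = align_to_reference(cfg, space.mean_shape_, dataset.scheme)
            scores_full = space.transform(aligned)
            x = scores_full[:k][None]
        except Exception as e:  # propagate per specimen, continue others
            errors[cfg.specimen_id] = str(e)
            continue
        d2 = model.mahalanobis_d2(x)[0]
        typ = model.typicality_probability(x)[0]
        post = model.posterior_probability(x)[0]
        pd_to_group = {
            g: procrustes_distance(aligned, group_mean_shapes[g]) for g in glabels
        }
        best_typ = glabels[int(np.argmax(typ))]
        best_post = glabels[int(np.argmax(post))]
        row = {"specimen_id": cfg.specimen_id}
        for j, g in enumerate(glabels):
            row[f"procrustes_dist_{g}"] = pd_to_group[g]
            row[f"mahalanobis_d2_{g}"] = d2[j]
            row[f"typicality_{g}"] = typ[j]
            row[f"posterior_{g}"] = post[j]
        row["typicality_call"] = best_typ if typ.max() > typicality_threshold else ""
        row["posterior_call"] = best_post
        row["no_clear_affinity"] = bool(typ.max() < no_affinity_threshold)
        rows.append(row)
    return ClassificationReport(
        groups=glabels,
        table=pd.DataFrame(rows),
        typicality_threshold=typicality_threshold,
        errors=errors,
    )
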