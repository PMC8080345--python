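"""Hypothesis tests on aligned shape data.

Procrustes ANOVA (shape ~ genus * log size) with residual-randomization
permutation (RRPP), pairwise mean-shape permutation tests, one-way
centroid-size ANOVA with Tukey HSD, and the multivariate phylogenetic-signal
statistic K_mult.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import AlignedDataset
from .procrustes import procrustes_distance

__all__ = [
    "AnovaResult",
    "SignalResult",
    "procrustes_anova",
    "pairwise_group_tests",
    "size_anova_tukey",
    "kmult",
    "tree_covariance",
]


@dataclass
class AnovaResult:
    """Sequential (type-I) multivariate ANOVA table with permutation p-values."""

    terms: list[str]
    ss: np.ndarray
    df: np.ndarray
    ms: np.ndarray
    f: np.ndarray
    r2: np.ndarray
    p: np.ndarray
    ss_residual: float
    df_residual: int
    ss_total: float
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        rows = list(zip(self.terms, self.df, self.ss, self.ms, self.f, self.r2, self.p))
        rows.append(("residual", self.df_residual, self.ss_residual,
                     self.ss_residual / self.df_residual, np.nan, np.nan, np.nan))
        rows.append(("total", self.df.sum() + self.df_residual, self.ss_total,
                     np.nan, np.nan, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["term", "df", "SS", "MS", "F", "R2", "p"])


@dataclass
class SignalResult:
    """Multivariate phylogenetic signal (K_mult) with permutation p-value."""

    k_mult: float
    p_value: float
    n_permutations: int
    phylo_mean: np.ndarray = field(repr=False)
    tree_cov: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _dummies(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded dummies (first level dropped)."""
    levels = sorted(set(labels))
    out = np.zeros((len(labels), len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        out[:, j] = labels == lev
    return out


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def procrustes_anova(
    dataset: AlignedDataset,
    terms: tuple[str, ...] = ("genus", "log_size", "interaction"),
    group_field: str = "genus",
    n_perm: int = 1000,
    seed: int | None = None,
    log_size: bool = True,
) -> AnovaResult:
    """Procrustes ANOVA of shape on group and size.

    A linear model on the vectorized shape coordinates, built term by term
    (sequential, type-I sums of squares in the order given). Sums of squares
    are summed squared residual distances; F for each term uses the
    full-model residual. Significance is assessed by residual randomization
    (RRPP): for each term, the residuals of the reduced model (all preceding
    terms) are permuted, added back to the reduced fit, and the term's F
    recomputed; p = (#{F* ≥ F_obs} + 1)/(n_perm + 1) with the observed
    permutation included.

    ``size`` enters as log centroid size by default (``log_size=False`` uses
    raw centroid size).
    """
    y = dataset.flat()
    n = y.shape[0]
    groups = dataset.column(group_field).astype(str)
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = levels[counts < 2].tolist()
        raise ValueError(f"singleton groups: {small}")
    size = np.log(dataset.centroid_sizes) if log_size else dataset.centroid_sizes.copy()
    size = size - size.mean()

    g = _dummies(groups)
    blocks: dict[str, np.ndarray] = {
        "genus": g,
        "group": g,
        "log_size": size[:, None],
        "size": size[:, None],
        "interaction": g * size[:, None],
    }
    unknown = [t for t in terms if t not in blocks]
    if unknown:
        raise ValueError(f"unknown terms: {unknown}")

    ones = np.ones((n, 1))
    designs = [ones]
    for t in terms:
        designs.append(np.hstack([designs[-1], blocks[t]]))
    for i, t in enumerate(terms):
        if np.linalg.matrix_rank(designs[i + 1]) - np.linalg.matrix_rank(designs[i]) < blocks[t].shape[1]:
            raise ValueError(f"collinear term: {t}")

    hats = [_hat(X) for X in designs]
    eye = np.eye(n)
    ss_total = float(((eye - hats[0]) @ y * y).sum())
    df_terms = np.array([designs[i + 1].shape[1] - designs[i].shape[1] for i in range(len(terms))])
    df_res = n - designs[-1].shape[1]
    if df_res <= 0:
        raise ValueError("model saturates the data; no residual df")

    def _stats(ymat: np.ndarray) -> tuple[np.ndarray, float]:
        rss = np.array(
            [float(((eye - h) @ ymat * ymat).sum()) for h in hats]
        )
        ss_terms = rss[:-1] - rss[1:]
        return ss_terms, rss[-1]

    ss_terms, ss_res = _stats(y)
    ms_terms = ss_terms / df_terms
    ms_res = ss_res / df_res
    f_obs = ms_terms / ms_res
    r2 = ss_terms / ss_total

    rng = np.random.default_rng(seed)
    p = np.ones(len(terms))
    if n_perm > 0:
        count = np.ones(len(terms))  # observed permutation included
        resid_red = [(eye - hats[i]) @ y for i in range(len(terms))]
        fit_red = [hats[i] @ y for i in range(len(terms))]
        for _ in range(n_perm):
            perm = rng.permutation(n)
            for i in range(len(terms)):
                y_star = fit_red[i] + resid_red[i][perm]
                rss_red = float(((eye - hats[i]) @ y_star * y_star).sum())
                rss_term = float(((eye - hats[i + 1]) @ y_star * y_star).sum())
                rss_full = float(((eye - hats[-1]) @ y_star * y_star).sum())
                f_star = ((rss_red - rss_term) / df_terms[i]) / (rss_full / df_res)
                if f_star >= f_obs[i] - 1e-12:
                    count[i] += 1
        p = count / (n_perm + 1)

    return AnovaResult(
        terms=list(terms),
        ss=ss_terms,
        df=df_terms,
        ms=ms_terms,
        f=f_obs,
        r2=r2,
        p=p,
        ss_residual=ss_res,
        df_residual=df_res,
        ss_total=ss_total,
        n_permutations=n_perm,
    )


def pairwise_group_tests(
    dataset: AlignedDataset,
    group_field: str = "genus",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise mean-shape distances between groups with permutation
    p-values.

    The statistic for each pair is the Procrustes distance between the two
    group mean shapes; the null distribution permutes group labels within
    the pair. Raw (uncorrected) p-values are reported.
    """
    groups = dataset.column(group_field).astype(str)
    levels = sorted(set(groups))
    shapes = dataset.shapes
    rng = np.random.default_rng(seed)
    rows = []
    for a_i in range(len(levels)):
        for b_i in range(a_i + 1, len(levels)):
            a, b = levels[a_i], levels[b_i]
            mask = (groups == a) | (groups == b)
            sub = shapes[mask]
            lab = (groups[mask] == b).astype(int)
            d_obs = procrustes_distance(sub[lab == 0].mean(0), sub[lab == 1].mean(0))
            count = 1
            for _ in range(n_perm):
                perm = rng.permutation(lab)
                d_star = procrustes_distance(
                    sub[perm == 0].mean(0), sub[perm == 1].mean(0)
                )
                if d_star >= d_obs - 1e-15:
                    count += 1
            rows.append((a, b, d_obs, count / (n_perm + 1)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "distance", "p"])


def size_anova_tukey(
    dataset: AlignedDataset,
    group_field: str = "genus",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA of centroid size between groups with Tukey HSD
    post-hoc comparisons.

    Returns ``(anova_table, tukey_table, group_summary)`` where the summary
    holds each group's mean ± sd centroid size.
    """
    groups = dataset.column(group_field).astype(str)
    cs = dataset.centroid_sizes
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    by = [cs[groups == g] for g in levels]
    if min(len(b) for b in by) < 2:
        raise ValueError("every group needs at least two members")
    grand = cs.mean()
    ssb = sum(len(b) * (b.mean() - grand) ** 2 for b in by)
    ssw = sum(((b - b.mean()) ** 2).sum() for b in by)
    dfb, dfw = len(levels) - 1, len(cs) - len(levels)
    if ssw == 0:
        raise ValueError("zero pooled variance")
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    anova = pd.DataFrame(
        {
            "term": [group_field, "residual"],
            "df": [dfb, dfw],
            "SS": [ssb, ssw],
            "MS": [ssb / dfb, ssw / dfw],
            "F": [f, np.nan],
            "p": [p, np.nan],
        }
    )
    hsd = pairwise_tukeyhsd(cs, groups)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    summary = pd.DataFrame(
        {
            "group": levels,
            "n": [len(b) for b in by],
            "mean_cs": [b.mean() for b in by],
            "sd_cs": [b.std(ddof=1) for b in by],
        }
    )
    return anova, tukey, summary


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

def tree_covariance(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Brownian-motion covariance matrix C of a rooted tree: C[i, j] is the
    shared root-to-MRCA path length of tips i and j; C[i, i] is the
    root-to-tip depth."""
    tree = tree.clone(depth=1)
    for nd in tree.preorder_node_iter():
        parent_depth = 0.0 if nd.parent_node is None else nd.parent_node._depth
        length = nd.edge.length or 0.0
        nd._depth = parent_depth + (0.0 if nd.parent_node is None else length)
    n = len(labels)
    index = {lb: i for i, lb in enumerate(labels)}
    C = np.zeros((n, n))
    # postorder: each node knows its descendant tips; MRCA depth fills blocks
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lb = nd.taxon.label
            if lb not in index:
                raise ValueError(f"tip {lb!r} not in requested labels")
            nd._tips = [index[lb]]
            C[index[lb], index[lb]] = nd._depth
        else:
            kids = nd.child_nodes()
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]._tips:
                        for j in kids[b]._tips:
                            C[i, j] = C[j, i] = nd._depth
            nd._tips = [i for k in kids for i in k._tips]
    covered = sorted(tree.seed_node._tips)
    if covered != list(range(n)):
        missing = [labels[i] for i in set(range(n)) - set(covered)]
        raise ValueError(f"species without tree tips: {missing}")
    return C


def kmult(
    species_values: dict[str, np.ndarray],
    tree: dendropy.Tree,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SignalResult:
    """Multivariate phylogenetic signal K_mult.

    The multivariate generalization of Blomberg's K: the ratio of observed
    to Brownian-expected phylogenetic structure in multivariate traits, equal
    to 1 in expectation under Brownian motion on the given tree. With tree
    covariance C, phylogenetically weighted mean
    a = (1ᵀC⁻¹1)⁻¹ 1ᵀC⁻¹Y and centred data E = Y − 1a:

        K = [tr(EᵀE) / tr(EᵀC⁻¹E)] ÷ [(tr(C) − n / 1ᵀC⁻¹1) / (n − 1)]

    Significance is by phylogenetic permutation: shuffle the data across the
    tips, recompute K, p = proportion of permutations (observed included)
    with K ≥ the observed value.
    """
    labels = sorted(species_values)
    Y = np.vstack([np.atleast_1d(np.asarray(species_values[lb], float)) for lb in labels])
    n = Y.shape[0]
    C = tree_covariance(tree, labels)
    Cinv = np.linalg.inv(C)
    ones = np.ones((n, 1))
    denom_a = float((ones.T @ Cinv @ ones).item())
    expected = (float(np.trace(C)) - n / denom_a) / (n - 1)

    def _k(Ymat: np.ndarray) -> float:
        a = (ones.T @ Cinv @ Ymat) / denom_a
        E = Ymat - ones @ a
        num = float(np.trace(E.T @ E))
        den = float(np.trace(E.T @ Cinv @ E))
        if den == 0.0:
            raise ValueError("zero phylogenetically weighted variance")
        return (num / den) / expected

    y_sd = Y.std(axis=0).sum()
    if y_sd == 0:
        raise ValueError("data identical at all tips; K undefined")
    k_obs = _k(Y)
    rng = np.random.default_rng(seed)
    count, total = 1, 1
    for _ in range(max(n_perm - 1, 0)):
        k_star = _k(Y[rng.permutation(n)])
        total += 1
        if k_star >= k_obs - 1e-15:
            count += 1
    a_obs = ((ones.T @ Cinv @ Y) / denom_a).ravel()
    return SignalResult(
        k_mult=k_obs,
        p_value=count / total,
        n_permutations=total,
        phylo_mean=a_obs,
        tree_cov=C,
    )
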