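"""Population-differentiation battery for song feature tables.

The battery mirrors the standard design for hierarchical bioacoustic
data — songs nested in individuals nested in populations:

* PCA on the correlation matrix of the 14 spectral variables,
  retaining components with eigenvalue > 1;
* nested MANOVA on the retained scores (population tested against
  individual-within-population variation, individual against the
  residual) using Wilks' Λ with Rao's F approximation, plus the
  univariate nested ANOVA per component;
* canonical discriminant analysis (DFA) classifying songs to
  populations, reporting canonical correlations and the
  resubstitution correct-classification rate;
* non-metric multidimensional scaling (NMDS) on Euclidean distances
  between z-scored feature vectors;
* Kruskal–Wallis with Dunn's pairwise follow-up (Bonferroni) for the
  CVM rates, which are far from normal.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.manifold import smacof
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import LeaveOneGroupOut, cross_val_predict

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "NestedModelResult",
    "DFAModel",
    "OrdinationResult",
    "RankTestResult",
    "pca_reduce",
    "nested_anova",
    "nested_manova",
    "nested_anova_per_pc",
    "discriminant_analysis",
    "nmds",
    "kruskal_dunn",
    "DesignError",
]


class DesignError(ValueError):
    """The grouping structure cannot support the requested test."""


# ---------------------------------------------------------------- PCA


@dataclass
class PCAModel:
    feature_names: list[str]
    loadings: np.ndarray  # p x p eigenvectors (columns), descending
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    k: int  # retained components (eigenvalue > cutoff)
    scores: pd.DataFrame  # song x retained PRIN columns
    dropped_constant: list[str]

    @property
    def retained_variance(self) -> float:
        return float(self.variance_fractions[: self.k].sum())

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PRIN{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.feature_names, columns=cols)


def pca_reduce(
    features: pd.DataFrame,
    eigenvalue_cutoff: float = 1.0,
    feature_names: list[str] | None = None,
) -> PCAModel:
    """Correlation-matrix PCA with eigenvalue-> cutoff retention.

    Variables are z-scored (they mix Hz, seconds, counts and
    proportions), components come from the eigendecomposition of the
    correlation matrix, and the retained count is the number of
    eigenvalues above ``eigenvalue_cutoff`` (default 1.0, the
    mean-eigenvalue rule), capped at the matrix rank.  Component signs
    are fixed by making each component's largest-|loading| element
    positive, so outputs are reproducible.
    """
    if feature_names is None:
        feature_names = [
            c for c in features.columns if features[c].dtype.kind in "fi"
        ]
    X = features[feature_names].to_numpy(dtype=float)
    keep, dropped = [], []
    for j, name in enumerate(feature_names):
        if np.std(X[:, j]) == 0:
            dropped.append(name)
        else:
            keep.append(j)
    if dropped:
        logger.warning("dropping constant columns from PCA: %s", dropped)
    names = [feature_names[j] for j in keep]
    X = X[:, keep]
    n, p = X.shape
    if n < p + 1:
        logger.warning("only %d songs for %d variables; rank-deficient PCA", n, p)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    # deterministic sign: largest-|loading| element positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    rank = int(np.sum(evals > 1e-10))
    k = int(np.sum(evals > eigenvalue_cutoff))
    k = max(1, min(k, rank))
    scores = Z @ evecs[:, :k]
    score_df = pd.DataFrame(
        scores, columns=[f"PRIN{i + 1}" for i in range(k)], index=features.index
    )
    for lbl in ("song_id", "individual_id", "population_id"):
        if lbl in features.columns:
            score_df[lbl] = features[lbl].to_numpy()
    return PCAModel(
        feature_names=names,
        loadings=evecs,
        eigenvalues=evals,
        variance_fractions=evals / evals.sum(),
        k=k,
        scores=score_df,
        dropped_constant=dropped,
    )


# ------------------------------------------------- nested ANOVA/MANOVA


@dataclass
class NestedModelResult:
    effect: str  # "population" or "individual"
    statistic_name: str  # "Wilks" or "F"
    statistic: float
    approx_f: float
    df_num: float
    df_den: float
    pvalue: float


def _nested_sscp(
    Y: np.ndarray, pop: np.ndarray, ind: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int, int]:
    """Hypothesis and error SSCP matrices for the two-level nested design."""
    N, k = Y.shape
    grand = Y.mean(axis=0)
    pops = np.unique(pop)
    inds = np.unique(ind)
    if len(pops) < 2:
        raise DesignError("need at least 2 populations")
    H_pop = np.zeros((k, k))
    H_ind = np.zeros((k, k))
    E = np.zeros((k, k))
    n_ind_total = 0
    for p in pops:
        mask_p = pop == p
        Yp = Y[mask_p]
        mp = Yp.mean(axis=0)
        d = (mp - grand)[:, None]
        H_pop += len(Yp) * (d @ d.T)
        for i in np.unique(ind[mask_p]):
            mask_i = mask_p & (ind == i)
            Yi = Y[mask_i]
            mi = Yi.mean(axis=0)
            d = (mi - mp)[:, None]
            H_ind += len(Yi) * (d @ d.T)
            E += (Yi - mi).T @ (Yi - mi)
            n_ind_total += 1
    df_pop = len(pops) - 1
    df_ind = n_ind_total - len(pops)
    df_res = N - n_ind_total
    if df_ind < 1:
        raise DesignError(
            "population effect unestimable: no individual-within-population "
            "degrees of freedom (≥2 individuals in ≥1 population required)"
        )
    if df_res < 1:
        raise DesignError("individual effect unestimable: ≥2 songs per individual required")
    return H_pop, H_ind, E, df_pop, df_ind, df_res


def _wilks_rao(H: np.ndarray, E: np.ndarray, df_h: int, df_e: int) -> NestedModelResult:
    k = H.shape[0]
    lam = np.real(linalg.det(E) / linalg.det(E + H))
    lam = float(np.clip(lam, np.finfo(float).tiny, 1.0))
    q = df_h
    if k * k + q * q - 5 > 0:
        s = np.sqrt((k * k * q * q - 4) / (k * k + q * q - 5))
    else:
        s = 1.0
    df1 = k * q
    w = df_e + q - (k + q + 1) / 2
    df2 = w * s - (k * q) / 2 + 1
    lam_s = lam ** (1 / s)
    F = (1 - lam_s) / lam_s * df2 / df1
    p = float(stats.f.sf(F, df1, df2)) if df2 > 0 else float("nan")
    return NestedModelResult(
        effect="",
        statistic_name="Wilks",
        statistic=lam,
        approx_f=float(F),
        df_num=float(df1),
        df_den=float(df2),
        pvalue=p,
    )


def nested_manova(
    scores: pd.DataFrame,
    score_cols: list[str] | None = None,
    pop_col: str = "population_id",
    ind_col: str = "individual_id",
) -> list[NestedModelResult]:
    """Nested MANOVA: songs within individuals within populations.

    The population effect is tested against the individual-within-
    population SSCP, the individual effect against the song-level
    residual.  Wilks' Λ is converted to an approximate F by Rao's
    transformation; for one response the test reduces exactly to the
    classical nested ANOVA F.
    """
    if score_cols is None:
        score_cols = [c for c in scores.columns if c.startswith("PRIN")]
    Y = scores[score_cols].to_numpy(dtype=float)
    pop = scores[pop_col].to_numpy()
    ind = scores[ind_col].to_numpy()
    H_pop, H_ind, E, df_pop, df_ind, df_res = _nested_sscp(Y, pop, ind)
    r_pop = _wilks_rao(H_pop, H_ind, df_pop, df_ind)
    r_pop.effect = "population"
    r_ind = _wilks_rao(H_ind, E, df_ind, df_res)
    r_ind.effect = "individual"
    return [r_pop, r_ind]


def nested_anova(
    values: np.ndarray, pop: np.ndarray, ind: np.ndarray
) -> list[NestedModelResult]:
    """Univariate two-level nested ANOVA by sums of squares.

    F(population) = MS_population / MS_individual(population);
    F(individual) = MS_individual(population) / MS_residual.
    """
    Y = np.asarray(values, dtype=float).reshape(-1, 1)
    H_pop, H_ind, E, df_pop, df_ind, df_res = _nested_sscp(Y, np.asarray(pop), np.asarray(ind))
    ss_pop, ss_ind, ss_res = float(H_pop[0, 0]), float(H_ind[0, 0]), float(E[0, 0])
    f_pop = (ss_pop / df_pop) / (ss_ind / df_ind)
    f_ind = (ss_ind / df_ind) / (ss_res / df_res)
    return [
        NestedModelResult(
            "population", "F", f_pop, f_pop, df_pop, df_ind,
            float(stats.f.sf(f_pop, df_pop, df_ind)),
        ),
        NestedModelResult(
            "individual", "F", f_ind, f_ind, df_ind, df_res,
            float(stats.f.sf(f_ind, df_ind, df_res)),
        ),
    ]


def nested_anova_per_pc(
    scores: pd.DataFrame,
    score_cols: list[str] | None = None,
    pop_col: str = "population_id",
    ind_col: str = "individual_id",
) -> pd.DataFrame:
    """Nested ANOVA on each retained component separately."""
    if score_cols is None:
        score_cols = [c for c in scores.columns if c.startswith("PRIN")]
    rows = []
    for col in score_cols:
        for r in nested_anova(
            scores[col].to_numpy(), scores[pop_col].to_numpy(), scores[ind_col].to_numpy()
        ):
            rows.append(
                {
                    "variable": col,
                    "effect": r.effect,
                    "F": r.approx_f,
                    "df_num": r.df_num,
                    "df_den": r.df_den,
                    "p": r.pvalue,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- DFA


@dataclass
class DFAModel:
    canonical_correlations: np.ndarray  # descending, in [0, 1]
    variance_explained: np.ndarray  # per canonical axis
    axes: np.ndarray  # k x n_axes discriminant directions
    canonical_scores: pd.DataFrame
    predictions: np.ndarray
    correct_rate: float
    confusion: pd.DataFrame
    cv_correct_rate: float | None = None


def discriminant_analysis(
    scores: pd.DataFrame,
    score_cols: list[str] | None = None,
    pop_col: str = "population_id",
    ind_col: str = "individual_id",
    cross_validate_individuals: bool = False,
) -> DFAModel:
    """Canonical discriminant analysis of songs onto populations.

    Canonical axes maximize the between/within variance ratio (the
    generalized eigenproblem B v = λ W v); canonical correlation per
    axis is sqrt(λ/(1+λ)).  The reported correct-classification rate is
    resubstitution, matching the usual reporting of a fitted
    discriminant model; pass ``cross_validate_individuals=True`` for an
    honest leave-one-individual-out rate as well.
    """
    if score_cols is None:
        score_cols = [c for c in scores.columns if c.startswith("PRIN")]
    X = scores[score_cols].to_numpy(dtype=float)
    y = scores[pop_col].to_numpy()
    groups = np.unique(y)
    if len(groups) < 2:
        raise DesignError("need at least 2 populations for a DFA")
    k = X.shape[1]
    grand = X.mean(axis=0)
    B = np.zeros((k, k))
    W = np.zeros((k, k))
    for g in groups:
        Xg = X[y == g]
        if len(Xg) < 2:
            raise DesignError(f"population {g!r} has fewer than 2 songs")
        mg = Xg.mean(axis=0)
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)
        W += (Xg - mg).T @ (Xg - mg)
    # ridge-regularize a singular within matrix
    eps = 0.0
    if np.linalg.cond(W) > 1e10:
        eps = 1e-8 * np.trace(W) / k
        logger.warning("within-group SSCP near singular; ridge epsilon %.3g", eps)
        W = W + eps * np.eye(k)
    evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1]
    n_axes = min(k, len(groups) - 1)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    axes = evecs[:, order][:, :n_axes]
    for j in range(axes.shape[1]):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    can_corr = np.sqrt(evals / (1 + evals))
    var_exp = evals / evals.sum() if evals.sum() > 0 else np.zeros_like(evals)
    can_scores = (X - grand) @ axes
    can_df = pd.DataFrame(
        can_scores, columns=[f"CAN{i + 1}" for i in range(n_axes)], index=scores.index
    )
    for lbl in ("song_id", ind_col, pop_col):
        if lbl in scores.columns:
            can_df[lbl] = scores[lbl].to_numpy()

    lda = LinearDiscriminantAnalysis()
    lda.fit(X, y)
    pred = lda.predict(X)
    rate = float(np.mean(pred == y))
    conf = pd.DataFrame(
        confusion_matrix(y, pred, labels=groups), index=groups, columns=groups
    )
    cv_rate = None
    if cross_validate_individuals:
        logo = LeaveOneGroupOut()
        cv_pred = cross_val_predict(
            LinearDiscriminantAnalysis(), X, y, groups=scores[ind_col], cv=logo
        )
        cv_rate = float(np.mean(cv_pred == y))
    return DFAModel(
        canonical_correlations=can_corr,
        variance_explained=var_exp,
        axes=axes,
        canonical_scores=can_df,
        predictions=pred,
        correct_rate=rate,
        confusion=conf,
        cv_correct_rate=cv_rate,
    )


# ---------------------------------------------------------------- NMDS


@dataclass
class OrdinationResult:
    configuration: np.ndarray  # n x dims
    stress: float  # normalized stress-1
    iterations: int
    converged: bool
    degenerate: bool = False


def nmds(
    features: pd.DataFrame | np.ndarray,
    feature_names: list[str] | None = None,
    dims: int = 2,
    restarts: int = 20,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 300,
    precomputed: bool = False,
) -> OrdinationResult:
    """Non-metric MDS of songs on Euclidean distances of z-scored
    variables (or a precomputed square dissimilarity matrix).

    Runs SMACOF with monotone regression from ``restarts`` random
    initializations (seeded) and keeps the lowest-stress solution;
    stress is Kruskal's normalized stress-1.
    """
    if precomputed:
        D = np.asarray(features, dtype=float)
    else:
        if isinstance(features, pd.DataFrame):
            if feature_names is None:
                feature_names = [
                    c for c in features.columns if features[c].dtype.kind in "fi"
                ]
            X = features[feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(Z))
    if D.shape[0] < dims + 2:
        raise ValueError(f"need at least {dims + 2} songs for a {dims}-D NMDS")
    off = D[~np.eye(D.shape[0], dtype=bool)]
    if np.allclose(off, off[0]):
        logger.warning("all dissimilarities equal; NMDS solution is degenerate")
        rng = np.random.default_rng(0)
        return OrdinationResult(
            configuration=rng.normal(size=(D.shape[0], dims)),
            stress=0.0,
            iterations=0,
            converged=True,
            degenerate=True,
        )
    rs = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos, stress, n_iter = smacof(
            D,
            metric=False,
            n_components=dims,
            n_init=restarts,
            max_iter=max_iter,
            random_state=np.random.RandomState(rs.integers(2**31 - 1)),
            normalized_stress=True,
            return_n_iter=True,
        )
    return OrdinationResult(
        configuration=pos,
        stress=float(stress),
        iterations=int(n_iter),
        converged=n_iter < max_iter,
    )


# -------------------------------------------------- Kruskal-Wallis/Dunn


@dataclass
class RankTestResult:
    statistic: float  # KW chi-square, tie-corrected
    df: int
    pvalue: float
    dunn: pd.DataFrame  # pairwise z, raw p, Bonferroni-adjusted p


def kruskal_dunn(values: np.ndarray, groups: np.ndarray) -> RankTestResult:
    """Kruskal–Wallis rank-sum test with Dunn's pairwise follow-up.

    Dunn's z uses mean ranks from the pooled ranking with the standard
    tie correction; pairwise p-values are two-sided normal and
    Bonferroni-adjusted over all pairs.  A globally tied input returns
    statistic 0 and p = 1 with empty z-scores.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise DesignError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise DesignError("every group must be non-empty")
    df = len(labels) - 1
    if np.all(values == values[0]):
        dunn = _dunn_frame(labels, None, None, None)
        return RankTestResult(0.0, df, 1.0, dunn)
    stat, p = stats.kruskal(*samples)
    # Dunn's test
    N = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    ns = {g: int((groups == g).sum()) for g in labels}
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (N - 1))
    pairs, zs, ps = [], [], []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt((N * (N + 1) / 12 - tie_term) * (1 / ns[a] + 1 / ns[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pairs.append((a, b))
        zs.append(z)
        ps.append(2 * stats.norm.sf(abs(z)))
    m = len(pairs)
    dunn = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "z": zs,
            "p_raw": ps,
            "p_bonferroni": np.minimum(1.0, np.array(ps) * m),
        }
    )
    return RankTestResult(float(stat), df, float(p), dunn)


def _dunn_frame(labels, zs, ps, padj) -> pd.DataFrame:
    pairs = list(itertools.combinations(labels, 2))
    return pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "z": 0.0 if zs is None else zs,
            "p_raw": 1.0 if ps is None else ps,
            "p_bonferroni": 1.0 if padj is None else padj,
        }
    )
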