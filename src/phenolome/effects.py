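"""Drought-effect statistics on the metabolite table.

Pipeline: ``log2(1e9 * x)`` transform, per-treatment factorial ANOVA
(variety x day x condition) with Bonferroni family-wise control across
metabolites, classification of each metabolite into a response
category, drought-minus-control effect profiles, clustering of time
profiles by the maximum inter-group sum-of-squares criterion with
Mahalanobis distances between clusters, and the treatment x category
contingency table with a fixed-margin permutation chi-square test.

Response categories
-------------------
``D``       drought effect similar for all variety x time variants,
``VD``      effect modified by variety,
``TD``      effect modified by time (treatment duration),
``VD_TD``   effect modified by variety and time additively,
``VTD``     effect modified by the variety x time interaction,
``NoEffect`` no significant drought-related effect.

The categories are mutually exclusive; precedence when several
families are significant is VTD > VD&TD > TD > VD > D.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .anova import balanced_factorial_anova
from .simdata import CATEGORIES

__all__ = [
    "DESIGN_COLUMNS",
    "variable_columns",
    "log_transform",
    "EffectClassification",
    "classify_effects",
    "compute_effects",
    "time_profiles",
    "ClusterResult",
    "cluster_time_profiles",
    "mahalanobis_between_clusters",
    "category_table",
    "permutation_chisq",
]

logger = logging.getLogger(__name__)

#: Columns of a metabolite table that describe the design, not variables.
DESIGN_COLUMNS = (
    "sample_id", "variety", "treatment", "condition",
    "day", "replicate", "sample_mass",
)

#: ANOVA effect family corresponding to each response category.
_FAMILY_OF = {
    "D": "condition",
    "VD": "variety:condition",
    "TD": "day:condition",
    "VTD": "variety:day:condition",
}


def variable_columns(table: pd.DataFrame) -> list[str]:
    """Metabolite variable columns = everything outside the design columns."""
    return [c for c in table.columns if c not in DESIGN_COLUMNS]


def log_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Transform every variable by ``log2(1e9 * x)``.

    Zeros are replaced by half the smallest positive value of that
    variable (with a warning) before transforming; negative values are
    an error.
    """
    out = table.copy()
    for col in variable_columns(table):
        v = out[col].to_numpy(dtype=float).copy()
        if np.any(v < 0):
            raise ValueError(f"variable {col!r} has negative values")
        zeros = v == 0
        if zeros.any():
            positive = v[v > 0]
            if positive.size == 0:
                raise ValueError(f"variable {col!r} is identically zero")
            v[zeros] = positive.min() / 2.0
            warnings.warn(
                f"variable {col!r}: {int(zeros.sum())} zero value(s) replaced "
                "by half the smallest positive value before log transform",
                stacklevel=2,
            )
        out[col] = np.log2(1e9 * v)
    return out


@dataclass
class EffectClassification:
    """Per-treatment metabolite response categories and family p-values."""

    #: DataFrame metabolites x treatments of category labels
    categories: pd.DataFrame
    #: long DataFrame (treatment, metabolite, family, p, significant)
    pvalues: pd.DataFrame
    alpha_fwer: float = 0.05


def classify_effects(
    table: pd.DataFrame,
    alpha_fwer: float = 0.05,
) -> EffectClassification:
    """Classify every metabolite's drought response per treatment.

    For each treatment the full fixed-effects factorial model
    variety * day * condition is fitted per metabolite; within each
    drought-related effect family (condition, variety:condition,
    day:condition, variety:day:condition) significance is declared at
    the Bonferroni level ``alpha_fwer / m`` across the ``m``
    metabolites, controlling the family-wise error rate within each
    family.  Day levels are treatment-specific (the combined treatment
    adds day 1).
    """
    variables = variable_columns(table)
    m = len(variables)
    if m == 0:
        raise ValueError("no metabolite variables in table")
    treatments = sorted(table["treatment"].unique().tolist())
    cat_rows = {}
    pv_rows = []
    for trt in treatments:
        sub = table[table["treatment"] == trt]
        res = balanced_factorial_anova(
            sub, ["variety", "day", "condition"], variables
        )
        sig: dict[str, np.ndarray] = {}
        for cat, family in _FAMILY_OF.items():
            p = res.p.loc[family].to_numpy()
            sig[cat] = p < alpha_fwer / m
            for met, pv, s in zip(variables, p, sig[cat]):
                pv_rows.append(
                    {
                        "treatment": trt,
                        "metabolite": met,
                        "family": family,
                        "p": pv,
                        "significant": bool(s),
                    }
                )
        cats = np.where(
            sig["VTD"],
            "VTD",
            np.where(
                sig["VD"] & sig["TD"],
                "VD_TD",
                np.where(
                    sig["TD"],
                    "TD",
                    np.where(sig["VD"], "VD", np.where(sig["D"], "D", "NoEffect")),
                ),
            ),
        )
        cat_rows[trt] = pd.Series(cats, index=variables)
    categories = pd.DataFrame(cat_rows)
    categories.index.name = "metabolite"
    return EffectClassification(
        categories=categories,
        pvalues=pd.DataFrame(pv_rows),
        alpha_fwer=alpha_fwer,
    )


def compute_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Drought-minus-control effects per experimental combination.

    Returns a long DataFrame (treatment, metabolite, variety, day,
    effect) where effect = mean(drought cell) - mean(matched control
    cell) on the scale of the input table (log2 after
    :func:`log_transform`).  Cells without a matched control get a
    missing effect and are excluded from any marginal averaging.
    """
    variables = variable_columns(table)
    means = (
        table.groupby(["treatment", "variety", "day", "condition"], sort=True)[
            variables
        ]
        .mean()
        .unstack("condition")
    )
    rows = []
    for (trt, variety, day), row in means.iterrows():
        for met in variables:
            drought = row.get((met, "drought"), np.nan)
            control = row.get((met, "control"), np.nan)
            if pd.isna(control) or pd.isna(drought):
                effect = np.nan
                if pd.isna(control) and not pd.isna(drought):
                    logger.warning(
                        "no matched control for %s / %s day %s", trt, variety, day
                    )
            else:
                effect = drought - control
            rows.append(
                {
                    "treatment": trt,
                    "metabolite": met,
                    "variety": variety,
                    "day": day,
                    "effect": effect,
                }
            )
    return pd.DataFrame(rows)


def time_profiles(
    effects: pd.DataFrame, treatment: str, metabolites: list[str] | None = None
) -> pd.DataFrame:
    """Effect time profiles averaged over varieties (metabolites x days)."""
    sub = effects[effects["treatment"] == treatment]
    if metabolites is not None:
        sub = sub[sub["metabolite"].isin(metabolites)]
    prof = sub.pivot_table(index="metabolite", columns="day", values="effect")
    return prof.sort_index(axis=1)


# ---------------------------------------------------------------------------
# clustering of time profiles


@dataclass
class ClusterResult:
    """Partition of effect time profiles maximizing between-group SS."""

    assignment: pd.Series  # metabolite -> cluster label 'A'..'D'
    means: pd.DataFrame  # cluster label x day
    between_ss: float
    within_ss: float
    total_ss: float
    profiles: pd.DataFrame = field(repr=False, default=None)
    method: str = ""


def _within_ss(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    w = 0.0
    for c in range(k):
        xc = x[labels == c]
        if xc.size:
            w += float(((xc - xc.mean(axis=0)) ** 2).sum())
    return w


def _partitions_into_k(n: int, k: int):
    """Restricted-growth strings of length n using exactly k symbols."""
    a = np.zeros(n, dtype=int)

    def rec(i: int, used: int):
        if n - i < k - used:  # cannot still reach k parts
            return
        if i == n:
            if used == k:
                yield a.copy()
            return
        for v in range(min(used + 1, k)):
            a[i] = v
            yield from rec(i + 1, max(used, v + 1))

    yield from rec(1, 1)  # first element always in part 0


def cluster_time_profiles(
    profiles: pd.DataFrame,
    k: int = 4,
    n_restarts: int = 20,
    seed: int = 0,
    exhaustive_max: int = 12,
) -> ClusterResult:
    """Cluster effect time profiles into ``k`` groups.

    The criterion is maximum between-group sum of squares, equivalently
    minimum within-group SS (time points act as separate variables).
    For up to ``exhaustive_max`` profiles every partition into ``k``
    non-empty groups is enumerated, guaranteeing the global optimum;
    above that a k-means search with ``n_restarts`` restarts and a
    fixed seed is used.  Cluster labels A..D are assigned by descending
    cluster mean at the first time point.
    """
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} profiles, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("profiles contain missing values")
    total_ss = float(((x - x.mean(axis=0)) ** 2).sum())

    if n <= exhaustive_max:
        best_w = np.inf
        best = None
        for labels in _partitions_into_k(n, k):
            w = _within_ss(x, labels, k)
            if w < best_w - 1e-12:
                best_w = w
                best = labels
        labels = best
        within = best_w
        method = "exhaustive"
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
        within = float(km.inertia_)
        method = "kmeans"

    means = np.vstack([x[labels == c].mean(axis=0) for c in range(k)])
    # deterministic labeling: descending mean at the first time point
    order = np.argsort(-means[:, 0], kind="stable")
    letter = {int(c): chr(ord("A") + rank) for rank, c in enumerate(order)}
    assignment = pd.Series(
        [letter[int(c)] for c in labels], index=profiles.index, name="cluster"
    )
    mean_df = pd.DataFrame(
        means[order], index=[chr(ord("A") + i) for i in range(k)],
        columns=profiles.columns,
    )
    return ClusterResult(
        assignment=assignment,
        means=mean_df,
        between_ss=total_ss - within,
        within_ss=within,
        total_ss=total_ss,
        profiles=profiles,
        method=method,
    )


def mahalanobis_between_clusters(
    result: ClusterResult, ridge: bool = True
) -> pd.DataFrame:
    """Pairwise Mahalanobis distances between cluster means.

    Uses the pooled within-cluster covariance; when it is singular a
    ridge of ``1e-8 * trace(S)/p`` is added to the diagonal (or an
    error raised if ``ridge`` is disabled).
    """
    x = result.profiles.to_numpy(dtype=float)
    labels = result.assignment.to_numpy()
    names = sorted(result.means.index)
    p = x.shape[1]
    n = x.shape[0]
    k = len(names)
    pooled = np.zeros((p, p))
    for c in names:
        xc = x[labels == c]
        if len(xc) > 1:
            d = xc - xc.mean(axis=0)
            pooled += d.T @ d
    denom = max(n - k, 1)
    s = pooled / denom
    if np.linalg.matrix_rank(s) < p:
        if not ridge:
            raise np.linalg.LinAlgError(
                "singular pooled within-cluster covariance (ridge disabled)"
            )
        s = s + np.eye(p) * max(1e-8 * np.trace(s) / p, 1e-300)
    sinv = np.linalg.pinv(s) if np.linalg.matrix_rank(s) < p else np.linalg.inv(s)
    dist = np.zeros((k, k))
    mu = result.means.loc[names].to_numpy()
    for i, j in combinations(range(k), 2):
        d = mu[i] - mu[j]
        dist[i, j] = dist[j, i] = float(np.sqrt(d @ sinv @ d))
    return pd.DataFrame(dist, index=names, columns=names)


# ---------------------------------------------------------------------------
# category table and permutation chi-square


def category_table(classification: EffectClassification) -> pd.DataFrame:
    """Treatments x categories contingency table of metabolite counts."""
    cats = classification.categories
    out = pd.DataFrame(
        {
            trt: [(cats[trt] == c).sum() for c in CATEGORIES]
            for trt in cats.columns
        },
        index=list(CATEGORIES),
    ).T
    out.index.name = "treatment"
    return out


def _pearson_chi2(obs: np.ndarray) -> float:
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def permutation_chisq(
    counts: pd.DataFrame | np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Chi-square test for independence using permutations.

    The Pearson chi-square statistic of the observed table is compared
    with its distribution over ``n_perm`` Monte-Carlo contingency
    tables drawn uniformly with both margins fixed (Patefield
    sampling); the p-value includes the observed table,
    ``p = (1 + #{chi2_sim >= chi2_obs}) / (1 + n_perm)``.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if obs.sum() == 0:
        raise ValueError("all-zero contingency table")
    # drop all-zero margins: they carry no information and break sampling
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    chi2_obs = _pearson_chi2(obs)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(obs.sum(axis=1), obs.sum(axis=0))
    sims = sampler.rvs(n_perm, random_state=rng)
    row = obs.sum(axis=1)[:, None]
    col = obs.sum(axis=0)[None, :]
    expected = row * col / obs.sum()
    chi2_sim = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    p = (1.0 + np.count_nonzero(chi2_sim >= chi2_obs - 1e-12)) / (1.0 + n_perm)
    return chi2_obs, float(p)
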