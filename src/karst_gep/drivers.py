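"""Driver analysis: correlations, one-way ANOVA with LSD, and random-forest
relative importance of village-level indicators.

The village table carries two dependent variables — GEP per unit area
(GEP_PUA) and the value realization rate (VRR) — and thirteen candidate
drivers spanning grassland endowment (GAR, AGR, AA, GPD, BRRG), climate
(AAP, AAT), accessibility (DC, DTA) and socioeconomics (PD, PCDIF, PMW,
PPLF).  Association strength is screened with Pearson correlations, group
contrasts with one-way ANOVA followed by Fisher's least-significant-
difference pairwise test, and relative importance is ranked with a random
forest regressor (impurity importance, normalized to sum to 1) evaluated on
a held-out split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "DEPENDENT_VARS",
    "INDEPENDENT_VARS",
    "ImportanceReport",
    "correlation_matrix",
    "anova_lsd",
    "rf_importance",
    "regression_metrics",
]

DEPENDENT_VARS = ("GEP_PUA", "VRR")
INDEPENDENT_VARS = (
    "GAR", "AGR", "AA", "AAP", "AAT", "GPD", "BRRG",
    "PD", "PCDIF", "DC", "DTA", "PMW", "PPLF",
)


def correlation_matrix(table: pd.DataFrame, two_tailed: bool = True) -> pd.DataFrame:
    """Pairwise Pearson r with p-values and significance stars.

    Returns a DataFrame indexed by (row, col) pairs in wide form with
    MultiIndex columns ``(stat,)`` in {'r', 'p', 'stars'}.  Constant columns
    are flagged with NaN entries rather than dropped.
    """
    cols = list(table.columns)
    r_mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p_mat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    constant = {c for c in cols if np.isclose(table[c].std(ddof=1), 0.0) or table[c].isna().all()}
    if constant:
        logger.warning("correlation_matrix: constant column(s) flagged: %s", sorted(constant))
    for a, b in combinations(cols, 2):
        if a in constant or b in constant:
            r, p = np.nan, np.nan
        else:
            alt = "two-sided" if two_tailed else "greater"
            r, p = stats.pearsonr(table[a], table[b], alternative=alt)
        r_mat.loc[a, b] = r_mat.loc[b, a] = r
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
    for c in constant:
        r_mat.loc[c, c] = np.nan
        p_mat.loc[c, c] = np.nan

    def star(p: float) -> str:
        if np.isnan(p):
            return ""
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    stars = p_mat.map(star)
    np.fill_diagonal(stars.values, "")
    return pd.concat({"r": r_mat, "p": p_mat, "stars": stars}, axis=1)


@dataclass
class AnovaLsdResult:
    """One-way ANOVA F/p, pairwise LSD decisions and display letters."""

    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, mean_diff, lsd, p, significant
    letters: dict[str, str]  # compact letter display, 'a' = highest mean
    alpha: float


def anova_lsd(
    values,
    group_labels,
    alpha: float = 0.05,
    one_tailed: bool = False,
) -> AnovaLsdResult:
    """One-way ANOVA followed by Fisher's LSD pairwise comparisons.

    LSD compares each pair of group means against t(α)·√(MSE·(1/na+1/nb))
    using the pooled within-group mean square.  ``one_tailed`` halves the
    reported ANOVA p (the F test itself is inherently one-sided; the flag
    governs the pairwise t-tests' sidedness).  Letters are assigned so that
    groups sharing a letter are not significantly different.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    groups = list(pd.unique(g))
    if len(groups) < 2:
        raise ValueError("anova_lsd needs at least 2 groups")
    samples = {k: y[g == k] for k in groups}
    for k, s in samples.items():
        if len(s) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")

    f_stat, p_value = stats.f_oneway(*samples.values())

    n_total = len(y)
    k_groups = len(groups)
    df_within = n_total - k_groups
    grand = {k: s.mean() for k, s in samples.items()}
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / df_within

    rows = []
    sig_pairs: set[frozenset] = set()
    for a, b in combinations(groups, 2):
        na, nb = len(samples[a]), len(samples[b])
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        diff = grand[a] - grand[b]
        if se == 0:
            t_val, p_pair = (np.inf if diff != 0 else 0.0), (0.0 if diff != 0 else 1.0)
        else:
            t_val = diff / se
            p_pair = stats.t.sf(abs(t_val), df_within) * (1 if one_tailed else 2)
        t_crit = stats.t.ppf(1 - (alpha if one_tailed else alpha / 2), df_within)
        lsd = t_crit * se
        significant = bool(abs(diff) > lsd)
        if significant:
            sig_pairs.add(frozenset((a, b)))
        rows.append(
            {"group_a": a, "group_b": b, "mean_diff": diff, "lsd": lsd,
             "p": p_pair, "significant": significant}
        )

    letters = _letter_display(groups, grand, sig_pairs)
    return AnovaLsdResult(
        f_stat=float(f_stat), p_value=float(p_value),
        pairwise=pd.DataFrame(rows), letters=letters, alpha=alpha,
    )


def _letter_display(groups, means, sig_pairs) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm."""
    order = sorted(groups, key=lambda k: -means[k])
    letter_sets: list[set] = []
    for grp in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((grp, other)) not in sig_pairs for other in s):
                s.add(grp)
                placed = True
        if not placed:
            letter_sets.append({grp})
    # absorb subsets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    out = {g: "" for g in groups}
    for s, char in zip(letter_sets, "abcdefghijklmnopqrstuvwxyz"):
        for g in s:
            out[g] += char
    return {g: "".join(sorted(out[g])) for g in groups}


@dataclass
class ImportanceReport:
    """Random-forest relative importance and held-out regression metrics."""

    target: str
    importances: dict[str, float]
    metrics: dict[str, float]
    n_trees: int
    seed: int
    split_fraction: float
    n_train: int
    n_test: int
    small_sample_warning: bool = False
    notes: tuple[str, ...] = field(default_factory=tuple)


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """R², MAE, MSE, RMSE and MAPE (as a fraction).

    Observations with zero truth are excluded from MAPE with a logged count.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size < 2:
        raise ValueError("regression_metrics needs equal-length vectors of size >= 2")
    resid = yt - yp
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    nz = yt != 0
    n_excluded = int((~nz).sum())
    if n_excluded:
        logger.warning("regression_metrics: %d zero-truth observations excluded from MAPE", n_excluded)
    mape = float(np.mean(np.abs(resid[nz] / yt[nz]))) if nz.any() else np.nan
    return {
        "r2": r2,
        "mae": float(np.mean(np.abs(resid))),
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mape": mape,
    }


def rf_importance(
    table: pd.DataFrame,
    target: str = "VRR",
    seed: int = 20230801,
    n_trees: int = 500,
    test_fraction: float = 0.3,
    features: tuple[str, ...] = INDEPENDENT_VARS,
) -> ImportanceReport:
    """Random-forest relative importance of the driver indicators.

    Fits on a train split, reports impurity importances normalized to sum
    to 1, and evaluates R²/MAE/MSE/RMSE/MAPE on the held-out split.  Fully
    deterministic given (data, seed).
    """
    missing = [c for c in (target, *features) if c not in table.columns]
    if missing:
        raise KeyError(f"driver table lacks column(s): {missing}")
    if len(table) < 8:
        raise ValueError(f"rf_importance needs n >= 8 rows, got {len(table)}")
    y = table[target].to_numpy(dtype=float)
    if np.isclose(y.std(ddof=1), 0.0):
        raise ValueError(f"degenerate target {target!r}: zero variance")
    X = table[list(features)].to_numpy(dtype=float)

    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=test_fraction, random_state=seed)
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    forest.fit(X_tr, y_tr)
    imp = forest.feature_importances_
    imp = imp / imp.sum()
    metrics = regression_metrics(y_te, forest.predict(X_te))

    notes = []
    small = len(table) < 30
    if small:
        notes.append(
            f"small sample (n={len(table)}): held-out metrics are high-variance; no cross-validation claimed"
        )
        warnings.warn(notes[-1], UserWarning, stacklevel=2)
    notes.append("metrics computed on the held-out test split, not the full data")
    return ImportanceReport(
        target=target,
        importances={f: float(v) for f, v in zip(features, imp)},
        metrics=metrics,
        n_trees=n_trees,
        seed=seed,
        split_fraction=test_fraction,
        n_train=len(y_tr),
        n_test=len(y_te),
        small_sample_warning=small,
        notes=tuple(notes),
    )
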