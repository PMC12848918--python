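"""Seasonal/stand statistics and environmental-driver screens.

Includes the dry/wet seasonal summaries, percent differences and wet:dry
ratios, a Pearson correlation screen of respiration against environmental
factors, one-way ANOVA with unadjusted LSD pairwise tests rendered as a
compact letter display, and a permutation-based variable-importance ranking
backed by a random forest.

Method notes (package choices where the procedure is conventionally left
unstated): LSD uses the pooled ANOVA MSE with no multiple-testing
correction, which is anti-conservative by construction.  Importance
significance uses a response-permutation null with the max-across-features
statistic, controlling the family-wise error rate of the screen.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from fluxseason.data import assign_season
from fluxseason.models import significance_stars

ENV_FACTORS = ("ph", "som", "soc", "tn", "tp", "an", "ap", "prcp", "temp", "rh")


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with LSD letters for one variable."""

    variable: str
    f_stat: float
    p_value: float
    alpha: float
    means: dict  # group -> mean
    sds: dict  # group -> sd
    ns: dict  # group -> n
    letters: dict  # group -> compact letter display


def seasonal_summary(records: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Mean/sd/n of one measurement variable per stand and season."""
    if variable not in records.columns:
        raise ValueError(f"unknown variable: {variable!r}")
    season = pd.to_datetime(records["date"]).map(assign_season).rename("season")
    grouped = records.groupby([records["stand_id"], season])[variable]
    return grouped.agg(mean="mean", sd="std", n="count").reset_index()


def percent_difference(reference: float, other: float) -> float:
    """100 * (other / reference - 1); the reference must be positive."""
    if reference <= 0:
        raise ValueError("reference mean must be > 0")
    return 100.0 * (other / reference - 1.0)


def wet_dry_ratio(records: pd.DataFrame, variable: str) -> pd.Series:
    """Wet-season mean divided by dry-season mean, per stand."""
    summary = seasonal_summary(records, variable)
    wide = summary.pivot(index="stand_id", columns="season", values="mean")
    for season in ("dry", "wet"):
        if season not in wide.columns or wide[season].isna().any():
            missing = (
                list(wide.index)
                if season not in wide.columns
                else list(wide.index[wide[season].isna()])
            )
            raise ValueError(f"missing {season}-season data for stand(s) {missing}")
    if (wide["dry"] <= 0).any():
        raise ValueError("dry-season mean must be > 0")
    return (wide["wet"] / wide["dry"]).rename("wet_dry_ratio")


def season_table(
    measurements: pd.DataFrame,
    chemistry: pd.DataFrame,
    climate: pd.DataFrame,
) -> pd.DataFrame:
    """Stand x season rows of mean respiration plus environmental factors.

    Respiration and climate are averaged within each stand-season (precip as
    a mean monthly total); chemistry joins as-is.  This is the default
    granularity of the correlation screen.
    """
    rs = seasonal_summary(measurements, "rs")[["stand_id", "season", "mean"]]
    rs = rs.rename(columns={"mean": "rs"})
    clim = climate.copy()
    clim["season"] = pd.to_datetime(clim["date"]).map(assign_season)
    clim["month"] = pd.to_datetime(clim["date"]).dt.strftime("%Y-%m")
    monthly_precip = (
        clim.groupby(["stand_id", "season", "month"])["precip"].sum().reset_index()
    )
    agg = pd.merge(
        clim.groupby(["stand_id", "season"])[["air_temp", "rh"]].mean().reset_index(),
        monthly_precip.groupby(["stand_id", "season"])["precip"].mean().reset_index(),
        on=["stand_id", "season"],
    ).rename(columns={"air_temp": "temp", "precip": "prcp"})
    out = rs.merge(chemistry, on=["stand_id", "season"]).merge(agg, on=["stand_id", "season"])
    return out[["stand_id", "season", "rs", *ENV_FACTORS]]


def pearson_screen(
    table: pd.DataFrame,
    response: str = "rs",
    factors=None,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of the response against each factor.

    Returns columns ``variable, r, p_value, n, star``; a constant column is
    reported with NaN r rather than failing the whole screen.
    """
    factors = list(factors) if factors is not None else [c for c in ENV_FACTORS if c in table.columns]
    y = table[response].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 rows")
    rows = []
    for var in factors:
        x = table[var].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"variable": var, "r": np.nan, "p_value": np.nan, "n": len(y), "star": ""})
            continue
        res = stats.pearsonr(x, y)
        rows.append(
            {
                "variable": var,
                "r": float(res.statistic),
                "p_value": float(res.pvalue),
                "n": len(y),
                "star": significance_stars(float(res.pvalue)),
            }
        )
    return pd.DataFrame(rows)


def _lsd_pairwise_p(values_by_group: dict, mse: float, df_resid: int) -> dict:
    """Unadjusted pairwise t-test p-values using the pooled ANOVA MSE."""
    out = {}
    for g1, g2 in itertools.combinations(sorted(values_by_group), 2):
        v1, v2 = values_by_group[g1], values_by_group[g2]
        se = np.sqrt(mse * (1.0 / len(v1) + 1.0 / len(v2)))
        t = (np.mean(v1) - np.mean(v2)) / se if se > 0 else 0.0
        out[(g1, g2)] = 2.0 * float(stats.t.sf(abs(t), df_resid)) if se > 0 else 1.0
    return out


def _compact_letters(groups_by_mean: list, significant: set) -> dict:
    """Insert-and-absorb compact letter display.

    Start from one column holding every group; split each column on every
    significant pair it contains; absorb columns that are subsets of others.
    Groups share a letter iff their difference is not significant.
    """
    columns = [set(groups_by_mean)]
    for pair in sorted(significant):
        g1, g2 = pair
        next_cols = []
        for col in columns:
            if g1 in col and g2 in col:
                next_cols.append(col - {g1})
                next_cols.append(col - {g2})
            else:
                next_cols.append(col)
        # absorb subsets
        columns = []
        for col in sorted(next_cols, key=len, reverse=True):
            if col and not any(col <= kept for kept in columns):
                columns.append(col)
    # order columns by the best (highest-mean) group they contain
    order = {g: i for i, g in enumerate(groups_by_mean)}
    columns.sort(key=lambda col: min(order[g] for g in col))
    letters = {g: "" for g in groups_by_mean}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def anova_lsd_letters(values, groups, alpha: float = 0.05, variable: str = "") -> GroupComparison:
    """One-way ANOVA followed by LSD pairwise tests and letter display.

    Every group needs n >= 2.  Letters satisfy: two groups share a letter
    iff their LSD pairwise test is not significant at ``alpha``.
    """
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    by_group = {g: sub["value"].to_numpy() for g, sub in frame.groupby("group")}
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    k = len(by_group)
    n_total = len(frame)
    grand = frame["value"].mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w if df_w > 0 else 0.0
    if mse == 0:
        f_stat, p_value = (np.inf, 0.0) if ss_between > 0 else (0.0, 1.0)
    else:
        f_stat = (ss_between / df_b) / mse
        p_value = float(stats.f.sf(f_stat, df_b, df_w))
    pairwise = _lsd_pairwise_p(by_group, mse, df_w)
    significant = {pair for pair, p in pairwise.items() if p < alpha}
    ranked = sorted(by_group, key=lambda g: -by_group[g].mean())
    letters = _compact_letters(ranked, significant)
    return GroupComparison(
        variable=variable,
        f_stat=float(f_stat),
        p_value=float(p_value),
        alpha=alpha,
        means={g: float(v.mean()) for g, v in by_group.items()},
        sds={g: float(v.std(ddof=1)) for g, v in by_group.items()},
        ns={g: int(len(v)) for g, v in by_group.items()},
        letters=letters,
    )


def _oob_permutation_importance(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, rng
) -> np.ndarray:
    """Mean increase in out-of-bag squared error when each feature is permuted."""
    n, p = X.shape
    increases = np.zeros(p)
    counts = np.zeros(p)
    for tree, sample_idx in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sample_idx)
        if len(oob) < 2:
            continue
        x_oob = X[oob]
        m = len(oob)
        # stack [base, perm_1, ..., perm_p] into one predict call per tree
        stacked = np.tile(x_oob, (p + 1, 1))
        for j in range(p):
            block = slice((j + 1) * m, (j + 2) * m)
            stacked[block, j] = rng.permutation(x_oob[:, j])
        pred = tree.predict(stacked).reshape(p + 1, m)
        errs = np.mean((y[oob][None, :] - pred) ** 2, axis=1)
        increases += errs[1:] - errs[0]
        counts += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, increases / np.maximum(counts, 1), 0.0)


def rank_variable_importance(
    features: pd.DataFrame,
    response,
    n_trees: int = 500,
    n_permutations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation variable importance of environmental drivers.

    Fits a random forest and scores each feature by the mean increase in
    out-of-bag squared error when that feature is permuted.  Significance
    (when ``n_permutations > 0``) comes from refitting on permuted responses
    and comparing each observed importance against the null distribution of
    the maximum importance across features (family-wise control).  Columns
    are canonicalized to sorted order internally, so the ranking is
    invariant to the caller's column order.
    """
    if len(features) < 8:
        raise ValueError("need at least 8 rows")
    cols = sorted(features.columns)
    X = features[cols].to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    ss = np.random.SeedSequence(seed)
    fit_seed, perm_seed, null_seed = (s.generate_state(1)[0] for s in ss.spawn(3))

    def importances(y_vec, forest_seed, perm_rng):
        forest = RandomForestRegressor(
            n_estimators=n_trees, random_state=int(forest_seed), n_jobs=1
        )
        forest.fit(X, y_vec)
        return _oob_permutation_importance(forest, X, y_vec, perm_rng)

    obs = importances(y, fit_seed, np.random.default_rng(perm_seed))
    if n_permutations > 0:
        null_rng = np.random.default_rng(null_seed)
        null_max = np.empty(n_permutations)
        for i in range(n_permutations):
            y_perm = null_rng.permutation(y)
            imp = importances(y_perm, null_rng.integers(2**31), null_rng)
            null_max[i] = imp.max()
        p_values = (1.0 + np.array([(null_max >= v).sum() for v in obs])) / (n_permutations + 1.0)
    else:
        p_values = np.full(len(cols), np.nan)

    out = pd.DataFrame({"variable": cols, "importance": obs, "p_value": p_values})
    out = out.sort_values(["importance", "variable"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out["star"] = [
        significance_stars(p) if np.isfinite(p) else "" for p in out["p_value"]
    ]
    return out.reset_index(drop=True)[["variable", "importance", "rank", "p_value", "star"]]
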