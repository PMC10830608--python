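"""Statistical layer: variance decomposition and mating-failure GLM.

The factorial simulation output is analysed with ordinary linear models
containing the three main effects (habitat quality, fecundity, mating
system — all coded categorical) and their two-way interactions.  Each term's
importance is summarised with the LMG relative-importance measure: the
increment in R-squared contributed by the term, averaged over every order in
which the terms could enter the model.  For a term group g among p groups,

    LMG(g) = sum over subsets S not containing g of
             |S|! (p - |S| - 1)! / p!  *  (R2(S + g) - R2(S)),

computed here by direct subset enumeration (p = 6 groups -> 64 subsets).
Shares are non-negative and sum to the full-model R-squared.

Mating failure is modelled with a binomial GLM (logit link) on patch-level
proportions of unmated females, with a mating-system x patch-population-size
interaction and fecundity as a control main effect, weighted by the number
of females per patch through the successes/failures response form.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LinearFit",
    "GlmFit",
    "lmg_shares",
    "fit_lm_with_lmg",
    "fit_unmated_glm",
    "summarize_experiment1",
    "spread_rate_inclusion",
    "spread_window_table",
]


@dataclass
class LinearFit:
    response: str
    terms: list
    r_squared: float
    lmg: pd.Series  # share of variance per term, 0..100 scale
    anova: pd.DataFrame  # df, sum_sq, mean_sq, variance_explained_pct
    coefficients: pd.Series | None = None


@dataclass
class GlmFit:
    params: pd.Series
    bse: pd.Series
    summary: pd.DataFrame
    separation_warning: bool = False


def _dummy_block(series: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped) for one factor."""
    d = pd.get_dummies(series.astype("category"), drop_first=True, dtype=float)
    return d.to_numpy()


def _term_blocks(df: pd.DataFrame, factors) -> dict:
    """Column blocks for main effects and all two-way interactions."""
    mains = {f: _dummy_block(df[f]) for f in factors}
    blocks: dict = dict(mains)
    for a, b in itertools.combinations(factors, 2):
        A, B = mains[a], mains[b]
        inter = np.einsum("ni,nj->nij", A, B).reshape(len(df), -1)
        blocks[f"{a}:{b}"] = inter
    return blocks


def _r2(y: np.ndarray, X_parts) -> float:
    """R-squared of OLS of y on [1, X_parts...]; robust to rank deficiency."""
    n = y.size
    cols = [np.ones((n, 1))] + list(X_parts)
    X = np.hstack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss <= 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / tss)


def lmg_shares(y: np.ndarray, blocks: dict, respect_marginality: bool = True) -> pd.Series:
    """Average-over-orderings R-squared decomposition by enumeration.

    ``blocks`` maps term name -> design-matrix block (each factor's dummy
    columns, or an interaction's product columns, enter as one group).  An
    interaction term named ``"a:b"`` depends on main effects ``a`` and ``b``.

    With ``respect_marginality`` (the convention for models containing
    interactions) only orderings in which every interaction enters after
    both of its main effects are averaged; an interaction's share is then
    always an increment conditional on its mains, so main effects are never
    credited to interaction blocks.  Without it, all p! orderings count
    (the classic all-subsets weighting), which is equivalent when the model
    has no interaction terms.
    """
    names = list(blocks)
    p = len(names)
    y = np.asarray(y, dtype=float)
    requires = {
        i: frozenset(names.index(dep) for dep in name.split(":") if dep in names)
        if ":" in name
        else frozenset()
        for i, name in enumerate(names)
    }
    # cache R2 by subset bitmask, lazily
    r2_cache: dict[int, float] = {0: 0.0}

    def r2_of(mask: int) -> float:
        if mask not in r2_cache:
            parts = [blocks[names[i]] for i in range(p) if mask >> i & 1]
            r2_cache[mask] = _r2(y, parts)
        return r2_cache[mask]

    shares = np.zeros(p)
    if respect_marginality and any(requires.values()):
        n_valid = 0
        for perm in itertools.permutations(range(p)):
            seen = 0
            ok = True
            for i in perm:
                if any(not (seen >> d & 1) for d in requires[i]):
                    ok = False
                    break
                seen |= 1 << i
            if not ok:
                continue
            n_valid += 1
            mask = 0
            for i in perm:
                nxt = mask | (1 << i)
                shares[i] += r2_of(nxt) - r2_of(mask)
                mask = nxt
        shares /= n_valid
    else:
        fact = [float(math.factorial(k)) for k in range(p + 1)]
        for g in range(p):
            for mask in range(1 << p):
                if mask >> g & 1:
                    continue
                k = bin(mask).count("1")
                wgt = fact[k] * fact[p - k - 1] / fact[p]
                shares[g] += wgt * (r2_of(mask | (1 << g)) - r2_of(mask))
    return pd.Series(shares, index=names)


def _sequential_anova(y: np.ndarray, blocks: dict) -> pd.DataFrame:
    """Type-I (sequential) sums of squares in the given term order."""
    tss = float(((y - y.mean()) ** 2).sum())
    rows = []
    parts = []
    prev_r2 = 0.0
    prev_rank = 1
    for name, block in blocks.items():
        parts.append(block)
        r2 = _r2(y, parts)
        X = np.hstack([np.ones((y.size, 1))] + parts)
        rank = np.linalg.matrix_rank(X)
        df = rank - prev_rank
        ss = (r2 - prev_r2) * tss
        rows.append({"term": name, "df": df, "sum_sq": ss})
        prev_r2, prev_rank = r2, rank
    out = pd.DataFrame(rows).set_index("term")
    out["mean_sq"] = out["sum_sq"] / out["df"].replace(0, np.nan)
    return out


def fit_lm_with_lmg(
    table: pd.DataFrame,
    response: str,
    factors=("habitat_quality", "fecundity", "mating_system"),
) -> LinearFit:
    """OLS with categorical mains + two-way interactions and LMG shares.

    Raises if any factor is constant (rank-deficient design) and names it.
    """
    df = table.dropna(subset=[response]).reset_index(drop=True)
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(
                f"factor {f!r} has a single level in this table; "
                "the design is rank deficient"
            )
    y = df[response].to_numpy(dtype=float)
    blocks = _term_blocks(df, factors)
    shares = lmg_shares(y, blocks) * 100.0
    anova = _sequential_anova(y, blocks)
    full_r2 = _r2(y, list(blocks.values()))
    anova["variance_explained_pct"] = shares.reindex(anova.index)
    return LinearFit(
        response=response,
        terms=list(blocks),
        r_squared=full_r2,
        lmg=shares,
        anova=anova,
    )


def fit_unmated_glm(patch_table: pd.DataFrame) -> GlmFit:
    """Binomial GLM of unmated proportion per patch (two-sex runs only).

    Expects columns ``n_unmated_f``, ``n_adult_f`` (> 0), ``n_adult_m``,
    ``mating_system`` and ``fecundity``.  Patch population size is the adult
    count (both sexes), entered untransformed; mating system interacts with
    it and fecundity enters as a categorical control.
    """
    df = patch_table.copy()
    df = df[df["n_adult_f"] > 0].reset_index(drop=True)
    if (df["mating_system"] == "female_only").any():
        raise ValueError("female-only runs have no mating failure; exclude them")
    df["patch_size"] = (df["n_adult_f"] + df["n_adult_m"]).astype(float)
    endog = df[["n_unmated_f"]].copy()
    endog["n_mated"] = df["n_adult_f"] - df["n_unmated_f"]
    exog = pd.get_dummies(
        df[["mating_system", "fecundity"]].astype({"fecundity": "category"}),
        drop_first=True,
        dtype=float,
    )
    ms_cols = [c for c in exog.columns if c.startswith("mating_system")]
    exog["patch_size"] = df["patch_size"]
    for c in ms_cols:
        exog[f"{c}:patch_size"] = exog[c] * df["patch_size"]
    exog = sm.add_constant(exog)
    model = sm.GLM(endog.to_numpy(), exog, family=sm.families.Binomial())
    separation = False
    try:
        res = model.fit()
        mu = res.fittedvalues
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
            separation = True
    except Exception:
        res = model.fit_regularized(alpha=1e-8)
        separation = True
    params = pd.Series(np.asarray(res.params), index=exog.columns)
    bse = (
        pd.Series(np.asarray(res.bse), index=exog.columns)
        if hasattr(res, "bse")
        else pd.Series(np.nan, index=exog.columns)
    )
    summary = pd.DataFrame(
        {"estimate": params, "se": bse, "z": params / bse.replace(0, np.nan)}
    )
    return GlmFit(params=params, bse=bse, summary=summary, separation_warning=separation)


def spread_window_table(table: pd.DataFrame) -> pd.DataFrame:
    """Explode per-run ``window_rates`` into one row per five-year window."""
    df = table.dropna(subset=["spread_rate"]).copy()
    df["window_rate"] = df["window_rates"].astype(str).str.split(";")
    df = df.explode("window_rate")
    df = df[df["window_rate"].astype(str).str.len() > 0]
    df["window_rate"] = df["window_rate"].astype(float)
    return df.reset_index(drop=True)


def spread_rate_inclusion(table: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for spread-rate analysis.

    Spread is analysed only where it occurred for every mating system:
    habitat quality 1/b > 6 and fecundity > 2.0, restricted to runs that
    maintain quasi-equilibrium occupancy (extinct runs carry no spread rate).
    """
    sel = (
        (table["habitat_quality"] > 6)
        & (table["fecundity"] > 2.0)
        & table["quasi_equilibrium"]
        & table["spread_rate"].notna()
    )
    return table[sel]


def summarize_experiment1(table: pd.DataFrame) -> dict:
    """Headline summary of the mating-system experiment.

    Returns mean spread per mating system, spread relative to the
    female-only baseline (in %), absolute lags (rows/generation), extinction
    proportions, and — when the table supports it — the LMG tables for core
    occupancy and spread rate.
    """
    out: dict = {}
    spread_tbl = spread_rate_inclusion(table)
    means = spread_tbl.groupby("mating_system")["spread_rate"].mean()
    out["mean_spread"] = means
    if "female_only" in means.index:
        base = means["female_only"]
        out["relative_spread_pct"] = means / base * 100.0
        out["lag_rows_per_gen"] = base - means
    out["extinction_prop"] = table.groupby("mating_system")["extinct"].mean()
    try:
        out["lmg_occupancy"] = fit_lm_with_lmg(table, "core_occupancy")
    except ValueError:
        out["lmg_occupancy"] = None
    try:
        # per-window rates are the unit of analysis for the spread model:
        # the within-run window-to-window variability belongs in the
        # residual, not in the mating-system share
        out["lmg_spread"] = fit_lm_with_lmg(
            spread_window_table(spread_tbl), "window_rate"
        )
    except (KeyError, ValueError):
        try:
            out["lmg_spread"] = fit_lm_with_lmg(spread_tbl, "spread_rate")
        except ValueError:
            out["lmg_spread"] = None
    return out
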