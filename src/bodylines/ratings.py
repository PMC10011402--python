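"""Rating-table analysis: composites, consistency, split-plot ANOVA, post-hocs.

Operates on long-format rating tables with columns ``participant``,
``gender``, ``stimulus``, ``context``, ``direction``, ``rating`` (extra
columns are ignored).  The analysis chain is the one used for
attractiveness-rating studies of this kind:

1. a composite beauty score per participant x stimulus (mean of the
   short-term and long-term context ratings), with an exclusion report for
   incomplete cells;
2. per-stimulus Spearman rank correlation between the two contexts, as a
   consistency check justifying the composite;
3. a split-plot (mixed) ANOVA with one within-participant factor (stimulus)
   and one or two between-participant factors (rater gender, presentation
   direction), reporting F, Greenhouse-Geisser-corrected degrees of freedom
   and p for within effects, and generalized eta squared (GES) for every
   effect;
4. Bonferroni-adjusted paired t tests between all stimulus pairs, pooled
   across the between groups.

Generalized eta squared follows the standard definition for mixed designs
with manipulated factors only: ``SS_effect / (SS_effect + sum of all error
SS)``, where the error strata are the between-participants error (subjects
within groups) and the within error (stimulus x subjects within groups).
The Greenhouse-Geisser epsilon is estimated from the pooled within-group
covariance of the stimulus scores and applied to both numerator and
denominator dfs of every within effect; both corrected and uncorrected dfs
are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "composite_beauty",
    "spearman_by_stimulus",
    "mixed_anova",
    "bonferroni_posthoc",
    "AnovaReport",
    "validate_ratings",
]

REQUIRED_COLUMNS = ("participant", "gender", "stimulus", "context", "rating")


def validate_ratings(records: pd.DataFrame, scale: tuple[float, float] | None = None) -> None:
    """Check a long rating table for structural validity.

    Verifies required columns, uniqueness of (participant, stimulus, context)
    and, if an instrument scale is given, that ratings stay within bounds.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"rating table is missing columns: {missing}")
    dup = records.duplicated(subset=["participant", "stimulus", "context"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (participant, stimulus, context) rows"
        )
    if scale is not None:
        lo, hi = scale
        bad = (records["rating"] < lo) | (records["rating"] > hi)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} ratings outside the instrument scale {scale}"
            )


# ---------------------------------------------------------------------------
# composites and consistency
# ---------------------------------------------------------------------------


def composite_beauty(
    records: pd.DataFrame,
    contexts: tuple[str, str] = ("short_term", "long_term"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composite beauty score: mean of the two context ratings per cell.

    Returns ``(composite, exclusions)``.  ``composite`` is long-format with a
    ``beauty`` column; participant x stimulus cells missing either context
    are dropped and listed in ``exclusions``.
    """
    validate_ratings(records)
    sub = records[records["context"].isin(contexts)]
    wide = sub.pivot_table(
        index=["participant", "stimulus"], columns="context", values="rating",
        aggfunc="first",
    )
    for c in contexts:
        if c not in wide.columns:
            wide[c] = np.nan
    complete = wide[list(contexts)].notna().all(axis=1)
    exclusions = wide[~complete].reset_index()[["participant", "stimulus"]]
    good = wide[complete]
    composite = good[list(contexts)].mean(axis=1).rename("beauty").reset_index()
    meta_cols = [c for c in ("gender", "direction") if c in records.columns]
    if meta_cols:
        meta = records.drop_duplicates("participant").set_index("participant")[meta_cols]
        composite = composite.join(meta, on="participant")
    return composite, exclusions


def spearman_by_stimulus(
    records: pd.DataFrame,
    contexts: tuple[str, str] = ("short_term", "long_term"),
) -> pd.DataFrame:
    """Spearman rank correlation between the two contexts, per stimulus.

    Average ranks for ties; p-value from the t approximation (scipy).
    """
    validate_ratings(records)
    rows = []
    for stim, grp in records.groupby("stimulus", sort=True):
        wide = grp.pivot_table(
            index="participant", columns="context", values="rating", aggfunc="first"
        )
        if not all(c in wide.columns for c in contexts):
            raise ValueError(f"stimulus {stim!r} lacks one of the contexts {contexts}")
        wide = wide.dropna(subset=list(contexts))
        if len(wide) < 3:
            raise ValueError(
                f"stimulus {stim!r} has only {len(wide)} complete pairs (< 3)"
            )
        rho, p = stats.spearmanr(wide[contexts[0]], wide[contexts[1]])
        rows.append({"stimulus": stim, "rho": float(rho), "p": float(p),
                     "n": len(wide)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split-plot ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaReport:
    """Effect table of a split-plot ANOVA plus bookkeeping.

    ``table`` has one row per effect with columns ``effect, ss, df1, df2,
    df1_corr, df2_corr, F, p, ges, epsilon, stratum``.  Within effects carry
    Greenhouse-Geisser-corrected dfs and p; between effects are uncorrected
    (epsilon = NaN).
    """

    table: pd.DataFrame
    error_ss: dict = field(default_factory=dict)
    dropped_participants: tuple = ()
    epsilon: float = 1.0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "effects": self.table.to_dict(orient="records"),
            "error_ss": self.error_ss,
            "dropped_participants": list(self.dropped_participants),
            "greenhouse_geisser_epsilon": self.epsilon,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __str__(self) -> str:  # human-readable table
        with pd.option_context("display.width", 120):
            return self.table.to_string(index=False)


def _gg_epsilon(wide: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    k = wide.shape[1]
    if k < 2:
        return 1.0
    resid = np.empty_like(wide, dtype=float)
    g_count = 0
    for g in np.unique(groups):
        m = groups == g
        resid[m] = wide[m] - wide[m].mean(axis=0)
        g_count += 1
    denom = len(wide) - g_count
    if denom <= 0:
        return 1.0
    S = resid.T @ resid / denom
    # double-center
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    tr = np.trace(Sc)
    ss = float(np.sum(Sc**2))
    if ss <= 0 or tr <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * ss)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _effect_ss(y: np.ndarray, factors: dict[str, np.ndarray], terms) -> dict:
    """Sums of squares by sequential orthogonal projection (balanced designs)
    or Type-III-style partialling for mildly unbalanced between groups.

    Each term is a tuple of factor names; its design columns are the
    products of sum-to-zero (deviation) contrast codes.  SS of a term is the
    reduction in residual SS when the term's columns are added to the model
    containing all other terms (Type III with deviation coding).
    """
    cols: dict[tuple, np.ndarray] = {}
    for term in terms:
        mats = None
        for name in term:
            codes = factors[name]
            levels = np.unique(codes)
            # deviation coding: L-1 columns
            c = np.zeros((len(codes), len(levels) - 1))
            for j, lev in enumerate(levels[:-1]):
                c[codes == lev, j] = 1.0
                c[codes == levels[-1], j] = -1.0
            if mats is None:
                mats = c
            else:
                mats = np.concatenate(
                    [mats[:, i : i + 1] * c for i in range(mats.shape[1])], axis=1
                )
        cols[term] = mats
    intercept = np.ones((len(y), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full_X = np.hstack([intercept] + [cols[t] for t in terms])
    rss_full = rss(full_X)
    out = {}
    for term in terms:
        X_red = np.hstack(
            [intercept] + [cols[t] for t in terms if t != term]
        )
        out[term] = max(rss(X_red) - rss_full, 0.0)
    out["_rss_full"] = rss_full
    return out


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "beauty",
    within: str = "stimulus",
    between: str | list[str] = "gender",
    subject: str = "participant",
) -> AnovaReport:
    """Split-plot ANOVA: one within factor, one or two between factors.

    Participants are nested in the cells of the (crossed) between factors and
    each must provide every within level; incomplete participants are dropped
    and reported.  Within effects use the Greenhouse-Geisser correction;
    every effect gets a generalized eta squared.
    """
    between_list = [between] if isinstance(between, str) else list(between)
    if not 1 <= len(between_list) <= 2:
        raise ValueError("mixed_anova supports one or two between factors")
    needed = [subject, within, dv] + between_list
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")

    levels = np.sort(table[within].unique())
    k = len(levels)
    wide = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="first")
    complete = wide.notna().all(axis=1)
    dropped = tuple(wide.index[~complete])
    wide = wide[complete]
    n_subj = len(wide)
    if n_subj < 2:
        raise ValueError("fewer than 2 complete participants")

    meta = (
        table.drop_duplicates(subject).set_index(subject).loc[wide.index, between_list]
    )
    cell = meta[between_list].astype(str).agg("|".join, axis=1).to_numpy()
    cell_sizes = pd.Series(cell).value_counts()
    if (cell_sizes < 2).any():
        small = cell_sizes[cell_sizes < 2].index.tolist()
        raise ValueError(f"between cells with < 2 participants: {small}")

    Y = wide.to_numpy(dtype=float)  # subjects x within levels
    grand = Y.mean()
    ss_total = float(np.sum((Y - grand) ** 2))

    # ---- between stratum: one value (subject mean) per participant --------
    m = Y.mean(axis=1)
    bfac = {
        name: pd.factorize(meta[name].to_numpy(), sort=True)[0]
        for name in between_list
    }
    if len(between_list) == 1:
        b_terms = [(between_list[0],)]
    else:
        a, b = between_list
        b_terms = [(a,), (b,), (a, b)]
    b_ss = _effect_ss(m - m.mean(), bfac, b_terms)
    n_groups = len(np.unique(cell))
    ss_err_between = k * b_ss["_rss_full"]
    df_err_between = n_subj - n_groups

    # ---- within stratum: subject-centred scores ---------------------------
    Z = Y - m[:, None]
    z = Z.ravel()
    wcodes = np.tile(np.arange(k), n_subj)
    wfac = {within: wcodes}
    for name in between_list:
        wfac[name] = np.repeat(bfac[name], k)
    w_terms = [(within,)] + [(within,) + t for t in b_terms]
    w_ss = _effect_ss(z, wfac, w_terms)
    ss_err_within = w_ss["_rss_full"]
    df_err_within = (n_subj - n_groups) * (k - 1)

    eps = _gg_epsilon(Y, cell)
    ss_all_errors = ss_err_between + ss_err_within

    def effect_row(name, ss, df1, df2, ms_err, stratum, epsilon):
        if ss <= 1e-12 * max(ss_total, 1.0):
            f_val, p = 0.0, 1.0
        elif ms_err <= 0:
            f_val, p = np.inf, 0.0
        else:
            f_val = (ss / df1) / ms_err
            d1 = df1 * (epsilon if stratum == "within" else 1.0)
            d2 = df2 * (epsilon if stratum == "within" else 1.0)
            p = float(stats.f.sf(f_val, d1, d2))
        ges = ss / (ss + ss_all_errors) if (ss + ss_all_errors) > 0 else 0.0
        e = epsilon if stratum == "within" else np.nan
        return {
            "effect": name,
            "ss": ss,
            "df1": df1,
            "df2": df2,
            "df1_corr": df1 * epsilon if stratum == "within" else df1,
            "df2_corr": df2 * epsilon if stratum == "within" else df2,
            "F": f_val,
            "p": p,
            "ges": ges,
            "epsilon": e,
            "stratum": stratum,
        }

    rows = []
    ms_err_b = ss_err_between / df_err_between if df_err_between > 0 else 0.0
    lvl_counts = {name: len(np.unique(bfac[name])) for name in between_list}
    for term in b_terms:
        df1 = int(np.prod([lvl_counts[nm] - 1 for nm in term]))
        rows.append(
            effect_row(
                " x ".join(term), k * b_ss[term], df1, df_err_between, ms_err_b,
                "between", eps,
            )
        )
    ms_err_w = ss_err_within / df_err_within if df_err_within > 0 else 0.0
    for term in w_terms:
        extra = [nm for nm in term if nm != within]
        df1 = (k - 1) * int(np.prod([lvl_counts[nm] - 1 for nm in extra] or [1]))
        rows.append(
            effect_row(
                " x ".join(term), w_ss[term], df1, df_err_within, ms_err_w,
                "within", eps,
            )
        )
    report = pd.DataFrame(rows)
    return AnovaReport(
        table=report,
        error_ss={
            "between_error": ss_err_between,
            "within_error": ss_err_within,
            "total": ss_total,
        },
        dropped_participants=dropped,
        epsilon=eps,
    )


# ---------------------------------------------------------------------------
# post-hoc contrasts
# ---------------------------------------------------------------------------


def bonferroni_posthoc(
    table: pd.DataFrame,
    dv: str = "beauty",
    within: str = "stimulus",
    subject: str = "participant",
) -> pd.DataFrame:
    """Bonferroni-adjusted paired t tests between all within-level pairs.

    Pairs are pooled across any between-participant grouping (the design
    collapses over between factors once no interaction is present).  The
    adjusted p is ``min(1, p * C(k, 2))`` and df is ``n_participants - 1``.
    """
    wide = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="first")
    wide = wide.dropna()
    levels = list(wide.columns)
    if len(levels) < 2:
        raise ValueError("need at least 2 within levels for post-hoc contrasts")
    n = len(wide)
    m = len(levels) * (len(levels) - 1) // 2
    rows = []
    for a, b in combinations(levels, 2):
        d = wide[a].to_numpy() - wide[b].to_numpy()
        if np.allclose(d, 0.0):
            t_val, p = 0.0, 1.0
        else:
            t_val, p = stats.ttest_rel(wide[a], wide[b])
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": float(t_val),
                "df": n - 1,
                "p": float(p),
                "p_adj": float(min(1.0, p * m)),
                "mean_diff": float(np.mean(d)),
            }
        )
    return pd.DataFrame(rows)
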